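"""Published reference benchmark results for the six-class lesion problem.

These rows are the reported evaluations of four ImageNet-pretrained
backbones (MobileNetV2, EfficientNet-B0, ResNet-18, ResNet-50) on the
combined PAD-UFES-20 + HAM10000 dataset, for the flat six-class task and
for every binary task of the hierarchy.  Reproducing them requires the
public datasets and GPU-scale fine-tuning, which is out of scope here;
they ship as worked-example inputs for the metric formulas, the
recall-first selection rule and the structure comparison machinery.

All values are percentages, printed at two decimals.  Column order:
accuracy, precision, recall, f1, specificity, balanced_accuracy, g_mean.
"""

from __future__ import annotations

from .hierarchy import CandidateResult
from .metrics import MetricReport

METRIC_COLUMNS = (
    "accuracy",
    "precision",
    "recall",
    "f1",
    "specificity",
    "balanced_accuracy",
    "g_mean",
)


def _rows(table: dict) -> dict:
    return {
        model: dict(zip(METRIC_COLUMNS, values)) for model, values in table.items()
    }


#: Flat six-class baseline (macro-averaged).
FLAT_SIX_CLASS = _rows(
    {
        "mobilenetv2": (60.29, 68.50, 60.27, 62.63, 93.64, 76.95, 75.12),
        "efficientnet_b0": (59.01, 67.29, 58.91, 60.86, 93.42, 76.16, 74.18),
        "resnet18": (46.96, 54.45, 46.05, 48.50, 90.83, 68.44, 64.67),
        "resnet50": (47.42, 56.87, 47.42, 49.29, 91.36, 69.39, 65.82),
    }
)

#: Root task: Benign (positive) vs Malignant.
BENIGN_VS_MALIGNANT = _rows(
    {
        "mobilenetv2": (84.30, 92.70, 87.22, 89.88, 85.43, 86.32, 86.32),
        "efficientnet_b0": (74.42, 81.21, 81.65, 81.43, 66.98, 74.32, 73.96),
        "resnet18": (68.43, 74.22, 79.34, 76.69, 58.96, 69.15, 68.39),
        "resnet50": (69.96, 74.46, 77.84, 76.11, 57.93, 67.88, 67.15),
    }
)

#: One-vs-rest tasks inside the Benign group, keyed by peeled class.
BENIGN_PEELS = {
    "ACK": _rows(
        {
            "mobilenetv2": (99.87, 100.00, 97.99, 98.98, 100.00, 98.99, 98.99),
            "efficientnet_b0": (99.65, 100.00, 94.81, 97.33, 100.00, 97.40, 97.37),
            "resnet18": (99.05, 98.63, 96.00, 97.30, 99.82, 97.91, 97.89),
            "resnet50": (99.57, 99.32, 98.64, 98.98, 99.91, 99.28, 99.27),
        }
    ),
    "NEV": _rows(
        {
            "mobilenetv2": (86.95, 95.20, 90.45, 92.76, 88.56, 89.50, 89.50),
            "efficientnet_b0": (89.44, 90.74, 94.19, 92.43, 81.80, 87.99, 87.77),
            "resnet18": (81.93, 90.97, 87.67, 89.29, 79.21, 83.44, 83.33),
            "resnet50": (85.29, 93.83, 89.53, 91.63, 85.44, 87.49, 87.46),
        }
    ),
    "SEK": _rows(
        {
            "mobilenetv2": (85.85, 88.54, 95.26, 91.78, 65.49, 80.37, 78.98),
            "efficientnet_b0": (88.93, 94.71, 95.55, 95.13, 80.43, 87.99, 87.67),
            "resnet18": (81.08, 85.01, 93.43, 89.03, 57.38, 75.41, 73.22),
            "resnet50": (83.56, 84.72, 94.85, 89.50, 58.51, 76.68, 74.50),
        }
    ),
}

#: Residual pair of the Benign group after peeling ACK: NEV (positive) vs SEK.
NEV_VS_SEK = _rows(
    {
        "mobilenetv2": (85.94, 95.09, 93.06, 94.06, 82.66, 87.86, 87.71),
        "efficientnet_b0": (86.07, 96.11, 92.93, 94.49, 85.65, 89.29, 89.22),
        "resnet18": (80.12, 89.83, 90.87, 90.34, 67.87, 79.37, 78.53),
        "resnet50": (80.88, 93.60, 90.60, 92.07, 76.47, 83.53, 83.23),
    }
)

#: One-vs-rest tasks inside the Malignant group, keyed by peeled class.
MALIGNANT_PEELS = {
    "MEL": _rows(
        {
            "mobilenetv2": (97.54, 71.83, 98.26, 82.99, 61.99, 80.13, 78.04),
            "efficientnet_b0": (98.83, 76.90, 99.02, 86.57, 66.79, 82.90, 81.32),
            "resnet18": (95.41, 75.13, 97.37, 84.81, 64.49, 80.93, 79.24),
            "resnet50": (96.45, 67.77, 98.16, 80.18, 58.77, 78.46, 75.95),
        }
    ),
    "BCC": _rows(
        {
            "mobilenetv2": (79.01, 62.87, 88.60, 73.55, 81.05, 84.83, 84.74),
            "efficientnet_b0": (82.54, 76.10, 80.54, 78.26, 86.14, 83.34, 83.30),
            "resnet18": (73.43, 60.29, 72.89, 66.00, 78.44, 75.67, 75.62),
            "resnet50": (76.60, 82.72, 62.67, 71.32, 87.19, 74.93, 73.92),
        }
    ),
    "SCC": _rows(
        {
            "mobilenetv2": (69.51, 86.53, 80.63, 83.48, 63.04, 71.84, 71.30),
            "efficientnet_b0": (73.46, 77.23, 85.34, 81.08, 57.25, 71.29, 69.90),
            "resnet18": (67.60, 76.83, 80.83, 78.78, 52.44, 66.64, 65.11),
            "resnet50": (62.26, 81.98, 76.52, 79.16, 50.81, 63.67, 62.36),
        }
    ),
}

#: Residual pair of the Malignant group after peeling MEL: BCC (positive) vs SCC.
BCC_VS_SCC = _rows(
    {
        "mobilenetv2": (85.31, 91.47, 82.23, 86.61, 87.85, 85.04, 84.99),
        "efficientnet_b0": (81.21, 86.82, 87.16, 86.99, 83.89, 85.52, 85.51),
        "resnet18": (80.00, 82.17, 62.35, 70.90, 64.06, 63.21, 63.20),
        "resnet50": (67.35, 85.27, 72.61, 78.43, 76.97, 74.79, 74.76),
    }
)

#: Reported comparison of the flat baseline against the four assembled
#: hierarchical structures (macro-averaged on the shared test set).
STRUCTURE_COMPARISON = {
    "multiclass_baseline": dict(
        zip(METRIC_COLUMNS, (60.29, 68.50, 60.27, 62.63, 93.64, 76.96, 75.12))
    ),
    "structure-1": dict(
        zip(METRIC_COLUMNS, (85.75, 85.71, 82.62, 83.97, 96.67, 89.65, 89.37))
    ),
    "structure-2": dict(
        zip(METRIC_COLUMNS, (85.15, 85.21, 81.47, 83.02, 89.00, 96.53, 88.68))
    ),
    "structure-3": dict(
        zip(METRIC_COLUMNS, (85.65, 85.66, 82.33, 83.85, 89.47, 96.62, 89.19))
    ),
    "structure-4": dict(
        zip(METRIC_COLUMNS, (85.25, 85.20, 81.60, 83.09, 89.08, 96.57, 88.77))
    ),
}

#: Node -> backbone assignments of the four reported structures.  They
#: differ only at the NEV|SEK and BCC|SCC nodes, where the recall-first
#: winner and the all-other-metrics winner disagree.
STRUCTURE_PRESETS = {
    "structure-1": {
        "Benign|Malignant": "mobilenetv2",
        "ACK|NEV+SEK": "resnet50",
        "NEV|SEK": "mobilenetv2",
        "MEL|BCC+SCC": "efficientnet_b0",
        "BCC|SCC": "efficientnet_b0",
    },
    "structure-2": {
        "Benign|Malignant": "mobilenetv2",
        "ACK|NEV+SEK": "resnet50",
        "NEV|SEK": "efficientnet_b0",
        "MEL|BCC+SCC": "efficientnet_b0",
        "BCC|SCC": "efficientnet_b0",
    },
    "structure-3": {
        "Benign|Malignant": "mobilenetv2",
        "ACK|NEV+SEK": "resnet50",
        "NEV|SEK": "mobilenetv2",
        "MEL|BCC+SCC": "efficientnet_b0",
        "BCC|SCC": "mobilenetv2",
    },
    "structure-4": {
        "Benign|Malignant": "mobilenetv2",
        "ACK|NEV+SEK": "resnet50",
        "NEV|SEK": "efficientnet_b0",
        "MEL|BCC+SCC": "efficientnet_b0",
        "BCC|SCC": "mobilenetv2",
    },
}


def candidates_from_rows(rows: dict, positive_class: str, task_name: str) -> list:
    """Wrap a reference table's rows as :class:`CandidateResult` records."""
    out = []
    for i, (model, vals) in enumerate(rows.items()):
        out.append(
            CandidateResult(
                backbone_name=model,
                task_name=task_name,
                metrics=MetricReport.from_binary_row(
                    positive_class,
                    accuracy=vals["accuracy"],
                    precision=vals["precision"],
                    recall=vals["recall"],
                    f1=vals["f1"],
                    specificity=vals["specificity"],
                    balanced_accuracy=vals["balanced_accuracy"],
                    g_mean=vals["g_mean"],
                ),
                registration_index=i,
            )
        )
    return out
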