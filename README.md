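# lesiontree

Hierarchical binary classification for skin-lesion images, with
recall-first model selection and Grad-CAM explanations.

## The problem

Clinical triage of skin lesions spans six common diagnoses: three benign
(actinic keratosis **ACK**, nevus **NEV**, seborrheic keratosis **SEK**)
and three malignant (melanoma **MEL**, basal cell carcinoma **BCC**,
squamous cell carcinoma **SCC**). A single six-way CNN has to learn all
pairwise distinctions at once, and in practice struggles most with the
visually similar classes inside each group. `lesiontree` implements the
alternative: decompose the six-way problem into a tree of binary
decisions (a *local classifier per node*),

```
                 Benign | Malignant
                /                  \
        ACK | NEV+SEK          MEL | BCC+SCC
             /    \                 /    \
        ACK     NEV | SEK      MEL     BCC | SCC
```

train every node with several candidate backbones, and pick each node's
model by a **recall-first rule**: maximize recall (sensitivity), breaking
ties by F1-score, then precision, then accuracy. Recall leads because a
false negative — a missed malignancy — is the clinically costly error.

Evaluation uses seven metrics derived one-vs-rest from the confusion
matrix, reported per class and macro-averaged:

    accuracy  = (TP+TN)/(TP+TN+FP+FN)        precision = TP/(TP+FP)
    recall    = TP/(TP+FN)                   specificity = TN/(TN+FP)
    F1        = 2·P·R/(P+R)
    balanced accuracy = (recall+specificity)/2
    G-mean    = sqrt(recall·specificity)

Grad-CAM localization maps use channel weights
`alpha_k = (1/Z) * sum_ij d y_c / d A^k_ij` over the last convolutional
feature maps `A^k` and the rectified combination
`L_c = ReLU(sum_k alpha_k A^k)`.

The package ships the full pipeline — dataset preparation (resize,
80/20 split, rescale/reflect augmentation that balances every training
class to a fixed count, leakage checks), a pure-numpy small CNN backbone
with hand-written backpropagation and Adam so everything runs and tests
on one CPU, the selection and routing machinery, Grad-CAM, and a seeded
synthetic lesion generator that reproduces the group structure the
method exploits. The four ImageNet-scale backbones (MobileNetV2,
EfficientNet-B0, ResNet-18, ResNet-50) are registered names; building
them requires the optional `torch` extra. Published benchmark rows for
every binary task ship in `lesiontree.reference` as worked examples.

## Worked example

```python
>>> import lesiontree as lt
>>> from lesiontree.reference import NEV_VS_SEK, candidates_from_rows

# the tree and its training tasks
>>> nodes = lt.decision_nodes(lt.default_taxonomy())
>>> [n.node_id for n in nodes]
['Benign|Malignant', 'ACK|NEV+SEK', 'NEV|SEK', 'MEL|BCC+SCC', 'BCC|SCC']
>>> len(lt.enumerate_training_runs(nodes, ['mobilenetv2', 'efficientnet_b0',
...                                        'resnet18', 'resnet50']))
20

# metric formulas on published binary rows
>>> round(lt.f1(92.70, 87.22), 2)          # precision, recall
89.88
>>> round(lt.g_mean(87.22, 85.43), 2)      # recall, specificity
86.32

# recall-first selection on the published NEV-vs-SEK candidates:
# one backbone wins accuracy/precision/F1, another wins recall — recall decides
>>> best = lt.select_best(candidates_from_rows(NEV_VS_SEK, 'NEV', 'NEV|SEK'))
>>> best.backbone_name, best.metrics.key_metrics()['recall']
('mobilenetv2', 93.06)

# desk-scale replication on synthetic data: hierarchy vs flat six-way CNN
>>> res = lt.hierarchy_vs_flat(seed=0)
>>> round(res['hierarchy_macro_recall'], 2), round(res['flat_macro_recall'], 2)
(90.06, 81.94)
```

The last call generates a seeded synthetic six-class dataset (72
images/class at 64 px), splits 80/20, trains one small CNN per decision
node and one flat six-way CNN under the same 10-epoch budget, and
reports both macro recalls on the shared test side — the hierarchy
wins, mirroring the design rationale of the method.

## Command line

```bash
lesiontree synth    --out data/raw --imbalanced --size 64 --seed 1
lesiontree prepare  --data data/raw --out data/prep --size 64 --target 120 --seed 1
lesiontree train    --data data/prep --out runs --preset tiny --size 64 --seed 1
lesiontree select   --runs runs --out runs/assignment.json
lesiontree evaluate --data data/prep --runs runs \
                    --assignment runs/assignment.json --out reports
lesiontree explain  --model runs/Benign_Malignant__tiny_test_cnn.npz \
                    --image data/prep/test/MEL/<id>.png \
                    --class-code positive --out cam.png
```

`prepare` writes mirrored `train/`/`test/` class directories with
manifests and a leakage report; `evaluate` writes the six-class and
benign/malignant confusion matrices, the seven-metric report and a
comparison table against the flat baseline.

## Layout

- `src/lesiontree/taxonomy.py` — label tree, binary tasks, decision nodes
- `src/lesiontree/datapipe.py` — resize / split / augment / balance / leakage
- `src/lesiontree/synthgen.py` — seeded synthetic lesion generator
- `src/lesiontree/backbones.py` — backbone registry, numpy CNN, Adam trainer
- `src/lesiontree/metrics.py` — confusion matrices and the seven metrics
- `src/lesiontree/hierarchy.py` — selection, assembly, routing, evaluation
- `src/lesiontree/gradcam.py` — Grad-CAM weights, maps, overlays
- `src/lesiontree/reference.py` — published benchmark rows (worked examples)
- `src/lesiontree/cli.py` — the `lesiontree` command
- `docs/methods.md` — models, assumptions, numerical choices, limitations
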