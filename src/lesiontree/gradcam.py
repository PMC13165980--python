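"""Gradient-weighted class activation mapping (Grad-CAM).

For a target class ``c`` with pre-softmax score ``y_c`` and the last
convolutional layer's feature maps ``A^k`` (each H' x W', Z = H'W'
pixels), the channel importance weights are the globally averaged
gradients

    alpha_k = (1/Z) * sum_ij  d y_c / d A^k_ij

and the localization map is the ReLU-rectified weighted sum

    L_c = ReLU( sum_k alpha_k * A^k ),

upsampled bilinearly to the input size and rendered through a
blue -> yellow -> red colormap (high values red, low values blue; a map
of zeros renders fully blue).  ``y_c`` is taken before the softmax, so
the map reflects the class evidence rather than the normalized
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
from matplotlib import cm  # noqa: E402
import numpy as np  # noqa: E402
from PIL import Image  # noqa: E402

from .backbones import TrainedModel  # noqa: E402
from .datapipe import ImageRecord  # noqa: E402

__all__ = [
    "ActivationBundle",
    "GradCamMap",
    "GradCamError",
    "channel_weights",
    "cam",
    "explain",
]


class GradCamError(ValueError):
    pass


@dataclass
class ActivationBundle:
    """Feature maps and matching score gradients for one image and class.

    ``feature_maps`` and ``gradients`` are K x H' x W' arrays (channel
    first); ``score`` is the pre-softmax prediction for the target class.
    """

    feature_maps: np.ndarray
    gradients: np.ndarray
    class_index: int
    score: float = 0.0

    def __post_init__(self) -> None:
        self.feature_maps = np.asarray(self.feature_maps, dtype=float)
        self.gradients = np.asarray(self.gradients, dtype=float)
        if self.feature_maps.ndim != 3:
            raise GradCamError("feature_maps must be K x H' x W'")
        if self.feature_maps.shape != self.gradients.shape:
            raise GradCamError(
                f"shape mismatch: maps {self.feature_maps.shape} vs "
                f"gradients {self.gradients.shape}"
            )
        if self.feature_maps.shape[1] * self.feature_maps.shape[2] == 0:
            raise GradCamError("feature maps must be nonempty")

    @property
    def Z(self) -> int:
        return self.feature_maps.shape[1] * self.feature_maps.shape[2]


@dataclass
class GradCamMap:
    weights: np.ndarray  # K channel weights alpha_k
    raw_map: np.ndarray  # H' x W', nonnegative
    upsampled_map: np.ndarray | None = None  # input-size grid
    rendering: np.ndarray | None = None  # RGB uint8 heatmap
    overlay: np.ndarray | None = None  # heatmap blended onto the input


def channel_weights(bundle: ActivationBundle) -> np.ndarray:
    """Global average pooling of the score gradients, one weight per map."""
    return bundle.gradients.mean(axis=(1, 2))


def _render(norm_map: np.ndarray) -> np.ndarray:
    # jet runs blue -> cyan -> yellow -> red, matching the reading
    # "low = blue, mid = yellow, high = red"
    rgba = cm.jet(np.clip(norm_map, 0.0, 1.0))
    return (rgba[..., :3] * 255).astype(np.uint8)


def cam(bundle: ActivationBundle, input_size: int | None = None) -> GradCamMap:
    """Weights, ReLU-rectified map, bilinear upsampling and rendering.

    The rendering is normalized by the map maximum; an all-zero map
    (every weighted activation negative) renders fully blue.
    """
    alpha = channel_weights(bundle)
    raw = np.maximum(0.0, np.tensordot(alpha, bundle.feature_maps, axes=1))
    up = None
    if input_size is not None:
        up = np.asarray(
            Image.fromarray(raw.astype(np.float32), mode="F").resize(
                (input_size, input_size), resample=Image.BILINEAR
            ),
            dtype=float,
        )
    base = up if up is not None else raw
    peak = base.max()
    rendering = _render(base / peak if peak > 0 else base)
    return GradCamMap(weights=alpha, raw_map=raw, upsampled_map=up, rendering=rendering)


def explain(
    model: TrainedModel,
    image: ImageRecord,
    class_code: str,
    layer: str | None = None,
    overlay_alpha: float = 0.5,
) -> GradCamMap:
    """Grad-CAM for one image and class, plus a heatmap overlay.

    Activations and gradients are captured at the model's final
    convolutional feature layer (overridable by ``layer``); the heatmap
    is alpha-blended onto the input image.
    """
    if class_code not in model.class_order:
        raise GradCamError(
            f"unknown class {class_code!r}; model classes: {model.class_order}"
        )
    layer = layer or model.final_feature_layer
    x = image.pixels[None].astype(np.float64) / 255.0
    activation, gradient, scores = model.net.feature_gradients(
        x, model.class_order.index(class_code), layer
    )
    if activation.ndim != 4:
        raise GradCamError(f"layer {layer!r} does not produce spatial feature maps")
    bundle = ActivationBundle(
        feature_maps=np.moveaxis(activation[0], -1, 0),
        gradients=np.moveaxis(gradient[0], -1, 0),
        class_index=model.class_order.index(class_code),
        score=float(scores[0]),
    )
    result = cam(bundle, input_size=image.pixels.shape[0])
    blended = (
        overlay_alpha * result.rendering.astype(float)
        + (1 - overlay_alpha) * image.pixels.astype(float)
    )
    result.overlay = np.clip(blended, 0, 255).astype(np.uint8)
    return result
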