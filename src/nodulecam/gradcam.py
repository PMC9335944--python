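"""Gradient-weighted class activation mapping, from scratch.

For a target class score y (the pre-softmax logit, the standard Grad-CAM
choice — post-softmax gradients entangle both classes), channel k of the
final convolutional feature maps A^k gets the weight

    w_k = (1/Z) * sum_ij  dy / dA^k_ij          (Z = h*w)

and the localization map is ReLU(sum_k w_k A^k), upsampled bilinearly to the
input resolution, min-max rescaled, and rendered through a blue→red
colormap (blue = low contribution, red = high).

The model contract is minimal: ``forward(x)`` returning logits while storing
the final conv activations in ``feature_maps_``, and
``grad_features(dlogits)`` returning the gradient of ``sum(logits*dlogits)``
with respect to those activations.  Any object with those three members
works, which is what the analytic toy models in the test-suite use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize


@dataclass
class ChannelWeights:
    weights: np.ndarray  # one scalar per channel
    target_class: int
    score: float  # pre-softmax score of the target class


@dataclass
class Heatmap:
    raw: np.ndarray  # non-negative, feature-map resolution
    upsampled: np.ndarray | None = None  # input resolution, in [0, 1]
    rendered: np.ndarray | None = None  # RGB in [0, 1]
    overlay: np.ndarray | None = None  # RGB blend with the original image


def channel_weights(model, x: np.ndarray, target_class: int | None = None):
    """Per-channel importance weights (GAP of the logit gradient) plus the
    feature activations captured on the same forward pass.

    ``x`` is a single preprocessed input, shape (C, H, W).  When
    ``target_class`` is None the predicted class is explained.
    """
    x = np.asarray(x)
    if x.ndim == 3:
        x = x[None]
    logits = model.forward(x, train=False)
    feats = getattr(model, "feature_maps_", None)
    if feats is None:
        raise ValueError("model does not expose final conv feature maps "
                         "(feature_maps_ after forward)")
    if target_class is None:
        target_class = int(np.argmax(logits[0]))
    onehot = np.zeros_like(logits)
    onehot[0, target_class] = 1.0
    dfeat = model.grad_features(onehot)  # (1, C, h, w)
    w = dfeat[0].mean(axis=(1, 2))
    return (
        ChannelWeights(weights=np.asarray(w, dtype=float),
                       target_class=target_class,
                       score=float(logits[0, target_class])),
        np.asarray(feats[0], dtype=float),
    )


def compute_cam(activations: np.ndarray, weights: ChannelWeights | np.ndarray) -> Heatmap:
    """ReLU of the weight-summed feature maps, at feature-map resolution."""
    w = weights.weights if isinstance(weights, ChannelWeights) else np.asarray(weights, dtype=float)
    acts = np.asarray(activations, dtype=float)
    if acts.shape[0] != len(w):
        raise ValueError(f"channel mismatch: {acts.shape[0]} maps vs {len(w)} weights")
    raw = np.einsum("k,kij->ij", w, acts)
    return Heatmap(raw=np.maximum(raw, 0.0))


def apply_colormap(values: np.ndarray) -> np.ndarray:
    """Classic jet colormap (the OpenCV/Matlab formula):

        r = clip(1.5 - |4v - 3|),  g = clip(1.5 - |4v - 2|),  b = clip(1.5 - |4v - 1|)

    0 → dark blue (blue channel maximal), 1 → dark red (red channel
    maximal), with the characteristic saturated red plateau above v=0.875.
    Piecewise linear, hence analytically invertible, which pins down exactly
    which normalized heatmap values the red-capture stage selects."""
    v = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    out = np.empty(v.shape + (3,))
    out[..., 0] = np.clip(1.5 - np.abs(4 * v - 3.0), 0.0, 1.0)
    out[..., 1] = np.clip(1.5 - np.abs(4 * v - 2.0), 0.0, 1.0)
    out[..., 2] = np.clip(1.5 - np.abs(4 * v - 1.0), 0.0, 1.0)
    return out


def red_onset_value(hue_cutoff_deg: float = 20.0) -> float:
    """Normalized heatmap value above which the rendered colour has hue
    ≤ ``hue_cutoff_deg`` (i.e. falls in the red capture window).  On jet's
    yellow→red segment the colour is (1, g, 0) with g = 1.5 - (4v - 2) and
    hue 60g°, so hue ≤ cutoff ⇔ g ≤ cutoff/60 ⇔ v ≥ (3.5 - cutoff/60)/4."""
    return (3.5 - hue_cutoff_deg / 60.0) / 4.0


def render_heatmap(
    raw: Heatmap | np.ndarray,
    target_shape: tuple[int, int],
    original: np.ndarray | None = None,
    blend: float = 0.4,
) -> Heatmap:
    """Bilinear upsample → min-max rescale to [0,1] (an all-zero map stays
    zero) → colormap → optional α-blend overlay on the original image."""
    raw_map = raw.raw if isinstance(raw, Heatmap) else np.asarray(raw, dtype=float)
    up = _sk_resize(raw_map, target_shape, order=1, anti_aliasing=False,
                    preserve_range=True)
    up = np.maximum(up, 0.0)
    mx = up.max()
    if mx > 0:
        up = up / mx
    rendered = apply_colormap(up)
    overlay = None
    if original is not None:
        orig = np.asarray(original, dtype=float)
        if orig.ndim == 2:
            orig = np.repeat(orig[..., None], 3, axis=2)
        overlay = np.clip(blend * rendered + (1.0 - blend) * orig, 0.0, 1.0)
    return Heatmap(raw=raw_map, upsampled=up, rendered=rendered, overlay=overlay)


def explain(model, x: np.ndarray, target_class: int | None = None,
            target_shape: tuple[int, int] | None = None,
            original: np.ndarray | None = None, blend: float = 0.4) -> Heatmap:
    """channel_weights → compute_cam → render_heatmap in one call."""
    w, acts = channel_weights(model, x, target_class)
    hm = compute_cam(acts, w)
    if target_shape is None:
        target_shape = x.shape[-2:]
    return render_heatmap(hm, target_shape, original=original, blend=blend)
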