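"""Sigmoid-compressed diverging color overlays of PD maps.

PD values span several decades, so for display each value is passed
through ``tanh(pd / T)``: the threshold T is the curve's natural scale
and +/- infinity land on the two colormap extremes.  Typical thresholds
are 4e-3 months per intensity unit for in-mask maps and 4e-2 for
outside-mask maps, whose PDs run an order of magnitude larger.  A hard
clamp (``clip(pd / T, -1, 1)``) is available instead of the smooth
saturation.  Scores color a diverging blue-red map with a neutral
midpoint and are alpha-blended onto the grayscale anatomy; pixels
without a computed PD show the anatomy only.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np

from pdprobe.saliency import PDMap

DEFAULT_THRESHOLD_INSIDE = 4e-3   # months per intensity unit
DEFAULT_THRESHOLD_OUTSIDE = 4e-2


@dataclass
class OverlaySpec:
    threshold: float = DEFAULT_THRESHOLD_INSIDE
    cmap: str = "bwr"
    opacity: float = 0.5
    clamp: bool = False  # hard clip at +/-T instead of smooth tanh saturation

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("display threshold must be > 0")
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError("opacity must be in [0, 1]")


def sigmoid_score(pd, threshold: float):
    """Map PD values to (-1, 1): odd, strictly monotone, saturating.

    ``score = tanh(pd / threshold)``; pd = 0 sits at the colormap
    midpoint and pd = +/-threshold at tanh(1) ~ 0.762 of the way out.
    """
    if threshold <= 0:
        raise ValueError("display threshold must be > 0")
    return np.tanh(np.asarray(pd, dtype=np.float64) / threshold)


def _anatomy_to_gray(anatomy: np.ndarray) -> np.ndarray:
    """Coerce the anatomy image to an 8-bit grayscale grid."""
    arr = np.asarray(anatomy)
    if arr.ndim == 3:
        arr = arr.astype(np.float64).mean(axis=2)
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.floor((arr - lo) * (255.0 / (hi - lo)) + 0.5).astype(np.uint8)


def render_overlay(
    pdmap: PDMap, anatomy: np.ndarray, spec: OverlaySpec | None = None
) -> np.ndarray:
    """Composite colormapped PD scores onto the anatomy; returns uint8 RGB.

    The anatomy may be on the PD grid (299) or at double scale (598), in
    which case the PD map is upsampled by pixel replication.  Pixels
    outside the computed region are left as pure anatomy.
    """
    spec = spec or OverlaySpec()
    gray = _anatomy_to_gray(anatomy)
    values, computed = pdmap.values, pdmap.computed
    if gray.shape != values.shape:
        factor_r = gray.shape[0] // values.shape[0]
        factor_c = gray.shape[1] // values.shape[1]
        if (factor_r, factor_c) != (2, 2) or gray.shape != tuple(
            2 * s for s in values.shape
        ):
            raise ValueError(
                f"anatomy {gray.shape} is not aligned to the PD grid {values.shape}"
            )
        values = np.repeat(np.repeat(values, 2, axis=0), 2, axis=1)
        computed = np.repeat(np.repeat(computed, 2, axis=0), 2, axis=1)
    if spec.clamp:
        scores = np.clip(np.where(computed, values, 0.0) / spec.threshold, -1.0, 1.0)
    else:
        scores = sigmoid_score(np.where(computed, values, 0.0), spec.threshold)
    cmap = matplotlib.colormaps[spec.cmap]
    colors = cmap((scores + 1.0) / 2.0)[..., :3] * 255.0
    out = np.repeat(gray[:, :, None], 3, axis=2).astype(np.float64)
    blend = (1.0 - spec.opacity) * out + spec.opacity * colors
    out[computed] = blend[computed]
    return np.floor(out + 0.5).astype(np.uint8)


def render_panel(
    pdmap: PDMap, anatomy: np.ndarray, spec: OverlaySpec | None = None, gap: int = 8
) -> np.ndarray:
    """Side-by-side panel: grayscale anatomy | overlay."""
    overlay = render_overlay(pdmap, anatomy, spec)
    gray = _anatomy_to_gray(anatomy)
    left = np.repeat(gray[:, :, None], 3, axis=2)
    spacer = np.full((overlay.shape[0], gap, 3), 255, dtype=np.uint8)
    return np.concatenate([left, spacer, overlay], axis=1)


def save_overlay_png(path, rgb: np.ndarray) -> None:
    from PIL import Image

    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)
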