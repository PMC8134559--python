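"""Radiograph preparation chain.

Mirrors the preparation used for hand-radiograph bone-age models:
background subtraction, a thresholded binary hand mask cleaned by a
morphological erode/dilate cycle, zeroing of intensities outside the
hand, a square crop resized to 598x598, packing of each 2x2 pixel cell
into one 3-channel pixel of a 299x299 image, and min-max scaling to the
0-254 one-byte range.

Conventions: row-major, 0-based, origin top-left; masks and label maps
share the image grid exactly.  Within each 2x2 cell the bottom-left
pixel fills channel 1, the bottom-right channel 2, and the mean of the
two top pixels channel 3.  Hand orientation (upright left hand, palm
down) is the caller's responsibility; only a horizontal-flip flag is
offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import measure, morphology, transform
from skimage.filters import threshold_otsu

OUT_SIZE = 598
PACKED_SIZE = 299


def subtract_background(
    image: np.ndarray,
    estimator: str = "low-percentile",
    value: float = 1.0,
    return_level: bool = False,
):
    """Subtract a scalar background level, clipping at zero.

    ``estimator`` is ``"low-percentile"`` (``value`` = percentile in
    (0, 50], default 1) or ``"fixed-value"`` (``value`` = the level
    itself, non-negative).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if estimator == "low-percentile":
        if not 0.0 < value <= 50.0:
            raise ValueError(f"percentile must be in (0, 50], got {value}")
        level = float(np.percentile(image, value))
    elif estimator == "fixed-value":
        if value < 0:
            raise ValueError(f"fixed background level must be >= 0, got {value}")
        level = float(value)
    else:
        raise ValueError(f"unknown background estimator {estimator!r}")
    out = np.clip(image - level, 0.0, None)
    return (out, level) if return_level else out


def generate_mask(
    image: np.ndarray,
    threshold: str = "otsu",
    threshold_value: Optional[float] = None,
    struct_radius: int = 5,
) -> np.ndarray:
    """Binary hand mask: threshold, opening with a disk, largest component.

    The erode/dilate cycle (morphological opening with a disk of
    ``struct_radius``) removes isolated bright islands smaller than the
    structuring element; retaining the largest connected component then
    drops anything the opening left behind.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.max() == image.min():
        raise ValueError("constant image: no threshold separates foreground")
    if threshold == "otsu":
        thr = float(threshold_otsu(image))
    elif threshold == "fixed":
        if threshold_value is None:
            raise ValueError("fixed threshold requires threshold_value")
        thr = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold mode {threshold!r}")
    mask = image > thr
    if struct_radius > 0:
        mask = morphology.opening(mask, morphology.disk(struct_radius))
    if not mask.any():
        raise ValueError("empty mask after cleanup")
    labeled = measure.label(mask, connectivity=2)
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    return labeled == int(np.argmax(counts))


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every intensity outside the mask; leave the inside untouched."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} vs mask {mask.shape} dimension mismatch")
    return np.where(mask, image, 0.0)


@dataclass
class CropResult:
    """Square crop + resize of an image/mask (and optionally labels)."""

    image: np.ndarray
    mask: np.ndarray
    labels: Optional[np.ndarray]
    window: tuple  # (row_start, col_start, side) in source coordinates
    out_size: int = OUT_SIZE

    def to_source(self, rc: tuple) -> tuple:
        """Map an output-grid pixel centre back to source coordinates."""
        r0, c0, side = self.window
        s = side / self.out_size
        return (r0 + (rc[0] + 0.5) * s - 0.5, c0 + (rc[1] + 0.5) * s - 0.5)


def crop_square_resize(
    image: np.ndarray,
    mask: np.ndarray,
    margin_frac: float = 0.0,
    labels: Optional[np.ndarray] = None,
    out_size: int = OUT_SIZE,
) -> CropResult:
    """Square-crop to the mask bounding box (+margin) and resize bilinearly.

    The window is the bounding box expanded by ``margin_frac`` of its
    longer side on each side, made square about the box centre; parts of
    the window outside the frame are zero-padded.  The mask rides through
    the identical transform and is re-binarized at 0.5; labels use
    nearest-neighbour resampling.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image/mask dimension mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    if margin_frac < 0:
        raise ValueError("margin_frac must be >= 0")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    long_side = max(r1 - r0, c1 - c0)
    side = int(np.ceil(long_side * (1.0 + 2.0 * margin_frac)))
    cr, cc = (r0 + r1) / 2.0, (c0 + c1) / 2.0
    wr = int(round(cr - side / 2.0))
    wc = int(round(cc - side / 2.0))

    def extract(src, fill=0):
        out = np.full((side, side), fill, dtype=np.float64)
        sr0, sr1 = max(wr, 0), min(wr + side, src.shape[0])
        sc0, sc1 = max(wc, 0), min(wc + side, src.shape[1])
        if sr0 < sr1 and sc0 < sc1:
            out[sr0 - wr : sr1 - wr, sc0 - wc : sc1 - wc] = src[sr0:sr1, sc0:sc1]
        return out

    win_img = extract(image)
    win_mask = extract(mask.astype(np.float64))
    img_out = transform.resize(
        win_img, (out_size, out_size), order=1, mode="constant", cval=0.0,
        anti_aliasing=False, preserve_range=True,
    )
    mask_out = transform.resize(
        win_mask, (out_size, out_size), order=1, mode="constant", cval=0.0,
        anti_aliasing=False, preserve_range=True,
    ) >= 0.5
    labels_out = None
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != image.shape:
            raise ValueError("labels/image dimension mismatch")
        win_lab = extract(labels.astype(np.float64))
        labels_out = transform.resize(
            win_lab, (out_size, out_size), order=0, mode="constant", cval=0.0,
            anti_aliasing=False, preserve_range=True,
        ).astype(np.int64)
    return CropResult(img_out, mask_out, labels_out, (wr, wc, side), out_size)


def pack_cells(image598: np.ndarray) -> np.ndarray:
    """Pack 2x2 cells of a 598x598 grid into a real-valued 299x299x3 image.

    For a cell (top row a b / bottom row c d): channel1 = c, channel2 = d,
    channel3 = (a + b) / 2.
    """
    x = np.asarray(image598, dtype=np.float64)
    if x.shape != (OUT_SIZE, OUT_SIZE):
        raise ValueError(f"expected {(OUT_SIZE, OUT_SIZE)} input, got {x.shape}")
    a = x[0::2, 0::2]
    b = x[0::2, 1::2]
    c = x[1::2, 0::2]
    d = x[1::2, 1::2]
    return np.stack([c, d, (a + b) / 2.0], axis=-1)


def unpack_cells(packed: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_cells` up to the lost top-row split.

    The bottom row of each cell is restored exactly; both top pixels get
    the stored top-row mean (their individual values are not recoverable).
    """
    p = np.asarray(packed, dtype=np.float64)
    if p.shape != (PACKED_SIZE, PACKED_SIZE, 3):
        raise ValueError(f"expected {(PACKED_SIZE, PACKED_SIZE, 3)} input, got {p.shape}")
    out = np.empty((OUT_SIZE, OUT_SIZE))
    out[1::2, 0::2] = p[:, :, 0]
    out[1::2, 1::2] = p[:, :, 1]
    out[0::2, 0::2] = p[:, :, 2]
    out[0::2, 1::2] = p[:, :, 2]
    return out


def rescale_to_254(packed: np.ndarray) -> np.ndarray:
    """Affine map of [min, max] to [0, 254], rounded half-up to uint8."""
    x = np.asarray(packed, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("constant input: range is zero")
    scaled = (x - lo) * (254.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)


def downsample_mask(mask598: np.ndarray) -> np.ndarray:
    """Reduce a 598-scale mask to the 299 model grid by 2x2 majority.

    Ties (two of four pixels inside) count as inside.
    """
    m = np.asarray(mask598, dtype=bool)
    if m.shape != (OUT_SIZE, OUT_SIZE):
        raise ValueError(f"expected {(OUT_SIZE, OUT_SIZE)} mask, got {m.shape}")
    cells = m.reshape(PACKED_SIZE, 2, PACKED_SIZE, 2).sum(axis=(1, 3))
    return cells >= 2


def downsample_labels(labels598: np.ndarray, max_label: int = 5) -> np.ndarray:
    """Reduce a 598-scale label map to 299 by per-cell nonzero majority.

    A cell takes the nonzero label held by at least two of its four
    pixels (ties broken toward the smaller label); cells without a
    two-pixel nonzero majority are unassigned (0).
    """
    lab = np.asarray(labels598, dtype=np.int64)
    if lab.shape != (OUT_SIZE, OUT_SIZE):
        raise ValueError(f"expected {(OUT_SIZE, OUT_SIZE)} labels, got {lab.shape}")
    cells = lab.reshape(PACKED_SIZE, 2, PACKED_SIZE, 2).transpose(0, 2, 1, 3)
    cells = cells.reshape(PACKED_SIZE, PACKED_SIZE, 4)
    out = np.zeros((PACKED_SIZE, PACKED_SIZE), dtype=np.int64)
    best = np.ones_like(out)  # need count >= 2 to assign
    for lbl in range(1, max_label + 1):
        count = (cells == lbl).sum(axis=2)
        take = count > best
        out[take] = lbl
        best = np.maximum(best, count)
    return out


@dataclass
class PreprocessConfig:
    """Settings for the full preparation chain (all defaults overridable)."""

    background_estimator: str = "low-percentile"
    background_value: float = 1.0
    threshold: str = "otsu"
    threshold_value: Optional[float] = None
    struct_radius: int = 5
    margin_frac: float = 0.0
    flip: bool = False

    def as_dict(self) -> dict:
        return {
            "background_estimator": self.background_estimator,
            "background_value": self.background_value,
            "threshold": self.threshold,
            "threshold_value": self.threshold_value,
            "struct_radius": self.struct_radius,
            "margin_frac": self.margin_frac,
            "flip": self.flip,
        }


@dataclass
class PreprocessResult:
    packed: np.ndarray        # uint8 (299, 299, 3), 0-254
    image598: np.ndarray      # masked, cropped, resized intensity grid
    mask598: np.ndarray       # bool
    labels598: Optional[np.ndarray]
    mask299: np.ndarray       # bool, majority-reduced
    labels299: Optional[np.ndarray]
    background_level: float
    window: tuple


def preprocess_image(
    image: np.ndarray,
    config: Optional[PreprocessConfig] = None,
    mask: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
) -> PreprocessResult:
    """Run the full chain: subtract, mask, zero, crop/resize, pack, rescale.

    A user-supplied ``mask`` (e.g. manually traced for a nonuniform
    background) bypasses automatic mask generation.
    """
    cfg = config or PreprocessConfig()
    image = np.asarray(image, dtype=np.float64)
    if cfg.flip:
        image = np.fliplr(image)
        if mask is not None:
            mask = np.fliplr(np.asarray(mask, dtype=bool))
        if labels is not None:
            labels = np.fliplr(np.asarray(labels))
    sub, level = subtract_background(
        image, cfg.background_estimator, cfg.background_value, return_level=True
    )
    if mask is None:
        mask = generate_mask(
            sub, cfg.threshold, cfg.threshold_value, cfg.struct_radius
        )
    else:
        mask = np.asarray(mask, dtype=bool)
    masked = apply_mask(sub, mask)
    crop = crop_square_resize(masked, mask, cfg.margin_frac, labels=labels)
    packed = rescale_to_254(pack_cells(crop.image))
    mask299 = downsample_mask(crop.mask)
    labels299 = None
    if crop.labels is not None:
        lab = downsample_labels(crop.labels)
        lab[~mask299] = 0  # labeled pixels must stay inside the hand
        labels299 = lab
    return PreprocessResult(
        packed=packed,
        image598=crop.image,
        mask598=crop.mask,
        labels598=crop.labels,
        mask299=mask299,
        labels299=labels299,
        background_level=level,
        window=crop.window,
    )
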