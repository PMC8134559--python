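"""PNG and PD-map file I/O.

Grayscale radiographs come in as 8- or 16-bit single-channel PNGs; packed
model inputs go out as 3-channel 8-bit PNGs; masks are 0/255 single
channel; ROI label maps store the raw label values 0-5.  PD maps are
serialized either as a flat CSV (row, col, pd — full precision, computed
pixels only) or as a little-endian float32 grid behind a small text
header; NaN is the not-computed sentinel in the binary form.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def read_gray_png(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG as a float64 2-D array."""
    with Image.open(path) as im:
        if im.mode not in ("L", "I", "I;16", "F"):
            im = im.convert("L")
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel image, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_gray_png(path, image: np.ndarray, bits: int = 16) -> None:
    """Write a 2-D intensity grid as a grayscale PNG (values rounded half-up)."""
    arr = np.floor(np.asarray(image, dtype=np.float64) + 0.5)
    if bits == 8:
        Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8), mode="L").save(path)
    elif bits == 16:
        out = np.clip(arr, 0, 65535).astype(np.uint16)
        Image.fromarray(out).save(path)
    else:
        raise ValueError("bits must be 8 or 16")


def read_packed_png(path) -> np.ndarray:
    """Read a packed 3-channel 8-bit model-input PNG as uint8 (H, W, 3)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return arr.astype(np.uint8)


def write_packed_png(path, packed: np.ndarray) -> None:
    arr = np.asarray(packed)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"packed image must be (H, W, 3), got {arr.shape}")
    Image.fromarray(arr.astype(np.uint8), mode="RGB").save(path)


def read_mask_png(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def write_mask_png(path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def read_labels_png(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr.astype(np.int64)


def write_labels_png(path, labels: np.ndarray) -> None:
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("labels must fit in uint8")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def read_ages_csv(path) -> dict:
    """Read an ages CSV (columns image_id, age_months) into a dict."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"image_id": str})
    return dict(zip(df["image_id"], df["age_months"].astype(float)))


def write_ages_csv(path, ages: dict) -> None:
    with open(path, "w") as fh:
        fh.write("image_id,age_months\n")
        for image_id, age in ages.items():
            fh.write(f"{image_id},{float(age)!r}\n")


__all__ = [p for p in dir() if not p.startswith("_")]
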