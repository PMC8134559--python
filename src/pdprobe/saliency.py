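"""Finite-difference partial-derivative (PD) saliency maps.

The probe treats the regressor as a black box.  At one pixel of the
packed input the intensities of all three channels are incremented by
``step`` (default 1 intensity unit) and the age is re-inferred; the PD
in months per intensity unit is the change in inferred age divided by
the step.  Repeating this at every pixel of a region yields the PD map.
The baseline prediction is computed once and reused — valid because the
regressor contract requires deterministic predictions.

Forward differencing is exact for affine models and biased by at most
``step * B / 2`` for twice-differentiable models with curvature bound B
along the probe direction; a central-difference mode is available behind
a flag.  Inputs scaled to 0-254 can reach 255 after the +1 step; the
perturbed value is passed through unclamped and the model contract
requires accepting it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from pdprobe.preprocess import downsample_mask

GRID = (299, 299)


@dataclass
class PDMap:
    """Per-pixel partial derivative of predicted age w.r.t. input intensity.

    ``values`` holds months-per-intensity-unit where ``computed`` is set
    and NaN (the not-computed sentinel) elsewhere.
    """

    values: np.ndarray     # float64 (299, 299), NaN outside the region
    computed: np.ndarray   # bool (299, 299)
    baseline: float        # predicted age of the unperturbed image, months
    step: float            # perturbation size, intensity units

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.computed = np.asarray(self.computed, dtype=bool)
        if self.values.shape != self.computed.shape:
            raise ValueError("values/computed shape mismatch")
        if self.step <= 0:
            raise ValueError("step must be > 0")


def resolve_region(
    region,
    mask: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Turn a region selector into a boolean 299x299 grid.

    ``region`` may be a boolean grid (598-scale masks are reduced to the
    model grid by 2x2-cell majority, ties inside), or one of the strings
    ``"mask"``, ``"outside"``, ``"all"``, ``"labels:1,3"`` (requiring
    ``mask`` / ``labels`` as appropriate).
    """
    if isinstance(region, str):
        if region == "all":
            return np.ones(GRID, dtype=bool)
        if region in ("mask", "outside"):
            if mask is None:
                raise ValueError(f"region {region!r} requires a mask")
            m = np.asarray(mask, dtype=bool)
            if m.shape != GRID:
                m = downsample_mask(m)
            return m if region == "mask" else ~m
        if region.startswith("labels:"):
            if labels is None:
                raise ValueError("label-selection region requires a label map")
            wanted = [int(tok) for tok in region.split(":", 1)[1].split(",") if tok]
            lab = np.asarray(labels)
            if lab.shape != GRID:
                raise ValueError("label map must be on the 299x299 grid")
            return np.isin(lab, wanted)
        raise ValueError(f"unknown region selector {region!r}")
    m = np.asarray(region, dtype=bool)
    if m.shape != GRID:
        m = downsample_mask(m)
    return m


def fd_pd_at_pixel(model, image: np.ndarray, pixel: tuple, step: float = 1.0) -> float:
    """Forward-difference PD at one pixel (all 3 channels incremented)."""
    r, c = pixel
    if not (0 <= r < GRID[0] and 0 <= c < GRID[1]):
        raise IndexError(f"pixel {pixel} outside the {GRID} grid")
    if step < 1:
        raise ValueError("step must be >= 1 intensity unit")
    work = np.array(image, dtype=np.float64, copy=True)
    baseline = float(model.predict(work))
    work[r, c, :] += step
    perturbed = float(model.predict(work))
    return (perturbed - baseline) / step


def compute_pd_map(
    model,
    image: np.ndarray,
    region,
    step: float = 1.0,
    central: bool = False,
    mask: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
) -> PDMap:
    """PD map over every pixel of ``region`` (sequential evaluation).

    One pixel is perturbed at a time on a private working copy; the
    baseline prediction is computed once.  Evaluation order cannot
    affect the result for a deterministic model.
    """
    sel = resolve_region(region, mask=mask, labels=labels)
    if not sel.any():
        raise ValueError("empty probe region")
    if step < 1:
        raise ValueError("step must be >= 1 intensity unit")
    work = np.array(image, dtype=np.float64, copy=True)
    if work.shape[:2] != GRID:
        raise ValueError(f"expected a {GRID} packed image, got {work.shape}")
    baseline = float(model.predict(work))
    if not np.isfinite(baseline):
        raise ValueError("model returned a non-finite baseline prediction")
    values = np.full(GRID, np.nan)
    rows, cols = np.nonzero(sel)
    for r, c in zip(rows, cols):
        saved = work[r, c].copy()
        work[r, c] += step
        up = float(model.predict(work))
        if central:
            work[r, c] = saved - step
            down = float(model.predict(work))
            pd = (up - down) / (2.0 * step)
        else:
            pd = (up - baseline) / step
        work[r, c] = saved
        if not np.isfinite(pd):
            raise ValueError(f"model returned a non-finite prediction at {(r, c)}")
        values[r, c] = pd
    return PDMap(values, sel.copy(), baseline, step)


def batch_pd_map(
    model,
    image: np.ndarray,
    region,
    step: float = 1.0,
    batch_size: int = 32,
    mask: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
) -> PDMap:
    """PD map via batched prediction; bit-identical to :func:`compute_pd_map`.

    Uses ``model.predict_batch`` (collection of images -> one scalar
    each) when available, otherwise falls back to the sequential path.
    """
    predict_batch = getattr(model, "predict_batch", None)
    if predict_batch is None or batch_size <= 1:
        return compute_pd_map(model, image, region, step=step, mask=mask, labels=labels)
    sel = resolve_region(region, mask=mask, labels=labels)
    if not sel.any():
        raise ValueError("empty probe region")
    if step < 1:
        raise ValueError("step must be >= 1 intensity unit")
    base_img = np.array(image, dtype=np.float64, copy=True)
    if base_img.shape[:2] != GRID:
        raise ValueError(f"expected a {GRID} packed image, got {base_img.shape}")
    baseline = float(model.predict(base_img))
    if not np.isfinite(baseline):
        raise ValueError("model returned a non-finite baseline prediction")
    values = np.full(GRID, np.nan)
    rows, cols = np.nonzero(sel)
    # one persistent stack of baseline copies; each chunk perturbs one
    # pixel per slot and restores it afterwards (exact for integer steps)
    n_slots = min(batch_size, rows.size)
    stack = np.repeat(base_img[None, :, :, :], n_slots, axis=0)
    for start in range(0, rows.size, batch_size):
        rr = rows[start : start + batch_size]
        cc = cols[start : start + batch_size]
        idx = np.arange(rr.size)
        saved = stack[idx, rr, cc, :].copy()
        stack[idx, rr, cc, :] += step
        preds = np.asarray(predict_batch(stack[: rr.size]), dtype=np.float64)
        stack[idx, rr, cc, :] = saved
        if preds.shape != (rr.size,):
            raise ValueError("predict_batch must return one scalar per image")
        if not np.all(np.isfinite(preds)):
            raise ValueError("model returned a non-finite prediction in a batch")
        values[rr, cc] = (preds - baseline) / step
    return PDMap(values, sel.copy(), baseline, step)


# ---------------------------------------------------------------------------
# serialization

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def save_pd_csv(pdmap: PDMap, path) -> None:
    """Flat CSV (row, col, pd) of the computed pixels, full precision."""
    with open(path, "w") as fh:
        fh.write(f"# baseline={pdmap.baseline!r} step={pdmap.step!r}\n")
        fh.write("row,col,pd\n")
        rows, cols = np.nonzero(pdmap.computed)
        vals = pdmap.values[rows, cols]
        for r, c, v in zip(rows, cols, vals):
            fh.write(f"{r},{c},{_FLOAT_FMT % v}\n")


def load_pd_csv(path, shape: tuple = GRID) -> PDMap:
    baseline, step = np.nan, 1.0
    values = np.full(shape, np.nan)
    computed = np.zeros(shape, dtype=bool)
    with open(path) as fh:
        header = fh.readline()
        if header.startswith("#"):
            for tok in header[1:].split():
                key, _, val = tok.partition("=")
                if key == "baseline":
                    baseline = float(val)
                elif key == "step":
                    step = float(val)
            fh.readline()  # column header
        for line in fh:
            line = line.strip()
            if not line:
                continue
            r_s, c_s, v_s = line.split(",")
            r, c = int(r_s), int(c_s)
            values[r, c] = float(v_s)
            computed[r, c] = True
    return PDMap(values, computed, baseline, step)


def save_pd_binary(pdmap: PDMap, path) -> None:
    """Float32 grid with a small text header; NaN marks uncomputed pixels."""
    header = (
        f"pdmap rows={pdmap.values.shape[0]} cols={pdmap.values.shape[1]} "
        f"step={pdmap.step!r} baseline={pdmap.baseline!r}\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(pdmap.values.astype("<f4").tobytes())


def load_pd_binary(path) -> PDMap:
    with open(Path(path), "rb") as fh:
        header = fh.readline().decode("ascii").split()
        meta = dict(tok.split("=", 1) for tok in header[1:])
        rows, cols = int(meta["rows"]), int(meta["cols"])
        values = np.frombuffer(fh.read(rows * cols * 4), dtype="<f4")
    values = values.reshape(rows, cols).astype(np.float64)
    return PDMap(values, ~np.isnan(values), float(meta["baseline"]), float(meta["step"]))
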