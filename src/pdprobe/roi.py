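"""ROI-level quantification of PD maps and cohort trend statistics.

Five anatomical regions are used for hand radiographs: 1 = wrist
(carpals, distal radius/ulna, proximal metacarpals), 2 = middle sections
of the five metacarpals, 3 = metacarpal-phalanx joints, 4 = fingers,
5 = the thumb-web muscle bundle between the first and second metacarpals
(a region with no skeletal-maturity information, carried as a
vulnerability probe).  Label maps are integer grids aligned to the PD
grid, 0 = unassigned.

The per-ROI statistic is the mean absolute PD (APD).  Per image, each
ROI's mean APD is normalized by the sum of the mean APDs of ROIs 1-4,
giving the dimensionless "relative mean APD"; ROI 5 shares that same
denominator so its values are comparable across images.  Cohort-level
trends are ordinary least-squares regressions of relative mean APD
against reference age with the classical two-sided t-test on the slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pdprobe.saliency import PDMap

logger = logging.getLogger(__name__)

NORMALIZATION_ROIS = (1, 2, 3, 4)
ALL_ROIS = (1, 2, 3, 4, 5)


def mean_apd(pdmap: PDMap, labels: np.ndarray, roi: int) -> float:
    """Arithmetic mean of |PD| over the ROI's computed pixels.

    Labeled pixels without a computed PD (clipped at the edge of the
    mask reduction) are excluded; the exclusion count is logged.
    """
    labels = np.asarray(labels)
    if labels.shape != pdmap.values.shape:
        raise ValueError("label map and PD map are misaligned")
    in_roi = labels == roi
    usable = in_roi & pdmap.computed
    n_excluded = int(in_roi.sum() - usable.sum())
    if n_excluded:
        logger.info("ROI %d: %d labeled pixels lack a computed PD; excluded",
                    roi, n_excluded)
    if not usable.any():
        raise ValueError(f"ROI {roi} has no labeled pixel with a computed PD")
    return float(np.mean(np.abs(pdmap.values[usable])))


def relative_mean_apd(
    means: Mapping[int, float],
    normalization_set: Sequence[int] = NORMALIZATION_ROIS,
) -> dict:
    """Normalize per-ROI mean APDs by the sum over the normalization set.

    Every ROI present in ``means`` (including ROI 5) is divided by the
    same denominator, so the normalization-set values sum to one.
    """
    missing = [r for r in normalization_set if r not in means]
    if missing:
        raise ValueError(f"normalization ROIs missing from records: {missing}")
    denom = float(sum(means[r] for r in normalization_set))
    if denom <= 0:
        raise ValueError("normalization denominator is zero")
    return {roi: float(val) / denom for roi, val in means.items()}


def area_fraction(labels: np.ndarray, mask: np.ndarray, roi: int) -> float:
    """ROI area as a percentage of the hand-mask area."""
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    if labels.shape != mask.shape:
        raise ValueError("label map and mask are misaligned")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("empty mask")
    return 100.0 * float((labels == roi).sum()) / n_mask


def image_roi_stats(
    pdmap: PDMap,
    labels: np.ndarray,
    mask: np.ndarray,
    image_id: str,
    rois: Sequence[int] = ALL_ROIS,
    normalization_set: Sequence[int] = NORMALIZATION_ROIS,
) -> pd.DataFrame:
    """Per-image ROI records: area %, mean APD, relative mean APD."""
    present = [r for r in rois if np.any(np.asarray(labels) == r)]
    means = {r: mean_apd(pdmap, labels, r) for r in present}
    rel = relative_mean_apd(means, normalization_set)
    rows = [
        {
            "image_id": image_id,
            "roi": r,
            "area_pct": area_fraction(labels, mask, r),
            "mean_apd": means[r],
            "rel_mean_apd": rel[r],
        }
        for r in present
    ]
    return pd.DataFrame(rows)


@dataclass
class TrendRegressionResult:
    """OLS fit of relative mean APD against reference age (months)."""

    roi: Optional[int]
    slope: float           # per month
    intercept: float
    pvalue: float          # two-sided t-test on nonzero slope
    n: int
    stderr: float          # standard error of the slope

    def equation(self) -> str:
        return f"y = {self.slope:.5f}x + {self.intercept:.5f}"


def trend_regression(
    values: Iterable[float],
    ages: Iterable[float],
    roi: Optional[int] = None,
) -> TrendRegressionResult:
    """Unweighted OLS of ``values`` on ``ages`` with the classical slope t-test."""
    y = np.asarray(list(values), dtype=np.float64)
    x = np.asarray(list(ages), dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("values and ages differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all ages equal")
    fit = stats.linregress(x, y)
    return TrendRegressionResult(
        roi=roi,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pvalue=float(fit.pvalue),
        n=int(x.size),
        stderr=float(fit.stderr),
    )


def cohort_trends(
    stats_df: pd.DataFrame,
    ages: Mapping[str, float],
    rois: Sequence[int] = ALL_ROIS,
) -> pd.DataFrame:
    """Per-ROI trend regressions of relative mean APD vs reference age."""
    rows = []
    for roi in rois:
        sub = stats_df[stats_df["roi"] == roi]
        pairs = [
            (float(ages[i]), float(v))
            for i, v in zip(sub["image_id"], sub["rel_mean_apd"])
            if i in ages
        ]
        if len(pairs) < 3 or np.ptp([p[0] for p in pairs]) == 0:
            logger.warning("ROI %d: not enough usable (age, value) pairs", roi)
            continue
        res = trend_regression([p[1] for p in pairs], [p[0] for p in pairs], roi=roi)
        rows.append(
            {
                "roi": roi,
                "slope": res.slope,
                "intercept": res.intercept,
                "p": res.pvalue,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def cohort_table(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-ROI table: mean +/- sample SD of area % and mean APD."""
    ids = stats_df["image_id"].unique()
    if len(ids) < 2:
        raise ValueError("cohort table needs at least 2 images")
    rows = []
    for roi, sub in stats_df.groupby("roi"):
        rows.append(
            {
                "roi": int(roi),
                "n": int(len(sub)),
                "area_pct_mean": float(sub["area_pct"].mean()),
                "area_pct_sd": float(sub["area_pct"].std(ddof=1)),
                "mean_apd_mean": float(sub["mean_apd"].mean()),
                "mean_apd_sd": float(sub["mean_apd"].std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)
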