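"""Synthetic hand phantoms with ground-truth masks and 5-ROI label maps.

The phantom is a geometric stand-in for a left-hand radiograph: a bright
hand silhouette (palm ellipse, four finger capsules, a slanted thumb
capsule and a wrist block) on a dark background, with bone-like bright
cores whose contrast and width grow monotonically with an ``age_months``
parameter.  Optional small bright background islands exercise the mask
cleanup, and Gaussian noise exercises thresholding robustness.  Phantoms
are geometric, not photorealistic — they exist to carry exactly the
structural features the pipeline consumes: a maskable silhouette,
disjoint anatomically-roled ROIs, and an age-correlated intensity
signal.

The stored ground-truth mask is the silhouette after a morphological
opening with the same default structuring element the mask generator
uses, so the automatic mask is pixel-identical to the ground truth on a
clean phantom.  ROI roles: 1 wrist band, 2 five disconnected
mid-metacarpal patches, 3 five metacarpal-phalanx joint patches,
4 finger regions, 5 a small thumb-web patch between digits 1 and 2
(always the smallest ROI).

All geometry is defined at the 598-pixel reference scale and scaled
linearly for other frame sizes.  Everything is driven by
``numpy.random.default_rng(seed)`` — no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure, morphology

from pdprobe import io as _io

AGE_RANGE = (15.0, 216.0)  # months; the bone-age test range emulated
_BASE_FRAME = 598


@dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    age_months: float = 120.0
    frame: int = _BASE_FRAME
    background_level: float = 10.0
    tissue_level: float = 80.0
    noise_sd: float = 2.0
    island_count: int = 0
    island_radius: int = 4
    struct_radius: int = 5  # opening radius baked into the silhouette

    def __post_init__(self):
        if not AGE_RANGE[0] <= self.age_months <= AGE_RANGE[1]:
            raise ValueError(
                f"age_months must be in [{AGE_RANGE[0]}, {AGE_RANGE[1]}]"
            )
        if self.frame < 256:
            raise ValueError("frame too small for the hand silhouette")


@dataclass
class PhantomBundle:
    image: np.ndarray          # float64 (frame, frame)
    mask: np.ndarray           # bool ground truth
    labels: np.ndarray         # int, 0-5
    roi_counts: dict           # declared per-ROI pixel counts
    age_months: float
    spec: PhantomSpec = field(repr=False, default=None)


def _seg_dist(shape, p0, p1):
    """Distance from every grid pixel to the segment p0-p1 (row, col)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = p0
    r1, c1 = p1
    dr, dc = r1 - r0, c1 - c0
    len2 = dr * dr + dc * dc
    if len2 == 0:
        return np.hypot(rr - r0, cc - c0)
    t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / len2, 0.0, 1.0)
    return np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))


def _ellipse(shape, center, semi):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _rect(shape, r0, r1, c0, c1):
    out = np.zeros(shape, dtype=bool)
    out[max(r0, 0) : r1, max(c0, 0) : c1] = True
    return out


def _disk(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate one phantom; identical specs give bit-identical bundles."""
    rng = np.random.default_rng(spec.seed)
    s = spec.frame / _BASE_FRAME
    shape = (spec.frame, spec.frame)

    def S(v):  # scale a base-frame coordinate / length
        return v * s

    # small seeded geometry jitter (base-frame units)
    tip_jit = rng.integers(-8, 9, size=4)
    palm_jit = rng.integers(-5, 6, size=2)
    thumb_jit = rng.integers(-6, 7, size=2)

    finger_cols = [225.0, 275.0, 325.0, 375.0]
    finger_tips = [150.0 + tip_jit[0], 130.0 + tip_jit[1],
                   140.0 + tip_jit[2], 170.0 + tip_jit[3]]
    finger_r = 16.0
    palm_c = (385.0 + palm_jit[0], 300.0 + palm_jit[1])
    palm_semi = (90.0, 105.0)
    thumb_p0 = (370.0, 210.0)
    thumb_p1 = (290.0 + thumb_jit[0], 110.0 + thumb_jit[1])
    thumb_r = 18.0

    silhouette = _ellipse(shape, (S(palm_c[0]), S(palm_c[1])),
                          (S(palm_semi[0]), S(palm_semi[1])))
    silhouette |= _rect(shape, int(S(460)), int(S(560)), int(S(240)), int(S(360)))
    thumb_d = _seg_dist(shape, (S(thumb_p0[0]), S(thumb_p0[1])),
                        (S(thumb_p1[0]), S(thumb_p1[1])))
    silhouette |= thumb_d <= S(thumb_r)
    for col, tip in zip(finger_cols, finger_tips):
        d = _seg_dist(shape, (S(330), S(col)), (S(tip), S(col)))
        silhouette |= d <= S(finger_r)

    # bake the default opening into the silhouette so a clean phantom's
    # generated mask is pixel-identical to the ground truth
    opened = morphology.opening(silhouette, morphology.disk(spec.struct_radius))
    labeled = measure.label(opened, connectivity=2)
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    mask = labeled == int(np.argmax(counts))
    if not mask.any():
        raise ValueError("frame too small: silhouette vanished under opening")

    rr = np.mgrid[0 : shape[0], 0 : shape[1]][0]

    # ---- ROI label map (assignment order protects the small regions) ----
    labels = np.zeros(shape, dtype=np.int64)

    def assign(region, lbl):
        sel = region & mask & (labels == 0)
        labels[sel] = lbl

    # ROI 1: wrist band
    assign(rr >= S(440), 1)
    # ROI 3: five MP-joint patches
    for col in finger_cols:
        assign(_disk(shape, (S(315), S(col)), S(12)), 3)
    assign(_disk(shape, (S(335), S(165)), S(10)), 3)
    # ROI 5: thumb-web muscle patch between digits 1 and 2 (smallest)
    assign(_disk(shape, (S(350), S(198)), S(13)), 5)
    # ROI 2: five disconnected mid-metacarpal bands
    for col in finger_cols:
        assign(_rect(shape, int(S(360)), int(S(408)),
                     int(S(col - 14)), int(S(col + 15))), 2)
    assign(_rect(shape, int(S(412)), int(S(448)), int(S(205)), int(S(236))), 2)
    # ROI 4: fingers (everything distal of the MP joints) + distal thumb
    assign((rr <= S(295)) | ((thumb_d <= S(thumb_r)) &
           (np.mgrid[0 : shape[0], 0 : shape[1]][1] <= S(165))), 4)

    roi_counts = {int(k): int(v) for k, v in
                  zip(*np.unique(labels[labels > 0], return_counts=True))}

    # ---- age-dependent bone cores ----
    t = (spec.age_months - AGE_RANGE[0]) / (AGE_RANGE[1] - AGE_RANGE[0])
    amp = 50.0 + 0.45 * spec.age_months          # core contrast, strictly inc.
    width = S(6.0 * (0.7 + 0.3 * t))             # core half-width, strictly inc.
    cores = np.zeros(shape)
    segs = []
    for col in finger_cols:  # metacarpals converge toward the wrist
        base_col = 300.0 + 0.62 * (col - 300.0)
        segs.append(((455.0, base_col), (345.0, col)))
        segs.append(((325.0, col), (finger_tips[finger_cols.index(col)] + 10.0, col)))
    segs.append(((450.0, 250.0), (365.0, 200.0)))   # thumb metacarpal
    segs.append((thumb_p0, thumb_p1))               # thumb phalanges
    for p0, p1 in segs:
        d = _seg_dist(shape, (S(p0[0]), S(p0[1])), (S(p1[0]), S(p1[1])))
        cores += amp * np.exp(-((d / width) ** 2))
    for cc0 in (275.0, 305.0, 335.0):               # carpal blobs
        d = _seg_dist(shape, (S(458), S(cc0)), (S(458), S(cc0)))
        cores += amp * np.exp(-((d / (1.6 * width)) ** 2))

    image = np.full(shape, spec.background_level)
    image += (spec.tissue_level + cores) * mask

    # bright background islands (mask-cleanup fixtures), kept in the top
    # margin band, far from the silhouette
    if spec.island_count > 0:
        cols_avail = np.arange(int(S(60)), int(S(540)), max(int(S(60)), 1))
        picks = rng.choice(cols_avail, size=min(spec.island_count, cols_avail.size),
                           replace=False)
        row_band = rng.integers(int(S(25)), int(S(55)) + 1, size=picks.size)
        for cr, cc0 in zip(row_band, picks):
            image[_disk(shape, (cr, cc0), spec.island_radius)] = (
                spec.background_level + spec.tissue_level
            )
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)
    image = np.clip(image, 0.0, None)

    return PhantomBundle(image=image, mask=mask, labels=labels,
                         roi_counts=roi_counts, age_months=spec.age_months,
                         spec=spec)


def make_cohort(
    n: int,
    seed: int = 0,
    age_range: tuple = AGE_RANGE,
    out_dir=None,
    **spec_overrides,
):
    """n phantoms with ages uniform on ``age_range`` under one master seed.

    Returns ``(bundles, ages)`` where ``ages`` maps image id to
    age_months; with ``out_dir`` the phantoms and an ``ages.csv`` are
    also written to disk.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    bundles, age_map = [], {}
    for i, (age, child) in enumerate(zip(ages, child_seeds)):
        spec = PhantomSpec(seed=int(child), age_months=float(age), **spec_overrides)
        bundle = make_phantom(spec)
        image_id = f"ph{i:03d}"
        bundles.append((image_id, bundle))
        age_map[image_id] = float(age)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for image_id, bundle in bundles:
            write_bundle(bundle, out_dir, image_id)
        _io.write_ages_csv(out_dir / "ages.csv", age_map)
    return bundles, age_map


def write_bundle(bundle: PhantomBundle, out_dir, image_id: str) -> None:
    """Write ``<id>_image.png`` (16-bit), ``<id>_mask.png``, ``<id>_labels.png``."""
    out_dir = Path(out_dir)
    _io.write_gray_png(out_dir / f"{image_id}_image.png", bundle.image, bits=16)
    _io.write_mask_png(out_dir / f"{image_id}_mask.png", bundle.mask)
    _io.write_labels_png(out_dir / f"{image_id}_labels.png", bundle.labels)
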