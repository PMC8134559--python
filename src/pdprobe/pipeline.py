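"""End-to-end run orchestration: preprocess -> probe -> ROI stats -> render.

A run consumes a directory of ``<id>_image.png`` grayscale images with
optional ``<id>_mask.png`` / ``<id>_labels.png`` companions and an
``ages.csv`` (columns image_id, age_months), and produces per image a
packed model-input PNG, a PD-map CSV, an overlay PNG and ROI stats rows,
plus cohort descriptive and trend-regression CSVs and a machine-readable
manifest.  Images are processed in isolation: one failure is logged and
skipped, and the run fails only if every image fails.  Re-running on a
completed output directory reuses the per-image artifacts (stage status
is tracked in the manifest), so repeated runs are cheap and
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from pdprobe import io as _io
from pdprobe import roi as _roi
from pdprobe import saliency, visualize
from pdprobe.config import dump_config, parse_config
from pdprobe.models import load_surrogate_config
from pdprobe.preprocess import PreprocessConfig, preprocess_image

logger = logging.getLogger(__name__)

_CSV_FMT = "%.17g"  # full float64 precision -> bit-identical reruns


@dataclass
class RunConfig:
    input_dir: str = ""
    out_dir: str = ""
    model_config: str = ""
    region: str = "mask"
    step: float = 1.0
    batch_size: int = 32
    background_estimator: str = "low-percentile"
    background_value: float = 1.0
    threshold: str = "otsu"
    threshold_value: Optional[float] = None
    struct_radius: int = 5
    margin_frac: float = 0.0
    flip: bool = False
    overlay_threshold: Optional[float] = None  # None -> 4e-3 inside / 4e-2 outside
    overlay_cmap: str = "bwr"
    overlay_opacity: float = 0.5
    normalization_rois: str = "1,2,3,4"
    seed: int = 0
    verbose: bool = False

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            background_estimator=self.background_estimator,
            background_value=self.background_value,
            threshold=self.threshold,
            threshold_value=self.threshold_value,
            struct_radius=self.struct_radius,
            margin_frac=self.margin_frac,
            flip=self.flip,
        )

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = parse_config(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        Path(path).write_text(dump_config(self.as_dict()))


def _discover_images(input_dir: Path):
    ids = sorted(p.name[: -len("_image.png")] for p in input_dir.glob("*_image.png"))
    if not ids:
        raise FileNotFoundError(f"no *_image.png inputs in {input_dir}")
    return ids


def _stage_done(entry: dict, stage: str, files) -> bool:
    return entry.get(stage) in ("done", "cached") and all(Path(f).exists() for f in files)


def run_pipeline(config: RunConfig) -> Path:
    """Execute (or resume) a full run; returns the output directory."""
    input_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("pdprobe")
    root.addHandler(handler)
    root.setLevel(logging.DEBUG if config.verbose else logging.INFO)

    try:
        return _run(config, input_dir, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, input_dir: Path, out_dir: Path) -> Path:
    config_text = dump_config(config.as_dict())
    (out_dir / "config.txt").write_text(config_text)
    config_hash = hashlib.sha256(config_text.encode()).hexdigest()

    manifest_path = out_dir / "manifest.json"
    manifest = {"config_hash": config_hash, "images": {}, "files": []}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") == config_hash:
            manifest["images"] = previous.get("images", {})
        else:
            logger.info("config changed; recomputing everything")

    model = load_surrogate_config(config.model_config)
    ids = _discover_images(input_dir)
    ages_path = input_dir / "ages.csv"
    ages = _io.read_ages_csv(ages_path) if ages_path.exists() else {}
    pp_cfg = config.preprocess_config()
    norm_set = tuple(int(t) for t in config.normalization_rois.split(","))

    stats_frames = []
    n_failed = 0
    files: list = ["config.txt", "manifest.json", "run.log"]

    for image_id in ids:
        entry = manifest["images"].setdefault(image_id, {})
        paths = {
            "packed": out_dir / f"{image_id}_packed.png",
            "mask299": out_dir / f"{image_id}_mask299.png",
            "labels299": out_dir / f"{image_id}_labels299.png",
            "pd": out_dir / f"{image_id}_pd.csv",
            "overlay": out_dir / f"{image_id}_overlay.png",
        }
        t0 = time.perf_counter()
        try:
            has_labels = (input_dir / f"{image_id}_labels.png").exists()

            stage_files = [paths["packed"], paths["mask299"]]
            if has_labels:
                stage_files.append(paths["labels299"])
            if _stage_done(entry, "preprocess", stage_files):
                entry["preprocess"] = "cached"
                packed = _io.read_packed_png(paths["packed"])
                mask299 = _io.read_mask_png(paths["mask299"])
                labels299 = (
                    _io.read_labels_png(paths["labels299"]) if has_labels else None
                )
            else:
                image = _io.read_gray_png(input_dir / f"{image_id}_image.png")
                user_mask_path = input_dir / f"{image_id}_mask.png"
                user_mask = (
                    _io.read_mask_png(user_mask_path)
                    if user_mask_path.exists()
                    else None
                )
                labels = (
                    _io.read_labels_png(input_dir / f"{image_id}_labels.png")
                    if has_labels
                    else None
                )
                res = preprocess_image(image, pp_cfg, mask=user_mask, labels=labels)
                packed, mask299, labels299 = res.packed, res.mask299, res.labels299
                _io.write_packed_png(paths["packed"], packed)
                _io.write_mask_png(paths["mask299"], mask299)
                if labels299 is not None:
                    _io.write_labels_png(paths["labels299"], labels299)
                entry["preprocess"] = "done"

            if _stage_done(entry, "probe", [paths["pd"]]):
                entry["probe"] = "cached"
                pdmap = saliency.load_pd_csv(paths["pd"])
            else:
                pdmap = saliency.batch_pd_map(
                    model,
                    packed,
                    config.region,
                    step=config.step,
                    batch_size=config.batch_size,
                    mask=mask299,
                    labels=labels299,
                )
                saliency.save_pd_csv(pdmap, paths["pd"])
                entry["probe"] = "done"

            if _stage_done(entry, "render", [paths["overlay"]]):
                entry["render"] = "cached"
            else:
                threshold = config.overlay_threshold
                if threshold is None:
                    threshold = (
                        visualize.DEFAULT_THRESHOLD_OUTSIDE
                        if config.region == "outside"
                        else visualize.DEFAULT_THRESHOLD_INSIDE
                    )
                overlay = visualize.render_overlay(
                    pdmap,
                    np.asarray(packed, dtype=np.float64).mean(axis=2),
                    visualize.OverlaySpec(
                        threshold=threshold,
                        cmap=config.overlay_cmap,
                        opacity=config.overlay_opacity,
                    ),
                )
                visualize.save_overlay_png(paths["overlay"], overlay)
                entry["render"] = "done"

            if labels299 is not None:
                stats_frames.append(
                    _roi.image_roi_stats(
                        pdmap, labels299, mask299, image_id,
                        normalization_set=norm_set,
                    )
                )
            entry["seconds"] = round(time.perf_counter() - t0, 3)
            entry["status"] = "ok"
            files += [p.name for p in paths.values() if p.exists()]
            logger.info("%s: ok (%.2fs)", image_id, entry["seconds"])
        except Exception as exc:  # per-image isolation
            n_failed += 1
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            logger.exception("%s: failed", image_id)

    if n_failed == len(ids):
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError("all images failed; see run.log")

    if stats_frames:
        import pandas as pd

        stats_df = pd.concat(stats_frames, ignore_index=True)
        stats_df.to_csv(out_dir / "stats.csv", index=False, float_format=_CSV_FMT)
        files.append("stats.csv")
        if stats_df["image_id"].nunique() >= 2:
            _roi.cohort_table(stats_df).to_csv(
                out_dir / "cohort.csv", index=False, float_format=_CSV_FMT
            )
            files.append("cohort.csv")
        if ages:
            trends = _roi.cohort_trends(stats_df, ages)
            if len(trends):
                trends.to_csv(
                    out_dir / "regression.csv", index=False, float_format=_CSV_FMT
                )
                files.append("regression.csv")

    manifest["files"] = sorted(set(files))
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir
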