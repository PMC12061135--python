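"""End-to-end orchestration: phantom cohorts or tomogram directories in,
labels, per-cell metrics, cohort statistics and growth summaries out.

A run is fully described by a :class:`RunConfig` (loadable from YAML) and a
seed; the manifest written into the run directory records the config hash,
seed and per-stage counts, and a rerun with the same config and seed
produces a byte-identical ``cells.csv``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError, DiatomHTError
from .morpho import build_cell_record
from .phantom import CohortSpec, GrowthSpec, PhantomSpec, generate_cohort, generate_growth
from .segment import SegmentationConfig, segment_by_ri
from .stats import (
    DEFAULT_FEATURES,
    centroid_table,
    distance_table,
    growth_summary_table,
    summary_table,
    ttest_table,
)
from .tomio import read_tomogram, write_growth_csv, write_labelmap, write_metrics_csv, records_to_frame

logger = logging.getLogger(__name__)

#: metrics reported in the per-time t-test tables
DEFAULT_TEST_METRICS = (
    "whole_mean_ri", "whole_concentration_pg_um3",
    "delta_mean_ri", "complement_concentration",
)


@dataclass
class RunConfig:
    """One pipeline run: exactly one input mode, all stage configs, one seed."""

    mode: str = "phantom"  # "phantom" | "directory"
    out_dir: str | Path = "run"
    seed: int = 0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    growth: GrowthSpec | None = None
    input_dir: str | Path | None = None
    reference_condition: str = "CTRL"
    standardize_distances: bool = False
    save_labels: bool = True
    skip_bad: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in {"phantom", "directory"}:
            raise ConfigError(f"mode must be 'phantom' or 'directory', got {self.mode!r}")
        if self.mode == "directory":
            if self.input_dir is None:
                raise ConfigError("directory mode requires input_dir")
            if not Path(self.input_dir).is_dir():
                raise ConfigError(f"input_dir does not exist: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "segmentation" in raw:
            seg = raw.pop("segmentation")
            if "intervals" in seg:
                seg["intervals"] = {k: tuple(v) for k, v in seg["intervals"].items()}
            if "precedence" in seg:
                seg["precedence"] = tuple(seg["precedence"])
            kwargs["segmentation"] = SegmentationConfig(**seg)
        for key, cls_ in (("phantom", PhantomSpec), ("cohort", CohortSpec), ("growth", GrowthSpec)):
            if key in raw and raw[key] is not None:
                section = raw.pop(key)
                for f in dataclasses.fields(cls_):
                    if f.name in section and isinstance(section[f.name], list):
                        section[f.name] = tuple(
                            tuple(v) if isinstance(v, list) else v for v in section[f.name]
                        )
                kwargs[key] = cls_(**section)
        kwargs.update(raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            if isinstance(obj, Path):
                return str(obj)
            return str(obj)
        payload = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _iter_cells(config: RunConfig):
    """Yield (tomogram, labelmap-or-None, annotations) per cell for either mode."""
    if config.mode == "phantom":
        cohort = dataclasses.replace(config.cohort, seed=config.seed)
        for tomo, labelmap, ann in generate_cohort(cohort, config.phantom, config.segmentation):
            yield tomo, ann
    else:
        paths = sorted(
            p for p in Path(config.input_dir).iterdir()
            if p.suffix.lower() in {".tif", ".tiff", ".h5", ".hdf5"}
        )
        if not paths:
            raise ConfigError(f"no tomogram files found in {config.input_dir}")
        for p in paths:
            try:
                tomo = read_tomogram(p)
            except Exception as exc:
                raise DiatomHTError(f"failed to read tomogram {p.name}: {exc}") from exc
            ann = {"cell_id": p.stem, **tomo.meta}
            yield tomo, ann


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Stages: segment each tomogram → per-cell metrics (``cells.csv``) →
    statistics (``stats/``: t-tests, group summaries, centroids, centroid
    distances) → growth summary if a growth input is configured → manifest.
    A malformed cell halts the run naming the cell and stage, unless
    ``skip_bad`` is set (excluded cells are logged and counted).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_file = logging.FileHandler(out / "run.log")
    logger.addHandler(log_file)
    labels_dir = out / "labels"
    if config.save_labels:
        labels_dir.mkdir(exist_ok=True)

    records = []
    n_seen = n_skipped = 0
    try:
        for tomo, ann in _iter_cells(config):
            n_seen += 1
            cell_id = ann.get("cell_id", f"cell_{n_seen:04d}")
            stage = "segment"
            try:
                labelmap = segment_by_ri(tomo, config.segmentation)
                if config.save_labels:
                    write_labelmap(labelmap, labels_dir / f"{cell_id}.tif")
                stage = "metrics"
                records.append(build_cell_record(tomo, labelmap, config.segmentation, ann))
            except DiatomHTError as exc:
                if config.skip_bad:
                    n_skipped += 1
                    logger.warning("skipping cell %s at stage %s: %s", cell_id, stage, exc)
                    continue
                raise DiatomHTError(f"stage {stage!r} failed for cell {cell_id!r}: {exc}") from exc

        if not records:
            raise DiatomHTError("pipeline produced no cell records")
        frame = records_to_frame(records)
        write_metrics_csv(frame, out / "cells.csv")

        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        metrics = [m for m in DEFAULT_TEST_METRICS if m in frame.columns]
        ttest_table(frame, metrics, config.reference_condition).to_csv(
            stats_dir / "ttests.csv", index=False)
        summary_table(frame, metrics).to_csv(stats_dir / "summaries.csv", index=False)
        centroid_table(frame, DEFAULT_FEATURES).to_csv(stats_dir / "centroids.csv", index=False)
        distance_table(frame, config.reference_condition, DEFAULT_FEATURES,
                       config.standardize_distances).to_csv(stats_dir / "distances.csv", index=False)

        n_growth = 0
        if config.growth is not None:
            growth_spec = dataclasses.replace(config.growth, seed=config.seed)
            growth = generate_growth(growth_spec)
            write_growth_csv(growth, out / "growth.csv")
            growth_summary_table(growth, config.reference_condition).to_csv(
                out / "growth_summary.csv", index=False)
            n_growth = len(growth.table)

        manifest = {
            "diatomht_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "mode": config.mode,
            "n_cells_seen": n_seen,
            "n_cells_skipped": n_skipped,
            "n_cells_recorded": len(records),
            "n_growth_observations": n_growth,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        logger.removeHandler(log_file)
        log_file.close()
    return out
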