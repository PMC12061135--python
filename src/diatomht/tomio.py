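"""Readers and writers for tomograms, label maps, metrics tables and growth tables.

Conventions used throughout the package:

* Volumes are stored z-slowest, i.e. arrays are indexed ``(z, y, x)``.
* ``voxel_size`` is ``(dx, dy, dz)`` in micrometres, so ``voxel_size[2]``
  (dz) corresponds to array axis 0.
* Units: lengths in µm, volumes in µm³, dry mass in pg, concentration in
  pg/µm³.  With these units 1 mL/g ≡ 1 µm³/pg, so the specific refractive
  increment can be quoted interchangeably in either.

On-disk formats are open interchange formats: multi-page float32 TIFF or
HDF5 (dataset ``"ri"``) for RI volumes, uint8 TIFF plus a JSON legend
sidecar for label maps, CSV for metrics, CSV/XLSX for growth counts.
TIFF volumes carry their metadata in a ``<file>.json`` sidecar because
baseline TIFF has no standard slot for voxel spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

try:  # h5py is a hard dependency, but keep the import failure readable
    import h5py
except ImportError as _exc:  # pragma: no cover
    raise ImportError("diatomht requires h5py for HDF5 tomogram IO") from _exc

from .errors import IntegrityError, MetadataError, ValidationError

# RI sanity envelope for aqueous biological samples.
RI_MIN = 1.0
RI_MAX = 1.6

#: Compartment label legend, fixed across the package.
LABEL_LEGEND = {
    0: "background",
    1: "frustule",
    2: "protoplasm",
    3: "vacuole",
    4: "chloroplast",
}
LABEL_OF = {name: code for code, name in LABEL_LEGEND.items()}
COMPARTMENTS = ("frustule", "protoplasm", "vacuole", "chloroplast")

#: Metadata keys carried by a Tomogram.
META_KEYS = ("condition", "time_point", "fixation", "cell_id")


@dataclass
class Tomogram:
    """A 3D refractive-index field with voxel spacing and cohort annotations.

    Parameters
    ----------
    ri:
        float array indexed ``(z, y, x)``; dimensionless refractive index.
    voxel_size:
        ``(dx, dy, dz)`` in µm.
    meta:
        free-form annotations; recognised keys are ``condition``,
        ``time_point``, ``fixation`` and ``cell_id``.
    """

    ri: np.ndarray
    voxel_size: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ri = np.asarray(self.ri)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.validate()

    def validate(self) -> None:
        if self.ri.ndim != 3:
            raise ValidationError(f"tomogram must be 3D, got ndim={self.ri.ndim}")
        if min(self.ri.shape) < 4:
            raise ValidationError(f"degenerate tomogram shape {self.ri.shape}; all dims must be >= 4")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        lo, hi = float(self.ri.min()), float(self.ri.max())
        if lo < RI_MIN or hi > RI_MAX:
            raise ValidationError(
                f"RI outside the physical envelope [{RI_MIN}, {RI_MAX}]: min={lo:.4f}, max={hi:.4f}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ri.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class LabelMap:
    """Per-voxel compartment labels aligned with a :class:`Tomogram`."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    legend: dict = field(default_factory=lambda: dict(LABEL_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.validate()

    def validate(self) -> None:
        if self.labels.ndim != 3:
            raise ValidationError(f"label map must be 3D, got ndim={self.labels.ndim}")
        present = set(np.unique(self.labels).tolist())
        allowed = set(self.legend)
        if not present <= allowed:
            raise ValidationError(f"labels {sorted(present - allowed)} not in legend {sorted(allowed)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, compartment: str) -> np.ndarray:
        """Boolean mask of one named compartment."""
        return self.labels == LABEL_OF[compartment]


@dataclass
class GrowthSeries:
    """Cell-count trajectories: long table with columns
    ``time_h, condition, replicate, density_cells_per_ml``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time_h", "condition", "replicate", "density_cells_per_ml"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"growth table missing columns: {sorted(missing)}")
        if (self.table["density_cells_per_ml"] < 0).any():
            bad = self.table.loc[self.table["density_cells_per_ml"] < 0].iloc[0]
            raise ValidationError(f"negative density {bad['density_cells_per_ml']} at t={bad['time_h']} h")
        # canonical ordering makes the series independent of input row order
        self.table = (
            self.table.sort_values(["condition", "replicate", "time_h"], kind="mergesort")
            .reset_index(drop=True)
        )
        for (cond, rep), grp in self.table.groupby(["condition", "replicate"], sort=False):
            t = grp["time_h"].to_numpy(float)
            if not np.all(np.diff(t) > 0):
                raise ValidationError(f"times not strictly increasing for {cond!r} replicate {rep!r}")

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.table["time_h"].to_numpy(float))

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique().tolist())

    def final_densities(self, condition: str) -> np.ndarray:
        """Replicate densities at the last shared time point of a condition."""
        sub = self.table[self.table["condition"] == condition]
        if sub.empty:
            raise ValidationError(f"unknown condition {condition!r}")
        t_final = sub["time_h"].max()
        return sub.loc[sub["time_h"] == t_final, "density_cells_per_ml"].to_numpy(float)


# ---------------------------------------------------------------------------
# volume IO
# ---------------------------------------------------------------------------

def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in {".h5", ".hdf5", ".hdf"}


def write_tomogram(tomo: Tomogram, path: str | Path) -> Path:
    """Write a tomogram as multi-page float32 TIFF (+ JSON sidecar) or HDF5."""
    path = Path(path)
    data = tomo.ri.astype(np.float32)
    meta = {k: tomo.meta.get(k) for k in META_KEYS if tomo.meta.get(k) is not None}
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("ri", data=data)
            ds.attrs["voxel_size_um"] = np.asarray(tomo.voxel_size, dtype=float)
            for k, v in meta.items():
                ds.attrs[k] = v
    else:
        tifffile.imwrite(path, data)
        sidecar = {"voxel_size_um": list(tomo.voxel_size), **meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_tomogram(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
    force_override: bool = False,
) -> Tomogram:
    """Read a tomogram written by :func:`write_tomogram`.

    File metadata wins over ``voxel_size_override`` unless ``force_override``
    is set; the override is the only source of spacing for bare TIFFs with no
    sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    voxel_size = None
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "ri" not in f:
                raise MetadataError(f"{path}: HDF5 file has no 'ri' dataset")
            ds = f["ri"]
            data = ds[...]
            if "voxel_size_um" in ds.attrs:
                voxel_size = tuple(float(v) for v in np.asarray(ds.attrs["voxel_size_um"]).ravel())
            for k in META_KEYS:
                if k in ds.attrs:
                    v = ds.attrs[k]
                    meta[k] = v.decode() if isinstance(v, bytes) else str(v)
    else:
        data = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
            if "voxel_size_um" in info:
                voxel_size = tuple(float(v) for v in info["voxel_size_um"])
            meta = {k: info[k] for k in META_KEYS if k in info}
    if force_override and voxel_size_override is not None:
        voxel_size = tuple(voxel_size_override)
    elif voxel_size is None:
        if voxel_size_override is None:
            raise MetadataError(f"{path}: no voxel size in metadata and no override given")
        voxel_size = tuple(voxel_size_override)
    return Tomogram(ri=data, voxel_size=voxel_size, meta=meta)


def write_labelmap(labelmap: LabelMap, path: str | Path) -> Path:
    """Write labels as uint8 TIFF with the legend in a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, labelmap.labels.astype(np.uint8))
    sidecar = {
        "voxel_size_um": list(labelmap.voxel_size),
        "legend": {str(k): v for k, v in labelmap.legend.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_labelmap(path: str | Path) -> LabelMap:
    path = Path(path)
    labels = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise MetadataError(f"{path}: missing legend sidecar {sidecar.name}")
    info = json.loads(sidecar.read_text())
    legend = {int(k): v for k, v in info["legend"].items()}
    return LabelMap(labels=labels, voxel_size=tuple(info["voxel_size_um"]), legend=legend)


# ---------------------------------------------------------------------------
# metrics tables
# ---------------------------------------------------------------------------

#: per-region metric column stems; sphericity is reported for the whole cell only
REGIONS = ("whole", "chloroplast", "complement")
REGION_METRIC_NAMES = ("volume_um3", "mean_ri", "dry_mass_pg", "concentration_pg_um3")

METRICS_COLUMNS = (
    ["cell_id", "condition", "time_point", "fixation"]
    + [f"{r}_{m}" for r in REGIONS for m in REGION_METRIC_NAMES]
    + ["whole_sphericity", "delta_mean_ri", "complement_concentration"]
)


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Flatten CellRecords into the canonical metrics table (one row per cell)."""
    from .morpho import CellRecord  # deferred: morpho imports tomio types

    rows = []
    for rec in records:
        if not isinstance(rec, CellRecord):
            raise TypeError(f"expected CellRecord, got {type(rec).__name__}")
        rows.append(rec.as_row())
    frame = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    dups = frame.duplicated(subset=["cell_id", "condition", "time_point"])
    if dups.any():
        bad = frame.loc[dups, "cell_id"].iloc[0]
        raise IntegrityError(f"duplicate cell id {bad!r} within a condition/time group")
    return frame


def write_metrics_csv(records: Sequence, path: str | Path) -> Path:
    """One row per cell; absent regions produce empty cells, never dropped rows."""
    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"cell_id": str, "condition": str, "time_point": str, "fixation": str})
    missing = set(METRICS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"metrics table missing columns: {sorted(missing)}")
    dups = frame.duplicated(subset=["cell_id", "condition", "time_point"])
    if dups.any():
        raise IntegrityError(f"duplicate cell id {frame.loc[dups, 'cell_id'].iloc[0]!r}")
    return frame


def read_metrics_records(path: str | Path) -> list:
    """Read a metrics CSV back into CellRecord objects (lossless round trip)."""
    from .morpho import CellRecord

    return [CellRecord.from_row(row) for _, row in read_metrics_csv(path).iterrows()]


# ---------------------------------------------------------------------------
# growth tables
# ---------------------------------------------------------------------------

GROWTH_COLUMNS = ("time_h", "condition", "replicate", "density_cells_per_ml")


def read_growth_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sheet: str | int = 0,
) -> GrowthSeries:
    """Read growth counts from CSV or XLSX.

    ``column_map`` maps the file's column names onto the canonical schema
    ``{file_column: canonical_column}`` — the documented one-time mapping for
    externally formatted tables (e.g. a study's supplementary spreadsheet).
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = set(GROWTH_COLUMNS) - set(raw.columns)
    if missing:
        raise ValidationError(f"growth table missing columns: {sorted(missing)} (use column_map)")
    table = raw.loc[:, list(GROWTH_COLUMNS)].copy()
    table["time_h"] = table["time_h"].astype(float)
    table["density_cells_per_ml"] = table["density_cells_per_ml"].astype(float)
    table["condition"] = table["condition"].astype(str)
    return GrowthSeries(table=table)


def write_growth_csv(series: GrowthSeries, path: str | Path) -> Path:
    path = Path(path)
    series.table.to_csv(path, index=False)
    return path
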