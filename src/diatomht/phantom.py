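"""Synthetic diatom phantoms, cohorts and growth curves with ground truth.

The phantom emulates a single chain-forming centric diatom: a hollow
cylindrical silica shell (frustule) with end valves, protoplasm filling the
interior, spherical vacuoles and ellipsoidal chloroplast lobes.  Per-voxel
RI is drawn from truncated Gaussians confined to each compartment's
refractive-index band, then degraded by an axial Gaussian blur (a stand-in
for the missing-cone elongation of transmission tomography) and additive
Gaussian noise.  The pre-blur labels are the ground truth.

Heavy-metal stress is modelled as a multiplicative depression of the RI
contrast (RI − medium) of all non-chloroplast compartments — the chloroplast
is deliberately left untouched, matching the observation that it carries no
dose signal.  Growth is logistic with a per-condition inhibition factor on
the rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, SizingError, ValidationError
from .segment import SegmentationConfig, recoverable_intervals
from .tomio import COMPARTMENTS, LABEL_OF, GrowthSeries, LabelMap, Tomogram

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

#: default per-compartment RI means: centres of the published bands
#: (frustule slightly low, inside its uniquely recoverable sub-band)
DEFAULT_RI_MEAN = {
    "frustule": 1.3560,
    "protoplasm": 1.3705,
    "vacuole": 1.3915,
    "chloroplast": 1.4155,
}
#: within-compartment RI texture; small relative to the band widths
#: (0.007–0.041) so ground truth stays recoverable under instrument noise —
#: between-cell variation is modelled separately by the cohort jitter
DEFAULT_RI_SD = {name: 0.0005 for name in COMPARTMENTS}


@dataclass
class PhantomSpec:
    """Geometry and optics of one synthetic cell.

    Lengths in µm.  The cylinder axis runs along x (the fast array axis);
    z is the optical axis carrying the blur.  Defaults approximate a small
    *Skeletonema*-like cell; the species' true dimensions are not published,
    so radius/length are plausible placeholders, not literature values.
    """

    cell_radius: float = 2.5
    cell_length: float = 8.0
    frustule_thickness: float = 0.4
    n_chloroplast_lobes: int = 2
    chloroplast_lobe_radius: float = 0.9
    n_vacuoles: int = 2
    vacuole_radius: float = 1.2
    ri_mean: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RI_MEAN))
    ri_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RI_SD))
    medium_ri: float = 1.339
    noise_sd: float = 0.0
    axial_blur_sigma: float = 0.05  # µm along z
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.2)  # (dx, dy, dz)
    grid_shape: tuple[int, int, int] = (40, 64, 96)  # (z, y, x)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, config: SegmentationConfig | None = None) -> None:
        if self.frustule_thickness >= self.cell_radius:
            raise ConfigError("frustule_thickness must be smaller than cell_radius")
        for name in ("cell_radius", "cell_length", "frustule_thickness",
                     "chloroplast_lobe_radius", "vacuole_radius"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigError(f"voxel sizes must be positive, got {self.voxel_size}")
        if self.n_chloroplast_lobes < 0 or self.n_vacuoles < 0:
            raise ConfigError("component counts must be non-negative")
        if self.noise_sd < 0 or self.axial_blur_sigma < 0:
            raise ConfigError("noise_sd and axial_blur_sigma must be non-negative")
        intervals = (config or SegmentationConfig()).intervals
        for name in COMPARTMENTS:
            lo, hi = intervals[name]
            if not (lo <= self.ri_mean[name] <= hi):
                raise ConfigError(
                    f"ri_mean[{name!r}]={self.ri_mean[name]} outside its band [{lo}, {hi}]"
                )
            if self.ri_sd[name] < 0:
                raise ConfigError(f"ri_sd[{name!r}] must be non-negative")
        self._check_grid()

    def _check_grid(self) -> None:
        # cell half-extents in µm per axis (z, y, x); 2-voxel margin each side
        dx, dy, dz = self.voxel_size
        nz, ny, nx = self.grid_shape
        extents = {
            "z": (2 * self.cell_radius, dz, nz),
            "y": (2 * self.cell_radius, dy, ny),
            "x": (self.cell_length, dx, nx),
        }
        for axis, (extent, vs, n) in extents.items():
            need = math.ceil(extent / vs) + 4
            if n < need:
                raise SizingError(
                    f"grid too small along {axis}: need >= {need} voxels "
                    f"for a {extent:.2f} µm extent at {vs} µm spacing, got {n}"
                )


@dataclass
class CohortSpec:
    """A dose × time cohort of phantom cells with injected stress effects.

    ``effects`` maps a condition label to the fractional depression of
    non-chloroplast RI contrast at full effect; ``time_profile`` scales it
    per time point (exposure starts after T0).  Conditions whose
    ``adaptation`` flag is set fall back to ``adaptation_residual`` × their
    full effect at the last time point, emulating recovery.  Per-cell
    contrast and geometry jitter give the cohort realistic between-cell
    variance (without it every downstream test statistic is degenerate).
    """

    conditions: tuple = (
        ("CTRL", 0.0, None),
        ("Cd-10", 10.0, "Cd"),
        ("Cd-25", 25.0, "Cd"),
        ("Cu-10", 10.0, "Cu"),
        ("Cu-25", 25.0, "Cu"),
    )
    time_points: tuple[str, ...] = ("T0", "T1", "T2", "T3")
    cells_per_group: int = 30
    #: None → derived from dose at 0.014 per µM (0.14 at 10 µM, 0.35 at 25 µM)
    effects: dict[str, float] | None = None
    time_profile: dict[str, float] | None = None  # None → 0 at the first time, 1 after
    #: None → sublethal (dose ≤ 10 µM, non-zero) conditions adapt
    adaptation: dict[str, bool] | None = None
    adaptation_residual: float = 0.0
    ri_jitter_cv: float = 0.05       # per-cell multiplicative contrast jitter
    geometry_jitter_cv: float = 0.05  # per-cell radius/length jitter
    fixation: str = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effects is None:
            self.effects = {label: 0.014 * float(dose) for label, dose, _ in self.conditions}
        if self.time_profile is None:
            self.time_profile = {tp: (0.0 if i == 0 else 1.0)
                                 for i, tp in enumerate(self.time_points)}
        if self.adaptation is None:
            self.adaptation = {label: 0 < float(dose) <= 10
                               for label, dose, _ in self.conditions}
        self.validate()

    def validate(self) -> None:
        if self.cells_per_group < 2:
            raise ConfigError("cells_per_group must be >= 2")
        labels = [c[0] for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigError("condition labels must be unique")
        unknown = set(self.effects) - set(labels)
        if unknown:
            raise ConfigError(f"effects reference unknown conditions: {sorted(unknown)}")
        unknown = set(self.adaptation) - set(labels)
        if unknown:
            raise ConfigError(f"adaptation flags reference unknown conditions: {sorted(unknown)}")
        if any(e < 0 for e in self.effects.values()):
            raise ConfigError("effect sizes must be >= 0")
        if not (0 <= self.adaptation_residual <= 1):
            raise ConfigError("adaptation_residual must be in [0, 1]")
        if self.ri_jitter_cv < 0 or self.geometry_jitter_cv < 0:
            raise ConfigError("jitter CVs must be non-negative")

    def effect_at(self, condition: str, time_point: str) -> float:
        """Fractional contrast depression for one group."""
        base = self.effects.get(condition, 0.0)
        profile = self.time_profile.get(time_point, 1.0)
        if self.adaptation.get(condition, False) and time_point == self.time_points[-1]:
            profile = self.adaptation_residual * self.time_profile.get(self.time_points[1], 1.0) \
                if len(self.time_points) > 1 else self.adaptation_residual
        return base * profile


@dataclass
class GrowthSpec:
    """Logistic growth with per-condition rate inhibition.

    Trajectories follow ``N(t) = K / (1 + ((K - N0)/N0) exp(-r (1 - i) t))``
    with inhibition ``i`` in [0, 1]; ``i = 1`` freezes the culture at the
    inoculum.  Replicate noise is multiplicative lognormal with unit mean.
    """

    initial_density: float = 60_000.0           # cells/mL
    carrying_capacity: float = 1.5e6            # cells/mL
    growth_rate: float = 0.05                   # 1/h
    inhibition: dict[str, float] = field(default_factory=lambda: {
        "CTRL": 0.0, "Cu-10": 0.25, "Cd-10": 0.17, "Cd-25": 0.90, "Cu-25": 0.95,
    })
    times: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    n_replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.initial_density <= 0:
            raise ConfigError("initial_density must be positive")
        if self.carrying_capacity < self.initial_density:
            raise ConfigError("carrying_capacity must be >= initial_density")
        if any(not (0 <= i <= 1) for i in self.inhibition.values()):
            raise ConfigError("inhibition factors must lie in [0, 1]")
        t = np.asarray(self.times, float)
        if t.size < 1 or not np.all(np.diff(t) > 0):
            raise ValidationError(f"sampling times must be strictly increasing, got {self.times}")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _coordinate_grids(spec: PhantomSpec):
    """Centered physical coordinates (µm) per axis, broadcastable to the grid."""
    dx, dy, dz = spec.voxel_size
    nz, ny, nx = spec.grid_shape
    z = (np.arange(nz) - (nz - 1) / 2.0)[:, None, None] * dz
    y = (np.arange(ny) - (ny - 1) / 2.0)[None, :, None] * dy
    x = (np.arange(nx) - (nx - 1) / 2.0)[None, None, :] * dx
    return z, y, x


def _render_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Paint ground-truth labels: frustule shell, protoplasm, vacuoles, lobes."""
    z, y, x = _coordinate_grids(spec)
    R, L, t = spec.cell_radius, spec.cell_length, spec.frustule_thickness
    r2 = y**2 + z**2
    outer = (np.abs(x) <= L / 2) & (r2 <= R**2)
    inner = (np.abs(x) <= L / 2 - t) & (r2 <= (R - t) ** 2)
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[outer & ~inner] = LABEL_OF["frustule"]
    labels[inner] = LABEL_OF["protoplasm"]

    # chloroplast lobe centres first (deterministic): ellipsoids elongated
    # along the cell axis, evenly spaced
    n_lobes = spec.n_chloroplast_lobes
    a = 1.6 * spec.chloroplast_lobe_radius  # semi-axis along x
    b = spec.chloroplast_lobe_radius
    lobe_centers: list[float] = []
    lobe_y = 0.0
    if n_lobes > 0:
        hx_lobe = L / 2 - t - a
        if hx_lobe < 0:
            raise SizingError("chloroplast lobe longer than the cell interior")
        if b > R - t:
            raise SizingError("chloroplast lobe wider than the cell interior")
        # parietal placement: lobes rest against the inner wall on the +y side,
        # leaving the opposite half of the lumen free for vacuoles
        lobe_y = R - t - b
        lobe_centers = [0.0] if n_lobes == 1 else list(np.linspace(-hx_lobe, hx_lobe, n_lobes))

    def sample_vacuole_center(rv: float) -> tuple[float, float, float]:
        # rejection-sample a centre keeping the sphere inside the interior
        # and clear of every chloroplast lobe (so ground-truth vacuoles are
        # never shattered into sub-threshold fragments)
        hx = L / 2 - t - rv
        hr = R - t - rv
        if hx < 0 or hr < 0:
            raise SizingError("vacuole larger than the cell interior")
        for _ in range(1000):
            cx = rng.uniform(-hx, hx)
            cy = rng.uniform(-hr, hr)
            cz = rng.uniform(-hr, hr)
            if cy**2 + cz**2 > hr**2:
                continue
            clear = all(
                ((cx - lx) / (a + rv)) ** 2 + ((cy - lobe_y) / (b + rv)) ** 2
                + (cz / (b + rv)) ** 2 > 1.0
                for lx in lobe_centers
            )
            if clear:
                return cz, cy, cx
        raise SizingError("could not place a vacuole clear of the chloroplast lobes")

    for _ in range(spec.n_vacuoles):
        rv = spec.vacuole_radius
        cz, cy, cx = sample_vacuole_center(rv)
        sphere = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) <= rv**2
        labels[sphere & inner] = LABEL_OF["vacuole"]

    for cx in lobe_centers:
        ell = ((x - cx) / a) ** 2 + ((y - lobe_y) / b) ** 2 + (z / b) ** 2 <= 1.0
        labels[ell & inner] = LABEL_OF["chloroplast"]
    return labels


def _draw_ri(
    labels: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Fill compartments with truncated-Gaussian RI draws on a medium background.

    Draws are clipped to each compartment's uniquely recoverable sub-band
    (see :func:`diatomht.segment.recoverable_intervals`), so a noiseless,
    blur-free phantom segments back to the ground truth exactly.
    """
    bands = recoverable_intervals(config or SegmentationConfig())
    ri = np.full(labels.shape, spec.medium_ri, dtype=np.float64)
    for name in COMPARTMENTS:  # fixed order keeps the draw stream deterministic
        mask = labels == LABEL_OF[name]
        n = int(mask.sum())
        if n == 0:
            continue
        lo, hi = _float32_safe_band(*bands[name])
        vals = rng.normal(spec.ri_mean[name], spec.ri_sd[name], size=n)
        ri[mask] = np.clip(vals.astype(np.float32), lo, hi)
    return ri


def _float32_safe_band(lo: float, hi: float) -> tuple[np.float32, np.float32]:
    """Shrink a band to float32 values that stay inside it after rounding.

    Tomograms are stored float32; a float64 value clipped exactly to a band
    edge can round across it.  Returns the smallest float32 >= lo and the
    largest float32 <= hi.
    """
    lo32 = np.float32(lo)
    if float(lo32) < lo:
        lo32 = np.nextafter(lo32, np.float32(np.inf))
    hi32 = np.float32(hi)
    if float(hi32) > hi:
        hi32 = np.nextafter(hi32, np.float32(-np.inf))
    return lo32, hi32


def _degrade(ri: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Apply axial blur (missing-cone stand-in) then additive noise."""
    dz = spec.voxel_size[2]
    if spec.axial_blur_sigma > 0:
        ri = ndimage.gaussian_filter1d(ri, sigma=spec.axial_blur_sigma / dz, axis=0, mode="nearest")
    if spec.noise_sd > 0:
        ri = ri + rng.normal(0.0, spec.noise_sd, size=ri.shape)
    return np.clip(ri, 1.0, 1.6)


def generate_phantom(
    spec: PhantomSpec,
    config: SegmentationConfig | None = None,
    meta: Mapping | None = None,
    _contrast_scale: float = 1.0,
) -> tuple[Tomogram, LabelMap]:
    """Render one phantom cell: RI tomogram plus pre-blur ground-truth labels.

    Deterministic for a given spec and seed.  ``_contrast_scale`` is the
    internal hook the cohort generator uses to depress non-chloroplast RI
    contrast multiplicatively after rendering.
    """
    spec.validate(config)
    rng = np.random.default_rng(spec.seed)
    labels = _render_labels(spec, rng)
    ri = _draw_ri(labels, spec, rng, config)
    if _contrast_scale != 1.0:
        stressed = (labels > 0) & (labels != LABEL_OF["chloroplast"])
        ri[stressed] = spec.medium_ri + (ri[stressed] - spec.medium_ri) * _contrast_scale
    ri = _degrade(ri, spec, rng)
    tomo = Tomogram(ri=ri.astype(np.float32), voxel_size=spec.voxel_size, meta=dict(meta or {}))
    return tomo, LabelMap(labels=labels, voxel_size=spec.voxel_size)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _jittered_spec(base: PhantomSpec, cohort: CohortSpec, rng: np.random.Generator,
                   cell_seed: int) -> PhantomSpec:
    """Per-cell copy of the base spec with geometry jitter and its own seed."""
    g = 1.0 + cohort.geometry_jitter_cv * rng.standard_normal(4) if cohort.geometry_jitter_cv > 0 \
        else np.ones(4)
    g = np.clip(g, 0.9, 1.1)  # 2 sigma at the default CV; keeps geometry feasible
    return replace(
        base,
        cell_radius=base.cell_radius * float(g[0]),
        cell_length=base.cell_length * float(g[1]),
        chloroplast_lobe_radius=base.chloroplast_lobe_radius * float(g[2]),
        vacuole_radius=base.vacuole_radius * float(g[3]),
        seed=cell_seed,
    )


def generate_cohort(
    cohort: CohortSpec,
    base: PhantomSpec | None = None,
    config: SegmentationConfig | None = None,
) -> Iterator[tuple[Tomogram, LabelMap, dict]]:
    """Yield ``(tomogram, labelmap, annotations)`` for every cell of the cohort.

    Per group, ``cells_per_group`` phantoms whose non-chloroplast RI contrast
    is depressed by the group's effect size; chloroplast RI is identical in
    distribution across groups.  Wrap in ``list()`` to materialise.
    """
    base = base or PhantomSpec()
    master = np.random.default_rng(cohort.seed)
    for label, dose, metal in cohort.conditions:
        for time_point in cohort.time_points:
            effect = cohort.effect_at(label, time_point)
            for i in range(cohort.cells_per_group):
                cell_seed = int(master.integers(0, 2**31 - 1))
                cell_rng = np.random.default_rng(cell_seed + 1)  # jitter stream
                spec_i = _jittered_spec(base, cohort, cell_rng, cell_seed)
                contrast = (1.0 - effect)
                if cohort.ri_jitter_cv > 0:
                    contrast *= float(np.clip(
                        1.0 + cohort.ri_jitter_cv * cell_rng.standard_normal(), 0.5, 1.5))
                ann = {
                    "condition": label,
                    "dose_um": dose,
                    "metal": metal,
                    "time_point": time_point,
                    "fixation": cohort.fixation,
                    "cell_id": f"{label}_{time_point}_{i:03d}",
                }
                tomo, labelmap = generate_phantom(spec_i, config, meta=ann,
                                                  _contrast_scale=contrast)
                yield tomo, labelmap, ann


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def logistic_density(t, n0: float, k: float, rate: float):
    """Closed-form logistic trajectory N(t)."""
    t = np.asarray(t, float)
    if rate == 0.0:
        return np.full_like(t, n0)
    return k / (1.0 + (k - n0) / n0 * np.exp(-rate * t))


def generate_growth(spec: GrowthSpec) -> GrowthSeries:
    """Logistic trajectories per condition with lognormal replicate noise."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    times = np.asarray(spec.times, float)
    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    else:
        sigma = 0.0
    for condition in spec.inhibition:
        rate = spec.growth_rate * (1.0 - spec.inhibition[condition])
        clean = logistic_density(times, spec.initial_density, spec.carrying_capacity, rate)
        for rep in range(1, spec.n_replicates + 1):
            if sigma > 0:
                noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=times.size)
            else:
                noise = np.ones_like(times)
            for t, d in zip(times, clean * noise):
                rows.append({"time_h": t, "condition": condition,
                             "replicate": rep, "density_cells_per_ml": float(d)})
    return GrowthSeries(table=pd.DataFrame(rows))
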