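# Methods

This note records the scientific and numerical choices behind `diatomht`:
what is modelled, which parameters matter, what the synthetic generator does
and does not emulate, and where design was genuinely open.

## 1. RI-interval segmentation

A holotomogram is a scalar refractive-index field stored float32, indexed
`(z, y, x)` with voxel size `(dx, dy, dz)` in µm (z is the optical axis).
Segmentation assigns each voxel the compartment whose closed RI band
contains it:

| compartment | band | note |
|---|---|---|
| frustule | [1.3520, 1.3630] | overlaps protoplasm on [1.3600, 1.3630] |
| protoplasm | [1.3600, 1.3810] | |
| vacuole | [1.3880, 1.3950] | shares 1.3950 with chloroplast |
| chloroplast | [1.3950, 1.4360] | |

The bands are not disjoint and leave a true gap (1.3810–1.3880). Ambiguity
is resolved by an explicit precedence list, default
**chloroplast > vacuole > protoplasm > frustule** — the interior, higher-RI
organelles win. The opposite reading (frustule claims the overlap) is one
config field away; both orders are tested. Gap voxels stay background but
still belong to the whole cell (below), so they contribute to whole-cell
metrics: the whole cell is mask-defined, not label-defined.

Numerical contract: volumes are float32, but band comparisons are made in
float64. Under NumPy's weak scalar promotion a float32 comparison would
round the band edges and move voxels sitting exactly on the shared
vacuole/chloroplast endpoint across the boundary.

Post-processing: connected components smaller than `min_object_size`
(default 27 voxels ≈ a 3³ speckle) are relabelled background, per
compartment. The **whole-cell mask** is the union of the four labels,
morphologically closed (ball radius `closing_radius`, default 2 voxels),
hole-filled, restricted to the largest connected component. Closing and
filling only add voxels, so every label lies inside the mask. The
**chloroplast complement** is the mask minus the chloroplast label; by
construction complement ∪ chloroplast = whole and the two are disjoint,
which makes the dry-mass additivity below exact.

## 2. Morphometrics

For a region mask M with voxel volume dV:

* volume `V = |M|·dV` (µm³)
* mean RI: arithmetic mean of n over M
* dry mass `m = Σ_M max(n − n₀, 0)/α · dV` (pg)
* concentration `m/V` (pg/µm³)
* sphericity `Ψ = π^(1/3)(6V)^(2/3)/A` (whole cell only)

**α and n₀ are not measurable from a tomogram** and must be supplied:
defaults α = 0.185 µm³/pg (the standard protein value of the quantitative
phase literature; silica-rich regions violate the protein assumption, which
is why α is config-exposed) and n₀ = 1.339 (seawater, salinity 36, visible
wavelength). With lengths in µm and mass in pg, 1 mL/g ≡ 1 µm³/pg, so α
needs no unit conversion. Voxels whose RI dips below the medium (possible
under noise) would contribute negative mass; they are clipped to zero
per voxel by default (`clip_negative_mass=False` keeps them signed).

**Surface area.** Voxel-face counting overestimates oblique surfaces by up
to ~50%, so A comes from a marching-cubes triangulation of the mask at level
0.5 with the physical spacing. Raw marching cubes on a *binary* field still
overestimates smooth surfaces by ~9% (staircase diamonds) and underestimates
sharp-edged solids slightly (edge chamfer). Twenty iterations of shrink-free
Taubin λ|µ smoothing (λ = 0.5, µ = −0.53) relax the staircase while keeping
planar faces planar; measured against analytic solids: voxelised ball
r = 20 voxels → Ψ = 0.994, the same ball under 2:1 anisotropic spacing →
0.987, cube of 60 voxels → +1.3% of the exact (π/6)^(1/3). Cube error decays
as 1/side (chamfer is a perimeter effect), so small masks (< ~15 voxels
across) carry a few percent sphericity bias.

**Per cell**, whole-cell metrics use the filled mask, chloroplast metrics
use raw label voxels, complement metrics use mask∖chloroplast. The two
stress features are `delta_mean_ri = |mean RI(whole) − mean RI(chloroplast)|`
and the complement concentration. A cell without chloroplast voxels gets
NaN in chloroplast-dependent fields plus a warning — never silent zeros.

## 3. Statistics

Group comparisons are **two-sided unpaired Welch t-tests**
(Welch–Satterthwaite degrees of freedom). The variant is a deliberate
default: with n≈30 biological replicates per group, equal variances cannot
be assumed; Student's form is available via `equal_var=True`. Two groups
with zero variance and equal means return t = 0, p = 1 instead of NaN.
Significance stars follow the conventional tiers (\*0.01<p≤0.05, \*\*p≤0.01,
\*\*\*p≤0.001, \*\*\*\*p≤0.0001). No multiple-testing correction is applied
by default — the stars are per-comparison readouts; Benjamini–Hochberg is an
explicit opt-in column.

Cluster analysis works in the 2D stress-feature plane. Group centroids are
arithmetic means; treatment-vs-control separation is the Euclidean distance
between centroids at one time point. Distances are computed on **raw**
features by default; because the two features differ in scale by roughly an
order of magnitude, a pooled z-scoring option (`standardize=True`) exists
for scale-free distances. Incomplete cells (missing either feature) are
excluded with a logged count, never imputed.

Growth curves reduce to the **relative final density**: 100 × (mean
treatment final density)/(mean control final density), replicate-averaged
at the last shared time point.

## 4. The synthetic phantom

The generator emulates a single cylindrical, chain-forming centric diatom:
a hollow cylindrical frustule shell with end valves, protoplasm filling the
lumen, spherical vacuoles, and parietal ellipsoidal chloroplast lobes
(semi-axes 1.6r × r × r, resting against the wall, evenly spaced along the
cell axis). Simple analytic solids were chosen so exact volume/position
oracles exist. The species' true dimensions are not published; the default
radius 2.5 µm × length 8 µm is a plausible placeholder, stated as such.

Per-voxel RI is drawn from a truncated Gaussian per compartment
(σ = 0.0005), clipped to the sub-band that default segmentation *uniquely*
recovers — e.g. frustule draws stay strictly below the protoplasm low —
and to float32-representable values. This makes a noiseless, blur-free
phantom recoverable voxel-for-voxel, which in turn anchors every downstream
oracle. Degradation is applied after rendering: a Gaussian blur along z
standing in for the missing-cone elongation of transmission tomography,
then additive Gaussian noise. The ground-truth labels are pre-blur.

Default voxel size (0.1, 0.1, 0.2) µm: the instrument class resolves
~110 nm laterally and ~370 nm axially, but resolution is not sampling; the
sampling here is a free choice, set fine enough that the thinnest structure
(the shell) spans several voxels.

**Axial blur default σ = 0.05 µm.** With σ = 0.15 µm the blur transition at
every z-facing vacuole cap crosses the entire 0.007-wide vacuole band into
the protoplasm–vacuole gap, capping vacuole Dice near 0.83 regardless of
noise — incompatible with the recoverability target below. The stronger
σ = 0.15 remains a valid setting for stress-testing segmentation and is
exercised in the docs/tests; it is simply not the default.

**Recoverability calibration.** The generator's defaults are required (by
design) to satisfy: noiseless + blur-free → exact label recovery; additive
noise σ ≤ 0.002 → per-compartment Dice ≥ 0.90. The free parameters
(frustule thickness 0.4 µm, lobe radius 0.9 µm, vacuole radius 1.2 µm,
texture σ 0.0005) were set once to meet those margins (worst Dice over
8 seeds at noise 0.002: frustule 0.97, vacuole 0.95, others ≥ 0.99).

**Cohorts.** A cohort is conditions × time points × n cells (default 30 per
group, matching typical HT cohort sizes). Heavy-metal stress is injected as
a multiplicative depression of RI *contrast* (n − n₀) on all non-chloroplast
ground-truth voxels — the chloroplast is left untouched, reflecting the
observation that it carries no dose signal; excluding it is exactly why the
complement features are sensitive. The per-condition depression defaults to
0.014 per µM of dose (0.14 at 10 µM, 0.35 at 25 µM), zero at the first
(pre-exposure) time point and full afterwards; conditions flagged as
*adapting* (default: non-zero doses ≤ 10 µM) fall back to a residual
(default 0) of their full effect at the last time point, emulating recovery.
Between-cell realism comes from two jitters, both CV 5%: a per-cell
multiplicative contrast factor and a per-cell geometry factor on radii and
length (clipped at ±2σ to keep geometry feasible). Without between-cell
variance every downstream test statistic would be degenerate.

What the phantom does **not** emulate: the optical forward model (no wave
propagation or hologram synthesis), chains of cells (one cell per volume),
spatially correlated noise, reconstruction artefacts other than axial blur,
per-organelle instance variation in shape. A green cohort test therefore
establishes that the *analysis* recovers injected effects of realistic size
under Gaussian degradation — not that the instrument would produce them.

**Growth** is logistic, `N(t) = K/(1 + (K−N₀)/N₀ · e^{−r(1−i)t})`, with
per-condition inhibition i ∈ [0, 1] on the rate and unit-mean lognormal
replicate noise (CV 5%). Defaults: N₀ = 60 000 cells/mL (standard inoculum),
K = 1.5×10⁶ cells/mL, r = 0.05 h⁻¹, i = {0, 0.17, 0.25, 0.90, 0.95} for
{CTRL, Cd 10, Cu 10, Cd 25, Cu 25}. A rate-inhibition logistic cannot fall
below the inoculum, so true die-off (final density a few percent of control
*and below N₀*) is outside this model; the 25 µM defaults reproduce the
near-total growth suppression only down to ~8–9% of control.

## 5. Pipeline and reproducibility

One `RunConfig` (YAML-loadable) drives either a phantom cohort or a
directory of volumes through segmentation → per-cell records → statistics →
growth summary, writing a manifest with the config hash, seed and per-stage
counts. All randomness flows from the single seed (per-cell child seeds are
drawn from one master generator); analysis stages are deterministic, so the
same config + seed yields a byte-identical `cells.csv`. Malformed cells
fail the run fast, naming the cell and stage; `skip_bad=True` downgrades
that to logged, counted exclusions.

## 6. Known limitations

* Exact reproduction of published dry-mass values is impossible without the
  α and n₀ the original software used; only the closed-form behaviour of
  the pipeline is asserted.
* Whether the original analysis gave the frustule or the protoplasm the
  overlapping band, and whether its "whole cell" includes gap-RI voxels,
  is unknowable from the text; both choices here are config-exposed and one
  defensible default is picked.
* Sphericity carries a few-percent positive bias for masks under ~15 voxels
  across (chamfer effect).
* The t-test tables treat cells as independent; chain-mates or repeated
  acquisitions of one cell would violate that.
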