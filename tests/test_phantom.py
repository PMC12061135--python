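"""Phantom generator: determinism, band containment, cohort effects, growth."""

import dataclasses

import numpy as np
import pytest

import diatomht as d
from diatomht.errors import ConfigError, SizingError, ValidationError
from diatomht.phantom import logistic_density
from diatomht.segment import recoverable_intervals
from diatomht.tomio import COMPARTMENTS


class TestGeneratePhantom:
    def test_noiseless_voxels_stay_inside_their_bands(self, clean_small_spec, default_config):
        tomo, truth = d.generate_phantom(clean_small_spec)
        for name in COMPARTMENTS:
            lo, hi = default_config.intervals[name]
            vals = tomo.ri[truth.mask(name)]
            assert vals.size > 0
            assert vals.min() >= lo and vals.max() <= hi

    def test_background_is_medium(self, clean_small_spec):
        tomo, truth = d.generate_phantom(clean_small_spec)
        bg = tomo.ri[truth.labels == 0]
        assert np.allclose(bg, clean_small_spec.medium_ri, atol=1e-6)

    def test_same_seed_is_bit_identical(self, small_spec):
        a, la = d.generate_phantom(small_spec)
        b, lb = d.generate_phantom(small_spec)
        assert np.array_equal(a.ri, b.ri)
        assert np.array_equal(la.labels, lb.labels)

    def test_different_seed_differs(self, small_spec):
        a, _ = d.generate_phantom(small_spec)
        b, _ = d.generate_phantom(dataclasses.replace(small_spec, seed=small_spec.seed + 1))
        assert not np.array_equal(a.ri, b.ri)

    def test_no_vacuoles_means_no_vacuole_label(self, small_spec):
        spec = dataclasses.replace(small_spec, n_vacuoles=0)
        _, truth = d.generate_phantom(spec)
        assert not truth.mask("vacuole").any()

    def test_grid_too_small_names_the_axis(self, small_spec):
        spec = dataclasses.asdict(small_spec)
        with pytest.raises(SizingError, match="along x"):
            d.PhantomSpec(**{**spec, "grid_shape": (28, 48, 32)})
        with pytest.raises(SizingError, match="along z"):
            d.PhantomSpec(**{**spec, "grid_shape": (8, 48, 72)})

    def test_ri_mean_outside_band_rejected(self, small_spec):
        bad = dict(small_spec.ri_mean, vacuole=1.40)
        with pytest.raises(ConfigError, match="vacuole"):
            dataclasses.replace(small_spec, ri_mean=bad)

    def test_draws_avoid_higher_precedence_overlap(self, clean_small_spec, default_config):
        """Frustule draws stay below the protoplasm band so recovery is unique."""
        tomo, truth = d.generate_phantom(clean_small_spec)
        bands = recoverable_intervals(default_config)
        fr = tomo.ri[truth.mask("frustule")]
        assert fr.max() <= bands["frustule"][1]


class TestGenerateCohort:
    def test_dose_ordering_of_whole_cell_mean_ri(self, small_spec):
        """Sample mean whole-cell RI at full effect orders CTRL > 10 µM > 25 µM."""
        cohort = d.CohortSpec(
            conditions=(("CTRL", 0.0, None), ("Cd-10", 10.0, "Cd"), ("Cd-25", 25.0, "Cd")),
            time_points=("T1",),
            time_profile={"T1": 1.0},  # full effect at the only sampled time
            cells_per_group=5,
            adaptation={},
            seed=11,
        )
        means = {}
        for tomo, truth, ann in d.generate_cohort(cohort, small_spec):
            cell_vals = tomo.ri[truth.labels > 0]
            means.setdefault(ann["condition"], []).append(float(cell_vals.mean()))
        m = {k: np.mean(v) for k, v in means.items()}
        assert m["CTRL"] > m["Cd-10"] > m["Cd-25"]

    def test_chloroplast_untouched_by_effect(self, clean_small_spec):
        """Depression hits non-chloroplast compartments only."""
        cohort = d.CohortSpec(
            conditions=(("CTRL", 0.0, None), ("Cd-25", 25.0, "Cd")),
            time_points=("T1",),
            time_profile={"T1": 1.0},
            cells_per_group=2,
            ri_jitter_cv=0.0,
            geometry_jitter_cv=0.0,
            adaptation={},
            seed=5,
        )
        cells = list(d.generate_cohort(cohort, clean_small_spec))
        by_cond = {}
        for tomo, truth, ann in cells:
            by_cond.setdefault(ann["condition"], []).append(
                (float(tomo.ri[truth.mask("chloroplast")].mean()),
                 float(tomo.ri[truth.mask("protoplasm")].mean()))
            )
        chl_ctrl = np.mean([c for c, _ in by_cond["CTRL"]])
        chl_cd = np.mean([c for c, _ in by_cond["Cd-25"]])
        pro_ctrl = np.mean([p for _, p in by_cond["CTRL"]])
        pro_cd = np.mean([p for _, p in by_cond["Cd-25"]])
        assert abs(chl_ctrl - chl_cd) < 5e-4       # same distribution
        assert pro_ctrl - pro_cd > 5e-3            # clearly depressed

    def test_adaptation_zeroes_last_time_point(self):
        cohort = d.CohortSpec(seed=0)
        assert cohort.effect_at("Cd-10", "T1") > 0
        assert cohort.effect_at("Cd-10", "T3") == 0.0          # default residual 0
        assert cohort.effect_at("Cd-25", "T3") == cohort.effect_at("Cd-25", "T1")
        half = dataclasses.replace(cohort, adaptation_residual=0.5)
        assert half.effect_at("Cd-10", "T3") == pytest.approx(
            0.5 * half.effect_at("Cd-10", "T1"))

    def test_unknown_condition_in_effect_model(self):
        with pytest.raises(ConfigError, match="unknown"):
            d.CohortSpec(effects={"CTRL": 0.0, "Zn-10": 0.1})

    def test_annotations_and_cardinality(self, small_spec):
        cohort = d.CohortSpec(
            conditions=(("CTRL", 0.0, None), ("Cu-10", 10.0, "Cu")),
            time_points=("T0", "T1"),
            cells_per_group=2,
            seed=3,
        )
        cells = list(d.generate_cohort(cohort, small_spec))
        assert len(cells) == 2 * 2 * 2
        ids = {ann["cell_id"] for _, _, ann in cells}
        assert len(ids) == len(cells)
        assert all(ann["fixation"] == "fixed" for _, _, ann in cells)


class TestGenerateGrowth:
    def test_closed_form_without_noise_or_inhibition(self):
        spec = d.GrowthSpec(inhibition={"CTRL": 0.0}, noise_cv=0.0, n_replicates=1)
        series = d.generate_growth(spec)
        got = series.table["density_cells_per_ml"].to_numpy()
        expected = logistic_density(np.asarray(spec.times), spec.initial_density,
                                    spec.carrying_capacity, spec.growth_rate)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_full_inhibition_stays_at_inoculum(self):
        spec = d.GrowthSpec(inhibition={"dead": 1.0}, noise_cv=0.0, n_replicates=1)
        series = d.generate_growth(spec)
        assert (series.table["density_cells_per_ml"] == spec.initial_density).all()

    def test_inhibited_culture_has_relative_final_density_below_100(self):
        spec = d.GrowthSpec(inhibition={"CTRL": 0.0, "treated": 0.5}, noise_cv=0.0)
        series = d.generate_growth(spec)
        rel = d.relative_final_density(series, "treated", "CTRL")
        # independent evaluation of the logistic closed form
        n_t = logistic_density(72.0, spec.initial_density, spec.carrying_capacity,
                               spec.growth_rate * 0.5)
        n_c = logistic_density(72.0, spec.initial_density, spec.carrying_capacity,
                               spec.growth_rate)
        assert rel == pytest.approx(100.0 * float(n_t) / float(n_c))
        assert rel < 100.0

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValidationError):
            d.GrowthSpec(times=(0.0, 24.0, 24.0))

    def test_noise_is_seeded_and_multiplicative(self):
        a = d.generate_growth(d.GrowthSpec(seed=4))
        b = d.generate_growth(d.GrowthSpec(seed=4))
        c = d.generate_growth(d.GrowthSpec(seed=5))
        assert a.table.equals(b.table)
        assert not a.table.equals(c.table)
        assert (a.table["density_cells_per_ml"] > 0).all()
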