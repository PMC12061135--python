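"""Group statistics: Welch tests, star codes, summaries, centroids, growth ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import diatomht as d
from diatomht.errors import ValidationError
from diatomht.stats import (
    centroid_table,
    cluster_features,
    distance_table,
    group_summary,
    growth_summary_table,
    ttest_table,
)
from diatomht.tomio import GrowthSeries


def welch_oracle(a, b):
    """Hand-rolled Welch t and Welch–Satterthwaite p (two-sided)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, p


class TestWelchTTest:
    def test_identical_groups(self):
        res = d.welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.significance_code == "ns"

    def test_zero_variance_equal_means(self):
        res = d.welch_ttest([2.0, 2.0], [2.0, 2.0])
        assert (res.t_statistic, res.p_value, res.significance_code) == (0.0, 1.0, "ns")

    def test_group_too_small_rejected(self):
        with pytest.raises(ValidationError):
            d.welch_ttest([1.0], [1.0, 2.0])

    def test_matches_hand_rolled_oracle(self):
        """100 random cases agree with the Welch–Satterthwaite formula to 1e-10."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            na, nb = rng.integers(2, 40, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=nb)
            res = d.welch_ttest(a, b)
            t, p = welch_oracle(a, b)
            assert res.t_statistic == pytest.approx(t, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize(
        "p, code",
        [(0.5, "ns"), (0.0501, "ns"), (0.05, "*"), (0.03, "*"), (0.01, "**"),
         (0.002, "**"), (0.001, "***"), (0.0002, "***"), (0.0001, "****"), (1e-9, "****")],
    )
    def test_significance_tiers(self, p, code):
        assert d.significance_code(p) == code


class TestGroupSummary:
    def _frame(self, values, condition="CTRL", time_point="T1"):
        return pd.DataFrame({"condition": condition, "time_point": time_point,
                             "metric": values}).assign(metric=values)

    def test_basic_summary(self):
        frame = pd.DataFrame({"condition": "CTRL", "time_point": "T1",
                              "x": [1.0, 2.0, 3.0, 4.0]})
        (s,) = group_summary(frame, "x")
        assert (s.median, s.minimum, s.maximum, s.n) == (2.5, 1.0, 4.0, 4)
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_constant_group_sd_zero(self):
        frame = pd.DataFrame({"condition": "CTRL", "time_point": "T1", "x": [5.0] * 6})
        (s,) = group_summary(frame, "x")
        assert s.sd == 0.0 and s.minimum == s.median == s.maximum == 5.0

    def test_order_invariance(self):
        base = pd.DataFrame({"condition": "CTRL", "time_point": "T1",
                             "x": [3.0, 1.0, 4.0, 1.5, 9.0]})
        shuffled = base.sample(frac=1.0, random_state=2)
        (a,), (b,) = group_summary(base, "x"), group_summary(shuffled, "x")
        assert (a.median, a.minimum, a.maximum, a.n) == (b.median, b.minimum, b.maximum, b.n)
        assert a.sd == pytest.approx(b.sd, rel=1e-12)


class TestClusterFeatures:
    def _frame(self):
        return pd.DataFrame({
            "condition": ["CTRL"] * 30,
            "time_point": ["T1"] * 30,
            "delta_mean_ri": np.linspace(0.02, 0.05, 30),
            "complement_concentration": np.linspace(0.10, 0.14, 30),
        })

    def test_projection_and_cardinality(self):
        frame = self._frame()
        points = cluster_features(frame)
        assert len(points) == 30
        assert points.iloc[0]["delta_mean_ri"] == pytest.approx(0.02)

    def test_incomplete_cells_excluded(self):
        frame = self._frame()
        frame.loc[4, "delta_mean_ri"] = np.nan
        assert len(cluster_features(frame)) == 29


class TestCentroidDistances:
    def _frame(self, ctrl_center=(0.0, 0.0), treat_center=(3.0, 4.0), n=12, spread=0.0):
        rng = np.random.default_rng(0)
        rows = []
        for cond, (cx, cy) in (("CTRL", ctrl_center), ("Cd-25", treat_center)):
            for i in range(n):
                dx, dy = (spread * rng.standard_normal(2)) if spread else (0.0, 0.0)
                rows.append({"condition": cond, "time_point": "T1",
                             "delta_mean_ri": cx + dx,
                             "complement_concentration": cy + dy})
        return pd.DataFrame(rows)

    def test_identical_groups_distance_zero(self):
        frame = self._frame(treat_center=(0.0, 0.0))
        assert d.centroid_distances(frame, "CTRL", "T1")["Cd-25"] == pytest.approx(0.0)

    def test_three_four_five(self):
        frame = self._frame()
        assert d.centroid_distances(frame, "CTRL", "T1")["Cd-25"] == pytest.approx(5.0)

    def test_translation_invariance_and_symmetry(self):
        frame = self._frame(spread=0.3)
        base = d.centroid_distances(frame, "CTRL", "T1")["Cd-25"]
        shifted = frame.copy()
        shifted[["delta_mean_ri", "complement_concentration"]] += 7.5
        assert d.centroid_distances(shifted, "CTRL", "T1")["Cd-25"] == pytest.approx(base)
        swapped = frame.replace({"condition": {"CTRL": "Cd-25", "Cd-25": "CTRL"}})
        assert d.centroid_distances(swapped, "CTRL", "T1")["Cd-25"] == pytest.approx(base)

    def test_recovers_injected_feature_shift(self):
        """A pure shift of the treatment cloud is recovered within MC error."""
        frame = self._frame(treat_center=(0.0, 0.0), n=30, spread=0.002)
        shift = 0.01
        frame.loc[frame.condition == "Cd-25", "delta_mean_ri"] += shift
        got = d.centroid_distances(frame, "CTRL", "T1")["Cd-25"]
        mc_err = 3 * 0.002 * math.sqrt(2.0 / 30.0)
        assert abs(got - shift) < mc_err

    def test_standardized_distance_rescales_features(self):
        frame = self._frame(treat_center=(1.0, 0.0), spread=0.1)
        raw = d.centroid_distances(frame, "CTRL", "T1")["Cd-25"]
        z = d.centroid_distances(frame, "CTRL", "T1", standardize=True)["Cd-25"]
        assert raw != pytest.approx(z)

    def test_centroid_is_group_mean(self):
        frame = self._frame(spread=0.5)
        for c in d.centroids(frame):
            sub = frame[frame.condition == c.group[0]]
            np.testing.assert_allclose(
                c.centroid, sub[["delta_mean_ri", "complement_concentration"]].mean())


class TestRelativeFinalDensity:
    def _series(self, treat_final, ctrl_final=(100e3, 100e3, 100e3)):
        rows = []
        for cond, finals in (("CTRL", ctrl_final), ("Cu-10", treat_final)):
            for rep, v in enumerate(finals, start=1):
                rows.append({"time_h": 0.0, "condition": cond, "replicate": rep,
                             "density_cells_per_ml": 60e3})
                rows.append({"time_h": 72.0, "condition": cond, "replicate": rep,
                             "density_cells_per_ml": v})
        return GrowthSeries(table=pd.DataFrame(rows))

    def test_single_ratio(self):
        series = self._series((64e3, 64e3, 64e3))
        assert d.relative_final_density(series, "Cu-10", "CTRL") == pytest.approx(64.0)

    def test_identity(self):
        series = self._series((100e3, 100e3, 100e3))
        assert d.relative_final_density(series, "Cu-10", "CTRL") == pytest.approx(100.0)

    def test_replicate_mean(self):
        series = self._series((60e3, 64e3, 68e3))
        assert d.relative_final_density(series, "Cu-10", "CTRL") == pytest.approx(64.0)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValidationError):
            d.relative_final_density(self._series((1.0, 1.0, 1.0)), "Zn-10", "CTRL")


class TestCohortTables:
    def test_tables_from_phantom_cohort(self, small_cohort_frame):
        frame = small_cohort_frame
        tt = ttest_table(frame, ["whole_mean_ri", "complement_concentration"])
        assert set(tt["condition"]) == {"Cd-10", "Cd-25"}
        assert ((tt["p_value"] >= 0) & (tt["p_value"] <= 1)).all()
        cents = centroid_table(frame)
        assert len(cents) == 3 * 4  # conditions × times
        dists = distance_table(frame)
        assert set(dists["condition"]) == {"Cd-10", "Cd-25"}
        assert (dists["distance_to_reference"] >= 0).all()

    def test_bh_option_adds_column(self, small_cohort_frame):
        tt = ttest_table(small_cohort_frame, ["whole_mean_ri"], bh_correct=True)
        assert "p_bh" in tt.columns
        assert (tt["p_bh"] >= tt["p_value"] - 1e-15).all()

    def test_growth_summary_table(self):
        growth = d.generate_growth(d.GrowthSpec(noise_cv=0.0))
        table = growth_summary_table(growth)
        by_cond = dict(zip(table["condition"], table["relative_final_density_pct"]))
        # dose ordering of the default inhibition factors
        assert by_cond["Cd-10"] > by_cond["Cu-10"] > by_cond["Cd-25"] > by_cond["Cu-25"]
        assert all(0 < v < 100 for v in by_cond.values())
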