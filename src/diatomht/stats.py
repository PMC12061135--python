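"""Cohort statistics: Welch t-tests with star codes, group summaries,
2D stress-feature clusters, centroid distances, and growth-curve ratios.

The two stress features are ``delta_mean_ri`` (absolute difference between
whole-cell and chloroplast mean RI) and ``complement_concentration``
(dry-mass concentration of the chloroplast complement).  Group comparisons
use the unpaired two-sided Welch test; significance stars follow the
conventional tiers *0.01<p≤0.05, **p≤0.01, ***p≤0.001, ****p≤0.0001.
No multiple-testing correction is applied by default (per-comparison
stars); Benjamini–Hochberg is available as an explicit opt-in.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .tomio import GrowthSeries

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = ("delta_mean_ri", "complement_concentration")

#: (upper p bound, code), scanned in order
_SIGNIFICANCE_TIERS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


def significance_code(p_value: float) -> str:
    """Map a p-value to the star code of the conventional tiers."""
    if not (0.0 <= p_value <= 1.0) or math.isnan(p_value):
        raise ValidationError(f"p-value outside [0, 1]: {p_value}")
    for bound, code in _SIGNIFICANCE_TIERS:
        if p_value <= bound:
            return code
    return "ns"


@dataclass
class TTestResult:
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    significance_code: str


@dataclass
class GroupSummary:
    """Distribution summary per group, as drawn in box plots: median,
    SD (n−1), min, max, n."""

    metric: str
    group: tuple
    median: float
    sd: float
    minimum: float
    maximum: float
    n: int


@dataclass
class ClusterSummary:
    """Centroid (arithmetic mean) of one group's 2D stress-feature cloud."""

    group: tuple
    features: tuple[str, str]
    centroid: tuple[float, float]
    n: int


def welch_ttest(a: Sequence[float], b: Sequence[float], equal_var: bool = False) -> TTestResult:
    """Two-sided unpaired t-test, Welch (unequal variance) by default.

    ``equal_var=True`` gives the classic Student variant.  Two zero-variance
    groups with equal means return t=0, p=1 rather than NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError(f"each group needs n >= 2, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("groups must be finite")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, a.size, b.size, "ns")
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()), 0.0,
                           a.size, b.size, "****")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(t), float(p), a.size, b.size, significance_code(float(p)))


def group_summary(
    frame: pd.DataFrame,
    metric: str,
    by: Sequence[str] = ("condition", "time_point"),
) -> list[GroupSummary]:
    """Median, SD (n−1 denominator), min, max and n per group.

    Groups with no finite values are omitted with a warning.
    """
    if metric not in frame.columns:
        raise ValidationError(f"unknown metric {metric!r}")
    out: list[GroupSummary] = []
    for key, grp in frame.groupby(list(by), sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp[metric].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"group {key} has no finite {metric!r} values; omitted", stacklevel=2)
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(GroupSummary(metric=metric, group=tuple(key),
                                median=float(np.median(vals)), sd=sd,
                                minimum=float(vals.min()), maximum=float(vals.max()),
                                n=int(vals.size)))
    return out


def cluster_features(
    frame: pd.DataFrame,
    features: Sequence[str] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Per-cell 2D stress-feature vectors; incomplete cells are excluded
    (count logged), never imputed."""
    missing_cols = set(features) - set(frame.columns)
    if missing_cols:
        raise ValidationError(f"missing feature columns: {sorted(missing_cols)}")
    complete = frame.loc[np.isfinite(frame[list(features)].to_numpy(float)).all(axis=1)]
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        logger.info("cluster_features: excluded %d cell(s) missing %s", n_dropped, tuple(features))
    return complete


def centroids(
    frame: pd.DataFrame,
    features: Sequence[str] = DEFAULT_FEATURES,
    by: Sequence[str] = ("condition", "time_point"),
) -> list[ClusterSummary]:
    """Arithmetic-mean centroid per group in stress-feature space."""
    complete = cluster_features(frame, features)
    out = []
    for key, grp in complete.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        c = grp[list(features)].to_numpy(float).mean(axis=0)
        out.append(ClusterSummary(group=tuple(key), features=tuple(features),
                                  centroid=(float(c[0]), float(c[1])), n=len(grp)))
    return out


def centroid_distances(
    frame: pd.DataFrame,
    reference_condition: str,
    time_point: str,
    features: Sequence[str] = DEFAULT_FEATURES,
    standardize: bool = False,
) -> dict[str, float]:
    """Euclidean distance between each treatment centroid and the reference
    centroid at one time point.

    With ``standardize`` the features are z-scored with the pooled mean/SD
    over all compared groups before distancing (the two default features
    differ in scale by roughly an order of magnitude); the default is raw
    feature space.
    """
    sub = cluster_features(frame[frame["time_point"] == time_point], features)
    if (sub["condition"] == reference_condition).sum() == 0:
        raise ValidationError(
            f"reference condition {reference_condition!r} absent at {time_point!r}")
    X = sub[list(features)].to_numpy(float)
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        sub = sub.copy()
        sub[list(features)] = (X - mu) / sd
    ref_centroid = sub.loc[sub["condition"] == reference_condition, list(features)] \
        .to_numpy(float).mean(axis=0)
    out: dict[str, float] = {}
    for cond, grp in sub.groupby("condition", sort=True):
        if cond == reference_condition:
            continue
        if len(grp) < 1:
            warnings.warn(f"group {cond!r} empty at {time_point!r}; skipped", stacklevel=2)
            continue
        c = grp[list(features)].to_numpy(float).mean(axis=0)
        out[str(cond)] = float(np.linalg.norm(c - ref_centroid))
    return out


def relative_final_density(growth: GrowthSeries, treatment: str, control: str) -> float:
    """Replicate-averaged final density of a treatment as a percentage of the
    control's."""
    t_final = growth.table["time_h"].max()
    for cond in (treatment, control):
        sub = growth.table[growth.table["condition"] == cond]
        if sub.empty:
            raise ValidationError(f"unknown condition {cond!r}")
        if t_final not in set(sub["time_h"]):
            raise ValidationError(f"{cond!r} has no observation at the final time {t_final} h")
    mean_at = lambda cond: growth.table.loc[
        (growth.table["condition"] == cond) & (growth.table["time_h"] == t_final),
        "density_cells_per_ml"].mean()
    ctrl = mean_at(control)
    if ctrl <= 0:
        raise ValidationError(f"control {control!r} final density is not positive")
    return 100.0 * mean_at(treatment) / ctrl


# ---------------------------------------------------------------------------
# cohort-level tables (pipeline outputs)
# ---------------------------------------------------------------------------

def ttest_table(
    frame: pd.DataFrame,
    metrics: Sequence[str],
    reference_condition: str = "CTRL",
    equal_var: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pairwise reference-vs-treatment Welch tests per metric and time point.

    ``bh_correct`` adds a Benjamini–Hochberg adjusted p column (off by
    default — the per-comparison stars are the headline readout).
    """
    rows = []
    for time_point in sorted(frame["time_point"].dropna().unique()):
        sub = frame[frame["time_point"] == time_point]
        ref = sub[sub["condition"] == reference_condition]
        if len(ref) < 2:
            continue
        for cond in sorted(sub["condition"].dropna().unique()):
            if cond == reference_condition:
                continue
            grp = sub[sub["condition"] == cond]
            for metric in metrics:
                a = ref[metric].to_numpy(float)
                b = grp[metric].to_numpy(float)
                a, b = a[np.isfinite(a)], b[np.isfinite(b)]
                if a.size < 2 or b.size < 2:
                    continue
                res = welch_ttest(a, b, equal_var=equal_var)
                rows.append({
                    "time_point": time_point, "condition": cond, "metric": metric,
                    "t_statistic": res.t_statistic, "p_value": res.p_value,
                    "n_ref": res.n_a, "n_treat": res.n_b,
                    "significance": res.significance_code,
                })
    table = pd.DataFrame(rows)
    if bh_correct and not table.empty:
        table["p_bh"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    return table


def summary_table(frame: pd.DataFrame, metrics: Sequence[str]) -> pd.DataFrame:
    rows = []
    for metric in metrics:
        for s in group_summary(frame, metric):
            rows.append({
                "metric": s.metric, "condition": s.group[0], "time_point": s.group[1],
                "median": s.median, "sd": s.sd, "min": s.minimum, "max": s.maximum, "n": s.n,
            })
    return pd.DataFrame(rows)


def centroid_table(frame: pd.DataFrame, features: Sequence[str] = DEFAULT_FEATURES) -> pd.DataFrame:
    rows = []
    for c in centroids(frame, features):
        rows.append({
            "condition": c.group[0], "time_point": c.group[1],
            f"centroid_{features[0]}": c.centroid[0],
            f"centroid_{features[1]}": c.centroid[1], "n": c.n,
        })
    return pd.DataFrame(rows)


def distance_table(
    frame: pd.DataFrame,
    reference_condition: str = "CTRL",
    features: Sequence[str] = DEFAULT_FEATURES,
    standardize: bool = False,
) -> pd.DataFrame:
    rows = []
    for time_point in sorted(frame["time_point"].dropna().unique()):
        try:
            dists = centroid_distances(frame, reference_condition, time_point,
                                       features, standardize)
        except ValidationError:
            continue
        for cond, d in dists.items():
            rows.append({"time_point": time_point, "condition": cond,
                         "distance_to_reference": d})
    return pd.DataFrame(rows)


def growth_summary_table(growth: GrowthSeries, control: str = "CTRL") -> pd.DataFrame:
    """Relative final density (%) of every non-control condition."""
    rows = []
    for cond in growth.conditions:
        if cond == control:
            continue
        rows.append({"condition": cond, "control": control,
                     "relative_final_density_pct": relative_final_density(growth, cond, control)})
    return pd.DataFrame(rows)
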