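"""Apoptotic index, body-weight change and the group-comparison decision tree.

The statistical workflow mirrors common practice in quantitative histology:
per-group normality is screened with a Kolmogorov–Smirnov test and variance
homogeneity with Levene's test; when both pass, a one-way (or two-way)
ANOVA with Tukey's post hoc is used, otherwise Kruskal–Wallis with Dunn's
post hoc.  Designated pairwise endpoints use the two-tailed Mann–Whitney U
test.  Every branch decision is recorded in the result so the analysis is a
pure, reproducible function of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd


# ---------------------------------------------------------------------------
# apoptotic index and body weight
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldCount:
    """TUNEL counts in one microscopic field."""

    field_id: int
    apoptotic_cells: int
    total_cells: int

    def __post_init__(self) -> None:
        if not 0 <= self.apoptotic_cells <= self.total_cells:
            raise ValueError("need 0 <= apoptotic <= total")


@dataclass
class ApoptoticIndexResult:
    """Per-field percentages and the pooled per-animal index."""

    per_field: list[float]
    animal_index: float
    n_fields: int
    pooling: str


def apoptotic_index(fields: Sequence[FieldCount],
                    pooling: str = "pooled_counts") -> ApoptoticIndexResult:
    """Apoptotic index = apoptotic cells / total cells × 100%.

    ``pooled_counts`` divides the summed counts across fields (default);
    ``mean_of_fields`` averages the per-field percentages.  The two agree
    whenever all fields have equal totals.
    """
    if not fields:
        raise ValueError("at least one field required")
    if pooling not in ("pooled_counts", "mean_of_fields"):
        raise ValueError("pooling must be 'pooled_counts' or 'mean_of_fields'")
    total = sum(f.total_cells for f in fields)
    if total == 0:
        raise ValueError("no cells counted in any field")
    per_field = [f.apoptotic_cells / f.total_cells * 100.0
                 for f in fields if f.total_cells > 0]
    if pooling == "pooled_counts":
        idx = sum(f.apoptotic_cells for f in fields) / total * 100.0
    else:
        idx = float(np.mean(per_field))
    return ApoptoticIndexResult(per_field, idx, len(fields), pooling)


@dataclass
class WeightRecord:
    """Body weights (g) at days 1, 7, 14, 21 of the protocol."""

    day1: float
    day7: float | None = None
    day14: float | None = None
    day21: float | None = None

    def __post_init__(self) -> None:
        for w in (self.day1, self.day7, self.day14, self.day21):
            if w is not None and w <= 0:
                raise ValueError("weights must be positive")


def body_weight_percent(record: WeightRecord) -> float:
    """Body weight% = (day-21 weight × 100 / day-1 weight) − 100."""
    if record.day21 is None:
        raise ValueError("day-21 weight missing")
    return record.day21 * 100.0 / record.day1 - 100.0


# ---------------------------------------------------------------------------
# Dunn's post hoc (rank-based pairwise comparisons after Kruskal–Wallis)
# ---------------------------------------------------------------------------

def dunn_test(groups: Mapping[str, np.ndarray],
              adjust: str | None = None) -> pd.DataFrame:
    """Dunn's z-test on mean ranks, with tie correction.

    ``adjust`` may be None (unadjusted, the default), "bonferroni" or
    "holm".
    """
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(data)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))

    mean_ranks, sizes = {}, {}
    pos = 0
    for g, d in zip(labels, data):
        mean_ranks[g] = ranks[pos:pos + len(d)].mean()
        sizes[g] = len(d)
        pos += len(d)

    rows = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_value": p})
    df = pd.DataFrame(rows)
    m = len(df)
    if adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(df["p_value"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(df["p_value"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank_i, i in enumerate(order):
            running = max(running, df["p_value"].iloc[i] * (m - rank_i))
            adj[i] = min(running, 1.0)
        df["p_adjusted"] = adj
    elif adjust is not None:
        raise ValueError("adjust must be None, 'bonferroni' or 'holm'")
    return df


# ---------------------------------------------------------------------------
# group-comparison decision tree
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Outcome of one endpoint's group comparison, branch decisions included."""

    endpoint: str
    design: str
    test_used: str
    statistic: float
    p_value: float
    normality_p: dict[str, float] = field(default_factory=dict)
    levene_p: float = float("nan")
    parametric: bool | None = None
    posthoc: pd.DataFrame | None = None
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def _ks_normality(x: np.ndarray) -> float:
    """KS test against a normal with the sample's own mean and sd."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0 or len(x) < 3:
        return 0.0  # degenerate samples fail the normality screen
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def compare_groups(values_by_group: Mapping[str, Sequence[float]],
                   design: str = "one_way",
                   endpoint: str = "endpoint",
                   alpha: float = 0.05,
                   dunn_adjust: str | None = None,
                   branch: str = "auto",
                   compute_posthoc: bool = True) -> ComparisonResult:
    """Run the comparison decision tree on per-group values.

    design = "one_way": KS normality per group + Levene; both pass →
    one-way ANOVA with Tukey post hoc, otherwise Kruskal–Wallis with Dunn
    post hoc.  design = "pairwise": two-tailed Mann–Whitney U for every
    pair (the omnibus p is the smallest pairwise p when more than two
    groups are given).  For two-way designs use :func:`two_way_anova`.

    ``branch`` forces the parametric or nonparametric arm regardless of
    the screens ("auto" follows them); ``compute_posthoc=False`` skips the
    pairwise tables, which is useful in large resimulation loops.
    """
    if design not in ("one_way", "pairwise"):
        raise ValueError("design must be 'one_way' or 'pairwise'")
    if branch not in ("auto", "parametric", "nonparametric"):
        raise ValueError("branch must be 'auto', 'parametric' or 'nonparametric'")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least 2 values per group")

    data = list(groups.values())
    degenerate = bool(np.ptp(np.concatenate(data)) == 0)

    if design == "pairwise":
        rows = []
        for g1, g2 in combinations(groups, 2):
            if degenerate:
                u, p = float(len(groups[g1]) * len(groups[g2]) / 2.0), 1.0
            else:
                res = sps.mannwhitneyu(groups[g1], groups[g2],
                                       alternative="two-sided")
                u, p = float(res.statistic), float(res.pvalue)
            rows.append({"group1": g1, "group2": g2, "U": u, "p_value": p})
        posthoc = pd.DataFrame(rows)
        p_min = float(posthoc["p_value"].min())
        return ComparisonResult(endpoint, design, "mann-whitney",
                                statistic=float("nan"), p_value=p_min,
                                posthoc=posthoc, alpha=alpha,
                                degenerate=degenerate)

    normality = {g: _ks_normality(v) for g, v in groups.items()}
    if degenerate:
        return ComparisonResult(endpoint, design, "kruskal-wallis",
                                statistic=0.0, p_value=1.0,
                                normality_p=normality, parametric=False,
                                alpha=alpha, degenerate=True)
    try:
        levene_p = float(sps.levene(*data).pvalue)
    except ValueError:
        levene_p = 0.0
    normal_ok = all(p >= alpha for p in normality.values())
    if branch == "auto":
        parametric = normal_ok and levene_p >= alpha
    else:
        parametric = branch == "parametric"

    if parametric:
        stat, p = sps.f_oneway(*data)
        posthoc = None
        if compute_posthoc:
            flat = np.concatenate(data)
            labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
            tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
            posthoc = pd.DataFrame(tk.summary().data[1:],
                                   columns=tk.summary().data[0])
        return ComparisonResult(endpoint, design, "one-way-anova+tukey",
                                float(stat), float(p), normality, levene_p,
                                True, posthoc, alpha)
    try:
        stat, p = sps.kruskal(*data)
    except ValueError:  # all values identical within the test
        stat, p = 0.0, 1.0
    posthoc = dunn_test(groups, adjust=dunn_adjust) if compute_posthoc else None
    return ComparisonResult(endpoint, design, "kruskal-wallis+dunn",
                            float(stat), float(p), normality, levene_p,
                            False, posthoc, alpha)


def two_way_anova(df: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str, endpoint: str = "endpoint",
                  alpha: float = 0.05) -> ComparisonResult:
    """Two-way ANOVA with interaction (e.g. group × day for body weight)."""
    work = df[[value, factor_a, factor_b]].copy()
    work.columns = ["y", "fa", "fb"]
    model = ols("y ~ C(fa) * C(fb)", data=work).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p = float(table.loc["C(fa)", "PR(>F)"])
    stat = float(table.loc["C(fa)", "F"])
    return ComparisonResult(endpoint, "two_way", "two-way-anova", stat, p,
                            posthoc=table.reset_index(), alpha=alpha,
                            parametric=True)


def levene_variance_test(values_by_group: Mapping[str, Sequence[float]],
                         endpoint: str = "endpoint",
                         alpha: float = 0.05) -> ComparisonResult:
    """Levene's test for equality of variances across groups."""
    data = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    stat, p = sps.levene(*data)
    return ComparisonResult(endpoint, "variance", "levene", float(stat),
                            float(p), alpha=alpha)
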