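"""Scores and statistical validation battery for the integrated atlas.

Implements the atlas' defined measures — the per-protein variability score
(|CV|/n on linear values), the location specificity index (difference of
mean natural-log concentrations), top-percentile protein selection and
pairwise correlation tables — plus the validation machinery: a
Kruskal-Wallis + Conover post-hoc (Holm-adjusted) median-equality check
across studies, a two-group battery (DBM/OVS effect size, Mann-Whitney U,
Kolmogorov-Smirnov, Brown-Forsythe and Fligner-Killeen), a permutation
procedure that repeatedly resamples N=100 from each group (with a pooled
control mode calibrating to the nominal alpha), and a fold-change +
p-value differential-concentration analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "VariabilityScore",
    "SpecificityIndex",
    "BatteryResult",
    "MedianEqualityResult",
    "variability_score",
    "specificity_index",
    "top_percentile_proteins",
    "correlation_tables",
    "conover_posthoc",
    "median_equality_battery",
    "two_group_battery",
    "permutation_battery",
    "differential_concentration",
    "BATTERY_TESTS",
]

BATTERY_TESTS = ("mwu", "ks", "brown_forsythe", "fligner_killeen")


@dataclass(frozen=True)
class VariabilityScore:
    gene: str
    data_type: str
    score: float  # |CV| / n, dimensionless
    n: int


@dataclass(frozen=True)
class SpecificityIndex:
    gene: str
    location: str
    index: float  # difference of mean ln concentrations


def variability_score(values: Sequence[float], gene: str = "?", data_type: str = "all") -> VariabilityScore | None:
    """|coefficient of variation| scaled to the measurement count.

    Computed on linear values (no log transform) with the sample standard
    deviation; the score is zero iff the CV is zero.  Undefined (returns
    ``None``) for fewer than two values or zero mean.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        return None
    mean = v.mean()
    if mean == 0:
        return None
    cv = abs(v.std(ddof=1) / mean)
    return VariabilityScore(gene=gene, data_type=data_type, score=cv / n, n=n)


def specificity_index(
    conc_by_location: Mapping[str, Sequence[float]], target: str, gene: str = "?"
) -> SpecificityIndex:
    """Mean ln concentration in the target location minus the complement.

    Non-positive concentrations are dropped with a warning before taking
    logs.  Swapping target and complement negates the index.
    """
    if target not in conc_by_location:
        raise ValueError(f"target location {target!r} absent")

    def _logs(vals: Iterable[float], where: str) -> np.ndarray:
        arr = np.asarray(list(vals), dtype=float)
        bad = arr <= 0
        if bad.any():
            logger.warning("dropping %d non-positive concentrations in %s", int(bad.sum()), where)
        return np.log(arr[~bad])

    target_logs = _logs(conc_by_location[target], target)
    other_logs = _logs(
        (v for loc, vals in conc_by_location.items() if loc != target for v in vals),
        "complement",
    )
    if target_logs.size == 0 or other_logs.size == 0:
        raise ValueError("need at least one positive concentration on each side")
    return SpecificityIndex(gene=gene, location=target, index=float(target_logs.mean() - other_logs.mean()))


def top_percentile_proteins(
    entries: pd.DataFrame, group_by: str, q: float = 0.99
) -> dict[str, set[str]]:
    """Per-location sets of genes above the global q-quantile concentration.

    The quantile (linear interpolation) is taken over ALL concentrations;
    selection is strictly greater-than, so a constant table selects nothing.
    """
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0,1)")
    if q == 0:  # degenerate quantile: everything qualifies
        return {str(loc): set(sub["canonical_gene"])
                for loc, sub in entries.groupby(group_by)}
    cutoff = float(entries["concentration_uM"].quantile(q, interpolation="linear"))
    return {
        str(loc): set(sub.loc[sub["concentration_uM"] > cutoff, "canonical_gene"])
        for loc, sub in entries.groupby(group_by)
    }


def correlation_tables(
    entries: pd.DataFrame, group_by: str, min_common: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r on ln concentrations plus common-protein counts.

    Every pair is compared on the proteins common to that pair only
    (per-gene mean of ln uM within each group); pairs with fewer than
    ``min_common`` shared proteins get NaN.
    """
    groups = {}
    for key, sub in entries.groupby(group_by):
        pos = sub[sub["concentration_uM"] > 0]
        groups[str(key)] = np.log(pos["concentration_uM"]).groupby(
            pos["canonical_gene"].values
        ).mean()
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    n = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for name in names:
        n.loc[name, name] = len(groups[name])
    for a, b in combinations(names, 2):
        common = groups[a].index.intersection(groups[b].index)
        n.loc[a, b] = n.loc[b, a] = len(common)
        if len(common) < min_common:
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        rr = float(sps.pearsonr(groups[a][common], groups[b][common]).statistic)
        r.loc[a, b] = r.loc[b, a] = rr
    return r, n


def conover_posthoc(groups: Sequence[np.ndarray], h_stat: float) -> np.ndarray:
    """Pairwise Conover-Iman rank test after Kruskal-Wallis (raw p-values).

    t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))
    with S^2 the variance of the joint (tie-averaged) ranks and df = N - k.
    """
    sizes = np.array([len(g) for g in groups])
    k, N = len(groups), int(sizes.sum())
    ranks = sps.rankdata(np.concatenate(groups))
    splits = np.split(ranks, np.cumsum(sizes)[:-1])
    rank_means = np.array([s.mean() for s in splits])
    s2 = (np.sum(ranks**2) - N * (N + 1) ** 2 / 4) / (N - 1)
    scale = s2 * (N - 1 - h_stat) / (N - k)
    p = np.ones((k, k))
    for i, j in combinations(range(k), 2):
        se = np.sqrt(scale * (1 / sizes[i] + 1 / sizes[j]))
        t = (rank_means[i] - rank_means[j]) / se
        pij = 2 * sps.t.sf(abs(t), df=N - k)
        p[i, j] = p[j, i] = min(1.0, pij)
    return p


@dataclass
class MedianEqualityResult:
    h_statistic: float
    p_value: float
    rejected: bool
    posthoc_holm: pd.DataFrame | None  # None when KW does not reject


def median_equality_battery(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> MedianEqualityResult:
    """Kruskal-Wallis across studies, Conover post-hoc on rejection.

    Post-hoc p-values are Holm-adjusted over all pairs and returned as a
    symmetric matrix; the post-hoc runs only if KW rejects at ``alpha``.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("need at least 3 groups; use a two-sample test for 2")
    arrays = [np.asarray(groups[nm], dtype=float) for nm in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    h, p = sps.kruskal(*arrays)
    rejected = p < alpha
    posthoc = None
    if rejected:
        raw = conover_posthoc(arrays, h)
        iu = np.triu_indices(len(names), k=1)
        adj = multipletests(raw[iu], method="holm")[1]
        mat = np.ones((len(names), len(names)))
        mat[iu] = adj
        mat[(iu[1], iu[0])] = adj
        posthoc = pd.DataFrame(mat, index=names, columns=names)
    return MedianEqualityResult(float(h), float(p), bool(rejected), posthoc)


def _whiskers(x: np.ndarray) -> tuple[float, float]:
    """Boxplot whiskers: extreme data points within 1.5*IQR of the quartiles."""
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min()
    hi = x[x <= q3 + 1.5 * iqr].max()
    return float(lo), float(hi)


@dataclass
class BatteryResult:
    """Two-group comparison: effect size plus location/shape/scale tests."""

    dbm_ovs: float  # |median difference| / overall visible spread (NaN if spread 0)
    mwu_p: float
    ks_p: float
    brown_forsythe_p: float
    fligner_killeen_p: float

    def p_values(self) -> dict[str, float]:
        return {
            "mwu": self.mwu_p,
            "ks": self.ks_p,
            "brown_forsythe": self.brown_forsythe_p,
            "fligner_killeen": self.fligner_killeen_p,
        }


def two_group_battery(a: Sequence[float], b: Sequence[float]) -> BatteryResult:
    """DBM/OVS plus two-sided MWU, KS and two variance-equality tests.

    The overall visible spread is the span of the two groups' 1.5*IQR
    boxplot whiskers; zero spread leaves DBM/OVS undefined (NaN).
    Brown-Forsythe is Levene's test with median centering; Fligner-Killeen
    is its fully non-parametric counterpart.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise ValueError("each group needs at least 5 values")
    lo_x, hi_x = _whiskers(x)
    lo_y, hi_y = _whiskers(y)
    spread = max(hi_x, hi_y) - min(lo_x, lo_y)
    dbm = abs(np.median(x) - np.median(y))
    if spread == 0:
        logger.warning("zero overall visible spread; DBM/OVS undefined")
        dbm_ovs = float("nan")
    else:
        dbm_ovs = float(dbm / spread)
    return BatteryResult(
        dbm_ovs=dbm_ovs,
        mwu_p=float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue),
        ks_p=float(sps.ks_2samp(x, y, alternative="two-sided").pvalue),
        brown_forsythe_p=float(sps.levene(x, y, center="median").pvalue),
        fligner_killeen_p=float(sps.fligner(x, y).pvalue),
    )


def permutation_battery(
    a: Sequence[float],
    b: Sequence[float],
    n: int = 100,
    reps: int = 1000,
    seed: int | None = None,
    control: bool = False,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Rejection rates of the two-group battery under repeated subsampling.

    Each repetition draws ``n`` values from each group (without replacement
    when the group is large enough, otherwise with replacement as a
    documented fallback) and records rejections at ``alpha``.  In control
    mode both samples are drawn jointly, without replacement, from the
    pooled data — an exact exchangeability null whose rejection rates
    calibrate to ``alpha``.
    """
    if n < 5 or reps < 1:
        raise ValueError("require n >= 5 and reps >= 1")
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    rejections = {t: 0 for t in BATTERY_TESTS}
    pooled = np.concatenate([x, y])
    for _ in range(reps):
        if control:
            if len(pooled) >= 2 * n:
                draw = rng.choice(pooled, size=2 * n, replace=False)
            else:
                draw = rng.choice(pooled, size=2 * n, replace=True)
            sa, sb = draw[:n], draw[n:]
        else:
            sa = rng.choice(x, size=n, replace=len(x) < n)
            sb = rng.choice(y, size=n, replace=len(y) < n)
        result = two_group_battery(sa, sb)
        for test, p in result.p_values().items():
            if p < alpha:
                rejections[test] += 1
    return {t: c / reps for t, c in rejections.items()}


def differential_concentration(
    group_a: Mapping[str, Sequence[float]],
    group_b: Mapping[str, Sequence[float]],
    mode: str = "linear",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fold-change + p-value selection of differential proteins.

    Fold change is mean(A)/mean(B) on linear concentrations; the p-value is
    a Welch two-sample t on ln concentrations.  Linear mode flags up at
    fold change >= 1.15 and down at <= 0.87; log2 mode at |log2 FC| >= 2.
    Genes with fewer than 2 replicates on either side are skipped.
    Swapping A and B maps up to down with reciprocal fold changes.
    """
    if mode not in {"linear", "log2"}:
        raise ValueError(f"unknown mode {mode!r}")
    common = sorted(set(group_a) & set(group_b))
    if not common:
        raise ValueError("empty gene intersection between groups")
    rows = []
    for gene in common:
        va = np.asarray(group_a[gene], dtype=float)
        vb = np.asarray(group_b[gene], dtype=float)
        va, vb = va[va > 0], vb[vb > 0]
        if len(va) < 2 or len(vb) < 2:
            continue
        fc = va.mean() / vb.mean()
        p = float(sps.ttest_ind(np.log(va), np.log(vb), equal_var=False).pvalue)
        if np.isnan(p):  # degenerate zero-variance groups: decide by equality
            p = 1.0 if np.isclose(np.log(va).mean(), np.log(vb).mean()) else 0.0
        log2_fc = np.log2(fc)
        if mode == "linear":
            direction = "up" if (fc >= 1.15 and p < alpha) else (
                "down" if (fc <= 0.87 and p < alpha) else "ns"
            )
        else:
            direction = "up" if (log2_fc >= 2 and p < alpha) else (
                "down" if (log2_fc <= -2 and p < alpha) else "ns"
            )
        rows.append((gene, fc, log2_fc, p, direction))
    return pd.DataFrame(
        rows, columns=["gene", "fold_change", "log2_fc", "p_value", "direction"]
    )
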