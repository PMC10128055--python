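"""Correlation screens and nonparametric group comparisons.

Pearson tests and Kruskal-Wallis come from scipy; Benjamini-Hochberg
adjustment from statsmodels.  The Dunn post hoc test (rank-based pairwise
comparison after Kruskal-Wallis, with the tie-corrected pooled variance) is
implemented here.  Mid-ranks are used for ties throughout and p-values rely
on the usual normal/chi-square asymptotics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedStatisticError, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    characteristic: str
    n: int
    r: float
    p_raw: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class DunnPair:
    group_i: str
    group_j: str
    z: float
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class GroupTestResult:
    characteristic: str
    h: float
    df: int
    p: float
    pairs: tuple[DunnPair, ...] = ()


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise UndefinedStatisticError("Pearson test needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("Pearson correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k - 1).

    A fully tied data set gives H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("Kruskal-Wallis groups must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValidationError("Kruskal-Wallis needs total n >= 3")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), df, float(p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str = "bh",
) -> list[DunnPair]:
    """Pairwise Dunn z tests on the pooled mid-ranks.

    z_ij = (mean rank_i - mean rank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    where T = sum(t^3 - t)/(12(N-1)) corrects for ties.  Two-sided normal
    p-values; adjusted across pairs by Benjamini-Hochberg (default), Holm,
    or left unadjusted.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("Dunn test needs at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValidationError("Dunn test groups must be non-empty")
    if labels is None:
        labels = [str(i) for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))

    zs, ps, pairs = [], [], []
    for i, j in combinations(range(len(arrays)), 2):
        var = var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        if var <= 0:
            z = 0.0  # every observation tied
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
        pairs.append((i, j))

    if adjust == "bh":
        p_adj = bh_adjust(ps)
    elif adjust == "holm":
        p_adj = multipletests(ps, method="holm")[1]
    elif adjust == "none":
        p_adj = np.asarray(ps)
    else:
        raise ValidationError(f"unknown Dunn adjustment {adjust!r}")
    return [
        DunnPair(labels[i], labels[j], float(z), float(p), float(pa))
        for (i, j), z, p, pa in zip(pairs, zs, ps, p_adj)
    ]


def feature_activity_screen(
    census: pd.DataFrame,
    activity: pd.DataFrame,
    features: Sequence[str] | None = None,
    characteristics: Sequence[str] | None = None,
    alpha: float = 0.05,
    bh_family: int | None = None,
) -> list[CorrelationResult]:
    """Pearson screen of every (feature, characteristic) pair across units.

    ``census`` and ``activity`` are unit-indexed DataFrames (feature
    abundances and activity characteristics); units are aligned on the
    index.  P-values are Benjamini-Hochberg adjusted within each
    characteristic; the family size defaults to the number of features
    actually tested but can be pinned with ``bh_family`` (adjusted values
    are then scaled as if that many tests were run).
    """
    units = census.index.intersection(activity.index)
    if len(units) < 3:
        raise UndefinedStatisticError("screen needs at least 3 aligned units")
    if features is None:
        features = list(census.columns)
    if characteristics is None:
        characteristics = list(activity.columns)
    results: list[CorrelationResult] = []
    for char in characteristics:
        y = activity.loc[units, char].to_numpy(dtype=float)
        rows = []
        for feat in features:
            x = census.loc[units, feat].to_numpy(dtype=float)
            r, p = pearson_test(x, y)
            rows.append((feat, r, p))
        raw = [p for _, _, p in rows]
        m = bh_family if bh_family is not None else len(raw)
        if m < len(raw):
            raise ValidationError("bh_family smaller than the number of tests")
        padded = list(raw) + [1.0] * (m - len(raw))
        adj = bh_adjust(padded)[: len(raw)]
        for (feat, r, p), pa in zip(rows, adj):
            results.append(
                CorrelationResult(
                    feature=feat,
                    characteristic=char,
                    n=len(units),
                    r=r,
                    p_raw=p,
                    p_adj=float(pa),
                    significant=bool(pa < alpha),
                )
            )
    return results


def write_correlation_table(results: Sequence[CorrelationResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
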