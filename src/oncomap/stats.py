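"""Cohort-level statistics: exact 2x2 Fisher, Mann-Whitney U, log-rank,
one-way ANOVA, Benjamini-Hochberg FDR, and Fisher-based pathway enrichment.

All tests are two-sided.  The Fisher test uses the minimum-likelihood
two-sided rule (sum of hypergeometric probabilities not exceeding that of
the observed table); the U test is exact for small untied samples and
normal-approximated with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "logrank_test",
    "one_way_anova",
    "bh_fdr",
    "pathway_enrichment",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    pvalue: float
    method: str
    df: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or np.isnan(self.pvalue)):
            raise ValueError(f"p-value outside [0, 1]: {self.pvalue}")


def _validate_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("contingency table cells must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table cells must be integers")
    if arr.sum() == 0:
        raise ValueError("contingency table is empty (all margins zero)")
    return arr.astype(np.int64)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Rows are groups, columns outcomes.  The two-sided p-value follows the
    minimum-likelihood convention: the sum over all tables with the observed
    margins whose hypergeometric probability does not exceed the observed
    table's (up to a 1 + 1e-7 relative slack).
    """
    arr = _validate_table(table)
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        statistic=float(odds),
        pvalue=float(p),
        method="fisher_exact",
        n=int(arr.sum()),
    )


def mann_whitney_u(x, y, exact_threshold: int = 20) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both samples have at most
    ``exact_threshold`` observations and no ties are present across the
    pooled data; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must contain at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size <= exact_threshold and y.size <= exact_threshold
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        method=f"mann_whitney_u_{method}",
        n=int(x.size + y.size),
    )


def logrank_test(time, event, group) -> TestResult:
    """Multi-group log-rank chi-square test with df = n_groups - 1.

    Tied event times are handled by simultaneous risk-set accounting.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if time.size != event.size or time.size != group.size:
        raise ValueError("time, event and group must have equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    labels = np.unique(group)
    if labels.size < 2:
        raise ValueError("log-rank test requires at least two groups")
    if event.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(time, group, event)
    return TestResult(
        statistic=float(res.test_statistic),
        pvalue=float(res.p_value),
        method="logrank",
        df=float(labels.size - 1),
        n=int(time.size),
    )


def one_way_anova(*groups) -> TestResult:
    """Classical one-way fixed-effects ANOVA F test.

    Degenerate input in which every group is constant is resolved by
    convention: equal means give F = 0, p = 1 (with a warning); unequal
    constant groups give p = 0.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least two observations")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    within_var = sum(float(np.var(a)) for a in arrs)
    if within_var == 0.0:
        means = [float(a.mean()) for a in arrs]
        if np.allclose(means, means[0]):
            warnings.warn(
                "all groups constant with equal means; F = 0, p = 1 by convention"
            )
            return TestResult(0.0, 1.0, "anova", df=float(k - 1), n=n_total)
        return TestResult(np.inf, 0.0, "anova", df=float(k - 1), n=n_total)
    f, p = sps.f_oneway(*arrs)
    return TestResult(float(f), float(p), "anova", df=float(k - 1), n=n_total)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pathway_enrichment(
    hit_genes: Sequence[str],
    pathways: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Per-pathway 2x2 Fisher enrichment of a hit-gene list.

    For each pathway the table is (in/out of pathway) x (hit/not hit) over
    ``universe``; results are sorted by ascending p with BH q-values.

    Raises if any hit gene is absent from the universe.
    """
    universe_set = set(universe)
    hits = set(hit_genes)
    stray = sorted(hits - universe_set)
    if stray:
        raise ValueError(f"hit genes not in universe: {stray}")
    if not pathways:
        raise ValueError("no pathways supplied")
    rows = []
    for name, genes in pathways.items():
        in_path = set(genes) & universe_set
        a = len(in_path & hits)
        b = len(in_path - hits)
        c = len(hits - in_path)
        d = len(universe_set) - a - b - c
        res = fisher_exact_2x2([[a, b], [c, d]])
        rows.append(
            {
                "pathway": name,
                "n_pathway": len(in_path),
                "n_hit_in_pathway": a,
                "odds_ratio": res.statistic,
                "pvalue": res.pvalue,
            }
        )
    out = pd.DataFrame(rows).sort_values("pvalue", kind="stable").reset_index(drop=True)
    out["qvalue"] = bh_fdr(out["pvalue"].to_numpy())
    return out
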