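"""NMF consensus subtyping of expression profiles with survival analysis.

The expression matrix (log2(FPKM+1), genes x samples) is factorized at a
range of ranks with restarts; sample co-assignment frequencies across
restarts form a consensus matrix whose cophenetic correlation guides rank
selection.  Samples are assigned to metagene clusters by dominant activity,
restricted to tumor-specific metagenes; continuous signatures are scored by
correlation or mean-difference against up/down gene templates, and groups
are compared by log-rank tests on Kaplan-Meier curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from . import stats as cstats
from ._nmf import nmf_mu

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

__all__ = [
    "MetageneModel",
    "nmf_metagenes",
    "assign_clusters",
    "tumor_specific_metagenes",
    "preranked_gsea",
    "signature_score",
    "stratify_and_survive",
    "UNASSIGNED",
]


@dataclass
class MetageneModel:
    """Consensus NMF factorization across candidate ranks."""

    W: pd.DataFrame  # genes x k basis (best restart at selected k)
    H: pd.DataFrame  # k x samples activities
    rank: int
    cophenetic: dict[int, float]  # per candidate rank
    consensus: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    objective: float = np.nan


def _consensus_cophenetic(consensus: np.ndarray) -> float:
    """Cophenetic correlation of average-linkage clustering of 1 - consensus."""
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        return 1.0  # degenerate: all pairwise distances equal
    Z = average(condensed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        c, _ = cophenet(Z, condensed)
    return float(c) if np.isfinite(c) else 1.0


def nmf_metagenes(
    matrix: pd.DataFrame,
    k_range=range(2, 11),
    restarts: int = 30,
    seed=None,
    n_top_genes: int | None = 2000,
    cophenetic_threshold: float = 0.95,
    max_iter: int = 300,
) -> MetageneModel:
    """Consensus NMF over a rank range with cophenetic rank selection.

    Euclidean multiplicative updates; per restart, each sample is assigned
    to its dominant metagene and the consensus matrix records co-assignment
    frequency.  The selected rank is the largest candidate whose cophenetic
    correlation is >= ``cophenetic_threshold`` (falling back to the
    smallest candidate with a warning).  ``n_top_genes`` restricts the
    factorization to the most variable genes.
    """
    X = matrix.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("expression matrix must be non-negative")
    n_samples = X.shape[1]
    k_range = [k for k in k_range]
    if max(k_range) >= n_samples:
        raise ValueError("max rank must be smaller than the number of samples")
    if n_top_genes is not None and n_top_genes < matrix.shape[0]:
        var = X.var(axis=1)
        keep = np.argsort(var)[::-1][:n_top_genes]
        keep.sort()
        matrix = matrix.iloc[keep]
        X = matrix.to_numpy(dtype=float)

    ss = np.random.SeedSequence(seed)
    cophenetics: dict[int, float] = {}
    consensus_by_k: dict[int, np.ndarray] = {}
    best_by_k: dict[int, tuple] = {}
    for k in k_range:
        co = np.zeros((n_samples, n_samples))
        best = None
        for child in ss.spawn(restarts):
            res = nmf_mu(X, k, loss="frobenius", max_iter=max_iter, seed=child)
            assign = np.argmax(res.H, axis=0)
            co += (assign[:, None] == assign[None, :]).astype(float)
            if best is None or res.objective < best.objective:
                best = res
        co /= restarts
        consensus_by_k[k] = co
        cophenetics[k] = _consensus_cophenetic(co)
        best_by_k[k] = best

    stable = [k for k in k_range if cophenetics[k] >= cophenetic_threshold]
    if stable:
        rank = max(stable)
    else:
        rank = min(k_range)
        logger.warning(
            "no rank reached cophenetic >= %.2f; falling back to k=%d",
            cophenetic_threshold,
            rank,
        )
    best = best_by_k[rank]
    names = [f"NMF{i + 1}" for i in range(rank)]
    return MetageneModel(
        W=pd.DataFrame(best.W, index=matrix.index, columns=names),
        H=pd.DataFrame(best.H, index=names, columns=matrix.columns),
        rank=rank,
        cophenetic=cophenetics,
        consensus=consensus_by_k,
        objective=best.objective,
    )


def tumor_specific_metagenes(model: MetageneModel, tumor_samples) -> list[str]:
    """Metagenes whose mean activity in tumors exceeds that in the rest
    (normal tissue) of the cohort."""
    tumor = [s for s in model.H.columns if s in set(tumor_samples)]
    normal = [s for s in model.H.columns if s not in set(tumor_samples)]
    if not normal:
        return list(model.H.index)
    mean_t = model.H[tumor].mean(axis=1)
    mean_n = model.H[normal].mean(axis=1)
    return list(model.H.index[mean_t > mean_n])


def assign_clusters(model: MetageneModel, tumor_signature_ids) -> pd.Series:
    """Assign each sample to its dominant metagene if tumor-specific.

    A sample dominated by a non-tumor metagene, or with an exact tie
    between tumor metagenes, is UNASSIGNED.
    """
    ids = list(tumor_signature_ids)
    if not ids:
        raise ValueError("tumor_signature_ids must be non-empty")
    unknown = set(ids) - set(model.H.index)
    if unknown:
        raise ValueError(f"unknown metagenes: {sorted(unknown)}")
    out = {}
    for sample in model.H.columns:
        col = model.H[sample]
        top = col.max()
        winners = list(col.index[col == top])
        if len(winners) > 1:
            logger.warning("activity tie for %s; UNASSIGNED", sample)
            out[sample] = UNASSIGNED
        elif winners[0] in ids:
            out[sample] = winners[0]
        else:
            out[sample] = UNASSIGNED
    return pd.Series(out, name="cluster")


def _es_statistic(ranked_genes: np.ndarray, scores: np.ndarray, in_set: np.ndarray, p: float) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score."""
    w = np.abs(scores) ** p
    hit = np.where(in_set, w, 0.0)
    hit_total = hit.sum()
    if hit_total == 0:
        return 0.0
    n_miss = (~in_set).sum()
    step = hit / hit_total - np.where(in_set, 0.0, 1.0 / n_miss)
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranked_scores: pd.Series, gene_set, nperm: int = 1000, p: float = 1.0, seed=None
) -> dict[str, float]:
    """Pre-ranked GSEA: weighted KS enrichment score with a gene-label
    permutation null and sign-matched tail p-value.

    ``ranked_scores`` maps gene -> ranking score (any order; sorted
    descending internally).  Returns es, nes and pvalue.
    """
    sr = ranked_scores.sort_values(ascending=False)
    genes = sr.index.to_numpy()
    scores = sr.to_numpy(dtype=float)
    gene_set = set(gene_set)
    in_set = np.isin(genes, list(gene_set))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set is disjoint from the ranked universe")
    if n_in == len(genes):
        raise ValueError("gene set covers the whole universe")
    es = _es_statistic(genes, scores, in_set, p)
    rng = np.random.default_rng(seed)
    null = np.empty(nperm)
    for b in range(nperm):
        perm = np.zeros(len(genes), dtype=bool)
        perm[rng.choice(len(genes), size=n_in, replace=False)] = True
        null[b] = _es_statistic(genes, scores, perm, p)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        pval = 1.0 / (nperm + 1)
    else:
        pval = (1 + (np.abs(same_sign) >= abs(es)).sum()) / (1 + same_sign.size)
    nes = es / max(np.abs(same_sign).mean(), 1e-12) if same_sign.size else np.nan
    return {"es": es, "nes": float(nes), "pvalue": float(min(pval, 1.0)), "n_genes": n_in}


def signature_score(
    matrix: pd.DataFrame, up_genes, down_genes=(), mode: str = "correlation"
) -> pd.Series:
    """Per-sample score against an up/down gene signature.

    Genes are z-scored across samples (zero-variance rows dropped with a
    warning).  Correlation mode: Pearson r between the sample's z-profile
    over the signature genes and the +1/-1 template.  Mean-difference mode:
    mean z(up) - mean z(down); with no down genes this is the mean z of the
    up genes (plain module score).
    """
    if mode not in ("correlation", "mean_diff"):
        raise ValueError("mode must be 'correlation' or 'mean_diff'")
    up = [g for g in up_genes if g in matrix.index]
    down = [g for g in down_genes if g in matrix.index]
    if not up and not down:
        raise ValueError("no signature gene present in the matrix")
    sub = matrix.loc[up + down]
    sd = sub.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("dropping %d zero-variance signature genes", int(zero_var.sum()))
        sub = sub.loc[~zero_var]
        up = [g for g in up if g in sub.index]
        down = [g for g in down if g in sub.index]
    if sub.empty:
        raise ValueError("all signature genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    if mode == "mean_diff":
        score = z.loc[up].mean(axis=0) - (z.loc[down].mean(axis=0) if down else 0.0)
        return pd.Series(score, name="signature_score")
    template = np.array([1.0] * len(up) + [-1.0] * len(down))
    zz = z.loc[up + down].to_numpy()
    t_c = template - template.mean()
    out = {}
    for j, sample in enumerate(z.columns):
        v = zz[:, j] - zz[:, j].mean()
        denom = np.linalg.norm(v) * np.linalg.norm(t_c)
        out[sample] = float(v @ t_c / denom) if denom > 0 else 0.0
    return pd.Series(out, name="signature_score")


def stratify_and_survive(
    groups: pd.Series, survival: pd.DataFrame, median_split: bool = False
) -> tuple[cstats.TestResult, pd.DataFrame]:
    """Log-rank comparison of survival across groups, plus KM curves.

    ``groups`` maps sample -> group label, or (with median_split=True)
    sample -> continuous score split at the cohort median (scores equal to
    the median go to the low group).  Returns the test result and a tidy
    table of Kaplan-Meier step coordinates per group.
    """
    sv = survival.set_index("sample_id") if "sample_id" in survival.columns else survival
    common = [s for s in groups.index if s in sv.index]
    g = groups.loc[common]
    if median_split:
        med = float(np.median(g.to_numpy(dtype=float)))
        g = pd.Series(
            np.where(g.to_numpy(dtype=float) <= med, "low", "high"), index=g.index
        )
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("stratification produced fewer than two groups")
    counts = g.value_counts()
    if (counts == 0).any():
        raise ValueError("empty group after stratification")
    times = sv.loc[g.index, "time"].to_numpy(float)
    events = sv.loc[g.index, "event"].to_numpy(int)
    result = cstats.logrank_test(times, events, g.to_numpy())
    km_rows = []
    kmf = KaplanMeierFitter()
    for label in labels:
        mask = (g == label).to_numpy()
        kmf.fit(times[mask], events[mask], label=str(label))
        sf = kmf.survival_function_
        for t, s in zip(sf.index, sf.iloc[:, 0]):
            km_rows.append({"group": label, "time": float(t), "survival": float(s)})
    return result, pd.DataFrame(km_rows)
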