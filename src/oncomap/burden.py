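"""Tumor mutation burden, purity adjustment, hypermutation calling, group
comparisons, and a context-corrected dN/dS selection surrogate.

TMB is the count of exonic somatic mutations per sample, optionally
normalized per Mb of callable target.  The purity correction multiplies the
raw count by 1/purity (mutation detection is diluted proportionally to the
fraction of neoplastic cells); the correction factor is pluggable.

The selection statistic is a deliberately simple surrogate for covariate-
based dN/dS models: observed nonsynonymous/synonymous counts are compared
against a mutational-opportunity expectation via a two-sided binomial test,
with a 0.5 pseudocount keeping ratios finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as cstats
from .variants import annotate_classes

__all__ = [
    "compute_tmb",
    "purity_adjust_tmb",
    "call_hypermutation",
    "compare_burden_and_maf",
    "OpportunityModel",
    "dnds_surrogate",
]


def compute_tmb(variants: pd.DataFrame, target_mb: float, samples=None) -> pd.DataFrame:
    """Per-sample exonic mutation counts and per-Mb burden.

    Counts include silent and non-silent records alike.  ``samples``
    optionally fixes the sample universe so zero-mutation samples appear.
    """
    if target_mb <= 0:
        raise ValueError("target_mb must be positive")
    counts = variants.groupby("sample_id").size()
    if samples is not None:
        counts = counts.reindex(list(samples), fill_value=0)
    out = pd.DataFrame(
        {"sample_id": counts.index, "exonic_count": counts.to_numpy(dtype=int)}
    )
    out["tmb_per_mb"] = out["exonic_count"] / target_mb
    return out.reset_index(drop=True)


def purity_adjust_tmb(
    count, purity, factor: Callable[[float], float] = lambda p: 1.0 / p
):
    """Purity-corrected mutation count: count x factor(purity), default 1/purity."""
    count = np.asarray(count, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if np.any((purity <= 0) | (purity > 1)):
        raise ValueError("purity must be in (0, 1]")
    adj = count * np.vectorize(factor)(purity)
    return adj if adj.ndim else float(adj)


def call_hypermutation(tmb_per_mb, cutoff: float = 10.0) -> tuple[np.ndarray, float]:
    """Hypermutation flags (strictly > cutoff mutations/Mb) and cohort frequency."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tmb = np.asarray(tmb_per_mb, dtype=float)
    flags = tmb > cutoff
    return flags, float(flags.mean()) if flags.size else 0.0


def compare_burden_and_maf(
    variants: pd.DataFrame, metadata: pd.DataFrame, target_mb: float
) -> dict[str, cstats.TestResult]:
    """Benign-vs-malignant U tests on TMB, purity-adjusted TMB, and pooled
    per-mutation allele fractions."""
    groups = metadata.set_index("sample_id")["histology"]
    burden = compute_tmb(variants, target_mb, samples=metadata["sample_id"])
    burden = burden.merge(metadata[["sample_id", "histology", "purity"]], on="sample_id")
    burden["adjusted"] = purity_adjust_tmb(burden["exonic_count"], burden["purity"])
    benign = burden[burden["histology"] == "benign"]
    malig = burden[burden["histology"] == "malignant"]
    if len(benign) < 2 or len(malig) < 2:
        raise ValueError("each histology group needs at least two samples")
    v = variants.merge(metadata[["sample_id", "histology"]], on="sample_id")
    vafs_b = v.loc[v["histology"] == "benign", "vaf"].dropna()
    vafs_m = v.loc[v["histology"] == "malignant", "vaf"].dropna()
    if len(vafs_b) < 2 or len(vafs_m) < 2:
        raise ValueError("each group needs at least two mutations with VAF")
    return {
        "tmb": cstats.mann_whitney_u(benign["exonic_count"], malig["exonic_count"]),
        "adjusted_tmb": cstats.mann_whitney_u(benign["adjusted"], malig["adjusted"]),
        "vaf": cstats.mann_whitney_u(vafs_b, vafs_m),
    }


@dataclass(frozen=True)
class OpportunityModel:
    """Mutational-opportunity expectation for the dN/dS surrogate.

    ``opportunities`` is a genes x (E_N, E_S) table: the expected
    nonsynonymous and synonymous site-change opportunity per gene, already
    weighted by the cohort's channel mutation rates.
    """

    opportunities: pd.DataFrame  # index gene, columns E_N, E_S

    def __post_init__(self) -> None:
        if np.any(self.opportunities[["E_N", "E_S"]].to_numpy() < 0):
            raise ValueError("opportunities must be non-negative")

    @classmethod
    def uniform(cls, genes, ratio_n_to_s: float = 3.0) -> "OpportunityModel":
        """Flat model: every gene has the same E_N:E_S ratio (default 3:1,
        the coding-genome ballpark under the standard code)."""
        df = pd.DataFrame(
            {"E_N": ratio_n_to_s, "E_S": 1.0}, index=pd.Index(genes, name="gene")
        )
        return cls(opportunities=df)


def dnds_surrogate(
    variants: pd.DataFrame, model: OpportunityModel, scope: str = "gene"
) -> pd.DataFrame:
    """Observed-vs-expected nonsynonymous enrichment per gene or per sample.

    dN/dS = ((n_obs + 0.5) / (s_obs + 0.5)) / (E_N / E_S); the p-value is a
    two-sided binomial test of n_obs among n_obs + s_obs against the
    expected proportion E_N / (E_N + E_S), BH-adjusted across the scope.
    """
    if scope not in ("gene", "sample"):
        raise ValueError("scope must be 'gene' or 'sample'")
    v = variants if "non_silent" in variants.columns else annotate_classes(variants)
    v = v[v["variant_class"] == "SNV"] if "variant_class" in v.columns else v
    opp = model.opportunities
    missing = set(v["gene"].dropna()) - set(opp.index)
    if missing:
        raise ValueError(f"opportunity model missing genes: {sorted(missing)[:5]}")
    key = "gene" if scope == "gene" else "sample_id"
    rows = []
    for name, grp in v.groupby(key):
        n_obs = int(grp["non_silent"].sum())
        s_obs = int((~grp["non_silent"]).sum())
        if scope == "gene":
            e_n, e_s = opp.loc[name, "E_N"], opp.loc[name, "E_S"]
        else:
            sub = opp.loc[grp["gene"].dropna().unique()]
            e_n, e_s = float(sub["E_N"].sum()), float(sub["E_S"].sum())
        if e_s == 0:
            raise ValueError(f"E_S = 0 for {scope} {name}: dN/dS undefined")
        p_exp = e_n / (e_n + e_s)
        dnds = ((n_obs + 0.5) / (s_obs + 0.5)) / (e_n / e_s)
        if n_obs + s_obs == 0:
            p = 1.0
        else:
            p = float(sps.binomtest(n_obs, n_obs + s_obs, p_exp).pvalue)
        rows.append(
            {key: name, "n_obs": n_obs, "s_obs": s_obs, "dnds": dnds, "pvalue": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["qvalue"] = cstats.bh_fdr(out["pvalue"].to_numpy())
    return out
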