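"""Post-calling variant filters and mutation-landscape tabulations.

Implements the alignment-error rule based on mean optimal (AS) versus mean
suboptimal (XS) alignment scores of alt-supporting reads, the six-class
functional consequence mapping, recurrent-gene selection, the germline
candidate filter cascade, and pathway aberration fractions.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SITE_KEY = ["chrom", "pos", "ref", "alt"]

MUTATION_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "in-frame indel",
    "splice",
    "silent",
)


def _load_consequence_map() -> dict[str, tuple[str, bool]]:
    with resources.files("oncomap").joinpath("data/consequence_map.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {
        r.consequence: (r.mutation_class, bool(r.non_silent))
        for r in df.itertuples(index=False)
    }


_CONSEQUENCE_MAP = _load_consequence_map()


def classify_consequence(consequence: str) -> tuple[str, bool]:
    """Map a Sequence Ontology consequence term to one of the six mutation
    classes plus a non-silent flag.

    Unknown terms map to ("other", False) with a logged warning; an empty
    string is an error.
    """
    if not consequence:
        raise ValueError("empty consequence string")
    # annotations may carry multiple '&'-joined terms; the first known wins
    for term in str(consequence).split("&"):
        if term in _CONSEQUENCE_MAP:
            return _CONSEQUENCE_MAP[term]
    logger.warning("unknown consequence term %r -> class 'other'", consequence)
    return ("other", False)


def annotate_classes(variants: pd.DataFrame) -> pd.DataFrame:
    """Add mutation_class and non_silent columns derived from consequence.

    Indels override ambiguous annotation: an indel whose net length change
    is divisible by 3 is an in-frame indel, otherwise frameshift.
    """
    out = variants.copy()
    classes, silent_flags = [], []
    for row in out.itertuples(index=False):
        mc, ns = classify_consequence(row.consequence)
        dlen = abs(len(str(row.ref)) - len(str(row.alt)))
        if dlen > 0:
            mc = "in-frame indel" if dlen % 3 == 0 else "frameshift"
            ns = True
        classes.append(mc)
        silent_flags.append(ns)
    out["mutation_class"] = classes
    out["non_silent"] = silent_flags
    return out


def alignment_error_filter(
    variants: pd.DataFrame, scores: pd.DataFrame, ratio: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition variants by the alignment-error rule meanXS >= ratio * meanAS.

    ``scores`` holds one row per alt-supporting read (chrom, pos, ref, alt,
    AS, XS), pooled over all samples sharing the site.  A read with no
    suboptimal hit should carry XS = 0 (missing XS is treated as 0).
    Returns (kept, rejected, audit) where audit lists per-site meanAS and
    meanXS at full precision.
    """
    sc = scores.copy()
    sc["XS"] = sc["XS"].fillna(0.0)
    if not np.isfinite(sc[["AS", "XS"]].to_numpy(dtype=float)).all():
        raise ValueError("alignment scores must be finite")
    site_means = (
        sc.groupby(_SITE_KEY, as_index=False)
        .agg(mean_as=("AS", "mean"), mean_xs=("XS", "mean"), n_reads=("AS", "size"))
    )
    merged = variants.merge(site_means, on=_SITE_KEY, how="left")
    missing = merged["mean_as"].isna()
    if missing.any():
        keys = merged.loc[missing, _SITE_KEY].drop_duplicates()
        raise ValueError(
            "variants with no scored alt-supporting reads: "
            + ", ".join(f"{r.chrom}:{r.pos} {r.ref}>{r.alt}" for r in keys.itertuples())
        )
    rejected_mask = merged["mean_xs"] >= ratio * merged["mean_as"]
    audit = site_means.assign(
        rejected=site_means["mean_xs"] >= ratio * site_means["mean_as"]
    )
    cols = list(variants.columns)
    kept = merged.loc[~rejected_mask, cols].reset_index(drop=True)
    rejected = merged.loc[rejected_mask, cols].reset_index(drop=True)
    return kept, rejected, audit


def mutation_matrix(variants: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Binary genes x samples matrix of non-silent mutation status."""
    if metadata.empty:
        raise ValueError("empty cohort")
    v = variants if "non_silent" in variants.columns else annotate_classes(variants)
    v = v[v["non_silent"] & v["gene"].notna()]
    samples = list(metadata["sample_id"])
    mat = (
        v.assign(hit=1)
        .pivot_table(index="gene", columns="sample_id", values="hit", aggfunc="max", fill_value=0)
        .reindex(columns=samples, fill_value=0)
    )
    return mat.astype(int)


def recurrent_gene_table(
    variants: pd.DataFrame, metadata: pd.DataFrame, min_fraction: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recurrently mutated genes: non-silent in strictly more than
    ``min_fraction`` of samples.

    Returns (matrix, table) where table lists genes ordered by descending
    frequency, ties alphabetical.
    """
    mat = mutation_matrix(variants, metadata)
    n = len(metadata)
    freq = mat.sum(axis=1) / n
    table = (
        pd.DataFrame({"gene": freq.index, "n_mutated": mat.sum(axis=1).values, "frequency": freq.values})
        .sort_values(["frequency", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    table = table[table["frequency"] > min_fraction].reset_index(drop=True)
    return mat, table


_KEEP_PATHOGENICITY = {"truncating", "pathogenic", "likely_pathogenic"}


def filter_germline_candidates(
    records: pd.DataFrame, maf_cutoff: float = 0.05, min_depth: int = 10
) -> pd.DataFrame:
    """Germline predisposing-variant filter cascade.

    Keep a record iff (i) read depth >= min_depth in both tumor and normal,
    or only the normal sample is present with depth >= min_depth; (ii)
    pathogenicity is truncating / pathogenic / likely pathogenic; (iii)
    population MAF is missing (novel) or < maf_cutoff; and (iv) the
    within-cohort MAF is < maf_cutoff.
    """
    df = records.copy()
    dt = df["depth_tumor"]
    dn = df["depth_normal"]
    if (dt.fillna(0) < 0).any() or (dn.fillna(0) < 0).any():
        raise ValueError("negative read depth")
    depth_ok = (dt.notna() & (dt >= min_depth) & (dn >= min_depth)) | (
        dt.isna() & (dn >= min_depth)
    )
    patho_ok = df["pathogenicity"].isin(_KEEP_PATHOGENICITY)
    pop_ok = df["population_maf"].isna() | (df["population_maf"] < maf_cutoff)
    cohort_ok = df["cohort_maf"] < maf_cutoff
    return df[depth_ok & patho_ok & pop_ok & cohort_ok].reset_index(drop=True)


def pathway_aberration_fraction(
    matrix: pd.DataFrame, scna_gene_calls: pd.DataFrame | None, gene_set
) -> float:
    """Fraction of samples with >= 1 non-silent mutation or SCNA call in the
    gene set.  ``scna_gene_calls`` is a genes x samples 0/1 matrix (or None)."""
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    samples = list(matrix.columns)
    sub = matrix.reindex(index=genes).fillna(0)
    hit = set(sub.columns[(sub > 0).any(axis=0)])
    if scna_gene_calls is not None:
        sub = scna_gene_calls.reindex(index=genes, columns=samples).fillna(0)
        hit |= set(sub.columns[(sub > 0).any(axis=0)])
    return len(hit) / len(samples)
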