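"""UCSC chain parsing and cross-genome coordinate projection.

Chains describe gapped syntenic alignments between a source (target, "t")
and destination (query, "q") assembly; all coordinates are 0-based
half-open, tStrand is always '+', and negative-strand q coordinates live on
the reversed sequence (forward position = qSize - 1 - chain offset).
Interval projection maps through aligned blocks only; segment-level copy-
number profiles are projected coverage-weighted onto a fixed bin grid of
the destination genome and re-segmented with CBS.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scna import cbs_segment

logger = logging.getLogger(__name__)

__all__ = [
    "ChainBlock",
    "ChainAlignment",
    "parse_chain",
    "project_interval",
    "project_scna_profile",
    "resegment_profile",
    "cross_cohort_correlation",
]


@dataclass(frozen=True)
class ChainBlock:
    size: int
    dt: int = 0  # gap in target following the block (0 on last)
    dq: int = 0  # gap in query following the block


@dataclass(frozen=True)
class ChainAlignment:
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: tuple[ChainBlock, ...]
    chain_id: str

    def validate(self, line_no: int | None = None) -> None:
        where = f" (chain {self.chain_id}, line {line_no})" if line_no else ""
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"block sizes + dt = {t_span} != tEnd - tStart = "
                f"{self.t_end - self.t_start}{where}"
            )
        if q_span != self.q_end - self.q_start:
            raise ValueError(
                f"block sizes + dq = {q_span} != qEnd - qStart = "
                f"{self.q_end - self.q_start}{where}"
            )
        if any(b.size <= 0 for b in self.blocks):
            raise ValueError(f"non-positive block size{where}")
        if any(b.dt < 0 or b.dq < 0 for b in self.blocks):
            raise ValueError(f"negative gap{where}")


def parse_chain(source) -> list[ChainAlignment]:
    """Parse UCSC chain text (string, path, or .gz path) with validation."""
    if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(str(source)).exists():
        p = Path(source)
        opener = gzip.open if p.suffix == ".gz" else open
        with opener(p, "rt") as fh:
            text = fh.read()
    else:
        text = str(source)
    chains: list[ChainAlignment] = []
    header = None
    blocks: list[tuple[int, int, int]] = []
    header_line = 0
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("chain"):
            if header is not None:
                chains.append(_finish_chain(header, blocks, header_line))
            parts = line.split()
            if len(parts) != 13:
                raise ValueError(f"malformed chain header at line {ln}")
            header = parts
            blocks = []
            header_line = ln
        else:
            parts = line.split()
            if len(parts) == 3:
                blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
            elif len(parts) == 1:
                blocks.append((int(parts[0]), 0, 0))
            else:
                raise ValueError(f"malformed block line at line {ln}: {raw!r}")
    if header is not None:
        chains.append(_finish_chain(header, blocks, header_line))
    return chains


def _finish_chain(parts: list[str], blocks, line_no: int) -> ChainAlignment:
    (_, score, t_name, t_size, t_strand, t_start, t_end,
     q_name, q_size, q_strand, q_start, q_end, cid) = parts
    if t_strand != "+":
        raise ValueError(f"tStrand must be '+' (chain {cid}, line {line_no})")
    chain = ChainAlignment(
        score=float(score),
        t_name=t_name,
        t_size=int(t_size),
        t_start=int(t_start),
        t_end=int(t_end),
        q_name=q_name,
        q_size=int(q_size),
        q_strand=q_strand,
        q_start=int(q_start),
        q_end=int(q_end),
        blocks=tuple(ChainBlock(*b) for b in blocks),
        chain_id=cid,
    )
    chain.validate(line_no)
    return chain


def _chain_pieces(chain: ChainAlignment):
    """Aligned (t_start, t_end, q_chain_start) pieces of one chain."""
    t, q = chain.t_start, chain.q_start
    for b in chain.blocks:
        yield t, t + b.size, q
        t += b.size + b.dt
        q += b.size + b.dq


def _map_subinterval(chain: ChainAlignment, start: int, end: int):
    """Map [start, end) through one chain's aligned blocks.

    Yields (t_lo, t_hi, q_name, q_fwd_lo, q_fwd_hi, strand) pieces in
    forward destination coordinates.
    """
    for t_lo, t_hi, q_lo in _chain_pieces(chain):
        lo, hi = max(start, t_lo), min(end, t_hi)
        if lo >= hi:
            continue
        qc_lo = q_lo + (lo - t_lo)
        qc_hi = qc_lo + (hi - lo)
        if chain.q_strand == "+":
            yield lo, hi, chain.q_name, qc_lo, qc_hi, "+"
        else:
            yield lo, hi, chain.q_name, chain.q_size - qc_hi, chain.q_size - qc_lo, "-"


def _project_pieces(chrom: str, start: int, end: int, chains) -> list[tuple]:
    """Source-to-destination pieces for an interval, best-scoring chain
    winning wherever several chains cover the same source base."""
    relevant = sorted(
        (c for c in chains if c.t_name == chrom), key=lambda c: -c.score
    )
    uncovered = [(start, end)]
    pieces = []
    for chain in relevant:
        if not uncovered:
            break
        remaining = []
        for lo, hi in uncovered:
            hits = sorted(_map_subinterval(chain, lo, hi))
            cursor = lo
            for t_lo, t_hi, q_name, q_lo, q_hi, strand in hits:
                if t_lo > cursor:
                    remaining.append((cursor, t_lo))
                pieces.append((t_lo, t_hi, q_name, q_lo, q_hi, strand))
                cursor = t_hi
            if cursor < hi:
                remaining.append((cursor, hi))
        uncovered = remaining
    return sorted(pieces)


def project_interval(
    chrom: str, start: int, end: int, chains
) -> tuple[list[tuple[str, int, int]], int]:
    """Project a source interval onto the destination genome.

    Returns (intervals, unmapped_bp): destination (chrom, start, end)
    triples merged when adjacent, plus the number of source bases falling
    into alignment gaps or off every chain.
    """
    if start >= end:
        raise ValueError("interval must be non-empty, 0-based half-open")
    pieces = _project_pieces(chrom, start, end, chains)
    mapped_bp = sum(p[1] - p[0] for p in pieces)
    # merge only pieces contiguous in BOTH source and destination
    merged: list[dict] = []
    for t_lo, t_hi, q_name, q_lo, q_hi, strand in pieces:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and t_lo == prev["t_hi"]
            and q_name == prev["q_name"]
            and strand == prev["strand"]
            and (
                (strand == "+" and q_lo == prev["q_hi"])
                or (strand == "-" and q_hi == prev["q_lo"])
            )
        ):
            prev["q_lo"] = min(prev["q_lo"], q_lo)
            prev["q_hi"] = max(prev["q_hi"], q_hi)
            prev["t_hi"] = t_hi
        else:
            merged.append(
                {"q_name": q_name, "q_lo": q_lo, "q_hi": q_hi, "t_hi": t_hi, "strand": strand}
            )
    out = [(m["q_name"], m["q_lo"], m["q_hi"]) for m in merged]
    return out, (end - start) - mapped_bp


def _dest_bins(chains, bin_size: int) -> pd.DataFrame:
    sizes: dict[str, int] = {}
    for c in chains:
        sizes[c.q_name] = max(sizes.get(c.q_name, 0), c.q_size)
    rows = []
    for name in sorted(sizes):
        starts = np.arange(0, sizes[name], bin_size)
        ends = np.minimum(starts + bin_size, sizes[name])
        rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def project_scna_profile(
    segments: pd.DataFrame, chains, bin_size: int = 1_000_000
) -> pd.DataFrame:
    """Coverage-weighted projection of segment log2 ratios onto destination
    bins.

    Each destination bin's value is the mapped-bp-weighted mean of the
    source segments projecting into it; bins with no mapped coverage carry
    NaN.  Columns of ``segments``: chrom, start, end, seg_mean.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins = _dest_bins(chains, bin_size)
    weight = np.zeros(len(bins))
    value = np.zeros(len(bins))
    bin_index = {
        name: np.flatnonzero(bins["chrom"].to_numpy() == name) for name in bins["chrom"].unique()
    }
    any_mapped = False
    for seg in segments.itertuples(index=False):
        for _t_lo, _t_hi, q_name, q_lo, q_hi, _strand in _project_pieces(
            seg.chrom, int(seg.start), int(seg.end), chains
        ):
            any_mapped = True
            idxs = bin_index.get(q_name, ())
            for bi in idxs:
                b_lo, b_hi = bins["start"].iat[bi], bins["end"].iat[bi]
                ov = min(q_hi, b_hi) - max(q_lo, b_lo)
                if ov > 0:
                    weight[bi] += ov
                    value[bi] += ov * seg.seg_mean
    if not any_mapped:
        logger.warning("no chain overlap: projected profile is all-missing")
    out = bins.copy()
    out["coverage"] = weight.astype(int)
    out["value"] = np.where(weight > 0, value / np.maximum(weight, 1e-300), np.nan)
    return out


def resegment_profile(
    binned: pd.DataFrame, smooth_window: int = 5, seed=None, **cbs_kwargs
) -> pd.DataFrame:
    """Centered moving-median smoothing then CBS on a projected profile.

    Bins without coverage are dropped before segmentation.
    """
    df = binned.dropna(subset=["value"]).copy()
    if df.empty:
        raise ValueError("projected profile has no covered bins")
    if smooth_window > 1:
        df["value"] = (
            df.groupby("chrom", sort=False)["value"]
            .transform(lambda s: s.rolling(smooth_window, center=True, min_periods=1).median())
        )
    prof = df.rename(columns={"value": "log2_ratio"})[
        ["chrom", "start", "end", "log2_ratio"]
    ]
    return cbs_segment(prof, seed=seed, **cbs_kwargs)


def cross_cohort_correlation(
    cohort_a: list[pd.DataFrame], cohort_b: list[pd.DataFrame]
) -> dict[str, float]:
    """Pearson correlation of per-bin cohort amplification and deletion
    scores between two cohorts of projected (binned) profiles.

    The per-bin cohort score sums the positive parts (amplification) or
    negative parts (deletion, sign-flipped) of sample values; r is computed
    over bins covered in both cohorts.
    """

    def cohort_scores(cohort):
        vals = np.vstack([p["value"].to_numpy(float) for p in cohort])
        cov = np.vstack([p["coverage"].to_numpy(float) for p in cohort])
        covered = (cov > 0).any(axis=0)
        vals = np.nan_to_num(vals, nan=0.0)
        amp = np.maximum(vals, 0.0).sum(axis=0)
        dele = np.maximum(-vals, 0.0).sum(axis=0)
        return amp, dele, covered

    amp_a, del_a, cov_a = cohort_scores(cohort_a)
    amp_b, del_b, cov_b = cohort_scores(cohort_b)
    if amp_a.size != amp_b.size:
        raise ValueError("cohorts must share the destination bin grid")
    shared = cov_a & cov_b
    if shared.sum() < 3:
        raise ValueError("fewer than 3 bins covered in both cohorts")
    r_amp = sps.pearsonr(amp_a[shared], amp_b[shared]).statistic
    r_del = sps.pearsonr(del_a[shared], del_b[shared]).statistic
    return {"amplification_r": float(r_amp), "deletion_r": float(r_del)}
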