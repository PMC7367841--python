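"""Copy-number analysis from binned tumor/normal read depths.

GC correction divides each bin's depth ratio by the median ratio of its GC
decile; circular binary segmentation (CBS) recursively splits each
chromosome at the arc maximizing a mean-shift z statistic, accepting splits
by permutation test; cohort recurrence uses a simplified G score
(frequency x amplitude above threshold) with a cyclic-shift permutation
null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as cstats

__all__ = [
    "gc_correct_ratio",
    "cbs_segment",
    "genome_fraction_altered",
    "recurrence_peaks",
    "segments_to_bins",
]


def gc_correct_ratio(depth_bins: pd.DataFrame, n_deciles: int = 10) -> pd.DataFrame:
    """GC-corrected log2 tumor/normal depth-ratio profile.

    The raw ratio t/n is normalized by its genome-wide median, then divided
    by the median ratio of the bin's GC decile; log2 is taken last.  Bins
    with zero tumor or normal depth are masked (dropped).  Works on a
    single sample or a multi-sample table (grouped by sample_id).
    """
    if "sample_id" in depth_bins.columns and depth_bins["sample_id"].nunique() > 1:
        return pd.concat(
            [
                gc_correct_ratio(grp, n_deciles)
                for _, grp in depth_bins.groupby("sample_id", sort=False)
            ],
            ignore_index=True,
        )
    df = depth_bins.copy()
    if (df["n_depth"] == 0).all():
        raise ValueError("all normal depths are zero")
    df = df[(df["n_depth"] > 0) & (df["t_depth"] > 0)].copy()
    ratio = df["t_depth"].to_numpy(float) / df["n_depth"].to_numpy(float)
    ratio = ratio / np.median(ratio)
    gc = df["gc"].to_numpy(float)
    if np.unique(gc).size >= n_deciles:
        edges = np.quantile(gc, np.linspace(0, 1, n_deciles + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        decile = np.searchsorted(edges, gc, side="right") - 1
        for d in np.unique(decile):
            med = np.median(ratio[decile == d])
            if med > 0:
                ratio[decile == d] /= med
    df["log2_ratio"] = np.log2(ratio)
    cols = ["chrom", "start", "end", "gc", "log2_ratio"]
    if "sample_id" in df.columns:
        cols = ["sample_id"] + cols
    return df[cols].reset_index(drop=True)


def _max_arc_stat(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal |z| over circular arcs of a centred profile.

    Because the arc statistic equals that of its complement, scanning
    contiguous windows of width min_width..n-min_width suffices.  Returns
    (max |z|, i, j) for the best window x[i:j].
    """
    n = x.size
    S = np.concatenate([[0.0], np.cumsum(x)])
    mean = S[-1] / n
    sd = x.std()
    if sd == 0:
        return 0.0, 0, n
    best, bi, bj = -1.0, 0, n
    for w in range(min_width, n - min_width + 1):
        d = S[w:] - S[:-w]  # window sums, all starts
        z = np.abs(d - w * mean) / (sd * np.sqrt(w * (1.0 - w / n)))
        k = int(np.argmax(z))
        if z[k] > best:
            best, bi, bj = float(z[k]), k, k + w
    return best, bi, bj


def _split_perm_p(
    x: np.ndarray, observed: float, min_width: int, nperm: int, alpha: float,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value for the best arc split, with early stopping once
    significance at ``alpha`` is impossible."""
    exceed = 0
    limit = int(np.floor(alpha * nperm))
    for b in range(nperm):
        perm = rng.permutation(x)
        stat, _, _ = _max_arc_stat(perm, min_width)
        if stat >= observed:
            exceed += 1
            if exceed > limit:
                return (exceed) / (b + 1)
    return exceed / nperm


def _segment_one(
    x: np.ndarray, offset: int, alpha: float, nperm: int, min_width: int,
    rng: np.random.Generator, out: list,
) -> None:
    n = x.size
    if n < 2 * min_width:
        out.append((offset, offset + n))
        return
    stat, i, j = _max_arc_stat(x, min_width)
    if stat <= 0:
        out.append((offset, offset + n))
        return
    p = _split_perm_p(x, stat, min_width, nperm, alpha, rng)
    if p > alpha:
        out.append((offset, offset + n))
        return
    cuts = [c for c in (i, j) if 0 < c < n]
    if not cuts:
        out.append((offset, offset + n))
        return
    prev = 0
    for c in cuts + [n]:
        _segment_one(x[prev:c], offset + prev, alpha, nperm, min_width, rng, out)
        prev = c


def cbs_segment(
    profile: pd.DataFrame,
    alpha: float = 0.01,
    nperm: int = 1000,
    min_width: int = 3,
    seed=None,
) -> pd.DataFrame:
    """Circular binary segmentation of a log2-ratio profile.

    Per chromosome, the arc maximizing the mean-shift z statistic is tested
    against ``nperm`` within-chromosome permutations; splits with p <= alpha
    are accepted recursively.  Segments never cross chromosome boundaries.
    Columns of ``profile``: chrom, start, end, log2_ratio (bins ordered).
    Returns segments with chrom, start, end (bp), n_bins, seg_mean.
    """
    if profile.empty:
        raise ValueError("empty profile")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in profile.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        x = grp["log2_ratio"].to_numpy(float)
        starts = grp["start"].to_numpy(int)
        ends = grp["end"].to_numpy(int)
        pieces: list[tuple[int, int]] = []
        _segment_one(x, 0, alpha, nperm, min_width, rng, pieces)
        pieces.sort()
        for lo, hi in pieces:
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[lo]),
                    "end": int(ends[hi - 1]),
                    "n_bins": hi - lo,
                    "seg_mean": float(x[lo:hi].mean()),
                }
            )
    return pd.DataFrame(rows)


def genome_fraction_altered(segments: pd.DataFrame, threshold: float = 0.2) -> float:
    """Length fraction of the segmented genome with |seg_mean| strictly
    above ``threshold``."""
    length = (segments["end"] - segments["start"]).to_numpy(float)
    altered = np.abs(segments["seg_mean"].to_numpy(float)) > threshold
    total = length.sum()
    if total == 0:
        raise ValueError("segments have zero total length")
    return float(length[altered].sum() / total)


def segments_to_bins(segments: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Per-bin seg_mean vector on a fixed bin grid (NaN where uncovered)."""
    values = np.full(len(bins), np.nan)
    b_chrom = bins["chrom"].to_numpy()
    b_start = bins["start"].to_numpy(int)
    b_end = bins["end"].to_numpy(int)
    for seg in segments.itertuples(index=False):
        mask = (b_chrom == seg.chrom) & (b_start < seg.end) & (b_end > seg.start)
        values[mask] = seg.seg_mean
    return values


def recurrence_peaks(
    sample_segments: list[pd.DataFrame],
    bins: pd.DataFrame,
    amp_thr: float = 0.2,
    del_thr: float = -0.2,
    nperm: int = 1000,
    q_cutoff: float = 0.25,
    seed=None,
) -> pd.DataFrame:
    """Recurrent amplification/deletion peaks by a simplified G score.

    Per bin, G_amp = sum over samples of max(seg_mean - amp_thr, 0) (and the
    mirror image for deletions).  The null preserves each sample's segment
    structure by cyclic shift of its whole-genome bin profile; per-bin
    p-values come from the pooled null distribution, BH-adjusted, and peaks
    are maximal same-chromosome runs of bins with q <= q_cutoff.
    """
    if len(sample_segments) < 2:
        raise ValueError("recurrence requires at least two samples")
    rng = np.random.default_rng(seed)
    profiles = np.vstack([segments_to_bins(s, bins) for s in sample_segments])
    profiles = np.nan_to_num(profiles, nan=0.0)
    n_bins = profiles.shape[1]

    def g_scores(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        amp = np.maximum(mat - amp_thr, 0.0).sum(axis=0)
        dele = np.maximum(del_thr - mat, 0.0).sum(axis=0)
        return amp, dele

    g_amp, g_del = g_scores(profiles)
    null_amp = np.empty((nperm, n_bins))
    null_del = np.empty((nperm, n_bins))
    for b in range(nperm):
        shifted = np.vstack(
            [np.roll(row, rng.integers(0, n_bins)) for row in profiles]
        )
        null_amp[b], null_del[b] = g_scores(shifted)

    def bin_q(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
        pooled = np.sort(null.ravel())
        p = 1.0 - np.searchsorted(pooled, obs, side="left") / pooled.size
        p = np.clip(p, 1.0 / pooled.size, 1.0)
        return cstats.bh_fdr(p)

    rows = []
    for kind, g, null in (("amplification", g_amp, null_amp), ("deletion", g_del, null_del)):
        if g.max() <= 0:
            continue
        q = bin_q(g, null)
        sig = (q <= q_cutoff) & (g > 0)
        chroms = bins["chrom"].to_numpy()
        i = 0
        while i < n_bins:
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < n_bins and sig[j + 1] and chroms[j + 1] == chroms[i]:
                j += 1
            rows.append(
                {
                    "kind": kind,
                    "chrom": chroms[i],
                    "start": int(bins["start"].iloc[i]),
                    "end": int(bins["end"].iloc[j]),
                    "g_score": float(g[i : j + 1].max()),
                    "q": float(q[i : j + 1].min()),
                }
            )
            i = j + 1
    return pd.DataFrame(rows, columns=["kind", "chrom", "start", "end", "g_score", "q"])
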