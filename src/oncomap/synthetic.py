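"""Synthetic tumor-cohort generator with planted ground truth.

Emulates every input of the comparative-oncogenomics pipeline: a cohort of
benign and malignant tumors with histology-dependent driver-mutation
frequencies and signature-mixture-driven trinucleotide spectra, purity-
diluted allele fractions, binned tumor/normal read depths with GC bias and
planted copy-number segments, a toy two-genome chain alignment with an
exact per-base map, and a block-structured expression matrix with planted
metagene clusters whose hazard rates differ.

Reproducibility contract: every generator derives one RNG sub-stream per
sample (or per logical unit) from ``(seed, stream-tag, index)`` so that
enlarging a cohort never reshuffles previously generated samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mutsig import CHANNELS, SignatureCatalog, revcomp

__all__ = [
    "CohortSpec",
    "GenomeSpec",
    "ExpressionSpec",
    "ToyChainMap",
    "generate_reference",
    "generate_mutation_cohort",
    "generate_depth_bins",
    "generate_expression_cohort",
    "generate_toy_chain",
    "default_catalog",
]

# fixed stream tags: adding samples must not reshuffle earlier ones
_STREAM_MUT = 11
_STREAM_PURITY = 12
_STREAM_DEPTH = 13
_STREAM_GC = 14
_STREAM_EXPR = 15
_STREAM_SURV = 16
_STREAM_REF = 17


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic DNA cohort.

    ``driver_freqs`` maps gene name to (benign, malignant) per-sample
    mutation probabilities; ``signature_weights`` mixes the rows of a
    signature catalog; ``tmb_rate`` is the mean number of exonic background
    mutations per sample; ``target_mb`` the callable-region size in Mb.
    """

    n_samples: int
    benign_fraction: float
    driver_freqs: Mapping[str, tuple[float, float]]
    signature_weights: tuple[float, ...]
    tmb_rate: float
    purity_range: tuple[float, float] = (0.7, 1.0)
    target_mb: float = 38.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.benign_fraction <= 1.0:
            raise ValueError("benign_fraction must be in [0, 1]")
        w = np.asarray(self.signature_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("signature_weights must be non-negative and sum to 1")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must satisfy 0 < low <= high <= 1")
        for gene, (bf, mf) in self.driver_freqs.items():
            if not (0.0 <= bf <= 1.0 and 0.0 <= mf <= 1.0):
                raise ValueError(f"driver frequencies for {gene} must be in [0, 1]")
        if self.tmb_rate <= 0:
            raise ValueError("tmb_rate must be positive")

    @property
    def n_benign(self) -> int:
        return int(round(self.benign_fraction * self.n_samples))


@dataclass(frozen=True)
class GenomeSpec:
    """Toy genome layout: chromosome sizes, depth bins, planted segments.

    ``planted_segments`` are (chrom, start, end, true_log2) tuples in bp,
    0-based half-open; ``gc_profile`` optionally fixes the per-bin GC
    fraction (otherwise drawn once per depth-generation call).
    """

    chrom_lengths: Mapping[str, int]
    bin_size: int
    planted_segments: tuple[tuple[str, int, int, float], ...] = ()
    gc_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, start, end, _log2 in self.planted_segments:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"planted segment on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"planted segment out of bounds: {chrom}:{start}-{end}")
        if self.gc_profile is not None:
            gc = np.asarray(self.gc_profile, float)
            if len(gc) != len(self.bins()):
                raise ValueError("gc_profile length must equal the number of bins")
            if np.any((gc < 0) | (gc > 1)):
                raise ValueError("gc fractions must be in [0, 1]")

    def bins(self) -> pd.DataFrame:
        """Half-open bins tiling every chromosome (last bin truncated)."""
        rows = []
        for chrom, length in self.chrom_lengths.items():
            starts = np.arange(0, length, self.bin_size)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def true_log2_per_bin(self) -> np.ndarray:
        bins = self.bins()
        log2 = np.zeros(len(bins))
        for chrom, start, end, value in self.planted_segments:
            mask = (
                (bins["chrom"] == chrom)
                & (bins["start"] < end)
                & (bins["end"] > start)
            )
            log2[mask.to_numpy()] = value
        return log2


@dataclass(frozen=True)
class ExpressionSpec:
    """Planted-metagene expression cohort with cluster-specific hazards."""

    n_samples: int
    n_genes: int
    k_true: int
    cluster_props: tuple[float, ...]
    hazards: tuple[float, ...]
    loading_scale: float = 5.0
    noise_sd: float = 0.5
    censor_rate: float = 0.02
    n_normal: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.k_true > self.n_samples:
            raise ValueError("k_true cannot exceed n_samples")
        props = np.asarray(self.cluster_props, float)
        if len(props) != self.k_true or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_props must have length k_true and sum to 1")
        if len(self.hazards) != self.k_true or any(h <= 0 for h in self.hazards):
            raise ValueError("hazards must be positive, one per cluster")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.loading_scale <= 0:
            raise ValueError("loading_scale must be positive")


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream, index)))


def generate_reference(genome: GenomeSpec, seed: int = 0) -> dict[str, str]:
    """I.i.d. uniform ACGT reference sequence for each chromosome."""
    bases = np.array(list("ACGT"))
    ref = {}
    for i, (chrom, length) in enumerate(genome.chrom_lengths.items()):
        rng = _rng(seed, _STREAM_REF, i)
        ref[chrom] = "".join(bases[rng.integers(0, 4, size=length)])
    return ref


def default_catalog(n_signatures: int = 4, seed: int = 12345) -> SignatureCatalog:
    """A small synthetic signature catalog.

    The first signature mimics the dominance of spontaneous CpG-deamination
    style C>T mutations (mass concentrated on C>T channels); the others are
    random sparse profiles, so mixtures remain identifiable.
    """
    rng = np.random.default_rng(seed)
    K = n_signatures
    profiles = np.zeros((K, 96))
    ct = [i for i, c in enumerate(CHANNELS) if "[C>T]" in c]
    profiles[0, ct] = rng.dirichlet(np.full(len(ct), 2.0))
    for k in range(1, K):
        support = rng.choice(96, size=24, replace=False)
        profiles[k, support] = rng.dirichlet(np.full(24, 1.0))
    names = [f"SYN{k + 1}" for k in range(K)]
    return SignatureCatalog(
        profiles=pd.DataFrame(profiles, index=names, columns=list(CHANNELS))
    )


def _context_index(reference: Mapping[str, str]) -> dict[str, list[tuple[str, int, int]]]:
    """Map each pyrimidine-centred triplet to (chrom, pos, strand) sites.

    strand +1: forward triplet equals the key; -1: forward triplet is the
    key's reverse complement (reference base is the purine partner).
    """
    index: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, seq in reference.items():
        s = str(seq).upper()
        for pos in range(1, len(s) - 1):
            tri = s[pos - 1 : pos + 2]
            if "N" in tri:
                continue
            if tri[1] in "CT":
                index.setdefault(tri, []).append((chrom, pos, +1))
            else:
                index.setdefault(revcomp(tri), []).append((chrom, pos, -1))
    return index


def _sample_ids(spec: CohortSpec) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(spec.n_samples)]


def _histologies(spec: CohortSpec) -> np.ndarray:
    n_b = spec.n_benign
    return np.array(["benign"] * n_b + ["malignant"] * (spec.n_samples - n_b))


def sample_purities(spec: CohortSpec) -> np.ndarray:
    """Per-sample tumor purity, one dedicated sub-stream per sample."""
    lo, hi = spec.purity_range
    return np.array(
        [
            _rng(spec.seed, _STREAM_PURITY, i).uniform(lo, hi)
            for i in range(spec.n_samples)
        ]
    )


_BACKGROUND_CSQ = ("missense_variant", "synonymous_variant", "stop_gained", "splice_acceptor_variant")
_BACKGROUND_CSQ_P = (0.55, 0.30, 0.10, 0.05)


def generate_mutation_cohort(
    spec: CohortSpec,
    genome: GenomeSpec,
    reference: Mapping[str, str],
    catalog: SignatureCatalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Somatic variant table plus sample metadata with planted truth.

    Per sample: background mutation count ~ Poisson(tmb_rate); trinucleotide
    channels drawn from the catalog mixture and placed at matching reference
    positions; driver genes mutated by histology-specific Bernoulli draws;
    VAF = clonal fraction x purity / 2 with binomial read-sampling noise at
    depth 100.  Clonal fractions are Uniform(0.2, 1) in benign and
    Uniform(0.5, 1) in malignant samples, so malignant allele fractions are
    stochastically larger.
    """
    if catalog is None:
        catalog = default_catalog(n_signatures=len(spec.signature_weights))
    weights = np.asarray(spec.signature_weights, float)
    if len(weights) != len(catalog.names):
        raise ValueError("signature_weights length must match catalog size")
    channel_p = weights @ catalog.matrix()
    channel_p = channel_p / channel_p.sum()

    ctx_index = _context_index(reference)
    ids = _sample_ids(spec)
    histology = _histologies(spec)
    purity = sample_purities(spec)
    drivers = sorted(spec.driver_freqs)

    rows = []
    for i, sid in enumerate(ids):
        rng = _rng(spec.seed, _STREAM_MUT, i)
        benign = histology[i] == "benign"
        cf_lo = 0.2 if benign else 0.5
        n_mut = rng.poisson(spec.tmb_rate)
        channels = rng.choice(96, size=n_mut, p=channel_p)
        planted = [(int(ch), None) for ch in channels]
        for gene in drivers:
            bf, mf = spec.driver_freqs[gene]
            if rng.random() < (bf if benign else mf):
                planted.append((int(rng.choice(96, p=channel_p)), gene))
        for ch_idx, gene in planted:
            ch = CHANNELS[ch_idx]
            five, mid, three = ch[0], ch[2:5], ch[6]
            ref_base, alt_base = mid.split(">")
            tri = five + ref_base + three
            sites = ctx_index.get(tri)
            if not sites:
                raise ValueError(f"reference contains no site for channel {ch}")
            chrom, pos, strand = sites[rng.integers(0, len(sites))]
            if strand < 0:
                ref_base, alt_base = revcomp(ref_base), revcomp(alt_base)
            cf = rng.uniform(cf_lo, 1.0)
            true_vaf = cf * purity[i] / 2.0
            depth = 100
            vaf = rng.binomial(depth, true_vaf) / depth
            if gene is None:
                csq = _BACKGROUND_CSQ[rng.choice(len(_BACKGROUND_CSQ), p=_BACKGROUND_CSQ_P)]
                gene_name = f"BG{rng.integers(0, 500):03d}"
            else:
                csq = "missense_variant"
                gene_name = gene
            rows.append(
                {
                    "sample_id": sid,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref_base,
                    "alt": alt_base,
                    "variant_class": "SNV",
                    "consequence": csq,
                    "gene": gene_name,
                    "vaf": vaf,
                }
            )
    variants = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chrom", "pos", "ref", "alt",
            "variant_class", "consequence", "gene", "vaf",
        ],
    )
    ages = np.array(
        [float(_rng(spec.seed, _STREAM_SURV, i).integers(5, 15)) for i in range(spec.n_samples)]
    )
    metadata = pd.DataFrame(
        {"sample_id": ids, "histology": histology, "purity": purity, "age": ages}
    )
    return variants, metadata


def generate_depth_bins(
    spec: CohortSpec,
    genome: GenomeSpec,
    base_depth: float = 100.0,
    tumor_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binned tumor/normal read depths with GC bias and planted segments.

    Normal depth is Poisson around a GC-dependent mean (monotone bias,
    mean = base_depth * (0.5 + gc)); tumor depth is additionally scaled by
    the purity-diluted copy ratio of any planted segment overlapping the
    bin.  Columns: sample_id, chrom, start, end, gc, t_depth, n_depth.
    """
    bins = genome.bins()
    n_bins = len(bins)
    if genome.gc_profile is not None:
        gc = np.asarray(genome.gc_profile, float)
    else:
        gc = _rng(spec.seed, _STREAM_GC).uniform(0.3, 0.7, size=n_bins)
    true_log2 = genome.true_log2_per_bin()
    purity = sample_purities(spec)
    ids = _sample_ids(spec)
    if tumor_samples is not None:
        keep = set(tumor_samples)
        picks = [(i, s) for i, s in enumerate(ids) if s in keep]
    else:
        picks = list(enumerate(ids))
    mean_n = base_depth * (0.5 + gc)
    frames = []
    for i, sid in picks:
        rng = _rng(spec.seed, _STREAM_DEPTH, i)
        ratio = purity[i] * np.exp2(true_log2) + (1.0 - purity[i])
        n_depth = rng.poisson(mean_n)
        t_depth = rng.poisson(mean_n * ratio)
        df = bins.copy()
        df.insert(0, "sample_id", sid)
        df["gc"] = gc
        df["t_depth"] = t_depth
        df["n_depth"] = n_depth
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_expression_cohort(
    spec: ExpressionSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Expression matrix, survival table and true cluster labels.

    Genes are split into k_true blocks; a sample in cluster c expresses
    block c at ``loading_scale`` plus half-normal noise everywhere.  Tumor
    survival times are exponential with per-cluster hazard under independent
    exponential censoring.  Optional ``n_normal`` appends normal samples
    expressing a dedicated extra gene block (no survival records).
    """
    k = spec.k_true
    props = np.asarray(spec.cluster_props, float)
    # largest-remainder apportionment keeps every cluster populated
    counts = np.floor(props * spec.n_samples).astype(int)
    while counts.sum() < spec.n_samples:
        counts[np.argmax(props * spec.n_samples - counts)] += 1
    labels = np.repeat(np.arange(k), counts)
    perm = _rng(spec.seed, _STREAM_EXPR, 0).permutation(spec.n_samples)
    labels = labels[perm]

    n_blocks = k + (1 if spec.n_normal > 0 else 0)
    block_edges = np.linspace(0, spec.n_genes, n_blocks + 1).astype(int)
    total = spec.n_samples + spec.n_normal
    ids = [f"T{i + 1:03d}" for i in range(spec.n_samples)] + [
        f"N{i + 1:03d}" for i in range(spec.n_normal)
    ]
    X = np.zeros((spec.n_genes, total))
    for j in range(total):
        rng = _rng(spec.seed, _STREAM_EXPR, j + 1)
        block = labels[j] if j < spec.n_samples else k
        lo, hi = block_edges[block], block_edges[block + 1]
        col = np.abs(rng.normal(0.0, spec.noise_sd, size=spec.n_genes))
        col[lo:hi] += spec.loading_scale
        X[:, j] = col
    expr = pd.DataFrame(
        X, index=[f"G{g + 1:04d}" for g in range(spec.n_genes)], columns=ids
    )

    times, events = [], []
    for j in range(spec.n_samples):
        rng = _rng(spec.seed, _STREAM_SURV, j + 1)
        t_event = rng.exponential(1.0 / spec.hazards[labels[j]])
        t_cens = (
            rng.exponential(1.0 / spec.censor_rate) if spec.censor_rate > 0 else np.inf
        )
        times.append(min(t_event, t_cens))
        events.append(int(t_event <= t_cens))
    survival = pd.DataFrame(
        {"sample_id": ids[: spec.n_samples], "time": times, "event": events}
    )
    label_sr = pd.Series(
        list(labels) + ["normal"] * spec.n_normal, index=ids, name="true_cluster"
    )
    return expr, survival, label_sr


@dataclass
class ToyChainMap:
    """A generated chain file plus its exact per-base source-to-target map."""

    text: str
    per_base: dict[str, list]  # chrom -> list of (q_chrom, q_pos) or None

    def map_base(self, chrom: str, pos: int):
        lst = self.per_base.get(chrom)
        if lst is None or pos < 0 or pos >= len(lst):
            return None
        return lst[pos]


def generate_toy_chain(
    genome: GenomeSpec,
    edits: Sequence[tuple[str, int, int, str, str, int]],
    q_chrom_sizes: Mapping[str, int],
) -> ToyChainMap:
    """Emit UCSC chain text for a toy two-genome alignment.

    Each edit is (t_chrom, t_start, t_end, q_chrom, q_strand, q_start) with
    q_start in chain coordinates (i.e. on the reversed sequence when
    q_strand is '-').  Consecutive collinear edits merge into one chain
    with dt/dq gaps; an exact per-base forward-strand map accompanies the
    text for oracle testing.  Overlapping source blocks are an error.
    """
    by_chrom: dict[str, list] = {}
    for e in edits:
        t_chrom, t_start, t_end, q_chrom, q_strand, q_start = e
        if t_chrom not in genome.chrom_lengths:
            raise ValueError(f"unknown source chromosome {t_chrom}")
        if q_chrom not in q_chrom_sizes:
            raise ValueError(f"unknown target chromosome {q_chrom}")
        if not (0 <= t_start < t_end <= genome.chrom_lengths[t_chrom]):
            raise ValueError(f"block out of source bounds: {e}")
        size = t_end - t_start
        if not (0 <= q_start and q_start + size <= q_chrom_sizes[q_chrom]):
            raise ValueError(f"block out of target bounds: {e}")
        if q_strand not in "+-":
            raise ValueError(f"bad strand {q_strand!r}")
        by_chrom.setdefault(t_chrom, []).append(e)

    per_base = {
        chrom: [None] * length for chrom, length in genome.chrom_lengths.items()
    }
    chains: list[list] = []  # groups of collinear edits
    for chrom, blocks in by_chrom.items():
        blocks = sorted(blocks, key=lambda b: b[1])
        for prev, cur in zip(blocks, blocks[1:]):
            if cur[1] < prev[2]:
                raise ValueError(f"overlapping source blocks on {chrom}: {prev} / {cur}")
        group: list = []
        for b in blocks:
            if group:
                p = group[-1]
                collinear = (
                    b[3] == p[3]
                    and b[4] == p[4]
                    and b[1] >= p[2]
                    and b[5] >= p[5] + (p[2] - p[1])
                )
            else:
                collinear = False
            if collinear:
                group.append(b)
            else:
                if group:
                    chains.append(group)
                group = [b]
        if group:
            chains.append(group)

    lines = []
    for cid, group in enumerate(chains, start=1):
        t_chrom = group[0][0]
        q_chrom, q_strand = group[0][3], group[0][4]
        t_size = genome.chrom_lengths[t_chrom]
        q_size = q_chrom_sizes[q_chrom]
        t_start, t_end = group[0][1], group[-1][2]
        q_start = group[0][5]
        q_end = group[-1][5] + (group[-1][2] - group[-1][1])
        score = sum(b[2] - b[1] for b in group)
        lines.append(
            f"chain {score} {t_chrom} {t_size} + {t_start} {t_end} "
            f"{q_chrom} {q_size} {q_strand} {q_start} {q_end} {cid}"
        )
        for i, b in enumerate(group):
            size = b[2] - b[1]
            for off in range(size):
                qc = b[5] + off
                fwd = qc if q_strand == "+" else q_size - 1 - qc
                per_base[t_chrom][b[1] + off] = (q_chrom, fwd)
            if i + 1 < len(group):
                nxt = group[i + 1]
                dt = nxt[1] - b[2]
                dq = nxt[5] - (b[5] + size)
                lines.append(f"{size}\t{dt}\t{dq}")
            else:
                lines.append(f"{size}")
        lines.append("")
    return ToyChainMap(text="\n".join(lines) + "\n", per_base=per_base)
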