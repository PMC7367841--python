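"""Trinucleotide mutational-signature analysis.

Single-base substitutions are tabulated into the standard 96 channels
(6 pyrimidine-strand substitution classes x 16 flanking-base contexts),
deconvolved de novo by KL-loss NMF, matched to a reference catalog by
cosine similarity, and attributed to catalog signatures by non-negative
least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._nmf import NMFResult, nmf_best_of

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Fixed 96-channel order: substitution classes in the order above, flanking
#: contexts alphabetical within each class, e.g. "A[C>A]A", "A[C>A]C", ...
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, five: str, three: str) -> str:
    """Channel name for an SNV, reverse-complemented to the pyrimidine strand."""
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
        five, three = _COMP[three], _COMP[five]
    name = f"{five}[{ref}>{alt}]{three}"
    if name not in _CHANNEL_INDEX:
        raise ValueError(f"not a valid substitution channel: {name}")
    return name


def build_spectrum(variants: pd.DataFrame, reference) -> pd.DataFrame:
    """Per-sample 96-channel trinucleotide spectra.

    ``variants`` needs columns sample_id, chrom, pos (0-based), ref, alt;
    ``reference`` maps chromosome name to sequence (dict of str or a
    pyfaidx.Fasta).  Non-SNV records are skipped (count logged), as are
    SNVs whose +/-1 context contains N.  A position outside the reference
    is an error.
    """
    samples = list(pd.unique(variants["sample_id"]))
    counts = pd.DataFrame(
        np.zeros((len(samples), 96), dtype=int), index=samples, columns=list(CHANNELS)
    )
    counts.index.name = "sample_id"
    n_indel = 0
    n_skipped_context = 0
    for row in variants.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            n_indel += 1
            continue
        seq = reference[row.chrom]
        pos = int(row.pos)
        if pos < 1 or pos + 1 >= len(seq):
            raise ValueError(
                f"SNV at {row.chrom}:{pos} lacks +/-1 context in the reference"
            )
        tri = str(seq[pos - 1 : pos + 2]).upper()
        if tri[1] != ref:
            raise ValueError(
                f"reference mismatch at {row.chrom}:{pos}: expected {ref}, found {tri[1]}"
            )
        if "N" in tri:
            n_skipped_context += 1
            continue
        ch = channel_of(ref, alt, tri[0], tri[2])
        counts.loc[row.sample_id, ch] += 1
    if n_indel:
        logger.info("build_spectrum: skipped %d non-SNV records", n_indel)
    if n_skipped_context:
        logger.warning(
            "build_spectrum: skipped %d SNVs with N in context", n_skipped_context
        )
    return counts


@dataclass
class SignatureCatalog:
    """Reference signature catalog: K row-stochastic 96-channel profiles."""

    profiles: pd.DataFrame  # K x 96, rows sum to 1

    def __post_init__(self) -> None:
        prof = self.profiles.reindex(columns=list(CHANNELS))
        if prof.isna().any().any():
            missing = [c for c in CHANNELS if c not in self.profiles.columns]
            raise ValueError(f"catalog missing channels, e.g. {missing[:3]}")
        arr = prof.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise ValueError("catalog profiles must be non-negative")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("catalog rows must sum to 1 within 1e-6")
        self.profiles = prof

    @property
    def names(self) -> list[str]:
        return list(self.profiles.index)

    def matrix(self) -> np.ndarray:
        return self.profiles.to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        # accept either orientation: channels x signatures or signatures x channels
        if set(df.index) >= set(CHANNELS):
            df = df.T
        return cls(profiles=df.astype(float))

    def to_tsv(self, path) -> None:
        self.profiles.T.to_csv(path, sep="\t")


@dataclass
class ExposureSolution:
    """Non-negative attribution of a spectrum to catalog signatures."""

    exposures: pd.Series  # mutations attributed per signature
    residual: float  # Euclidean norm of the unexplained counts
    cosine_to_reconstruction: float

    @property
    def proportions(self) -> pd.Series:
        total = self.exposures.sum()
        return self.exposures / total if total > 0 else self.exposures


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_catalog(profile, catalog: SignatureCatalog) -> pd.DataFrame:
    """Cosine similarity of a 96-channel profile to every catalog signature,
    ranked descending; ties keep catalog order."""
    p = np.asarray(profile, dtype=float)
    if p.shape != (96,):
        raise ValueError("profile must be a 96-vector")
    if np.any(p < 0):
        raise ValueError("profile must be non-negative")
    if p.sum() == 0:
        raise ValueError("profile is all-zero")
    sims = [_cosine(p, row) for row in catalog.matrix()]
    out = pd.DataFrame({"signature": catalog.names, "cosine": sims})
    return out.sort_values("cosine", ascending=False, kind="stable").reset_index(
        drop=True
    )


def fit_exposures(spectrum, catalog: SignatureCatalog) -> ExposureSolution:
    """Attribute a 96-channel count spectrum to catalog signatures by NNLS.

    Solves min ||counts - A e||_2 over e >= 0 where A's columns are the
    catalog profiles.
    """
    c = np.asarray(spectrum, dtype=float)
    if c.shape != (96,):
        raise ValueError("spectrum must be a 96-vector")
    if c.sum() == 0:
        raise ValueError("spectrum is empty")
    A = catalog.matrix().T  # 96 x K
    e, rnorm = nnls(A, c)
    recon = A @ e
    return ExposureSolution(
        exposures=pd.Series(e, index=catalog.names),
        residual=float(rnorm),
        cosine_to_reconstruction=_cosine(c, recon),
    )


@dataclass
class DeNovoResult:
    """De novo NMF deconvolution of a spectra matrix at one rank."""

    signatures: pd.DataFrame  # rank x 96, rows sum to 1
    activities: pd.DataFrame  # rank x samples (mutation counts attributed)
    objective: float  # generalized KL divergence at the optimum
    objective_trace: list[float]


def denovo_signatures(
    spectra: pd.DataFrame, rank: int, *, restarts: int = 10, seed=None
) -> DeNovoResult:
    """De novo signature extraction by KL-loss multiplicative-update NMF.

    ``spectra`` is samples x 96 counts.  All-zero samples are removed before
    factorization.  The best of ``restarts`` random initializations (by the
    generalized KL objective) is kept; extracted signatures are normalized to
    sum to 1 with activities rescaled so the product is unchanged.
    """
    spectra = spectra.loc[spectra.sum(axis=1) > 0]
    n_samples = spectra.shape[0]
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank >= min(96, n_samples + 1):
        raise ValueError(f"rank {rank} too large for {n_samples} samples")
    X = spectra.to_numpy(dtype=float).T  # 96 x samples
    res: NMFResult = nmf_best_of(X, rank, restarts=restarts, loss="kl", seed=seed)
    col_sums = res.W.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    W = res.W / col_sums
    H = res.H * col_sums[:, None]
    names = [f"SBS-denovo-{i + 1}" for i in range(rank)]
    return DeNovoResult(
        signatures=pd.DataFrame(W.T, index=names, columns=list(CHANNELS)),
        activities=pd.DataFrame(H, index=names, columns=spectra.index),
        objective=res.objective,
        objective_trace=res.objective_trace,
    )
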