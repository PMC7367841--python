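"""Multiplicative-update NMF with an explicit objective trace.

Two losses are provided: generalized Kullback-Leibler divergence (used for
mutation-signature deconvolution) and squared Frobenius error (used for
expression metagene factorization).  The multiplicative updates of Lee &
Seung guarantee a non-increasing objective, which the returned per-iteration
trace makes checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass
class NMFResult:
    W: np.ndarray  # (n_features, rank)
    H: np.ndarray  # (rank, n_samples)
    objective: float
    objective_trace: list[float] = field(default_factory=list)


def _kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    # generalized KL: sum(x log(x / wh) - x + wh), with x = 0 contributing wh
    mask = X > 0
    div = float(WH.sum() - X.sum())
    div += float((X[mask] * np.log(X[mask] / np.maximum(WH[mask], _EPS))).sum())
    return div


def nmf_mu(
    X,
    rank: int,
    *,
    loss: str = "kl",
    max_iter: int = 500,
    tol: float = 1e-6,
    seed=None,
) -> NMFResult:
    """Factor a non-negative matrix X ~= W @ H by multiplicative updates.

    ``loss`` is "kl" (generalized Kullback-Leibler) or "frobenius".
    Initialization is uniform random from ``seed``; convergence is declared
    when the relative objective decrease falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("NMF input must be non-negative")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    n, m = X.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / rank) if X.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(n, rank)) * scale
    H = rng.uniform(0.1, 1.0, size=(rank, m)) * scale

    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        if loss == "kl":
            WH = np.maximum(W @ H, _EPS)
            W *= (X / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
            WH = np.maximum(W @ H, _EPS)
            H *= W.T @ (X / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            obj = _kl_divergence(X, np.maximum(W @ H, _EPS))
        elif loss == "frobenius":
            W *= (X @ H.T) / np.maximum(W @ (H @ H.T), _EPS)
            H *= (W.T @ X) / np.maximum((W.T @ W) @ H, _EPS)
            obj = 0.5 * float(np.linalg.norm(X - W @ H) ** 2)
        else:
            raise ValueError(f"unknown loss: {loss!r}")
        trace.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(abs(prev), 1.0):
            break
        prev = obj
    return NMFResult(W=W, H=H, objective=trace[-1], objective_trace=trace)


def nmf_best_of(
    X,
    rank: int,
    *,
    restarts: int = 10,
    loss: str = "kl",
    max_iter: int = 500,
    tol: float = 1e-6,
    seed=None,
) -> NMFResult:
    """Best of ``restarts`` random initializations by final objective."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    ss = np.random.SeedSequence(seed)
    best: NMFResult | None = None
    for child in ss.spawn(restarts):
        res = nmf_mu(X, rank, loss=loss, max_iter=max_iter, tol=tol, seed=child)
        if best is None or res.objective < best.objective:
            best = res
    assert best is not None
    return best
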