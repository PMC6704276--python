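"""Spatial segmentation of tumor spectra by non-negative matrix factorization.

The TIC-normalized tumor spectra ``X`` (pixels × channels, non-negative) are
factorized as ``X ≈ W H`` with non-negative scores ``W`` and basis spectra
``H``; each pixel is assigned to the component with the highest score.  The
number of segments ``k`` is scanned (default 2..5) and chosen to maximize
the mean silhouette coefficient of the resulting labeling, computed on the
spectra themselves so the metric space is identical across ``k``.

The factorization uses multiplicative updates for the Frobenius loss with
seeded uniform random initialization and a small number of restarts keeping
the lowest-loss solution.  Basis rows are normalized to unit L2 norm (scores
rescaled accordingly) so per-component scores are comparable when taking the
arg-max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

_EPS = 1e-12

#: Largest pixel count used for silhouette evaluation; larger inputs are
#: subsampled (seeded) to keep the O(n^2) distance matrix tractable.
MAX_SILHOUETTE_PIXELS = 2000


@dataclass
class NNMFModel:
    """A fitted rank-``k`` non-negative factorization ``X ≈ scores @ basis``."""

    k: int
    scores: np.ndarray  # (n_pixels, k), >= 0
    basis: np.ndarray  # (k, n_channels), >= 0
    loss_trace: np.ndarray  # Frobenius reconstruction error per iteration
    seed: int

    def reconstruction_error(self) -> float:
        return float(self.loss_trace[-1])


@dataclass
class SegmentationResult:
    """Labels plus the model-selection record across the scanned ``k`` range."""

    labels: np.ndarray  # per-pixel segment id in 1..k
    model: NNMFModel
    silhouette_by_k: dict
    chosen_k: int


def _mu_nnmf(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list]:
    """One multiplicative-update run from a random start; returns (W, H, trace)."""
    n, m = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = rng.uniform(0.0, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.0, 1.0, size=(k, m)) * scale
    trace = []
    prev = np.linalg.norm(X - W @ H)
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        loss = np.linalg.norm(X - W @ H)
        trace.append(loss)
        if prev > 0 and (prev - loss) / prev < tol:
            break
        prev = loss
    return W, H, trace


def nnmf_decompose(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    restarts: int = 3,
) -> NNMFModel:
    """Factorize a non-negative matrix by multiplicative Frobenius updates.

    Runs ``restarts`` seeded random initializations and keeps the solution
    with the lowest final reconstruction error.  Deterministic for a given
    ``seed``.

    Raises
    ------
    ValueError
        If ``X`` has negative entries or ``k`` is outside ``1..min(X.shape)``.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("NNMF requires a non-negative matrix")
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"k={k} out of range 1..{min(X.shape)}")
    restart_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=restarts)
    best: NNMFModel | None = None
    for rs in restart_seeds:
        W, H, trace = _mu_nnmf(X, k, np.random.default_rng(int(rs)), max_iter, tol)
        if best is None or trace[-1] < best.loss_trace[-1]:
            best = NNMFModel(k=k, scores=W, basis=H, loss_trace=np.array(trace), seed=seed)
    assert best is not None
    # normalize basis rows to unit L2 norm so component scores are comparable
    norms = np.linalg.norm(best.basis, axis=1)
    norms[norms == 0] = 1.0
    best.basis /= norms[:, None]
    best.scores *= norms[None, :]
    return best


def assign_labels(model: NNMFModel) -> np.ndarray:
    """Per-pixel segment id 1..k: the component with the highest score.

    Ties break toward the lowest component index (np.argmax convention).
    """
    return np.argmax(model.scores, axis=1) + 1


def mean_silhouette(X: np.ndarray, labels: Sequence[int]) -> float:
    """Mean silhouette coefficient of a labeling under Euclidean distance.

    ``s(i) = (b(i) − a(i)) / max(a(i), b(i))`` with ``a`` the mean
    intra-cluster distance (excluding self) and ``b`` the smallest mean
    distance to another cluster.  Points in singleton clusters contribute 0,
    as does a point with ``a = b = 0``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = cdist(X, X)
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    s = np.zeros(len(X))
    for c in uniq:
        idx = members[c]
        if len(idx) == 1:
            continue  # singleton convention: s = 0
        a = D[np.ix_(idx, idx)].sum(axis=1) / (len(idx) - 1)
        b = np.full(len(idx), np.inf)
        for other in uniq:
            if other == c:
                continue
            b = np.minimum(b, D[np.ix_(idx, members[other])].mean(axis=1))
        denom = np.maximum(a, b)
        with np.errstate(invalid="ignore"):
            si = np.where(denom > 0, (b - a) / denom, 0.0)
        s[idx] = si
    return float(s.mean())


def select_k(
    X: np.ndarray,
    k_range: Iterable[int] = range(2, 6),
    seed: int = 0,
    restarts: int = 3,
    max_iter: int = 200,
    tol: float = 1e-6,
    max_silhouette_pixels: int = MAX_SILHOUETTE_PIXELS,
) -> SegmentationResult:
    """Scan ``k`` and keep the segmentation maximizing the mean silhouette.

    For every ``k`` the matrix is factorized, pixels labeled by maximum
    score, and the mean silhouette computed on (a seeded subsample of) the
    rows of ``X``.  A ``k`` whose labeling collapses to a single non-empty
    cluster is recorded with silhouette ``-inf`` and skipped.  Ties prefer
    the smaller ``k``.
    """
    X = np.asarray(X, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if X.shape[0] < max(ks) + 1:
        raise ValueError("not enough pixels for the requested k range")
    if len(X) > max_silhouette_pixels:
        sub = np.random.default_rng(seed).choice(
            len(X), size=max_silhouette_pixels, replace=False
        )
    else:
        sub = np.arange(len(X))
    silhouette_by_k: dict[int, float] = {}
    fits: dict[int, tuple[NNMFModel, np.ndarray]] = {}
    for k in ks:
        model = nnmf_decompose(X, k, seed=seed, max_iter=max_iter, tol=tol, restarts=restarts)
        labels = assign_labels(model)
        fits[k] = (model, labels)
        if len(np.unique(labels[sub])) < 2:
            logger.warning("select_k: k=%d collapsed to one cluster; skipped", k)
            silhouette_by_k[k] = float("-inf")
            continue
        silhouette_by_k[k] = mean_silhouette(X[sub], labels[sub])
    finite = {k: v for k, v in silhouette_by_k.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("every k in the scanned range collapsed to one cluster")
    chosen_k = min(finite, key=lambda k: (-finite[k], k))
    model, labels = fits[chosen_k]
    return SegmentationResult(
        labels=labels, model=model, silhouette_by_k=silhouette_by_k, chosen_k=chosen_k
    )
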