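"""Per-item PCA, retained-component selection, and eigenvalue-based weights.

Each MTS item is reduced to its principal-component (PC) series: the item's
columns are mean-centered, the sample covariance matrix is eigendecomposed,
and the centered data are projected onto the unit eigenvectors.  Column ``i``
of the projection is the i-th PC series and its sample variance equals the
i-th eigenvalue.

For whole-sequence matching a single retained count ``p`` is chosen so that
the first ``p`` components retain strictly more than a threshold fraction
(default 90%) of total variance in *every* item.  Dimension weights aggregate
the i-th eigenvalue across items (min/mean/max strategy) and normalize the
aggregates to sum to one:

    w_i = f(V_i) / sum_j f(V_j)

where ``V_i`` collects the i-th eigenvalues over items (a single element for
subsequence matching).

Determinism conventions: eigenvalues are sorted descending with stable tie
order, and each eigenvector's sign is flipped so its largest-magnitude entry
is positive — DTW on PC series is sign-sensitive, so a fixed convention is
required for reproducible distances across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .data_model import MTSItem

__all__ = [
    "PCAResult",
    "WeightVector",
    "DegenerateInputError",
    "fit_pca",
    "choose_num_components",
    "project",
    "compute_weights",
]

Strategy = Literal["min", "mean", "max"]


class DegenerateInputError(ValueError):
    """The input admits no meaningful decomposition (e.g. zero covariance)."""


@dataclass
class PCAResult:
    """Eigenstructure of one item's covariance matrix plus its PC series.

    ``eigenvectors`` holds unit eigenvectors in columns, ordered by descending
    ``eigenvalues``; ``projected`` is the centered data times the first ``p``
    eigenvectors; ``mean`` is the column mean removed before projection (kept
    so other series can be projected into the same basis).
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    projected: np.ndarray
    p: int
    retained_fraction: float
    mean: np.ndarray


@dataclass
class WeightVector:
    """Nonnegative per-dimension weights summing to one."""

    weights: np.ndarray
    strategy: Strategy
    normalized_inputs: bool

    def __len__(self) -> int:
        return len(self.weights)


def fit_pca(item: MTSItem, p: int | None = None) -> PCAResult:
    """Eigendecompose the sample covariance of ``item`` and project it.

    Raises :class:`DegenerateInputError` when every column is constant (zero
    covariance), since no principal direction is defined.
    """
    X = item.values
    m, n = X.shape
    if m < 2:
        raise ValueError(f"item {item.id!r}: need m >= 2 time points for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (m - 1)
    if not np.isfinite(cov).all():
        raise ValueError(f"item {item.id!r}: covariance matrix is not finite")
    if np.allclose(cov, 0.0):
        raise DegenerateInputError(
            f"item {item.id!r}: zero covariance (all columns constant)"
        )
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(-evals, kind="stable")
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign convention: flip each eigenvector so its entry sum
    # is positive (falling back to the largest-|entry| rule when the sum is
    # numerically zero).  DTW on PC series is sign-sensitive, and the sum
    # aggregates every loading, so near-identical items get consistent signs
    # even when individual entries are closely tied.
    sums = evecs.sum(axis=0)
    anchor = np.argmax(np.abs(evecs), axis=0)
    fallback = np.sign(evecs[anchor, np.arange(n)])
    signs = np.where(np.abs(sums) > 1e-12, np.sign(sums), fallback)
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    if p is None:
        p = n
    if not 1 <= p <= n:
        raise ValueError(f"p={p} out of range 1..{n}")
    total = float(evals.sum())
    retained = float(evals[:p].sum() / total)
    projected = Xc @ evecs[:, :p]
    return PCAResult(evecs, evals, projected, p, retained, mean)


def choose_num_components(
    eigenvalue_lists: Sequence[Sequence[float]], threshold: float = 0.9
) -> int:
    """Smallest ``p`` retaining > ``threshold`` of total variance in every item.

    The inequality is strict ("more than"); ``p = n`` always qualifies.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    lists = [np.asarray(ev, dtype=float) for ev in eigenvalue_lists]
    if not lists or any(ev.size == 0 for ev in lists):
        raise ValueError("need at least one nonempty eigenvalue list")
    n = min(ev.size for ev in lists)
    fractions = [np.cumsum(ev[:n]) / ev.sum() for ev in lists]
    for p in range(1, n + 1):
        if all(frac[p - 1] > threshold for frac in fractions):
            return p
    return n


def project(item: MTSItem, pca: PCAResult, p: int) -> np.ndarray:
    """First ``p`` principal-component series of ``item`` in ``pca``'s basis."""
    n = pca.eigenvectors.shape[1]
    if not 1 <= p <= n:
        raise ValueError(f"p={p} out of range 1..{n}")
    return (item.values - pca.mean) @ pca.eigenvectors[:, :p]


_AGGREGATORS = {"min": np.min, "mean": np.mean, "max": np.max}


def compute_weights(
    eigenvalues_per_item: Iterable[Sequence[float]],
    p: int | None = None,
    strategy: Strategy = "mean",
    normalize: bool = True,
) -> WeightVector:
    """Aggregate the i-th eigenvalue across items into dimension weights.

    Parameters
    ----------
    eigenvalues_per_item
        One full descending eigenvalue vector per item (a single vector for
        subsequence matching).
    p
        Number of leading dimensions to weight (default: all).
    strategy
        Aggregation ``f`` applied to each dimension's eigenvalues across items.
    normalize
        Divide each item's eigenvalue vector by its own total variance before
        aggregating, making items with different overall scale comparable.
    """
    mat = np.asarray([np.asarray(ev, dtype=float) for ev in eigenvalues_per_item])
    if mat.ndim != 2 or mat.size == 0:
        raise ValueError("need a nonempty list of equal-length eigenvalue vectors")
    if (mat < 0).any():
        raise ValueError("eigenvalues must be nonnegative")
    if strategy not in _AGGREGATORS:
        raise ValueError(f"unknown strategy {strategy!r}")
    if p is None:
        p = mat.shape[1]
    if not 1 <= p <= mat.shape[1]:
        raise ValueError(f"p={p} out of range 1..{mat.shape[1]}")
    if normalize:
        totals = mat.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("an item has zero total variance")
        mat = mat / totals
    agg = _AGGREGATORS[strategy](mat[:, :p], axis=0)
    total = float(agg.sum())
    if total <= 0:
        raise ValueError("all aggregated variances are zero; weights undefined")
    return WeightVector(agg / total, strategy, normalize)
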