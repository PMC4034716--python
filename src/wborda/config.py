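"""Search configuration shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

__all__ = ["SearchConfig"]


@dataclass
class SearchConfig:
    """Knobs of the dimension-combination kNN search.

    Attributes
    ----------
    measure
        Final ranking scheme: ``"wborda"`` (distance-gap weighted voting) or
        ``"borda"`` (positional points only).
    k
        Number of multivariate neighbors to return.
    kprime
        Per-dimension univariate neighbors to fetch before truncation;
        defaults to ``2 * k``.
    band_fraction
        Sakoe-Chiba band as a fraction of the longer series length.
    pca_threshold
        Variance fraction that the retained components must strictly exceed
        in every item.
    strategy, normalize
        Eigenvalue aggregation strategy and whether per-item eigenvalue
        vectors are normalized before aggregation.
    exclusion_zone
        Maximum tolerated overlap (in points) between returned subsequence
        windows; defaults to half the query length.
    recompute_all
        Re-measure every dimension of an aligned candidate instead of reusing
        stored per-dimension distances.
    p
        Fixed number of retained components; ``None`` selects it by the
        variance threshold.
    """

    measure: Literal["wborda", "borda"] = "wborda"
    k: int = 1
    kprime: int | None = None
    band_fraction: float = 0.05
    pca_threshold: float = 0.9
    strategy: Literal["min", "mean", "max"] = "mean"
    normalize: bool = True
    exclusion_zone: float | None = None
    recompute_all: bool = False
    p: int | None = None

    def resolved_kprime(self) -> int:
        return self.kprime if self.kprime is not None else 2 * self.k

    def snapshot(self) -> dict:
        return asdict(self)
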