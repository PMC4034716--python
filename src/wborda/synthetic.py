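"""Seeded generators for labeled MTS datasets and planted-motif long series.

The labeled generator emulates multichannel recordings whose classes differ
in latent principal-component structure: each class is defined by
``latent_rank`` smooth latent waveforms (sums of random sinusoids); each item
adds its own smooth within-class deviation, a random monotone time warp of up
to 5% of the series length (so elastic matching is actually exercised), and
projects the latents through a shared column-orthogonal loading matrix with
geometrically decaying gains before adding white Gaussian noise.  The
``separation`` parameter is the between-class latent distance in units of the
within-class deviation: 0 makes classes statistically exchangeable, large
values make them trivially separable.

The motif generator plants noisy copies of a smooth multivariate motif at
known, well-separated positions in a white-noise background series and
returns the clean motif as the query, giving ground truth for subsequence
search.

Identical spec + seed reproduce identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import LongSeries, MTSDataset, MTSItem

__all__ = ["SyntheticSpec", "generate_labeled_mts", "generate_long_with_motifs"]

#: standard deviation of the long-series background noise relative to the
#: unit-RMS motif latents
_BACKGROUND_SD = 0.5

#: maximum time-warp jitter as a fraction of the series length
_WARP_FRACTION = 0.05

#: per-component loading gain decay; makes eigenvalues distinct
_GAIN_DECAY = 0.7


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic labeled dataset."""

    n_classes: int = 3
    items_per_class: int = 20
    m: int = 60
    n: int = 6
    latent_rank: int = 2
    separation: float = 10.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank > self.n:
            raise ValueError("latent_rank must not exceed n")
        if self.separation < 0 or self.noise_sd < 0:
            raise ValueError("separation and noise_sd must be nonnegative")


def _smooth_waveforms(rng: np.random.Generator, m: int, r: int) -> np.ndarray:
    """``m x r`` matrix of unit-RMS, zero-mean sums of random sinusoids."""
    t = np.arange(m) / m
    out = np.empty((m, r))
    for q in range(r):
        wave = np.zeros(m)
        for _ in range(3):
            freq = rng.uniform(1.0, 4.0)
            phase = rng.uniform(0.0, 2 * np.pi)
            amp = rng.uniform(0.5, 1.0)
            wave += amp * np.sin(2 * np.pi * freq * t + phase)
        wave -= wave.mean()
        out[:, q] = wave / np.sqrt(np.mean(wave**2))
    return out


def _loading_matrix(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    """Column-orthogonal ``n x r`` loadings with geometric gains."""
    A = rng.normal(size=(n, r))
    Q, _ = np.linalg.qr(A)
    return Q[:, :r] * (_GAIN_DECAY ** np.arange(r))


def _warp(latent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth monotone time warp with peak shift <= 5% of the length."""
    m = latent.shape[0]
    t = np.arange(m, dtype=float)
    amount = rng.uniform(-_WARP_FRACTION, _WARP_FRACTION) * m
    src = np.clip(t + amount * np.sin(np.pi * t / (m - 1)), 0, m - 1)
    return np.column_stack(
        [np.interp(src, t, latent[:, q]) for q in range(latent.shape[1])]
    )


def generate_labeled_mts(spec: SyntheticSpec) -> MTSDataset:
    """A labeled dataset whose classes differ in latent waveform shape."""
    rng = np.random.default_rng(spec.seed)
    loadings = _loading_matrix(rng, spec.n, spec.latent_rank)
    class_latents = [
        _smooth_waveforms(rng, spec.m, spec.latent_rank)
        for _ in range(spec.n_classes)
    ]
    items = []
    for c in range(spec.n_classes):
        for i in range(spec.items_per_class):
            deviation = _smooth_waveforms(rng, spec.m, spec.latent_rank)
            latent = spec.separation * class_latents[c] + deviation
            latent = _warp(latent, rng)
            values = latent @ loadings.T
            values += rng.normal(0.0, spec.noise_sd, size=values.shape)
            items.append(MTSItem(f"c{c}_i{i:02d}", values, label=f"class{c}"))
    return MTSDataset(items)


def generate_long_with_motifs(
    n_dims: int,
    M: int,
    l: int,
    n_motifs: int,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[LongSeries, list[int], MTSItem]:
    """A background series with noisy motif copies planted at known starts.

    Returns the long series, the sorted planted starts, and the clean motif
    as the query item.  Starts are drawn one per equal slot of the admissible
    range with enough margin that planted windows never overlap (and, when
    the slots allow, stay at least ``1.5 * l`` apart so each copy is a
    distinct event for any half-length exclusion zone).
    """
    if n_motifs * l > M / 2:
        raise ValueError(f"cannot pack {n_motifs} motifs of length {l} into M={M}")
    rng = np.random.default_rng(seed)
    r = min(2, n_dims)
    motif = _smooth_waveforms(rng, l, r) @ _loading_matrix(rng, n_dims, r).T
    background = rng.normal(0.0, _BACKGROUND_SD, size=(M, n_dims))
    starts: list[int] = []
    if n_motifs > 0:
        span = (M - l) / n_motifs
        margin = 1.5 * l if span >= 1.5 * l else l
        if span < margin:
            raise ValueError(
                f"cannot place {n_motifs} non-overlapping motifs of length {l}"
            )
        for i in range(n_motifs):
            offset = rng.uniform(0.0, span - margin) if span > margin else 0.0
            starts.append(int(round(i * span + offset)))
        for t in starts:
            background[t : t + l] = motif + rng.normal(
                0.0, noise_sd, size=motif.shape
            )
    query = MTSItem("query", motif)
    return LongSeries("long", background), sorted(starts), query
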