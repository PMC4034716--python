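"""Shared fixtures and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from wborda import Match, MTSDataset, MTSItem


def dtw_enumerate(a, b) -> float:
    """Unconstrained DTW by exhaustive enumeration of all monotone paths.

    Deliberately naive (no dynamic programming) so it is an independent
    oracle; usable only for short series.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    best = [math.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += (a[i] - b[j]) ** 2
        if cost >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = cost
            return
        if i + 1 < len(a) and j + 1 < len(b):
            walk(i + 1, j + 1, cost)
        if i + 1 < len(a):
            walk(i + 1, j, cost)
        if j + 1 < len(b):
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return math.sqrt(best[0])


def overlap_chain_matches() -> list[Match]:
    """Nine matches, three per dimension, encoding the worked truncation
    scenario: one three-dimension chain, two two-member groups, and two
    matches overlapping nothing."""
    l = 20
    return [
        Match(0, "long", 100, l, 0.30),  # s11
        Match(0, "long", 400, l, 0.50),  # s12
        Match(0, "long", 500, l, 0.70),  # s13
        Match(1, "long", 108, l, 0.20),  # s21
        Match(1, "long", 409, l, 0.40),  # s22
        Match(1, "long", 600, l, 0.60),  # s23
        Match(2, "long", 116, l, 0.10),  # s31
        Match(2, "long", 300, l, 0.90),  # s32
        Match(2, "long", 507, l, 0.80),  # s33
    ]


@pytest.fixture
def figure_matches() -> list[Match]:
    return overlap_chain_matches()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_item(values, item_id="item", label=None) -> MTSItem:
    return MTSItem(item_id, np.asarray(values, dtype=float), label)


@pytest.fixture
def tiny_dataset() -> MTSDataset:
    """Three labeled 2-channel items with distinct shapes."""
    t = np.linspace(0, 2 * np.pi, 12)
    items = [
        make_item(np.column_stack([np.sin(t), np.cos(t)]), "a", "s"),
        make_item(np.column_stack([np.sin(t) + 0.01, np.cos(t)]), "b", "s"),
        make_item(np.column_stack([t / 4, -t / 4]), "c", "r"),
    ]
    return MTSDataset(items)
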