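"""1NN classification, repeated stratified cross-validation, component
scanning, and the paired Wilcoxon signed-rank comparison of measures.

The validation protocol: each dataset is split into stratified folds (default
10); every held-out item is classified with the label of its single nearest
neighbor in the training folds under the configured similarity measure; the
fold error is the misclassified percentage and the whole procedure is
repeated (default 10 times) with fresh random fold assignments.  Two measures
evaluated on the same collection of datasets are compared with the Wilcoxon
signed-rank test on the paired mean error rates.

The Wilcoxon variant is pinned: zero differences dropped, average ranks for
ties, normal approximation without continuity correction, two-sided.

Because every item's principal-component series depend only on the item
itself (each item carries its own PCA basis), per-item projections and
pairwise per-dimension DTW distances are computed once and shared across all
folds and repeats, which makes the repeated protocol cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .config import SearchConfig
from .data_model import MTSDataset, MTSItem, warn_once
from .dtw_search import dtw_distance
from .pca_weights import choose_num_components, compute_weights, fit_pca, project
from .voting import _whole_search, knn_search

__all__ = [
    "EvalReport",
    "PairedTestResult",
    "one_nn_classify",
    "cross_validate",
    "scan_components",
    "wilcoxon_signed_rank",
]


@dataclass
class EvalReport:
    """Per-fold error rates (%) of one measure on one dataset."""

    measure: str
    p_used: list[int]
    fold_errors: np.ndarray  # repeats x folds, percent
    mean_error: float
    config: dict
    seed: int

    @property
    def repeat_means(self) -> np.ndarray:
        return self.fold_errors.mean(axis=1)


@dataclass
class PairedTestResult:
    """Wilcoxon signed-rank comparison of two paired samples."""

    w_plus: float
    z: float
    p_value: float
    n_nonzero: int


def one_nn_classify(
    query: MTSItem, training: MTSDataset, config: SearchConfig | None = None
) -> str:
    """Label of the query's single nearest neighbor in the training set."""
    if len(training) == 0:
        raise ValueError("training set is empty")
    unlabeled = [it.id for it in training if it.label is None]
    if unlabeled:
        raise ValueError(f"unlabeled training items: {unlabeled}")
    config = config or SearchConfig()
    config = SearchConfig(**{**config.snapshot(), "k": 1})
    results = knn_search(query, training, config)
    return results[0].label


def _stratified_folds(
    labels: list[str], folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold index per item: classes shuffled independently, dealt round-robin."""
    assignment = np.empty(len(labels), dtype=int)
    by_class: dict[str, list[int]] = {}
    for idx, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(idx)
    offset = 0
    for lab in sorted(by_class):
        members = np.array(by_class[lab])
        rng.shuffle(members)
        for pos, idx in enumerate(members):
            assignment[idx] = (pos + offset) % folds
        offset += len(members)  # stagger classes across folds
    return assignment


def cross_validate(
    dataset: MTSDataset,
    config: SearchConfig | None = None,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified k-fold 1NN error of the configured measure.

    Deterministic given ``seed``; the report records every fold error, the
    retained component count used in each repeat, and the configuration.
    """
    config = config or SearchConfig()
    labels = [item.label for item in dataset]
    if any(lab is None for lab in labels):
        raise ValueError("cross-validation requires a fully labeled dataset")
    classes = sorted(set(labels))
    if len(classes) == 1:
        warn_once("single-class dataset: error is trivially 0")
    min_class = min(labels.count(c) for c in classes)
    if min_class < folds:
        warn_once(f"smallest class has {min_class} items; reducing folds")
        folds = max(2, min_class)

    pcas = {item.id: fit_pca(item) for item in dataset}
    full_pc = {item.id: project(item, pcas[item.id], item.n) for item in dataset}
    label_of = {item.id: item.label for item in dataset}
    ids = dataset.ids

    memo: dict[tuple, float] = {}

    def dist_fn(dim, id_a, series_a, id_b, series_b):
        key = (dim, id_a, id_b) if id_a < id_b else (dim, id_b, id_a)
        if key not in memo:
            memo[key] = dtw_distance(series_a, series_b, config.band_fraction)
        return memo[key]

    search_cfg = SearchConfig(**{**config.snapshot(), "k": 1})
    fold_errors = np.zeros((repeats, folds))
    p_used: list[int] = []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        assignment = _stratified_folds(labels, folds, rng)
        for fold in range(folds):
            test_ids = [ids[i] for i in range(len(ids)) if assignment[i] == fold]
            train_ids = [ids[i] for i in range(len(ids)) if assignment[i] != fold]
            train_eigs = [pcas[sid].eigenvalues for sid in train_ids]
            p = config.p or choose_num_components(train_eigs, config.pca_threshold)
            weights = compute_weights(
                train_eigs, p, config.strategy, config.normalize
            )
            train_pc = {sid: full_pc[sid][:, :p] for sid in train_ids}
            wrong = 0
            for qid in test_ids:
                scored = _whole_search(
                    qid, full_pc[qid][:, :p], train_pc, weights, search_cfg, dist_fn
                )
                predicted = label_of[scored[0].candidate.source_id]
                if predicted != label_of[qid]:
                    wrong += 1
            fold_errors[rep, fold] = 100.0 * wrong / max(1, len(test_ids))
        p_used.append(p)
    return EvalReport(
        config.measure,
        p_used,
        fold_errors,
        float(fold_errors.mean()),
        config.snapshot(),
        seed,
    )


def scan_components(
    dataset: MTSDataset,
    config: SearchConfig | None = None,
    threshold: float = 0.9,
    seed: int = 0,
    folds: int = 10,
    repeats: int = 10,
    evaluator: Callable[[int], float] | None = None,
) -> tuple[int, float, dict[int, float]]:
    """Scan consecutive retained-component counts for the lowest CV error.

    Starts at the smallest ``p`` exceeding the variance threshold in every
    item (smaller counts are never evaluated) and walks upward, stopping as
    soon as the error rises above the previous value — the previous point was
    the first local minimum — or ``p`` reaches the number of variables.
    Returns the best ``p``, its error, and the table of all evaluated counts.
    """
    config = config or SearchConfig()
    n = dataset.n
    eigvals = [fit_pca(item).eigenvalues for item in dataset]
    p_min = choose_num_components(eigvals, threshold)
    if evaluator is None:

        def evaluator(p: int) -> float:
            cfg = SearchConfig(**{**config.snapshot(), "p": p})
            return cross_validate(dataset, cfg, folds, repeats, seed).mean_error

    table: dict[int, float] = {}
    best_p, best_err = p_min, float("inf")
    prev_err = float("inf")
    for p in range(p_min, n + 1):
        err = evaluator(p)
        table[p] = err
        if err < best_err:
            best_p, best_err = p, err
        if err > prev_err:
            break
        prev_err = err
    return best_p, best_err, table


def wilcoxon_signed_rank(x, y) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Differences ``y - x``; zeros dropped; average ranks for tied absolute
    differences; ``W+`` is the positive-rank sum;
    ``z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)`` with the two-sided p-value
    from the normal tail, no continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples with at least 2 pairs")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    z = (w_plus - mu) / sigma
    p = float(2 * stats.norm.sf(abs(z)))
    return PairedTestResult(w_plus, float(z), min(p, 1.0), n)
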