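"""Adaptive-K weighted nearest-neighbor classification.

The neighborhood size K is chosen per query from the shape of the
class-count curves over a grid of candidate k (multiples of 5):

* if the leading class changes somewhere along the grid, the class
  distributions overlap; K is halved from the first intersection point
  p_f of the count curves (K = max(1, floor(p_f / 2)));
* otherwise, if the lead over the runner-up is small (count ratio < 2),
  K = 5;
* otherwise every k is scored by purity v = s/k plus density
  den = k / (pi d^2) (s = leading-class count, d = the largest distance
  among leading-class members inside the k nearest), each normalized by
  its maximum over the grid, and the best-scoring k wins.

Votes are weighted: each neighbor contributes its train-set weight q to
its class.  After a risk-qualified sample, the weights of the chosen K
neighbors are reinforced (q <- 3 / (1 + e^-q), bounded above by 3) or
penalized (q <- q / 4) depending on whether their label matches the
qualified label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synergy import SynergyFeature
from .trainset import WeightedTrainSet

__all__ = [
    "NeighborTable",
    "KSelectionTrace",
    "Prediction",
    "neighbor_table",
    "select_k",
    "classify",
    "update_weights",
    "reinforce_weight",
    "penalize_weight",
]

_D_GUARD = 1e-12


@dataclass
class NeighborTable:
    """Train-set indices sorted by ascending squared distance to the query."""

    order: np.ndarray
    distances: np.ndarray  # squared Euclidean, non-decreasing along order


@dataclass
class KSelectionTrace:
    """How K was chosen: the k grid, per-k counts and the decision path."""

    k_grid: np.ndarray
    per_k_counts: list[dict[int, int]]  # recorded (top ceil(N/2)) classes per k
    decision_path: str  # "intersection" | "ratio_small" | "score"
    p_f: int | None
    scores: np.ndarray | None
    chosen_K: int


@dataclass
class Prediction:
    label: int
    trace: KSelectionTrace
    neighbor_indices: np.ndarray  # the chosen_K nearest train indices
    vote_tally: dict[int, float]


def neighbor_table(x: SynergyFeature | np.ndarray, trainset: WeightedTrainSet) -> NeighborTable:
    """Squared Euclidean distances to every train sample, stably sorted."""
    xv = np.asarray(x.w if isinstance(x, SynergyFeature) else x, dtype=float)
    if trainset.n_train == 0:
        raise ValueError("empty train set")
    if xv.shape[0] != trainset.m:
        raise ValueError(
            f"dimension mismatch: query has {xv.shape[0]}, train set has {trainset.m}"
        )
    d2 = ((trainset.samples - xv) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")
    return NeighborTable(order, d2[order])


def _top_classes(counts: np.ndarray, how_many: int) -> dict[int, int]:
    """The ``how_many`` most frequent classes (count desc, label asc ties)."""
    present = np.nonzero(counts)[0]
    ranked = sorted(present, key=lambda c: (-counts[c], c))[:how_many]
    return {int(c): int(counts[c]) for c in ranked}


def select_k(
    table: NeighborTable,
    labels: np.ndarray,
    gesture_count: int,
    k_step: int = 5,
    k_max: int | None = None,
) -> KSelectionTrace:
    """Choose the neighborhood size K from the class-count curves.

    ``labels`` are the train labels (indexed by ``table.order``);
    ``gesture_count`` is N, the number of gesture categories.  The grid is
    the multiples of ``k_step`` up to ``k_max`` (default min(100, train
    size)).
    """
    labels = np.asarray(labels, dtype=int)
    n = table.order.size
    if n == 0:
        raise ValueError("empty neighbor table")
    if k_max is None:
        k_max = min(100, n)
    k_max = min(k_max, n)
    grid = np.arange(k_step, k_max + 1, k_step, dtype=int)
    if grid.size == 0:
        grid = np.array([k_max], dtype=int)

    sorted_labels = labels[table.order]
    n_classes = int(labels.max()) + 1
    record = max(1, int(np.ceil(gesture_count / 2)))

    per_k_counts: list[dict[int, int]] = []
    leaders = np.empty(grid.size, dtype=int)
    counts_at_k: list[np.ndarray] = []
    for gi, k in enumerate(grid):
        counts = np.bincount(sorted_labels[:k], minlength=n_classes)
        counts_at_k.append(counts)
        per_k_counts.append(_top_classes(counts, record))
        # leader: max count, ties to the smaller label id
        leaders[gi] = int(np.argmax(counts))

    leader0 = leaders[0]
    if np.any(leaders != leader0):
        # Class distributions overlap: find the first k where another
        # recorded class's count reaches the (initial) leading class's.
        p_f = None
        for gi, k in enumerate(grid):
            lead_count = counts_at_k[gi][leader0]
            others = [
                c for c in per_k_counts[gi] if c != leader0
            ]
            if others and max(counts_at_k[gi][c] for c in others) >= lead_count:
                p_f = int(k)
                break
        if p_f is None:  # leader changed but curves never met on the grid
            p_f = int(grid[np.argmax(leaders != leader0)])
        return KSelectionTrace(
            grid, per_k_counts, "intersection", p_f, None, max(1, p_f // 2)
        )

    # Stable leader: ratio test at k_max.
    final_counts = counts_at_k[-1]
    top = final_counts[leader0]
    runner = max(
        (final_counts[c] for c in range(n_classes) if c != leader0), default=0
    )
    ratio = np.inf if runner == 0 else top / runner
    if ratio < 2:
        return KSelectionTrace(grid, per_k_counts, "ratio_small", None, None, k_step)

    # Purity/density score over the grid.
    v = np.empty(grid.size)
    den = np.empty(grid.size)
    for gi, k in enumerate(grid):
        s = counts_at_k[gi][leader0]
        v[gi] = s / k
        in_class = sorted_labels[:k] == leader0
        d = np.sqrt(table.distances[:k][in_class].max()) if in_class.any() else 0.0
        d = max(d, _D_GUARD)
        den[gi] = k / (np.pi * d**2)
    scores = v / v.max() + den / den.max()
    best = int(np.argmax(scores))  # first (smallest k) maximizer
    return KSelectionTrace(
        grid, per_k_counts, "score", None, scores, int(grid[best])
    )


def classify(
    x: SynergyFeature | np.ndarray,
    trainset: WeightedTrainSet,
    k_step: int = 5,
    k_max: int | None = None,
) -> Prediction:
    """Weighted vote among the adaptively chosen K nearest neighbors.

    The winning class maximizes the sum of neighbor weights q; ties are
    broken by the smaller summed distance, then by the smaller class id.
    """
    table = neighbor_table(x, trainset)
    trace = select_k(table, trainset.labels, trainset.gesture_count, k_step, k_max)
    k = min(trace.chosen_K, table.order.size)
    idx = table.order[:k]
    neigh_labels = trainset.labels[idx]
    neigh_weights = trainset.weights[idx]
    neigh_d = table.distances[:k]

    tally: dict[int, float] = {}
    dist_sum: dict[int, float] = {}
    for lab, w, d in zip(neigh_labels, neigh_weights, neigh_d):
        lab = int(lab)
        tally[lab] = tally.get(lab, 0.0) + float(w)
        dist_sum[lab] = dist_sum.get(lab, 0.0) + float(d)
    label = min(tally, key=lambda c: (-tally[c], dist_sum[c], c))
    return Prediction(label=label, trace=trace, neighbor_indices=idx, vote_tally=tally)


def reinforce_weight(q: np.ndarray | float) -> np.ndarray | float:
    """q <- 3 / (1 + e^-q): monotone growth bounded above by 3."""
    return 3.0 / (1.0 + np.exp(-np.asarray(q, dtype=float)))


def penalize_weight(q: np.ndarray | float) -> np.ndarray | float:
    """q <- q / 4: proportional shrink that preserves positivity."""
    return np.asarray(q, dtype=float) / 4.0


def update_weights(
    trainset: WeightedTrainSet,
    prediction: Prediction,
    qualified_label: int,
    inplace: bool = True,
) -> WeightedTrainSet:
    """Adjust the weights of the chosen-K neighbors after a qualified sample.

    Neighbors whose label equals ``qualified_label`` are reinforced, the
    others penalized; all remaining train samples are untouched.
    """
    ts = trainset if inplace else trainset.copy()
    idx = prediction.neighbor_indices
    match = trainset.labels[idx] == qualified_label
    ts.weights[idx[match]] = reinforce_weight(ts.weights[idx[match]])
    ts.weights[idx[~match]] = penalize_weight(ts.weights[idx[~match]])
    return ts
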