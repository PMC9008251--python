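"""Per-gesture k-means templates and the representative-sample train set.

One cluster per gesture is refined by Lloyd iterations, seeded at the
class mean (supervised prototype refinement rather than unsupervised
k-means with random restarts).  The final centroids are the gesture
templates mu_i.  For each (user, gesture) pair the 30 features closest to
the gesture's template become the representative samples; together with
unit initial weights they form the weighted train set the online
classifier operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synergy import SynergyFeature

__all__ = [
    "Template",
    "WeightedTrainSet",
    "KMeansTrace",
    "kmeans_fit",
    "select_representatives",
    "trainset_from_features",
]


@dataclass(frozen=True)
class Template:
    """Per-gesture centroid mu used for prototype selection and risk scoring."""

    mu: np.ndarray
    gesture: int
    user_scope: str = "global"


@dataclass
class KMeansTrace:
    """Record of the Lloyd iterations: centroids of every generation."""

    centroid_history: list[np.ndarray]
    iterations: int
    converged: bool


@dataclass
class WeightedTrainSet:
    """Representative samples with per-sample weights and gesture templates.

    ``weights`` start at 1 and live in (0, 3): the reinforcement update
    3/(1+e^-q) is bounded above by 3 and the penalty q/4 keeps positivity.
    """

    samples: np.ndarray  # (n_train, m)
    labels: np.ndarray  # (n_train,)
    weights: np.ndarray  # (n_train,)
    source_user: list[str]
    templates: dict[int, Template]
    gesture_count: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.gesture_count == 0:
            self.gesture_count = len(np.unique(self.labels))

    @property
    def n_train(self) -> int:
        return self.samples.shape[0]

    @property
    def m(self) -> int:
        return self.samples.shape[1]

    def copy(self) -> "WeightedTrainSet":
        return WeightedTrainSet(
            self.samples.copy(),
            self.labels.copy(),
            self.weights.copy(),
            list(self.source_user),
            dict(self.templates),
            self.gesture_count,
        )


def kmeans_fit(
    features: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 100,
    move_tol: float = 0.02,
    displacement: str = "max",
) -> tuple[list[Template], KMeansTrace]:
    """Refine one centroid per gesture by Lloyd iterations.

    Centroids start at the per-gesture means; points are then reassigned to
    the nearest centroid (squared Euclidean) and centroids recomputed until
    the largest centroid displacement falls below ``move_tol`` or 100
    iterations pass.  ``displacement`` may be "max" (default) or "mean".

    Raises
    ------
    ValueError : if some gesture label has no features.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 1:
        raise ValueError("no features")

    centroids = np.empty((classes.size, features.shape[1]))
    for ci, c in enumerate(classes):
        mask = labels == c
        if not mask.any():
            raise ValueError(f"gesture class {c} has no features")
        centroids[ci] = features[mask].mean(axis=0)

    history = [centroids.copy()]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((features[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        new_centroids = centroids.copy()  # empty clusters keep their centroid
        for ci in range(classes.size):
            mask = assign == ci
            if mask.any():
                new_centroids[ci] = features[mask].mean(axis=0)
        moved = np.linalg.norm(new_centroids - centroids, axis=1)
        shift = moved.max() if displacement == "max" else moved.mean()
        centroids = new_centroids
        history.append(centroids.copy())
        if shift < move_tol:
            converged = True
            break

    templates = [Template(centroids[ci], int(c)) for ci, c in enumerate(classes)]
    return templates, KMeansTrace(history, it, converged)


def select_representatives(
    features: np.ndarray,
    labels: np.ndarray,
    templates: list[Template] | dict[int, Template],
    source_user: list[str] | np.ndarray | None = None,
    per_class: int = 30,
) -> WeightedTrainSet:
    """Keep, per (user, gesture), the ``per_class`` features nearest the template.

    Distances are squared Euclidean to the gesture's template; ties keep the
    earlier sample (stable sort).  Classes with fewer than ``per_class``
    features keep everything.  Weights are initialized to 1.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = features.shape[0]
    if source_user is None:
        source_user = ["anonymous"] * n
    source_user = list(source_user)
    tmpl = (
        {t.gesture: t for t in templates}
        if not isinstance(templates, dict)
        else dict(templates)
    )
    missing = set(np.unique(labels)) - set(tmpl)
    if missing:
        raise ValueError(f"templates missing for gestures {sorted(missing)}")

    keep_idx: list[int] = []
    users_in_order = list(dict.fromkeys(source_user))  # first-seen order
    for user in users_in_order:
        for gesture in sorted(tmpl):
            idx = np.array(
                [
                    i
                    for i in range(n)
                    if source_user[i] == user and labels[i] == gesture
                ],
                dtype=int,
            )
            if idx.size == 0:
                continue
            d2 = ((features[idx] - tmpl[gesture].mu) ** 2).sum(axis=1)
            order = np.argsort(d2, kind="stable")[:per_class]
            keep_idx.extend(idx[order].tolist())

    keep = np.array(sorted(keep_idx), dtype=int)
    return WeightedTrainSet(
        samples=features[keep],
        labels=labels[keep],
        weights=np.ones(keep.size),
        source_user=[source_user[i] for i in keep],
        templates=tmpl,
        gesture_count=len(tmpl),
    )


def trainset_from_features(
    features: list[SynergyFeature],
    per_class: int = 30,
    max_iter: int = 100,
    move_tol: float = 0.02,
) -> WeightedTrainSet:
    """Convenience: templates + representative selection from a feature list."""
    X = np.vstack([f.w for f in features])
    y = np.array([f.label for f in features], dtype=int)
    users = [f.user_id for f in features]
    templates, _ = kmeans_fit(X, y, max_iter=max_iter, move_tol=move_tol)
    return select_representatives(X, y, templates, users, per_class=per_class)
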