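"""Risk evaluation and qualified-sample replacement of train-set rows.

A candidate feature A assigned to gesture 1 (its predicted class) is
scored by

    risk(A) = 1 / ( cos(A, mu_1) + sum_{j != 1} ||A - mu_j||^2 )

where mu_1 is the template of the assigned class and mu_j the other
class templates: the cosine term measures intra-class similarity, the
squared distances measure inter-class separation, and a small risk means
the sample sits close to its own class and far from the others.  If the
test sample is strictly less risky than the farthest train sample of its
class, it replaces that sample (keeping per-class counts constant), its
weight is reset to 1, and the neighbor weights are updated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .knn import Prediction, update_weights
from .synergy import SynergyFeature
from .trainset import Template, WeightedTrainSet

__all__ = ["RiskScore", "UpdateEvent", "risk", "farthest_point", "evaluate_and_update"]

_DENOM_GUARD = 1e-12


@dataclass
class RiskScore:
    value: float
    cosine_term: float
    separation_term: float


@dataclass
class UpdateEvent:
    """Outcome of one risk evaluation: accepted replacements and their scores."""

    accepted: bool
    replaced_index: int | None
    test_feature: np.ndarray
    assigned_label: int
    risk_test: "RiskScore"
    risk_far: "RiskScore"


def risk(
    a: np.ndarray, label: int, templates: dict[int, Template] | list[Template]
) -> RiskScore:
    """Score a feature vector against its class template and the others."""
    a = np.asarray(a, dtype=float)
    tmpl = (
        {t.gesture: t for t in templates}
        if not isinstance(templates, dict)
        else templates
    )
    if label not in tmpl:
        raise ValueError(f"no template for gesture {label}")
    mu1 = np.asarray(tmpl[label].mu, dtype=float)
    na, nmu = np.linalg.norm(a), np.linalg.norm(mu1)
    if na <= 0 or nmu <= 0:
        raise ValueError("zero-norm feature or template: risk undefined")
    cosine = float(a @ mu1 / (na * nmu))
    # inter-class distances are per-coordinate (the channel count m is the
    # characteristic length), keeping them commensurate with the cosine term
    separation = float(
        sum(
            ((a - np.asarray(t.mu, dtype=float)) ** 2).mean()
            for g, t in tmpl.items()
            if g != label
        )
    )
    denom = cosine + separation
    value = np.inf if denom <= _DENOM_GUARD else 1.0 / denom
    return RiskScore(value, cosine, separation)


def farthest_point(trainset: WeightedTrainSet, label: int) -> tuple[int, np.ndarray]:
    """The class sample farthest (squared Euclidean) from its template.

    Ties resolve to the lowest train-set index.
    """
    idx = np.nonzero(trainset.labels == label)[0]
    if idx.size == 0:
        raise ValueError(f"no train samples for gesture {label}")
    mu = trainset.templates[label].mu
    d2 = ((trainset.samples[idx] - mu) ** 2).sum(axis=1)
    pos = int(idx[np.argmax(d2)])  # argmax returns the first maximizer
    return pos, trainset.samples[pos].copy()


def evaluate_and_update(
    trainset: WeightedTrainSet,
    x: SynergyFeature | np.ndarray,
    prediction: Prediction,
    new_user: str = "new",
    recompute_templates: bool = False,
    inplace: bool = True,
) -> tuple[WeightedTrainSet, UpdateEvent]:
    """Gate a classified test sample through the risk evaluator.

    If risk(x) < risk(farthest same-class sample), strictly, the farthest
    sample is replaced by x (weight reset to 1, source set to
    ``new_user``) and the chosen-K neighbor weights are updated with the
    qualified label; otherwise the train set is returned unchanged.
    ``recompute_templates`` refreshes the class centroid after an accepted
    replacement (off by default: frozen templates keep risk comparisons
    stationary across a session).
    """
    xv = np.asarray(x.w if isinstance(x, SynergyFeature) else x, dtype=float)
    label = prediction.label
    far_idx, far_vec = farthest_point(trainset, label)
    r_test = risk(xv, label, trainset.templates)
    r_far = risk(far_vec, label, trainset.templates)
    accepted = r_test.value < r_far.value

    ts = trainset if inplace else trainset.copy()
    if accepted:
        update_weights(ts, prediction, qualified_label=label, inplace=True)
        ts.samples[far_idx] = xv
        ts.labels[far_idx] = label
        ts.weights[far_idx] = 1.0
        ts.source_user[far_idx] = new_user
        if recompute_templates:
            mask = ts.labels == label
            ts.templates[label] = Template(
                ts.samples[mask].mean(axis=0), label, "global"
            )
    event = UpdateEvent(
        accepted=accepted,
        replaced_index=far_idx if accepted else None,
        test_feature=xv,
        assigned_label=label,
        risk_test=r_test,
        risk_far=r_far,
    )
    return ts, event
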