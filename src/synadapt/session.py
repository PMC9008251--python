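"""Online recognition sessions and the cross-user evaluation protocol.

A session streams analysis windows from a new user through the pipeline:
synergy feature -> adaptive-K weighted KNN -> risk evaluator.  Qualified
samples replace the remote train-set rows and trigger weight updates, so
the classifier adapts to the new user without any calibration recordings.

``crossvalidate`` implements M-fold leave-one-user-out evaluation with
four benchmark schemes:

* A — pooled baseline: every existing-user synergy is the train set;
* B — frozen representative-sample train set (no adaptation);
* C — user-dependent ceiling: per-user 70/30 split;
* D — the full adaptive method (B's train set + risk-gated updates).

Per cycle, the held-out user's repetition groups (one repetition index of
every gesture) are presented in a seeded random order until all groups
are tested; the per-step accuracies trace how recognition improves with
the frequency of use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import EmgRecording
from .knn import classify
from .preprocess import (
    AnalysisWindow,
    extract_active_segments,
    lowpass_envelope,
    rectify,
    sliding_windows,
)
from .risk import UpdateEvent, evaluate_and_update
from .synergy import SynergyFeature, window_to_feature
from .trainset import WeightedTrainSet, kmeans_fit, select_representatives, trainset_from_features

__all__ = [
    "PipelineConfig",
    "SessionState",
    "EvaluationReport",
    "extract_features",
    "run_session",
    "crossvalidate",
    "channel_weight_summary",
]


@dataclass
class PipelineConfig:
    """Shared preprocessing/classifier parameters.

    window_ms/overlap_ms follow the 200/50 ms online-recognition choice;
    threshold_coef and active_fraction control burst detection; k_step and
    k_max bound the adaptive-K grid (capped at 10 by default so that
    weighted votes and weight updates stay local to the query, the regime
    sketched in the weight-update diagram); per_class is the
    representative-sample budget per (user, gesture).
    """

    window_ms: float = 200.0
    overlap_ms: float = 50.0
    filter_order: int = 3
    cutoff_hz: float = 1.0
    threshold_coef: float = 0.015
    active_fraction: float = 35.0 / 40.0
    per_class: int = 30
    k_step: int = 5
    k_max: int | None = 10
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-6
    recompute_templates: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SessionState:
    """Evolving classifier state over one online session."""

    trainset: WeightedTrainSet
    history: list[tuple[SynergyFeature, int, int, UpdateEvent | None]] = field(
        default_factory=list
    )
    config: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        if not self.history:
            return float("nan")
        correct = sum(1 for _, pred, true, _ in self.history if pred == true)
        return correct / len(self.history)


@dataclass
class EvaluationReport:
    """Cross-validated accuracies for one benchmark scheme."""

    scheme: str
    per_user_accuracy: dict[str, float]
    per_cycle_accuracy: np.ndarray  # (cycles, steps), averaged over users
    step_accuracy: np.ndarray  # (users, cycles, steps)
    mean_accuracy: float
    segment_accuracy: float | None = None  # majority vote per movement


def extract_features(
    recording: EmgRecording,
    seed: int | np.random.Generator = 0,
    config: PipelineConfig | None = None,
) -> list[SynergyFeature]:
    """Full preprocessing + synergy extraction for one recording."""
    cfg = config or PipelineConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    env = lowpass_envelope(rectify(recording), cfg.filter_order, cfg.cutoff_hz)
    segments = extract_active_segments(
        env, cfg.window_ms, cfg.active_fraction, cfg.threshold_coef
    )
    features = []
    for seg in segments:
        for win in sliding_windows(seg, env, cfg.window_ms, cfg.overlap_ms):
            features.append(
                _feature_with_rep(win, rng, cfg)
            )
    return features


def _feature_with_rep(
    window: AnalysisWindow, rng: np.random.Generator, cfg: PipelineConfig
) -> SynergyFeature:
    feat = window_to_feature(window, seed=rng, max_iter=cfg.nmf_max_iter, tol=cfg.nmf_tol)
    feat.repetition = window.repetition  # carried for protocol grouping
    return feat


def run_session(
    initial: WeightedTrainSet,
    stream: list[AnalysisWindow] | list[SynergyFeature],
    adapt: bool = True,
    seed: int | np.random.Generator = 0,
    config: PipelineConfig | None = None,
    new_user: str = "new",
    force_reject: bool = False,
) -> SessionState:
    """Run one online recognition session over a window (or feature) stream.

    With ``adapt=False`` the train set is frozen (scheme-B behaviour) and
    the final state is identical to ``initial``.  ``force_reject`` runs
    the risk evaluator but vetoes every replacement — useful to verify
    that the adaptive scheme with all updates rejected reduces exactly to
    the frozen one.
    """
    cfg = config or PipelineConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = SessionState(trainset=initial.copy() if adapt else initial, config=cfg.as_dict())

    for item in stream:
        feat = (
            item
            if isinstance(item, SynergyFeature)
            else _feature_with_rep(item, rng, cfg)
        )
        pred = classify(feat, state.trainset, cfg.k_step, cfg.k_max)
        event: UpdateEvent | None = None
        if adapt:
            if force_reject:
                # score but never accept: replacement gate closed
                ts, event = evaluate_and_update(
                    state.trainset.copy(), feat, pred, new_user=new_user,
                    recompute_templates=cfg.recompute_templates,
                )
                event = UpdateEvent(
                    accepted=False, replaced_index=None,
                    test_feature=event.test_feature,
                    assigned_label=event.assigned_label,
                    risk_test=event.risk_test, risk_far=event.risk_far,
                )
            else:
                _, event = evaluate_and_update(
                    state.trainset, feat, pred, new_user=new_user,
                    recompute_templates=cfg.recompute_templates, inplace=True,
                )
        state.history.append((feat, pred.label, feat.label, event))
    return state


def _features_by_rep(features: list[SynergyFeature]) -> dict[int, list[SynergyFeature]]:
    groups: dict[int, list[SynergyFeature]] = {}
    for f in features:
        groups.setdefault(getattr(f, "repetition", 0), []).append(f)
    return groups


def _segment_accuracy(records: list[tuple[SynergyFeature, int, int]]) -> float | None:
    """Majority-vote accuracy per movement (user, repetition, true gesture)."""
    votes: dict[tuple, list[tuple[int, int]]] = {}
    for feat, pred, true in records:
        key = (feat.user_id, getattr(feat, "repetition", 0), true)
        votes.setdefault(key, []).append((pred, true))
    if not votes:
        return None
    correct = 0
    for key, pairs in votes.items():
        preds = [p for p, _ in pairs]
        counts = np.bincount(preds)
        correct += int(np.argmax(counts) == pairs[0][1])
    return correct / len(votes)


def crossvalidate(
    users: list[EmgRecording],
    scheme: str,
    cycles: int = 10,
    seed: int = 0,
    config: PipelineConfig | None = None,
    features_per_user: list[list[SynergyFeature]] | None = None,
) -> EvaluationReport:
    """M-fold leave-one-user-out evaluation of one benchmark scheme.

    ``features_per_user`` may carry precomputed synergy features (in the
    same order as ``users``) so several schemes can share one extraction
    pass; otherwise features are extracted here, seeded from ``seed``.
    """
    scheme = scheme.upper()
    if scheme not in "ABCD" or len(scheme) != 1:
        raise ValueError("scheme must be one of A, B, C, D")
    if len(users) < 2 and scheme != "C":
        raise ValueError("need at least 2 users for leave-one-user-out")
    cfg = config or PipelineConfig()
    master = np.random.SeedSequence(seed)
    feat_seeds, order_seed = master.spawn(2)

    if features_per_user is None:
        user_seeds = feat_seeds.spawn(len(users))
        features_per_user = [
            extract_features(rec, np.random.default_rng(s), cfg)
            for rec, s in zip(users, user_seeds)
        ]
    order_rng = np.random.default_rng(order_seed)

    all_gestures = sorted(
        {f.label for feats in features_per_user for f in feats}
    )

    if scheme == "C":
        return _scheme_c(users, features_per_user, cfg, order_rng)

    per_user_acc: dict[str, float] = {}
    step_acc_cells: list[np.ndarray] = []
    seg_records: list[tuple[SynergyFeature, int, int]] = []
    n_steps_ref: int | None = None

    for fold, rec in enumerate(users):
        test_feats = features_per_user[fold]
        train_feats = [
            f for i, feats in enumerate(features_per_user) if i != fold for f in feats
        ]
        fold_gestures = {f.label for f in test_feats}
        train_gestures = {f.label for f in train_feats}
        if set(all_gestures) - fold_gestures or set(all_gestures) - train_gestures:
            warnings.warn(
                f"fold for user {rec.user_id} skipped: missing gesture classes"
            )
            continue

        if scheme == "A":
            X = np.vstack([f.w for f in train_feats])
            y = np.array([f.label for f in train_feats])
            templates, _ = kmeans_fit(X, y)
            base = select_representatives(
                X, y, templates,
                [f.user_id for f in train_feats],
                per_class=len(train_feats),  # keep everything: pooled baseline
            )
        else:  # B or D share the representative-sample initial train set
            base = trainset_from_features(train_feats, per_class=cfg.per_class)

        groups = _features_by_rep(test_feats)
        rep_ids = sorted(groups)
        n_steps = len(rep_ids)
        n_steps_ref = n_steps if n_steps_ref is None else min(n_steps_ref, n_steps)

        if scheme in "AB":
            # Frozen train set: predictions are order-independent; classify
            # once and assemble per-cycle step accuracies from the orders.
            preds = {
                rep: np.array(
                    [classify(f, base, cfg.k_step, cfg.k_max).label for f in groups[rep]]
                )
                for rep in rep_ids
            }
            correct = {
                rep: preds[rep] == np.array([f.label for f in groups[rep]])
                for rep in rep_ids
            }
            for rep in rep_ids:
                for f, p in zip(groups[rep], preds[rep]):
                    seg_records.append((f, int(p), f.label))
            fold_cells = np.empty((cycles, n_steps))
            for c in range(cycles):
                order = order_rng.permutation(rep_ids)
                for s, rep in enumerate(order):
                    fold_cells[c, s] = correct[rep].mean()
            acc = float(np.mean(np.concatenate([correct[r] for r in rep_ids])))
        else:  # D
            fold_cells = np.empty((cycles, n_steps))
            n_ok = n_tot = 0
            for c in range(cycles):
                order = order_rng.permutation(rep_ids)
                stream = [f for rep in order for f in groups[rep]]
                state = run_session(
                    base, stream, adapt=True, config=cfg, new_user=rec.user_id
                )
                pos = 0
                for s, rep in enumerate(order):
                    k = len(groups[rep])
                    chunk = state.history[pos : pos + k]
                    fold_cells[c, s] = np.mean(
                        [pred == true for _, pred, true, _ in chunk]
                    )
                    pos += k
                n_ok += sum(1 for _, p, t, _ in state.history if p == t)
                n_tot += len(state.history)
                seg_records.extend(
                    (f, p, t) for f, p, t, _ in state.history
                )
            acc = n_ok / n_tot

        per_user_acc[rec.user_id] = acc
        step_acc_cells.append(fold_cells)

    if not per_user_acc:
        raise ValueError("every fold was skipped; no evaluable users")

    n_steps = n_steps_ref or 0
    step_accuracy = np.stack([c[:, :n_steps] for c in step_acc_cells])
    return EvaluationReport(
        scheme=scheme,
        per_user_accuracy=per_user_acc,
        per_cycle_accuracy=step_accuracy.mean(axis=0),
        step_accuracy=step_accuracy,
        mean_accuracy=float(np.mean(list(per_user_acc.values()))),
        segment_accuracy=_segment_accuracy(seg_records),
    )


def _scheme_c(
    users: list[EmgRecording],
    features_per_user: list[list[SynergyFeature]],
    cfg: PipelineConfig,
    rng: np.random.Generator,
) -> EvaluationReport:
    """User-dependent ceiling: per-user random 70/30 train/test split."""
    per_user_acc: dict[str, float] = {}
    seg_records: list[tuple[SynergyFeature, int, int]] = []
    for rec, feats in zip(users, features_per_user):
        if len(feats) < 4:
            warnings.warn(f"user {rec.user_id} skipped: too few features")
            continue
        idx = rng.permutation(len(feats))
        n_train = int(round(0.7 * len(feats)))
        train = [feats[i] for i in idx[:n_train]]
        test = [feats[i] for i in idx[n_train:]]
        if {f.label for f in feats} - {f.label for f in train}:
            warnings.warn(f"user {rec.user_id} skipped: split lost a gesture")
            continue
        ts = trainset_from_features(train, per_class=len(train))
        ok = 0
        for f in test:
            pred = classify(f, ts, cfg.k_step, cfg.k_max).label
            ok += pred == f.label
            seg_records.append((f, pred, f.label))
        per_user_acc[rec.user_id] = ok / len(test)
    if not per_user_acc:
        raise ValueError("no evaluable users for scheme C")
    accs = np.array(list(per_user_acc.values()))
    return EvaluationReport(
        scheme="C",
        per_user_accuracy=per_user_acc,
        per_cycle_accuracy=np.array([[accs.mean()]]),
        step_accuracy=accs[:, None, None],
        mean_accuracy=float(accs.mean()),
        segment_accuracy=_segment_accuracy(seg_records),
    )


def channel_weight_summary(
    source: WeightedTrainSet | list[SynergyFeature],
    stage: str = "existing",
) -> pd.DataFrame:
    """Per-gesture mean of normalized synergy vectors (channel-weight table).

    Rows are gestures, columns channels; ``stage`` labels which stage of
    the pipeline the summary describes (existing / initial / updated /
    test) for side-by-side comparison of train-set and new-user channel
    activation.
    """
    if isinstance(source, WeightedTrainSet):
        X, y = source.samples, source.labels
    else:
        if len(source) == 0:
            raise ValueError("no features to summarize")
        X = np.vstack([f.w for f in source])
        y = np.array([f.label for f in source])
    gestures = np.unique(y)
    rows = {int(g): X[y == g].mean(axis=0) for g in gestures}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gesture"
    df.columns = [f"ch{i}" for i in range(X.shape[1])]
    df.insert(0, "stage", stage)
    return df
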