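"""Muscle-synergy feature extraction via rank-1 nonnegative matrix factorization.

Each analysis window (an m-channel envelope slice of length n) is factored
as V ~ w h, with w the m-vector of channel synergy weights and h the
1 x n activation time course.  A single synergy (rank 1) is used; the
normalized w is the classified feature.  Factors are found by the classic
multiplicative updates

    w <- w * (V h) / (w (h.h))
    h <- h * (w.V) / ((w.w) h)

which keep the factors nonnegative and never increase the Frobenius
reconstruction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import AnalysisWindow

__all__ = [
    "SynergyFeature",
    "NmfResult",
    "nmf_rank1",
    "normalize_minmax",
    "window_to_feature",
]

_EPS = 1e-12


@dataclass
class SynergyFeature:
    """A normalized m-channel synergy weight vector for one window."""

    w: np.ndarray  # entries in [0, 1]; min 0 and max 1 unless constant
    label: int
    user_id: str = "anonymous"
    window_index: int = 0
    repetition: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)


@dataclass
class NmfResult:
    """Outcome of a rank-1 factorization V ~ w h."""

    w: np.ndarray
    h: np.ndarray
    reconstruction_error: float
    iterations: int
    error_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def nmf_rank1(
    v: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | np.random.Generator = 0,
) -> NmfResult:
    """Rank-1 NMF by alternating multiplicative updates.

    Parameters
    ----------
    v : nonnegative (m, n) matrix.
    max_iter : iteration cap.
    tol : stop when the relative change of the reconstruction error over
        one sweep falls below this.
    seed : int seed or Generator for the strictly positive random
        initialization (uniform in (0.1, 1.1]).

    Raises
    ------
    ValueError : if ``v`` has negative entries or is entirely zero.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 2:
        raise ValueError("v must be a 2-D matrix")
    if (v < 0).any():
        raise ValueError("NMF input must be elementwise nonnegative")
    if not (v > 0).any():
        raise ValueError("degenerate input: all-zero matrix has no rank-1 synergy")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, n = v.shape
    w = 0.1 + rng.uniform(0.0, 1.0, size=m)
    h = 0.1 + rng.uniform(0.0, 1.0, size=n)

    err = float(np.linalg.norm(v - np.outer(w, h)))
    history = [err]
    it = 0
    for it in range(1, max_iter + 1):
        w = w * (v @ h) / (w * (h @ h) + _EPS)
        h = h * (w @ v) / ((w @ w) * h + _EPS)
        new_err = float(np.linalg.norm(v - np.outer(w, h)))
        history.append(new_err)
        if err > 0 and abs(err - new_err) / max(err, _EPS) < tol:
            err = new_err
            break
        err = new_err

    # Resolve the scale ambiguity: unit-sum h, scale absorbed into w.
    s = h.sum()
    if s > 0:
        h = h / s
        w = w * s
    return NmfResult(w, h, err, it, np.asarray(history))


def normalize_minmax(x: np.ndarray) -> np.ndarray:
    """Min-max normalization (x - min) / (max - min); constant -> zeros."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def window_to_feature(
    window: AnalysisWindow,
    seed: int | np.random.Generator = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SynergyFeature:
    """Extract the normalized synergy vector of one analysis window.

    The envelope slice (win_len x m) is transposed to channels x time,
    factored at rank 1, and the channel weights are min-max normalized.
    """
    v = np.asarray(window.envelope_slice, dtype=float).T
    res = nmf_rank1(v, max_iter=max_iter, tol=tol, seed=seed)
    return SynergyFeature(
        w=normalize_minmax(res.w),
        label=window.label,
        user_id=window.user_id,
        window_index=window.start,
    )
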