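"""Envelope extraction and active-segment / sliding-window segmentation.

The preprocessing chain is full-wave rectification, a causal third-order
Butterworth low-pass (1 Hz cut-off) giving the muscle-activity envelope,
data-driven active-segment extraction, and 200 ms windows overlapped by
50 ms for online recognition.  Filtering is forward-only (no ``filtfilt``)
because online recognition cannot look ahead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .data_io import EmgRecording

__all__ = [
    "EnvelopeSignal",
    "ActiveSegment",
    "AnalysisWindow",
    "rectify",
    "lowpass_envelope",
    "extract_active_segments",
    "discard_outlier_repetitions",
    "sliding_windows",
    "window_samples",
]


@dataclass
class EnvelopeSignal:
    """Nonnegative low-pass envelope of a rectified recording."""

    envelope: np.ndarray  # (n_samples, m), clamped at 0
    fs: float
    source: EmgRecording

    @property
    def n_samples(self) -> int:
        return self.envelope.shape[0]


@dataclass(frozen=True)
class ActiveSegment:
    """A contiguous burst of muscle activity: one gesture execution.

    ``start``/``end`` are half-open sample indices into the source signal.
    """

    start: int
    end: int
    label: int
    repetition: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment must have end > start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnalysisWindow:
    """One classification unit: a fixed-length slice of the envelope."""

    start: int
    end: int
    envelope_slice: np.ndarray  # (win_len, m)
    label: int
    repetition: int
    user_id: str


def window_samples(window_ms: float, fs: float) -> int:
    """Window length in samples: round(window_ms * fs / 1000)."""
    n = int(round(window_ms * fs / 1000.0))
    if n < 1:
        raise ValueError("window shorter than one sample")
    return n


def rectify(recording: EmgRecording) -> EmgRecording:
    """Full-wave rectification: elementwise absolute value of the signal."""
    return EmgRecording(
        np.abs(recording.signal),
        recording.fs,
        recording.labels,
        recording.repetition,
        user_id=recording.user_id,
    )


def lowpass_envelope(
    recording: EmgRecording, order: int = 3, cutoff_hz: float = 1.0
) -> EnvelopeSignal:
    """Causal Butterworth low-pass per channel; output clamped at zero.

    Filter ringing can push the output slightly negative; the envelope is a
    nonnegative amplitude so it is clamped at 0.
    """
    if cutoff_hz >= recording.fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({recording.fs / 2} Hz)"
        )
    sos = scipy.signal.butter(order, cutoff_hz, fs=recording.fs, output="sos")
    env = scipy.signal.sosfilt(sos, recording.signal, axis=0)
    return EnvelopeSignal(np.clip(env, 0.0, None), recording.fs, recording)


def _majority_nonzero_label(labels: np.ndarray) -> int:
    """Majority vote over nonzero labels; ties broken by smallest label id."""
    nz = labels[labels > 0]
    if nz.size == 0:
        return 0
    counts = np.bincount(nz)
    return int(np.argmax(counts))  # argmax returns the first (smallest) maximizer


def extract_active_segments(
    env: EnvelopeSignal,
    window_ms: float = 200.0,
    active_fraction: float = 35.0 / 40.0,
    threshold_coef: float = 0.015,
) -> list[ActiveSegment]:
    """Detect gesture bursts from the envelope by amplitude thresholding.

    The m channels are combined into a single activity summary (per-sample
    mean envelope).  The signal is tiled by windows of
    ``round(window_ms*fs/1000)`` samples; a window is active when at least
    ``ceil(active_fraction * win_len)`` of its samples exceed
    ``threshold_coef`` times the peak of the summary envelope.  Runs of
    active windows between two resting windows merge into one segment.
    Each segment is labelled by the majority nonzero per-sample label;
    segments whose samples are all rest are discarded.
    """
    if env.n_samples == 0:
        raise ValueError("empty envelope")
    if not (0 < active_fraction <= 1):
        raise ValueError("active_fraction must be in (0, 1]")
    win_len = window_samples(window_ms, env.fs)
    if win_len > env.n_samples:
        raise ValueError("window longer than signal")

    summary = env.envelope.mean(axis=1)
    threshold = threshold_coef * summary.max()
    need = int(np.ceil(active_fraction * win_len))

    n_windows = env.n_samples // win_len
    active = np.empty(n_windows, dtype=bool)
    for i in range(n_windows):
        chunk = summary[i * win_len : (i + 1) * win_len]
        active[i] = int(np.sum(chunk > threshold)) >= need

    segments: list[ActiveSegment] = []
    labels = env.source.labels
    reps = env.source.repetition
    i = 0
    while i < n_windows:
        if not active[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_windows and active[j + 1]:
            j += 1
        start, end = i * win_len, (j + 1) * win_len
        label = _majority_nonzero_label(labels[start:end])
        if label > 0:
            seg_reps = reps[start:end][labels[start:end] == label]
            rep = int(np.bincount(seg_reps).argmax()) if seg_reps.size else 0
            segments.append(ActiveSegment(start, end, label, rep))
        i = j + 1
    return segments


def discard_outlier_repetitions(
    segments: list[ActiveSegment],
    env: EnvelopeSignal,
    z_threshold: float = 3.0,
) -> list[ActiveSegment]:
    """Drop repetitions that differ visibly from the rest of their gesture.

    For each gesture, every segment is summarized by its mean-envelope
    m-vector; segments whose distance to the per-gesture median vector is
    more than ``z_threshold`` robust z-scores (median / 1.4826*MAD) from
    typical are discarded.  Gestures with fewer than 3 repetitions are
    passed through unchanged.
    """
    by_gesture: dict[int, list[ActiveSegment]] = {}
    for seg in segments:
        by_gesture.setdefault(seg.label, []).append(seg)

    keep: set[ActiveSegment] = set()
    for gesture, segs in by_gesture.items():
        if len(segs) < 3:
            keep.update(segs)
            continue
        feats = np.vstack(
            [env.envelope[s.start : s.end].mean(axis=0) for s in segs]
        )
        center = np.median(feats, axis=0)
        dist = np.linalg.norm(feats - center, axis=1)
        mad = np.median(np.abs(dist - np.median(dist)))
        scale = 1.4826 * mad
        if scale < 1e-12:
            # All repetitions essentially identical except possibly gross
            # outliers: fall back to distance relative to the median distance.
            z = np.where(dist > 1e-9, np.inf, 0.0) if np.median(dist) < 1e-12 else dist / max(np.median(dist), 1e-12)
        else:
            z = (dist - np.median(dist)) / scale
        keep.update(s for s, zi in zip(segs, z) if zi <= z_threshold)
    return [s for s in segments if s in keep]


def sliding_windows(
    segment: ActiveSegment,
    env: EnvelopeSignal,
    window_ms: float = 200.0,
    overlap_ms: float = 50.0,
    user_id: str | None = None,
) -> list[AnalysisWindow]:
    """Cut a segment into overlapping analysis windows.

    Step = round((window_ms - overlap_ms) * fs / 1000); the last partial
    window is dropped.  A segment shorter than one window yields an empty
    list (not an error), mirroring online operation where short bursts are
    simply skipped.
    """
    win_len = window_samples(window_ms, env.fs)
    step = int(round((window_ms - overlap_ms) * env.fs / 1000.0))
    if step < 1:
        raise ValueError("overlap too large: step must be >= 1 sample")
    if segment.length < win_len:
        return []
    uid = user_id if user_id is not None else env.source.user_id
    windows = []
    for start in range(segment.start, segment.end - win_len + 1, step):
        windows.append(
            AnalysisWindow(
                start=start,
                end=start + win_len,
                envelope_slice=env.envelope[start : start + win_len],
                label=segment.label,
                repetition=segment.repetition,
                user_id=uid,
            )
        )
    return windows
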