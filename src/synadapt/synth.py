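"""Seeded synthetic multi-user sEMG cohort generator.

Emulates the statistical structure the classifier assumes, at the level
of the rectified envelope: each gesture has a nonnegative base pattern of
channel activations; each user distorts it by a per-channel multiplicative
gain (the cross-user variability that breaks user-independent
recognition); an optional per-repetition drift emulates slow within-session
change such as fatigue.  Gestures appear as smooth (Hann-shaped) bursts
separated by near-silent rest, so active-segment extraction, windowing,
synergy extraction and the full adaptive protocol are all exercised
end-to-end without any external recordings.

This is an envelope-level simulation, not raw interference EMG: the
classifier only ever sees 1 Hz envelopes, so post-envelope morphology is
what matters and generation stays fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.ndimage
import scipy.signal

from .data_io import EmgRecording

__all__ = ["SynthConfig", "default_base_patterns", "generate_cohort", "generate_fixture_files"]


def default_base_patterns(gestures: int, channels: int) -> np.ndarray:
    """Smooth, pairwise well-separated channel-activation patterns.

    Gesture g activates a bump of channels centred at a distinct location,
    over a small common baseline — mimicking how different gestures recruit
    different electrode sites.
    """
    ch = np.arange(channels)
    width = max(1.0, 1.4 * channels / gestures)
    while True:
        pats = np.empty((gestures, channels))
        for g in range(gestures):
            center = (g + 0.5) * channels / gestures
            pats[g] = 0.05 + np.exp(-0.5 * ((ch - center) / width) ** 2)
        worst = max(
            (
                pats[a] @ pats[b] / (np.linalg.norm(pats[a]) * np.linalg.norm(pats[b]))
                for a in range(gestures)
                for b in range(a + 1, gestures)
            ),
            default=0.0,
        )
        # keep neighboring gestures strongly overlapping (realistic shared
        # channel recruitment) but clearly distinguishable
        if worst < 0.94 or width <= 1.0:
            return pats
        width *= 0.9


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a small DB5-like cohort: 6 users, 4 gestures,
    16 channels, 6 repetitions at 200 Hz, 2.5 s movement bursts with 2 s
    rest, spatially correlated per-channel user gains (spread 0.3), slow
    within-burst channel fluctuation, an occasional mis-executed
    repetition, and a small additive noise floor (~1% of burst amplitude,
    as for a clean rectified-envelope recording).
    """

    users: int = 6
    gestures: int = 4
    channels: int = 16
    repetitions: int = 6
    fs: float = 200.0
    burst_ms: float = 2500.0
    rest_ms: float = 2000.0
    base_patterns: np.ndarray | None = None
    user_gain_sd: float = 0.3
    gain_corr_len: float = 3.0
    rep_gain_sd: float = 0.1
    burst_mod_amp: float = 0.4
    burst_mod_hz: float = 0.75
    drift_rate: float = 0.0
    bad_rep_rate: float = 0.06
    bad_rep_mix: float = 0.8
    transition_frac: float = 0.0
    artifact_rate: float = 0.0
    artifact_amp: float = 1.0
    artifact_ms: float = 400.0
    noise_sd: float = 0.002
    burst_shape: str = "hann"  # or "trapezoid"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.users, self.gestures, self.channels, self.repetitions) < 1:
            raise ValueError("all counts must be >= 1")
        if self.user_gain_sd < 0 or self.noise_sd < 0:
            raise ValueError("spreads must be >= 0")
        if self.base_patterns is None:
            self.base_patterns = default_base_patterns(self.gestures, self.channels)
        self.base_patterns = np.asarray(self.base_patterns, dtype=float)
        if self.base_patterns.shape != (self.gestures, self.channels):
            raise ValueError("base_patterns must be (gestures, channels)")
        # patterns must be distinguishable for the task to be well-posed
        for a in range(self.gestures):
            for b in range(a + 1, self.gestures):
                pa, pb = self.base_patterns[a], self.base_patterns[b]
                cos = pa @ pb / (np.linalg.norm(pa) * np.linalg.norm(pb))
                if cos >= 0.95:
                    raise ValueError(
                        f"base patterns {a} and {b} are near-collinear (cos={cos:.3f})"
                    )


def _burst_profile(n: int, shape: str) -> np.ndarray:
    if shape == "hann":
        return scipy.signal.windows.hann(n)
    if shape == "trapezoid":
        ramp = max(1, n // 5)
        prof = np.ones(n)
        prof[:ramp] = np.linspace(0, 1, ramp)
        prof[-ramp:] = np.linspace(1, 0, ramp)
        return prof
    raise ValueError(f"unknown burst shape {shape!r}")


def _smooth_channel_noise(
    rng: np.random.Generator, channels: int, sd: float, corr_len: float
) -> np.ndarray:
    """Zero-mean per-channel noise, spatially correlated along the electrode ring.

    Neighboring electrodes sit over overlapping muscle territory, so
    cross-user gain differences (arm geometry, skin impedance, slight
    armband rotation) vary smoothly around the ring rather than
    independently per channel.
    """
    eps = rng.normal(0.0, 1.0, channels)
    if corr_len > 0:
        eps = scipy.ndimage.gaussian_filter1d(eps, corr_len, mode="wrap")
        eps = eps / max(eps.std(), 1e-9)
    return eps * sd


def user_gains(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-channel multiplicative gain of one user: 1 + eps, clipped at 0.1.

    eps is Gaussian with spread ``user_gain_sd`` and is spatially
    correlated over ``gain_corr_len`` channels.
    """
    eps = _smooth_channel_noise(rng, cfg.channels, cfg.user_gain_sd, cfg.gain_corr_len)
    return np.clip(1.0 + eps, 0.1, None)


def generate_cohort(
    cfg: SynthConfig, return_truth: bool = False
) -> list[EmgRecording] | tuple[list[EmgRecording], dict]:
    """Generate one recording per user.

    Per user u: gain vector g_u; per repetition r the gains drift to
    g_u * (1 + drift_rate * r * delta_u) along a fixed per-user random
    per-channel direction delta_u (slow within-session change such as
    fatigue or electrode-contact change), and every individual burst carries its own
    per-channel gain jitter (rep_gain_sd) — repeated movements are never
    exact copies.  Within a burst, channels fluctuate slowly
    (burst_mod_amp/burst_mod_hz) so successive analysis windows differ, as
    they do in real recordings.  Repetition r of the session presents every
    gesture once (burst + rest), giving NinaPro-style repetition groups.
    Labels are the gesture id during bursts and 0 at rest; repetition
    indices are 1-based during bursts and 0 at rest.
    """
    rng = np.random.default_rng(cfg.master_seed)
    burst_n = int(round(cfg.burst_ms * cfg.fs / 1000.0))
    rest_n = int(round(cfg.rest_ms * cfg.fs / 1000.0))
    profile = _burst_profile(burst_n, cfg.burst_shape)

    recordings = []
    truth: dict = {"user_gains": {}, "segments": {}, "base_patterns": cfg.base_patterns.tolist()}
    for u in range(cfg.users):
        uid = f"synth{u:02d}"
        gains = user_gains(cfg, rng)
        # drift tilts channels in a fixed per-user random direction; a
        # uniform scale-up would be invisible to scale-invariant synergy
        # features, so the drift must reshape the activation pattern
        drift_dir = _smooth_channel_noise(rng, cfg.channels, 1.0, cfg.gain_corr_len)
        chunks, labels, reps = [], [], []
        seg_truth = []
        cursor = 0

        def _rest(n: int) -> None:
            nonlocal cursor
            chunks.append(np.abs(rng.normal(0.0, cfg.noise_sd, (n, cfg.channels))))
            labels.append(np.zeros(n, dtype=int))
            reps.append(np.zeros(n, dtype=int))
            cursor += n

        _rest(rest_n)
        for r in range(cfg.repetitions):
            g = np.clip(gains * (1.0 + cfg.drift_rate * r * drift_dir), 0.1, None)
            for gesture in range(cfg.gestures):
                pattern = cfg.base_patterns[gesture]
                if cfg.bad_rep_rate > 0 and cfg.gestures > 1 and rng.uniform() < cfg.bad_rep_rate:
                    # occasional mis-executed movement: the subject blends the
                    # intended gesture with another one (hesitation, wrong
                    # grip) — the reason offline preparation screens
                    # repetitions that differ from their siblings
                    other = int(rng.integers(0, cfg.gestures - 1))
                    other += other >= gesture
                    pattern = (
                        (1 - cfg.bad_rep_mix) * pattern
                        + cfg.bad_rep_mix * cfg.base_patterns[other]
                    )
                jitter = np.clip(
                    1.0 + rng.normal(0.0, cfg.rep_gain_sd, cfg.channels), 0.1, None
                )
                amp = g * jitter * pattern
                burst = profile[:, None] * amp[None, :]
                if cfg.transition_frac > 0:
                    # onset/offset co-contraction: the gesture-specific
                    # pattern emerges from (and decays back into) a broad,
                    # gesture-nonspecific activation, so windows near the
                    # burst edges carry little class information
                    t_n = max(1, int(round(cfg.transition_frac * burst_n)))
                    alpha = np.ones(burst_n)
                    ramp = np.linspace(0.0, 1.0, t_n)
                    alpha[:t_n] = ramp
                    alpha[-t_n:] = np.minimum(alpha[-t_n:], ramp[::-1])
                    common = g * 0.6 * float(cfg.base_patterns[gesture].mean())
                    burst = (
                        alpha[:, None] * burst
                        + (1 - alpha)[:, None] * profile[:, None] * common[None, :]
                    )
                if cfg.artifact_rate > 0 and rng.uniform() < cfg.artifact_rate:
                    # transient heavy-tailed per-channel distortion (electrode
                    # movement, contact change): a short span of the movement
                    # where channel amplitudes are scrambled, contaminating a
                    # few analysis windows
                    a_n = min(burst_n, int(round(cfg.artifact_ms * cfg.fs / 1000.0)))
                    a_start = rng.integers(0, burst_n - a_n + 1)
                    a_prof = scipy.signal.windows.hann(a_n)
                    chan_mult = np.exp(rng.normal(0.0, cfg.artifact_amp, cfg.channels))
                    span = burst[a_start : a_start + a_n]
                    span *= 1.0 + a_prof[:, None] * (chan_mult[None, :] - 1.0)
                if cfg.burst_mod_amp > 0:
                    # slow per-channel fluctuation (below the envelope cut-off)
                    # so successive analysis windows are not exact copies
                    t = np.arange(burst_n) / cfg.fs
                    phase = rng.uniform(0, 2 * np.pi, cfg.channels)
                    fmod = cfg.burst_mod_hz * rng.uniform(0.5, 1.5, cfg.channels)
                    mod = 1.0 + cfg.burst_mod_amp * np.sin(
                        2 * np.pi * fmod[None, :] * t[:, None] + phase[None, :]
                    )
                    burst = burst * np.clip(mod, 0.0, None)
                burst = burst + np.abs(
                    rng.normal(0.0, cfg.noise_sd, burst.shape)
                )
                seg_truth.append(
                    {"start": cursor, "end": cursor + burst_n,
                     "label": gesture + 1, "repetition": r + 1}
                )
                chunks.append(burst)
                labels.append(np.full(burst_n, gesture + 1, dtype=int))
                reps.append(np.full(burst_n, r + 1, dtype=int))
                cursor += burst_n
                _rest(rest_n)

        recordings.append(
            EmgRecording(
                np.vstack(chunks),
                cfg.fs,
                np.concatenate(labels),
                np.concatenate(reps),
                user_id=uid,
            )
        )
        truth["user_gains"][uid] = gains.tolist()
        truth["segments"][uid] = seg_truth

    if return_truth:
        return recordings, truth
    return recordings


def generate_fixture_files(cfg: SynthConfig, out_dir: str | Path) -> list[Path]:
    """Write MAT- and CSV-format fixtures plus a ground-truth JSON.

    Each user yields ``<uid>.mat`` (NinaPro-convention fields emg,
    stimulus, repetition) and ``<uid>.csv``; ``truth.json`` records the
    base patterns, per-user gains and true segment boundaries.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings, truth = generate_cohort(cfg, return_truth=True)
    written = []
    for rec in recordings:
        mat_path = out_dir / f"{rec.user_id}.mat"
        scipy.io.savemat(
            str(mat_path),
            {
                "emg": rec.signal,
                "stimulus": rec.labels[:, None].astype(float),
                "repetition": rec.repetition[:, None].astype(float),
            },
        )
        df = pd.DataFrame(rec.signal, columns=[f"ch{i}" for i in range(rec.channel_count)])
        df["label"] = rec.labels
        df["repetition"] = rec.repetition
        csv_path = out_dir / f"{rec.user_id}.csv"
        df.to_csv(csv_path, index=False, float_format="%.9g")
        written += [mat_path, csv_path]
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    written.append(truth_path)
    return written
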