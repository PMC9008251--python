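"""Readers and writers for multichannel sEMG recordings and feature tables.

Recordings follow the NinaPro convention: a MATLAB v5 container with an
``emg`` matrix (samples x channels), a per-sample gesture label vector
(``stimulus``, or the timing-refined ``restimulus``) and a per-sample
``repetition`` index.  Plain CSV matrices with ``label`` and ``repetition``
columns are supported as a text-friendly equivalent.  Feature tables are
written as CSV with one normalized synergy vector per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import scipy.io

if TYPE_CHECKING:  # pragma: no cover
    from .synergy import SynergyFeature

__all__ = [
    "EmgRecording",
    "FormatError",
    "IntegrityError",
    "DATABASE_PROFILES",
    "read_ninapro_mat",
    "read_csv_recording",
    "write_features",
    "read_features",
]

#: Sampling rates of the supported acquisition profiles.  NinaPro MAT files
#: do not store the sampling rate, so it must be supplied per database.
DATABASE_PROFILES = {"db1": 100.0, "db5": 200.0}


class FormatError(ValueError):
    """A file does not follow the expected container layout."""


class IntegrityError(ValueError):
    """Fields of a container disagree (e.g. mismatched lengths)."""


@dataclass
class EmgRecording:
    """One user's multichannel sEMG recording with per-sample annotations.

    Attributes
    ----------
    signal : ndarray, shape (n_samples, m_channels)
        Raw or envelope amplitudes (volts or normalized a.u.).
    fs : float
        Sampling rate in Hz.
    labels : ndarray of int, shape (n_samples,)
        0 = rest, 1..N = gesture id.
    repetition : ndarray of int, shape (n_samples,)
        Repetition index of the movement each sample belongs to.
    user_id : str
        Opaque subject identifier.
    """

    signal: np.ndarray
    fs: float
    labels: np.ndarray
    repetition: np.ndarray
    user_id: str = "anonymous"

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        self.repetition = np.asarray(self.repetition, dtype=int).ravel()
        n = self.signal.shape[0]
        if self.labels.shape[0] != n or self.repetition.shape[0] != n:
            raise IntegrityError(
                f"signal ({n}), labels ({self.labels.shape[0]}) and repetition "
                f"({self.repetition.shape[0]}) must share length"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def channel_count(self) -> int:
        return self.signal.shape[1]


def _column(mat: dict, name: str, n: int, path: str | Path) -> np.ndarray:
    arr = np.asarray(mat[name]).ravel()
    if arr.shape[0] != n:
        raise IntegrityError(
            f"{path}: field '{name}' has {arr.shape[0]} samples, emg has {n}"
        )
    return arr


def read_ninapro_mat(
    path: str | Path,
    user_id: str,
    fs: float | None = None,
    database: str = "db5",
    label_field: str | None = None,
) -> EmgRecording:
    """Read a NinaPro-convention MATLAB v5 file into an :class:`EmgRecording`.

    Parameters
    ----------
    path : path to the ``.mat`` file.
    user_id : subject identifier attached to the recording.
    fs : sampling rate in Hz; if None, taken from ``database``.
    database : profile key ("db1" -> 100 Hz, "db5" -> 200 Hz).
    label_field : force "stimulus" or "restimulus"; by default
        ``restimulus`` (refined movement timing) is preferred when present.
    """
    if fs is None:
        try:
            fs = DATABASE_PROFILES[database.lower()]
        except KeyError:
            raise ValueError(
                f"unknown database profile {database!r}; pass fs explicitly"
            ) from None
    mat = scipy.io.loadmat(str(path))
    if "emg" not in mat:
        raise FormatError(f"{path}: missing required field 'emg'")
    emg = np.atleast_2d(np.asarray(mat["emg"], dtype=float))
    n = emg.shape[0]

    if label_field is not None:
        if label_field not in mat:
            raise FormatError(f"{path}: missing required field '{label_field}'")
        labels = _column(mat, label_field, n, path)
    elif "restimulus" in mat:
        labels = _column(mat, "restimulus", n, path)
    elif "stimulus" in mat:
        labels = _column(mat, "stimulus", n, path)
    else:
        raise FormatError(f"{path}: missing required field 'stimulus'/'restimulus'")

    if "repetition" in mat:
        repetition = _column(mat, "repetition", n, path)
    elif "rerepetition" in mat:
        repetition = _column(mat, "rerepetition", n, path)
    else:
        raise FormatError(f"{path}: missing required field 'repetition'")

    return EmgRecording(emg, float(fs), labels, repetition, user_id=user_id)


def read_csv_recording(path: str | Path, fs: float, user_id: str) -> EmgRecording:
    """Read a recording from CSV: m signal columns + 'label' + 'repetition'."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    for col in ("label", "repetition"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    sig_cols = [c for c in df.columns if c not in ("label", "repetition")]
    if not sig_cols:
        raise FormatError(f"{path}: no signal columns")
    sig = df[sig_cols]
    bad = sig.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        row = int(np.where(bad.isna().any(axis=1))[0][0])
        raise FormatError(f"{path}: non-numeric signal value at data row {row}")
    return EmgRecording(
        bad.to_numpy(dtype=float),
        float(fs),
        df["label"].to_numpy(),
        df["repetition"].to_numpy(),
        user_id=user_id,
    )


def write_features(features: Sequence["SynergyFeature"], path: str | Path) -> None:
    """Write synergy features to CSV (m columns + label, user_id, window_index).

    Values are stored with 12 significant digits, enough for a lossless
    round-trip of normalized features at test tolerances.
    """
    if len(features) == 0:
        raise ValueError("cannot write an empty feature list")
    m = len(features[0].w)
    for f in features:
        if len(f.w) != m:
            raise ValueError(
                f"heterogeneous feature dimensions: expected {m}, got {len(f.w)}"
            )
    rows = np.vstack([np.asarray(f.w, dtype=float) for f in features])
    df = pd.DataFrame(rows, columns=[f"w{i}" for i in range(m)])
    df["label"] = [f.label for f in features]
    df["user_id"] = [f.user_id for f in features]
    df["window_index"] = [f.window_index for f in features]
    df.to_csv(path, index=False, float_format="%.12g")


def read_features(path: str | Path) -> list["SynergyFeature"]:
    """Read back a feature CSV written by :func:`write_features`."""
    from .synergy import SynergyFeature

    df = pd.read_csv(path)
    w_cols = [c for c in df.columns if c.startswith("w") and c[1:].isdigit()]
    w_cols.sort(key=lambda c: int(c[1:]))
    if not w_cols:
        raise FormatError(f"{path}: no feature columns (w0, w1, ...)")
    out = []
    for _, row in df.iterrows():
        out.append(
            SynergyFeature(
                w=row[w_cols].to_numpy(dtype=float),
                label=int(row["label"]),
                user_id=str(row["user_id"]),
                window_index=int(row["window_index"]),
            )
        )
    return out
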