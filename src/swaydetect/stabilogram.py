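"""Stabilogram reconstruction from tri-axial acceleration.

The sensor's longitudinal axis (``Ay``) is gravity-aligned at rest; ``Az``
points anterior and ``Ax`` lateral.  Antero-posterior and medio-lateral
displacements of the node follow from the lever-arm geometry:

    DAP = H1 * Az / sqrt(Ay^2 + Ax^2)
    DML = H2 * Ax / sqrt(Ay^2 + Az^2)

Raw accelerations are low-pass filtered (zero phase) before the
displacement reconstruction; the DC gravity component is preserved, since
it carries the tilt information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "AccelWindow",
    "Stabilogram",
    "prefilter",
    "compute_displacements",
    "sliding_windows",
    "read_accel_csv",
    "write_stabilogram_csv",
]

DEFAULT_CUTOFF_HZ = 5.0
DEFAULT_FILTER_ORDER = 4


@dataclass
class AccelWindow:
    """One segment of tri-axial acceleration with its lever-arm geometry."""

    t0: float
    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    H1: float
    H2: float

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("acceleration series must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.ax)


@dataclass
class Stabilogram:
    """Paired AP/ML displacement series (m) with a per-sample validity mask.

    Samples flagged invalid (near-free-fall denominators) carry NaN and are
    excluded from downstream feature computations.
    """

    dap: np.ndarray
    dml: np.ndarray
    fs: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dap = np.asarray(self.dap, dtype=float)
        self.dml = np.asarray(self.dml, dtype=float)
        if len(self.dap) != len(self.dml):
            raise ValueError("dap and dml must have equal length")
        if self.valid is None:
            self.valid = np.ones(len(self.dap), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != len(self.dap):
                raise ValueError("validity mask length mismatch")

    def __len__(self) -> int:
        return len(self.dap)

    def valid_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (dap, dml) restricted to valid samples."""
        return self.dap[self.valid], self.dml[self.valid]


def prefilter(
    accel: np.ndarray,
    fs: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter preserving the DC component.

    Applied forward-backward (``filtfilt``), so the effective attenuation is
    the squared magnitude response and the phase is exactly zero.  Works on
    a 1-D series or on a 2-D array filtered along axis 0.
    """
    accel = np.asarray(accel, dtype=float)
    if fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if accel.shape[0] <= padlen:
        raise ValueError(
            f"series of length {accel.shape[0]} shorter than filter warm-up ({padlen + 1})"
        )
    return filtfilt(b, a, accel, axis=0)


def compute_displacements(window: AccelWindow) -> Stabilogram:
    """Reconstruct the stabilogram of one window via the lever-arm model.

    Samples whose projection denominator vanishes (free-fall-like) are
    flagged invalid rather than interpolated.
    """
    ax, ay, az = window.ax, window.ay, window.az
    den_ap = np.sqrt(ay**2 + ax**2)
    den_ml = np.sqrt(ay**2 + az**2)
    eps = 1e-12
    valid = (den_ap > eps) & (den_ml > eps)
    if not np.all(valid):
        warnings.warn(
            f"{int((~valid).sum())} sample(s) with vanishing denominator "
            "flagged invalid",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        dap = np.where(valid, window.H1 * az / den_ap, np.nan)
        dml = np.where(valid, window.H2 * ax / den_ml, np.nan)
    return Stabilogram(dap=dap, dml=dml, fs=window.fs, valid=valid)


def sliding_windows(
    series: np.ndarray,
    fs: float,
    window_s: float = 10.0,
    shift_s: float = 1.0,
) -> list[np.ndarray]:
    """Segment a record into overlapping windows (views along axis 0).

    Windows are ``window_s * fs`` samples long with successive starts
    ``shift_s * fs`` samples apart; the number of windows is
    ``floor((L - window) / shift) + 1`` and an empty list (with a warning)
    is returned when the record is shorter than one window.
    """
    series = np.asarray(series)
    n_win = int(round(window_s * fs))
    n_shift = int(round(shift_s * fs))
    if n_win < 1 or n_shift < 1:
        raise ValueError("window and shift must span at least one sample")
    L = series.shape[0]
    if L < n_win:
        warnings.warn(
            f"record of {L} samples shorter than one {n_win}-sample window",
            RuntimeWarning,
            stacklevel=2,
        )
        return []
    starts = range(0, L - n_win + 1, n_shift)
    return [series[s : s + n_win] for s in starts]


def read_accel_csv(path: str | Path, H1: float, H2: float) -> AccelWindow:
    """Read a (t, ax, ay, az) CSV record into an :class:`AccelWindow`."""
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("record must contain at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return AccelWindow(
        t0=float(t[0]), fs=fs,
        ax=df["ax"].to_numpy(), ay=df["ay"].to_numpy(), az=df["az"].to_numpy(),
        H1=H1, H2=H2,
    )


def write_stabilogram_csv(stab: Stabilogram, path: str | Path) -> None:
    """Write a stabilogram as a (t, dap, dml) CSV (invalid samples as NaN)."""
    t = np.arange(len(stab)) / stab.fs
    pd.DataFrame({"t": t, "dap": stab.dap, "dml": stab.dml}).to_csv(path, index=False)
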