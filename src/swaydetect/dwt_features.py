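"""Wavelet-domain stabilogram features.

Each displacement window (DAP and DML) is decomposed by a 5-level discrete
wavelet transform (Daubechies-4, periodization boundary — an orthogonal
transform, so coefficient energy equals signal energy exactly whenever the
window length is divisible by 2^levels; otherwise the periodization padding
of odd intermediate lengths inflates it by a fraction of a percent).  At 100 Hz the
detail levels cover roughly d1: 25-50 Hz, d2: 12.5-25 Hz, d3: 6.25-12.5 Hz,
d4: 3.1-6.25 Hz, d5: 1.6-3.1 Hz; postural sway concentrates its detail
energy in the lower-frequency levels d3-d5, which alone feed the
classifier.

Per level three statistics are computed over the coefficient series
T(a, k): mean value MV, sample standard deviation STD and energy
E = sum_k T(a, k)^2.  The 9-input feature vector is (MV, STD, E) x
(d3, d4, d5), each entry being the DAP-window value plus the DML-window
value, in the fixed order MV_d3, MV_d4, MV_d5, STD_d3, ..., E_d5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .stabilogram import Stabilogram

__all__ = [
    "DWT_FEATURE_ORDER",
    "DwtFeatureVector",
    "WaveletDecomposition",
    "dwt_decompose",
    "level_features",
    "extract_dwt_features",
]

DEFAULT_WAVELET = "db4"
DEFAULT_MODE = "periodization"
N_LEVELS = 5
SELECTED_LEVELS = ("d3", "d4", "d5")
DWT_FEATURE_ORDER = tuple(
    f"{feat}_{lvl}" for feat in ("MV", "STD", "E") for lvl in SELECTED_LEVELS
)


@dataclass
class WaveletDecomposition:
    """Multilevel DWT coefficients keyed by level name (a5, d5..d1)."""

    levels: dict[str, np.ndarray]
    wavelet_name: str
    mode: str = DEFAULT_MODE

    @property
    def K(self) -> dict[str, int]:
        return {name: len(c) for name, c in self.levels.items()}

    def coeff_list(self) -> list[np.ndarray]:
        """Coefficients in pywt's wavedec order [cA5, cD5, ..., cD1]."""
        names = [f"a{N_LEVELS}"] + [f"d{k}" for k in range(N_LEVELS, 0, -1)]
        return [self.levels[n] for n in names]

    def reconstruct(self) -> np.ndarray:
        return pywt.waverec(self.coeff_list(), self.wavelet_name, mode=self.mode)


def dwt_decompose(
    signal: np.ndarray,
    wavelet_name: str = DEFAULT_WAVELET,
    n_levels: int = N_LEVELS,
    mode: str = DEFAULT_MODE,
) -> WaveletDecomposition:
    """Multilevel DWT of a 1-D signal; requires length >= 2**n_levels."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if len(signal) < 2**n_levels:
        raise ValueError(
            f"signal of length {len(signal)} too short for {n_levels}-level DWT"
        )
    coeffs = pywt.wavedec(signal, wavelet_name, mode=mode, level=n_levels)
    names = [f"a{n_levels}"] + [f"d{k}" for k in range(n_levels, 0, -1)]
    return WaveletDecomposition(
        levels=dict(zip(names, coeffs)), wavelet_name=wavelet_name, mode=mode
    )


def level_features(coefficients: np.ndarray) -> tuple[float, float, float]:
    """(MV, STD, E) of one level's coefficient series.

    MV is the arithmetic mean, STD the unbiased (n-1) standard deviation
    and E the sum of squared coefficients.
    """
    c = np.asarray(coefficients, dtype=float)
    if len(c) == 0:
        raise ValueError("empty coefficient series")
    if len(c) < 2:
        raise ValueError("need at least 2 coefficients for STD")
    return float(np.mean(c)), float(np.std(c, ddof=1)), float(np.sum(c**2))


@dataclass(frozen=True)
class DwtFeatureVector:
    """The 9 wavelet features: (MV, STD, E) x (d3, d4, d5), DAP + DML."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(DWT_FEATURE_ORDER):
            raise ValueError("expected 9 feature values")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DWT_FEATURE_ORDER, self.values))

    def as_array(self) -> np.ndarray:
        return np.array(self.values)


def extract_dwt_features(
    stab: Stabilogram, wavelet_name: str = DEFAULT_WAVELET
) -> DwtFeatureVector:
    """Compute the 9-input DWT feature vector of one stabilogram window.

    Features are computed independently on the DAP and the DML window at
    detail levels d3-d5 and summed per (feature, level) pair; the d1/d2
    levels (sensor-noise band) and the a5 approximation (carrying the
    window mean) never enter the result.
    """
    dap, dml = stab.valid_arrays()
    dec_ap = dwt_decompose(dap, wavelet_name)
    dec_ml = dwt_decompose(dml, wavelet_name)
    per_level_ap = {lvl: level_features(dec_ap.levels[lvl]) for lvl in SELECTED_LEVELS}
    per_level_ml = {lvl: level_features(dec_ml.levels[lvl]) for lvl in SELECTED_LEVELS}
    values = []
    for idx in range(3):  # MV, STD, E
        for lvl in SELECTED_LEVELS:
            values.append(per_level_ap[lvl][idx] + per_level_ml[lvl][idx])
    return DwtFeatureVector(values=tuple(values))
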