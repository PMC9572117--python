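"""Time-domain stabilogram features.

Six features per analysis window: the signed extrema of the AP and ML
displacements, the RMS step length of the trajectory, and the area of the
ellipse containing 95% of the stabilogram points:

    DRMS  = sqrt( sum_i dp(i)^2 / N_pairs ),  dp(i) the Euclidean distance
            between adjacent (DAP, DML) points,
    CEA95 = pi * (CSF * sigma_AP) * (CSF * sigma_ML),  CSF = 2.4477.

The confidence scaling factor CSF maps per-axis standard deviations to the
semi-axes of the coverage ellipse of an uncorrelated bivariate Gaussian;
for 95% coverage it is sqrt(chi2_2^-1(0.95)) = 2.4477.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .stabilogram import Stabilogram

__all__ = [
    "TIME_FEATURE_ORDER",
    "TimeFeatureVector",
    "csf_for_confidence",
    "extract_time_features",
]

TIME_FEATURE_ORDER = ("DAPmax", "DAPmin", "DMLmax", "DMLmin", "DRMS", "CEA95")

#: 95% confidence scaling factor, sqrt(chi2.ppf(0.95, df=2)).
CSF_95 = 2.4477


def csf_for_confidence(p: float) -> float:
    """Scaling factor c such that the ellipse with semi-axes c*sigma covers
    fraction ``p`` of an uncorrelated bivariate Gaussian.

    For a point (X, Y) with independent N(0, sigma^2) components,
    (X/sigma)^2 + (Y/sigma)^2 is chi-squared with 2 dof, hence
    c = sqrt(chi2_2^-1(p)) = sqrt(-2 ln(1 - p)); c(0.95) = 2.4477.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    return float(np.sqrt(chi2.ppf(p, df=2)))


@dataclass(frozen=True)
class TimeFeatureVector:
    """Named time-domain features of one window (m, m and m^2)."""

    DAPmax: float
    DAPmin: float
    DMLmax: float
    DMLmin: float
    DRMS: float
    CEA95: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TIME_FEATURE_ORDER}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in TIME_FEATURE_ORDER])


def extract_time_features(stab: Stabilogram, csf: float = CSF_95) -> TimeFeatureVector:
    """Compute the six time-domain features of one stabilogram window.

    Extrema are signed.  DRMS averages over adjacent-pair distances (so the
    two-point trajectory yields exactly the single step length) and sigma
    uses the unbiased (n-1) estimator.  Invalid samples are dropped before
    computation; at least two valid samples are required.
    """
    dap, dml = stab.valid_arrays()
    if len(dap) < 2:
        raise ValueError("need at least 2 valid samples to extract features")
    dp = np.hypot(np.diff(dap), np.diff(dml))
    drms = float(np.sqrt(np.mean(dp**2)))
    sigma_ap = float(np.std(dap, ddof=1))
    sigma_ml = float(np.std(dml, ddof=1))
    cea95 = float(np.pi * (csf * sigma_ap) * (csf * sigma_ml))
    return TimeFeatureVector(
        DAPmax=float(np.max(dap)),
        DAPmin=float(np.min(dap)),
        DMLmax=float(np.max(dml)),
        DMLmin=float(np.min(dml)),
        DRMS=drms,
        CEA95=cea95,
    )
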