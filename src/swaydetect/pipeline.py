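"""End-to-end helpers: pattern -> prefilter -> stabilogram -> feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dwt_features import DWT_FEATURE_ORDER, extract_dwt_features
from .rig import LabeledDataset, SwayPattern
from .stabilogram import AccelWindow, Stabilogram, compute_displacements, prefilter
from .time_features import TIME_FEATURE_ORDER, extract_time_features

__all__ = [
    "pattern_stabilogram",
    "time_feature_table",
    "dwt_feature_table",
    "feature_tables",
]


def pattern_stabilogram(pattern: SwayPattern, filter_cutoff_hz: float = 5.0) -> Stabilogram:
    """Prefilter one pattern's accelerations and reconstruct its stabilogram."""
    cfg = pattern.config
    filtered = prefilter(pattern.accel, cfg.fs, cutoff_hz=filter_cutoff_hz)
    window = AccelWindow(
        t0=0.0,
        fs=cfg.fs,
        ax=filtered[:, 0],
        ay=filtered[:, 1],
        az=filtered[:, 2],
        H1=cfg.H1,
        H2=cfg.H2,
    )
    return compute_displacements(window)


def time_feature_table(dataset: LabeledDataset, include_label: bool = True) -> pd.DataFrame:
    """Six time-domain features per pattern, one row per window."""
    rows = []
    for p in dataset.patterns:
        stab = pattern_stabilogram(p)
        rows.append(extract_time_features(stab).as_dict())
    df = pd.DataFrame(rows, columns=list(TIME_FEATURE_ORDER))
    if include_label:
        df["label"] = dataset.labels
    return df


def dwt_feature_table(dataset: LabeledDataset, include_label: bool = True) -> pd.DataFrame:
    """Nine DWT features (MV/STD/E at d3-d5, AP + ML) per pattern."""
    rows = []
    for p in dataset.patterns:
        stab = pattern_stabilogram(p)
        rows.append(extract_dwt_features(stab).as_dict())
    df = pd.DataFrame(rows, columns=list(DWT_FEATURE_ORDER))
    if include_label:
        df["label"] = dataset.labels
    return df


def feature_tables(dataset: LabeledDataset) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """(time table, DWT table, binary labels) for a labeled dataset.

    Stabilograms are computed once and shared by both feature extractors.
    """
    time_rows, dwt_rows = [], []
    for p in dataset.patterns:
        stab = pattern_stabilogram(p)
        time_rows.append(extract_time_features(stab).as_dict())
        dwt_rows.append(extract_dwt_features(stab).as_dict())
    time_df = pd.DataFrame(time_rows, columns=list(TIME_FEATURE_ORDER))
    dwt_df = pd.DataFrame(dwt_rows, columns=list(DWT_FEATURE_ORDER))
    return time_df, dwt_df, dataset.labels
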