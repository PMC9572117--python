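"""Accuracy / reliability indexes, dataset splitting and robustness protocols.

The accuracy index of a binary postural-status classifier is

    Q% = 100 * (1 - sum_i |PSPred_i - PSExp_i| / N),

and per-method reliability is summarized by the mean and the sample
standard deviation of the per-pattern reliability index RI.  The
noise-robustness protocol corrupts extracted features with additive
zero-mean Gaussian noise whose std is a percentage of the feature's
maximum absolute value over the dataset, then re-evaluates models that
were fit on clean training data (optionally also corrupting the training
split), replicating over noise seeds.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import anfis as _anfis
from . import threshold as _threshold

__all__ = [
    "EvaluationReport",
    "q_index",
    "ri_summary",
    "split_indices",
    "split_dataset",
    "evaluate_threshold",
    "evaluate_anfis",
    "roi_sweep",
    "add_feature_noise",
    "noise_robustness_protocol",
]


@dataclass
class EvaluationReport:
    """Per-method accuracy and reliability summary on one dataset split."""

    method: str  # one of {"Th", "NF", "DWT"}
    q_pct: float
    ri_mean_pct: float
    ri_std_pct: float
    per_pattern: pd.DataFrame = field(repr=False)  # expected, predicted, ri
    noise_level_pct: float = 0.0

    @property
    def N(self) -> int:
        return len(self.per_pattern)

    def summary_dict(self) -> dict:
        return {
            "method": self.method,
            "noise_level_pct": self.noise_level_pct,
            "q_pct": self.q_pct,
            "ri_mean_pct": self.ri_mean_pct,
            "ri_std_pct": self.ri_std_pct,
            "n_patterns": self.N,
        }


def q_index(predicted: Sequence[int], expected: Sequence[int]) -> float:
    """Accuracy index Q% = 100 * (1 - mismatch fraction)."""
    predicted = np.asarray(predicted, dtype=int)
    expected = np.asarray(expected, dtype=int)
    if predicted.shape != expected.shape:
        raise ValueError("prediction and expectation lengths differ")
    if predicted.size == 0:
        raise ValueError("need at least one pattern")
    return 100.0 * (1.0 - np.mean(np.abs(predicted - expected)))


def ri_summary(ri_values: Sequence[float]) -> tuple[float, float]:
    """(mean, sample std) of per-pattern reliability values; std 0 for n=1."""
    ri = np.asarray(ri_values, dtype=float)
    if ri.size == 0:
        raise ValueError("need at least one reliability value")
    std = float(np.std(ri, ddof=1)) if ri.size > 1 else 0.0
    return float(np.mean(ri)), std


def split_indices(
    n: int, train_fraction: float = 0.6, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffled split: first round(train_fraction * n) go to train."""
    if n < 2:
        raise ValueError("need at least 2 patterns to split")
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in (0, 1]")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_fraction * n))
    if n_train == n:
        warnings.warn("empty test split", RuntimeWarning, stacklevel=2)
    return perm[:n_train], perm[n_train:]


def split_dataset(dataset, train_fraction: float = 0.6, seed: int = 0):
    """Split a sequence, a LabeledDataset or a DataFrame into train/test."""
    if isinstance(dataset, pd.DataFrame):
        tr, te = split_indices(len(dataset), train_fraction, seed)
        return dataset.iloc[tr], dataset.iloc[te]
    if hasattr(dataset, "patterns"):
        tr, te = split_indices(len(dataset.patterns), train_fraction, seed)
        cls = type(dataset)
        return (
            cls([dataset.patterns[i] for i in tr]),
            cls([dataset.patterns[i] for i in te]),
        )
    tr, te = split_indices(len(dataset), train_fraction, seed)
    return [dataset[i] for i in tr], [dataset[i] for i in te]


def evaluate_threshold(
    model: "_threshold.ThresholdModel",
    features: pd.DataFrame,
    labels: Sequence[int],
    noise_level_pct: float = 0.0,
) -> EvaluationReport:
    """Evaluate the threshold voting classifier; RI column is RI_Th."""
    preds = _threshold.predict_table(features, model)
    labels = np.asarray(labels, dtype=int)
    per_pattern = pd.DataFrame(
        {
            "expected": labels,
            "predicted": preds["ps_pred"].to_numpy(),
            "ri": preds["ri_th"].to_numpy(),
            "ri_jf": preds["ri_jf"].to_numpy(),
        }
    )
    mean, std = ri_summary(per_pattern["ri"])
    return EvaluationReport(
        method="Th",
        q_pct=q_index(per_pattern["predicted"], labels),
        ri_mean_pct=mean,
        ri_std_pct=std,
        per_pattern=per_pattern,
        noise_level_pct=noise_level_pct,
    )


def evaluate_anfis(
    model: "_anfis.AnfisModel",
    X: np.ndarray,
    labels: Sequence[int],
    method: str = "NF",
    noise_level_pct: float = 0.0,
) -> EvaluationReport:
    """Evaluate a neuro-fuzzy classifier (time- or DWT-feature flavor)."""
    ps, ps_round, ri = _anfis.predict_status(model, np.atleast_2d(X))
    labels = np.asarray(labels, dtype=int)
    per_pattern = pd.DataFrame(
        {"expected": labels, "predicted": ps_round, "ri": ri, "ps_pred": ps}
    )
    mean, std = ri_summary(ri)
    return EvaluationReport(
        method=method,
        q_pct=q_index(ps_round, labels),
        ri_mean_pct=mean,
        ri_std_pct=std,
        per_pattern=per_pattern,
        noise_level_pct=noise_level_pct,
    )


def roi_sweep(
    X_train: np.ndarray,
    y_train: Sequence[int],
    X_test: np.ndarray,
    y_test: Sequence[int],
    roi_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6),
    base_config: "_anfis.TrainConfig | None" = None,
    method: str = "NF",
) -> tuple[float, dict[float, EvaluationReport]]:
    """Train one neuro-fuzzy model per range-of-influence value.

    The winner maximizes test Q%; ties go to the larger reliability mean,
    then the smaller reliability std, then the smallest radius.
    """
    if len(roi_grid) == 0:
        raise ValueError("empty range-of-influence grid")
    base_config = base_config or _anfis.TrainConfig()
    reports: dict[float, EvaluationReport] = {}
    for roi in roi_grid:
        config = dataclasses.replace(base_config, range_of_influence=roi)
        try:
            model, _ = _anfis.fit_anfis(X_train, np.asarray(y_train, float), config)
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad grid points
            warnings.warn(
                f"training failed for roi={roi}: {exc}", RuntimeWarning, stacklevel=2
            )
            continue
        reports[roi] = evaluate_anfis(model, X_test, y_test, method=method)
    if not reports:
        raise RuntimeError("training failed at every grid point")
    best = min(
        reports,
        key=lambda r: (
            -reports[r].q_pct,
            -reports[r].ri_mean_pct,
            reports[r].ri_std_pct,
            r,
        ),
    )
    return best, reports


def add_feature_noise(
    features: pd.DataFrame, level_pct: float, seed: int = 0
) -> pd.DataFrame:
    """Corrupt each feature column with additive zero-mean Gaussian noise.

    The noise std per column is (level_pct / 100) times the maximum
    absolute value of that column, giving every feature a homogeneous
    relative corruption.  A 'label' column, if present, is left untouched.
    """
    if level_pct < 0:
        raise ValueError("noise level must be non-negative")
    out = features.copy()
    if level_pct == 0:
        return out
    rng = np.random.default_rng(seed)
    for col in out.columns:
        if col == "label":
            continue
        scale = (level_pct / 100.0) * float(np.max(np.abs(out[col].to_numpy())))
        out[col] = out[col].to_numpy() + rng.normal(0.0, scale, len(out))
    return out


def noise_robustness_protocol(
    tables: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    y_train: Sequence[int],
    y_test: Sequence[int],
    levels: Sequence[float] = (0.0, 5.0, 10.0, 20.0),
    n_seeds: int = 10,
    seed: int = 0,
    anfis_config: "_anfis.TrainConfig | None" = None,
    corrupt_train: bool = False,
) -> dict[str, dict[float, dict[str, EvaluationReport]]]:
    """Noise-robustness comparison of the classification strategies.

    ``tables`` maps a method key to its clean (train, test) feature tables:
    ``"Th"`` runs the threshold voting classifier, any other key (``"NF"``,
    ``"DWT"``) a neuro-fuzzy model.  Models are fit once on the clean
    training features; at each noise level both splits are corrupted and
    re-evaluated, replicated over ``n_seeds`` noise realizations, and the
    seed-averaged indexes are reported per (method, level, split).  Level 0
    reproduces the clean reports exactly.  With ``corrupt_train=True`` the
    models are instead re-fit on corrupted training features.
    """
    if 0.0 not in [float(l) for l in levels]:
        raise ValueError("noise levels must include 0")
    if n_seeds < 1:
        raise ValueError("need at least one noise seed")
    y_train = np.asarray(y_train, dtype=int)
    y_test = np.asarray(y_test, dtype=int)
    anfis_config = anfis_config or _anfis.TrainConfig()
    ss = np.random.SeedSequence(seed)
    noise_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_seeds)]

    def _fit(method: str, train_df: pd.DataFrame):
        if method == "Th":
            return _threshold.fit_thresholds(train_df, y_train)
        model, _ = _anfis.fit_anfis(
            train_df.to_numpy(dtype=float), y_train.astype(float), anfis_config
        )
        return model

    def _eval(method: str, model, df: pd.DataFrame, labels, level) -> EvaluationReport:
        if method == "Th":
            return evaluate_threshold(model, df, labels, noise_level_pct=level)
        return evaluate_anfis(
            model, df.to_numpy(dtype=float), labels, method=method,
            noise_level_pct=level,
        )

    results: dict[str, dict[float, dict[str, EvaluationReport]]] = {}
    for method, (train_df, test_df) in tables.items():
        clean_model = _fit(method, train_df)
        results[method] = {}
        for level in levels:
            level = float(level)
            split_reports: dict[str, list[EvaluationReport]] = {"train": [], "test": []}
            seeds_here = [noise_seeds[0]] if level == 0.0 else noise_seeds
            for ns in seeds_here:
                noisy_train = add_feature_noise(train_df, level, seed=ns)
                noisy_test = add_feature_noise(test_df, level, seed=ns + 1)
                model = _fit(method, noisy_train) if corrupt_train else clean_model
                split_reports["train"].append(
                    _eval(method, model, noisy_train, y_train, level)
                )
                split_reports["test"].append(
                    _eval(method, model, noisy_test, y_test, level)
                )
            results[method][level] = {
                split: _average_reports(reps, method, level)
                for split, reps in split_reports.items()
            }
    return results


def _average_reports(
    reports: list[EvaluationReport], method: str, level: float
) -> EvaluationReport:
    per_pattern = reports[0].per_pattern if len(reports) == 1 else pd.concat(
        [r.per_pattern for r in reports], ignore_index=True
    )
    return EvaluationReport(
        method=method,
        q_pct=float(np.mean([r.q_pct for r in reports])),
        ri_mean_pct=float(np.mean([r.ri_mean_pct for r in reports])),
        ri_std_pct=float(np.mean([r.ri_std_pct for r in reports])),
        per_pattern=per_pattern,
        noise_level_pct=level,
    )
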