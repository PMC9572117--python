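"""ROC-calibrated threshold voting classifier with reliability indexes.

Each stabilogram feature J_F is compared against a threshold J_th chosen on
the training set at the Youden-optimal point of the feature's ROC curve
(maximizing sensitivity + specificity - 1 over candidate cut-points).  The
comparison yields a binary vote per feature; direction-specific extrema
features (AP and ML maxima; AP and ML minima) are each combined by a
logical OR, since a single-axis instability fires only the matching axis.
A window is classified potentially unstable when at least 50% of the
effective votes are set.

Two reliability indexes accompany each prediction:

``RI_Th``
    distance of the mean binary vote from the class separator 0.5,
    ``100 * |mean(J_fbin) - 0.5| / 0.5`` — 100 for a unanimous vote;
``RI_JF``
    mean normalized feature-to-threshold distance, counting a feature only
    when its own vote agrees with the final prediction (max-pooled inside
    OR groups), ``100 * mean_q(J_P,q)`` with
    ``J_P,q = |JND_q|`` if aligned else 0 and
    ``JND_q = (J_F,q - J_th,q) / max_train|J_F,q - J_th,q|`` clipped to
    [-1, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .time_features import TIME_FEATURE_ORDER

__all__ = [
    "DEFAULT_OR_GROUPS",
    "ThresholdModel",
    "BinaryVote",
    "ThresholdPrediction",
    "fit_thresholds",
    "binarize",
    "classify",
    "reliability_th",
    "reliability_jf",
    "predict",
    "predict_table",
]

#: Direction-specific extrema are OR-combined: a purely antero-posterior
#: instability fires DAPmax/DAPmin but not the ML counterparts, and vice
#: versa, so the per-direction pairs act as single "any-axis exceedance"
#: votes.  DRMS and CEA95 respond to instability on either axis and vote
#: individually; the effective vote count is therefore 4.
DEFAULT_OR_GROUPS: tuple[tuple[str, ...], ...] = (
    ("DAPmax", "DMLmax"),
    ("DAPmin", "DMLmin"),
)


@dataclass
class ThresholdModel:
    """Per-feature thresholds, vote directions, JND normalizers, OR groups.

    ``directions[q]`` is +1 when values above the threshold indicate
    instability and -1 when values below do (signed minima).
    """

    thresholds: dict[str, float]
    directions: dict[str, int]
    normalizers: dict[str, float]
    feature_order: tuple[str, ...] = TIME_FEATURE_ORDER
    or_groups: tuple[tuple[str, ...], ...] = DEFAULT_OR_GROUPS

    def __post_init__(self) -> None:
        for name in self.feature_order:
            if name not in self.thresholds:
                raise ValueError(f"missing threshold for feature {name!r}")
        grouped = [n for g in self.or_groups for n in g]
        if len(grouped) != len(set(grouped)):
            raise ValueError("a feature appears in more than one OR group")

    def effective_groups(self) -> list[tuple[str, ...]]:
        """OR groups followed by the remaining individually-voting features."""
        grouped = {n for g in self.or_groups for n in g}
        groups = [tuple(g) for g in self.or_groups]
        groups.extend((name,) for name in self.feature_order if name not in grouped)
        return groups

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "directions": self.directions,
            "normalizers": self.normalizers,
            "feature_order": list(self.feature_order),
            "or_groups": [list(g) for g in self.or_groups],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            thresholds=payload["thresholds"],
            directions={k: int(v) for k, v in payload["directions"].items()},
            normalizers=payload["normalizers"],
            feature_order=tuple(payload["feature_order"]),
            or_groups=tuple(tuple(g) for g in payload["or_groups"]),
        )


@dataclass
class BinaryVote:
    """Effective binary votes of one window after OR grouping."""

    jfbin: dict[str, int]

    @property
    def n_effective(self) -> int:
        return len(self.jfbin)

    @property
    def fraction_over(self) -> float:
        if not self.jfbin:
            raise ValueError("no effective features to vote")
        return float(np.mean(list(self.jfbin.values())))


@dataclass(frozen=True)
class ThresholdPrediction:
    ps_pred: int
    ri_th: float
    ri_jf: float


def _youden_scan(
    values: np.ndarray, labels: np.ndarray, direction: int
) -> tuple[float, float]:
    """Best (J, threshold) for votes '1 iff direction*(v - th) > 0'.

    Candidate thresholds are the midpoints of sorted unique values plus
    sentinels outside the value range; ties on J are broken toward the
    larger threshold (conservative toward 'stable' for direction +1).
    """
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    span = max(uniq[-1] - uniq[0], 1.0)
    candidates = np.concatenate([[uniq[0] - span], mids, [uniq[-1] + span]])
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best_j, best_th = -np.inf, candidates[0]
    for th in candidates:
        votes = direction * (values - th) > 0
        sens = np.count_nonzero(votes & pos) / n_pos
        spec = np.count_nonzero(~votes & ~pos) / n_neg
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and th > best_th):
            best_j, best_th = j, th
    return best_j, float(best_th)


def fit_thresholds(
    features: pd.DataFrame,
    labels: Sequence[int],
    feature_order: Sequence[str] | None = None,
    or_groups: Sequence[Sequence[str]] | None = None,
) -> ThresholdModel:
    """Fit per-feature ROC thresholds (Youden optimum) on a training table.

    For each feature both vote orientations are scanned and the one with
    the larger Youden's J is kept, so signed minima (where instability
    drives the value *down*) binarize correctly.  The JND normalizer is the
    per-feature maximum |J_F - J_th| over the same training set.
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if not (len(classes) == 2 and set(classes) <= {0, 1}):
        raise ValueError("training labels must contain both classes 0 and 1")
    if feature_order is None:
        feature_order = [c for c in features.columns if c != "label"]
    if or_groups is None:
        or_groups = [
            g for g in DEFAULT_OR_GROUPS if all(n in feature_order for n in g)
        ]
    thresholds: dict[str, float] = {}
    directions: dict[str, int] = {}
    normalizers: dict[str, float] = {}
    for name in feature_order:
        values = features[name].to_numpy(dtype=float)
        if np.all(values == values[0]):
            warnings.warn(
                f"feature {name!r} is constant on the training set",
                RuntimeWarning,
                stacklevel=2,
            )
            thresholds[name] = float(values[0])
            directions[name] = 1
            normalizers[name] = 0.0
            continue
        j_up, th_up = _youden_scan(values, labels, +1)
        j_dn, th_dn = _youden_scan(values, labels, -1)
        if j_dn > j_up:
            thresholds[name], directions[name] = th_dn, -1
        else:
            thresholds[name], directions[name] = th_up, +1
        normalizers[name] = float(np.max(np.abs(values - thresholds[name])))
    return ThresholdModel(
        thresholds=thresholds,
        directions=directions,
        normalizers=normalizers,
        feature_order=tuple(feature_order),
        or_groups=tuple(tuple(g) for g in or_groups),
    )


def _member_binaries(features: Mapping[str, float], model: ThresholdModel) -> dict[str, int]:
    out = {}
    for name in model.feature_order:
        if name not in features:
            raise ValueError(f"missing feature {name!r}")
        d = model.directions.get(name, 1)
        out[name] = int(d * (features[name] - model.thresholds[name]) > 0)
    return out


def _group_name(group: tuple[str, ...]) -> str:
    return "|".join(group)


def binarize(features: Mapping[str, float], model: ThresholdModel) -> BinaryVote:
    """Per-feature strict-exceedance votes collapsed by OR groups."""
    member = _member_binaries(features, model)
    jfbin = {
        _group_name(g): int(any(member[n] for n in g))
        for g in model.effective_groups()
    }
    return BinaryVote(jfbin=jfbin)


def classify(vote: BinaryVote) -> int:
    """Potentially unstable (1) iff at least 50% of effective votes are set."""
    return int(vote.fraction_over >= 0.5)


def reliability_th(vote: BinaryVote) -> float:
    """RI_Th % — distance of the mean vote from the 0.5 separator."""
    return 100.0 * abs(vote.fraction_over - 0.5) / 0.5


def reliability_jf(
    features: Mapping[str, float], model: ThresholdModel, ps_pred: int
) -> float:
    """RI_JF % — mean normalized threshold distance of aligned features.

    JND is clipped to [-1, 1]; a feature contributes |JND| only when its
    own vote agrees with the final prediction; OR groups contribute the
    maximum over their members.  Features with a zero normalizer (constant
    on the training set) are skipped with a warning.
    """
    jnd: dict[str, float] = {}
    for name in model.feature_order:
        norm = model.normalizers.get(name, 0.0)
        if norm <= 0.0:
            warnings.warn(
                f"feature {name!r} has zero normalizer; skipped in RI_JF",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        d = model.directions.get(name, 1)
        jnd[name] = float(
            np.clip(d * (features[name] - model.thresholds[name]) / norm, -1.0, 1.0)
        )

    def j_p(name: str) -> float:
        if name not in jnd:
            return 0.0
        binary = int(jnd[name] > 0)
        return abs(jnd[name]) if binary == ps_pred else 0.0

    contributions = []
    for group in model.effective_groups():
        usable = [n for n in group if n in jnd]
        if not usable:
            continue
        contributions.append(max(j_p(n) for n in usable))
    if not contributions:
        raise ValueError("no usable features for RI_JF")
    return 100.0 * float(np.mean(contributions))


def predict(features: Mapping[str, float], model: ThresholdModel) -> ThresholdPrediction:
    """Classify one window and attach both reliability indexes."""
    vote = binarize(features, model)
    ps = classify(vote)
    return ThresholdPrediction(
        ps_pred=ps,
        ri_th=reliability_th(vote),
        ri_jf=reliability_jf(features, model, ps),
    )


def predict_table(features: pd.DataFrame, model: ThresholdModel) -> pd.DataFrame:
    """Vectorized predictions for a feature table; one row per window."""
    rows = []
    for _, row in features.iterrows():
        p = predict(row.to_dict(), model)
        rows.append({"ps_pred": p.ps_pred, "ri_th": p.ri_th, "ri_jf": p.ri_jf})
    return pd.DataFrame(rows, index=features.index)
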