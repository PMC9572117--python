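"""Sugeno neuro-fuzzy inference with subtractive-clustering initialization.

The classifier is a single-output first-order Sugeno fuzzy system.  Each
rule r has Gaussian antecedent membership functions (one per input, with
center c_rd and width sigma_rd) and a linear consequent
f_r(x) = p_r . [x, 1].  The output is the firing-strength-weighted average

    y(x) = sum_r w_r(x) f_r(x) / sum_r w_r(x),
    w_r(x) = prod_d exp(-(x_d - c_rd)^2 / (2 sigma_rd^2)).

Structure identification uses subtractive clustering (density-potential
peak extraction governed by the *range of influence* radius): each cluster
center seeds one rule, with sigma = roi * input_range / sqrt(8).  Training
is hybrid: consequents are re-fit by global linear least squares each
epoch while antecedent centers and widths follow a normalized gradient
step on the mean squared output error; the step size is halved whenever an
epoch fails to decrease the error, so the recorded training error is
non-increasing.

For postural-status prediction, the continuous output is rounded at the
0.5 class separator and the reliability index RI = 100 |y - 0.5| / 0.5
(clipped to [0, 100]) measures the distance from the separator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TrainConfig",
    "AnfisModel",
    "subtractive_clustering",
    "init_fis",
    "train_hybrid",
    "evaluate",
    "predict_status",
    "fit_anfis",
]

_SQUASH = 1.25
_ACCEPT = 0.5
_REJECT = 0.15
# Firing strengths are normalized in log space, so the weighted average is
# defined whenever the maximum log-strength is finite; the fallback to the
# mean rule constant only triggers when every rule's strength is exactly 0.


@dataclass(frozen=True)
class TrainConfig:
    """Hybrid-training hyper-parameters.

    range_of_influence is the dimensionless cluster-search radius on the
    unit hypercube; epochs the number of hybrid passes; step_size the
    initial normalized gradient step for the antecedent parameters.  The
    procedure is deterministic; ``seed`` is kept for API symmetry with the
    stochastic stages of the pipeline.
    """

    range_of_influence: float = 0.3
    epochs: int = 50
    step_size: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.range_of_influence <= 1.0:
            raise ValueError("range_of_influence must lie in (0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")


@dataclass
class AnfisModel:
    """Sugeno rule base: Gaussian antecedents plus linear consequents."""

    centers: np.ndarray  # (n_rules, n_inputs)
    sigmas: np.ndarray  # (n_rules, n_inputs), all > 0
    consequents: np.ndarray  # (n_rules, n_inputs + 1), last column constant
    input_min: np.ndarray  # (n_inputs,)
    input_max: np.ndarray  # (n_inputs,)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        self.consequents = np.atleast_2d(np.asarray(self.consequents, dtype=float))
        if self.centers.shape[0] < 1:
            raise ValueError("model needs at least one rule")
        if np.any(self.sigmas <= 0):
            raise ValueError("membership widths must be positive")
        if self.consequents.shape != (self.n_rules, self.n_inputs + 1):
            raise ValueError("consequent shape must be (n_rules, n_inputs + 1)")

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[1]

    def copy(self) -> "AnfisModel":
        return AnfisModel(
            centers=self.centers.copy(),
            sigmas=self.sigmas.copy(),
            consequents=self.consequents.copy(),
            input_min=np.array(self.input_min, dtype=float),
            input_max=np.array(self.input_max, dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centers": self.centers.tolist(),
            "sigmas": self.sigmas.tolist(),
            "consequents": self.consequents.tolist(),
            "input_min": np.asarray(self.input_min).tolist(),
            "input_max": np.asarray(self.input_max).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnfisModel":
        p = json.loads(Path(path).read_text())
        return cls(
            centers=np.array(p["centers"]),
            sigmas=np.array(p["sigmas"]),
            consequents=np.array(p["consequents"]),
            input_min=np.array(p["input_min"]),
            input_max=np.array(p["input_max"]),
        )


def subtractive_clustering(
    X: np.ndarray,
    roi: float,
    squash: float = _SQUASH,
    accept_ratio: float = _ACCEPT,
    reject_ratio: float = _REJECT,
) -> np.ndarray:
    """Density-potential cluster centers of points on the unit hypercube.

    Each point's potential is P_i = sum_j exp(-4 ||x_i - x_j||^2 / roi^2);
    peaks are extracted iteratively, each accepted center squashing nearby
    potential with radius ``squash * roi``.  Candidates between the accept
    and reject ratios are kept only when sufficiently far from existing
    centers (dmin/roi + P/P_ref >= 1).  Always returns at least one center.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("cannot cluster an empty dataset")
    if roi <= 0:
        raise ValueError("range of influence must be positive")
    alpha = 4.0 / roi**2
    beta = 4.0 / (squash * roi) ** 2
    sq_dists = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    potential = np.exp(-alpha * sq_dists).sum(axis=1)

    first = int(np.argmax(potential))
    p_ref = float(potential[first])
    centers = [first]
    potential = potential - potential[first] * np.exp(-beta * sq_dists[first])
    if p_ref <= 0:
        return X[centers]

    for _ in range(X.shape[0]):
        cand = int(np.argmax(potential))
        p_cand = float(potential[cand])
        if p_cand <= 0:
            break
        if p_cand > accept_ratio * p_ref:
            accepted = True
        elif p_cand < reject_ratio * p_ref:
            break
        else:
            dmin = np.sqrt(min(sq_dists[cand, c] for c in centers))
            accepted = dmin / roi + p_cand / p_ref >= 1.0
        if accepted:
            centers.append(cand)
            potential = potential - p_cand * np.exp(-beta * sq_dists[cand])
        else:
            potential[cand] = 0.0
    return X[centers]


def _log_firing(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Log rule firing strengths, shape (n_samples, n_rules)."""
    z = (X[:, None, :] - model.centers[None, :, :]) / model.sigmas[None, :, :]
    return -0.5 * np.sum(z**2, axis=-1)


def _normalized_firing(model: AnfisModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(normalized firing strengths, per-sample dead mask).

    The normalization is done in log space (softmax), so the weighted
    average stays well-defined however small the raw strengths are; a
    sample is dead only when every rule's log-strength is -inf.
    """
    lw = _log_firing(model, X)
    lw_max = lw.max(axis=1, keepdims=True)
    dead = ~np.isfinite(lw_max.ravel())
    shifted = np.where(np.isfinite(lw_max), lw - lw_max, 0.0)
    w_shift = np.exp(shifted)
    wn = w_shift / w_shift.sum(axis=1, keepdims=True)
    return wn, dead


def _rule_outputs(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Per-rule linear consequent outputs, shape (n_samples, n_rules)."""
    return X @ model.consequents[:, :-1].T + model.consequents[:, -1][None, :]


def _fit_consequents(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Global least-squares consequents given the current antecedents."""
    n, d = X.shape
    wn, _ = _normalized_firing(model, X)
    ones = np.ones((n, 1))
    Xa = np.concatenate([X, ones], axis=1)  # (n, d+1)
    # design[i, r*(d+1)+j] = wn[i, r] * Xa[i, j]
    design = (wn[:, :, None] * Xa[:, None, :]).reshape(n, model.n_rules * (d + 1))
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef.reshape(model.n_rules, d + 1)


def evaluate(model: AnfisModel, x: np.ndarray) -> np.ndarray | float:
    """Continuous Sugeno output for one sample or a batch.

    Firing-strength-weighted average of the rule consequents; when the
    total firing strength underflows, the unweighted mean of the rule
    constants is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected {model.n_inputs} inputs, got {X.shape[1]}"
        )
    wn, dead = _normalized_firing(model, X)
    f = _rule_outputs(model, X)
    if np.any(dead):
        warnings.warn(
            "total firing strength underflow; falling back to the mean rule "
            "constant for the affected sample(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.where(dead, np.mean(model.consequents[:, -1]), (wn * f).sum(axis=1))
    return float(out[0]) if single else out


def init_fis(X: np.ndarray, y: np.ndarray, roi: float) -> AnfisModel:
    """Build the initial rule base: one rule per subtractive-cluster center.

    Inputs are normalized to the unit hypercube for clustering; Gaussian
    widths are roi * input_range / sqrt(8) and the consequents come from a
    global least-squares fit with the initial antecedents.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y) or X.shape[0] == 0:
        raise ValueError("X and y must be non-empty with matching lengths")
    x_min = X.min(axis=0)
    x_max = X.max(axis=0)
    rng_span = np.where(x_max > x_min, x_max - x_min, 1.0)
    Xn = (X - x_min) / rng_span
    centers_n = subtractive_clustering(Xn, roi)
    centers = centers_n * rng_span + x_min
    sigmas = np.tile(roi * rng_span / np.sqrt(8.0), (centers.shape[0], 1))
    model = AnfisModel(
        centers=centers,
        sigmas=sigmas,
        consequents=np.zeros((centers.shape[0], X.shape[1] + 1)),
        input_min=x_min,
        input_max=x_max,
    )
    model.consequents = _fit_consequents(model, X, y)
    return model


def _rmse(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> float:
    out = evaluate(model, X)
    return float(np.sqrt(np.mean((out - y) ** 2)))


def _antecedent_gradients(
    model: AnfisModel, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the MSE w.r.t. centers and sigmas.

    Since dMSE/dw_r and dw_r/dparam both carry the raw firing strength
    only through the normalized ratio w_r / sum(w), the gradients are
    expressed with the softmax-normalized strengths and stay finite even
    when the raw strengths underflow.
    """
    n = X.shape[0]
    wn, _ = _normalized_firing(model, X)  # (n, r)
    f = _rule_outputs(model, X)  # (n, r)
    out = (wn * f).sum(axis=1, keepdims=True)
    err = out - y[:, None]  # (n, 1)
    # dMSE/dw_ir * w_ir = (2/n) err_i (f_ir - out_i) * wn_ir
    common = ((2.0 / n) * err * (f - out) * wn)[:, :, None]
    diff = X[:, None, :] - model.centers[None, :, :]  # (n, r, d)
    grad_c = np.sum(common * diff / model.sigmas[None, :, :] ** 2, axis=0)
    grad_s = np.sum(common * diff**2 / model.sigmas[None, :, :] ** 3, axis=0)
    return grad_c, grad_s


def train_hybrid(
    model: AnfisModel,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[AnfisModel, list[float]]:
    """Hybrid least-squares / gradient-descent training.

    Each epoch re-fits the consequents by least squares and moves the
    antecedent centers and widths one normalized gradient step downhill.
    A step that would increase the training RMSE is rejected and the step
    size halved, so the returned error history is non-increasing.  With
    ``epochs=0`` the model is returned unchanged (up to a copy).
    Raises ``RuntimeError`` if the error diverges beyond 1e6.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    current = model.copy()
    current.consequents = _fit_consequents(current, X, y)
    err = _rmse(current, X, y)
    history = [err]
    step = config.step_size
    span = np.where(
        np.asarray(current.input_max) > np.asarray(current.input_min),
        np.asarray(current.input_max) - np.asarray(current.input_min),
        1.0,
    )
    sigma_floor = 1e-6 * span
    for _ in range(config.epochs):
        if err > 1e6:
            raise RuntimeError(f"training diverged (RMSE={err:.3g})")
        grad_c, grad_s = _antecedent_gradients(current, X, y)
        # step in range-normalized coordinates so inputs of very different
        # physical scale move comparably
        g_cn = grad_c * span[None, :]
        g_sn = grad_s * span[None, :]
        norm = np.sqrt(np.sum(g_cn**2) + np.sum(g_sn**2))
        if norm < 1e-15 or step < 1e-15:
            history.append(err)
            continue
        candidate = current.copy()
        candidate.centers = current.centers - step * (g_cn / norm) * span[None, :]
        candidate.sigmas = np.maximum(
            current.sigmas - step * (g_sn / norm) * span[None, :],
            sigma_floor[None, :],
        )
        candidate.consequents = _fit_consequents(candidate, X, y)
        cand_err = _rmse(candidate, X, y)
        if cand_err <= err + 1e-9:
            current, err = candidate, cand_err
        else:
            step *= 0.5
        history.append(err)
    return current, history


def fit_anfis(
    X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None
) -> tuple[AnfisModel, list[float]]:
    """Convenience: subtractive-clustering init followed by hybrid training."""
    config = config or TrainConfig()
    model = init_fis(X, y, config.range_of_influence)
    return train_hybrid(model, X, y, config)


def predict_status(
    model: AnfisModel, x: np.ndarray
) -> tuple[np.ndarray | float, np.ndarray | int, np.ndarray | float]:
    """(continuous output, rounded class, reliability %) for sample(s).

    The class separator is 0.5; ties round up to 1 (unstable), the
    conservative choice for a safety application.  RI = 100 |y - 0.5| / 0.5
    clipped to 100, since the Sugeno output is not confined to [0, 1].
    """
    ps = evaluate(model, x)
    ps_arr = np.atleast_1d(np.asarray(ps, dtype=float))
    ps_round = (ps_arr >= 0.5).astype(int)
    ri = np.minimum(100.0, 100.0 * np.abs(ps_arr - 0.5) / 0.5)
    if np.isscalar(ps) or (isinstance(ps, float)):
        return float(ps_arr[0]), int(ps_round[0]), float(ri[0])
    return ps_arr, ps_round, ri
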