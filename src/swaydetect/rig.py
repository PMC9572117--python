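"""Synthetic rig simulator for labeled postural-sway acceleration patterns.

The simulator emulates a chest-height sensor node mounted on a two-joint
mechanical structure: tilting around the bottom joint (lever arm ``H1``)
produces antero-posterior (AP) displacement, tilting around the belt joint
(lever arm ``H2``) produces medio-lateral (ML) displacement.  Four movement
classes are generated:

``ST``
    quiet standing — low-amplitude sway on both axes (stable, label 0);
``AP`` / ``ML``
    over-threshold tilt on the named axis only (unstable, label 1);
``UNS``
    over-threshold tilt on both axes (unstable, label 1).

Tilt dynamics are band-limited stochastic processes built as a superposition
of five sinusoids with random frequencies inside the postural-sway band and
random phases, peak-normalized to the class amplitude.  Acceleration is the
quasi-static projection of gravity onto the tilted sensor axes, so that the
lever-arm displacement reconstruction ``D = H * tan(theta)`` holds exactly
for noiseless patterns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "STABLE_CLASSES",
    "CAMPAIGN_COUNTS",
    "RigConfig",
    "SwayPattern",
    "LabeledDataset",
    "default_cases",
    "simulate_tilt_trace",
    "tilt_to_acceleration",
    "generate_dataset",
]

CLASSES = ("ST", "AP", "ML", "UNS")
STABLE_CLASSES = frozenset({"ST"})

#: Pattern counts per movement class and geometry case of the reference
#: rig acquisition campaign (six node-position cases, ~50 patterns per
#: class and case, 1239 patterns in total).
CAMPAIGN_COUNTS: dict[int, dict[str, int]] = {
    1: {"ST": 47, "AP": 53, "ML": 52, "UNS": 49},
    2: {"ST": 50, "AP": 51, "ML": 48, "UNS": 52},
    3: {"ST": 58, "AP": 50, "ML": 52, "UNS": 50},
    4: {"ST": 58, "AP": 51, "ML": 52, "UNS": 50},
    5: {"ST": 53, "AP": 53, "ML": 47, "UNS": 52},
    6: {"ST": 51, "AP": 58, "ML": 50, "UNS": 52},
}

_N_SINUSOIDS = 5


@dataclass(frozen=True)
class RigConfig:
    """Geometry and signal parameters of one simulated node position.

    Parameters
    ----------
    H1, H2 : float
        Lever arms (m) of the bottom (AP) and belt (ML) joints.
    fs : float
        Sampling rate in Hz.
    window_s : float
        Pattern duration in seconds; ``window_s * fs`` must be an integer.
    g : float
        Gravitational acceleration, m/s^2.
    sway_band : (float, float)
        Frequency interval (Hz) from which tilt-dynamics sinusoid
        frequencies are drawn; upper edge must respect Nyquist.
    amp_stable, amp_unstable : float
        Peak tilt amplitude (rad) for stable and over-threshold sway.
    instability_displacement : float
        Displacement (m) above which a movement counts as unstable;
        used as a plausibility margin, labels are set by imposed class.
    sensor_noise_std : float
        Std of additive zero-mean Gaussian accelerometer noise, m/s^2.
    seed : int
        Base seed for reproducible generation.
    """

    H1: float = 1.1
    H2: float = 0.5
    fs: float = 100.0
    window_s: float = 10.0
    g: float = 9.81
    sway_band: tuple[float, float] = (0.1, 2.0)
    amp_stable: float = 0.005
    amp_unstable: float = 0.1
    instability_displacement: float = 0.04
    sensor_noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.H1 <= 0 or self.H2 <= 0:
            raise ValueError("lever arms H1, H2 must be positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (self.amp_unstable > self.amp_stable >= 0):
            raise ValueError("require amp_unstable > amp_stable >= 0")
        n = self.window_s * self.fs
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValueError("window_s * fs must be an integer >= 2")
        lo, hi = self.sway_band
        if not (0 <= lo < hi < self.fs / 2):
            raise ValueError("sway_band must lie inside (0, fs/2)")
        if self.sensor_noise_std < 0:
            raise ValueError("sensor_noise_std must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.window_s * self.fs))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sway_band"] = list(self.sway_band)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RigConfig":
        d = dict(d)
        if "sway_band" in d:
            d["sway_band"] = tuple(d["sway_band"])
        return cls(**d)


@dataclass
class SwayPattern:
    """One labeled window of simulated tri-axial acceleration."""

    label_class: str
    label_binary: int
    case_id: int
    accel: np.ndarray  # (n_samples, 3) columns ax, ay, az, m/s^2
    config: RigConfig
    theta_ap: np.ndarray | None = None  # imposed tilt traces (rad), kept
    theta_ml: np.ndarray | None = None  # for round-trip verification

    def __post_init__(self) -> None:
        if self.label_class not in CLASSES:
            raise ValueError(f"unknown movement class {self.label_class!r}")
        expected = 0 if self.label_class in STABLE_CLASSES else 1
        if self.label_binary != expected:
            raise ValueError("label_binary inconsistent with movement class")
        if len(self.accel) != self.config.n_samples:
            raise ValueError("acceleration length != window_s * fs")

    @property
    def ax(self) -> np.ndarray:
        return self.accel[:, 0]

    @property
    def ay(self) -> np.ndarray:
        return self.accel[:, 1]

    @property
    def az(self) -> np.ndarray:
        return self.accel[:, 2]


@dataclass
class LabeledDataset:
    """A list of :class:`SwayPattern` with convenience accessors."""

    patterns: list[SwayPattern] = field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.patterns)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label_binary for p in self.patterns], dtype=int)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "pattern_id": i,
                "case_id": p.case_id,
                "class": p.label_class,
                "label": p.label_binary,
                "H1": p.config.H1,
                "H2": p.config.H2,
                "seed": p.config.seed,
            }
            for i, p in enumerate(self.patterns)
        ]
        return pd.DataFrame(
            rows,
            columns=["pattern_id", "case_id", "class", "label", "H1", "H2", "seed"],
        )

    def write(self, out_dir: str | Path) -> Path:
        """Write one CSV per pattern plus a manifest CSV; returns manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, p in enumerate(self.patterns):
            t = np.arange(p.config.n_samples) / p.config.fs
            df = pd.DataFrame(
                {"t": t, "ax": p.ax, "ay": p.ay, "az": p.az}
            )
            df.to_csv(out_dir / f"pattern_{i:05d}.csv", index=False)
            with open(out_dir / f"pattern_{i:05d}.json", "w") as fh:
                json.dump(p.config.to_dict(), fh)
        manifest_path = out_dir / "manifest.csv"
        self.manifest().to_csv(manifest_path, index=False)
        return manifest_path

    @classmethod
    def read(cls, in_dir: str | Path) -> "LabeledDataset":
        in_dir = Path(in_dir)
        manifest = pd.read_csv(in_dir / "manifest.csv")
        patterns = []
        for _, row in manifest.iterrows():
            pid = int(row["pattern_id"])
            df = pd.read_csv(in_dir / f"pattern_{pid:05d}.csv")
            with open(in_dir / f"pattern_{pid:05d}.json") as fh:
                config = RigConfig.from_dict(json.load(fh))
            accel = df[["ax", "ay", "az"]].to_numpy()
            patterns.append(
                SwayPattern(
                    label_class=str(row["class"]),
                    label_binary=int(row["label"]),
                    case_id=int(row["case_id"]),
                    accel=accel,
                    config=config,
                )
            )
        return cls(patterns)


def default_cases(base: RigConfig | None = None) -> dict[int, RigConfig]:
    """Six geometry cases: H1 in {1.0, 1.1, 1.2} m x H2 in {0.5, 0.6} m."""
    base = base or RigConfig()
    cases = {}
    cid = 1
    for H1 in (1.0, 1.1, 1.2):
        for H2 in (0.5, 0.6):
            cases[cid] = dataclasses.replace(base, H1=H1, H2=H2)
            cid += 1
    return cases


def _band_limited_trace(rng: np.random.Generator, amp: float, n: int, fs: float,
                        band: tuple[float, float]) -> np.ndarray:
    """Sum of sinusoids with random frequencies/phases, peak-normalized to amp.

    Frequencies are drawn stratified — one per equal sub-band of the sway
    band — so every trace carries both slow and fast sway content; this
    keeps the spectral shape of the traces comparable across patterns
    while the phases and exact frequencies stay random.
    """
    edges = np.linspace(band[0], band[1], _N_SINUSOIDS + 1)
    freqs = rng.uniform(edges[:-1], edges[1:])
    phases = rng.uniform(0.0, 2.0 * np.pi, _N_SINUSOIDS)
    t = np.arange(n) / fs
    x = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    if amp == 0.0:
        return np.zeros(n)
    peak = np.max(np.abs(x))
    if peak == 0.0:  # astronomically unlikely, but keep it defined
        return np.zeros(n)
    return amp * x / peak


def simulate_tilt_trace(
    label_class: str, config: RigConfig, seed: int | np.random.SeedSequence | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate (theta_AP, theta_ML) tilt series in rad for one pattern.

    The peak absolute tilt equals ``amp_unstable`` on the axis (or axes)
    named by the movement class, ``amp_stable`` on both axes for quiet
    standing, and a random sub-stable value on the untouched axis of a
    single-axis movement.  Deterministic for a fixed seed.
    """
    if label_class not in CLASSES:
        raise ValueError(f"unknown movement class {label_class!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    # Single-axis movement classes keep their untouched joint slightly
    # calmer than quiet standing (the operator holds it while tilting the
    # other), drawn uniformly below the stable amplitude.
    sub_stable = rng.uniform(0.3, 0.9) * config.amp_stable
    if label_class == "ST":
        amp_ap = amp_ml = config.amp_stable
    elif label_class == "AP":
        amp_ap, amp_ml = config.amp_unstable, sub_stable
    elif label_class == "ML":
        amp_ap, amp_ml = sub_stable, config.amp_unstable
    else:  # UNS
        amp_ap = amp_ml = config.amp_unstable
    n = config.n_samples
    theta_ap = _band_limited_trace(rng, amp_ap, n, config.fs, config.sway_band)
    theta_ml = _band_limited_trace(rng, amp_ml, n, config.fs, config.sway_band)
    return theta_ap, theta_ml


def tilt_to_acceleration(
    theta_ap: np.ndarray,
    theta_ml: np.ndarray,
    config: RigConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Project gravity onto the tilted sensor axes (quasi-static model).

    The projection is the exact inverse of the lever-arm displacement
    reconstruction: with zero sensor noise,

        ``H1 * Az / sqrt(Ay^2 + Ax^2) == H1 * tan(theta_AP)`` and
        ``H2 * Ax / sqrt(Ay^2 + Az^2) == H2 * tan(theta_ML)``

    hold at every sample.  For a single-axis tilt this reduces to the
    familiar ``Az = g sin(theta_AP)``, ``Ay = g cos(theta_AP)``.
    Optional zero-mean Gaussian noise of std ``sensor_noise_std`` is added
    per axis.  Returns an (n, 3) array with columns (Ax, Ay, Az).
    """
    theta_ap = np.asarray(theta_ap, dtype=float)
    theta_ml = np.asarray(theta_ml, dtype=float)
    if theta_ap.shape != theta_ml.shape:
        raise ValueError("tilt series must have equal length")
    t = np.tan(theta_ap) ** 2
    u = np.tan(theta_ml) ** 2
    den = 1.0 - t * u
    if np.any(den <= 0):
        raise ValueError("tilt combination too extreme: tan^2(AP)*tan^2(ML) >= 1")
    # gravity unit vector components solving both displacement equations
    gamma2 = config.g**2 / (1.0 + (t * (1.0 + u) + u * (1.0 + t)) / den)
    ay = np.sqrt(gamma2)
    az = np.sign(theta_ap) * np.sqrt(t * gamma2 * (1.0 + u) / den)
    ax = np.sign(theta_ml) * np.sqrt(u * gamma2 * (1.0 + t) / den)
    accel = np.column_stack([ax, ay, az])
    if config.sensor_noise_std > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        accel = accel + rng.normal(0.0, config.sensor_noise_std, accel.shape)
    return accel


def _normalize_counts(
    counts: Mapping[str, int] | Mapping[int, Mapping[str, int]],
    case_ids: Sequence[int],
) -> dict[int, dict[str, int]]:
    first_val = next(iter(counts.values()), 0)
    if isinstance(first_val, Mapping):
        return {int(c): dict(counts.get(c, {})) for c in case_ids}  # type: ignore[call-overload]
    return {int(c): dict(counts) for c in case_ids}  # type: ignore[arg-type]


def generate_dataset(
    config_per_case: Mapping[int, RigConfig],
    counts_per_class_per_case: Mapping[str, int] | Mapping[int, Mapping[str, int]],
    seed: int = 0,
) -> LabeledDataset:
    """Generate a labeled dataset honoring per-class, per-case pattern counts.

    ``counts_per_class_per_case`` is either a single ``{class: count}``
    mapping applied to every case, or a nested ``{case_id: {class: count}}``
    mapping.  Generation is deterministic given ``seed``: each pattern gets
    an independent child seed derived by :class:`numpy.random.SeedSequence`.
    """
    case_ids = sorted(config_per_case)
    counts = _normalize_counts(counts_per_class_per_case, case_ids)
    for case_counts in counts.values():
        for cls_name, cnt in case_counts.items():
            if cls_name not in CLASSES:
                raise ValueError(f"unknown movement class {cls_name!r}")
            if cnt < 0:
                raise ValueError("pattern counts must be non-negative")
    total = sum(
        cnt for case_counts in counts.values() for cnt in case_counts.values()
    )
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(max(total, 1)))
    patterns: list[SwayPattern] = []
    for case_id in case_ids:
        config = config_per_case[case_id]
        for cls_name in CLASSES:
            for _ in range(counts[case_id].get(cls_name, 0)):
                child = next(children)
                tilt_ss, noise_ss = child.spawn(2)
                theta_ap, theta_ml = simulate_tilt_trace(cls_name, config, seed=tilt_ss)
                accel = tilt_to_acceleration(
                    theta_ap, theta_ml, config, rng=np.random.default_rng(noise_ss)
                )
                patterns.append(
                    SwayPattern(
                        label_class=cls_name,
                        label_binary=0 if cls_name in STABLE_CLASSES else 1,
                        case_id=case_id,
                        accel=accel,
                        config=config,
                        theta_ap=theta_ap,
                        theta_ml=theta_ml,
                    )
                )
    return LabeledDataset(patterns)
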