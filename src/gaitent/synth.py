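"""Synthetic insole gait cohorts.

Real insole recordings of the kind this package analyses (8 force-sensitive
resistors, four per foot, sampled at 20 Hz during a 10-15 s walk) are clinical
data and are not redistributable.  This module generates seeded surrogate
cohorts with the statistical structure the analysis pipeline assumes:

* each subject owns a fixed per-sensor stance pressure profile (the "walking
  habit" that detrending is meant to remove), with heel sensors peaking early
  in stance and toe sensors late;
* stance and swing phases alternate, with per-step duration drawn from
  configurable ranges and the left foot half a cycle out of phase;
* fluctuation around the habit profile is correlated (AR(1)) noise plus a
  smooth low-frequency sway component with random per-step phase, emulating
  the postural-sway corrections that distinguish balance-disorder gait;
* the diseased class has a larger fluctuation scale, larger step-to-step
  jitter of that scale, and a much larger sway component; on the heel sensors
  (S0, S4) the class contrast is attenuated, since even an unsteady walker
  loads the heel in a stereotyped way.

Also hosted here is the force/voltage calibration of the FSR voltage-divider
front end, used when recordings are expressed in volts instead of normalized
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SensorProfile",
    "CohortSpec",
    "WalkRecording",
    "generate_cohort",
    "generate_recording",
    "weight_to_voltage",
    "voltage_to_weight",
    "HEEL_SENSORS",
    "SENSOR_NAMES",
    "RIGHT_FOOT",
    "LEFT_FOOT",
]

SENSOR_NAMES = ("S0", "S1", "S2", "S3", "S4", "S5", "S6", "S7")
RIGHT_FOOT = ("S0", "S1", "S2", "S3")
LEFT_FOOT = ("S4", "S5", "S6", "S7")
#: under-the-heel sensors, one per foot; these carry the weakest class signal
HEEL_SENSORS = ("S0", "S4")

# FSR + 1 kOhm divider calibration constants (5 V supply):
#   w = exp((vo + _CAL_OFFSET) / _CAL_SLOPE)
_CAL_OFFSET = 0.2245
_CAL_SLOPE = 0.9265

# Step-to-step fluctuation-scale jitter: per-step scale is
# base * lognormal(0, _BASE_JITTER_SD * multiplier); healthy multiplier is 1.
_BASE_JITTER_SD = 0.25


def voltage_to_weight(vo):
    """Convert divider output voltage (V) to applied weight (N).

    Calibration of the FSR/1 kOhm voltage divider: ``w = exp((vo + 0.2245)/0.9265)``.
    """
    vo = np.asarray(vo, dtype=float)
    w = np.exp((vo + _CAL_OFFSET) / _CAL_SLOPE)
    return w if w.ndim else float(w)


def weight_to_voltage(w):
    """Inverse calibration: weight (N, strictly positive) to voltage (V)."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weight must be > 0 N for the log calibration")
    vo = _CAL_SLOPE * np.log(w) - _CAL_OFFSET
    return vo if vo.ndim else float(vo)


@dataclass(frozen=True)
class SensorProfile:
    """Shape of one sensor's noiseless stance pressure curve.

    The curve is a Gaussian bump in normalized stance time u in [0, 1]:
    ``amplitude * exp(-0.5 ((u - peak_fraction)/width)**2)``.
    """

    amplitude: float = 0.9
    peak_fraction: float = 0.5
    width: float = 0.18


def default_profiles() -> dict[str, SensorProfile]:
    """Heel sensors load early in stance, metatarsals mid, toe late."""
    per_foot = {
        0: SensorProfile(0.95, 0.22, 0.16),  # heel
        1: SensorProfile(0.85, 0.45, 0.20),  # lateral metatarsal
        2: SensorProfile(0.90, 0.58, 0.20),  # medial metatarsal
        3: SensorProfile(0.80, 0.78, 0.16),  # big toe
    }
    out = {}
    for i, name in enumerate(SENSOR_NAMES):
        out[name] = per_foot[i % 4]
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Durations are in seconds, the sample rate in Hz, fluctuation scales in
    normalized pressure units (the noiseless profiles peak near 0.9).
    ``step_jitter_diseased`` multiplies the log-sd of the per-step
    fluctuation-scale distribution for the diseased class;
    ``heel_attenuation`` in [0, 1] shrinks every class difference on the heel
    sensors S0/S4 (0 = no class difference there, 1 = full difference).
    """

    n_healthy: int = 30
    n_diseased: int = 30
    sample_rate: float = 20.0
    walk_duration: float = 12.0
    stance_duration_range: tuple[float, float] = (0.55, 0.75)
    swing_duration_range: tuple[float, float] = (0.35, 0.50)
    trend_shape_params: dict[str, SensorProfile] = field(default_factory=default_profiles)
    fluct_sigma_healthy: float = 0.02
    fluct_sigma_diseased: float = 0.06
    fluct_ar_coeff: float = 0.8
    step_jitter_diseased: float = 2.0
    sway_sigma_healthy: float = 0.005
    sway_sigma_diseased: float = 0.22
    sway_freq_range: tuple[float, float] = (0.6, 1.3)
    heel_attenuation: float = 0.3
    rng_seed: int = 0

    def validate(self) -> None:
        def _positive(name):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"CohortSpec.{name} must be > 0, got {v!r}")

        for name in ("sample_rate", "walk_duration"):
            _positive(name)
        if self.n_healthy < 0 or self.n_diseased < 0:
            raise ValueError("CohortSpec.n_healthy/n_diseased must be >= 0")
        for name in ("stance_duration_range", "swing_duration_range", "sway_freq_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"CohortSpec.{name} must satisfy 0 < low <= high")
        if not (0.0 <= self.heel_attenuation <= 1.0):
            raise ValueError("CohortSpec.heel_attenuation must lie in [0, 1]")
        if self.fluct_sigma_diseased < self.fluct_sigma_healthy:
            raise ValueError(
                "CohortSpec.fluct_sigma_diseased must be >= fluct_sigma_healthy"
            )
        if self.sway_sigma_diseased < self.sway_sigma_healthy:
            raise ValueError(
                "CohortSpec.sway_sigma_diseased must be >= sway_sigma_healthy"
            )
        if not (-1.0 < self.fluct_ar_coeff < 1.0):
            raise ValueError("CohortSpec.fluct_ar_coeff must lie in (-1, 1)")
        if self.step_jitter_diseased < 1.0:
            raise ValueError("CohortSpec.step_jitter_diseased must be >= 1")
        if self.fluct_sigma_healthy < 0 or self.sway_sigma_healthy < 0:
            raise ValueError("CohortSpec fluctuation scales must be >= 0")
        missing = set(SENSOR_NAMES) - set(self.trend_shape_params)
        if missing:
            raise ValueError(f"CohortSpec.trend_shape_params missing sensors {sorted(missing)}")

    def null(self) -> "CohortSpec":
        """A copy with no class effect (equal fluctuation/sway, no extra jitter)."""
        return replace(
            self,
            fluct_sigma_diseased=self.fluct_sigma_healthy,
            sway_sigma_diseased=self.sway_sigma_healthy,
            step_jitter_diseased=1.0,
        )


@dataclass
class WalkRecording:
    """One subject's walk: 8 equal-length force channels at a fixed rate.

    ``channels`` has shape (8, n_samples) ordered S0..S7; S0-S3 are the right
    foot, S4-S7 the left, with S0/S4 under the heel.
    """

    subject_id: str
    label: str  # "healthy" | "diseased"
    sample_rate: float
    channels: np.ndarray
    units: str = "normalized"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.shape[0] != 8 or self.channels.shape[1] < 2:
            raise ValueError("WalkRecording needs 8 channels of length >= 2")
        if self.label not in ("healthy", "diseased"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.units in ("normalized", "newtons") and np.any(self.channels < 0):
            raise ValueError(f"{self.units} channel values must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.channels[SENSOR_NAMES.index(name)]


def _step_timeline(spec: CohortSpec, rng: np.random.Generator, n: int, phase_offset: float):
    """Alternating (start, end) stance intervals in sample indices for one foot."""
    rate = spec.sample_rate
    intervals = []
    t = phase_offset
    while True:
        stance = rng.uniform(*spec.stance_duration_range)
        swing = rng.uniform(*spec.swing_duration_range)
        s = int(round(t * rate))
        e = int(round((t + stance) * rate))
        if s >= n:
            break
        intervals.append((s, min(e, n)))
        t += stance + swing
    return intervals


def _class_params(spec: CohortSpec, label: str, sensor: str):
    """Per-sensor fluctuation scale, sway scale and jitter log-sd for a class."""
    if label == "healthy":
        return spec.fluct_sigma_healthy, spec.sway_sigma_healthy, _BASE_JITTER_SD
    a = spec.heel_attenuation if sensor in HEEL_SENSORS else 1.0
    sigma = spec.fluct_sigma_healthy + a * (spec.fluct_sigma_diseased - spec.fluct_sigma_healthy)
    sway = spec.sway_sigma_healthy + a * (spec.sway_sigma_diseased - spec.sway_sigma_healthy)
    jitter = _BASE_JITTER_SD * (1.0 + a * (spec.step_jitter_diseased - 1.0))
    return sigma, sway, jitter


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = sigma * eps[0]
    innov = sigma * math.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov * eps[t]
    return x


def generate_recording(
    spec: CohortSpec,
    label: str,
    subject_id: str,
    seed_seq: np.random.SeedSequence,
    noise: bool = True,
) -> WalkRecording:
    """Generate one subject's walk; ``noise=False`` emits the bare habit trend."""
    rng = np.random.default_rng(seed_seq)
    n = int(round(spec.walk_duration * spec.sample_rate))
    rate = spec.sample_rate
    cycle = (sum(spec.stance_duration_range) + sum(spec.swing_duration_range)) / 2.0

    foot_intervals = {
        "right": _step_timeline(spec, rng, n, phase_offset=0.05),
        "left": _step_timeline(spec, rng, n, phase_offset=0.05 + cycle / 2.0),
    }

    channels = np.zeros((8, n))
    for ci, sensor in enumerate(SENSOR_NAMES):
        prof = spec.trend_shape_params[sensor]
        # subject-specific habit: fixed jittered copy of the template profile
        amp = prof.amplitude * (1.0 + 0.08 * rng.standard_normal())
        pf = np.clip(prof.peak_fraction + 0.04 * rng.standard_normal(), 0.05, 0.95)
        width = prof.width * (1.0 + 0.10 * rng.standard_normal())
        sigma, sway_amp, jitter_sd = _class_params(spec, label, sensor)

        intervals = foot_intervals["right" if sensor in RIGHT_FOOT else "left"]
        x = np.zeros(n)
        if noise:
            # swing floor: small positive noise so contact detection is non-trivial
            x = np.abs(0.004 * rng.standard_normal(n)) + 0.002
        for (s, e) in intervals:
            L = e - s
            if L < 2:
                continue
            u = np.arange(L) / (L - 1)
            trend = amp * np.exp(-0.5 * ((u - pf) / width) ** 2)
            step = trend
            if noise:
                # per-step fluctuation level: lognormal around the class scale;
                # the jitter applies to the AR noise only — postural sway has
                # its own per-step randomness through phase and frequency
                scale = math.exp(jitter_sd * rng.standard_normal() - 0.5 * jitter_sd**2)
                fluct = _ar1(rng, L, spec.fluct_ar_coeff, sigma * scale)
                f_sway = rng.uniform(*spec.sway_freq_range)
                phase = rng.uniform(0.0, 2.0 * math.pi)
                t_sec = np.arange(L) / rate
                sway = sway_amp * np.sin(2.0 * math.pi * f_sway * t_sec + phase)
                step = trend + fluct + sway
            x[s:e] = np.clip(step, 0.0, None)
        channels[ci] = x

    return WalkRecording(subject_id, label, rate, channels)


def generate_cohort(spec: CohortSpec, noise: bool = True) -> list[WalkRecording]:
    """Generate the full cohort; deterministic given ``spec.rng_seed``."""
    spec.validate()
    root = np.random.SeedSequence(spec.rng_seed)
    children = root.spawn(spec.n_healthy + spec.n_diseased)
    out = []
    for i in range(spec.n_healthy):
        out.append(generate_recording(spec, "healthy", f"H{i:03d}", children[i], noise))
    for j in range(spec.n_diseased):
        out.append(
            generate_recording(
                spec, "diseased", f"D{j:03d}", children[spec.n_healthy + j], noise
            )
        )
    return out
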