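"""Preprocessing of raw insole walks.

Turns an 8-channel force recording into per-sensor lists of stance "steps"
ready for detrending:

1. ground-contact detection per foot (the foot is in the air wherever the
   maximum of its four normalized channels stays below a threshold);
2. framing — the first and last detected step of each foot are dropped, since
   gait initiation and termination lack steady dynamics;
3. per-sensor min-max normalization to [0, 1];
4. 20-fold shape-preserving cubic Hermite (PCHIP) interpolation of each
   stance segment, so downstream histograms have enough samples per bin at
   the native 20 Hz acquisition rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .synth import LEFT_FOOT, RIGHT_FOOT, SENSOR_NAMES, WalkRecording

__all__ = [
    "DegenerateSignalError",
    "NoStepsError",
    "ContactParams",
    "StanceSegmentation",
    "StepSeries",
    "normalize",
    "stance_from_smax",
    "detect_contact",
    "frame_walk",
    "interpolate_steps",
    "preprocess_recording",
]


class DegenerateSignalError(ValueError):
    """A sensor channel is constant and carries no information."""


class NoStepsError(ValueError):
    """Contact detection found no stance interval on some foot."""


@dataclass(frozen=True)
class ContactParams:
    """Ground-contact detection settings.

    ``air_threshold`` is on the normalized [0, 1] scale; samples whose
    per-foot channel maximum falls below it count as foot-in-air.  Contact
    runs shorter than ``min_segment_samples`` are discarded as noise spikes.
    """

    air_threshold: float = 0.05
    min_segment_samples: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.air_threshold < 1.0):
            raise ValueError("air_threshold must lie in (0, 1)")
        if self.min_segment_samples < 1:
            raise ValueError("min_segment_samples must be >= 1")


@dataclass
class StanceSegmentation:
    """Per-foot stance intervals as 0-based half-open [start, end) pairs."""

    right: list[tuple[int, int]] = field(default_factory=list)
    left: list[tuple[int, int]] = field(default_factory=list)

    def foot(self, name: str) -> list[tuple[int, int]]:
        return self.right if name == "right" else self.left


@dataclass
class StepSeries:
    """Interpolated stance steps per sensor.

    ``steps[name]`` is the ordered list of that sensor's stance segments
    after interpolation, each a normalized array of length >= 2.
    """

    steps: dict[str, list[np.ndarray]]
    effective_rate: float

    def n_steps(self, sensor: str) -> int:
        return len(self.steps[sensor])


def normalize(x) -> np.ndarray:
    """Min-max scale a sequence to [0, 1]; raises on constant input."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("normalize requires at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSignalError("constant sequence cannot be normalized")
    return (x - lo) / (hi - lo)


def _contact_runs(above: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len, as [start, end) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
    starts, ends = idx[0::2], idx[1::2]
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def stance_from_smax(smax, params: ContactParams | None = None) -> list[tuple[int, int]]:
    """Stance intervals from an already-normalized per-foot channel maximum.

    A sample is in-air iff smax < air_threshold; qualifying contact runs are
    returned as [start, end) pairs.
    """
    params = params or ContactParams()
    smax = np.asarray(smax, dtype=float)
    if smax.size == 0:
        raise ValueError("empty recording")
    return _contact_runs(smax >= params.air_threshold, params.min_segment_samples)


def detect_contact(recording: WalkRecording, params: ContactParams | None = None) -> StanceSegmentation:
    """Find stance intervals per foot from the normalized channel maxima."""
    params = params or ContactParams()
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    seg = StanceSegmentation()
    for foot, sensors in (("right", RIGHT_FOOT), ("left", LEFT_FOOT)):
        norm = np.vstack([normalize(recording.channel(s)) for s in sensors])
        runs = stance_from_smax(norm.max(axis=0), params)
        if not runs:
            raise NoStepsError(f"no steps detected on {foot} foot")
        seg.foot(foot).extend(runs)
    return seg


def frame_walk(seg: StanceSegmentation) -> StanceSegmentation:
    """Drop the first and last stance interval of each foot."""
    out = StanceSegmentation()
    for foot in ("right", "left"):
        iv = seg.foot(foot)
        if len(iv) < 3:
            raise ValueError(
                f"walk too short to frame: {foot} foot has {len(iv)} stance intervals, need >= 3"
            )
        out.foot(foot).extend(iv[1:-1])
    return out


def _refine(y: np.ndarray, factor: int) -> np.ndarray:
    """PCHIP-interpolate a segment onto a factor-times finer grid.

    Original samples stay on the refined grid exactly (length factor*(L-1)+1).
    """
    L = y.size
    if L < 2:
        raise ValueError("segment too short to interpolate (length < 2)")
    if factor == 1:
        return y.copy()
    x = np.arange(L)
    xi = np.linspace(0.0, L - 1.0, factor * (L - 1) + 1)
    yi = PchipInterpolator(x, y)(xi)
    # guard against sub-eps excursions outside the local data range
    return np.clip(yi, y.min(), y.max())


def interpolate_steps(
    recording: WalkRecording,
    seg: StanceSegmentation,
    factor: int = 20,
    renormalize: bool = True,
) -> StepSeries:
    """Cut framed stance segments per sensor and refine them ``factor``-fold.

    With ``renormalize`` (default) each channel is min-max rescaled over the
    samples inside its foot's framed stance intervals before interpolation,
    so the retained walk spans the full [0, 1] range per sensor.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    steps: dict[str, list[np.ndarray]] = {}
    for foot, sensors in (("right", RIGHT_FOOT), ("left", LEFT_FOOT)):
        intervals = seg.foot(foot)
        for name in sensors:
            ch = recording.channel(name)
            if renormalize:
                stance_samples = np.concatenate([ch[s:e] for s, e in intervals])
                lo, hi = stance_samples.min(), stance_samples.max()
                if hi == lo:
                    raise DegenerateSignalError(f"sensor {name} constant over stance")
                ch = np.clip((ch - lo) / (hi - lo), 0.0, 1.0)
            steps[name] = [_refine(ch[s:e], factor) for s, e in intervals]
    return StepSeries(steps=steps, effective_rate=factor * recording.sample_rate)


def preprocess_recording(
    recording: WalkRecording,
    params: ContactParams | None = None,
    factor: int = 20,
) -> StepSeries:
    """Full preprocessing chain: contact detection, framing, interpolation."""
    seg = detect_contact(recording, params)
    return interpolate_steps(recording, frame_walk(seg), factor=factor)
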