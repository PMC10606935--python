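"""Stepwise detrending of stance pressure steps.

A subject's habitual pressure waveform (their "trend") is estimated
step-by-step: the previous step's trend curve is time-scaled to the current
step's length with nearest-neighbour interpolation, then blended with the
current step data,

    T_i = alpha * F_i + (1 - alpha) * Tcheck_{i-1},        T_1 = F_1,

where alpha in [0, alpha_max] measures how far the trend may move toward the
current step.  alpha is chosen as the smallest value for which the mean
absolute deviation eps = mean|T_i - F_i| drops below a threshold; because
eps(alpha) = (1 - alpha) * mean|Tcheck - F| is linear in alpha, the optimum
has the closed form alpha* = min(alpha_max, 1 - threshold / eps0).  The cap
alpha_max (default 0.23) keeps the trend from absorbing the very fluctuation
the residuals are supposed to expose.

Least-squares polynomial trends of degree 2-4 are provided as baselines for
comparison with the adaptive scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import StepSeries

__all__ = [
    "TrendParams",
    "StepTrendResult",
    "scale_trend",
    "fit_step_trend",
    "detrend_walk",
    "detrend_polynomial",
]


@dataclass(frozen=True)
class TrendParams:
    """alpha cap and convergence threshold of the stepwise trend update."""

    alpha_max: float = 0.23
    epsilon_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_max <= 1.0):
            raise ValueError("alpha_max must lie in (0, 1]")
        if not self.epsilon_threshold > 0:
            raise ValueError("epsilon_threshold must be > 0")


@dataclass
class StepTrendResult:
    """Per-sensor trends and residuals for one subject's walk.

    For every sensor, parallel lists over steps: the original step data F,
    the fitted trend T, the residual F - T, the adopted alpha and achieved
    eps = mean|T - F|.  The first step's residual is identically zero by
    construction (T_1 = F_1).
    """

    steps: dict[str, list[np.ndarray]]
    trend: dict[str, list[np.ndarray]] = field(default_factory=dict)
    residual: dict[str, list[np.ndarray]] = field(default_factory=dict)
    alpha: dict[str, list[float]] = field(default_factory=dict)
    epsilon: dict[str, list[float]] = field(default_factory=dict)
    method: str = "stepwise"

    @property
    def sensors(self) -> list[str]:
        return list(self.steps)


def scale_trend(prev_trend, new_length: int) -> np.ndarray:
    """Nearest-neighbour resample of a trend curve to a new length.

    Output index j maps to input index round_half_up(j * (Lp-1)/(Lc-1));
    a target length of 1 takes the first element.
    """
    prev = np.asarray(prev_trend, dtype=float)
    if prev.size == 0:
        raise ValueError("cannot scale an empty trend")
    if new_length < 1:
        raise ValueError("new_length must be >= 1")
    if new_length == 1:
        return prev[:1].copy()
    j = np.arange(new_length)
    pos = j * (prev.size - 1) / (new_length - 1)
    idx = np.floor(pos + 0.5).astype(int)  # round half-up
    return prev[np.minimum(idx, prev.size - 1)]


def fit_step_trend(F, prev_trend_scaled, params: TrendParams | None = None):
    """Blend the scaled previous trend toward the current step data.

    Returns ``(T, alpha, epsilon)`` with the smallest alpha in
    [0, alpha_max] achieving mean|T - F| <= epsilon_threshold, or
    alpha = alpha_max if no alpha in range does.
    """
    params = params or TrendParams()
    F = np.asarray(F, dtype=float)
    That = np.asarray(prev_trend_scaled, dtype=float)
    if F.shape != That.shape:
        raise ValueError(f"length mismatch: step {F.shape} vs scaled trend {That.shape}")
    eps0 = float(np.mean(np.abs(That - F)))
    if eps0 <= params.epsilon_threshold:
        alpha = 0.0
    else:
        alpha = min(params.alpha_max, 1.0 - params.epsilon_threshold / eps0)
    T = alpha * F + (1.0 - alpha) * That
    return T, alpha, (1.0 - alpha) * eps0


def detrend_walk(steps: StepSeries, params: TrendParams | None = None) -> StepTrendResult:
    """Chain the stepwise trend update over every sensor's steps."""
    params = params or TrendParams()
    res = StepTrendResult(steps=steps.steps, method="stepwise")
    for sensor, seq in steps.steps.items():
        if not seq:
            raise ValueError(f"sensor {sensor} has no steps")
        trends, resids, alphas, epss = [], [], [], []
        for i, F in enumerate(seq):
            if i == 0:
                T, a, e = np.asarray(F, dtype=float).copy(), 0.0, 0.0
            else:
                That = scale_trend(trends[-1], len(F))
                T, a, e = fit_step_trend(F, That, params)
            trends.append(T)
            resids.append(np.asarray(F, dtype=float) - T)
            alphas.append(a)
            epss.append(e)
        res.trend[sensor] = trends
        res.residual[sensor] = resids
        res.alpha[sensor] = alphas
        res.epsilon[sensor] = epss
    return res


def detrend_polynomial(steps: StepSeries, degree: int) -> StepTrendResult:
    """Baseline: per-step least-squares polynomial trend over normalized time."""
    if degree not in (2, 3, 4):
        raise ValueError("degree must be 2, 3 or 4")
    res = StepTrendResult(steps=steps.steps, method=f"poly{degree}")
    for sensor, seq in steps.steps.items():
        trends, resids, alphas, epss = [], [], [], []
        for F in seq:
            F = np.asarray(F, dtype=float)
            if F.size <= degree:
                raise ValueError(
                    f"step of length {F.size} too short for degree-{degree} fit"
                )
            t = np.linspace(0.0, 1.0, F.size)
            coef = np.polynomial.polynomial.polyfit(t, F, degree)
            T = np.polynomial.polynomial.polyval(t, coef)
            trends.append(T)
            resids.append(F - T)
            alphas.append(float("nan"))
            epss.append(float(np.mean(np.abs(T - F))))
        res.trend[sensor] = trends
        res.residual[sensor] = resids
        res.alpha[sensor] = alphas
        res.epsilon[sensor] = epss
    return res
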