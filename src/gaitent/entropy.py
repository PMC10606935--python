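"""Tsallis-entropy features of detrended gait residuals.

The Tsallis entropy of a discrete distribution {p_i, i=1..N},

    TE_q = (1 - sum_i p_i^q) / (q - 1),          TE_1 = -sum_i p_i ln p_i,

generalizes Shannon entropy to nonadditive systems: for independent X, Y,
TE(X+Y) = TE(X) + TE(Y) + (1-q) TE(X) TE(Y), so (1-q) measures the deviation
from additivity.  Human gait fluctuations are long-range correlated, which
motivates a sub-unity entropic index; q = 0.82 is the default here.

Distributions come from histograms of the absolute detrended residuals,
restricted to intervals where the sensor itself is actively loaded.  Two
features are computed per sensor:

* the entire-gait TE — entropy of all active residual samples pooled over
  steps (first step excluded: its residual is structurally zero);
* sigma_E' — the deviation from zero of the step-to-step entropy change,
  computed as the population standard deviation of the change series
  expanded by its negatives (equivalently its RMS).

With eight sensors this yields the 16-element feature row used for
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detrend import StepTrendResult
from .synth import SENSOR_NAMES

__all__ = [
    "EntropyParams",
    "HistogramPMF",
    "EntropyFeatures",
    "tsallis_entropy",
    "tsallis_additivity_gap",
    "build_histogram",
    "effective_bins",
    "mask_inactive",
    "sigma_e_prime",
    "sigma_e_prime_expanded",
    "extract_features",
    "feature_table",
    "q_sweep",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [f"{s}_te" for s in SENSOR_NAMES] + [f"{s}_sigma" for s in SENSOR_NAMES]


@dataclass(frozen=True)
class EntropyParams:
    """Entropic index, histogram bin cap and activity threshold.

    A sensor sample is "active" when its normalized value is at least
    ``activity_threshold``; inactive samples are dropped before histogramming
    (shared by default with the contact-detection air threshold).
    """

    q: float = 0.82
    n_bins: int = 25
    activity_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (2 <= self.n_bins <= 25):
            raise ValueError("n_bins must lie in [2, 25]")
        if not (0.0 <= self.activity_threshold < 1.0):
            raise ValueError("activity_threshold must lie in [0, 1)")


@dataclass
class HistogramPMF:
    """Probability mass function from an equal-width histogram."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_edges.size != self.probabilities.size + 1:
            raise ValueError("need n_bins + 1 edges")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        if np.any(self.probabilities < 0) or abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be >= 0 and sum to 1")


def _as_probs(pmf) -> np.ndarray:
    p = pmf.probabilities if isinstance(pmf, HistogramPMF) else np.asarray(pmf, dtype=float)
    if p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("invalid probability vector")
    return p


def tsallis_entropy(pmf, q: float) -> float:
    """TE_q of a pmf (HistogramPMF or probability array); q = 1 gives Shannon."""
    p = _as_probs(pmf)
    p = p[p > 0]  # zero-probability states contribute nothing
    if q == 1.0:
        return float(-np.sum(p * np.log(p)))
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


def tsallis_additivity_gap(pmf_x, pmf_y, q: float) -> tuple[float, float]:
    """Both sides of the pseudo-additivity identity for independent systems.

    Returns ``(TE(X x Y), TE(X) + TE(Y) + (1-q) TE(X) TE(Y))``; the two agree
    exactly (used as a numerical oracle).
    """
    px, py = _as_probs(pmf_x), _as_probs(pmf_y)
    joint = np.outer(px, py).ravel()
    lhs = tsallis_entropy(joint / joint.sum(), q)
    tex, tey = tsallis_entropy(px, q), tsallis_entropy(py, q)
    return lhs, tex + tey + (1.0 - q) * tex * tey


def build_histogram(residuals, n_bins: int) -> HistogramPMF:
    """Equal-width histogram pmf of absolute residuals over [0, max]."""
    x = np.asarray(residuals, dtype=float)
    if x.size == 0:
        raise ValueError("cannot histogram an empty sample")
    if np.any(x < 0):
        raise ValueError("residuals must be absolute-valued")
    m = x.max()
    if m == 0.0:
        return HistogramPMF(np.array([0.0, 1e-12]), np.array([1.0]), x.size)
    counts, edges = np.histogram(x, bins=n_bins, range=(0.0, m))
    return HistogramPMF(edges, counts / x.size, x.size)


def effective_bins(n_samples: int, n_bins: int = 25) -> int:
    """Bin count: the cap unless the sample is small (aim >= 4 samples/bin)."""
    if n_samples >= 4 * n_bins:
        return n_bins
    return max(2, n_samples // 4)


def mask_inactive(residuals, step_values, activity_threshold: float) -> np.ndarray:
    """Keep residual samples where the sensor itself is actively loaded."""
    r = np.asarray(residuals, dtype=float)
    v = np.asarray(step_values, dtype=float)
    if r.shape != v.shape:
        raise ValueError("residuals and step values must be aligned")
    return r[v >= activity_threshold]


def sigma_e_prime(E) -> float:
    """Deviation-from-zero of a value set: RMS of E.

    Identical to :func:`sigma_e_prime_expanded`, which follows the literal
    expanded-set construction; the RMS form is the algebraic shortcut.
    """
    E = np.asarray(E, dtype=float)
    if E.size == 0:
        raise ValueError("empty entropy-change series")
    return float(np.sqrt(np.mean(E**2)))


def sigma_e_prime_expanded(E) -> float:
    """Population std of E expanded by its negatives (mean exactly zero)."""
    E = np.asarray(E, dtype=float)
    if E.size == 0:
        raise ValueError("empty entropy-change series")
    expanded = np.concatenate([E, -E])
    return float(np.sqrt(np.mean((expanded - expanded.mean()) ** 2)))


@dataclass
class EntropyFeatures:
    """The 16-feature row of one subject: per-sensor entire-gait TE and sigma_E'."""

    te_entire_gait: dict[str, float]
    sigma_stepwise: dict[str, float]
    stepwise_max: dict[str, float]
    missing: set[str]
    label: str | None = None
    subject_id: str | None = None

    def row(self) -> np.ndarray:
        """Fixed order: [S0_te..S7_te, S0_sigma..S7_sigma]; missing -> NaN."""
        te = [self.te_entire_gait.get(s, float("nan")) for s in SENSOR_NAMES]
        sg = [self.sigma_stepwise.get(s, float("nan")) for s in SENSOR_NAMES]
        return np.array(te + sg, dtype=float)


def _step_entropies(
    residuals: list[np.ndarray],
    values: list[np.ndarray],
    params: EntropyParams,
    skip_first: bool,
    bin_mode: str,
) -> tuple[list[float], list[np.ndarray]]:
    """Per-step TE values and the masked absolute residuals that fed them.

    ``bin_mode="per-step"`` bins each step over its own [0, max] (per-step TE
    is then invariant to step amplitude); ``"shared"`` uses common edges over
    the walk-wide residual range, making per-step TE amplitude-sensitive.
    """
    start = 1 if skip_first else 0
    masked_all = [
        np.abs(mask_inactive(r, v, params.activity_threshold))
        for r, v in zip(residuals[start:], values[start:])
    ]
    masked_all = [m for m in masked_all if m.size]
    if not masked_all:
        return [], []
    shared_max = max(m.max() for m in masked_all)
    es = []
    for masked in masked_all:
        n_bins = effective_bins(masked.size, params.n_bins)
        if bin_mode == "shared" and shared_max > 0:
            edges = np.linspace(0.0, shared_max, n_bins + 1)
            counts, _ = np.histogram(masked, bins=edges)
            pmf = HistogramPMF(edges, counts / masked.size, masked.size)
        else:
            pmf = build_histogram(masked, n_bins)
        es.append(tsallis_entropy(pmf, params.q))
    return es, masked_all


def extract_features(
    trend_result: StepTrendResult,
    params: EntropyParams | None = None,
    stepwise_mode: str = "diff",
    bin_mode: str = "per-step",
    exclude_first_step: bool = True,
) -> EntropyFeatures:
    """Assemble the 16-feature row from a subject's detrended walk.

    ``stepwise_mode="diff"`` (default) applies the sigma_E' statistic to the
    step-to-step *changes* of TE — the quantity that is ideally zero for a
    steady walker; ``"raw"`` applies it to the per-step TE values themselves.
    ``bin_mode`` selects per-step ("per-step", default) or walk-shared
    ("shared") histogram edges for the stepwise entropies.
    """
    params = params or EntropyParams()
    if stepwise_mode not in ("diff", "raw"):
        raise ValueError("stepwise_mode must be 'diff' or 'raw'")
    if bin_mode not in ("per-step", "shared"):
        raise ValueError("bin_mode must be 'per-step' or 'shared'")
    te, sigma, swmax, missing = {}, {}, {}, set()
    for sensor in trend_result.sensors:
        resid = trend_result.residual[sensor]
        vals = trend_result.steps[sensor]
        if len(resid) < 3:
            raise ValueError(f"sensor {sensor}: need >= 3 steps, got {len(resid)}")
        es, masked_all = _step_entropies(resid, vals, params, exclude_first_step, bin_mode)
        if not masked_all:
            missing.add(sensor)
            continue
        pooled = np.concatenate(masked_all)
        pmf = build_histogram(pooled, effective_bins(pooled.size, params.n_bins))
        te[sensor] = tsallis_entropy(pmf, params.q)
        diffs = np.diff(es)
        if stepwise_mode == "diff":
            if diffs.size == 0:
                missing.add(sensor)
                continue
            sigma[sensor] = sigma_e_prime(diffs)
        else:
            sigma[sensor] = sigma_e_prime(es)
        swmax[sensor] = float(np.max(np.abs(diffs))) if diffs.size else float("nan")
    return EntropyFeatures(te, sigma, swmax, missing)


def feature_table(subjects, params: EntropyParams | None = None, **kwargs) -> pd.DataFrame:
    """Feature rows for many subjects.

    ``subjects`` yields ``(subject_id, label, StepTrendResult)`` triples;
    returns a DataFrame with subject_id index, label column and the 16
    feature columns in fixed order.
    """
    rows, ids, labels = [], [], []
    for subject_id, label, trend_result in subjects:
        feats = extract_features(trend_result, params, **kwargs)
        rows.append(feats.row())
        ids.append(subject_id)
        labels.append(label)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS, index=pd.Index(ids, name="subject_id"))
    df.insert(0, "label", labels)
    return df


def q_sweep(subjects, q_grid, eval_config=None, params: EntropyParams | None = None) -> tuple[float, pd.DataFrame]:
    """Cross-validated accuracy of the classifier suite as a function of q.

    Recomputes the feature table and the suite's best CV accuracy at each q
    in ``q_grid``; returns ``(best_q, table)`` with columns q/best_accuracy/
    best_classifier.
    """
    from .classify import EvalConfig, train_evaluate

    subjects = list(subjects)
    q_grid = list(q_grid)
    if not q_grid:
        raise ValueError("q_grid must be non-empty")
    base = params or EntropyParams()
    eval_config = eval_config or EvalConfig()
    rows = []
    for q in q_grid:
        p = EntropyParams(q=q, n_bins=base.n_bins, activity_threshold=base.activity_threshold)
        df = feature_table(subjects, p)
        report = train_evaluate(df, eval_config)
        name, acc = report.best()
        rows.append({"q": q, "best_accuracy": acc, "best_classifier": name})
    table = pd.DataFrame(rows)
    best_q = float(table.loc[table["best_accuracy"].idxmax(), "q"])
    return best_q, table
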