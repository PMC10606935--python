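"""Model/Results interface over the gait-entropy pipeline.

`GaitEntropyModel` holds a cohort's 16-feature table (built directly or via
`from_recordings`, which runs contact detection, framing, interpolation,
stepwise detrending and Tsallis-entropy feature extraction per subject);
`fit()` cross-validates the classifier suite and returns a
`GaitEntropyResults` with per-classifier metrics, confusion matrices, ROC
curves and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import EvalConfig, EvaluationReport, train_evaluate
from .detrend import StepTrendResult, TrendParams, detrend_polynomial, detrend_walk
from .entropy import EntropyParams, FEATURE_COLUMNS, feature_table
from .preprocess import ContactParams, preprocess_recording
from .synth import HEEL_SENSORS, SENSOR_NAMES, WalkRecording

__all__ = ["GaitEntropyModel", "GaitEntropyResults", "pipeline_features"]


def detrend_recording(
    recording: WalkRecording,
    contact_params: ContactParams | None = None,
    trend_params: TrendParams | None = None,
    method: str = "stepwise",
    factor: int = 20,
) -> StepTrendResult:
    """Preprocess one recording and detrend it with the chosen method."""
    steps = preprocess_recording(recording, contact_params, factor=factor)
    if method == "stepwise":
        return detrend_walk(steps, trend_params)
    if method in ("poly2", "poly3", "poly4"):
        return detrend_polynomial(steps, int(method[-1]))
    raise ValueError(f"unknown detrending method {method!r}")


def pipeline_features(
    recordings,
    contact_params: ContactParams | None = None,
    trend_params: TrendParams | None = None,
    entropy_params: EntropyParams | None = None,
    method: str = "stepwise",
    **feature_kwargs,
) -> pd.DataFrame:
    """Full pipeline over a cohort: recordings -> 16-feature table."""
    triples = (
        (
            rec.subject_id,
            rec.label,
            detrend_recording(rec, contact_params, trend_params, method),
        )
        for rec in recordings
    )
    return feature_table(triples, entropy_params, **feature_kwargs)


class GaitEntropyModel:
    """Healthy-vs-diseased gait classification model on entropy features.

    Parameters
    ----------
    features : DataFrame with a ``label`` column and the 16 feature columns
        (``S0_te``..``S7_te``, ``S0_sigma``..``S7_sigma``).
    """

    def __init__(self, features: pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS + ["label"] if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        self.features = features
        self._detrended: list[tuple[str, str, StepTrendResult]] | None = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_recordings(
        cls,
        recordings,
        contact_params: ContactParams | None = None,
        trend_params: TrendParams | None = None,
        entropy_params: EntropyParams | None = None,
        method: str = "stepwise",
        **feature_kwargs,
    ) -> "GaitEntropyModel":
        """Run the full per-subject pipeline and build the model."""
        recordings = list(recordings)
        detrended = [
            (
                rec.subject_id,
                rec.label,
                detrend_recording(rec, contact_params, trend_params, method),
            )
            for rec in recordings
        ]
        model = cls(feature_table(detrended, entropy_params, **feature_kwargs))
        model._detrended = detrended
        return model

    @classmethod
    def from_feature_table(cls, df: pd.DataFrame, label_column: str = "label") -> "GaitEntropyModel":
        df = df.rename(columns={label_column: "label"})
        return cls(df)

    # -- analysis ---------------------------------------------------------
    def fit(self, config: EvalConfig | None = None) -> "GaitEntropyResults":
        """Cross-validate the classifier suite on the feature table."""
        config = config or EvalConfig()
        return GaitEntropyResults(self, train_evaluate(self.features, config), config)

    def q_sweep(self, q_grid, eval_config: EvalConfig | None = None, params: EntropyParams | None = None):
        """Re-extract features over a grid of entropic indices (needs recordings)."""
        from .entropy import q_sweep as _q_sweep

        if self._detrended is None:
            raise ValueError("q_sweep requires a model built with from_recordings")
        return _q_sweep(self._detrended, q_grid, eval_config, params)

    def class_contrast(self) -> pd.DataFrame:
        """Diseased-minus-healthy mean of each feature, with a heel flag."""
        g = self.features.groupby("label")[FEATURE_COLUMNS].mean()
        diff = (g.loc["diseased"] - g.loc["healthy"]).rename("diseased_minus_healthy")
        out = diff.to_frame()
        out["heel_sensor"] = [c.split("_")[0] in HEEL_SENSORS for c in out.index]
        return out

    def plot_te_boxplot(self, ax=None):
        """Box plot of entire-gait TE per sensor, split by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        data, ticks = [], []
        for s in SENSOR_NAMES:
            for label in ("healthy", "diseased"):
                vals = self.features.loc[self.features["label"] == label, f"{s}_te"]
                data.append(vals.dropna().to_numpy())
                ticks.append(f"{s}\n{label[0].upper()}")
        ax.boxplot(data, tick_labels=ticks)
        ax.set_ylabel("entire-gait TE")
        return ax


@dataclass
class GaitEntropyResults:
    """Cross-validated evaluation of the classifier suite."""

    model: GaitEntropyModel
    report: EvaluationReport
    config: EvalConfig

    @property
    def best_classifier(self) -> str:
        return self.report.best()[0]

    @property
    def best_accuracy(self) -> float:
        return self.report.best()[1]

    def summary(self) -> str:
        """Plain-text table of the suite's cross-validated metrics."""
        df = self.report.to_frame()
        n = len(self.model.features)
        n_dis = int((self.model.features["label"] == "diseased").sum())
        lines = [
            "Gait entropy classification results",
            "=" * 74,
            f"subjects: {n} ({n - n_dis} healthy / {n_dis} diseased)   "
            f"scheme: {self.config.scheme} (k={self.config.k}, seed={self.config.rng_seed})",
            "-" * 74,
            df.to_string(index=False, float_format=lambda v: f"{v:7.3f}"),
            "-" * 74,
            f"best: {self.best_classifier}  mean CV accuracy {100 * self.best_accuracy:.1f}%",
        ]
        return "\n".join(lines)

    def plot_roc(self, names=None, ax=None):
        """ROC curves of the requested (default: all) classifiers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for name in names or self.report.per_classifier:
            rep = self.report.per_classifier[name]
            if rep.roc is None:
                continue
            fpr, tpr, _, auc = rep.roc
            ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.2f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=8)
        return ax

    def __str__(self) -> str:
        return self.summary()
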