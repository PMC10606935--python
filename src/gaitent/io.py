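"""CSV dialects for cohorts, step archives, residual archives and features.

All artefacts are plain CSV so intermediate pipeline stages can be inspected
and re-entered:

* cohort: one file per subject with columns ``t,S0..S7`` plus a manifest
  ``manifest.csv`` (subject_id, label, seed, file);
* step archive: ``sensor,step_index,sample_index,value`` per subject;
* residual archive: ``sensor,step_index,sample_index,value,trend,residual``;
* feature table: ``subject_id,label,S0_te..S7_te,S0_sigma..S7_sigma``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detrend import StepTrendResult
from .preprocess import StepSeries
from .synth import SENSOR_NAMES, WalkRecording

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_step_archive",
    "read_step_archive",
    "write_residual_archive",
    "read_residual_archive",
    "write_feature_table",
    "read_feature_table",
]


def write_cohort(recordings, out_dir, seed: int | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        df = pd.DataFrame(rec.channels.T, columns=list(SENSOR_NAMES))
        df.insert(0, "t", rec.time)
        df.to_csv(out / fname, index=False)
        rows.append(
            {"subject_id": rec.subject_id, "label": rec.label, "seed": seed, "file": fname}
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(in_dir) -> list[WalkRecording]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    recs = []
    for row in manifest.itertuples():
        df = pd.read_csv(in_dir / row.file)
        t = df["t"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 20.0
        channels = df[list(SENSOR_NAMES)].to_numpy().T
        recs.append(WalkRecording(str(row.subject_id), row.label, rate, channels))
    return recs


def write_step_archive(steps: StepSeries, path) -> Path:
    rows = []
    for sensor, seq in steps.steps.items():
        for k, step in enumerate(seq):
            for j, v in enumerate(step):
                rows.append((sensor, k, j, v))
    df = pd.DataFrame(rows, columns=["sensor", "step_index", "sample_index", "value"])
    df.to_csv(path, index=False)
    return Path(path)


def read_step_archive(path, effective_rate: float = 400.0) -> StepSeries:
    df = pd.read_csv(path)
    steps: dict[str, list[np.ndarray]] = {}
    for sensor, g in df.groupby("sensor", sort=False):
        steps[sensor] = [
            gg.sort_values("sample_index")["value"].to_numpy()
            for _, gg in g.groupby("step_index", sort=True)
        ]
    return StepSeries(steps=steps, effective_rate=effective_rate)


def write_residual_archive(result: StepTrendResult, path) -> Path:
    rows = []
    for sensor in result.sensors:
        for k, (F, T, R) in enumerate(
            zip(result.steps[sensor], result.trend[sensor], result.residual[sensor])
        ):
            for j in range(len(F)):
                rows.append((sensor, k, j, F[j], T[j], R[j]))
    df = pd.DataFrame(
        rows, columns=["sensor", "step_index", "sample_index", "value", "trend", "residual"]
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_residual_archive(path, method: str = "stepwise") -> StepTrendResult:
    df = pd.read_csv(path)
    res = StepTrendResult(steps={}, method=method)
    for sensor, g in df.groupby("sensor", sort=False):
        F, T, R = [], [], []
        for _, gg in g.groupby("step_index", sort=True):
            gg = gg.sort_values("sample_index")
            F.append(gg["value"].to_numpy())
            T.append(gg["trend"].to_numpy())
            R.append(gg["residual"].to_numpy())
        res.steps[sensor] = F
        res.trend[sensor] = T
        res.residual[sensor] = R
        res.alpha[sensor] = [float("nan")] * len(F)
        res.epsilon[sensor] = [float(np.mean(np.abs(r))) for r in R]
    return res


def write_feature_table(df: pd.DataFrame, path) -> Path:
    df.to_csv(path, index=True)
    return Path(path)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")
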