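"""Reading and writing trial datasets.

Canonical on-disk form: ``minutes.csv`` with one row per participant-minute
(columns ``participant_id, timestamp, steps, heart_rate, intensity``;
timestamps ISO 8601 at minute resolution; empty fields mark non-wear),
plus JSON sidecars ``prompts.json`` and ``ground_truth.json``.

A Fitabase-style minute-export dialect is also readable: per-signal files
with columns ``Id``, ``ActivityMinute`` (``M/D/YYYY h:mm:ss AM/PM``) and
``Steps`` or ``Value`` (heart rate), merged on Id + timestamp.
"""
from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import MINUTES_PER_DAY, SimulationConfig
from .core import MinuteSeries, PromptEvent, TrialData, classify_intensity

CANONICAL_COLUMNS = ["participant_id", "timestamp", "steps", "heart_rate", "intensity"]

_HHMM = [f"{m // 60:02d}:{m % 60:02d}" for m in range(MINUTES_PER_DAY)]


def trial_to_frame(trial: TrialData) -> pd.DataFrame:
    """Long-form minute table in canonical column order, deterministically
    sorted by participant then timestamp."""
    parts = []
    for ms in trial.days():
        ts = [f"{ms.date.isoformat()}T{h}" for h in _HHMM]
        parts.append(pd.DataFrame({
            "participant_id": ms.participant_id,
            "timestamp": ts,
            "steps": pd.array(np.where(np.isnan(ms.steps), None, ms.steps),
                              dtype="Int64"),
            "heart_rate": pd.array(np.where(np.isnan(ms.heart_rate), None,
                                            ms.heart_rate), dtype="Int64"),
            "intensity": [v if v is not None else "" for v in ms.intensity],
        }))
    if not parts:
        return pd.DataFrame(columns=CANONICAL_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def write_canonical_csv(trial: TrialData, out_dir: Union[str, Path]) -> Path:
    """Write ``minutes.csv`` plus prompt-log and ground-truth sidecars.

    Returns the dataset directory.  Output is byte-stable for a fixed
    dataset, so equal seeds round-trip to identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial_to_frame(trial).to_csv(out / "minutes.csv", index=False)
    prompts = [{"participant_id": e.participant_id, "date": e.date.isoformat(),
                "delivery_minute": e.delivery_minute} for e in sorted(
                    trial.prompts, key=lambda e: (e.participant_id, e.date))]
    (out / "prompts.json").write_text(json.dumps(prompts, indent=1) + "\n")
    sidecar = {"ground_truth": trial.ground_truth,
               "config": json.loads(trial.config.model_dump_json())
               if trial.config else None}
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1) + "\n")
    return out


def _frame_to_trial(df: pd.DataFrame) -> dict:
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"minutes table is missing required columns: {missing}")
    ts = pd.to_datetime(df["timestamp"], format="%Y-%m-%dT%H:%M", errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header and 1-basing
        raise ValueError(f"malformed timestamp on line(s) {lines}"
                         + (" ..." if bad.size > 10 else ""))
    df = df.assign(_date=ts.dt.date, _minute=ts.dt.hour * 60 + ts.dt.minute)
    series = {}
    for (pid, date), grp in df.groupby(["participant_id", "_date"], sort=True):
        if len(grp) != MINUTES_PER_DAY:
            raise ValueError(
                f"{pid} {date}: expected {MINUTES_PER_DAY} rows, got {len(grp)}")
        grp = grp.sort_values("_minute")
        steps = grp["steps"].to_numpy(dtype=float, na_value=np.nan)
        hr = grp["heart_rate"].to_numpy(dtype=float, na_value=np.nan)
        inten = np.empty(MINUTES_PER_DAY, dtype=object)
        inten[:] = [v if isinstance(v, str) and v else None
                    for v in grp["intensity"]]
        series[(str(pid), date)] = MinuteSeries(str(pid), date, steps, hr, inten)
    return series


def read_canonical_csv(dataset_dir: Union[str, Path]) -> TrialData:
    """Read a dataset written by :func:`write_canonical_csv` (lossless)."""
    root = Path(dataset_dir)
    path = root / "minutes.csv"
    if not path.exists():
        raise FileNotFoundError(f"no minutes.csv in {root}")
    df = pd.read_csv(path, dtype={"participant_id": str, "intensity": str},
                     keep_default_na=True)
    if "intensity" in df.columns:
        df["intensity"] = df["intensity"].fillna("")
    series = _frame_to_trial(df)

    prompts, ground_truth, config = [], {}, None
    pfile = root / "prompts.json"
    if pfile.exists():
        prompts = [PromptEvent(p["participant_id"],
                               dt.date.fromisoformat(p["date"]),
                               int(p["delivery_minute"]))
                   for p in json.loads(pfile.read_text())]
    gfile = root / "ground_truth.json"
    if gfile.exists():
        sidecar = json.loads(gfile.read_text())
        ground_truth = sidecar.get("ground_truth", {})
        if sidecar.get("config"):
            config = SimulationConfig.model_validate(sidecar["config"])
    return TrialData(series=series, prompts=prompts,
                     ground_truth=ground_truth, config=config)


def read_fitabase(steps_csv: Union[str, Path],
                  hr_csv: Optional[Union[str, Path]] = None,
                  cfg: Optional[SimulationConfig] = None) -> TrialData:
    """Read Fitabase-style minute exports.

    ``steps_csv`` needs columns ``Id``, ``ActivityMinute`` and ``Steps``;
    the optional ``hr_csv`` needs ``Id``, a timestamp column
    (``ActivityMinute`` or ``Time``) and ``Value``.  Minutes absent from the
    step file are treated as non-wear; days are padded to 1440 minutes.
    Intensity is derived from steps and heart rate with the configured
    cut-offs.
    """
    cfg = cfg or SimulationConfig()

    def _load(path, value_col_candidates):
        df = pd.read_csv(path, dtype={"Id": str})
        if "Id" not in df.columns:
            raise ValueError(f"{path}: missing required column Id")
        ts_col = next((c for c in ("ActivityMinute", "Time") if c in df.columns), None)
        if ts_col is None:
            raise ValueError(f"{path}: missing timestamp column ActivityMinute/Time")
        val_col = next((c for c in value_col_candidates if c in df.columns), None)
        if val_col is None:
            raise ValueError(f"{path}: missing value column {value_col_candidates}")
        ts = pd.to_datetime(df[ts_col], format="%m/%d/%Y %I:%M:%S %p", errors="coerce")
        bad = np.flatnonzero(ts.isna().to_numpy())
        if bad.size:
            raise ValueError(f"{path}: malformed timestamp on line "
                             f"{int(bad[0]) + 2}")
        return pd.DataFrame({"Id": df["Id"], "date": ts.dt.date,
                             "minute": ts.dt.hour * 60 + ts.dt.minute,
                             "value": pd.to_numeric(df[val_col])})

    sdf = _load(steps_csv, ("Steps",))
    hdf = _load(hr_csv, ("Value",)) if hr_csv is not None else None

    series = {}
    for (pid, date), grp in sdf.groupby(["Id", "date"], sort=True):
        steps = np.full(MINUTES_PER_DAY, np.nan)
        steps[grp["minute"].to_numpy()] = grp["value"].to_numpy(dtype=float)
        hr = np.full(MINUTES_PER_DAY, np.nan)
        if hdf is not None:
            sub = hdf[(hdf["Id"] == pid) & (hdf["date"] == date)]
            hr[sub["minute"].to_numpy()] = sub["value"].to_numpy(dtype=float)
        hr[np.isnan(steps)] = np.nan  # non-wear dominates
        inten = classify_intensity(steps, hr, cfg.moderate_steps_per_min,
                                   cfg.vigorous_steps_per_min, cfg.hr_elevated_bpm)
        series[(str(pid), date)] = MinuteSeries(str(pid), date, steps, hr, inten)
    return TrialData(series=series, prompts=[], ground_truth={}, config=None)
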