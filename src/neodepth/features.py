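"""Per-minute feature tables for the anesthetic-depth model.

Mouse LFP sessions yield 15 features per region (PFC and HP, 30 columns):
LFP power in 1-100 Hz in 10-Hz bins, the percentage of time in active
periods, median event length and event count, and median and maximum
envelope amplitude, each normalized to its median over the
non-anesthetized baseline minutes.

Infant EEG sessions yield 5 features for each of 11 signals (unfiltered
broadband plus 1-50 Hz in 5-Hz bins, 55 columns): the channel-averaged
median envelope amplitude plus the percentage of envelope samples falling
into each amplitude quartile, quartiles being computed once per subject on
the whole (artifact-free) trace.  Features are normalized to the median
over anesthetic-free minutes, falling back to the minutes at the lowest
recorded concentration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .events import OscillationEvent
from .metrics import band_power, welch_psd, windows_from_intervals
from .preprocess import (
    EpochMask,
    InvalidParameterError,
    TimeSeriesRecording,
    bandpass_filter,
    moving_average_envelope,
)

__all__ = [
    "FeatureTable",
    "AmplitudeQuartiles",
    "SubjectExcludedError",
    "mouse_features",
    "infant_features",
    "select_channels",
    "concat_tables",
    "write_feature_table",
    "read_feature_table",
    "MOUSE_POWER_BINS",
    "INFANT_POWER_BINS",
]

#: 10-Hz power bins for mouse LFP features, 1-100 Hz.
MOUSE_POWER_BINS: list[tuple[float, float]] = [(1.0, 10.0)] + [
    (float(lo), float(lo + 10)) for lo in range(10, 100, 10)
]
#: 5-Hz bins for infant EEG features, 1-50 Hz.
INFANT_POWER_BINS: list[tuple[float, float]] = [(1.0, 5.0)] + [
    (float(lo), float(lo + 5)) for lo in range(5, 50, 5)
]


class SubjectExcludedError(RuntimeError):
    """Raised when a subject fails the inclusion rule (e.g. < 20 valid minutes)."""

    def __init__(self, message: str, status: str = "excluded"):
        super().__init__(message)
        self.status = status


@dataclass
class AmplitudeQuartiles:
    """Quartile cut points of a channel-averaged envelope (one per subject)."""

    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.q2 <= self.q3):
            raise InvalidParameterError("quartiles must be nondecreasing")

    def class_percentages(self, env: np.ndarray) -> np.ndarray:
        """Percent of samples in each of the four quartile classes.

        Classes are half-open ``[q_{k-1}, q_k)`` with the top class closed,
        so the percentages partition the samples and sum to 100.
        """
        env = np.asarray(env, dtype=float)
        n = len(env)
        c1 = np.count_nonzero(env < self.q1)
        c2 = np.count_nonzero((env >= self.q1) & (env < self.q2))
        c3 = np.count_nonzero((env >= self.q2) & (env < self.q3))
        c4 = n - c1 - c2 - c3
        return np.array([c1, c2, c3, c4]) * 100.0 / n


@dataclass
class FeatureTable:
    """Per-1-minute feature rows with concentration labels and subject tags."""

    frame: pd.DataFrame
    feature_columns: list[str]
    label_column: str = "concentration"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_columns + [self.label_column] if c not in self.frame]
        if missing:
            raise InvalidParameterError(f"missing columns: {missing}")
        if self.frame[self.label_column].isna().any():
            raise InvalidParameterError("labels must not be missing")
        if not np.all(np.isfinite(self.frame[self.feature_columns].to_numpy())):
            raise InvalidParameterError("features must be finite after normalization")

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.label_column].to_numpy(dtype=float)

    @property
    def n_rows(self) -> int:
        return len(self.frame)


def concat_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Stack subject tables sharing the same feature columns."""
    cols = tables[0].feature_columns
    for t in tables[1:]:
        if t.feature_columns != cols:
            raise InvalidParameterError("tables have differing feature columns")
    frame = pd.concat([t.frame for t in tables], ignore_index=True)
    return FeatureTable(frame=frame, feature_columns=list(cols), label_column=tables[0].label_column)


def _normalize(frame: pd.DataFrame, feature_cols: list[str], baseline_rows: np.ndarray) -> dict[str, float]:
    """Divide each feature column by its median over the baseline rows."""
    if baseline_rows.sum() == 0:
        raise InvalidParameterError("normalization undefined: empty baseline")
    constants = {}
    for c in feature_cols:
        med = float(frame.loc[baseline_rows, c].median())
        if med != 0 and np.isfinite(med):
            frame[c] = frame[c] / med
        constants[c] = med
    return constants


def _mean_concentration(rec: TimeSeriesRecording, minute: int) -> float:
    """Mean of 1-Hz concentration samples within the minute."""
    t = 60.0 * minute + np.arange(60) + 0.5
    return float(np.mean([rec.concentration_at(ti) for ti in t]))


# ---------------------------------------------------------------------------
# mouse features
# ---------------------------------------------------------------------------

def _region_minute_features(
    rec: TimeSeriesRecording,
    events: list[OscillationEvent],
    minute: int,
    prefix: str,
    envelope: np.ndarray,
) -> dict[str, float]:
    fs = rec.sampling_rate_hz
    x = rec.data[0]
    lo_t, hi_t = 60.0 * minute, 60.0 * (minute + 1)
    i0, i1 = int(round(lo_t * fs)), int(round(hi_t * fs))
    seg = x[i0:i1]
    feats: dict[str, float] = {}
    psd = welch_psd(windows_from_intervals(seg, fs), fs)
    for lo, hi in MOUSE_POWER_BINS:
        feats[f"{prefix}_pow_{int(lo)}_{int(hi)}"] = band_power(psd, (lo, hi))
    clipped = [
        (max(ev.start_s, lo_t), min(ev.stop_s, hi_t))
        for ev in events
        if ev.stop_s > lo_t and ev.start_s < hi_t
    ]
    covered = sum(b - a for a, b in clipped)
    feats[f"{prefix}_pct_active"] = 100.0 * covered / 60.0
    feats[f"{prefix}_n_events"] = float(len(clipped))
    feats[f"{prefix}_median_event_len"] = float(np.median([b - a for a, b in clipped])) if clipped else 0.0
    env_seg = envelope[i0:i1]
    feats[f"{prefix}_median_amp"] = float(np.median(env_seg))
    feats[f"{prefix}_max_amp"] = float(env_seg.max())
    return feats


def mouse_features(
    rec_pfc: TimeSeriesRecording,
    rec_hp: TimeSeriesRecording,
    events_pfc: list[OscillationEvent],
    events_hp: list[OscillationEvent],
    baseline_window: tuple[float, float] = (0.0, 900.0),
    subject_id: str = "mouse",
) -> FeatureTable:
    """Per-minute mouse LFP feature table (30 columns, baseline-normalized).

    The baseline window must be labeled concentration 0; every feature
    column is divided by its median over the baseline minutes, so baseline
    medians equal 1 after normalization.
    """
    n_minutes = int(rec_pfc.duration_s // 60)
    if int(rec_hp.duration_s // 60) != n_minutes:
        raise InvalidParameterError("PFC and HP recordings must cover the same minutes")
    b0, b1 = baseline_window
    mid = (b0 + b1) / 2
    if rec_pfc.concentration_at(mid) != 0:
        raise InvalidParameterError("baseline window must be labeled concentration 0")

    env = {
        "PFC": moving_average_envelope(rec_pfc.data[0], int(round(rec_pfc.sampling_rate_hz)))[0],
        "HP": moving_average_envelope(rec_hp.data[0], int(round(rec_hp.sampling_rate_hz)))[0],
    }
    rows = []
    for m in range(n_minutes):
        row: dict[str, float] = {"minute": m}
        row.update(_region_minute_features(rec_pfc, events_pfc, m, "PFC", env["PFC"]))
        row.update(_region_minute_features(rec_hp, events_hp, m, "HP", env["HP"]))
        row["concentration"] = rec_pfc.concentration_at(60.0 * m + 30.0)
        row["subject_id"] = subject_id
        rows.append(row)
    frame = pd.DataFrame(rows)
    feature_cols = [c for c in frame.columns if c.startswith(("PFC_", "HP_"))]
    minute_mid = 60.0 * frame["minute"].to_numpy() + 30.0
    baseline_rows = (minute_mid >= b0) & (minute_mid < b1)
    constants = _normalize(frame, feature_cols, baseline_rows)
    return FeatureTable(
        frame=frame,
        feature_columns=feature_cols,
        meta={"normalization": constants, "species": "mouse", "subject_id": subject_id},
    )


# ---------------------------------------------------------------------------
# infant features
# ---------------------------------------------------------------------------

def select_channels(rec: TimeSeriesRecording, subset: Sequence[str]) -> TimeSeriesRecording:
    """Restrict a recording to a channel subset (montage reduction)."""
    unknown = [s for s in subset if s not in rec.channel_labels]
    if unknown:
        raise InvalidParameterError(f"unknown channels: {unknown}")
    idx = [rec.channel_labels.index(s) for s in subset]
    return TimeSeriesRecording(
        data=rec.data[idx],
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_labels=list(subset),
        modality=rec.modality,
        region_of_channel={s: rec.region_of_channel.get(s, "") for s in subset},
        timeline=list(rec.timeline),
    )


def infant_features(
    rec: TimeSeriesRecording,
    mask: EpochMask,
    subject_id: str = "subject",
    age_months: float | None = None,
    age_group: str | None = None,
    min_valid_minutes: int = 20,
    manual_baseline_minutes: Sequence[int] | None = None,
) -> FeatureTable:
    """Per-valid-minute infant EEG feature table (55 columns, normalized).

    For the unfiltered signal and each 5-Hz band (1-50 Hz): channel-averaged
    median envelope amplitude and the percentage of envelope samples in each
    amplitude-quartile class, quartiles computed on the subject's whole
    valid trace.  Rows for invalid minutes are absent.  Subjects with fewer
    than ``min_valid_minutes`` valid minutes are excluded
    (:class:`SubjectExcludedError`).  Normalization uses anesthetic-free
    minutes, falling back to the minutes at the lowest concentration;
    ``manual_baseline_minutes`` overrides this for recordings started after
    induction.
    """
    fs = rec.sampling_rate_hz
    n_minutes = int(rec.duration_s // 60)
    valid_minutes = [m for m in range(n_minutes) if m < len(mask.minute_valid) and mask.minute_valid[m]]
    if len(valid_minutes) < min_valid_minutes:
        raise SubjectExcludedError(
            f"subject {subject_id}: only {len(valid_minutes)} valid minutes "
            f"(< {min_valid_minutes})",
            status="excluded_too_few_valid_minutes",
        )

    win = int(round(fs))
    signals: dict[str, np.ndarray] = {}
    env_bb = moving_average_envelope(rec.data, win).mean(axis=0)
    signals["broadband"] = env_bb
    for lo, hi in INFANT_POWER_BINS:
        filt = bandpass_filter(rec, lo, hi)
        signals[f"band_{int(lo)}_{int(hi)}"] = moving_average_envelope(filt.data, win).mean(axis=0)

    minute_len = int(round(60 * fs))
    valid_sample_mask = np.zeros(rec.n_samples, dtype=bool)
    for m in valid_minutes:
        valid_sample_mask[m * minute_len: (m + 1) * minute_len] = True

    quartiles = {
        name: AmplitudeQuartiles(*np.percentile(env[valid_sample_mask], [25, 50, 75]))
        for name, env in signals.items()
    }

    rows = []
    for m in valid_minutes:
        sl = slice(m * minute_len, (m + 1) * minute_len)
        row: dict[str, float] = {"minute": m}
        for name, env in signals.items():
            seg = env[sl]
            row[f"{name}_median_amp"] = float(np.median(seg))
            pct = quartiles[name].class_percentages(seg)
            for k in range(4):
                row[f"{name}_q{k + 1}_pct"] = float(pct[k])
        row["concentration"] = _mean_concentration(rec, m)
        row["subject_id"] = subject_id
        if age_months is not None:
            row["age_months"] = age_months
        if age_group is not None:
            row["age_group"] = age_group
        rows.append(row)
    frame = pd.DataFrame(rows)
    feature_cols = [c for c in frame.columns if c.endswith(("_median_amp", "_pct"))]

    labels = frame["concentration"].to_numpy()
    if manual_baseline_minutes is not None:
        baseline_rows = frame["minute"].isin(list(manual_baseline_minutes)).to_numpy()
    else:
        baseline_rows = labels == 0
        if not baseline_rows.any():
            baseline_rows = labels == labels.min()
    constants = _normalize(frame, feature_cols, baseline_rows)
    return FeatureTable(
        frame=frame,
        feature_columns=feature_cols,
        meta={
            "normalization": constants,
            "species": "human",
            "subject_id": subject_id,
            "quartiles": {k: (v.q1, v.q2, v.q3) for k, v in quartiles.items()},
        },
    )


# ---------------------------------------------------------------------------
# round-trip I/O
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, csv_path: str | Path) -> None:
    """CSV for the rows plus a JSON sidecar with column roles and constants."""
    csv_path = Path(csv_path)
    table.frame.to_csv(csv_path, index=False)
    sidecar = {
        "feature_columns": table.feature_columns,
        "label_column": table.label_column,
        "meta": {
            k: v for k, v in table.meta.items() if isinstance(v, (str, int, float, dict, list))
        },
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, default=float))


def read_feature_table(csv_path: str | Path) -> FeatureTable:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    return FeatureTable(
        frame=frame,
        feature_columns=list(sidecar["feature_columns"]),
        label_column=sidecar["label_column"],
        meta=sidecar.get("meta", {}),
    )
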