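"""Signal conditioning and I/O for developmental LFP/EEG recordings.

This module holds the in-memory recording container used throughout the
package, the standard conditioning steps (zero-phase band-pass filtering,
anti-aliased downsampling, common-average referencing, amplitude envelopes)
and the epoch-based artifact-rejection scheme used for infant scalp EEG:
the signal is scored in 5-s epochs, an epoch is rejected when the signal
saturates, exceeds 150 uV, or the cross-channel median envelope exceeds
30 uV, and any minute containing more than 10 s of contaminated signal is
dropped from analysis.

Recordings round-trip through an HDF5 container; EDF files are imported
through :mod:`mne`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "InvalidParameterError",
    "RecordingParseError",
    "TimeSeriesRecording",
    "ArtifactRules",
    "EpochMask",
    "bandpass_filter",
    "downsample",
    "common_average_reference",
    "auto_exclude_channels",
    "score_epochs",
    "amplitude_envelope",
    "moving_average_envelope",
    "write_recording",
    "read_recording",
    "read_edf",
]


class InvalidParameterError(ValueError):
    """A parameter violates a precondition (band edges, window sizes, ...)."""


class RecordingParseError(RuntimeError):
    """A recording file is malformed or truncated."""


# ---------------------------------------------------------------------------
# recording container
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesRecording:
    """A multichannel recording in microvolts with a concentration timeline.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` holding amplitudes in uV.
    sampling_rate_hz
        Sampling rate in Hz.
    channel_labels
        One label per channel (10/20 names for EEG, region+site for LFP).
    modality
        ``"LFP"`` (intracranial) or ``"EEG"`` (scalp).
    region_of_channel
        Map channel label -> anatomical region (``PFC``, ``HP``, ``LEC``,
        ``OB`` or ``scalp``).
    timeline
        Stepwise anesthetic-concentration timeline as ``(time_s, level)``
        pairs sorted by time; each level holds until the next entry.
    """

    data: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str]
    modality: str = "LFP"
    region_of_channel: dict[str, str] = field(default_factory=dict)
    timeline: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.sampling_rate_hz <= 0:
            raise InvalidParameterError("sampling_rate_hz must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise InvalidParameterError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        for t, _ in self.timeline:
            if t < 0 or t > self.duration_s + 1e-9:
                raise InvalidParameterError("timeline times must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def concentration_at(self, t: float) -> float:
        """Stepwise concentration at time ``t`` (0.0 before the first entry)."""
        level = 0.0
        for start, value in self.timeline:
            if t >= start:
                level = value
            else:
                break
        return level

    def with_data(self, data: np.ndarray, sampling_rate_hz: float | None = None) -> "TimeSeriesRecording":
        return replace(
            self,
            data=np.asarray(data, dtype=np.float64),
            sampling_rate_hz=sampling_rate_hz or self.sampling_rate_hz,
            channel_labels=list(self.channel_labels),
            region_of_channel=dict(self.region_of_channel),
            timeline=list(self.timeline),
        )


# ---------------------------------------------------------------------------
# filtering / resampling / referencing
# ---------------------------------------------------------------------------

def _butter_sos(low_hz: float, high_hz: float, fs: float, order: int) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz):
        raise InvalidParameterError(f"need 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise InvalidParameterError(
            f"high edge {high_hz} Hz at or above Nyquist ({nyq} Hz)"
        )
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    rec: TimeSeriesRecording, low_hz: float, high_hz: float, order: int = 3
) -> TimeSeriesRecording:
    """Zero-phase Butterworth band-pass (forward-backward application).

    The filter is applied once forward and once backward, so the group delay
    cancels and the effective magnitude response is the squared Butterworth
    response (effective order ``2 * order``).
    """
    sos = _butter_sos(low_hz, high_hz, rec.sampling_rate_hz, order)
    return rec.with_data(sps.sosfiltfilt(sos, rec.data, axis=-1))


def filter_array(
    x: np.ndarray, low_hz: float, high_hz: float, fs: float, order: int = 3
) -> np.ndarray:
    """Zero-phase band-pass for a bare array (same filter as bandpass_filter)."""
    sos = _butter_sos(low_hz, high_hz, fs, order)
    return sps.sosfiltfilt(sos, x, axis=-1)


def downsample(rec: TimeSeriesRecording, target_hz: float) -> TimeSeriesRecording:
    """Anti-aliased downsampling to ``target_hz`` (polyphase resampling).

    The concentration timeline is untouched; only the signal grid changes.
    """
    if target_hz > rec.sampling_rate_hz:
        raise InvalidParameterError(
            f"target {target_hz} Hz exceeds source rate {rec.sampling_rate_hz} Hz"
        )
    if math.isclose(target_hz, rec.sampling_rate_hz):
        return rec.with_data(rec.data.copy())
    ratio = Fraction(target_hz / rec.sampling_rate_hz).limit_denominator(10000)
    out = sps.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=-1)
    return rec.with_data(out, sampling_rate_hz=rec.sampling_rate_hz * ratio.numerator / ratio.denominator)


def common_average_reference(
    rec: TimeSeriesRecording, excluded_channels: Iterable[str] = ()
) -> TimeSeriesRecording:
    """Re-reference retained channels to their instantaneous mean.

    Excluded channels are dropped from the output; at every sample the mean
    over the retained channels of the output is exactly zero.
    """
    excluded = set(excluded_channels)
    unknown = excluded - set(rec.channel_labels)
    if unknown:
        raise InvalidParameterError(f"unknown channels to exclude: {sorted(unknown)}")
    keep = [i for i, lab in enumerate(rec.channel_labels) if lab not in excluded]
    if len(keep) < 2:
        raise InvalidParameterError("common average reference needs >= 2 retained channels")
    data = rec.data[keep]
    data = data - data.mean(axis=0, keepdims=True)
    labels = [rec.channel_labels[i] for i in keep]
    return TimeSeriesRecording(
        data=data,
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_labels=labels,
        modality=rec.modality,
        region_of_channel={k: v for k, v in rec.region_of_channel.items() if k in labels},
        timeline=list(rec.timeline),
    )


def auto_exclude_channels(
    rec: TimeSeriesRecording, low_frac: float = 0.01, high_factor: float = 100.0
) -> set[str]:
    """Channels flagged for poor signal-to-noise by a variance rule.

    A channel is excluded when its broadband variance is below ``low_frac``
    of, or more than ``high_factor`` times, the cross-channel median
    variance — a reproducible proxy for visual channel screening.
    """
    var = rec.data.var(axis=1)
    med = float(np.median(var))
    if med == 0:
        return set(rec.channel_labels)
    bad = (var < low_frac * med) | (var > high_factor * med)
    return {lab for lab, b in zip(rec.channel_labels, bad) if b}


# ---------------------------------------------------------------------------
# amplitude envelope
# ---------------------------------------------------------------------------

def moving_average_envelope(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of ``|x|`` with shrinking edge windows.

    For interior samples the window covers ``window`` samples centered on the
    sample (for even windows, one more sample to the right); at the edges the
    window is clipped to the trace and the mean is taken over the samples
    actually covered.
    """
    x = np.atleast_2d(x)
    n = x.shape[-1]
    if window <= 0:
        raise InvalidParameterError("window must be positive")
    if window > n:
        raise InvalidParameterError(f"window {window} longer than trace {n}")
    a = np.abs(x)
    c = np.concatenate([np.zeros(a.shape[:-1] + (1,)), np.cumsum(a, axis=-1)], axis=-1)
    idx = np.arange(n)
    left = (window - 1) // 2
    lo = np.clip(idx - left, 0, n)
    hi = np.clip(idx - left + window, 0, n)
    env = (np.take(c, hi, axis=-1) - np.take(c, lo, axis=-1)) / (hi - lo)
    return env


def amplitude_envelope(rec: TimeSeriesRecording, window_s: float = 1.0) -> TimeSeriesRecording:
    """Per-channel smoothed rectified signal (1-s moving average by default)."""
    if window_s <= 0:
        raise InvalidParameterError("window_s must be positive")
    window = int(round(window_s * rec.sampling_rate_hz))
    return rec.with_data(moving_average_envelope(rec.data, window))


# ---------------------------------------------------------------------------
# epoch scoring (artifact rejection)
# ---------------------------------------------------------------------------

@dataclass
class ArtifactRules:
    """Rules for automatic epoch scoring of scalp EEG.

    ``saturation_value_uv`` is the digitizer rail in uV; a run of at least
    ``saturation_run`` consecutive samples at the rail counts as saturation.
    The default rail corresponds to a 16-bit digitizer at 0.1 uV per LSB.
    """

    epoch_length_s: float = 5.0
    amplitude_limit_uv: float = 150.0
    median_envelope_limit_uv: float = 30.0
    saturation_value_uv: float = 3276.8
    saturation_run: int = 3
    envelope_window_s: float = 1.0
    contaminated_limit_s_per_min: float = 10.0
    auto_channel_exclusion: bool = True


@dataclass
class EpochMask:
    """Result of epoch scoring: per-epoch and per-minute validity."""

    epoch_length_s: float
    epoch_valid: np.ndarray          # bool per epoch, length ceil(duration / epoch_length)
    minute_valid: np.ndarray         # bool per minute
    per_channel_excluded: set[str] = field(default_factory=set)

    @property
    def n_valid_minutes(self) -> int:
        return int(self.minute_valid.sum())


def _has_saturation_run(x: np.ndarray, rail: float, run: int) -> bool:
    at_rail = np.isclose(np.abs(x), rail, rtol=1e-6, atol=1e-9)
    if not at_rail.any():
        return False
    # length of longest True run
    padded = np.concatenate([[False], at_rail, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return bool(len(starts) and (ends - starts).max() >= run)


def score_epochs(rec: TimeSeriesRecording, rules: ArtifactRules | None = None) -> EpochMask:
    """Score a recording in fixed epochs and derive minute-level validity.

    An epoch is rejected if (a) any retained channel saturates (>=
    ``saturation_run`` consecutive samples at the digitizer rail), (b) any
    retained-channel sample exceeds ``amplitude_limit_uv`` in magnitude, or
    (c) the per-sample median across retained channels of the amplitude
    envelope exceeds ``median_envelope_limit_uv`` anywhere in the epoch.
    A minute is invalid when its contaminated time strictly exceeds
    ``contaminated_limit_s_per_min``.

    The epoch grid is anchored at t = 0; a partial trailing epoch is scored
    only if at least half of it is present (otherwise it is left valid).
    """
    rules = rules or ArtifactRules()
    if rec.n_samples == 0:
        raise InvalidParameterError("empty recording")
    fs = rec.sampling_rate_hz
    epoch_len = int(round(rules.epoch_length_s * fs))
    n_epochs = int(math.ceil(rec.n_samples / epoch_len))

    excluded: set[str] = set()
    if rules.auto_channel_exclusion and rec.n_channels >= 3:
        excluded = auto_exclude_channels(rec)
        if len(excluded) >= rec.n_channels - 1:  # never exclude (almost) everything
            excluded = set()
    keep = [i for i, lab in enumerate(rec.channel_labels) if lab not in excluded]
    data = rec.data[keep]

    env = moving_average_envelope(data, int(round(rules.envelope_window_s * fs)))
    med_env = np.median(env, axis=0)

    epoch_valid = np.ones(n_epochs, dtype=bool)
    for e in range(n_epochs):
        sl = slice(e * epoch_len, min((e + 1) * epoch_len, rec.n_samples))
        present = sl.stop - sl.start
        if present < epoch_len and present < 0.5 * epoch_len:
            continue  # too short to score; left valid
        seg = data[:, sl]
        bad = bool(np.any(np.abs(seg) > rules.amplitude_limit_uv))
        if not bad:
            bad = bool(np.any(med_env[sl] > rules.median_envelope_limit_uv))
        if not bad:
            bad = any(
                _has_saturation_run(seg[c], rules.saturation_value_uv, rules.saturation_run)
                for c in range(seg.shape[0])
            )
        epoch_valid[e] = not bad

    epochs_per_min = int(round(60.0 / rules.epoch_length_s))
    n_minutes = int(math.ceil(rec.duration_s / 60.0))
    minute_valid = np.ones(n_minutes, dtype=bool)
    for m in range(n_minutes):
        eslice = epoch_valid[m * epochs_per_min: (m + 1) * epochs_per_min]
        contaminated_s = float((~eslice).sum()) * rules.epoch_length_s
        minute_valid[m] = contaminated_s <= rules.contaminated_limit_s_per_min
    return EpochMask(
        epoch_length_s=rules.epoch_length_s,
        epoch_valid=epoch_valid,
        minute_valid=minute_valid,
        per_channel_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_recording(rec: TimeSeriesRecording, path: str | Path) -> None:
    """Write a recording to an HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.data)
        f["signal"].attrs["sampling_rate_hz"] = rec.sampling_rate_hz
        f["signal"].attrs["modality"] = rec.modality
        f.create_dataset(
            "channel_labels",
            data=np.array(rec.channel_labels, dtype=h5py.string_dtype()),
        )
        regions = [rec.region_of_channel.get(lab, "") for lab in rec.channel_labels]
        f.create_dataset("regions", data=np.array(regions, dtype=h5py.string_dtype()))
        timeline = np.asarray(rec.timeline, dtype=np.float64).reshape(-1, 2)
        f.create_dataset("timeline", data=timeline)


def read_recording(path: str | Path) -> TimeSeriesRecording:
    """Read a recording written by :func:`write_recording`."""
    try:
        with h5py.File(path, "r") as f:
            for key in ("signal", "channel_labels", "regions", "timeline"):
                if key not in f:
                    raise RecordingParseError(f"{path}: missing dataset {key!r}")
            data = f["signal"][()]
            fs = float(f["signal"].attrs["sampling_rate_hz"])
            modality = str(f["signal"].attrs["modality"])
            labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_labels"][()]]
            regions = [s.decode() if isinstance(s, bytes) else str(s) for s in f["regions"][()]]
            timeline = [(float(t), float(c)) for t, c in f["timeline"][()]]
    except OSError as exc:
        raise RecordingParseError(f"{path}: not a readable HDF5 recording ({exc})") from exc
    return TimeSeriesRecording(
        data=data,
        sampling_rate_hz=fs,
        channel_labels=labels,
        modality=modality,
        region_of_channel={lab: r for lab, r in zip(labels, regions) if r},
        timeline=timeline,
    )


def read_edf(path: str | Path) -> TimeSeriesRecording:
    """Import an EDF file as an EEG recording (amplitudes converted to uV)."""
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises several types for malformed files
        raise RecordingParseError(f"{path}: failed to parse EDF ({exc})") from exc
    data_uv = raw.get_data() * 1e6
    labels = list(raw.ch_names)
    return TimeSeriesRecording(
        data=data_uv,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=labels,
        modality="EEG",
        region_of_channel={lab: "scalp" for lab in labels},
    )
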