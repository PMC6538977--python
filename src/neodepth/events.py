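"""MUA spike detection and unsupervised detection of discontinuous active periods.

Multi-unit activity (MUA) is detected on the 500-5000 Hz band as negative
deflections exceeding ``k`` times the standard deviation of the filtered
trace whose topographic prominence is larger than half the peak itself.

Active periods (the transient oscillatory episodes of discontinuous
neonatal activity) are detected on the 1-100 Hz band: the sliding-window
root mean square (RMS) is thresholded at ``mu + k_sigma * sigma`` of a
Gaussian fitted to the noise floor of the RMS histogram (bins from 0 up to
and including the histogram's modal bin).  Supra-threshold runs closer
than 200 ms are merged and only events lasting more than 1 s are kept;
occurrence, duration and amplitude are computed per event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .preprocess import InvalidParameterError, TimeSeriesRecording, filter_array

__all__ = [
    "SpikeTrain",
    "OscillationEvent",
    "DetectionThreshold",
    "detect_mua",
    "firing_rate",
    "rms_timecourse",
    "fit_detection_threshold",
    "merge_and_filter_intervals",
    "detect_active_periods",
    "occurrence_timecourse",
    "event_recall_jaccard",
]


# ---------------------------------------------------------------------------
# spike (MUA) detection
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Detected MUA event times for one channel."""

    channel: str
    times_s: np.ndarray
    threshold_used_uv: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise InvalidParameterError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return len(self.times_s)


def detect_mua(rec: TimeSeriesRecording, k_sd: float = 5.0) -> list[SpikeTrain]:
    """Detect multi-unit spikes per channel on a 500-5000 Hz filtered trace.

    A spike is a local minimum whose value lies below ``-k_sd`` times the
    channel's standard deviation (computed over the full trace) and whose
    prominence on the inverted trace exceeds half the peak magnitude.
    Constant or empty channels yield empty trains.
    """
    out = []
    fs = rec.sampling_rate_hz
    for label, x in zip(rec.channel_labels, rec.data):
        sd = float(x.std())
        if sd == 0 or len(x) == 0:
            out.append(SpikeTrain(channel=label, times_s=np.zeros(0), threshold_used_uv=0.0))
            continue
        thr = k_sd * sd
        idx, props = find_peaks(-x, height=thr, prominence=0.0)
        peak_heights = props["peak_heights"]
        keep = props["prominences"] > 0.5 * peak_heights
        out.append(
            SpikeTrain(channel=label, times_s=idx[keep] / fs, threshold_used_uv=thr)
        )
    return out


def firing_rate(
    train: SpikeTrain,
    windows: list[tuple[float, float]],
    union: bool = False,
) -> np.ndarray | float:
    """Spike count divided by window duration, in Hz.

    With ``union=True`` a single rate over the union of the (non-overlapping)
    intervals is returned — the "within active periods" firing rate.
    """
    windows = [(float(a), float(b)) for a, b in windows]
    for a, b in windows:
        if b <= a:
            raise InvalidParameterError(f"zero-length or inverted window ({a}, {b})")
    t = train.times_s
    counts = np.array([np.count_nonzero((t >= a) & (t < b)) for a, b in windows])
    durations = np.array([b - a for a, b in windows])
    if union:
        total = durations.sum()
        if total == 0:
            raise InvalidParameterError("empty union of windows")
        return float(counts.sum() / total)
    return counts / durations


# ---------------------------------------------------------------------------
# active-period detection
# ---------------------------------------------------------------------------

@dataclass
class OscillationEvent:
    """One detected active period."""

    start_s: float
    stop_s: float
    amplitude_uv: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class DetectionThreshold:
    """Variance-dependent RMS threshold fitted to the noise floor.

    ``threshold_value = gaussian_mu + k_sigma * gaussian_sigma`` where the
    Gaussian is fitted by least squares to the RMS histogram bins from 0 up
    to and including the modal (global-maximum) bin.
    """

    rms_window_s: float
    rms_overlap: float
    band_hz: tuple[float, float]
    histogram_bins: int
    gaussian_mu: float
    gaussian_sigma: float
    k_sigma: float
    threshold_value: float

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise InvalidParameterError("fitted sigma must be positive")
        expected = self.gaussian_mu + self.k_sigma * self.gaussian_sigma
        if not math.isclose(self.threshold_value, expected, rel_tol=1e-9):
            raise InvalidParameterError("threshold_value != mu + k_sigma * sigma")

    def rescaled(self, factor: float) -> "DetectionThreshold":
        """Threshold for a signal scaled by ``factor`` (homogeneity)."""
        return DetectionThreshold(
            rms_window_s=self.rms_window_s,
            rms_overlap=self.rms_overlap,
            band_hz=self.band_hz,
            histogram_bins=self.histogram_bins,
            gaussian_mu=self.gaussian_mu * factor,
            gaussian_sigma=self.gaussian_sigma * factor,
            k_sigma=self.k_sigma,
            threshold_value=self.threshold_value * factor,
        )


def rms_timecourse(
    x: np.ndarray, fs: float, window_s: float = 0.2, overlap: float = 0.5
) -> tuple[np.ndarray, float, int]:
    """Sliding-window RMS.

    Returns ``(rms, hop_s, window_samples)`` where window ``i`` covers
    ``[i * hop_s, i * hop_s + window_s]`` seconds.
    """
    win = int(round(window_s * fs))
    hop = max(1, int(round(win * (1.0 - overlap))))
    n = len(x)
    if n < win:
        raise InvalidParameterError("trace shorter than one RMS window")
    sq = np.concatenate([[0.0], np.cumsum(x.astype(np.float64) ** 2)])
    starts = np.arange(0, n - win + 1, hop)
    rms = np.sqrt((sq[starts + win] - sq[starts]) / win)
    return rms, hop / fs, win


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_detection_threshold(
    rec: TimeSeriesRecording,
    band: tuple[float, float] = (1.0, 100.0),
    rms_window_s: float = 0.2,
    k_sigma: float = 3.5,
    histogram_bins: int = 100,
    rms_overlap: float = 0.5,
    channel: int = 0,
) -> DetectionThreshold:
    """Fit the variance-dependent detection threshold on one channel.

    The channel is band-pass filtered, its sliding-window RMS histogrammed
    (``histogram_bins`` bins from 0 to the maximum RMS), and a Gaussian is
    least-squares fitted to bin centers from 0 through the modal bin — the
    noise floor of a discontinuous recording.  The threshold is
    ``mu + k_sigma * sigma``.
    """
    fs = rec.sampling_rate_hz
    x = filter_array(rec.data[channel], band[0], band[1], fs)
    rms, _, _ = rms_timecourse(x, fs, rms_window_s, rms_overlap)
    if len(rms) < 100:
        raise InvalidParameterError("trace too short: need >= 100 RMS samples")
    if rms.max() - rms.min() < 1e-12 * max(rms.max(), 1.0):
        raise InvalidParameterError("no noise floor: constant trace")
    counts, edges = np.histogram(rms, bins=histogram_bins, range=(0.0, float(rms.max())))
    centers = 0.5 * (edges[:-1] + edges[1:])
    modal = int(np.argmax(counts))
    if modal < 2:
        raise InvalidParameterError("no noise floor: RMS histogram mode at origin")
    xs, ys = centers[: modal + 1], counts[: modal + 1]
    sigma0 = max(centers[modal] / 3.0, 1e-6)
    try:
        popt, _ = curve_fit(
            _gaussian,
            xs,
            ys,
            p0=(float(counts[modal]), float(centers[modal]), sigma0),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise InvalidParameterError(f"Gaussian fit to RMS noise floor failed: {exc}") from exc
    _, mu, sigma = popt
    sigma = abs(float(sigma))
    mu = float(mu)
    return DetectionThreshold(
        rms_window_s=rms_window_s,
        rms_overlap=rms_overlap,
        band_hz=(float(band[0]), float(band[1])),
        histogram_bins=histogram_bins,
        gaussian_mu=mu,
        gaussian_sigma=sigma,
        k_sigma=k_sigma,
        threshold_value=mu + k_sigma * sigma,
    )


def merge_and_filter_intervals(
    intervals: list[tuple[float, float]] | list[list[float]],
    merge_gap_s: float = 0.2,
    min_duration_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Apply the event rules: merge gaps < merge_gap_s, keep duration > min.

    Candidate intervals occurring within ``merge_gap_s`` of each other are
    considered one event; only merged events lasting strictly more than
    ``min_duration_s`` survive.  Input order does not matter.
    """
    if not len(intervals):
        return []
    ordered = sorted([list(iv) for iv in intervals])
    merged = [ordered[0][:]]
    for a, b in ordered[1:]:
        if a - merged[-1][1] < merge_gap_s:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged if b - a > min_duration_s]


def detect_active_periods(
    rec: TimeSeriesRecording,
    thr: DetectionThreshold,
    merge_gap_s: float = 0.2,
    min_duration_s: float = 1.0,
    channel: int = 0,
) -> list[OscillationEvent]:
    """Detect active periods as supra-threshold runs of the sliding RMS.

    Candidate events closer than ``merge_gap_s`` are considered one event;
    events lasting no more than ``min_duration_s`` are discarded (strict
    ``> min_duration_s`` rule).  Event amplitude is the maximum absolute
    deflection of the band-filtered trace within the event.
    """
    fs = rec.sampling_rate_hz
    x = filter_array(rec.data[channel], thr.band_hz[0], thr.band_hz[1], fs)
    rms, hop_s, win = rms_timecourse(x, fs, thr.rms_window_s, thr.rms_overlap)
    supra = rms > thr.threshold_value  # strict > at the threshold
    if not supra.any():
        return []
    padded = np.concatenate([[False], supra, [False]])
    d = np.diff(padded.astype(int))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive window index
    win_s = win / fs
    total_s = len(x) / fs
    candidates = [
        [s * hop_s, min((e - 1) * hop_s + win_s, total_s)]
        for s, e in zip(run_starts, run_ends)
    ]
    events = []
    for a, b in merge_and_filter_intervals(candidates, merge_gap_s, min_duration_s):
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        amp = float(np.abs(x[i0:i1]).max()) if i1 > i0 else 0.0
        events.append(OscillationEvent(start_s=float(a), stop_s=float(b), amplitude_uv=amp))
    return events


def occurrence_timecourse(
    events: list[OscillationEvent], total_s: float, bin_s: float = 60.0
) -> np.ndarray:
    """Fraction of each time bin covered by events (events split at edges)."""
    for ev in events:
        if ev.start_s < 0 or ev.stop_s > total_s + 1e-9:
            raise InvalidParameterError("events must lie within [0, total_s]")
    n_bins = int(math.ceil(total_s / bin_s))
    frac = np.zeros(n_bins)
    for k in range(n_bins):
        lo, hi = k * bin_s, min((k + 1) * bin_s, total_s)
        covered = sum(
            max(0.0, min(ev.stop_s, hi) - max(ev.start_s, lo)) for ev in events
        )
        frac[k] = covered / (hi - lo)
    return frac


# ---------------------------------------------------------------------------
# detector evaluation against ground truth
# ---------------------------------------------------------------------------

def event_recall_jaccard(
    detected: list[OscillationEvent],
    true_intervals: np.ndarray,
) -> tuple[float, float]:
    """Event-wise recall and mean temporal Jaccard against true intervals.

    A true interval counts as recalled when at least one detected event
    overlaps it; its Jaccard index is taken with the union of all detected
    events restricted to the best-overlapping detected event.  The mean
    Jaccard is over recalled intervals (0 contribution if none recalled).
    """
    true_intervals = np.asarray(true_intervals, dtype=float).reshape(-1, 2)
    if len(true_intervals) == 0:
        return float("nan"), float("nan")
    recalled = 0
    jaccards = []
    for a, b in true_intervals:
        best = 0.0
        hit = False
        for ev in detected:
            inter = max(0.0, min(ev.stop_s, b) - max(ev.start_s, a))
            if inter > 0:
                hit = True
                union = max(ev.stop_s, b) - min(ev.start_s, a)
                best = max(best, inter / union)
        if hit:
            recalled += 1
            jaccards.append(best)
    recall = recalled / len(true_intervals)
    mean_j = float(np.mean(jaccards)) if jaccards else 0.0
    return recall, mean_j
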