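"""Quantitative signal metrics for developmental LFP/EEG analysis.

Welch power spectral density over concatenated 1-s windows (full signal or
active periods only), band powers and the modulation index
``(post - pre) / (post + pre)``, imaginary coherence, spike-field pairwise
phase consistency (PPC), the aperiodic 1/f slope fitted robustly over
20-40 Hz in 1-min bins, sample entropy in 1.5-s windows over 2-Hz bands,
and Spearman's rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .preprocess import InvalidParameterError, filter_array

__all__ = [
    "PsdResult",
    "BandDefinition",
    "DEFAULT_BANDS",
    "SlopeEstimate",
    "welch_psd",
    "windows_from_intervals",
    "modulation_index",
    "band_power",
    "imaginary_coherence",
    "magnitude_coherence",
    "ppc",
    "ppc_from_phases",
    "aperiodic_slope",
    "aperiodic_slope_per_minute",
    "sampen",
    "sample_entropy_bands",
    "spearman_rho",
]


# ---------------------------------------------------------------------------
# power spectral density
# ---------------------------------------------------------------------------

@dataclass
class PsdResult:
    """Welch PSD: power (uV^2/Hz) on a frequency grid."""

    freqs_hz: np.ndarray
    power: np.ndarray
    n_windows: int
    source: str = "full_signal"  # or "active_periods"


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float


#: delta / theta-alpha / beta / gamma band edges.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 2.0, 4.0),
    "theta_alpha": BandDefinition("theta_alpha", 4.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 100.0),
}


def windows_from_intervals(
    x: np.ndarray,
    fs: float,
    intervals: np.ndarray | None = None,
    window_s: float = 1.0,
) -> list[np.ndarray]:
    """Cut non-overlapping windows from the full signal or from intervals.

    With ``intervals`` given (e.g. detected or true active periods), only
    complete windows falling inside each interval are taken — the
    concatenation used for within-active-period spectra.
    """
    win = int(round(window_s * fs))
    segments = []
    if intervals is None:
        for i in range(len(x) // win):
            segments.append(x[i * win: (i + 1) * win])
    else:
        for a, b in np.asarray(intervals, dtype=float).reshape(-1, 2):
            i0 = int(math.ceil(a * fs))
            i1 = int(math.floor(b * fs))
            for i in range((i1 - i0) // win):
                segments.append(x[i0 + i * win: i0 + (i + 1) * win])
    return segments


def welch_psd(segments: list[np.ndarray], fs: float, source: str = "full_signal") -> PsdResult:
    """Welch PSD of concatenated equal-length windows, non-overlapping.

    Every segment must be exactly ``round(fs * 1 s)`` samples (for 1-s
    windows the frequency resolution is 1 Hz); the periodograms of the
    windows are averaged.
    """
    if not segments:
        raise InvalidParameterError("no segments to estimate PSD from")
    win = len(segments[0])
    if any(len(s) != win for s in segments):
        raise InvalidParameterError("all segments must have the same length")
    concat = np.concatenate(segments)
    freqs, power = sps.welch(
        concat, fs=fs, window="hann", nperseg=win, noverlap=0, detrend="constant"
    )
    return PsdResult(freqs_hz=freqs, power=power, n_windows=len(segments), source=source)


def modulation_index(p_pre, p_post):
    """Normalized change (post - pre) / (post + pre), elementwise in [-1, 1].

    Entries where both powers are zero are undefined and returned as NaN.
    """
    p_pre = np.asarray(p_pre, dtype=float)
    p_post = np.asarray(p_post, dtype=float)
    if np.any(p_pre < 0) or np.any(p_post < 0):
        raise InvalidParameterError("powers must be nonnegative")
    denom = p_post + p_pre
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = np.where(denom > 0, (p_post - p_pre) / denom, np.nan)
    return mi if mi.ndim else float(mi)


def band_power(psd: PsdResult, band: BandDefinition | tuple[float, float]) -> float:
    """Integrated power over a band by the trapezoid rule on the PSD grid."""
    lo, hi = (band.lo_hz, band.hi_hz) if isinstance(band, BandDefinition) else band
    if lo < psd.freqs_hz[0] or hi > psd.freqs_hz[-1]:
        raise InvalidParameterError(f"band ({lo}, {hi}) outside PSD range")
    m = (psd.freqs_hz >= lo) & (psd.freqs_hz <= hi)
    return float(np.trapezoid(psd.power[m], psd.freqs_hz[m]))


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def _cross_spectra(x, y, fs, segment_s=1.0, overlap=0.5):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("signals must have equal length")
    nper = int(round(segment_s * fs))
    nover = int(round(nper * overlap))
    n_segments = 1 + max(0, (len(x) - nper)) // (nper - nover)
    if n_segments < 2:
        raise InvalidParameterError("need >= 2 segments for a normalized cross-spectrum")
    kw = dict(fs=fs, window="hann", nperseg=nper, noverlap=nover, detrend="constant")
    f, sxx = sps.welch(x, **kw)
    _, syy = sps.welch(y, **kw)
    _, sxy = sps.csd(x, y, **kw)
    return f, sxx, syy, sxy


def imaginary_coherence(x, y, fs, segment_s: float = 1.0, overlap: float = 0.5):
    """|Im| of the normalized cross-spectrum per frequency, in [0, 1].

    Insensitive to zero-lag (volume-conducted) coupling: an identical or
    linearly mixed copy of a signal contributes no imaginary part.
    Estimated with 1-s Hann segments at 50% overlap.
    """
    f, sxx, syy, sxy = _cross_spectra(x, y, fs, segment_s, overlap)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = sxy / np.sqrt(sxx * syy)
    return f, np.abs(np.imag(c))


def magnitude_coherence(x, y, fs, segment_s: float = 1.0, overlap: float = 0.5):
    """Ordinary magnitude coherence |Sxy| / sqrt(Sxx Syy) (same estimator)."""
    f, sxx, syy, sxy = _cross_spectra(x, y, fs, segment_s, overlap)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(sxy) / np.sqrt(sxx * syy)
    return f, c


# ---------------------------------------------------------------------------
# pairwise phase consistency
# ---------------------------------------------------------------------------

def ppc_from_phases(phases: np.ndarray) -> float:
    """Mean cosine of pairwise phase differences over all unordered pairs.

    Computed in closed form from the resultant vector:
    ``((sum cos)^2 + (sum sin)^2 - n) / (n (n - 1))`` — the unbiased
    population statistic whose expectation is the squared mean resultant
    length.  Undefined (NaN) for fewer than two phases.
    """
    phases = np.asarray(phases, dtype=float)
    n = len(phases)
    if n < 2:
        return float("nan")
    c = np.cos(phases).sum()
    s = np.sin(phases).sum()
    return float((c * c + s * s - n) / (n * (n - 1)))


def ppc(
    spike_times: np.ndarray,
    lfp: np.ndarray,
    band: tuple[float, float],
    fs: float,
) -> float:
    """Spike-field pairwise phase consistency in a frequency band.

    The field is band-pass filtered (zero phase), its instantaneous phase
    extracted with the Hilbert transform, and the PPC of the phases at the
    spike times returned.  NaN for fewer than two in-range spikes.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    filt = filter_array(np.asarray(lfp, dtype=float), band[0], band[1], fs)
    phase = np.angle(sps.hilbert(filt))
    idx = np.round(spike_times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < len(phase))]
    if len(idx) < 2:
        return float("nan")
    return ppc_from_phases(phase[idx])


# ---------------------------------------------------------------------------
# aperiodic (1/f) slope
# ---------------------------------------------------------------------------

@dataclass
class SlopeEstimate:
    """Robust log-log linear fit of the PSD over a frequency range."""

    slope: float
    intercept: float
    fit_range_hz: tuple[float, float] = (20.0, 40.0)
    bin_s: float = 60.0


def aperiodic_slope(
    psd: PsdResult, fit_range: tuple[float, float] = (20.0, 40.0), bin_s: float = 60.0
) -> SlopeEstimate | None:
    """Robust (iteratively reweighted, bisquare) fit of log10 power on log10 f.

    Only frequencies inside ``fit_range`` enter the fit; nonpositive powers
    are dropped, and if fewer than three points remain the estimate is
    missing (None).
    """
    m = (psd.freqs_hz >= fit_range[0]) & (psd.freqs_hz <= fit_range[1])
    f = psd.freqs_hz[m]
    p = psd.power[m]
    good = p > 0
    f, p = f[good], p[good]
    if len(f) < 3:
        return None
    X = sm.add_constant(np.log10(f))
    fit = sm.RLM(np.log10(p), X, M=sm.robust.norms.TukeyBiweight()).fit()
    return SlopeEstimate(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        fit_range_hz=(float(fit_range[0]), float(fit_range[1])),
        bin_s=bin_s,
    )


def aperiodic_slope_per_minute(
    x: np.ndarray,
    fs: float,
    fit_range: tuple[float, float] = (20.0, 40.0),
    bin_s: float = 60.0,
) -> list[SlopeEstimate | None]:
    """1/f slope in consecutive 1-min bins (Welch PSD of 1-s windows per bin)."""
    n_bin = int(round(bin_s * fs))
    out = []
    for k in range(len(x) // n_bin):
        seg = x[k * n_bin: (k + 1) * n_bin]
        psd = welch_psd(windows_from_intervals(seg, fs), fs)
        out.append(aperiodic_slope(psd, fit_range, bin_s))
    return out


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

def sampen(x: np.ndarray, m: int = 2, r: float | None = None, tau: int = 1) -> float:
    """Sample entropy: -ln(A/B) with template length m and tolerance r.

    ``B`` counts template pairs of length ``m`` within Chebyshev distance
    ``r`` (self-matches excluded), ``A`` the corresponding count at length
    ``m + 1``; both use the same ``n - m`` templates.  ``r`` defaults to
    0.2 times the standard deviation of the (lag-subsampled) signal.
    Returns NaN when ``B = 0`` (undefined) and +inf when ``A = 0``.
    """
    x = np.asarray(x, dtype=float)[::tau]
    n = len(x)
    if n < m + 2:
        return float("nan")
    if r is None:
        r = 0.2 * float(x.std())
    n_templates = n - m
    xm = sliding_window_view(x, m)[:n_templates]
    xm1 = sliding_window_view(x, m + 1)
    if m == 1:
        dm = pdist(xm.reshape(-1, 1), "chebyshev")
    else:
        dm = pdist(xm, "chebyshev")
    dm1 = pdist(xm1, "chebyshev")
    b = int(np.count_nonzero(dm <= r))
    a = int(np.count_nonzero(dm1 <= r))
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return float(-math.log(a / b))


def sample_entropy_bands(
    x: np.ndarray,
    fs: float,
    m: int = 2,
    r_factor: float = 0.2,
    tau: int = 1,
    window_s: float = 1.5,
    band_hz: float = 2.0,
    band_range: tuple[float, float] = (1.0, 49.0),
    analysis_fs: float = 200.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Sample entropy per (1.5-s window, 2-Hz band).

    Each band (grid anchored at 1 Hz) is extracted with a 4th-order
    zero-phase band-pass; the band signal is decimated to ``analysis_fs``
    (windows must retain at least 50 samples) and SampEn is computed per
    window with tolerance ``r_factor`` times the window's standard
    deviation.  Returns an array of shape ``(n_windows, n_bands)`` and the
    band edges.
    """
    x = np.asarray(x, dtype=float)
    bands = []
    lo = band_range[0]
    while lo + band_hz <= band_range[1] + 1e-9:
        bands.append((lo, lo + band_hz))
        lo += band_hz
    step = max(1, int(round(fs / analysis_fs)))
    win = int(round(window_s * fs / step))
    if win < 50:
        raise InvalidParameterError("window too short: needs >= 50 samples after downsampling")
    n_windows = (len(x) // step) // win
    out = np.full((n_windows, len(bands)), np.nan)
    for b, (blo, bhi) in enumerate(bands):
        xb = filter_array(x, blo, bhi, fs, order=4)[::step]
        for w in range(n_windows):
            seg = xb[w * win: (w + 1) * win]
            out[w, b] = sampen(seg, m=m, r=r_factor * float(seg.std()), tau=tau)
    return out, bands


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman's rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise InvalidParameterError("need equal-length sequences of length >= 3")
    return float(spearmanr(x, y).statistic)
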