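"""Synthetic developmental LFP/EEG sessions with ground truth.

Three session generators emulate the statistical structure of brain
activity under volatile anesthesia at different developmental stages:

* :func:`gen_neonatal_session` — discontinuous neonatal LFP: transient
  active periods of mixed-frequency oscillations riding on a 1/f
  background, alternating with silent periods.  Anesthetic concentration
  suppresses the *occurrence* of active periods (a multiplicative,
  nonincreasing dose law) while leaving the within-period spectral mix and
  firing unchanged.  Multi-unit spikes are placed inside active periods
  with von Mises phase locking to a configurable band.
* :func:`gen_juvenile_session` — continuous juvenile/adult-like LFP where
  anesthesia shifts power between bands (delta up, beta/gamma down) by
  configured log-power slopes.
* :func:`gen_infant_session` — multichannel infant scalp EEG whose
  broadband amplitude follows a signed linear law in end-tidal anesthetic
  concentration (negative in the youngest group, positive in the oldest),
  with injected artifacts (digitizer saturation, high-amplitude
  transients, high-median segments) recorded in the ground truth.

Every generator is deterministic given its seed: identical parameters and
seed yield bit-identical signals and ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import hilbert
from scipy.stats import norm

from .preprocess import InvalidParameterError, TimeSeriesRecording, filter_array

__all__ = [
    "BAND_EDGES",
    "NeonatalLfpParams",
    "InfantEegParams",
    "ArtifactSpec",
    "TrueBurst",
    "GroundTruth",
    "colored_noise",
    "band_noise",
    "gen_neonatal_session",
    "gen_juvenile_session",
    "gen_infant_session",
    "default_infant_params",
    "write_ground_truth",
    "read_ground_truth",
    "DEFAULT_EEG_LABELS",
]

#: Canonical frequency bands (Hz) for developmental LFP analysis.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta_alpha": (4.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}

#: Modified 10/20 montage labels used for synthetic infant EEG.  The leading
#: entries form the reduced montages of clinical long-term monitoring
#: (F4/P4/F3/P3 and P4/P3), so small-channel-count sessions stay realistic.
DEFAULT_EEG_LABELS: list[str] = [
    "F3", "F4", "P3", "P4", "C3", "C4", "O1", "O2",
    "Fp1", "Fp2", "Fpz", "F7", "F8", "Fz", "Cz", "T7",
    "T8", "Pz", "P7", "P8", "Oz", "FC1", "FC2", "FC5",
    "FC6", "CP1", "CP2", "CP5", "CP6", "PO3", "PO4", "PO7", "PO8",
]


# ---------------------------------------------------------------------------
# noise primitives
# ---------------------------------------------------------------------------

def colored_noise(
    n: int,
    fs: float,
    exponent: float,
    sd: float,
    rng: np.random.Generator,
    flatten_below_hz: float = 0.0,
) -> np.ndarray:
    """Gaussian noise with power spectrum P(f) ~ f**exponent.

    White noise is shaped in the frequency domain with an f**(exponent/2)
    amplitude filter (DC removed), then rescaled to standard deviation
    ``sd``.  This gives an exactly controllable aperiodic slope, which the
    1/f-slope estimator is validated against.  ``flatten_below_hz`` holds
    the spectrum constant below that frequency (emulating the hardware
    high-pass of a physiological amplifier, which keeps steep spectra from
    being dominated by drift); the slope above it is unaffected.
    """
    if n < 2:
        raise InvalidParameterError("need at least 2 samples")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    f_eff = freqs if flatten_below_hz <= 0 else np.maximum(freqs, flatten_below_hz)
    shape[1:] = f_eff[1:] ** (exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def band_noise(
    n: int, fs: float, lo_hz: float, hi_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi) by an FFT mask."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo_hz) | (freqs >= hi_hz)] = 0.0
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    if s > 0:
        x /= s
    return x


def _cosine_taper(n: int, ramp: int) -> np.ndarray:
    """Flat window with raised-cosine on/off ramps of ``ramp`` samples."""
    w = np.ones(n)
    ramp = min(ramp, n // 2)
    if ramp > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        w[:ramp] = r
        w[-ramp:] = r[::-1]
    return w


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class NeonatalLfpParams:
    """Parameters of the discontinuous neonatal-LFP generator.

    ``dose_response`` maps anesthetic concentration to a multiplicative
    factor in [0, 1] on the active-period initiation rate; it must equal 1
    at concentration 0 and be nonincreasing in concentration.
    ``burst_band_mix`` gives relative *power* weights of the four canonical
    bands inside an active period; the mix is identical at every
    concentration (only occurrence is dose dependent).
    """

    sampling_rate_hz: float = 1000.0
    duration_s: float = 300.0
    burst_rate_hz: float = 0.12
    burst_duration_s: tuple[float, float] = (4.0, 1.5)   # mean, sd (>1 s mean)
    burst_min_duration_s: float = 2.0
    burst_band_mix: dict[str, float] = field(
        default_factory=lambda: {"delta": 1.0, "theta_alpha": 0.8, "beta": 0.25, "gamma": 0.1}
    )
    aperiodic_exponent: float = -2.0
    noise_sd_uv: float = 10.0
    burst_snr_mean: float = 5.0
    burst_snr_spread: float = 0.25                        # lognormal sigma (log units)
    spike_rate_hz: float = 10.0
    spike_lock_kappa: float = 2.0
    spike_lock_band: tuple[float, float] = (4.0, 12.0)
    spike_amp_uv: float = 30.0
    dose_response: dict[float, float] = field(default_factory=lambda: {0.0: 1.0})
    band_dose_slopes: dict[str, float] = field(default_factory=dict)  # continuous mode only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise InvalidParameterError("duration and sampling rate must be positive")
        if self.burst_duration_s[0] <= 1.0:
            raise InvalidParameterError("mean burst duration must exceed 1 s")
        if any(w < 0 for w in self.burst_band_mix.values()):
            raise InvalidParameterError("band mix weights must be nonnegative")
        if set(self.burst_band_mix) - set(BAND_EDGES):
            raise InvalidParameterError(f"unknown bands in mix: {set(self.burst_band_mix) - set(BAND_EDGES)}")
        levels = sorted(self.dose_response)
        if not math.isclose(self.dose_response[levels[0]], 1.0) or levels[0] != 0.0:
            raise InvalidParameterError("dose_response must contain {0: 1.0}")
        vals = [self.dose_response[k] for k in levels]
        if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
            raise InvalidParameterError("dose_response must be nonincreasing in concentration")
        if any(not 0 <= v <= 1 for v in vals):
            raise InvalidParameterError("dose_response factors must lie in [0, 1]")

    def dose_factor(self, level: float) -> float:
        """Occurrence factor for a concentration (nearest configured level)."""
        keys = np.array(sorted(self.dose_response))
        k = float(keys[np.argmin(np.abs(keys - level))])
        return self.dose_response[k]


@dataclass
class ArtifactSpec:
    """Counts of injected artifact epochs per infant session."""

    n_saturation_epochs: int = 0
    n_transient_epochs: int = 0
    n_high_median_epochs: int = 0
    saturation_value_uv: float = 3276.8
    transient_amplitude_uv: float = 300.0

    @property
    def total(self) -> int:
        return self.n_saturation_epochs + self.n_transient_epochs + self.n_high_median_epochs


@dataclass
class InfantEegParams:
    """Parameters of the infant scalp-EEG generator.

    ``concentration_profile`` is a stepwise per-minute end-tidal
    concentration, given as (minute, level) pairs; each level holds until
    the next entry.  Concentration is expressed as a dimensionless fraction
    of an age-adjusted reference.  ``amplitude_dose_slope`` is the signed
    linear coefficient of broadband amplitude on concentration: the
    0-2-month group requires a nonpositive slope and the 4-6-month group a
    nonnegative one, mirroring the developmental switch of the
    amplitude-concentration correlation.
    """

    age_group: str = "0-2"                                 # {"0-2", "2-4", "4-6"} months
    n_channels: int = 8
    sampling_rate_hz: float = 256.0
    concentration_profile: Sequence[tuple[int, float]] = (
        (0, 0.0), (6, 0.5), (12, 1.0), (18, 1.5), (24, 1.0),
    )
    duration_min: int = 30
    amplitude_dose_slope: float = -0.4
    band_dose_slopes: Sequence[float] = ()                 # per 5-Hz band, ln-power per unit conc
    base_amplitude_uv: float = 15.0
    sensor_noise_uv: float = 3.0
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    channel_labels: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_group not in {"0-2", "2-4", "4-6"}:
            raise InvalidParameterError("age_group must be one of '0-2', '2-4', '4-6'")
        if self.n_channels < 2:
            raise InvalidParameterError("need >= 2 channels (common average reference undefined)")
        if self.n_channels > 41:
            raise InvalidParameterError("at most 41 channels supported")
        if any(c < 0 for _, c in self.concentration_profile):
            raise InvalidParameterError("concentrations must be nonnegative")
        if self.age_group == "0-2" and self.amplitude_dose_slope > 0:
            raise InvalidParameterError("0-2 months requires a nonpositive amplitude_dose_slope")
        if self.age_group == "4-6" and self.amplitude_dose_slope < 0:
            raise InvalidParameterError("4-6 months requires a nonnegative amplitude_dose_slope")

    def concentration_per_minute(self) -> np.ndarray:
        conc = np.zeros(self.duration_min)
        profile = sorted(self.concentration_profile)
        for m in range(self.duration_min):
            for start, level in profile:
                if m >= start:
                    conc[m] = level
        return conc

    def labels(self) -> list[str]:
        if self.channel_labels is not None:
            if len(self.channel_labels) != self.n_channels:
                raise InvalidParameterError("channel_labels length must match n_channels")
            return list(self.channel_labels)
        return DEFAULT_EEG_LABELS[: self.n_channels]


def default_infant_params(age_group: str, seed: int = 0, **overrides) -> InfantEegParams:
    """Study-condition defaults per age group.

    The 0-2-month group carries a negative broadband amplitude-dose slope
    (frequency-unspecific suppression), the 4-6-month group a positive one,
    and the 2-4-month group a weak broadband slope with frequency-specific
    band slopes (low bands up, high bands down).
    """
    n_bands = 10
    if age_group == "0-2":
        amp, bands = -0.4, np.zeros(n_bands)
    elif age_group == "2-4":
        amp = 0.1
        bands = np.linspace(0.5, -0.5, n_bands)
    elif age_group == "4-6":
        amp = 0.4
        bands = np.linspace(0.3, -0.3, n_bands)
    else:
        raise InvalidParameterError(f"unknown age group {age_group!r}")
    kwargs = dict(
        age_group=age_group,
        amplitude_dose_slope=amp,
        band_dose_slopes=tuple(bands),
        seed=seed,
    )
    kwargs.update(overrides)
    return InfantEegParams(**kwargs)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class TrueBurst:
    """One true active period: interval, anesthetic level and burst SNR."""

    start_s: float
    stop_s: float
    snr: float = 1.0
    level: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class GroundTruth:
    """Everything the generators know that the analysis must recover."""

    events: list[TrueBurst] = field(default_factory=list)
    spike_times: dict[str, np.ndarray] = field(default_factory=dict)
    artifact_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    concentration_per_minute: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        starts = [e.start_s for e in self.events]
        if starts != sorted(starts):
            raise InvalidParameterError("ground-truth events must be sorted")
        for a, b in zip(self.events, self.events[1:]):
            if b.start_s < a.stop_s:
                raise InvalidParameterError("ground-truth events must not overlap")

    def event_intervals(self) -> np.ndarray:
        return np.array([[e.start_s, e.stop_s] for e in self.events]).reshape(-1, 2)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "events": [
            {"start_s": e.start_s, "stop_s": e.stop_s, "snr": e.snr, "level": e.level}
            for e in truth.events
        ],
        "spike_times": {k: np.asarray(v).tolist() for k, v in truth.spike_times.items()},
        "artifact_mask": truth.artifact_mask.astype(int).tolist(),
        "concentration_per_minute": np.asarray(truth.concentration_per_minute).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        events=[TrueBurst(**e) for e in payload["events"]],
        spike_times={k: np.asarray(v, dtype=float) for k, v in payload["spike_times"].items()},
        artifact_mask=np.asarray(payload["artifact_mask"], dtype=bool),
        concentration_per_minute=np.asarray(payload["concentration_per_minute"], dtype=float),
    )


# ---------------------------------------------------------------------------
# neonatal (discontinuous) sessions
# ---------------------------------------------------------------------------

def _level_at(concentrations: Sequence[tuple[float, float]], t: float) -> float:
    level = 0.0
    for start, value in concentrations:
        if t >= start:
            level = value
    return level


def _burst_waveform(
    n: int,
    fs: float,
    band_mix: Mapping[str, float],
    lock_band: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-RMS mixed-band burst and the instantaneous phase of its lock band.

    Returns the tapered waveform (100-ms cosine ramps, so bursts wax and
    wane rather than switching on) and the Hilbert phase of the lock-band
    component before tapering.
    """
    total = np.zeros(n)
    lock_comp = None
    for name, weight in band_mix.items():
        if weight <= 0:
            continue
        lo, hi = BAND_EDGES[name]
        comp = band_noise(n, fs, lo, hi, rng) * math.sqrt(weight)
        total += comp
        if (lo, hi) == tuple(lock_band):
            lock_comp = comp
    if lock_comp is None:
        lock_comp = band_noise(n, fs, lock_band[0], lock_band[1], rng)
    s = total.std()
    if s > 0:
        total /= s
    phase = np.angle(hilbert(lock_comp))
    total *= _cosine_taper(n, int(round(0.1 * fs)))
    return total, phase


def _spike_kernel(fs: float) -> np.ndarray:
    """Biphasic extracellular spike waveform (~1.2 ms), unit negative peak."""
    n = max(3, int(round(1.2e-3 * fs)))
    t = np.linspace(0, 1, n)
    w = -np.sin(np.pi * t) + 0.35 * np.sin(2 * np.pi * t)
    return w / abs(w.min())


def _draw_spike_times(
    phase: np.ndarray,
    fs: float,
    start_s: float,
    rate_hz: float,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson spike count with von Mises phase preference within a burst."""
    dur = len(phase) / fs
    n_sp = rng.poisson(rate_hz * dur)
    if n_sp == 0:
        return np.zeros(0)
    targets = rng.vonmises(0.0, kappa, size=n_sp) if kappa > 0 else rng.uniform(-np.pi, np.pi, n_sp)
    times = np.empty(n_sp)
    for i, theta in enumerate(targets):
        d = np.abs(np.angle(np.exp(1j * (phase - theta))))
        close = np.flatnonzero(d < 0.1)
        idx = int(rng.choice(close)) if len(close) else int(np.argmin(d))
        times[i] = start_s + idx / fs
    return np.unique(times)  # sorted; drops same-sample duplicates


def gen_neonatal_session(
    params: NeonatalLfpParams,
    concentrations: Sequence[tuple[float, float]] | None = None,
    region: str = "PFC",
) -> tuple[TimeSeriesRecording, GroundTruth]:
    """Generate one discontinuous neonatal LFP channel plus ground truth.

    Active-period starts follow a thinned Poisson process: candidates at
    the baseline rate are accepted with probability ``dose_response(level)``
    for the concentration in force at the candidate time, and rejected when
    they would overlap (or come within 300 ms of) an already placed burst.
    The within-burst band mix, burst-amplitude law and within-burst firing
    are identical at every concentration.
    """
    concentrations = list(concentrations or [(0.0, 0.0)])
    if concentrations and max(t for t, _ in concentrations) >= params.duration_s:
        raise InvalidParameterError("duration must cover all concentration segments")
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate_hz
    n = int(round(params.duration_s * fs))
    signal = colored_noise(
        n, fs, params.aperiodic_exponent, params.noise_sd_uv, rng, flatten_below_hz=1.0
    )
    # burst SNR is defined against the background's RMS in the 1-100 Hz
    # detection band, so "SNR >= 3" means detectable by the RMS detector
    hi = min(100.0, 0.45 * fs)
    bg_band_rms = float(filter_array(signal, 1.0, hi, fs).std())

    # --- burst placement: thinned Poisson with overlap rejection.
    # Candidates are drawn at a dead-time-compensated rate so the *realized*
    # initiation rate equals burst_rate_hz * dose_factor(level): for an
    # exponential-gap process with refractory dead time D per accepted burst,
    # drawing candidates at r / (1 - r d D) and thinning by d yields rate r d.
    mean_dur, sd_dur = params.burst_duration_s
    guard = 0.3  # s, keeps true events separated beyond the detector merge gap
    a = (params.burst_min_duration_s - mean_dur) / sd_dur if sd_dur > 0 else 0.0
    # E[max(min_dur, Normal(mean, sd))]
    e_dur = (
        params.burst_min_duration_s * norm.cdf(a)
        + mean_dur * (1.0 - norm.cdf(a))
        + sd_dur * norm.pdf(a)
    )
    dead = e_dur + guard
    r = params.burst_rate_hz

    def _cand_rate(d: float) -> float:
        return r / max(0.2, 1.0 - r * d * dead)

    r_max = _cand_rate(1.0)
    events: list[TrueBurst] = []
    t = rng.exponential(1.0 / r_max)
    last_stop = -guard
    while t < params.duration_s:
        level = _level_at(concentrations, t)
        d = params.dose_factor(level)
        accept = rng.uniform() < _cand_rate(d) * d / r_max
        dur = max(params.burst_min_duration_s, rng.normal(mean_dur, sd_dur))
        if accept and t >= last_stop + guard and t + dur <= params.duration_s:
            snr = rng.lognormal(
                math.log(params.burst_snr_mean) - params.burst_snr_spread**2 / 2,
                params.burst_snr_spread,
            )
            events.append(TrueBurst(start_s=t, stop_s=t + dur, snr=snr, level=level))
            last_stop = t + dur
        t += rng.exponential(1.0 / r_max)

    # --- burst waveforms and phase-locked spikes
    label = f"{region}1"
    spike_times: list[float] = []
    kernel = _spike_kernel(fs)
    for ev in events:
        i0 = int(round(ev.start_s * fs))
        i1 = int(round(ev.stop_s * fs))
        wave, phase = _burst_waveform(
            i1 - i0, fs, params.burst_band_mix, params.spike_lock_band, rng
        )
        signal[i0:i1] += wave * ev.snr * bg_band_rms
        if params.spike_rate_hz > 0:
            st = _draw_spike_times(
                phase, fs, ev.start_s, params.spike_rate_hz, params.spike_lock_kappa, rng
            )
            spike_times.extend(st.tolist())
            for s in st:
                j = int(round(s * fs))
                seg = signal[j: j + len(kernel)]
                seg += params.spike_amp_uv * kernel[: len(seg)]

    n_minutes = int(math.ceil(params.duration_s / 60.0))
    conc_pm = np.array(
        [_level_at(concentrations, 60.0 * m + 30.0) for m in range(n_minutes)]
    )
    rec = TimeSeriesRecording(
        data=signal[np.newaxis, :],
        sampling_rate_hz=fs,
        channel_labels=[label],
        modality="LFP",
        region_of_channel={label: region},
        timeline=[(float(t0), float(c)) for t0, c in concentrations],
    )
    truth = GroundTruth(
        events=events,
        spike_times={label: np.asarray(sorted(spike_times))},
        artifact_mask=np.zeros(int(math.ceil(params.duration_s / 5.0)), dtype=bool),
        concentration_per_minute=conc_pm,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# juvenile (continuous) sessions
# ---------------------------------------------------------------------------

def gen_juvenile_session(
    params: NeonatalLfpParams,
    concentrations: Sequence[tuple[float, float]] | None = None,
    region: str = "PFC",
) -> tuple[TimeSeriesRecording, GroundTruth]:
    """Continuous LFP with dose-dependent band-power shifts.

    The burst process is disabled; oscillatory activity covers the whole
    trace.  Each canonical band's *log power* is offset by
    ``band_dose_slopes[band] * concentration`` (natural-log units), so a
    positive delta slope raises delta power under anesthesia while negative
    beta/gamma slopes suppress fast activity.
    """
    concentrations = list(concentrations or [(0.0, 0.0)])
    if concentrations and max(t for t, _ in concentrations) >= params.duration_s:
        raise InvalidParameterError("duration must cover all concentration segments")
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate_hz
    n = int(round(params.duration_s * fs))
    times = np.arange(n) / fs
    conc = np.array([_level_at(concentrations, t) for t in times])

    background = colored_noise(
        n, fs, params.aperiodic_exponent, 0.3 * params.noise_sd_uv, rng, flatten_below_hz=1.0
    )
    total_w = sum(params.burst_band_mix.values())
    signal = background.copy()
    for name, weight in params.burst_band_mix.items():
        if weight <= 0:
            continue
        lo, hi = BAND_EDGES[name]
        comp = band_noise(n, fs, lo, hi, rng)
        slope = params.band_dose_slopes.get(name, 0.0)
        gain = np.exp(0.5 * slope * conc)  # amplitude gain: ln-power offset = slope * conc
        signal += comp * gain * params.noise_sd_uv * math.sqrt(weight / total_w)

    label = f"{region}1"
    n_minutes = int(math.ceil(params.duration_s / 60.0))
    rec = TimeSeriesRecording(
        data=signal[np.newaxis, :],
        sampling_rate_hz=fs,
        channel_labels=[label],
        modality="LFP",
        region_of_channel={label: region},
        timeline=[(float(t0), float(c)) for t0, c in concentrations],
    )
    truth = GroundTruth(
        events=[],
        spike_times={},
        artifact_mask=np.zeros(int(math.ceil(params.duration_s / 5.0)), dtype=bool),
        concentration_per_minute=np.array(
            [_level_at(concentrations, 60.0 * m + 30.0) for m in range(n_minutes)]
        ),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# infant EEG sessions
# ---------------------------------------------------------------------------

def gen_infant_session(params: InfantEegParams) -> tuple[TimeSeriesRecording, GroundTruth]:
    """Generate a multichannel infant EEG session plus ground truth.

    All channels share band-limited sources (1-50 Hz in 5-Hz bands) with
    per-channel topographic gains, so information survives common-average
    referencing; broadband amplitude is modulated multiplicatively by
    ``1 + amplitude_dose_slope * concentration`` and each band additionally
    by its own log-power slope.  Artifact epochs are injected per
    ``artifact_spec`` on the 5-s epoch grid and recorded in the ground
    truth; the session must retain at least 20 artifact-free minutes.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate_hz
    n_min = params.duration_min
    n = int(round(n_min * 60 * fs))
    n_ch = params.n_channels
    labels = params.labels()

    conc_pm = params.concentration_per_minute()
    conc = np.repeat(conc_pm, int(round(60 * fs)))[:n]
    amp_gain = np.clip(1.0 + params.amplitude_dose_slope * conc, 0.05, None)

    band_edges = [(1.0 + 5.0 * b, 6.0 + 5.0 * b) for b in range(10)]  # 1-50 Hz, 5-Hz bins
    band_slopes = np.asarray(params.band_dose_slopes, dtype=float)
    if band_slopes.size == 0:
        band_slopes = np.zeros(len(band_edges))
    if band_slopes.size != len(band_edges):
        raise InvalidParameterError("band_dose_slopes needs one value per 5-Hz band")
    centers = np.array([(lo + hi) / 2 for lo, hi in band_edges])
    weights = centers ** -2.0
    weights /= weights.sum()

    data = rng.standard_normal((n_ch, n)) * params.sensor_noise_uv
    for b, (lo, hi) in enumerate(band_edges):
        src = band_noise(n, fs, lo, hi, rng)
        gains = rng.uniform(0.5, 1.5, size=n_ch)
        band_gain = np.exp(0.5 * band_slopes[b] * conc)
        comp = src * band_gain * amp_gain * params.base_amplitude_uv * math.sqrt(weights[b])
        data += gains[:, np.newaxis] * comp[np.newaxis, :]

    # --- artifacts on the 5-s epoch grid
    epoch_len = int(round(5.0 * fs))
    n_epochs = int(math.ceil(n / epoch_len))
    spec = params.artifact_spec
    mask = np.zeros(n_epochs, dtype=bool)
    if spec.total:
        if spec.total > n_epochs:
            raise InvalidParameterError("more artifact epochs requested than epochs available")
        chosen = rng.choice(n_epochs, size=spec.total, replace=False)
        kinds = (
            ["saturation"] * spec.n_saturation_epochs
            + ["transient"] * spec.n_transient_epochs
            + ["high_median"] * spec.n_high_median_epochs
        )
        for e, kind in zip(chosen, kinds):
            mask[e] = True
            i0 = e * epoch_len
            i1 = min(i0 + epoch_len, n)
            if kind == "saturation":
                ch = int(rng.integers(n_ch))
                j1 = min(i0 + int(round(0.5 * fs)), i1)
                data[ch, i0:j1] = spec.saturation_value_uv
            elif kind == "transient":
                ch = int(rng.integers(n_ch))
                width = min(int(round(0.2 * fs)), i1 - i0)
                j0 = int(rng.integers(i0, max(i0 + 1, i1 - width)))
                data[ch, j0: j0 + width] += spec.transient_amplitude_uv * _cosine_taper(width, width // 4)
            else:  # high_median: all channels raised for 2 s
                j1 = min(i0 + int(round(2.0 * fs)), i1)
                data[:, i0:j1] *= 8.0

    # inclusion rule: a usable synthetic subject has >= 20 artifact-free minutes
    epochs_per_min = 12
    bad_minutes = {
        m
        for m in range(n_min)
        if mask[m * epochs_per_min: (m + 1) * epochs_per_min].sum() * 5.0 > 10.0
    }
    if n_min - len(bad_minutes) < 20:
        raise InvalidParameterError(
            "session would retain fewer than 20 artifact-free minutes; "
            "lengthen the session or reduce artifact counts"
        )

    rec = TimeSeriesRecording(
        data=data,
        sampling_rate_hz=fs,
        channel_labels=labels,
        modality="EEG",
        region_of_channel={lab: "scalp" for lab in labels},
        timeline=[(60.0 * m, float(c)) for m, c in enumerate(conc_pm)],
    )
    truth = GroundTruth(
        events=[],
        spike_times={},
        artifact_mask=mask,
        concentration_per_minute=conc_pm,
    )
    return rec, truth
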