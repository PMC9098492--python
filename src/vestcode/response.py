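"""Firing-rate construction and gain/phase system identification.

Spike trains are converted to a binary sequence at 1 kHz (1000 in a 1-ms
bin containing a spike, 0 otherwise) whose mean is the firing rate in
spk/s. The continuous firing rate is obtained by zero-phase low-pass
filtering with a Kaiser-window FIR whose cutoff sits 0.5 Hz above the
stimulus frequency (17.5 Hz for broadband naturalistic stimuli).

Two estimators quantify the rate/stimulus relation:

* for periodic stimuli (sinusoids, ramp windows), the rate is aligned to
  the stimulus at the cross-correlation peak; the phase follows from the
  lag and the gain is the least-squares slope of rate against the aligned
  stimulus;
* for naturalistic stimuli, gain and phase are the modulus and argument
  of the cross-spectrum between stimulus and rate divided by the stimulus
  power spectrum (segment-averaged periodograms, band-averaged at the
  evaluation frequencies).

Phase is reported in degrees with positive values meaning the response
leads the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .stimuli import HeadVelocityTrace, SpikeTrain, generate_spikes, ramp_envelope

__all__ = [
    "RateSequence",
    "FrequencyResponse",
    "SpectrumWithBand",
    "spikes_to_binary",
    "kaiser_lowpass",
    "gain_phase_xcorr",
    "gain_phase_spectral",
    "spectrum_with_poisson_band",
    "ramp_gain_profile",
    "orient_type_ii",
]

FS = 1000.0
NATURALISTIC_CUTOFF = 17.5  # Hz; 0.5 Hz above the highest natural-range frequency
KAISER_BETA = 8.0
KAISER_TRANSITION_HZ = 1.0
SPECTRUM_SEGMENT_S = 4.0  # 0.25-Hz resolution


@dataclass
class RateSequence:
    """A 1-kHz sequence in spk/s: the scaled binary spike sequence or a filtered rate."""

    samples: np.ndarray
    kind: str = "filtered"  # {"binary_scaled", "filtered"}
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.kind == "binary_scaled":
            vals = np.unique(self.samples)
            if not np.all(np.isin(vals, (0.0, 1000.0))):
                raise ValueError("binary_scaled samples must be exactly 0 or 1000")
        elif not np.all(np.isfinite(self.samples)):
            raise ValueError("filtered samples must be finite")

    @property
    def mean_rate(self) -> float:
        return float(self.samples.mean())

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([np.arange(self.samples.size) / 1000.0,
                                          self.samples]),
                   fmt="%.6g", delimiter=",", header="time_s,rate_spk_s", comments="")

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "filtered",
                 source: str = "") -> "RateSequence":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 1], kind, source)


@dataclass
class FrequencyResponse:
    """Gain (spk/s per deg/s) and phase (deg, positive = response leads) per frequency."""

    frequencies: np.ndarray
    gain: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        self.phase = wrap_phase_deg(np.asarray(self.phase, dtype=float))
        if np.any(self.gain < 0):
            raise ValueError("gain must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"frequency_hz": self.frequencies, "gain": self.gain, "phase_deg": self.phase}
        ).to_csv(path, index=False)


@dataclass
class SpectrumWithBand:
    """Power spectrum of a rate sequence with a 95% homogeneous-Poisson reference band."""

    frequencies: np.ndarray
    power: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    band_center: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"frequency_hz": self.frequencies, "power": self.power,
             "band_low": self.band_low, "band_center": self.band_center,
             "band_high": self.band_high}
        ).to_csv(path, index=False)


def wrap_phase_deg(phase: np.ndarray | float):
    """Wrap phase in degrees to (-180, 180]."""
    wrapped = np.mod(np.asarray(phase, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def spikes_to_binary(spikes: SpikeTrain) -> RateSequence:
    """Discretize spike times into 1-ms bins: 1000 if a spike fell in [i, i+1) ms."""
    if spikes.spike_times.size and np.any(np.diff(spikes.spike_times) <= 0):
        raise ValueError("spike times must be sorted")
    n = round(spikes.duration * 1000)
    seq = np.zeros(n)
    idx = np.floor(spikes.spike_times * 1000).astype(int)
    seq[idx] = 1000.0
    return RateSequence(seq, "binary_scaled", spikes.neuron_label)


def _kaiser_fir(cutoff: float, fs: float, max_taps: int) -> np.ndarray:
    """Symmetric Kaiser-window FIR, beta=8, ~1-Hz transition width, unit DC gain."""
    attenuation_db = KAISER_BETA / 0.1102 + 8.7
    numtaps, _ = signal.kaiserord(attenuation_db, KAISER_TRANSITION_HZ / (fs / 2))
    numtaps = min(numtaps | 1, max_taps | 1)  # odd length, bounded by signal size
    return signal.firwin(numtaps, cutoff, window=("kaiser", KAISER_BETA), fs=fs)


def kaiser_lowpass(
    seq: RateSequence | np.ndarray,
    stimulus_frequency: float | None = None,
    cutoff: float | None = None,
    fs: float = FS,
) -> RateSequence:
    """Zero-phase Kaiser low-pass of a rate sequence.

    The cutoff is ``stimulus_frequency + 0.5`` Hz for single-frequency
    stimuli; pass ``cutoff=17.5`` (the default when neither argument is
    given) for naturalistic stimuli. The symmetric FIR is applied centered
    with reflected edges, so filtering introduces no phase shift and the
    DC gain is exactly 1.
    """
    x = np.asarray(getattr(seq, "samples", seq), dtype=float)
    source = getattr(seq, "source", "")
    if cutoff is None:
        cutoff = NATURALISTIC_CUTOFF if stimulus_frequency is None else stimulus_frequency + 0.5
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    h = _kaiser_fir(cutoff, fs, max_taps=max(3, x.size - 1))
    h = h / h.sum()
    pad = h.size // 2
    xp = np.pad(x, pad, mode="reflect")
    y = signal.fftconvolve(xp, h, mode="same")[pad:-pad]
    return RateSequence(y, "filtered", source)


def _xcorr_peak_lag(rate: np.ndarray, stim: np.ndarray, max_lag: int) -> float:
    """Lag (in samples, sub-sample interpolated) at the cross-correlation peak.

    Positive lag means ``rate`` lags ``stim`` (rate[t] tracks stim[t - lag]).
    The search is restricted to ``|lag| <= max_lag``; ties break toward
    smaller ``|lag|``.
    """
    r = rate - rate.mean()
    s = stim - stim.mean()
    # c[k] = mean_t r[t] * s[t - k] for k in [-max_lag, max_lag]; dividing by
    # the overlap count removes the finite-record bias toward zero lag
    full = signal.correlate(r, s, mode="full", method="fft")
    mid = s.size - 1
    lags = np.arange(-max_lag, max_lag + 1)
    c = full[mid + lags] / (s.size - np.abs(lags))
    order = np.lexsort((np.abs(lags), -c))  # max c, then smaller |lag|
    best = order[0]
    lag = float(lags[best])
    if 0 < best < c.size - 1:  # parabolic refinement
        y0, y1, y2 = c[best - 1], c[best], c[best + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag += 0.5 * (y0 - y2) / denom
    return lag


def _aligned_slope(rate: np.ndarray, stim: np.ndarray, lag: float) -> float:
    """Least-squares slope of rate against the lag-aligned stimulus."""
    shift = int(round(lag))
    if shift > 0:
        r, s = rate[shift:], stim[: stim.size - shift]
    elif shift < 0:
        r, s = rate[:shift], stim[-shift:]
    else:
        r, s = rate, stim
    s = s - s.mean()
    return float(np.dot(s, r - r.mean()) / np.dot(s, s))


def gain_phase_xcorr(
    rate: RateSequence | np.ndarray,
    stim: HeadVelocityTrace,
    frequency: float | None = None,
) -> tuple[float, float]:
    """Gain and phase of a rate response to a periodic stimulus.

    The rate is aligned to the stimulus at the cross-correlation peak
    (search limited to half a stimulus period); the phase in degrees is
    ``360 * frequency * lag`` (positive = response leads) and the gain is
    the least-squares slope of the rate versus the aligned stimulus.
    """
    r = np.asarray(getattr(rate, "samples", rate), dtype=float)
    s = stim.samples
    if r.size != s.size:
        raise ValueError("rate and stimulus must have equal length")
    if s.std() == 0:
        raise ValueError("stimulus has zero variance")
    if frequency is None:
        frequency = stim.kind_params.get("frequency")
    if frequency is None:
        raise ValueError("stimulus frequency required for the periodic estimator")
    half_period = max(1, int(stim.sample_rate / frequency / 2))
    lag = _xcorr_peak_lag(r, s, min(half_period, s.size // 2 - 1))
    # a rate that leads the stimulus peaks at negative lag
    phase = float(wrap_phase_deg(-360.0 * frequency * lag / stim.sample_rate))
    gain = _aligned_slope(r, s, lag)
    return gain, phase


def gain_phase_spectral(
    rate: RateSequence | np.ndarray,
    stim: HeadVelocityTrace,
    eval_frequencies=None,
    power_floor_fraction: float = 1e-4,
    band_halfwidth: float = 0.25,
) -> FrequencyResponse:
    """Cross-spectral transfer-function estimate for broadband stimuli.

    ``H(f) = P_sr(f) / P_ss(f)`` from Hann-windowed, 50%-overlap
    segment-averaged spectra (4-s segments, 0.25-Hz resolution), with
    complex band averaging over ``+/- band_halfwidth`` around each
    evaluation frequency. Frequencies where the stimulus power falls below
    ``power_floor_fraction`` of its maximum are rejected.
    """
    from .stimuli import STUDY_FREQUENCIES

    r = np.asarray(getattr(rate, "samples", rate), dtype=float)
    s = stim.samples
    if r.size != s.size:
        raise ValueError("rate and stimulus must have equal length")
    if eval_frequencies is None:
        eval_frequencies = STUDY_FREQUENCIES
    eval_frequencies = np.asarray(eval_frequencies, dtype=float)
    fs = stim.sample_rate
    nperseg = min(int(SPECTRUM_SEGMENT_S * fs), s.size)
    freqs, pss = signal.welch(s, fs, nperseg=nperseg)
    _, psr = signal.csd(s, r, fs, nperseg=nperseg)
    floor = power_floor_fraction * pss.max()
    gains, phases = [], []
    for fe in eval_frequencies:
        band = np.abs(freqs - fe) <= band_halfwidth + 1e-9
        band &= freqs > 0
        if not band.any() or pss[band].mean() < floor:
            raise ValueError(f"stimulus power below floor at {fe} Hz")
        h = psr[band].mean() / pss[band].mean()
        gains.append(np.abs(h))
        phases.append(np.degrees(np.angle(h)))
    return FrequencyResponse(eval_frequencies, np.array(gains), np.array(phases))


def spectrum_with_poisson_band(
    seq: RateSequence,
    n_boot: int = 100,
    seed: int = 0,
    fs: float = FS,
) -> SpectrumWithBand:
    """Power spectrum of a binary spike sequence with a 95% Poisson reference band.

    The band is built by simulating ``n_boot`` homogeneous spike trains at
    the sequence's mean rate, computing each spectrum with the identical
    estimator, and taking pointwise 2.5/97.5 percentiles; a flat spectrum
    is the signature of a constant-rate Poisson process.
    """
    if seq.kind != "binary_scaled":
        raise ValueError("expected a binary_scaled sequence")
    x = seq.samples
    nperseg = min(int(SPECTRUM_SEGMENT_S * fs), x.size)
    freqs, power = signal.welch(x - x.mean(), fs, nperseg=nperseg)
    mean_rate = seq.mean_rate
    boots = np.empty((n_boot, power.size))
    for b in range(n_boot):
        train = generate_spikes(np.zeros(x.size), resting_rate=mean_rate, seed=seed + b)
        xb = np.zeros(x.size)
        xb[np.floor(train.spike_times * 1000).astype(int)] = 1000.0
        _, boots[b] = signal.welch(xb - xb.mean(), fs, nperseg=nperseg)
    return SpectrumWithBand(
        freqs, power,
        np.percentile(boots, 2.5, axis=0),
        np.percentile(boots, 97.5, axis=0),
        boots.mean(axis=0),
    )


def ramp_gain_profile(
    rate: RateSequence | np.ndarray,
    stim: HeadVelocityTrace,
    window_s: float = 4.0,
) -> pd.DataFrame:
    """Windowed gain/phase of a response to a ramp stimulus.

    The record is cut into non-overlapping windows of ``window_s``
    seconds (each must hold at least two stimulus cycles); gain and phase
    are estimated per window with the periodic estimator and tagged with
    the envelope amplitude at the window midpoint. Ramp-up and ramp-down
    windows are averaged at matched amplitudes.

    Returns a DataFrame with columns ``amplitude``, ``gain``, ``phase_deg``.
    """
    r = np.asarray(getattr(rate, "samples", rate), dtype=float)
    if stim.kind != "ramp":
        raise ValueError("stimulus must be a ramp")
    freq = stim.kind_params["frequency"]
    peak = stim.kind_params["peak_amplitude"]
    ramp_dur = stim.kind_params["ramp_duration"]
    if window_s * freq < 2:
        raise ValueError("window must contain at least 2 stimulus cycles")
    wlen = int(window_s * stim.sample_rate)
    n_win = r.size // wlen
    rows = []
    for w in range(n_win):
        sl = slice(w * wlen, (w + 1) * wlen)
        t_mid = (w + 0.5) * window_s
        amp = float(ramp_envelope(np.array([t_mid]), peak, ramp_dur)[0])
        if amp <= 0:
            continue
        win_stim = HeadVelocityTrace(
            stim.samples[sl], stim.sample_rate, "ramp", stim.kind_params
        )
        gain, phase = gain_phase_xcorr(r[sl], win_stim, frequency=freq)
        rows.append({"amplitude": amp, "half": "up" if t_mid < ramp_dur else "down",
                     "gain": gain, "phase_deg": phase})
    df = pd.DataFrame(rows)
    # average the two halves at matched amplitudes (symmetric envelope)
    df["amplitude"] = df["amplitude"].round(6)
    out = (
        df.groupby("amplitude", as_index=False)
        .agg(gain=("gain", "mean"), phase_deg=("phase_deg", _circmean_deg))
        .sort_values("amplitude", ignore_index=True)
    )
    return out


def _circmean_deg(values) -> float:
    ang = np.radians(np.asarray(values, dtype=float))
    return float(np.degrees(np.angle(np.exp(1j * ang).mean())))


def orient_type_ii(stim: HeadVelocityTrace, neuron_type: str) -> HeadVelocityTrace:
    """Sign convention for neuron response polarity.

    Type I neurons (excited by ipsilateral rotation) use the stimulus as
    is; for type II neurons the head-velocity stimulus is inverted.
    """
    if neuron_type not in ("I", "II"):
        raise ValueError("neuron_type must be 'I' or 'II'")
    if neuron_type == "I":
        return stim
    return HeadVelocityTrace(-stim.samples, stim.sample_rate, stim.kind, dict(stim.kind_params))
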