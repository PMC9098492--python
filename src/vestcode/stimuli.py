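"""Synthesis of head-velocity stimuli and simulated spike trains.

Three stimulus classes drive every analysis in this package:

* **sinusoids** — single-frequency yaw rotations at constant amplitude
  (0.5–17 Hz, 15 deg/s), the classical probe for vestibular dynamics;
* **ramps** — a fixed-frequency sinusoid whose amplitude rises linearly
  from 0 to a peak (default 100 deg/s over 100 s) and back, used to
  measure gain as a function of stimulus amplitude;
* **naturalistic** traces — broadband noise emulating recorded self-motion:
  a power spectrum that decays with frequency, a slowly varying amplitude
  envelope (spectral content below ~2 Hz), and a near-Gaussian marginal
  velocity distribution with peaks well above the artificial stimuli.

Spike trains are drawn from firing-rate sequences with an independent
Bernoulli draw per 1-ms bin (an inhomogeneous Poisson process at this
resolution), matching the binary-sequence convention used throughout the
analysis: at most one spike per 1-ms bin.

All generators are pure functions of their parameters and seed. Sample
``i`` of a trace corresponds to time ``t = i / sample_rate`` (left-edge
convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "HeadVelocityTrace",
    "SpikeTrain",
    "NaturalisticGenParams",
    "generate_sinusoid",
    "generate_ramp",
    "generate_naturalistic",
    "generate_spikes",
    "ramp_envelope",
]

DEFAULT_SAMPLE_RATE = 1000.0
STUDY_FREQUENCIES = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 8.0, 17.0)
SINUSOID_AMPLITUDE = 15.0  # deg/s
RAMP_PEAK = 100.0  # deg/s
RAMP_DURATION = 100.0  # s each way


@dataclass
class HeadVelocityTrace:
    """Uniformly sampled yaw head velocity in deg/s.

    Parameters
    ----------
    samples
        Velocity per sample, deg/s.
    sample_rate
        Sampling rate in Hz (default 1000).
    kind
        One of ``{"naturalistic", "sinusoid", "ramp"}``.
    kind_params
        Generator metadata: frequency, amplitude, ramp peak/duration,
        seed and spectral parameters, as applicable.
    """

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    kind: str = "naturalistic"
    kind_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    def to_csv(self, path: str | Path) -> None:
        """Write a two-column CSV (time_s, velocity_deg_s) plus a JSON sidecar."""
        path = Path(path)
        arr = np.column_stack([self.times, self.samples])
        np.savetxt(path, arr, fmt="%.6g", delimiter=",",
                   header="time_s,velocity_deg_s", comments="")
        meta = {"sample_rate": self.sample_rate, "kind": self.kind,
                "kind_params": _jsonable(self.kind_params)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "HeadVelocityTrace":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        else:
            dt = float(np.median(np.diff(arr[:, 0])))
            meta = {"sample_rate": 1.0 / dt, "kind": "naturalistic", "kind_params": {}}
        return cls(arr[:, 1], meta["sample_rate"], meta["kind"], meta.get("kind_params", {}))


def _jsonable(d: dict) -> dict:
    return {k: (v.item() if isinstance(v, np.generic) else v) for k, v in d.items()}


@dataclass
class SpikeTrain:
    """Spike times in seconds on [0, duration), strictly increasing."""

    spike_times: np.ndarray
    duration: float
    neuron_label: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.spike_times[0] < 0 or self.spike_times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def to_txt(self, path: str | Path) -> None:
        np.savetxt(path, self.spike_times, fmt="%.6f")

    @classmethod
    def from_txt(cls, path: str | Path, duration: float, neuron_label: str = "") -> "SpikeTrain":
        times = np.atleast_1d(np.loadtxt(path))
        return cls(times, duration, neuron_label)


@dataclass
class NaturalisticGenParams:
    """Parameters of the naturalistic head-velocity generator.

    The synthesis recipe multiplies a band-limited noise carrier whose
    power decays as a Lorentzian, ``P(f) ∝ 1/(1 + (f/f0)^2)``, by an
    independent strictly positive slow envelope (low-pass filtered noise
    offset to positivity), then rescales the product to ``target_sd``.
    The mild envelope modulation depth keeps the marginal velocity
    distribution near-Gaussian while giving the trace the slow amplitude
    structure of recorded self-motion.

    Attributes
    ----------
    duration : float
        Trace length in seconds (>= 30 s recommended; at least 10
        envelope cycles are required).
    target_sd : float
        Sample standard deviation of the output, deg/s.
    carrier_f0 : float
        Lorentzian knee frequency of the carrier spectrum, Hz.
    carrier_band_limit : float
        Hard band limit of the carrier, Hz.
    envelope_cutoff : float
        Upper edge of the envelope's spectral content, Hz (default 2).
    envelope_depth : float
        Relative SD of the multiplicative envelope around its mean.
    seed : int
        Seed of the generator; identical seeds give identical traces.
    """

    duration: float = 300.0
    target_sd: float = 40.0
    carrier_f0: float = 1.0
    carrier_band_limit: float = 25.0
    envelope_cutoff: float = 2.0
    envelope_depth: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.envelope_cutoff <= 0:
            raise ValueError("envelope cutoff must be positive")
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")


def generate_sinusoid(
    frequency: float,
    amplitude: float = SINUSOID_AMPLITUDE,
    duration: float = 30.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> HeadVelocityTrace:
    """Constant-amplitude sinusoidal rotation, ``a*sin(2*pi*f*t)``."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if frequency >= sample_rate / 2:
        raise ValueError("frequency must be below Nyquist")
    t = np.arange(round(duration * sample_rate)) / sample_rate
    return HeadVelocityTrace(
        amplitude * np.sin(2 * np.pi * frequency * t),
        sample_rate,
        "sinusoid",
        {"frequency": frequency, "amplitude": amplitude},
    )


def ramp_envelope(t: np.ndarray, peak_amplitude: float, ramp_duration: float) -> np.ndarray:
    """Triangular amplitude envelope: 0 at t=0, peak at t=ramp_duration, 0 at 2*ramp_duration."""
    up = peak_amplitude * t / ramp_duration
    down = peak_amplitude * (2 - t / ramp_duration)
    return np.clip(np.minimum(up, down), 0.0, None)


def generate_ramp(
    frequency: float,
    peak_amplitude: float = RAMP_PEAK,
    ramp_duration: float = RAMP_DURATION,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> HeadVelocityTrace:
    """Sinusoid with a triangular amplitude envelope (ramp-up then ramp-down)."""
    if frequency >= sample_rate / 2:
        raise ValueError("frequency must be below Nyquist")
    t = np.arange(round(2 * ramp_duration * sample_rate)) / sample_rate
    env = ramp_envelope(t, peak_amplitude, ramp_duration)
    return HeadVelocityTrace(
        env * np.sin(2 * np.pi * frequency * t),
        sample_rate,
        "ramp",
        {"frequency": frequency, "peak_amplitude": peak_amplitude,
         "ramp_duration": ramp_duration},
    )


def generate_naturalistic(
    params: NaturalisticGenParams,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> HeadVelocityTrace:
    """Synthesize a naturalistic head-velocity trace.

    The output is zero-mean with sample SD equal to ``params.target_sd``,
    a power spectrum decaying over the natural range (0.5–17 Hz), and a
    Hilbert envelope whose spectral power is concentrated below
    ``params.envelope_cutoff``.
    """
    p = params
    n_env_cycles = p.duration * p.envelope_cutoff
    if n_env_cycles < 10:
        raise ValueError(
            f"duration too short: {n_env_cycles:.1f} envelope cycles, need >= 10"
        )
    n = round(p.duration * sample_rate)
    rng = np.random.default_rng(p.seed)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)

    # carrier: white noise shaped to a band-limited Lorentzian power spectrum
    shape = 1.0 / np.sqrt(1.0 + (freqs / p.carrier_f0) ** 2)
    shape[freqs > p.carrier_band_limit] = 0.0
    carrier = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * shape, n)
    carrier /= carrier.std()

    # slow positive envelope: low-pass noise around unity
    env_shape = (freqs < p.envelope_cutoff / 2.0).astype(float)
    env_noise = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * env_shape, n)
    env_noise /= env_noise.std()
    envelope = np.clip(1.0 + p.envelope_depth * env_noise, 0.05, None)

    out = carrier * envelope
    out = (out - out.mean()) / out.std() * p.target_sd
    meta = {"seed": p.seed, "target_sd": p.target_sd, "carrier_f0": p.carrier_f0,
            "envelope_cutoff": p.envelope_cutoff, "envelope_depth": p.envelope_depth}
    return HeadVelocityTrace(out, sample_rate, "naturalistic", meta)


def envelope_low_frequency_fraction(
    trace: HeadVelocityTrace, cutoff: float = 2.0
) -> float:
    """Fraction of the Hilbert-envelope spectral power at frequencies below ``cutoff``.

    Includes the DC component (the envelope has a large positive mean);
    used to verify that the amplitude structure of a trace is slow.
    """
    env = np.abs(hilbert(trace.samples))
    spec = np.abs(np.fft.rfft(env)) ** 2
    freqs = np.fft.rfftfreq(env.size, 1.0 / trace.sample_rate)
    return float(spec[freqs < cutoff].sum() / spec.sum())


def generate_spikes(
    rate,  # RateSequence or ndarray of spk/s at 1 kHz
    resting_rate: float = 0.0,
    seed: int = 0,
) -> SpikeTrain:
    """Draw a spike train from a firing-rate sequence.

    Each 1-ms bin spikes independently with probability
    ``clip(resting_rate + rate[i], 0, 1000) * 0.001``; at most one spike
    per bin, spike placed at the bin's left edge. Negative instantaneous
    rates are clipped to zero.
    """
    samples = np.asarray(getattr(rate, "samples", rate), dtype=float)
    prob = np.clip(resting_rate + samples, 0.0, 1000.0) * 1e-3
    rng = np.random.default_rng(seed)
    spikes = np.nonzero(rng.random(samples.size) < prob)[0]
    return SpikeTrain(spikes / 1000.0, samples.size / 1000.0)
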