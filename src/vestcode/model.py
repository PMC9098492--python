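"""Cascade models of vestibular-nuclei (VN) and thalamocortical (TC) neurons.

Both classes share a linear stage — the high-pass transfer function of
peripheral transduction and afferent filtering,

    T(f) = k * s (s*T1 + 1) / ((s*T2 + 1)(s*Tc + 1)),   s = 2*pi*i*f,

with k = 1.7207 spk/s/(deg/s), T1 = 0.06 s, T2 = 0.0006 s, Tc = 5.7 s —
followed by a bounded sigmoidal static nonlinearity

    SIG(X) = -25 + 50 / (1 + exp(-X/10))    (spk/s).

The TC class additionally applies instantaneous contrast gain control: the
stimulus is multiplied by a Lorentzian function of its own slowly varying
amplitude envelope A(t) (modulus of the analytic signal),

    G(t) = P1 / (P2 * A(t) + 1),     P1 = 2 spk/s/(deg/s), P2 = 0.037 s/deg,

so that response gain falls as stimulus amplitude grows. A fitted
degree-6 output polynomial maps the sigmoid output onto the observed
firing-rate range; it defaults to the identity. Model agreement is scored
with the variance-accounted-for, VAF = 1 - var(pred - actual)/var(actual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import hilbert

from .response import RateSequence
from .stimuli import HeadVelocityTrace

__all__ = [
    "LinearDynamicsParams",
    "GainControlParams",
    "EnvelopeDecomposition",
    "StaticNonlinearities",
    "NeuronModelParams",
    "transfer_function",
    "apply_linear_dynamics",
    "hilbert_decompose",
    "contrast_gain_scale",
    "sigmoid",
    "simulate_vn",
    "simulate_tc",
    "fit_lorentzian",
    "fit_output_nonlinearity",
    "vaf",
]


@dataclass
class LinearDynamicsParams:
    """Constants of the high-pass linear stage (spk/s per deg/s; seconds)."""

    k: float = 1.7207
    T1: float = 0.06
    T2: float = 0.0006
    Tc: float = 5.7

    def __post_init__(self) -> None:
        if min(self.T1, self.T2, self.Tc) <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class GainControlParams:
    """Lorentzian contrast-gain parameters: G(A) = P1 / (P2*A + 1)."""

    P1: float = 2.0  # spk/s per deg/s, gain in the zero-amplitude limit
    P2: float = 0.037  # s/deg, amplitude scale of gain decay

    def __post_init__(self) -> None:
        if self.P1 <= 0 or self.P2 < 0:
            raise ValueError("require P1 > 0 and P2 >= 0")

    def gain_at(self, amplitude) -> np.ndarray:
        return self.P1 / (self.P2 * np.asarray(amplitude, dtype=float) + 1.0)


@dataclass
class EnvelopeDecomposition:
    """Analytic-signal decomposition: amplitude, unwrapped phase, instantaneous frequency."""

    amplitude: np.ndarray
    analytic_phase: np.ndarray
    instantaneous_frequency: np.ndarray


@dataclass
class OutputPolynomial:
    """Degree-6 output nonlinearity with clamped extrapolation.

    Coefficients are in ``numpy.polynomial`` order (constant term first).
    Outside the fit domain the polynomial is held at its boundary values
    to prevent high-degree blow-up.
    """

    coefficients: np.ndarray | None = None
    domain: tuple[float, float] | None = None

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.coefficients is None:
            return x  # identity when unfitted
        lo, hi = self.domain
        return np.polynomial.polynomial.polyval(np.clip(x, lo, hi), self.coefficients)


@dataclass
class StaticNonlinearities:
    """Sigmoid constants plus the (optional) fitted output polynomial."""

    sigmoid_offset: float = -25.0
    sigmoid_range: float = 50.0
    sigmoid_slope_divisor: float = 10.0
    output_poly: OutputPolynomial = field(default_factory=OutputPolynomial)


@dataclass
class NeuronModelParams:
    """All constants of a model neuron.

    ``neuron_class`` is ``"VN"`` (no gain control) or ``"TC"`` (gain
    control present). ``gain_control_first`` selects the stage order for
    the TC cascade: gain control applied to the raw stimulus before the
    linear dynamics (the default) or after.
    """

    dynamics: LinearDynamicsParams = field(default_factory=LinearDynamicsParams)
    gain_control: GainControlParams | None = None
    nonlinearities: StaticNonlinearities = field(default_factory=StaticNonlinearities)
    resting_rate: float = 60.0
    neuron_class: str = "VN"
    gain_control_first: bool = True

    def __post_init__(self) -> None:
        if self.neuron_class not in ("VN", "TC"):
            raise ValueError("neuron_class must be 'VN' or 'TC'")
        if (self.neuron_class == "VN") != (self.gain_control is None):
            raise ValueError("gain_control must be absent iff neuron_class is VN")

    @classmethod
    def vn(cls, **kw) -> "NeuronModelParams":
        return cls(neuron_class="VN", gain_control=None, **kw)

    @classmethod
    def tc(cls, gain_control: GainControlParams | None = None, **kw) -> "NeuronModelParams":
        return cls(neuron_class="TC",
                   gain_control=gain_control or GainControlParams(), **kw)

    def to_json(self, path=None) -> str:
        import json

        d = {
            "dynamics": vars(self.dynamics),
            "gain_control": vars(self.gain_control) if self.gain_control else None,
            "sigmoid": {"offset": self.nonlinearities.sigmoid_offset,
                        "range": self.nonlinearities.sigmoid_range,
                        "slope_divisor": self.nonlinearities.sigmoid_slope_divisor},
            "output_poly": (
                None if self.nonlinearities.output_poly.coefficients is None
                else {"coefficients": list(map(float, self.nonlinearities.output_poly.coefficients)),
                      "domain": list(self.nonlinearities.output_poly.domain)}),
            "resting_rate": self.resting_rate,
            "neuron_class": self.neuron_class,
            "gain_control_first": self.gain_control_first,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NeuronModelParams":
        import json
        from pathlib import Path

        looks_like_path = isinstance(source, Path) or (
            isinstance(source, str) and "{" not in source)
        if looks_like_path and Path(source).exists():
            source = Path(source).read_text()
        d = json.loads(source)
        poly = OutputPolynomial()
        if d.get("output_poly"):
            poly = OutputPolynomial(np.asarray(d["output_poly"]["coefficients"]),
                                    tuple(d["output_poly"]["domain"]))
        sig = d.get("sigmoid", {})
        nl = StaticNonlinearities(
            sigmoid_offset=sig.get("offset", -25.0),
            sigmoid_range=sig.get("range", 50.0),
            sigmoid_slope_divisor=sig.get("slope_divisor", 10.0),
            output_poly=poly)
        gc = GainControlParams(**d["gain_control"]) if d.get("gain_control") else None
        return cls(dynamics=LinearDynamicsParams(**d["dynamics"]), gain_control=gc,
                   nonlinearities=nl, resting_rate=d["resting_rate"],
                   neuron_class=d["neuron_class"],
                   gain_control_first=d.get("gain_control_first", True))


def transfer_function(frequencies, p: LinearDynamicsParams | None = None) -> np.ndarray:
    """Complex T(f) of the linear stage, zero at DC."""
    p = p or LinearDynamicsParams()
    f = np.asarray(frequencies, dtype=float)
    s = 2j * np.pi * f
    return p.k * s * (s * p.T1 + 1) / ((s * p.T2 + 1) * (s * p.Tc + 1))


def apply_linear_dynamics(
    stim: HeadVelocityTrace | np.ndarray,
    p: LinearDynamicsParams | None = None,
    sample_rate: float = 1000.0,
) -> np.ndarray:
    """Filter a stimulus by T(f) in the frequency domain (real output, T(0)=0)."""
    x = np.asarray(getattr(stim, "samples", stim), dtype=float)
    sample_rate = getattr(stim, "sample_rate", sample_rate)
    freqs = np.fft.rfftfreq(x.size, 1.0 / sample_rate)
    T = transfer_function(freqs, p)
    T[0] = 0.0
    return np.fft.irfft(np.fft.rfft(x) * T, x.size)


def hilbert_decompose(
    stim: HeadVelocityTrace | np.ndarray,
    sample_rate: float = 1000.0,
    literal_frequency: bool = False,
) -> EnvelopeDecomposition:
    """Amplitude envelope and phase of the analytic signal of a stimulus.

    ``A(t)`` is the modulus of the analytic signal; the analytic phase is
    unwrapped. The instantaneous frequency is the time derivative of the
    unwrapped phase over ``2*pi`` (diagnostic only); set
    ``literal_frequency=True`` for the alternative convention
    ``phase / (2*pi*t)``, which is singular at t = 0.
    """
    x = np.asarray(getattr(stim, "samples", stim), dtype=float)
    sample_rate = getattr(stim, "sample_rate", sample_rate)
    analytic = hilbert(x)
    amplitude = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    if literal_frequency:
        t = np.arange(x.size) / sample_rate
        with np.errstate(divide="ignore", invalid="ignore"):
            finst = np.where(t > 0, phase / (2 * np.pi * np.where(t > 0, t, 1.0)), np.nan)
    else:
        finst = np.gradient(phase) * sample_rate / (2 * np.pi)
    return EnvelopeDecomposition(amplitude, phase, finst)


def contrast_gain_scale(
    stim: HeadVelocityTrace | np.ndarray,
    gp: GainControlParams,
    envelope: np.ndarray | None = None,
) -> np.ndarray:
    """Multiply the stimulus by the instantaneous contrast gain G(t).

    ``G(t) = P1 / (P2 * A(t) + 1)`` with A(t) the Hilbert envelope of the
    raw stimulus (or a caller-supplied envelope).
    """
    x = np.asarray(getattr(stim, "samples", stim), dtype=float)
    if envelope is None:
        envelope = hilbert_decompose(x).amplitude
    return gp.gain_at(envelope) * x


def sigmoid(x, nl: StaticNonlinearities | None = None) -> np.ndarray:
    """Bounded static nonlinearity SIG(X) = -25 + 50/(1 + exp(-X/10))."""
    nl = nl or StaticNonlinearities()
    x = np.asarray(x, dtype=float)
    return nl.sigmoid_offset + nl.sigmoid_range / (1.0 + np.exp(-x / nl.sigmoid_slope_divisor))


def sigmoid_inverse(y, nl: StaticNonlinearities | None = None,
                    margin: float = 1e-6) -> np.ndarray:
    """Inverse of the sigmoid, for linearizing observed rates before fitting.

    Values are clipped ``margin`` spk/s inside the sigmoid's open range so
    the inverse stays finite on noisy inputs (use a margin around 1 spk/s
    for spike-derived rates).
    """
    nl = nl or StaticNonlinearities()
    y = np.asarray(y, dtype=float)
    lo, hi = nl.sigmoid_offset, nl.sigmoid_offset + nl.sigmoid_range
    y = np.clip(y, lo + margin, hi - margin)
    return -nl.sigmoid_slope_divisor * np.log(nl.sigmoid_range / (y - nl.sigmoid_offset) - 1.0)


def simulate_vn(stim: HeadVelocityTrace, params: NeuronModelParams) -> RateSequence:
    """VN cascade: rate = clip(resting + SIG(T * S), 0)."""
    if params.neuron_class != "VN":
        raise ValueError("params must describe a VN neuron")
    x = sigmoid(apply_linear_dynamics(stim, params.dynamics), params.nonlinearities)
    rate = np.clip(params.resting_rate + x, 0.0, None)
    return RateSequence(rate, "filtered", "model:VN")


def simulate_tc(stim: HeadVelocityTrace, params: NeuronModelParams) -> RateSequence:
    """TC cascade: contrast gain control, linear dynamics, sigmoid, output polynomial.

    With the default stage order the raw stimulus is gain-scaled before
    the linear dynamics; ``params.gain_control_first=False`` applies the
    gain (still computed from the raw-stimulus envelope) to the output of
    the linear stage instead.
    """
    if params.neuron_class != "TC":
        raise ValueError("params must describe a TC neuron")
    if params.gain_control_first:
        scaled = contrast_gain_scale(stim, params.gain_control)
        pre = apply_linear_dynamics(scaled, params.dynamics, stim.sample_rate)
    else:
        env = hilbert_decompose(stim).amplitude
        pre = params.gain_control.gain_at(env) * apply_linear_dynamics(stim, params.dynamics)
    x = params.nonlinearities.output_poly(sigmoid(pre, params.nonlinearities))
    rate = np.clip(params.resting_rate + x, 0.0, None)
    return RateSequence(rate, "filtered", "model:TC")


def tc_pre_nonlinearity(stim: HeadVelocityTrace, params: NeuronModelParams) -> np.ndarray:
    """TC cascade output after the sigmoid but before the output polynomial (spk/s)."""
    if params.neuron_class != "TC":
        raise ValueError("params must describe a TC neuron")
    if params.gain_control_first:
        scaled = contrast_gain_scale(stim, params.gain_control)
        pre = apply_linear_dynamics(scaled, params.dynamics, stim.sample_rate)
    else:
        env = hilbert_decompose(stim).amplitude
        pre = params.gain_control.gain_at(env) * apply_linear_dynamics(stim, params.dynamics)
    return sigmoid(pre, params.nonlinearities)


def fit_transfer_function(
    frequencies, gains, phases_deg
) -> tuple[LinearDynamicsParams, float]:
    """Least-squares fit of the parametric T(f) form to gain/phase samples.

    All four constants (k, T1, T2, Tc) are free and constrained positive
    via a log parameterization; the residual is the stacked real and
    imaginary mismatch of the complex response. Returns the fitted
    parameters and the residual norm.
    """
    from scipy.optimize import least_squares

    f = np.asarray(frequencies, dtype=float)
    target = np.asarray(gains, dtype=float) * np.exp(1j * np.radians(phases_deg))

    def resid(logp):
        k, T1, T2, Tc = np.exp(logp)
        model_T = transfer_function(f, LinearDynamicsParams(k, T1, T2, Tc))
        d = model_T - target
        return np.concatenate([d.real, d.imag])

    x0 = np.log([1.0, 0.01, 0.001, 1.0])
    sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    k, T1, T2, Tc = np.exp(sol.x)
    return LinearDynamicsParams(float(k), float(T1), float(T2), float(Tc)), float(
        np.linalg.norm(sol.fun))


def fit_lorentzian(amplitudes, gains) -> tuple[GainControlParams, float]:
    """Least-squares fit of G(A) = P1/(P2*A + 1) to gain-versus-amplitude data.

    Returns the fitted parameters and the residual norm. Requires at
    least three distinct non-negative amplitudes.
    """
    A = np.asarray(amplitudes, dtype=float)
    g = np.asarray(gains, dtype=float)
    if np.any(A < 0):
        raise ValueError("amplitudes must be non-negative")
    if np.unique(A).size < 3:
        raise ValueError("need at least 3 distinct amplitudes")

    def lorentz(a, p1, p2):
        return p1 / (p2 * a + 1.0)

    p0 = (max(g.max(), 1e-6), 0.01)
    popt, _ = curve_fit(lorentz, A, g, p0=p0, bounds=([1e-9, 0.0], [np.inf, np.inf]),
                        maxfev=20000)
    residual = float(np.linalg.norm(g - lorentz(A, *popt)))
    return GainControlParams(P1=float(popt[0]), P2=float(popt[1])), residual


def fit_output_nonlinearity(
    pre_nl_prediction: RateSequence | np.ndarray,
    actual: RateSequence | np.ndarray,
    n_bins: int = 100,
    degree: int = 6,
    min_occupied: int = 20,
) -> OutputPolynomial:
    """Fit the degree-6 output polynomial mapping pre-nonlinearity prediction to rate.

    The prediction axis is discretized into ``n_bins`` equal-width bins
    over its observed range; the actual rate is averaged within each
    occupied bin and a polynomial is least-squares fitted to the
    (bin center, mean rate) pairs. Empty bins are skipped; fewer than
    ``min_occupied`` occupied bins is an error.
    """
    x = np.asarray(getattr(pre_nl_prediction, "samples", pre_nl_prediction), dtype=float)
    y = np.asarray(getattr(actual, "samples", actual), dtype=float)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = counts > 0
    if occupied.sum() < min_occupied:
        raise ValueError(f"only {occupied.sum()} occupied bins, need >= {min_occupied}")
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    xc = centers[occupied]
    yc = sums[occupied] / counts[occupied]
    coeffs = np.polynomial.polynomial.polyfit(xc, yc, degree)
    return OutputPolynomial(coeffs, (float(xc.min()), float(xc.max())))


def vaf(predicted, actual) -> float:
    """Variance accounted for: 1 - var(pred - actual)/var(actual); <= 1."""
    p = np.asarray(getattr(predicted, "samples", predicted), dtype=float)
    a = np.asarray(getattr(actual, "samples", actual), dtype=float)
    if p.size != a.size:
        raise ValueError("sequences must have equal length")
    va = a.var()
    if va == 0:
        raise ValueError("actual sequence has zero variance")
    return float(1.0 - (p - a).var() / va)
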