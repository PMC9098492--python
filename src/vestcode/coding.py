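"""Coding ambiguity, fractional sensory representations, and optimal tuning.

The ambiguity of a rate code for instantaneous stimulus value is
``1 - |R|``, with R the Pearson correlation between firing rate and
stimulus: 0 means a perfect linear readout of the instantaneous stimulus,
1 means none. Variants align the rate to the stimulus first (compensating
pure time shifts) or restrict the analysis to epochs where the stimulus
amplitude stays below a threshold.

A continuum of sensory representations of head motion — position
(alpha = -1) through velocity (0) to acceleration (+1) — is generated by
fractional differentiation, a frequency-domain filter

    H_alpha(f) = (2*pi*f)^alpha * exp(i*alpha*pi/2),

each order shifting phase by 90*alpha degrees. Efficient-coding theory
predicts that an optimal tuning curve is proportional to the cumulative
distribution of the represented variable (histogram equalization); the
optimality score compares a neuron's measured tuning curve to that
prediction across orders alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .response import RateSequence
from .stimuli import HeadVelocityTrace

__all__ = [
    "AmbiguityResult",
    "SensoryRepresentation",
    "TuningCurve",
    "OptimalityResult",
    "ambiguity",
    "ambiguity_phase_aligned",
    "ambiguity_thresholded",
    "fractional_differentiate",
    "best_alpha",
    "tuning_curve",
    "optimal_tuning",
    "optimality",
    "optimality_profile",
]

AMBIGUITY_THRESHOLDS = (30.0, 60.0, 90.0, 120.0, 150.0, np.inf)
DEFAULT_ALPHA_GRID = np.round(np.arange(-1.0, 1.0001, 0.05), 10)


@dataclass
class AmbiguityResult:
    """Ambiguity 1-|R| plus provenance of the variant that produced it."""

    value: float
    condition: str = ""
    variant: str = "plain"  # {"plain", "phase_aligned", "thresholded"}
    threshold: float = np.inf
    retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("ambiguity must lie in [0, 1]")
        if not 0.0 < self.retained_fraction <= 1.0:
            raise ValueError("retained_fraction must lie in (0, 1]")


@dataclass
class SensoryRepresentation:
    """A fractionally differentiated stimulus of order alpha in [-1, 1]."""

    alpha: float
    transformed: np.ndarray
    sample_rate: float = 1000.0

    @property
    def equivalent_phase(self) -> float:
        """Phase shift relative to velocity, deg (90 * alpha)."""
        return 90.0 * self.alpha


@dataclass
class TuningCurve:
    """Mean firing rate per stimulus-representation bin."""

    bin_centers: np.ndarray
    mean_rate: np.ndarray
    counts: np.ndarray


@dataclass
class OptimalityResult:
    """Optimality versus representation order, with the best order."""

    alphas: np.ndarray
    optimality_values: np.ndarray
    best_alpha: float
    max_optimality: float
    optimal_curve: TuningCurve | None = None

    @property
    def best_equivalent_phase(self) -> float:
        return 90.0 * self.best_alpha


def _corr(rate, stim) -> float:
    r = np.asarray(getattr(rate, "samples", rate), dtype=float)
    s = np.asarray(getattr(stim, "samples", stim), dtype=float)
    if r.size != s.size:
        raise ValueError("rate and stimulus must have equal length")
    if r.std() == 0 or s.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(r, s)[0, 1])


def ambiguity(
    rate: RateSequence | np.ndarray,
    stim: HeadVelocityTrace | np.ndarray,
    condition: str = "",
    method: str = "pearson",
) -> AmbiguityResult:
    """Ambiguity 1-|R| between a firing rate and the instantaneous stimulus.

    ``method`` selects Pearson (default) or Spearman correlation.
    """
    if method == "pearson":
        r = _corr(rate, stim)
    elif method == "spearman":
        rr = np.asarray(getattr(rate, "samples", rate), dtype=float)
        ss = np.asarray(getattr(stim, "samples", stim), dtype=float)
        if rr.std() == 0 or ss.std() == 0:
            raise ValueError("correlation undefined for constant input")
        r = float(stats.spearmanr(rr, ss).statistic)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return AmbiguityResult(min(1.0, 1.0 - abs(r)), condition, "plain")


def _dominant_period_samples(s: np.ndarray, fs: float) -> int:
    """Period (samples) of the stimulus spectral peak, for bounding lag searches."""
    nperseg = min(int(4 * fs), s.size)
    freqs, pxx = signal.welch(s - s.mean(), fs, nperseg=nperseg)
    pxx[0] = 0.0
    fdom = freqs[np.argmax(pxx)]
    if fdom <= 0:
        return s.size // 4
    return int(fs / fdom)


def ambiguity_phase_aligned(
    rate: RateSequence | np.ndarray,
    stim: HeadVelocityTrace | np.ndarray,
    condition: str = "",
    fs: float = 1000.0,
) -> AmbiguityResult:
    """Ambiguity after shifting the rate to the cross-correlation peak.

    The lag search is bounded to half the dominant stimulus period;
    alignment undoes pure time shifts, so this variant isolates ambiguity
    that is not a phase offset.
    """
    from .response import _xcorr_peak_lag

    r = np.asarray(getattr(rate, "samples", rate), dtype=float)
    s = np.asarray(getattr(stim, "samples", stim), dtype=float)
    if r.size != s.size:
        raise ValueError("rate and stimulus must have equal length")
    fs = getattr(stim, "sample_rate", fs)
    max_lag = max(1, min(_dominant_period_samples(s, fs) // 2, s.size // 4))
    lag = int(round(_xcorr_peak_lag(r, s, max_lag)))
    if lag > 0:
        r2, s2 = r[lag:], s[: s.size - lag]
    elif lag < 0:
        r2, s2 = r[:lag], s[-lag:]
    else:
        r2, s2 = r, s
    value = min(1.0, 1.0 - abs(_corr(r2, s2)))
    return AmbiguityResult(value, condition, "phase_aligned")


def ambiguity_thresholded(
    rate: RateSequence | np.ndarray,
    stim: HeadVelocityTrace | np.ndarray,
    threshold: float,
    condition: str = "",
    min_samples: int = 1000,
) -> AmbiguityResult:
    """Ambiguity restricted to epochs with |stimulus| below a threshold (deg/s).

    Samples with ``|stim| <= threshold`` are concatenated in time order
    (no realignment across the gaps) and 1-|R| is computed on the
    concatenation; at least one second of data must survive.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    r = np.asarray(getattr(rate, "samples", rate), dtype=float)
    s = np.asarray(getattr(stim, "samples", stim), dtype=float)
    if r.size != s.size:
        raise ValueError("rate and stimulus must have equal length")
    keep = np.abs(s) <= threshold
    if keep.sum() < min_samples:
        raise ValueError("fewer than 1 s of samples below threshold")
    value = min(1.0, 1.0 - abs(_corr(r[keep], s[keep])))
    return AmbiguityResult(value, condition, "thresholded",
                           float(threshold), float(keep.mean()))


def fractional_differentiate(
    stim: HeadVelocityTrace | np.ndarray,
    alpha: float,
    sample_rate: float = 1000.0,
) -> SensoryRepresentation:
    """Fractional derivative of order alpha via the filter H_alpha(f).

    The one-sided spectrum is multiplied by
    ``(2*pi*f)^alpha * exp(i*alpha*pi/2)`` and inverted; the DC bin is
    zeroed (the input is mean-subtracted first, since integrating a
    nonzero mean is unbounded). alpha = -1 integrates, +1 differentiates,
    0 returns the input.
    """
    if not -1.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [-1, 1]")
    x = np.asarray(getattr(stim, "samples", stim), dtype=float)
    sample_rate = getattr(stim, "sample_rate", sample_rate)
    x = x - x.mean()
    if alpha == 0.0:
        return SensoryRepresentation(0.0, x.copy(), sample_rate)
    freqs = np.fft.rfftfreq(x.size, 1.0 / sample_rate)
    H = np.zeros(freqs.size, dtype=complex)
    w = 2 * np.pi * freqs[1:]
    H[1:] = w**alpha * np.exp(1j * alpha * np.pi / 2)
    if x.size % 2 == 0:
        # keep the Nyquist bin real so the inverse transform is exact
        H[-1] = w[-1] ** alpha * np.cos(alpha * np.pi / 2)
    y = np.fft.irfft(np.fft.rfft(x) * H, x.size)
    return SensoryRepresentation(float(alpha), y, sample_rate)


def best_alpha(
    rate: RateSequence | np.ndarray,
    stim: HeadVelocityTrace | np.ndarray,
    grid=None,
    fs: float = 1000.0,
) -> float:
    """Representation order whose waveform is best time-aligned with the rate.

    For each alpha on the grid, the lag of the cross-correlation peak
    between rate and fractionally differentiated stimulus is found; the
    alpha minimizing |lag| wins, ties breaking toward smaller |alpha|.
    """
    from .response import _xcorr_peak_lag

    r = np.asarray(getattr(rate, "samples", rate), dtype=float)
    s = np.asarray(getattr(stim, "samples", stim), dtype=float)
    fs = getattr(stim, "sample_rate", fs)
    if grid is None:
        grid = DEFAULT_ALPHA_GRID
    max_lag = max(1, min(_dominant_period_samples(s, fs), s.size // 4))
    best = None
    for a in grid:
        rep = fractional_differentiate(s, float(a), fs).transformed
        if rep.std() == 0 or r.std() == 0:
            raise ValueError("constant input")
        lag = abs(_xcorr_peak_lag(r, rep, max_lag))
        key = (lag, abs(a))
        if best is None or key < best[0]:
            best = (key, float(a))
    return best[1]


def tuning_curve(
    rate: RateSequence | np.ndarray,
    x: SensoryRepresentation | np.ndarray,
    n_bins: int = 50,
    min_occupancy: int = 50,
) -> TuningCurve:
    """Mean firing rate versus binned sensory representation.

    Equal-width bins span the central 99% of the representation; bins
    with fewer than ``min_occupancy`` samples are dropped.
    """
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    r = np.asarray(getattr(rate, "samples", rate), dtype=float)
    xv = np.asarray(getattr(x, "transformed", x), dtype=float)
    if r.size != xv.size:
        raise ValueError("rate and representation must have equal length")
    lo, hi = np.percentile(xv, [0.5, 99.5])
    edges = np.linspace(lo, hi, n_bins + 1)
    inside = (xv >= lo) & (xv <= hi)
    idx = np.clip(np.digitize(xv[inside], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=r[inside], minlength=n_bins)
    keep = counts >= min_occupancy
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return TuningCurve(centers[keep], means[keep], counts[keep])


def optimal_tuning(
    x: SensoryRepresentation | np.ndarray,
    rate_min: float,
    rate_max: float,
    bin_centers: np.ndarray | None = None,
) -> TuningCurve:
    """Histogram-equalizing tuning curve predicted by efficient coding.

    ``f_opt(x) = rate_min + (rate_max - rate_min) * F(x)`` with F the
    empirical cumulative distribution of the representation, evaluated at
    the given bin centers (defaults to 50 bins over the central 99%).
    The curve's slope is maximal where the stimulus density is maximal.
    """
    if rate_max <= rate_min:
        raise ValueError("rate_max must exceed rate_min")
    xv = np.asarray(getattr(x, "transformed", x), dtype=float)
    if bin_centers is None:
        lo, hi = np.percentile(xv, [0.5, 99.5])
        edges = np.linspace(lo, hi, 51)
        bin_centers = 0.5 * (edges[:-1] + edges[1:])
    xs = np.sort(xv)
    cdf = np.searchsorted(xs, bin_centers, side="right") / xs.size
    curve = rate_min + (rate_max - rate_min) * cdf
    return TuningCurve(np.asarray(bin_centers, dtype=float), curve,
                       np.full(len(bin_centers), xv.size))


def optimality(actual: TuningCurve, optimal: TuningCurve) -> float:
    """Range-normalized agreement between measured and optimal tuning curves.

    ``max(0, 1 - RMSE/range(optimal))``: 1 iff the curves coincide;
    penalizes both shape and scale mismatch; clamped at 0.
    """
    if actual.bin_centers.size != optimal.bin_centers.size or not np.allclose(
        actual.bin_centers, optimal.bin_centers
    ):
        raise ValueError("curves must share bin centers")
    rng = optimal.mean_rate.max() - optimal.mean_rate.min()
    if rng <= 0:
        raise ValueError("optimal curve has zero range")
    rmse = float(np.sqrt(np.mean((actual.mean_rate - optimal.mean_rate) ** 2)))
    return max(0.0, 1.0 - rmse / rng)


def optimality_profile(
    rate: RateSequence | np.ndarray,
    stim: HeadVelocityTrace | np.ndarray,
    alpha_grid=None,
    rate_range: tuple[float, float] | None = None,
    n_bins: int = 50,
    min_occupancy: int = 50,
) -> OptimalityResult:
    """Optimality of the measured tuning curve across representation orders.

    For each alpha the stimulus is fractionally differentiated, the
    measured and optimal tuning curves built on shared bins, and the
    agreement scored; the optimal curve spans the measured curve's own
    rate range unless ``rate_range`` is given.
    """
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID
    r = np.asarray(getattr(rate, "samples", rate), dtype=float)
    s = np.asarray(getattr(stim, "samples", stim), dtype=float)
    fs = getattr(stim, "sample_rate", 1000.0)
    values = []
    best_curve = None
    for a in alpha_grid:
        rep = fractional_differentiate(s, float(a), fs)
        actual = tuning_curve(r, rep, n_bins, min_occupancy)
        if rate_range is None:
            lo, hi = float(actual.mean_rate.min()), float(actual.mean_rate.max())
            if hi <= lo:
                hi = lo + 1e-9
        else:
            lo, hi = rate_range
        opt = optimal_tuning(rep, lo, hi, actual.bin_centers)
        values.append(optimality(actual, opt))
    values = np.asarray(values)
    alphas = np.asarray(alpha_grid, dtype=float)
    i = int(np.argmax(values))
    # recompute the winning optimal curve for reporting
    rep = fractional_differentiate(s, float(alphas[i]), fs)
    actual = tuning_curve(r, rep, n_bins, min_occupancy)
    lo, hi = (rate_range if rate_range is not None
              else (float(actual.mean_rate.min()), float(actual.mean_rate.max())))
    best_curve = optimal_tuning(rep, lo, max(hi, lo + 1e-9), actual.bin_centers)
    return OptimalityResult(alphas, values, float(alphas[i]), float(values[i]), best_curve)
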