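# Methods

## Scope

`vestcode` implements a complete synthetic test bed for studying how
contrast gain control in the vestibular thalamocortical relay shapes the
encoding of naturalistic head motion: stimulus synthesis, cascade neuron
models, spike-train processing, frequency-domain system identification,
a coding-ambiguity statistic, and an efficient-coding tuning-curve
analysis. Everything runs on synthesized data; plain-text ingestion of
recorded spike times and velocity traces is supported but no recordings
ship with the package.

## Stimuli

All signals are sampled at 1 kHz; sample `i` is the value at
`t = i/1000 s` (left-edge convention).

**Sinusoids** are constant-amplitude probes at the eight study
frequencies 0.5, 1, 2, 3, 4, 5, 8, 17 Hz, default amplitude 15 deg/s.
**Ramps** are a fixed-frequency sinusoid under a triangular envelope
rising 0 to 100 deg/s over 100 s and back, used to measure gain as a
function of amplitude; up and down halves are averaged at matched
amplitudes.

**Naturalistic traces** are synthesized as (band-limited Lorentzian
carrier) x (slow positive envelope), rescaled to a target SD:

* carrier: Gaussian noise shaped to power ∝ 1/(1 + (f/f0)^2), f0 = 1 Hz,
  hard band limit 25 Hz. This gives the monotonically decaying spectrum
  of natural self-motion over the 0.5-17 Hz range.
* envelope: Gaussian noise low-passed at half the envelope cutoff
  (default cutoff 2 Hz), scaled to relative SD 0.08 around unity, floored
  at 0.05. The Hilbert envelope of the product keeps >= 95% of its
  spectral power below 2 Hz, counting the carrier's own (Rayleigh-like)
  envelope fluctuation.
* normalization: the product is centered and rescaled so the sample SD
  equals `target_sd` (default 40 deg/s; peaks then reach 120-180 deg/s,
  several-fold above the artificial stimuli).

The envelope depth of 0.08 is deliberately mild: multiplying a Gaussian
carrier by an independent envelope of relative SD r adds roughly 12 r^2
of excess kurtosis, and the generator contracts to deliver near-Gaussian
marginals (|skew| < 0.2, |excess kurtosis| < 0.5 on 300-s traces, checked
across 100 seeds in the suite). Real self-motion alternates quiet and
vigorous epochs and is far more deeply amplitude-modulated; under this
generator the contrast-gain stage therefore works mostly on the carrier's
intrinsic envelope fluctuations. Tests passing on these stimuli say
nothing about behaviors the generator does not emulate: rhythmic
locomotor structure, active-versus-passive asymmetries, or heavy-tailed
amplitude statistics.

**Spike trains** are Bernoulli draws per 1-ms bin with probability
`clip(rate, 0, 1000)/1000` — an inhomogeneous Poisson process at this
resolution, with at most one spike per bin, matching the binary-sequence
convention of the analysis chain (bin value 1000 spk/s if a spike fell in
the bin). Negative instantaneous rates are clipped to zero. Real central
vestibular neurons are substantially more regular than Poisson, so
spiking variants of the analyses are conservative about noise.

## Neuron models

Both classes share a linear high-pass stage
`T(f) = k s (s T1 + 1) / ((s T2 + 1)(s Tc + 1))`, `s = 2 pi i f`, with
k = 1.7207 (spk/s)/(deg/s), T1 = 0.06 s, T2 = 0.0006 s, Tc = 5.7 s,
applied in the frequency domain with T(0) = 0. Over the study band the
T1 zero dominates: gain rises ~6x and phase lead climbs from ~14 deg
(0.5 Hz) to ~78 deg (17 Hz). The static nonlinearity is
`SIG(X) = -25 + 50/(1 + exp(-X/10))` (spk/s), odd, bounded in (-25, 25).

* **VN**: `rate = clip(rest + SIG(T * S), 0)`.
* **TC**: the stimulus is first multiplied by the instantaneous contrast
  gain `G(t) = P1 / (P2 A(t) + 1)` (P1 = 2 (spk/s)/(deg/s),
  P2 = 0.037 s/deg), where A(t) is the Hilbert-envelope of the raw
  stimulus; then the linear stage, the sigmoid, and a degree-6 output
  polynomial (identity until fitted):
  `rate = clip(rest + poly(SIG(T * (G . S))), 0)`.

The stage order is configurable (`gain_control_first=False` applies the
gain after the linear stage instead); the default scales the raw
stimulus, the literal reading of a gain that multiplies S(t). Gain
control is instantaneous — no adaptation time constant is modeled. The
resting rate defaults to 60 spk/s so sigmoid-range modulations rarely
rectify. Eq.-style instantaneous frequency (analytic phase divided by
2 pi t) is numerically singular at t = 0 and drifts; the package reports
the derivative of the unwrapped analytic phase instead and keeps the
literal form behind a flag, for diagnostics only — only A(t) feeds the
model.

### What the cascade can and cannot reproduce

A structural property worth stating explicitly: for stimuli with
jointly-Gaussian statistics, the cross-spectrum between the stimulus and
*any* cascade of a real multiplicative envelope gain with a linear filter
has phase exactly `arg T(f)`. This follows from Stein's lemma — the
input/output cross-correlation of a memoryless function of the analytic
signal keeps only the linear kernel, and the quadrature coefficient
vanishes by the even symmetry of the envelope/phase distribution. The
package's simulations confirm it: the TC model's measured naturalistic
phase climbs along `arg T(f)` just as the VN model's does, and its
measured gain keeps the linear stage's tilt. An instantaneous envelope
gain flattens the *amplitude* statistics (it equalizes the envelope and
reduces envelope-induced ambiguity; the pure gain-control stage by
itself shows flat gain, ~0 deg phase, and ambiguity < 0.05) but cannot
cancel a linear stage's phase lead. Recorded thalamocortical neurons
show flat gain and near-zero phase under naturalistic stimulation, so
whatever cancels the upstream dynamics in vivo — dynamic feedback,
frequency-dependent adaptation, or mechanisms outside this model class —
is not captured by an instantaneous gain followed by fixed linear
dynamics. Population contrasts that hinge on that flattening (ambiguity
lower under naturalistic stimulation at *every* probe frequency,
velocity-centered optimality for TC units) accordingly do not all emerge
in this synthetic setting, and the package reports what it measures
rather than forcing them.

## Rate processing and system identification

* **Kaiser low-pass**: symmetric FIR, beta = 8, ~1 Hz transition width,
  cutoff 0.5 Hz above the stimulus frequency (17.5 Hz for broadband
  naturalistic stimuli). The filter is applied centered via FFT
  convolution with reflected edges — zero phase by symmetry, DC gain
  exactly 1 — so filtering cannot confound lead/lag estimates.
* **Periodic estimator** (sinusoids, ramp windows): the rate/stimulus
  cross-correlation is overlap-normalized (removing the finite-record
  bias toward zero lag), searched within half a stimulus period with
  ties broken toward smaller |lag|, and refined by parabolic
  interpolation; phase = -360 f lag (positive = response leads), gain =
  least-squares slope of rate on the lag-aligned stimulus.
* **Spectral estimator** (naturalistic): H(f) = P_sr / P_ss from
  Hann-windowed, 50%-overlap, 4-s segment averages (0.25-Hz resolution),
  complex band-averaged +/-0.25 Hz around each evaluation frequency;
  frequencies with stimulus power under a configurable floor are
  rejected. Parseval consistency of the estimator normalization is
  covered by the suite.
* **Poisson reference band**: spike-train spectra are compared to
  pointwise 2.5/97.5 percentiles of n_boot homogeneous Bernoulli trains
  at the matched mean rate, computed with the identical estimator.
* **Ramp profiles**: non-overlapping windows (default 4 s, at least two
  stimulus cycles; the window length is a free parameter, not a
  published value), each tagged with the envelope amplitude at the
  window midpoint; up/down halves averaged at matched amplitudes with a
  circular mean for phase.

## Parameter identification

Fitting the Lorentzian contrast gain directly to firing-rate window
gains conflates gain control with sigmoid saturation (at a 100 deg/s
ramp peak the pre-sigmoid signal reaches ~80 spk/s and the fitted decay
parameter inflates by ~40%). The identification chain therefore
linearizes first: observed rates are mapped back through the known
sigmoid (resting rate estimated as the mean rate — exact for symmetric
ramps since the sigmoid output of a symmetric input is zero-mean), the
windowed slope against the stimulus is divided by |T(f)|, and the
Lorentzian `G(A) = P1/(P2 A + 1)` is least-squares fitted to the pooled
(amplitude, contrast gain) samples across all eight frequencies.
Noiseless recovery is then within ~2-4% (median across a jittered
population). For spike-derived rates the sigmoid inverse is clipped
1 spk/s inside its range to keep the log finite.

The degree-6 output polynomial is fitted by discretizing the
pre-nonlinearity prediction into 100 equal-width bins, averaging the
observed rate per occupied bin, and fitting the (center, mean) pairs;
it is evaluated with clamping outside the fit domain to prevent
extrapolation blow-up. The polynomial maps prediction to observed rate
(the self-consistent direction) and absorbs the resting rate.

Model validation predicts each unit's naturalistic response from
ramp-only fits and scores it with VAF after low-pass filtering the
prediction at the same 17.5-Hz cutoff as the observed rate (bandwidth-
matched comparison). The spiking variant uses trial-averaged rates over
25 stimulus repeats: a single Poisson trial at 60 spk/s carries
~2000 (spk/s)^2 of broadband noise variance into a 17.5-Hz band, more
than the maximum signal variance a +/-25 spk/s sigmoid output allows, so
single-trial VAF is bounded near 0.2 regardless of model quality;
averaging 25 repeats is the standard way to estimate the underlying rate
and puts the noise floor well below the signal.

## Coding statistics

* **Ambiguity** = 1 - |R|, Pearson by default (Spearman available);
  invariant under positive affine maps and sign flips of either signal.
  The phase-aligned variant shifts the rate to the cross-correlation
  peak (bounded to half the dominant stimulus period) before
  correlating; alignment can only increase |R|. The thresholded variant
  keeps samples with |S| <= threshold (default grid 30...150, inf
  deg/s), concatenates the surviving segments in time order without
  realignment, and requires at least one second of surviving data.
* **Fractional differentiation**: one-sided spectrum multiplied by
  `(2 pi f)^alpha exp(i alpha pi/2)`; the DC bin is zeroed and inputs
  are mean-subtracted (integrating a nonzero mean is unbounded); the
  Nyquist bin keeps only the real factor so the inverse transform is
  exact. Orders compose (`H_a H_b = H_{a+b}`) on band-interior content.
* **Best order**: the alpha on a [-1, 1] grid (step 0.05) whose
  transformed stimulus minimizes |cross-correlation peak lag| against
  the rate; ties break toward smaller |alpha|. Equivalent phase is
  90 alpha degrees.
* **Tuning curves**: equal-width bins over the central 99% of the
  representation, mean rate per bin, bins under 50 samples dropped.
  The optimal curve is `rate_min + range * F(x)` with F the empirical
  CDF at the same bin centers — histogram equalization, maximum slope at
  the density mode. The scalar optimality is
  `max(0, 1 - RMSE/range(optimal))`: 1 iff the curves coincide,
  penalizing both shape and scale mismatch, clamped at zero. It is one
  defensible choice among monotone agreement scores; ordinal comparisons
  between neuron classes are robust to the choice, absolute values are
  not. Note that the score is shape-based: a strictly linear readout
  yields a nearly alpha-independent profile, so sharp best-order
  estimates require a saturating (CDF-like) response.

## Population experiments

Populations default to 28 TC / 27 VN units. Heterogeneity is independent
lognormal jitter (fractional SD 0.1, mean-preserving) on k, P1, P2 and
resting rate — a stated assumption, as per-unit parameter spreads are
not published. Every experiment is a pure function of (config, seed):
unit parameters and per-unit spike seeds derive from one generator, and
reports carry the config hash, seed and package version. Standard tests
(Kruskal-Wallis, Wilcoxon rank-sum) come from scipy.stats. Default
problem sizes — 300-s naturalistic traces, 30-s sinusoids, full 200-s
ramps at all eight frequencies — keep any single driver to a few minutes
on one core.

## Known limitations

* The generator's near-Gaussian, shallow-envelope contract (imposed so
  the marginal-moment checks hold) understates the amplitude
  nonstationarity of real self-motion; contrasts that depend on deep
  envelope modulation are weaker here than in recordings.
* Bernoulli spiking overstates the variability of regular central
  neurons; spiking analyses are noise-conservative.
* The instantaneous-gain cascade retains the linear stage's phase lead
  under all stimulus classes (see above); it reproduces gain-versus-
  amplitude adaptation and envelope equalization, not the phase
  flattening seen in recorded thalamocortical responses.
* No spiking biophysics (refractoriness, conductances), no
  active-motion attenuation, no finite adaptation timescale, and no
  information-theoretic optimality measures.
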