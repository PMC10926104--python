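# Methods

## Measurement model

A TCSPC (time-correlated single photon counting) instrument histograms
photon arrival times relative to a pulsed laser, on a uniform grid of
left-closed bins covering one repetition period `T = 1000/rate(MHz)` ns
(default 0.05 ns bins). The fluorescence decay of a probe in one
spectral window is modeled as a multi-exponential with pre-exponential
amplitudes `a_i` and lifetimes `tau_i`. Because excitation is periodic,
an incomplete decay wraps into later periods; summing the geometric
series gives, on `[0, T)`,

    f(t) = sum_i a_i exp(-t/tau_i) / (1 - exp(-T/tau_i)),

and the expected histogram is the *circular* convolution of `f` with
the instrument response function (IRF) plus a constant offset. Fitting
this periodic reconvolution model is the package's central operation;
the non-periodic variant (linear convolution of the unwrapped decay) is
kept available specifically to quantify the lifetime bias it incurs.
For a monoexponential, wraparound only rescales the decay, but for
multi-exponential decays it re-weights each amplitude by
`1/(1 - exp(-T/tau_i))`, boosting slow components: ignoring periodicity
therefore *overestimates* the intensity-weighted mean lifetime, the
more so the shorter the period. For amplitudes (0.7, 0.3) and lifetimes
(2, 7) ns — mean lifetime exactly 5 ns — the non-periodic bias is
+0.001 / +0.034 / +0.213 ns at 20 / 40 / 80 MHz, which the test suite
reproduces both on noise-free expected decays and as a paired
difference on Poisson realizations.

The scalar reported from every fit is the intensity-weighted mean
lifetime

    tau_AvInt = sum_i I_i tau_i / sum_i I_i,   I_i = a_i tau_i,

i.e. the photon-share-weighted mean of the component lifetimes.

Spectral contrast is summarized by the generalized polarization

    GP = (I_B - I_R) / (I_B + I_R)  in [-1, +1],

computed from the summed intensities of the windows containing a
blue-shifted (ordered-phase) and a red-shifted (disordered-phase)
wavelength. Bundled pairs: 550/670 nm (NR12S-like), 590/670 nm
(NR12A-like), 570/650 nm (Flipper-like). Wavelength lookup is by
containment in the half-open window `[lower, upper)` because the
detection ladder (20 nm windows tiling 500–700 nm) is far coarser than
a single wavelength.

The fit-free phasor representation maps a decay `c(t)` to

    g = sum c cos(n w0 t) / sum c,   s = sum c sin(n w0 t) / sum c,

with `w0 = 2 pi / T` and harmonic `n = 1` by default. Division by the
IRF's phasor calibrates out the instrument delay and width;
monoexponentials then lie on the universal semicircle (radius 0.5 at
(0.5, 0)), mixtures inside it on chords. Phase and modulation lifetimes
are `tan(phase)/w` and `sqrt(1/(g^2+s^2) - 1)/w`.

## Numerical implementation of reconvolution

Discrete convolution of two center-sampled histograms is misaligned by
half a bin, and applying sub-bin IRF shifts by Fourier phase factors
makes a near-delta IRF ring on the baseline. The model therefore

1. refines the IRF histogram to sub-bin masses (8x by default) by
   monotone PCHIP interpolation of its cumulative sum — smooth,
   shape-preserving, never negative;
2. evaluates the wrapped multi-exponential as a *closed-form*
   triangular bin average on the fine grid (second differences of the
   twice-integrated periodic exponential), with the IRF time shift
   entering the closed form so fractional shifts cost no interpolation;
3. convolves via FFT and regroups fine bins into histogram bins, which
   keeps the model exactly aligned with bin centers.

On noise-free expected curves the fit recovers generating amplitudes,
lifetimes, offset and shift essentially to machine precision. A
fundamental limit remains: the model knows the IRF only through its
histogram, so sub-bin information is lost; for the default 120 ps FWHM
IRF on 50 ps bins the residual model systematic contributes about 7
chi-square units per 10^6 photons (i.e. it is invisible below ~10^6
photons per decay).

## Fitting choices

- **Estimator.** Weighted least squares over the configured fit range,
  by default with Pearson (model-based) weights `1/max(model, 0.1)`:
  for Poisson counts the per-bin chi-square expectation is then exactly
  1 at every count level, making reduced chi-square a calibrated
  goodness-of-fit measure (verified: 0.93–1.08 at 10^6 photons). The
  Neyman weighting `1/max(count, 1)` used by some commercial fitters is
  available via `weighting="neyman"`, but its per-bin expectation
  ranges from 0.35 to 1.6 at low counts and inflates chi-square for
  these decays. The 0.1 floor keeps near-empty bins from dominating the
  weights without diluting the statistic.
- **Fit ranges.** 0.2–45 ns at 20 MHz and 0.2 ns to the full period at
  higher rates (0.2–25 ns at 40 MHz, 0.2–12.5 ns at 80 MHz);
  configurable.
- **Initialization.** Lifetimes log-spaced in [0.5, 6] ns, equal
  amplitudes scaled to the peak, offset from the pre-pulse baseline,
  zero shift — robust for nanosecond dyes. Lifetimes are bounded in
  [0.01, 100] ns, amplitudes and offset non-negative, shift in ±2 ns;
  lifetimes are sorted ascending after the fit for identifiability.
- **Quality control.** Decays under 10^4 photons are excluded before
  fitting (strict less-than). Advisory photon minima of 10^2 / 10^4 /
  10^6 apply to mono-/bi-/tri-exponential models. Fits with tau_AvInt
  outside 0.1–20 ns or reduced chi-square above 5 are flagged as
  outliers; non-convergence sets a flag rather than raising.
- **Repetition-rate advisory.** The inter-pulse interval should be ~10x
  the expected mean lifetime (5 ns -> 50 ns -> at most 20 MHz), keeping
  wraparound negligible while not wasting duty cycle.

In the rate-artifact comparison both the periodic and non-periodic fits
use a post-peak range (IRF center + 0.2 ns to the period end) with
lifetimes initialized at their generating values: at 80 MHz only ~1.8
decay times of the slow component fit in the window and the
biexponential likelihood develops a ridge (tau_AvInt scatter ±0.3 ns at
10^6 photons); the controlled range and initialization isolate the
model-induced bias from that separate identifiability limitation.

## Synthetic data generator

The generator is the package's source of ground-truth data and emulates
the photophysics and instrument effects of spectrally resolved FLIM of
solvatochromic membrane probes:

- **Solvent relaxation**, phenomenologically: the intensity-weighted
  mean lifetime of each 20 nm window follows a saturating curve
  `tau(l) = tau_max - (tau_max - tau_min) exp(-(l-500)/l_scale)`,
  clipped flat above a probe-specific plateau wavelength; per window, a
  fixed biexponential pair has its amplitude fraction solved so the
  window mean matches the curve exactly. This reproduces the
  window-level observable (rising-then-flat lifetime profiles) without
  modeling time-resolved emission spectra, excited-state kinetics or
  charge-transfer photophysics — which is all downstream analysis needs.
- **Emission spectra** as Gaussian brightness weights over the window
  ladder; ordered-phase variants are blue-shifted, giving positive GP.
- **Presets**: Flipper-like (small spectral shift, plateau 600 nm;
  liquid-ordered/disordered variants anchored to 5.6 and 4.0 ns at
  570 nm, a 1.6 ns contrast), NR12S-like (large shift, plateau 650 nm,
  larger Lo–Ld gap below 600 nm so the green channel resolves phases
  better), and a constant-lifetime AF488-like control (4.1 ns
  monoexponential, flat across windows). All preset numbers are
  simulator ground truth chosen to reproduce the qualitative
  photophysics; they are not measurements of the real dyes.
- **Photon generation**: arrival time = Gaussian IRF jitter (default
  FWHM 120 ps, center 2 ns to leave a pre-pulse baseline) + exponential
  delay with the component drawn by photon share, taken modulo the
  period (wraparound). The pulse-train path draws Poisson counts per
  pulse (mu = detected photons/pulse x per-window efficiency) and
  applies, per pulse, either classical **pile-up** (only the earliest
  photon is recorded; full-period dead time) or the **single-photon
  filter** (pulses with more than one arrival are discarded, mirroring
  a fast-counter filter; with it on, pile-up selection is moot). At
  mu = 0.5 pile-up depresses a 4.1 ns fit to ~3.6 ns; the filter
  restores it to within 1%.
- **Spectral series** split a grand photon total across windows by
  brightness x efficiency with largest-remainder apportionment, so the
  total is conserved exactly. **Two-phase images** assign Ld/Lo probe
  models to a disk's halves; each (pixel, channel) draws from an
  independent substream seeded by (seed, y, x, channel), so images are
  bit-identical for a given seed regardless of evaluation order.
  Background pixels get only (optional) uniform dark counts.

What the generator does *not* emulate: detector afterpulsing and
dark-count time structure, realistic vesicle geometry and out-of-focus
light, scattering/autofluorescence backgrounds, vendor file formats,
and continuous time-resolved emission spectra. Passing tests therefore
demonstrate correctness of the analysis chain under Poisson statistics
and the modeled artifacts, not robustness to everything a real
microscope produces.

## Image analysis and phasor maps

Full multi-exponential fits run only on pooled histograms (whole image
or mask-selected regions); per-pixel output is display-grade only — the
calibrated phasor phase lifetime, masked below 100 photons/pixel (the
monoexponential reliability floor). Pooling small lifetime contrasts
averages them out (a 0.2 ns two-phase contrast yields an intermediate
whole-image fit while per-phase masks resolve both); this caveat is
exercised in the tests. Phasor maps optionally apply a 3x3 spatial
median filter per time bin before the transform to tighten the photon
clouds; the median is slightly nonlinear on sparse counts, so cloud
centroids move marginally (< 0.05 in (g, s) in the tested conditions).
Phasor ROIs are circles in (g, s) units (default radius 0.05), and ROI
lifetimes are photon-weighted means of per-pixel phase lifetimes.

## Problem sizes used by the test suite

Parameter-recovery tests use 10^5-photon decays (10 replicates for the
1.6 ns contrast), chi-square calibration 10^6 photons, artifact studies
1–3.4 x 10^6 pulses, spectral profiles 5 x 10^4 photons per window, and
images 8x8 to 32x32 pixels at 10^2–3 x 10^3 photons per pixel — sizes
at which the statistical tolerances asserted in the tests (2% on
lifetimes, ±0.1 ns on the pooled contrast) hold with margin.

## Known limitations

- Biexponential component separation degrades when the period is
  shorter than ~2 slow lifetimes (80 MHz with 7 ns components); only
  pooled, not per-pixel, fits are supported by design.
- The IRF is assumed known exactly (the simulator's Gaussian); there is
  no estimate-from-scatter routine.
- GP wavelength selection inherits the 20 nm window granularity.
- Cubic-spline spectrum interpolation is presentation-only and never
  feeds GP or lifetime contrasts.
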