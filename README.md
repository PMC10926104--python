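# flimkit

Spectrally resolved fluorescence-lifetime (FLIM) analysis for
solvatochromic membrane probes: TCSPC decay simulation with realistic
instrument artifacts, periodic IRF-reconvolution multi-exponential
fitting, intensity-weighted mean lifetimes, generalized polarization
(GP), phasor analysis, and image/ROI pooling — with a small CLI tying
them into reproducible runs.

## Who this is for

Membrane-order probes such as Flipper or the Nile-Red derivatives
NR12S/NR12A report the liquid-ordered (Lo) vs liquid-disordered (Ld)
state of a lipid environment through both their emission spectrum and
their fluorescence lifetime. Quantifying that requires a chain of
analysis steps that are usually locked inside commercial FLIM software:
reconvolution fitting against the instrument response function (IRF),
handling of laser repetition-rate wraparound and detector pile-up,
per-window spectral lifetime profiles, GP, and phasor plots. `flimkit`
implements that chain as an open, tested Python library, together with
a synthetic-data generator that produces decays, spectral series and
two-phase vesicle images with *known* ground truth — so every step can
be validated end to end.

## The model in brief

With repetition period `T`, an incomplete multi-exponential decay
wraps into later periods; on `[0, T)` each component becomes
`a_i exp(-t/tau_i) / (1 - exp(-T/tau_i))`, and the measurement is the
circular convolution of this wrapped decay with the IRF plus an offset.
Fits report the intensity-weighted mean lifetime

```
tau_AvInt = sum_i I_i tau_i / sum_i I_i,    I_i = a_i tau_i.
```

Spectral contrast is the generalized polarization

```
GP = (I_B - I_R) / (I_B + I_R)  in [-1, +1]
```

between a blue- and a red-shifted emission window, and the fit-free
phasor transform maps each decay to `(g, s)` Fourier coordinates where
monoexponentials lie on the universal semicircle. Decays below 10^4
photons are excluded as unreliable to fit, and the advised inter-pulse
interval is ten times the expected lifetime (5 ns → 50 ns → 20 MHz).
See `docs/methods.md` for the full model, estimator and simulator
details.

## Worked example

Simulate a spectral series of an ordered-phase NR12S-like probe
(2 × 10^6 photons split over ten 20 nm windows by its emission
spectrum), fit every window with biexponential periodic reconvolution,
and compute GP and a phasor read-out:

```python
import flimkit as fk

acq = fk.AcquisitionConfig(rep_rate_mhz=20.0, seed=1)
irf = acq.irf()

probe = fk.get_probe("nr12s_lo")
hists = fk.simulate_spectral_series(probe, acq, total_photons=2_000_000, rng=1)
profile = fk.spectral_profile(hists, irf, n=2)

print("window   tau_AvInt   photons")
for w, tau, i in zip(profile.windows, profile.tau_av_int_ns, profile.intensities):
    print(f"{w.label:>7}   {tau:6.2f} ns   {int(i):>7}")

gp = fk.gp_from_profile(profile, fk.GPConfig.for_probe("nr12s"))
print(f"GP(550/670 nm) = {gp:+.3f}")

point = fk.calibrate(fk.phasor_transform(hists[3]), fk.irf_phasor(irf))
tau_phi, tau_m = fk.phasor_lifetimes(point)
print(f"phasor of the 570 nm window: g={point.g:.3f}, s={point.s:.3f}, "
      f"tau_phi={tau_phi:.2f} ns, tau_m={tau_m:.2f} ns")
```

Output:

```
UserWarning: window 690nm excluded by QC (6006 photons)
window   tau_AvInt   photons
  510nm     3.66 ns    210258
  530nm     4.18 ns    312124
  550nm     4.52 ns    380289
  570nm     4.83 ns    380289
  590nm     4.99 ns    312124
  610nm     5.14 ns    210259
  630nm     5.25 ns    116250
  650nm     5.32 ns     52753
  670nm     5.40 ns     19648
GP(550/670 nm) = +0.902
phasor of the 570 nm window: g=0.722, s=0.371, tau_phi=4.09 ns, tau_m=5.72 ns
```

Reading it: the fitted mean lifetime rises with emission wavelength
(solvent relaxation — later photons are redder) and levels off toward
the probe's 650 nm plateau; the dimmest window fails the 10^4-photon
quality gate and is excluded with a warning rather than silently. The
strongly positive GP reflects the blue-shifted, ordered-phase emission.
The phasor point sits *inside* the universal semicircle and its phase
lifetime is below its modulation lifetime — both signatures of a
multi-exponential decay.

The same workflow is available from the shell:

```
flimkit simulate --config scenario.yaml --seed 1 --out run/
flimkit spectral --config analyse.yaml --out run_analysis/
```

where the YAML holds the probe/acquisition/fit blocks (see
`flimkit.config.RunConfig`); every run writes CSV tables, a rejects
table for QC failures, and a `provenance.json` with the config, seed
and package version, so identical config + seed reproduces identical
bytes.

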