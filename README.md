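# apeeg

Quantifying what action potentials (APs) can contribute to scalp EEG.

Scalp EEG is usually attributed to synaptic currents; spikes are assumed too
brief and too asynchronous to matter. `apeeg` implements a complete modelling
pipeline for testing that assumption quantitatively: it represents each
neuron's AP contribution as a unitary current-dipole impulse response, models
pairwise spike synchrony with a distance- and jitter-parameterized
correlogram, assembles whole-population scalp spectra through a lead field,
and provides the spectral-trend (1/f) fitting and detrending machinery needed
to compare AP-generated power against synaptic power and measurement noise.
It is aimed at computational neuroscientists studying the biophysical origin
of broadband and high-frequency EEG signals.

## The model

A single neuron's dipole power spectrum separates into synaptic and spiking
parts,

    S(f) = S_syn(f) + beta * S_ap(f),

where `S_ap` is the energy spectrum of the unitary AP response (extracted by
spike-triggered averaging of active-minus-passive simulations) and the fitted
scale `beta` equals the firing rate. For N neurons at cortical positions x_i
seen through a lead field nu(x), the AP component of the scalp spectrum is

    |phi_AP(f)|^2 = sum_i Rspike_ii(f) |nu_i . K_i(f)|^2
                  + sum_{i != j} Rspike_ij(f) Re[(nu_i . K_i)(nu_j . K_j)*],

with K_i the Fourier transform of neuron i's dipole kernel. Pairwise spike
synchrony is modelled as a jittered, distance-damped (optionally rhythmic)
correlogram

    R_ij(tau) = lam * Rmax / sqrt(2 pi sigma_t^2) * exp(-d_ij^2 / 2 sigma_x^2)
                * exp(-tau^2 / 2 sigma_t^2) * cos(2 pi f0 tau),

whose closed-form transform drives both an exact double sum (small N) and a
Monte Carlo estimator with a Chebyshev stopping rule (large N, using the
cortical pair-distance density dN(r)). The aperiodic EEG trend is fitted as
two Lorentzian pairs from inhibitory and excitatory synaptic kinetics plus a
noise floor, and detrending utilities separate the additive (subtract first)
from the multiplicative (divide after) components.

All compartmental-simulation and head-model inputs of the original analysis
are replaced by a first-class synthetic-data module (`apeeg.synthetic`) that
generates band-pass unitary kernels, an 85%/15% excitatory/inhibitory class
table, correlated spike-train pairs, coloured-noise passive dipoles, and
trend-plus-peaks EEG spectra with known ground truth.

## Worked example

```bash
python examples/asynchronous_detectability.py
```

prints

```
abundance-weighted unitary scalp energy: 0.0795 pV^2*ms (0.85*0.09 + 0.15*0.02 = 0.0795)
lambda =   1.0 Hz: max density above 30 Hz = 9.68e-09 uV^2/Hz -> detectable: False
lambda = 100.0 Hz: max density above 30 Hz = 9.68e-07 uV^2/Hz -> detectable: False
noise floor 0.001 uV^2/Hz: asynchronous spiking alone cannot produce measurable scalp EEG.
```

The kernel bank is calibrated so that excitatory and inhibitory classes carry
the reference unitary scalp energies (0.09 and 0.02 pV^2*ms); their
abundance-weighted mean is 0.0795. Extrapolated to 16 billion uncorrelated
Poisson neurons, the spectral density stays orders of magnitude below the
1e-3 uV^2/Hz amplifier noise floor even at implausibly high rates — APs need
synchrony to be visible at the scalp. The other scripts in `examples/` walk
through each capability: `unitary_beta.py` (beta equals firing rate),
`synchrony_spectra.py` (correlogram transforms), `ensemble_monte_carlo.py`
(exact vs Monte Carlo pair term), `trend_fit.py` (double-Lorentzian round
trip), `detrending_toy.py` (divisive vs mixed detrending), and
`morphology_asymmetry.py` (dendrite asymmetry index from SWC).

A thin CLI exposes the same stages: `apeeg unitary`, `apeeg asymmetry`,
`apeeg pairdensity`, `apeeg ensemble`, `apeeg rhythm`, `apeeg trend fit`,
`apeeg detrend`, `apeeg synth` (all accept `--seed`).

## Layout

- `src/apeeg/spectra.py` — Spectrum/TimeSeries containers, Welch PSD/CSD,
  energy spectra
- `src/apeeg/synthetic.py` — generators for every input with known ground
  truth
- `src/apeeg/unitary.py` — spike detection, spike-triggered averaging, the
  linear AP model fit
- `src/apeeg/synchrony.py` — correlogram models and closed-form spectra
- `src/apeeg/geometry.py` — lead fields, cortical placement, pair-distance
  density dN(r)
- `src/apeeg/ensemble.py` — auto/pair ensemble spectra, exact and Monte Carlo
- `src/apeeg/morphometry.py` — SWC reader and the dendrite asymmetry index
- `src/apeeg/trend.py` — trend fitting, noise-floor handling, detrending,
  peak bookkeeping
- `src/apeeg/io.py`, `pipeline.py`, `cli.py` — file formats, provenance-
  stamped pipeline stages, command line

See `docs/methods.md` for modelling assumptions, parameter choices, and
numerical details.
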