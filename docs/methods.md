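# Methods

## Model overview

`apeeg` treats the scalp EEG as a linear superposition of a synaptic signal
and an AP-generated signal, with a null cross-spectrum between the two. Each
neuron contributes a time-varying current dipole; a lead field nu(x) maps a
dipole at cortical position x to the electrode potential. The AP component of
a neuron's dipole is modelled as a linear impulse-response system: a spike
train convolved with a fixed 3-component unitary kernel. Under this model the
ensemble AP spectrum splits into a diagonal term (each neuron with its spike
auto-spectrum, flat at the rate lambda for Poisson firing) and an off-diagonal
term carrying all synchrony structure.

Assumptions worth keeping in mind:

- Linearity of the AP contribution. The fitted scale beta matches the firing
  rate in our synthetic tests to a few percent; with real membrane dynamics
  the approximation degrades during sustained fast firing, which is why the
  suite also checks that a saturating nonlinearity lowers the linear model's
  R^2.
- Stationary, homogeneous synchrony: one (lambda, Rmax, sigma_x, sigma_t, f0)
  for all pairs, separable in space and time.
- The AP-synaptic cross-spectrum is taken as zero; only the AP term and the
  synaptic trend model are computed.
- Back-propagating somatodendritic APs only; forward axonal propagation is
  not modelled.

## Units

Positions mm, dipole moments nA*um, potentials uV, frequencies Hz, time axes
ms. Energy spectra are value^2*ms/Hz (their integral over Hz is
sum(u^2)*dt with dt in ms); power spectra are value^2/Hz. The single ms/s
conversion needed when a rate in Hz multiplies an energy density in
value^2*ms/Hz lives in `spectra.MS_PER_S` and is applied exactly once (in
`fit_linear_ap_model` and in `ensemble._ENERGY_TO_POWER`). Published unitary
scalp energies quoted in bare pV^2 are adopted as pV^2*ms calibration
targets; if they are instead read as pV^2*s the asynchronous whole-brain
spectrum rises by 1000x but still sits well below the 1e-3 uV^2/Hz noise
floor at physiological rates, so no conclusion in the test suite depends on
that reading.

## Synthetic data

The generator module replaces compartmental simulations, head models and
published spectra while preserving the statistical structure the analysis
assumes. Defaults define the study conditions:

- Population: 85% excitatory / 15% inhibitory abundance across 8 classes.
  Excitatory classes get stronger dipoles (2-5 nA*um) aligned within ~25 deg
  of the apical axis, band-pass peaks 80-120 Hz, and occasional slow
  after-hyperpolarizations; inhibitory classes are weaker (0.5-2 nA*um),
  strongly tilted (35-80 deg), and faster (100-160 Hz).
- Unitary kernels: two opposed-polarity Gaussians (AP up/downstroke) of width
  w = 0.15282/f_peak (the exact argmax of the resulting energy spectrum,
  root of cot(pi u) = 4 pi u), plus an optional exponential AHP tail that
  adds the low-frequency excess seen in slow-afterpotential cells. Kernels
  are deterministic functions of their class parameters.
- Calibration: kernel amplitudes are rescaled so class-mean scalp energies
  under the surrogate lead field equal 0.09 (excitatory) and 0.02
  (inhibitory) pV^2*ms, measured at the same location sample used later (the
  pipeline places every class at the same cortical sites, so class contrasts
  are not confounded by placement).
- Passive dipoles: coloured noise with the two-timescale synaptic trend
  shape; the active trace adds the kernel at Poisson spike times, and the
  voltage trace carries suprathreshold bumps exactly at those times.
- Correlated spike pairs: a mother Poisson process at rate lambda*Rmax copied
  into both trains with independent N(0, sigma_t/sqrt(2)) jitters, plus
  independent filler at lambda*(1-Rmax); the relative jitter then has std
  sigma_t, matching the correlogram model. For rhythmic synchrony the shared
  delays are drawn from g(d)*(1+cos(2 pi f0 d))/Z: a nonnegative coincidence
  density cannot reproduce the damped cosine exactly (it dips below zero), so
  the realized correlogram equals the rhythmic model plus an aperiodic
  Gaussian term that rolls off by ~1/(2 pi sigma_t). The quantitative
  simulation-vs-theory bridge test therefore uses the aperiodic model; the
  rhythmic generator is checked qualitatively (coincidences modulate at f0).
- EEG spectra: P(f) = (1 + peaks + 1/f^2) * trend + floor with optional
  multiplicative log-normal sampling noise.

What passing tests on these surrogates do not show: real morphologies, real
channel kinetics, spatially structured synaptic input, or head-model
inhomogeneities. The synthetic world is constructed to satisfy the model's
assumptions exactly, so the tests validate the estimators and the assembly
arithmetic, not the biophysics.

## Spectral estimation

Welch averaged periodograms (Hann window, 50% overlap, 2 s segments by
default; the estimator and window are package choices exposed in
`WindowConfig`). Spectra are one-sided with the DC bin retained but excluded
from fits. Energy spectra use either a zero-padded FFT or direct evaluation
on an arbitrary grid; the latter keeps all ensemble modules on one shared
log-spaced grid (1-1000 Hz, 200 points by default) without interpolation.

## Synchrony spectra

The Fourier convention is integral h(tau) exp(-2 pi i f tau) d tau, verified
against trapezoid quadrature of the correlogram to 1e-6 of the spectral peak
across sigma_t in {4, 11.3, 60, 100} ms and f0 in {0, 5, 40, 160} Hz. The
rhythmic transform is (lam Rmax/2)[G(f-f0) + G(f+f0)]: its value at f0
approaches lam*Rmax (the zero-jitter flat level) when sigma_t*f0 is small,
and exactly half that level once 8 pi^2 sigma_t^2 f0^2 >> 1, because the
negative-frequency image no longer overlaps. The "rhythmic peaks trace the
zero-jitter spectrum" property is therefore asserted in the sharp-rhythm
regime (sigma_t = 12/f0 ms in the tests, keeping the tracing error under
5%); at sigma_t = 11.3 ms and f0 = 40 Hz the value at f0 is 0.50 of the
zero-jitter level, a constant factor that is invisible on a log-log plot but
matters for quantitative comparisons.

The sigma_r spatial scale that appears in the factored cross-spectrum is the
same parameter as sigma_x in the correlogram; the package deliberately
exposes a single `sigma_x`.

## Ensemble assembly

Kernels are rotated from each neuron's local frame (z = outward cortical
normal) into the head frame before projection through the lead field, so
cross-correlations between apical and azimuthal dipole components emerge
from geometry rather than being imposed. The exact double sum is limited to
N <= 200; beyond that the pair term uses Monte Carlo:

- Population mode samples ordered pairs with probability proportional to
  their spatial weight exp(-d^2/2 sigma_x^2) (importance sampling; unbiased
  for the exact sum, and immune to the variance blow-up from the many
  uncorrelated distant pairs).
- Continuum mode follows the whole-cortex scheme: classes drawn by
  abundance, a location drawn uniformly by area, a displacement drawn from
  the pair-distance density dN(r) and snapped back to the surface through a
  KD-tree over a refined triangle cloud. The estimand is
  N * h(f) * integral exp(-r^2/2 sigma_x^2) Sxy(r) dN(r) dr (the explicit N
  factor makes the integral, whose density integrates to N-1 per source,
  agree with the double sum).

Stopping uses Chebyshev's inequality on the worst-frequency running
variance: sampling stops when Var/(n * delta_abs^2) <= confidence (default
1%), i.e. n >= Var/(confidence * delta_abs^2). The bound is conservative; in
100 seeded fixture runs the estimate stayed within delta_abs of the exact
sum every time. Runs that exhaust `max_draws` first are returned flagged
non-converged.

Brain-scale constants: N = 16e9 cortical neurons, amplifier noise floor
1e-3 uV^2/Hz. Fixture sizes were chosen to keep the default suite fast: the
oracle-equivalence fixture uses 50 neurons on a 20 mm sphere, the
pair-dominated rhythm fixture 60 neurons on a 3 mm sphere.

## Geometry

The default lead field is an infinite homogeneous medium (sigma = 0.33 S/m),
nu = 1e-3 rhat/(4 pi sigma r^2) in uV per nA*um with r in mm; head-model
lead fields load from HDF5 (vertices + per-vertex 3-vectors, nearest-vertex
lookup) behind the same interface. dN(r) is estimated by refining the mesh
to elements no larger than ~r_max/25 (clipped to 0.25-2 mm), accumulating
the surface area inside Euclidean balls around sampled centers, and
differentiating the mean count curve by central differences. The ball is
Euclidean, not geodesic; on a sphere the Euclidean form gives dN = 2 pi rho
r exactly (cap area pi r^2), within 0.7% of the geodesic-cap expression at
r/R = 0.2. Centers may be supplied explicitly, which the flat-patch tests
use to stay clear of the open boundary.

## Trend fitting and detrending

The double-Lorentzian trend is fitted by least squares in log10 power on a
log-spaced grid (equal weight per bin, hence per decade), with multi-start
initial time constants plus seeded perturbations; the excitatory pair (1 and
3 ms) is fixed by default because it is weakly identified next to the
dominant inhibitory pair, and a free-fit flag exists. Time-constant bounds
are 0.1-100 ms; the (tau1, tau2) labels are sorted after fitting since the
model is symmetric under their exchange. One degeneracy deserves care: as
tau1 -> tau2 the amplitude A diverges while A(tau1-tau2)^2 stays finite, so
amplitude coordinates are only meaningful when the two time constants are
well separated and the fit band is free of strong rhythm peaks — fit
noise-floor-corrected, peak-light spectra, or compare fitted curves rather
than coordinates.

The noise floor is handled subtractively everywhere: `subtract_noise_floor`
clips at 1e-12 uV^2/Hz and reports clipped bins; `detrend` offers divisive
(s/(trend+floor)), subtractive (s-floor), and the recommended mixed mode
((s-floor)/trend). Rhythm-peak bookkeeping defines peak amplitude relative
to the trend density at the peak center (not band-integrated power; a
band-power variant would be a straightforward extension), which makes
`translate_peak` a pure re-centering and gives the AP fraction of a combined
peak as ap/(ap+syn) with detectability judged against the floor.

## Known limitations

- The rhythmic spike-pair generator realizes the rhythmic correlogram only
  up to an unavoidable aperiodic term (see above).
- The 3-shell spherical head model is not implemented; the lead-field
  interface accepts file-based fields for anything beyond the infinite
  medium.
- Continuum Monte Carlo snaps displaced partners to a refined surface cloud,
  so realized pair distances deviate from the drawn r by up to the element
  size; the spatial weight uses the realized distance.
- Trend amplitudes inherit the tau1 ~ tau2 degeneracy described above.
- The linear AP model is exact in the synthetic world by construction; its
  real-data validity is an assumption, probed only through the saturation
  sensitivity check.
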