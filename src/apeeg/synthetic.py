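"""Synthetic inputs with the statistical structure the analysis assumes.

The real pipeline consumes compartmental-simulation dipoles, a head-model
lead field, and published scalp spectra.  This module generates surrogates
for each: band-pass unitary AP dipole kernels (up/downstroke Gaussian pair
plus an optional slow after-hyperpolarization tail), an 85%/15%
excitatory/inhibitory class table, coloured-noise passive dipoles with
Poisson-driven AP superpositions, jitter-correlated spike-train pairs, and
double-Lorentzian scalp spectra with Gaussian rhythm peaks and an additive
noise floor.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

from .morphometry import Morphology
from .spectra import MS_PER_S, Spectrum, TimeSeries
from .trend import PeakSpec, ToyModelParams, TrendParams, PARALYZED_EEG_TREND, toy_spectrum
from .unitary import UnitaryKernel

__all__ = [
    "KernelParams",
    "NeuronClassSpec",
    "NoiseConfig",
    "make_kernel_bank",
    "make_population",
    "population_to_specs",
    "make_morphology",
    "make_active_passive_traces",
    "make_eeg_spectrum",
    "make_correlated_spike_pair",
    "calibrate_kernel_bank",
]


@dataclass(frozen=True)
class KernelParams:
    """Shape of a class's unitary AP dipole response.

    peak_hz : band-pass peak of the energy spectrum (the AP up/downstroke
        timescale); ~100 Hz for cortical neurons
    amplitude : dipole amplitude scale, nA*um
    updown_ratio : relative amplitude of the downstroke Gaussian
    tilt_deg / azimuth_deg : dipole axis in the neuron's local frame
        (0 deg tilt = apical-basal axis); interneuron classes get larger
        tilts, mixing power into the azimuthal components
    ahp_amplitude : slow after-hyperpolarization amplitude, nA*um (0 = none)
    ahp_tau_ms : AHP decay time constant, ms
    """

    peak_hz: float = 100.0
    amplitude: float = 3.0
    updown_ratio: float = 1.0
    tilt_deg: float = 15.0
    azimuth_deg: float = 0.0
    ahp_amplitude: float = 0.0
    ahp_tau_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("kernel amplitude must be positive")
        if self.ahp_tau_ms <= 0:
            raise ValueError("AHP decay must be > 0")


@dataclass(frozen=True)
class NeuronClassSpec:
    name: str
    excitatory: bool
    abundance: float
    kernel_params: KernelParams = KernelParams()
    target_scalp_energy: float | None = None   # pV^2*ms

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


def make_kernel_bank(classes: list[NeuronClassSpec], rng_seed: int = 0,
                     dt_ms: float = 0.1,
                     window: tuple[float, float] = (-10.0, 150.0),
                     ) -> dict[str, UnitaryKernel]:
    """Deterministic 3-component dipole kernel per neuron class.

    The waveform is two opposed-polarity Gaussians (AP up/downstroke) whose
    width is set from the class peak frequency, plus an optional slow
    exponential after-hyperpolarization; the dipole axis is tilted within
    the local frame per the class params.  ``rng_seed`` is accepted for
    interface uniformity but the construction is fully deterministic.
    """
    if not classes:
        raise ValueError("need at least one neuron class")
    del rng_seed
    bank: dict[str, UnitaryKernel] = {}
    t = np.arange(window[0], window[1] + dt_ms / 2, dt_ms)
    for spec in classes:
        kp = spec.kernel_params
        # opposed Gaussians at +-w/2 of width w: |FT|^2 prop. to
        # sin^2(pi f w) exp(-4 pi^2 w^2 f^2), maximized at f*w = 0.15282
        # (root of cot(pi u) = 4 pi u)
        w = 0.1528183 * MS_PER_S / kp.peak_hz
        delta = w
        up = np.exp(-(t + delta / 2.0) ** 2 / (2.0 * w**2))
        down = kp.updown_ratio * np.exp(-(t - delta / 2.0) ** 2 / (2.0 * w**2))
        shape = up - down
        if kp.ahp_amplitude > 0:
            onset = np.clip(t / (2.0 * w), 0.0, None)
            ahp = -kp.ahp_amplitude / kp.amplitude * (
                (1.0 - np.exp(-onset)) * np.exp(-np.clip(t, 0, None) / kp.ahp_tau_ms))
            ahp[t < 0] = 0.0
            shape = shape + ahp
        theta = np.deg2rad(kp.tilt_deg)
        phi = np.deg2rad(kp.azimuth_deg)
        axis = np.array([np.sin(theta) * np.cos(phi),
                         np.sin(theta) * np.sin(phi),
                         np.cos(theta)])
        waveform = kp.amplitude * axis[:, None] * shape[None, :]
        bank[spec.name] = UnitaryKernel(dt_ms, waveform, window=window,
                                        label=spec.name)
    return bank


def make_population(excitatory_fraction: float = 0.85, class_count: int = 8,
                    seed: int = 0) -> pd.DataFrame:
    """Abundance-weighted neuron-class table.

    Excitatory classes (pyramidal-like: strong apical alignment, larger
    dipoles, some with slow AHPs) share ``excitatory_fraction`` of the total
    abundance; inhibitory classes (stellate-like: strongly tilted, smaller
    dipoles, faster spikes) share the rest.  Within each group abundances
    are drawn from a flat Dirichlet.
    """
    if not 0.0 <= excitatory_fraction <= 1.0:
        raise ValueError("excitatory fraction must be in [0, 1]")
    if class_count < 1:
        raise ValueError("need at least one class")
    rng = np.random.default_rng(seed)
    n_exc = int(round(class_count * excitatory_fraction))
    n_exc = min(max(n_exc, 1 if excitatory_fraction > 0 else 0), class_count)
    if excitatory_fraction == 0:
        n_exc = 0
    if excitatory_fraction == 1:
        n_exc = class_count
    n_inh = class_count - n_exc
    rows = []
    if n_exc:
        w = rng.dirichlet(np.ones(n_exc)) * excitatory_fraction
        for i in range(n_exc):
            rows.append(dict(
                name=f"exc_{i}", excitatory=True, abundance=w[i],
                peak_hz=rng.uniform(80.0, 120.0),
                amplitude=rng.uniform(2.0, 5.0),
                updown_ratio=rng.uniform(0.8, 1.2),
                tilt_deg=rng.uniform(5.0, 25.0),
                azimuth_deg=rng.uniform(0.0, 360.0),
                ahp_amplitude=(rng.uniform(0.05, 0.2) if rng.random() < 0.3 else 0.0),
                ahp_tau_ms=rng.uniform(30.0, 150.0),
                target_scalp_energy=0.09))
    if n_inh:
        w = rng.dirichlet(np.ones(n_inh)) * (1.0 - excitatory_fraction)
        for i in range(n_inh):
            rows.append(dict(
                name=f"inh_{i}", excitatory=False, abundance=w[i],
                peak_hz=rng.uniform(100.0, 160.0),
                amplitude=rng.uniform(0.5, 2.0),
                updown_ratio=rng.uniform(0.8, 1.2),
                tilt_deg=rng.uniform(35.0, 80.0),
                azimuth_deg=rng.uniform(0.0, 360.0),
                ahp_amplitude=0.0,
                ahp_tau_ms=50.0,
                target_scalp_energy=0.02))
    return pd.DataFrame(rows)


def population_to_specs(population: pd.DataFrame) -> list[NeuronClassSpec]:
    specs = []
    for _, row in population.iterrows():
        kp = KernelParams(peak_hz=row["peak_hz"], amplitude=row["amplitude"],
                          updown_ratio=row["updown_ratio"],
                          tilt_deg=row["tilt_deg"], azimuth_deg=row["azimuth_deg"],
                          ahp_amplitude=row["ahp_amplitude"],
                          ahp_tau_ms=row["ahp_tau_ms"])
        specs.append(NeuronClassSpec(
            name=row["name"], excitatory=bool(row["excitatory"]),
            abundance=float(row["abundance"]), kernel_params=kp,
            target_scalp_energy=float(row.get("target_scalp_energy", np.nan))))
    return specs


def make_morphology(asymmetry: float = 0.0, n_segments: int = 20,
                    seed: int = 0, extent_um: float = 100.0) -> Morphology:
    """Cone-segment arbour with a controllable centroid offset along z.

    ``asymmetry=0`` yields a point-symmetric, equal-volume segment set
    (asymmetry index exactly 0); increasing ``asymmetry`` translates the
    whole midpoint cloud along +z, which strictly increases the index.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    rng = np.random.default_rng(seed)
    n_half = max(1, n_segments // 2)
    half = rng.normal(scale=extent_um, size=(n_half, 3))
    parts = [half, -half]
    if n_segments % 2 == 1:
        parts.append(np.zeros((1, 3)))
    mids = np.vstack(parts) + np.array([0.0, 0.0, asymmetry])
    vols = np.ones(len(mids))
    return Morphology(mids, vols, label=f"synthetic-asym-{asymmetry:g}")


@dataclass(frozen=True)
class NoiseConfig:
    """Coloured-noise surrogate for the passive (synaptic) dipole.

    The passive dipole PSD is shaped like the two-timescale synaptic trend;
    ``scale`` sets its overall variance ((nA*um)^2), 0 disables noise.
    """

    scale: float = 1.0
    trend: TrendParams = PARALYZED_EEG_TREND


def _coloured_noise(n: int, dt_ms: float, cfg: NoiseConfig,
                    rng: np.random.Generator) -> np.ndarray:
    from .trend import eval_trend

    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=dt_ms / MS_PER_S)
    shape = eval_trend(cfg.trend, f)
    shape[0] = 0.0
    spec = np.fft.rfft(white) * np.sqrt(shape)
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return cfg.scale * x / rms if rms > 0 else x


def make_active_passive_traces(kernel: UnitaryKernel, lam_hz: float,
                               duration_ms: float,
                               noise_cfg: NoiseConfig | None = None,
                               seed: int = 0,
                               ) -> tuple[TimeSeries, TimeSeries, np.ndarray, TimeSeries]:
    """Surrogate active/passive dipole pair with known ground truth.

    passive: coloured-noise synaptic dipole (3 channels, same realization in
    both conditions).  active: passive plus the kernel superposed at Poisson
    spike times (rate ``lam_hz``).  The returned voltage trace is a -65 mV
    baseline with +80 mV bumps, so its suprathreshold peaks land exactly on
    the spike samples.
    """
    if lam_hz < 0:
        raise ValueError("firing rate must be >= 0")
    dt = kernel.dt
    k_span = kernel.n_samples * dt
    if duration_ms < k_span:
        raise ValueError(
            f"duration {duration_ms} ms too short for one kernel ({k_span} ms)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / dt))
    cfg = noise_cfg or NoiseConfig()
    if cfg.scale > 0:
        passive = np.stack([_coloured_noise(n, dt, cfg, rng) for _ in range(3)])
    else:
        passive = np.zeros((3, n))

    margin_lo = -kernel.window[0]
    margin_hi = kernel.window[1]
    n_spikes = rng.poisson(lam_hz * duration_ms / MS_PER_S)
    t_lo, t_hi = margin_lo, duration_ms - margin_hi - dt
    spike_times = np.sort(rng.uniform(t_lo, t_hi, size=n_spikes)) if n_spikes else np.array([])
    spike_idx = np.round(spike_times / dt).astype(int)
    spike_times = spike_idx * dt

    active = passive.copy()
    i0 = int(round(kernel.window[0] / dt))
    for idx in spike_idx:
        sl = slice(idx + i0, idx + i0 + kernel.n_samples)
        active[:, sl] += kernel.waveform

    v = np.full(n, -65.0)
    tgrid = np.arange(n) * dt
    for st in spike_times:
        v += 80.0 * np.exp(-(tgrid - st) ** 2 / (2.0 * 0.25**2))
    return (TimeSeries(dt, active), TimeSeries(dt, passive),
            spike_times, TimeSeries(dt, v))


def make_eeg_spectrum(trend: TrendParams, peaks: tuple[PeakSpec, ...] = (),
                      floor: float = 0.0, seed: int = 0,
                      freqs: np.ndarray | None = None,
                      noise_sd: float = 0.0,
                      hfo: PeakSpec | None = None,
                      one_over_f2: bool = True) -> Spectrum:
    """Scalp EEG power spectrum from the toy-model equation.

    ``P(f) = (1 + sum peaks + 1/f^2) * trend(f) + floor (+ hfo)``, with
    optional multiplicative log-normal sampling noise of log-sd ``noise_sd``.
    ``one_over_f2=False`` drops the low-frequency 1/f^2 excess, leaving the
    bare trend when no peaks or floor are requested.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    f = np.geomspace(1.0, 1000.0, 400) if freqs is None else np.asarray(freqs, float)
    from .trend import eval_trend

    p = ToyModelParams(trend=trend, peaks=tuple(peaks), noise=floor, hfo=hfo)
    vals = toy_spectrum(p, f)
    if not one_over_f2:
        vals = vals - eval_trend(trend, f) / f**2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals * np.exp(rng.normal(0.0, noise_sd, size=f.size))
    return Spectrum(f, vals, units="uV^2/Hz", kind="power")


def make_correlated_spike_pair(lam_hz: float, rmax: float, sigma_t_ms: float,
                               duration_ms: float, f0_hz: float = 0.0,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two spike trains, each marginally Poisson(lam), with jittered shared
    events.

    A mother Poisson process of rate ``lam * rmax`` is copied into both
    trains with independent Gaussian jitters of std ``sigma_t / sqrt(2)``,
    so the relative jitter of a shared pair has std ``sigma_t``; independent
    Poisson events of rate ``lam * (1 - rmax)`` fill each train.  The
    resulting cross-correlogram is the distance-0 aperiodic synchrony model.

    With ``f0_hz`` set, the relative delay of each shared pair is drawn from
    ``g(d) * (1 + cos(2 pi f0 d)) / Z`` — a nonnegative density cannot
    reproduce the damped-cosine correlogram exactly (it dips negative), so
    the realized correlogram is the rhythmic model plus an aperiodic
    Gaussian term that rolls off by ~1/(2 pi sigma_t).
    """
    if not 0.0 <= rmax <= 1.0:
        raise ValueError(f"rmax must be in [0, 1], got {rmax}")
    if lam_hz < 0 or sigma_t_ms < 0 or duration_ms <= 0:
        raise ValueError("rates, jitter, and duration must be non-negative")
    rng = np.random.default_rng(seed)
    dur_s = duration_ms / MS_PER_S
    n_shared = rng.poisson(lam_hz * rmax * dur_s)
    mother = rng.uniform(0.0, duration_ms, n_shared)
    if f0_hz <= 0 or sigma_t_ms == 0:
        jit = sigma_t_ms / np.sqrt(2.0)
        a_shared = mother + rng.normal(0.0, jit, n_shared)
        b_shared = mother + rng.normal(0.0, jit, n_shared)
    else:
        deltas = _sample_rhythmic_delays(n_shared, sigma_t_ms, f0_hz, rng)
        a_shared = mother - deltas / 2.0
        b_shared = mother + deltas / 2.0
    n_a = rng.poisson(lam_hz * (1.0 - rmax) * dur_s)
    n_b = rng.poisson(lam_hz * (1.0 - rmax) * dur_s)
    a = np.sort(np.concatenate([a_shared, rng.uniform(0, duration_ms, n_a)]))
    b = np.sort(np.concatenate([b_shared, rng.uniform(0, duration_ms, n_b)]))
    keep = lambda t: t[(t >= 0) & (t < duration_ms)]
    return keep(a), keep(b)


def _sample_rhythmic_delays(n: int, sigma_t_ms: float, f0_hz: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample delays with density prop. to g(d)*(1+cos(2 pi f0 d))."""
    out = np.empty(0)
    while out.size < n:
        cand = rng.normal(0.0, sigma_t_ms, size=max(2 * (n - out.size), 16))
        accept = rng.random(cand.size) < 0.5 * (
            1.0 + np.cos(2.0 * np.pi * f0_hz * cand / MS_PER_S))
        out = np.concatenate([out, cand[accept]])
    return out[:n]


def calibrate_kernel_bank(bank: dict[str, UnitaryKernel],
                          specs: list[NeuronClassSpec],
                          geometry, leadfield, n_locations: int = 200,
                          seed: int = 0) -> dict[str, UnitaryKernel]:
    """Scale kernel amplitudes so class-mean scalp energies hit their targets.

    For each class the location-averaged scalp energy (pV^2*ms) under the
    given lead field is measured with the ensemble machinery, and the kernel
    is rescaled by sqrt(target / measured).  Calibration is explicit: the
    returned bank is a new dict, the input is untouched.
    """
    from .ensemble import unitary_scalp_energy

    out = {}
    for spec in specs:
        kernel = bank[spec.name]
        target = spec.target_scalp_energy
        if target is None or not np.isfinite(target):
            out[spec.name] = kernel
            continue
        measured = unitary_scalp_energy(kernel, geometry, leadfield,
                                        n_locations=n_locations, seed=seed)
        if measured <= 0:
            raise ValueError(f"class {spec.name} produced zero scalp energy")
        out[spec.name] = kernel.scaled(float(np.sqrt(target / measured)))
    return out
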