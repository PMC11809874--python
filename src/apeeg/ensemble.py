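"""Ensemble apEEG spectra: auto term, exact double sum, Monte Carlo pair term.

The scalp power spectrum generated by N spiking neurons decomposes into a
diagonal (auto) term and an off-diagonal (pair) term::

    P(f) = sum_i Rspike_ii(f) |nu_i . Khat_i(f)|^2
         + sum_{i != j} Rspike_ij(f) Re[(nu_i . Khat_i)(nu_j . Khat_j)*]

where ``Khat_i`` is the Fourier transform of neuron i's unitary dipole
kernel rotated into the head frame and ``nu_i`` the lead field at its
location.  With Poisson firing the auto term is ``lambda * N * mean unitary
energy spectrum``; the pair term carries all the synchrony structure and is
either summed exactly (small N) or estimated by Monte Carlo with a
Chebyshev stopping rule.

All ensemble spectra are one-sided scalp power densities in uV^2/Hz;
unitary energy spectra are quoted in pV^2*ms/Hz (1 uV^2 = 1e12 pV^2, dt in
ms), and the single rate-times-energy unit conversion lives in
:data:`_ENERGY_TO_POWER`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CortexGeometry, LeadField, PairDensity
from .spectra import MS_PER_S, Spectrum
from .synchrony import SynchronyParams, cross_spectrum_analytic
from .unitary import UnitaryKernel

__all__ = [
    "MCConfig",
    "MCResult",
    "MeanUnitarySpectrum",
    "chebyshev_required_n",
    "scalp_kernel_spectra",
    "unitary_scalp_energy",
    "mean_unitary_spectrum",
    "asynchronous_spectrum",
    "ensemble_bruteforce",
    "pair_term_monte_carlo",
    "ensemble_spectrum",
    "synaptic_ensemble_spectrum",
    "N_CORTICAL_NEURONS",
    "default_frequency_grid",
]

#: total cortical neuron count used for whole-brain extrapolations
N_CORTICAL_NEURONS = 16e9

_UV2_TO_PV2 = 1e12
#: lambda [1/s] times energy density [pV^2*ms/Hz] -> power density [uV^2/Hz]
_ENERGY_TO_POWER = 1.0 / (_UV2_TO_PV2 * MS_PER_S)

_BRUTEFORCE_MAX_N = 200


def default_frequency_grid(n: int = 200, lo: float = 1.0,
                           hi: float = 1000.0) -> np.ndarray:
    """Log-spaced shared frequency grid, Hz."""
    return np.geomspace(lo, hi, n)


def chebyshev_required_n(variance: float, delta_abs: float,
                         confidence: float) -> int:
    """Draws needed so P(|mean error| > delta_abs) <= confidence.

    Chebyshev: Var/(n * delta^2) <= confidence  =>  n >= Var/(confidence * delta^2).
    """
    if delta_abs <= 0 or not 0 < confidence < 1:
        raise ValueError("delta_abs must be > 0 and confidence in (0, 1)")
    return int(np.ceil(variance / (confidence * delta_abs**2)))


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo pair-term settings.

    delta_abs : absolute error target on the pair spectrum, uV^2/Hz
    confidence : Chebyshev tail-probability bound (0.01 = "off by more than
        delta_abs with < 1% probability")
    """

    delta_abs: float = 1e-3
    confidence: float = 0.01
    batch_size: int = 10_000
    max_draws: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_abs <= 0:
            raise ValueError("delta_abs must be > 0")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")


@dataclass
class MCResult:
    spectrum: Spectrum
    delta_abs: float
    confidence: float
    n_draws: int
    converged: bool
    achieved_bound: float


@dataclass
class MeanUnitarySpectrum:
    """Abundance/location-averaged unitary scalp energy spectrum.

    ``spectrum`` is pV^2*ms/Hz; ``class_energy`` maps each class to its
    location-mean scalp energy in pV^2*ms; ``weights`` are the abundances.
    """

    spectrum: Spectrum
    class_energy: dict[str, float]
    weights: dict[str, float]
    per_class: dict[str, Spectrum] = field(default_factory=dict)

    @property
    def weighted_energy(self) -> float:
        """Abundance-weighted mean unitary scalp energy, pV^2*ms."""
        return float(sum(self.weights[k] * self.class_energy[k]
                         for k in self.class_energy))


def _rotated_kernel(kernel: UnitaryKernel, frame: np.ndarray) -> np.ndarray:
    """Kernel waveform rotated from the neuron's local frame to head frame."""
    return frame @ kernel.waveform


def scalp_kernel_spectra(placed: pd.DataFrame, bank: dict[str, UnitaryKernel],
                         leadfield: LeadField, freqs: np.ndarray) -> np.ndarray:
    """Complex scalp kernel spectra g_i(f) = nu_i . FT[frame_i K_i], uV*s."""
    from .spectra import fourier_transform

    n = len(placed)
    g = np.zeros((n, len(freqs)), dtype=complex)
    for i, row in enumerate(placed.itertuples(index=False)):
        kernel = bank[row.name]
        nu = leadfield(np.asarray(row.position))
        wav = _rotated_kernel(kernel, np.asarray(row.frame))
        g[i] = nu @ fourier_transform(wav, kernel.dt, freqs)
    return g


def unitary_scalp_energy(kernel: UnitaryKernel, geometry: CortexGeometry,
                         leadfield: LeadField, n_locations: int = 200,
                         seed: int = 0) -> float:
    """Location-averaged scalp energy of one unitary response, pV^2*ms."""
    from .geometry import _orthonormal_frames

    rng = np.random.default_rng(seed)
    pts, normals = geometry.sample_surface(n_locations, rng)
    frames = _orthonormal_frames(normals, rng)
    energies = np.empty(n_locations)
    for i in range(n_locations):
        nu = leadfield(pts[i])
        scalp = nu @ (frames[i] @ kernel.waveform)   # uV trace
        energies[i] = np.sum(scalp**2) * kernel.dt   # uV^2*ms
    return float(energies.mean() * _UV2_TO_PV2)


def mean_unitary_spectrum(bank: dict[str, UnitaryKernel],
                          population: pd.DataFrame, geometry: CortexGeometry,
                          leadfield: LeadField, n_locations: int = 100,
                          seed: int = 0, freqs: np.ndarray | None = None,
                          ) -> MeanUnitarySpectrum:
    """Average unitary scalp energy spectrum over classes and locations.

    Each class is placed at ``n_locations`` area-uniform cortical positions
    with its apical axis along the local normal; the one-sided scalp energy
    spectra (pV^2*ms/Hz) are averaged per class and combined with
    abundance weights.
    """
    if not bank:
        raise ValueError("empty kernel bank")
    if geometry.area_mm2 <= 0:
        raise ValueError("geometry has no surface area")
    from .geometry import _orthonormal_frames
    from .spectra import fourier_transform

    f = default_frequency_grid() if freqs is None else np.asarray(freqs, float)
    weights = {row["name"]: float(row["abundance"]) for _, row in population.iterrows()}
    wsum = sum(weights.values())
    weights = {k: v / wsum for k, v in weights.items()}

    per_class: dict[str, Spectrum] = {}
    class_energy: dict[str, float] = {}
    mean_vals = np.zeros_like(f)
    for name, w in weights.items():
        kernel = bank[name]
        # every class is evaluated at the same location sample (each model is
        # placed at the same set of cortical sites), so class comparisons are
        # not confounded by placement luck
        rng = np.random.default_rng(seed)
        pts, normals = geometry.sample_surface(n_locations, rng)
        frames = _orthonormal_frames(normals, rng)
        acc = np.zeros_like(f)
        e_acc = 0.0
        for i in range(n_locations):
            nu = leadfield(pts[i])
            wav = frames[i] @ kernel.waveform
            ghat = nu @ fourier_transform(wav, kernel.dt, f)      # uV*s
            acc += 2.0 * np.abs(ghat) ** 2 * MS_PER_S * _UV2_TO_PV2
            e_acc += np.sum((nu @ wav) ** 2) * kernel.dt * _UV2_TO_PV2
        per_class[name] = Spectrum(f, acc / n_locations,
                                   units="pV^2*ms/Hz", kind="energy")
        class_energy[name] = e_acc / n_locations
        mean_vals += w * per_class[name].values
    spectrum = Spectrum(f, mean_vals, units="pV^2*ms/Hz", kind="energy")
    return MeanUnitarySpectrum(spectrum, class_energy, weights, per_class)


def asynchronous_spectrum(lam_hz: float, n_neurons: float,
                          mean_unitary: MeanUnitarySpectrum | Spectrum,
                          ) -> Spectrum:
    """Whole-population spectrum for uncorrelated Poisson firing:
    ``lambda * N * mean unitary energy spectrum``, in uV^2/Hz."""
    if lam_hz < 0 or n_neurons < 0:
        raise ValueError("rate and neuron count must be >= 0")
    s = mean_unitary.spectrum if isinstance(mean_unitary, MeanUnitarySpectrum) else mean_unitary
    vals = lam_hz * n_neurons * s.values * _ENERGY_TO_POWER
    return Spectrum(s.freqs.copy(), vals, units="uV^2/Hz", kind="power")


def _pairwise_weights(positions: np.ndarray, sigma_x: float) -> np.ndarray:
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    m = np.exp(-d2 / (2.0 * sigma_x**2))
    np.fill_diagonal(m, 0.0)
    return m


def ensemble_bruteforce(placed: pd.DataFrame, bank: dict[str, UnitaryKernel],
                        synchrony: SynchronyParams, leadfield: LeadField,
                        freqs: np.ndarray) -> tuple[Spectrum, Spectrum]:
    """Exact diagonal/off-diagonal split of the ensemble double sum.

    Returns ``(auto, pair)`` one-sided spectra in uV^2/Hz.  Only feasible
    for small populations; larger ones take the Monte Carlo path.
    """
    n = len(placed)
    if n > _BRUTEFORCE_MAX_N:
        raise ValueError(
            f"{n} neurons exceeds the brute-force limit ({_BRUTEFORCE_MAX_N}); "
            "use pair_term_monte_carlo")
    f = np.asarray(freqs, float)
    g = scalp_kernel_spectra(placed, bank, leadfield, f)
    auto_vals = synchrony.lam * 2.0 * np.sum(np.abs(g) ** 2, axis=0)
    positions = np.stack(placed["position"].to_list())
    m = _pairwise_weights(positions, synchrony.sigma_x)
    # h0(f): distance-free part of the pair cross-spectrum
    h0 = cross_spectrum_analytic(synchrony, 0.0, f)
    cross = np.einsum("ij,if,jf->f", m, g, np.conj(g)).real
    pair_vals = h0 * 2.0 * cross
    auto = Spectrum(f, auto_vals, units="uV^2/Hz", kind="power")
    pair = Spectrum(f, pair_vals, units="uV^2/Hz", kind="cross")
    return auto, pair


def pair_term_monte_carlo(synchrony: SynchronyParams, mc: MCConfig,
                          freqs: np.ndarray,
                          placed: pd.DataFrame | None = None,
                          bank: dict[str, UnitaryKernel] | None = None,
                          leadfield: LeadField | None = None,
                          population: pd.DataFrame | None = None,
                          geometry: CortexGeometry | None = None,
                          pair_density: PairDensity | None = None,
                          n_neurons: float | None = None) -> MCResult:
    """Monte Carlo estimate of the off-diagonal (pair) spectrum.

    Two sampling modes share the Chebyshev stopping rule (stop once
    ``max_f Var_f / (n * delta_abs^2) <= confidence``):

    * population mode (``placed`` given): ordered neuron pairs are drawn
      uniformly from a placed population, so the estimator is unbiased for
      the exact brute-force double sum of that population.
    * continuum mode (``population``/``geometry``/``pair_density`` given):
      the whole-cortex scheme — two classes drawn by abundance, a cortical
      location drawn uniformly by area, a displacement distance drawn from
      dN(r) and projected back onto the surface; the estimator targets
      ``N * h(f) * integral exp(-r^2/2 sigma_x^2) Sxy(r) dN(r) dr``.
    """
    f = np.asarray(freqs, float)
    rng = np.random.default_rng(mc.seed)
    if placed is not None:
        draw = _population_draw(placed, bank, leadfield, synchrony, f)
    else:
        if any(v is None for v in (population, geometry, pair_density,
                                   bank, leadfield)):
            raise ValueError("continuum mode needs population, geometry, "
                             "pair_density, bank and leadfield")
        n_tot = geometry.total_neurons if n_neurons is None else n_neurons
        draw = _continuum_draw(population, geometry, pair_density, bank,
                               leadfield, synchrony, f, n_tot)

    count = 0
    mean = np.zeros_like(f)
    m2 = np.zeros_like(f)
    converged = False
    while count < mc.max_draws:
        batch = draw(min(mc.batch_size, mc.max_draws - count), rng)
        # Chan et al. pairwise combine of running (mean, M2) with the batch
        b = batch.shape[0]
        bmean = batch.mean(axis=0)
        bm2 = ((batch - bmean) ** 2).sum(axis=0)
        tot = count + b
        delta = bmean - mean
        mean = mean + delta * (b / tot)
        m2 = m2 + bm2 + delta**2 * (count * b / tot)
        count = tot
        if count >= 2:
            var = m2 / (count - 1)
            worst = float(np.max(var))
            if worst / (count * mc.delta_abs**2) <= mc.confidence:
                converged = True
                break
    var = m2 / max(count - 1, 1)
    achieved = float(np.sqrt(np.max(var) / (count * mc.confidence)))
    spec = Spectrum(f, mean, units="uV^2/Hz", kind="cross")
    return MCResult(spec, mc.delta_abs, mc.confidence, count, converged, achieved)


def _population_draw(placed, bank, leadfield, synchrony, f):
    """Importance-sampled pair draws: pairs picked with probability
    proportional to their spatial synchrony weight exp(-d^2/2 sigma_x^2),
    so distant (uncorrelated) pairs do not inflate the estimator variance.
    Unbiased for the exact double sum of the placed population."""
    n = len(placed)
    if n < 2:
        raise ValueError("need at least 2 placed neurons")
    g = scalp_kernel_spectra(placed, bank, leadfield, f)
    positions = np.stack(placed["position"].to_list())
    m = _pairwise_weights(positions, synchrony.sigma_x)
    total_weight = m.sum()
    if total_weight <= 0:
        return lambda b, rng: np.zeros((b, len(f)))
    probs = (m / total_weight).ravel()
    h0 = cross_spectrum_analytic(synchrony, 0.0, f)

    def draw(b: int, rng: np.random.Generator) -> np.ndarray:
        flat = rng.choice(n * n, size=b, p=probs)
        i, j = np.divmod(flat, n)
        cross = (g[i] * np.conj(g[j])).real
        return total_weight * h0[None, :] * 2.0 * cross

    return draw


def _continuum_draw(population, geometry, pair_density, bank, leadfield,
                    synchrony, f, n_total):
    from scipy.spatial import cKDTree

    from .geometry import _orthonormal_frames, _surface_point_cloud
    from .spectra import fourier_transform

    names = population["name"].to_numpy()
    probs = population["abundance"].to_numpy(float)
    probs = probs / probs.sum()
    n_partners = pair_density.integral()   # ~ N - 1 per source
    h0 = cross_spectrum_analytic(synchrony, 0.0, f)
    scale = n_total * n_partners
    # displaced partners snap to the nearest point of a refined surface cloud
    max_edge = float(np.clip(pair_density.radii[-1] / 50.0, 0.25, 2.0))
    cloud, _ = _surface_point_cloud(geometry, max_edge)
    cloud_normals = _cloud_normals(geometry, cloud)
    tree = cKDTree(cloud)

    def draw(b: int, rng: np.random.Generator) -> np.ndarray:
        pts, normals = geometry.sample_surface(b, rng)
        frames_a = _orthonormal_frames(normals, rng)
        r = pair_density.sample_r(b, rng)
        # random tangential displacement, projected back onto the surface
        tang = rng.standard_normal((b, 3))
        tang -= np.sum(tang * normals, axis=1, keepdims=True) * normals
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        target = pts + r[:, None] * tang
        _, idx = tree.query(target)
        proj = cloud[idx]
        pnormals = cloud_normals[idx]
        frames_b = _orthonormal_frames(pnormals, rng)
        ca = rng.choice(len(names), size=b, p=probs)
        cb = rng.choice(len(names), size=b, p=probs)
        out = np.empty((b, len(f)))
        for k in range(b):
            ka, kb = bank[names[ca[k]]], bank[names[cb[k]]]
            ga = leadfield(pts[k]) @ fourier_transform(
                frames_a[k] @ ka.waveform, ka.dt, f)
            gb = leadfield(proj[k]) @ fourier_transform(
                frames_b[k] @ kb.waveform, kb.dt, f)
            d = np.linalg.norm(proj[k] - pts[k])
            w = np.exp(-d**2 / (2.0 * synchrony.sigma_x**2))
            out[k] = scale * h0 * 2.0 * w * (ga * np.conj(gb)).real
        return out

    return draw


def _cloud_normals(geometry: CortexGeometry, cloud: np.ndarray) -> np.ndarray:
    """Outward normals for refined-surface cloud points (nearest face)."""
    from scipy.spatial import cKDTree

    centers = geometry.mesh.triangles_center
    _, face_idx = cKDTree(centers).query(cloud)
    return geometry.mesh.face_normals[face_idx]


def ensemble_spectrum(auto: Spectrum, pair: Spectrum) -> Spectrum:
    """Total ensemble spectrum; auto and pair must share a grid."""
    if not auto.same_grid(pair):
        raise ValueError("auto and pair terms are on different frequency grids")
    total = np.real(auto.values) + np.real(pair.values)
    return Spectrum(auto.freqs.copy(), np.maximum(total, 0.0),
                    units=auto.units, kind="power")


def synaptic_ensemble_spectrum(trend, sigma_gabar_mm: float,
                               sigma_ampar_mm: float,
                               pair_density: PairDensity | None,
                               n_neurons: float,
                               freqs: np.ndarray) -> Spectrum:
    """Ensemble synaptic spectrum with per-timescale spatial coherence.

    The single-neuron synaptic PSD splits into a GABAR (inhibitory
    Lorentzian pair) and an AMPAR (excitatory pair) component; each
    component's pairwise cross-spectrum decays spatially as a Gaussian with
    its own scale, so the ensemble is::

        N * [(1 + I_G) * P_GABA(f) + (1 + I_A) * P_AMPA(f)]

    with ``I_c = integral exp(-r^2/2 sigma_c^2) dN(r) dr`` the expected
    number of coherent partners for that component (0 when sigma_c = 0).
    """
    from .trend import _lorentz_pair

    if sigma_gabar_mm < 0 or sigma_ampar_mm < 0:
        raise ValueError("spatial scales must be >= 0")
    f = np.asarray(freqs, float)
    p_gaba = _lorentz_pair(f, trend.tau_i1, trend.tau_i2, trend.amp_inhibitory)
    p_ampa = _lorentz_pair(f, trend.tau_e1, trend.tau_e2, trend.amp_excitatory)

    def partners(sigma: float) -> float:
        if sigma == 0:
            return 0.0
        if pair_density is None:
            raise ValueError("pair_density required when a spatial scale > 0")
        return pair_density.gaussian_weighted_integral(sigma)

    vals = n_neurons * ((1.0 + partners(sigma_gabar_mm)) * p_gaba
                        + (1.0 + partners(sigma_ampar_mm)) * p_ampa)
    return Spectrum(f, vals, units="uV^2/Hz", kind="power")
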