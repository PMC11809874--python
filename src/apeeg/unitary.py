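"""Unitary AP response extraction and the linear spectral model.

The single-neuron dipole spectrum is modelled as the passive (synaptic)
spectrum plus the firing rate times the energy spectrum of the unitary AP
response:

    S(f) = S_syn(f) + beta * S_ap(f)

with ``beta`` in spikes/s.  The unitary response itself is the
spike-triggered average of the active-minus-passive dipole difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .spectra import MS_PER_S, Spectrum, TimeSeries

__all__ = [
    "UnitaryKernel",
    "LinearFitResult",
    "detect_spikes",
    "spike_triggered_average",
    "fit_linear_ap_model",
]


@dataclass
class UnitaryKernel:
    """3-component dipole impulse response of one action potential.

    waveform : (3, T) dipole moment in nA*um sampled at ``dt`` ms
    window : (pre, post) ms around the spike peak covered by the waveform
    """

    dt: float
    waveform: np.ndarray
    window: tuple[float, float] = (-10.0, 150.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.waveform = np.atleast_2d(np.asarray(self.waveform, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.waveform.shape[0] != 3:
            raise ValueError("waveform must have 3 components (x, y, z)")
        span = (self.waveform.shape[1] - 1) * self.dt
        if span + 1e-9 < self.window[1] - self.window[0]:
            raise ValueError("window exceeds waveform support")

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[1]

    def times_ms(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) * self.dt

    def energy(self) -> float:
        """Time-domain energy, (nA*um)^2 * ms."""
        return float((self.waveform**2).sum() * self.dt)

    def as_timeseries(self) -> TimeSeries:
        return TimeSeries(self.dt, self.waveform)

    def scaled(self, factor: float) -> "UnitaryKernel":
        return UnitaryKernel(self.dt, self.waveform * factor, self.window, self.label)


@dataclass
class LinearFitResult:
    beta: float                 # spikes/s
    r_squared: float            # <= 1
    residual: Spectrum          # S - S_syn - beta * S_ap on the fit grid


def detect_spikes(voltage: TimeSeries, min_height: float = 0.0,
                  refractory_ms: float | None = None) -> np.ndarray:
    """Times (ms) of local maxima of a single-channel trace above threshold.

    Peaks closer together than ``refractory_ms`` (default one sample) keep
    only the larger one.  An empty result is allowed.
    """
    if voltage.n_channels != 1:
        raise ValueError("spike detection expects a single-channel trace")
    v = np.ravel(voltage.samples)
    distance = 1
    if refractory_ms is not None:
        distance = max(1, int(round(refractory_ms / voltage.dt)))
    peaks, _ = scipy.signal.find_peaks(v, height=min_height, distance=distance)
    return peaks * voltage.dt


def spike_triggered_average(active: TimeSeries, passive: TimeSeries,
                            spike_times_ms: np.ndarray,
                            window: tuple[float, float] = (-10.0, 150.0),
                            min_spikes: int = 10,
                            exclude_overlapping: bool = False,
                            label: str = "") -> UnitaryKernel:
    """Mean of the active-minus-passive dipole aligned to spikes.

    Spikes whose window would run past the record are dropped (and counted
    against ``min_spikes``).  With ``exclude_overlapping`` set, spikes closer
    than the window length to a neighbour are also dropped (sensitivity
    check; a plain STA keeps them).
    """
    if active.dt != passive.dt:
        raise ValueError("active and passive traces must share dt")
    if active.n_samples != passive.n_samples:
        raise ValueError("active and passive traces must have equal length")
    diff = active.channels() - passive.channels()
    if diff.shape[0] == 1:
        diff = np.vstack([np.zeros_like(diff[0]), np.zeros_like(diff[0]), diff[0]])
    dt = active.dt
    i_pre = int(round(window[0] / dt))
    i_post = int(round(window[1] / dt))
    n = diff.shape[1]
    idx = np.round(np.asarray(spike_times_ms, dtype=float) / dt).astype(int)
    usable = idx[(idx + i_pre >= 0) & (idx + i_post < n)]
    if exclude_overlapping and usable.size:
        span = i_post - i_pre
        keep = np.ones(usable.size, dtype=bool)
        keep[1:] &= np.diff(usable) >= span
        keep[:-1] &= np.diff(usable) >= span
        usable = usable[keep]
    if usable.size < min_spikes:
        raise ValueError(
            f"only {usable.size} usable spikes (of {len(idx)} detected); "
            f"need at least {min_spikes} for averaging")
    snippets = np.stack([diff[:, i + i_pre:i + i_post + 1] for i in usable])
    return UnitaryKernel(dt, snippets.mean(axis=0),
                         window=(i_pre * dt, i_post * dt), label=label)


def _log_grid(band: tuple[float, float], n: int = 120) -> np.ndarray:
    return np.geomspace(band[0], band[1], n)


def fit_linear_ap_model(s: Spectrum, s_syn: Spectrum, s_ap: Spectrum,
                        band: tuple[float, float] = (1.0, 500.0),
                        nonnegative: bool = True,
                        n_grid: int = 120) -> LinearFitResult:
    """Least-squares scale of the unitary energy spectrum onto S - S_syn.

    The fit weights frequencies log-uniformly over ``band`` (the spectra are
    interpolated onto a log-spaced grid), which keeps the decades of the
    spectrum from being dominated by the dense high-frequency bins.  ``s``
    and ``s_syn`` are power densities (value^2/Hz); ``s_ap`` is an energy
    density (value^2*ms/Hz), so the fitted scale is converted once from
    1/ms to spikes/s.
    """
    if not (s.same_grid(s_syn)):
        raise ValueError("S and S_syn must share a frequency grid")
    lo = max(band[0], max(s.freqs[s.freqs > 0][0], s_ap.freqs[s_ap.freqs > 0][0]))
    hi = min(band[1], s.freqs[-1], s_ap.freqs[-1])
    if hi <= lo:
        raise ValueError(f"band {band} outside the common frequency grid")
    grid = _log_grid((lo, hi), n_grid)
    y = s.interp(grid) - s_syn.interp(grid)
    x = s_ap.interp(grid)
    if not np.any(x > 0):
        raise ValueError("S_ap is identically zero; beta is unidentifiable")
    beta_per_ms = float(np.dot(x, y) / np.dot(x, x))
    if nonnegative:
        beta_per_ms = max(0.0, beta_per_ms)
    beta = beta_per_ms * MS_PER_S
    pred = s_syn.interp(grid) + beta_per_ms * x
    obs = s.interp(grid)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    residual = Spectrum(grid, obs - pred, units=s.units, kind="cross")
    return LinearFitResult(beta=beta, r_squared=min(r2, 1.0), residual=residual)
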