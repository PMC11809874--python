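"""Spectral primitives shared by every stage of the apEEG pipeline.

All spectra live on a one-sided, strictly increasing frequency grid in Hz.
Time axes are in milliseconds throughout the package; energy spectra are
therefore densities of value^2*ms per Hz, so that integrating an energy
spectrum over frequency returns the time-domain energy  integral |u(t)|^2 dt
with dt in ms.  Power spectra are plain value^2 per Hz.  The single ms <-> s
conversion needed to make a firing rate in Hz multiply an energy density in
value^2*ms/Hz lives in :data:`MS_PER_S` and is applied exactly once per
formula (see :func:`apeeg.unitary.fit_linear_ap_model` and
:mod:`apeeg.ensemble`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

__all__ = [
    "MS_PER_S",
    "POWER_UNITS",
    "Spectrum",
    "TimeSeries",
    "WindowConfig",
    "estimate_psd",
    "estimate_csd",
    "energy_spectrum",
    "fourier_transform",
]

MS_PER_S = 1000.0

#: canonical unit tags; free strings are allowed but these are the ones the
#: pipeline produces
POWER_UNITS = "uV^2/Hz"


@dataclass
class TimeSeries:
    """Uniformly sampled signal, possibly with 3 channels (dipole x, y, z).

    ``samples`` has shape ``(n,)`` for a single channel or ``(c, n)`` for
    multichannel data; ``dt`` is the sampling interval in ms.
    """

    dt: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D or (channels, n)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz."""
        return MS_PER_S / self.dt

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def channels(self) -> np.ndarray:
        """Samples as a 2-D ``(channels, n)`` view."""
        return np.atleast_2d(self.samples)


@dataclass
class Spectrum:
    """One-sided spectral density on a strictly increasing grid of Hz.

    ``kind`` is one of ``power`` (real, >= 0), ``energy`` (real, >= 0) or
    ``cross`` (complex allowed).  Unit bookkeeping is by tag only; arithmetic
    helpers refuse to mix grids.
    """

    freqs: np.ndarray
    values: np.ndarray
    units: str = POWER_UNITS
    kind: str = "power"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values)
        if self.freqs.ndim != 1 or self.values.shape != self.freqs.shape:
            raise ValueError("freqs and values must be 1-D and equal length")
        if self.freqs.size and (np.any(np.diff(self.freqs) <= 0) or self.freqs[0] < 0):
            raise ValueError("freqs must be non-negative and strictly increasing")
        if self.kind not in ("power", "energy", "cross"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind in ("power", "energy"):
            if np.iscomplexobj(self.values):
                if np.any(np.abs(self.values.imag) > 0):
                    raise ValueError(f"{self.kind} spectrum must be real")
                self.values = self.values.real
            if np.any(self.values < 0):
                raise ValueError(f"{self.kind} spectrum must be non-negative")
            self.values = self.values.astype(float)

    def total(self) -> float:
        """Integral over frequency (trapezoid), e.g. variance or energy."""
        return float(np.trapezoid(np.real(self.values), self.freqs))

    def interp(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        if np.iscomplexobj(self.values):
            re = np.interp(f, self.freqs, self.values.real)
            im = np.interp(f, self.freqs, self.values.imag)
            return re + 1j * im
        return np.interp(f, self.freqs, self.values)

    def with_values(self, values: np.ndarray, kind: str | None = None,
                    units: str | None = None) -> "Spectrum":
        return Spectrum(self.freqs.copy(), np.asarray(values),
                        units=self.units if units is None else units,
                        kind=self.kind if kind is None else kind)

    def same_grid(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return (self.freqs.shape == other.freqs.shape
                and bool(np.allclose(self.freqs, other.freqs, atol=atol)))


@dataclass
class WindowConfig:
    """Welch averaged-periodogram settings.

    The default 2 s Hann segments with 50% overlap are a package choice; the
    segment length in ms is the knob that trades frequency resolution against
    the number of averages.
    """

    segment_ms: float = 2000.0
    overlap: float = 0.5
    window: str = "hann"
    detrend: str = "constant"

    def nperseg(self, dt_ms: float) -> int:
        return max(2, int(round(self.segment_ms / dt_ms)))


def _welch_like(func, a: TimeSeries, b: TimeSeries | None,
                cfg: WindowConfig) -> tuple[np.ndarray, np.ndarray]:
    nperseg = cfg.nperseg(a.dt)
    if a.n_samples < nperseg:
        raise ValueError(
            f"series of {a.n_samples} samples is shorter than one segment; "
            f"need at least {nperseg} samples ({cfg.segment_ms} ms at dt={a.dt} ms)")
    noverlap = int(nperseg * cfg.overlap)
    kw = dict(fs=a.fs_hz, window=cfg.window, nperseg=nperseg,
              noverlap=noverlap, detrend=cfg.detrend, return_onesided=True)
    xa = a.channels()
    if b is None:
        f, p = func(xa, **kw)
    else:
        f, p = func(xa, b.channels(), **kw)
    return f, p.sum(axis=0)  # total over channels (trace of the spectral matrix)


def estimate_psd(series: TimeSeries, segment_cfg: WindowConfig | None = None,
                 units: str = POWER_UNITS) -> Spectrum:
    """One-sided Welch power spectral density, summed over channels.

    Satisfies Parseval: the integral of the returned density over frequency
    approximates the (detrended) variance of the series, summed over channels.
    """
    cfg = segment_cfg or WindowConfig()
    f, p = _welch_like(scipy.signal.welch, series, None, cfg)
    return Spectrum(f, np.maximum(p.real, 0.0), units=units, kind="power")


def estimate_csd(a: TimeSeries, b: TimeSeries,
                 segment_cfg: WindowConfig | None = None,
                 units: str = POWER_UNITS) -> Spectrum:
    """One-sided Welch cross-spectral density between two series.

    Conjugate symmetric in its arguments: ``csd(a, b) == conj(csd(b, a))``.
    """
    if a.dt != b.dt:
        raise ValueError(f"sampling intervals differ: {a.dt} ms vs {b.dt} ms")
    if a.n_samples != b.n_samples:
        raise ValueError("series must have equal length")
    cfg = segment_cfg or WindowConfig()
    f, p = _welch_like(scipy.signal.csd, a, b, cfg)
    return Spectrum(f, p, units=units, kind="cross")


def fourier_transform(waveform: np.ndarray, dt_ms: float,
                      freqs_hz: np.ndarray) -> np.ndarray:
    """Continuous-time FT  integral u(t) exp(-2 pi i f t) dt  (dt in seconds).

    Evaluated by direct summation on an arbitrary frequency grid, which keeps
    every module on one shared grid without interpolation.  ``waveform`` may be
    ``(n,)`` or ``(c, n)``; the result has a matching leading shape.
    """
    w = np.atleast_2d(np.asarray(waveform, dtype=float))
    t_s = np.arange(w.shape[-1]) * dt_ms / MS_PER_S
    phase = np.exp(-2j * np.pi * np.outer(np.asarray(freqs_hz, float), t_s))
    out = (w @ phase.T) * (dt_ms / MS_PER_S)
    return out[0] if np.asarray(waveform).ndim == 1 else out


def energy_spectrum(kernel: TimeSeries, freqs: np.ndarray | None = None,
                    units: str = "value^2*ms/Hz") -> Spectrum:
    """One-sided energy spectral density |FT|^2 of a finite-duration kernel.

    The integral over frequency equals the time-domain energy
    ``sum(|u|^2) * dt`` in value^2*ms (channels summed).  With ``freqs`` given,
    the density is evaluated on that grid directly; otherwise a zero-padded
    FFT grid is used.
    """
    if kernel.n_samples == 0:
        raise ValueError("empty kernel has no energy spectrum")
    x = kernel.channels()
    if freqs is None:
        nfft = max(4096, 4 * x.shape[-1])
        spec = np.fft.rfft(x, n=nfft, axis=-1) * (kernel.dt / MS_PER_S)
        f = np.fft.rfftfreq(nfft, d=kernel.dt / MS_PER_S)
        esd = (np.abs(spec) ** 2).sum(axis=0)
    else:
        f = np.asarray(freqs, dtype=float)
        spec = fourier_transform(x, kernel.dt, f)
        esd = (np.abs(spec) ** 2).sum(axis=0)
    # two-sided -> one-sided, and value^2*s/Hz -> value^2*ms/Hz
    onesided = 2.0 * esd * MS_PER_S
    if freqs is None:
        onesided[0] /= 2.0
        if nfft % 2 == 0:
            onesided[-1] /= 2.0
    else:
        onesided[f == 0] /= 2.0
    return Spectrum(f, onesided, units=units, kind="energy")
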