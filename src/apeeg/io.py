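"""Readers and writers: spectrum CSV (+ JSON sidecar), HDF5 series/kernels,
YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .spectra import Spectrum, TimeSeries
from .unitary import UnitaryKernel

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "save_timeseries",
    "load_timeseries",
    "save_kernel_bank",
    "load_kernel_bank",
    "load_yaml_config",
]

_FMT = "%.17g"   # lossless float round trip


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    """Write freq_hz,value[,imag] columns plus a JSON sidecar with units/kind."""
    path = Path(path)
    cols = {"freq_hz": s.freqs}
    if np.iscomplexobj(s.values):
        cols["value"] = s.values.real
        cols["imag"] = s.values.imag
    else:
        cols["value"] = s.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FMT)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"units": s.units, "kind": s.kind},
                                  sort_keys=True) + "\n")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if "freq_hz" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: need freq_hz and value columns")
    freqs = df["freq_hz"].to_numpy(float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError(f"{path}: frequency column must be strictly increasing")
    units, kind = "uV^2/Hz", "power"
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        units, kind = meta.get("units", units), meta.get("kind", kind)
    if "imag" in df.columns:
        values = df["value"].to_numpy(float) + 1j * df["imag"].to_numpy(float)
    else:
        values = df["value"].to_numpy(float)
        if kind in ("power", "energy"):
            bad = np.flatnonzero(values < 0)
            if bad.size:
                raise ValueError(
                    f"{path}: negative {kind} value at data row {bad[0] + 1}")
    return Spectrum(freqs, values, units=units, kind=kind)


def save_timeseries(series: TimeSeries, path: str | Path,
                    name: str = "series") -> None:
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        ds = fh.create_dataset(name, data=series.channels())
        ds.attrs["dt_ms"] = series.dt


def load_timeseries(path: str | Path, name: str = "series") -> TimeSeries:
    with h5py.File(path, "r") as fh:
        ds = fh[name]
        data = np.asarray(ds)
        dt = float(ds.attrs["dt_ms"])
    return TimeSeries(dt, data[0] if data.shape[0] == 1 else data)


def save_kernel_bank(bank: dict[str, UnitaryKernel], path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        for name, k in bank.items():
            ds = fh.create_dataset(name, data=k.waveform)
            ds.attrs["dt_ms"] = k.dt
            ds.attrs["window_ms"] = list(k.window)


def load_kernel_bank(path: str | Path) -> dict[str, UnitaryKernel]:
    bank = {}
    with h5py.File(path, "r") as fh:
        for name, ds in fh.items():
            bank[name] = UnitaryKernel(
                float(ds.attrs["dt_ms"]), np.asarray(ds),
                window=tuple(ds.attrs["window_ms"]), label=name)
    return bank


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
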