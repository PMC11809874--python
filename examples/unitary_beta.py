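"""Fit the linear AP model to synthetic active/passive dipole traces.

Builds a band-pass unitary AP kernel, drives it with Poisson spikes on top
of a coloured-noise synaptic dipole, and fits S(f) = Ssyn(f) + beta*Sap(f).
The fitted beta should equal the firing rate.
"""

import numpy as np

from apeeg import (KernelParams, NeuronClassSpec, NoiseConfig, WindowConfig,
                   energy_spectrum, estimate_psd, fit_linear_ap_model,
                   make_active_passive_traces, make_kernel_bank)

spec = NeuronClassSpec("pyramidal", True, 1.0, KernelParams(amplitude=3.0))
kernel = make_kernel_bank([spec], dt_ms=0.25)["pyramidal"]
sap = energy_spectrum(kernel.as_timeseries())
cfg = WindowConfig(segment_ms=2000.0)

print("rate (Hz)   fitted beta (spikes/s)   R^2")
for i, lam in enumerate([2.0, 10.0, 40.0]):
    active, passive, spikes, _ = make_active_passive_traces(
        kernel, lam, 60_000.0, NoiseConfig(scale=2.0), seed=10 + i)
    res = fit_linear_ap_model(estimate_psd(active, cfg),
                              estimate_psd(passive, cfg), sap)
    print(f"{lam:8.1f}   {res.beta:20.2f}   {res.r_squared:.4f}")
print("beta tracks the firing rate: one AP adds one unitary energy "
      "spectrum per spike to the dipole power spectrum.")
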