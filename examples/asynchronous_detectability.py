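"""Whole-brain asynchronous apEEG versus the amplifier noise floor.

Calibrates the synthetic kernel bank so class-mean unitary scalp energies
match the reference values (0.09 / 0.02 pV^2*ms for excitatory /
inhibitory), then extrapolates to 16 billion uncorrelated Poisson neurons.
"""

from apeeg import (CortexGeometry, LeadField, N_CORTICAL_NEURONS,
                   NOISE_FLOOR_UV2_HZ, asynchronous_spectrum,
                   calibrate_kernel_bank, detectability, make_kernel_bank,
                   make_population, mean_unitary_spectrum, population_to_specs)

pop = make_population(excitatory_fraction=0.85, class_count=8, seed=0)
specs = population_to_specs(pop)
bank = make_kernel_bank(specs)
geom = CortexGeometry.sphere(radius_mm=70.0)
lf = LeadField.infinite_medium([0.0, 0.0, 85.0])
bank = calibrate_kernel_bank(bank, specs, geom, lf, n_locations=100, seed=0)

mu = mean_unitary_spectrum(bank, pop, geom, lf, n_locations=100, seed=0)
print(f"abundance-weighted unitary scalp energy: "
      f"{mu.weighted_energy:.4f} pV^2*ms (0.85*0.09 + 0.15*0.02 = 0.0795)")

for lam in (1.0, 100.0):
    s = asynchronous_spectrum(lam, N_CORTICAL_NEURONS, mu)
    peak, flag = detectability(s, floor=NOISE_FLOOR_UV2_HZ)
    print(f"lambda = {lam:5.1f} Hz: max density above 30 Hz = {peak:.2e} "
          f"uV^2/Hz -> detectable: {flag}")
print(f"noise floor {NOISE_FLOOR_UV2_HZ:g} uV^2/Hz: asynchronous spiking "
      "alone cannot produce measurable scalp EEG.")
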