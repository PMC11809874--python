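"""Double-Lorentzian spectral-trend fit round trip.

Generates a noiseless trend spectrum from the reference synaptic time
constants, adds the amplifier floor, then subtracts it and refits.
"""

import numpy as np

from apeeg import (Spectrum, PARALYZED_EEG_TREND, eval_trend, fit_trend,
                   subtract_noise_floor)

f = np.geomspace(1.0, 300.0, 200)
observed = Spectrum(f, eval_trend(PARALYZED_EEG_TREND, f) + 1e-3)

corrected, clipped = subtract_noise_floor(observed, 1e-3)
params, gof = fit_trend(corrected)

print(f"noise floor subtracted ({clipped} bins clipped)")
print(f"tau_I = ({params.tau_i1 * 1e3:.2f}, {params.tau_i2 * 1e3:.2f}) ms "
      f"(truth 4, 20)")
print(f"A_I = {params.amp_inhibitory:.3f} (truth 3.6), "
      f"A_E = {params.amp_excitatory:.3f} (truth 3.3), "
      f"log-space R^2 = {gof['r_squared_log']:.6f}")
print("the slow (GABA) pair sets the low-frequency knee; the fast (AMPA) "
      "pair contributes a shoulder near 100 Hz.")
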