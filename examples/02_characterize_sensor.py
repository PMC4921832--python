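"""Recover a sensor's spectral sensitivity from narrowband probing.

Emulates the monochromator procedure: shine unit-intensity narrowband light
at each grid wavelength, record the 3-channel response, and average repeats.
The recovered matrix is compared against the true sensitivity it came from.
"""

import numpy as np

import specdemux as sd

grid = sd.make_wavelength_grid()
true_sens = sd.synth_sensitivity(grid)

rng = np.random.default_rng(0)
responses = {}
for k, w in enumerate(grid.values):
    impulse = np.zeros(len(grid))
    impulse[k] = 1.0
    clean = sd.forward(true_sens, sd.ReflectanceSpectrum(grid, impulse)).values
    # 10 noisy repeats per wavelength, like replicate exposures
    responses[float(w)] = [clean + rng.normal(0, 0.005, 3) for _ in range(10)]

recovered = sd.characterize_from_narrowband(responses, grid, true_sens.channels)
err = np.max(np.abs(recovered.matrix - true_sens.matrix))
print(f"recovered a {recovered.matrix.shape} sensitivity matrix")
print(f"max abs deviation from the true sensitivity: {err:.4f}")
print("With 10 repeats of sigma=0.005 noise the column means land within "
      "a few thousandths of the true response; noise-free probing would "
      "recover it exactly.")
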