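"""Estimate directed connectivity (dDTF) from a planted two-channel system.

A theta-band coupling ch0 -> ch1 is planted in a VAR model; the ridge-fit
VAR / spectral-transfer / dDTF chain must show a large forward-to-reverse
asymmetry concentrated in the theta band.
"""

import numpy as np

from emolink import (
    PlantedEdge,
    band_average,
    ddtf,
    fit_var_ridge,
    make_band_coupled_var,
    simulate_var_eeg,
    transfer_function,
)
from emolink.connectivity import DEFAULT_FREQS

fs = 250.0
model = make_band_coupled_var(2, [PlantedEdge("ch0", "ch1", "theta", 0.3)], fs)
eeg = simulate_var_eeg(model, 20_000, seed=1)

fit = fit_var_ridge(eeg, order=15, ridge=1e-6, fs=fs)
tensor = band_average(ddtf(transfer_function(fit, DEFAULT_FREQS)))

print("band-averaged dDTF (planted direction ch0 -> ch1):")
for k, band in enumerate(tensor.bands):
    fwd = tensor.values[1, 0, k]
    rev = tensor.values[0, 1, k]
    print(f"  {band:6s}  forward {fwd:.2e}   reverse {rev:.2e}")
theta = tensor.bands.index("theta")
ratio = tensor.values[1, 0, theta] / tensor.values[0, 1, theta]
print(f"\ntheta forward/reverse ratio: {ratio:.0f}x")
# The planted direction dominates by orders of magnitude, and the
# coupling is concentrated in the theta band where it was planted.
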