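"""Ensemble empirical mode decomposition of a noisy breathing series.

Decomposes a breathing signal buried in noise into intrinsic mode
functions, prints each IMF's respiration-band energy ratio, and
reconstructs the breathing signal from the modes passing the 0.5 ratio
threshold.
"""

import numpy as np

from sbda import EEMDConfig, eemd, estimate_rate_fft, score_imfs, select_and_reconstruct

fs = 20.0
t = np.arange(int(90 * fs)) / fs
rng = np.random.default_rng(3)
signal = np.sin(2 * np.pi * 0.3 * t) + 0.5 * rng.standard_normal(t.size)

imfset = eemd(signal, EEMDConfig(n_trials=50, noise_sigma_ratio=0.2, rng_seed=0))
selection = score_imfs(imfset, fs, band_hz=(0.1, 0.8), delta_r=0.5)

print(f"{len(imfset)} IMFs extracted (index 1 = highest frequency)")
print("imf  band-energy ratio  selected")
for j, ratio in enumerate(selection.ratios, start=1):
    print(f"{j:>3}  {ratio:17.4f}  {j - 1 in selection.selected}")

breathing = select_and_reconstruct(imfset, fs, selection)
estimate = estimate_rate_fft(breathing, fs, method="sbda")
print(f"reconstructed rate: {estimate.rate_bpm:.2f} breaths/min (truth 18.00)")
# High-order IMFs carry the noise; the modes whose spectral energy
# concentrates in 0.1-0.8 Hz carry the 0.3 Hz breathing line.
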