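"""Empirical mode decomposition of a two-tone signal.

A 20 Hz + 2 Hz mixture should split cleanly: IMF1 carries the fast tone
and IMF2 the slow one. The script prints per-IMF zero-crossing counts
(decreasing down the ladder), the correlation of the first two IMFs with
the known tones, and the reconstruction error of the telescoping
identity sum(IMFs) + residual == input.
"""

import numpy as np

import emdad
from emdad.emd import zero_crossings

fs = 200.0
t = np.arange(1600) / fs
fast = np.sin(2 * np.pi * 20 * t)
slow = np.sin(2 * np.pi * 2 * t)
x = fast + slow

s = emdad.emd_decompose(x)
print("zero crossings per component:",
      [zero_crossings(imf) for imf in s.imfs], "+ residual")

center = slice(160, 1440)  # central 80%, away from boundary effects
r1 = np.corrcoef(s.imfs[0][center], fast[center])[0, 1]
r2 = np.corrcoef(s.imfs[1][center], slow[center])[0, 1]
print(f"corr(IMF1, 20 Hz tone) = {r1:.4f}")
print(f"corr(IMF2,  2 Hz tone) = {r2:.4f}")

err = np.max(np.abs(s.reconstruct() - x)) / np.max(np.abs(x))
print(f"max relative reconstruction error = {err:.2e}")
print("values near 1.0 mean each tone landed in its own mode; the")
print("reconstruction error is pure floating-point round-off.")
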