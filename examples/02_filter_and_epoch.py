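"""Design the elliptic band-pass, filter a recording, cut epochs.

Prints the filter's magnitude response at key frequencies (passband flat
within the ripple, 90 Hz strongly attenuated) and the epoch bookkeeping:
a recording's sample count fixes the number of 8-s windows, and window
counts account for total recorded duration.
"""

import numpy as np

import emdad

spec = emdad.design_bandpass(0.1, 60.0, fs=200.0)
for f in (0.05, 10.0, 30.0, 60.0, 90.0):
    mag = spec.frequency_response(f)[0]
    print(f"|H({f:5.2f} Hz)| = {mag:.4f} ({20 * np.log10(max(mag, 1e-12)):7.2f} dB)")

cohort = emdad.generate_cohort(
    emdad.CohortSpec(subjects_per_class=2, trials_per_subject=5,
                     n_channels=4, seed=1)
)
rec = emdad.apply_filter(cohort[0], spec)
epochs = emdad.epoch_signal(rec, epoch_seconds=8.0)
print(f"\n{rec.n_samples} samples at {rec.fs:.0f} Hz -> {len(epochs)} epochs "
      f"of {epochs[0].data.shape[1]} samples")

# the study-scale bookkeeping: window counts times 8 s give group durations
for group, n in [("neurotypical", 1426), ("mild AD", 1514), ("moderate AD", 930)]:
    print(f"{n:5d} eight-second windows -> "
          f"{emdad.total_duration_seconds(n, 8.0):8.0f} s of {group} EEG")
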