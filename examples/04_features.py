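"""Compute the seven per-component features on a decomposed epoch.

Decomposes one channel epoch and prints each feature for IMF1 and the
residual, then builds a full feature matrix for a tiny cohort and writes
it to CSV (lossless double-precision round trip via dataio).
"""

import numpy as np

import emdad
from emdad.features import COMPONENT_NAMES, FEATURE_NAMES, compute_feature

fs = 200.0
rng = np.random.default_rng(5)
x = rng.standard_normal(1600)
s = emdad.emd_decompose(x)

print(f"{'feature':>8} {'IMF1':>10} {'residual':>10}")
for name in FEATURE_NAMES:
    v1 = compute_feature(name, s.imfs[0], fs)
    vr = compute_feature(name, s.residual, fs)
    print(f"{name:>8} {v1:10.4f} {vr:10.4f}")
print("IMF1 is the fastest mode: highest mean frequency and zero-crossing")
print("rate; the residual is slow and regular (low ApEn, low mf).")

cohort = emdad.generate_cohort(
    emdad.CohortSpec(subjects_per_class=2, trials_per_subject=3,
                     n_channels=4, seed=9)
)
decomposed, channels = emdad.decompose_epochs(cohort)
fm = emdad.extract_features(decomposed, channels, ("lbp",))["lbp"]
print(f"\nfeature matrix: {fm.values.shape[0]} trials x "
      f"{fm.values.shape[1]} columns ({len(channels)} channels x "
      f"{len(COMPONENT_NAMES)} components)")
emdad.write_feature_matrix(fm, "scratch_lbp_features.csv")
back = emdad.read_feature_matrix("scratch_lbp_features.csv", "lbp")
print("CSV round trip bit-exact:", np.array_equal(back.values, fm.values))
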