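"""Generate a synthetic three-class EEG cohort and inspect its spectra.

Builds a small seeded cohort (neurotypical / mild AD / moderate AD) and
prints the per-class mean band power in the theta and alpha bands: the
generator encodes the canonical AD spectral shift, so alpha power should
fall and theta power rise with severity.
"""

import emdad

spec = emdad.CohortSpec(subjects_per_class=3, trials_per_subject=6,
                        n_channels=8, seed=42)
cohort = emdad.generate_cohort(spec)
print(f"{len(cohort)} recordings, "
      f"{cohort[0].n_channels} channels x {cohort[0].n_samples} samples each")

for band in ("theta", "alpha"):
    report = emdad.class_contrast_report(cohort, emdad.BANDS[band])
    pretty = {k: round(v, 2) for k, v in report.items()}
    print(f"{band} band power (uV^2): {pretty}")

print("alpha decreases and theta increases from neurotypical to moderate AD,")
print("mirroring the generator's 3/2/1 and 1/2/3 band-weight orderings.")
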