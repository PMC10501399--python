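# emdad

EEG-based decision support for Alzheimer's disease (AD) staging:
band-pass filtering, empirical mode decomposition (EMD), per-component
scalar features, and multi-classifier evaluation under trial-pooled and
subject-grouped cross-validation — with a seeded synthetic three-class
cohort generator standing in for clinical data.

## Who this is for

Researchers studying EEG spectral biomarkers of dementia who want a
tested, reproducible reference implementation of the
EMD-feature-classifier pipeline, and a controllable synthetic cohort to
probe its behaviour (class contrast, subject variability, SNR, CV
leakage) without access to clinical recordings.

## The method

Resting-state EEG shifts with AD severity: alpha (8–13 Hz) power falls,
theta/delta power rises. The pipeline quantifies this per 8-second
trial:

1. **Filter** — elliptic IIR band-pass 0.1–60 Hz, zero-phase (applied
   forward–backward as second-order sections).
2. **Decompose** — each channel epoch x(t) is sifted into intrinsic
   mode functions: envelopes E₊, E₋ through the local extrema (natural
   cubic splines), mean M = (E₊+E₋)/2 subtracted until the Cauchy
   criterion Σ(h_prev−h_new)²/Σh_prev² < 0.2 (max 10 sifts), giving

       x(t) = Σᵢ₌₁⁷ IMFᵢ(t) + R(t)

   exactly (telescoping), with zero-filled placeholders when modes are
   exhausted early.
3. **Features** — one scalar per component: approximate entropy
   ApEn(e=2, r=0.2·SD), energy Σx², log band power ln(Σx²/N), mean
   frequency ΣfⱼPⱼ/ΣPⱼ, norm √(Σx²), peak-to-peak, zero-crossing rate.
   A 20-channel trial yields a 160-wide row per feature type.
4. **Classify** — LDA, linear SVM, AdaBoost over trees, and small
   feed-forward / recurrent / convolutional networks, on five
   diagnostic contrasts (each pair of classes, neurotypical vs all AD,
   and the 3-class problem), under stratified 10-fold (trials pooled)
   and subject-grouped 20%-holdout CV, reporting precision / recall /
   accuracy per fold average.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
import emdad

spec = emdad.CohortSpec(subjects_per_class=5, trials_per_subject=10,
                        n_channels=8, seed=42)
cohort = emdad.generate_cohort(spec)

# class-level spectral contrast the generator encodes
print(emdad.class_contrast_report(cohort, emdad.BANDS["alpha"]))
# {'neurotypical': 3.07, 'mild_ad': 1.95, 'moderate_ad': 0.99}  µV², falls with severity

decomposed, channels = emdad.decompose_epochs(cohort)
mats = emdad.extract_features(decomposed, channels, ("lbp",))
records = emdad.run_issue(mats, "V", emdad.default_configs(("lda",), seed=0),
                          schemes=("kfold", "loso"), k=10, seed=0)
for r in records:
    print(r.cv_scheme, round(r.accuracy, 1))
# kfold 98.7
# loso 99.3
```

The alpha-band report shows the generator's monotone 3/2/1 power
ordering across severity; the accuracies show the three-class problem
is almost solved at this contrast (on a single small cohort the two
schemes are within noise of each other; averaged over replicates the
pooled scheme comes out on top — see the acceptance script). Runnable
scripts for each capability are under `examples/`.

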