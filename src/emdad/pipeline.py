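"""End-to-end convenience layer: cohort -> filter -> epochs -> EMD ->
feature matrices -> evaluation records."""

from __future__ import annotations



from .classify import default_configs

from .emd import SiftStopCriteria, emd_decompose
from .evaluate import run_issue
from .features import ApEnParams, FeatureMatrix, build_feature_matrix
from .preprocess import apply_filter, design_bandpass, epoch_signal


def decompose_epochs(
    recordings: list,
    epoch_seconds: float = 8.0,
    max_epochs: int | None = None,
    n_imfs: int = 7,
    stop: SiftStopCriteria = SiftStopCriteria(),
    bandpass: bool = True,
) -> tuple:
    """Filter, epoch and EMD-decompose a cohort.

    Returns ``(decomposed, channel_labels)`` where ``decomposed`` is a
    list of ``(epoch, [IMFSet per channel])`` pairs ordered by (subject,
    trial), ready for :func:`~emdad.features.build_feature_matrix`.
    """
    if not recordings:
        raise ValueError("empty cohort")
    fs = recordings[0].fs
    spec = design_bandpass(fs=fs) if bandpass else None
    decomposed = []
    for rec in recordings:
        filtered = apply_filter(rec, spec) if spec is not None else rec
        for epoch in epoch_signal(filtered, epoch_seconds, max_epochs):
            imfsets = [
                emd_decompose(epoch.data[ch], n_imfs=n_imfs, stop=stop)
                for ch in range(epoch.data.shape[0])
            ]
            decomposed.append((epoch, imfsets))
    return decomposed, recordings[0].channel_labels


def extract_features(
    decomposed: list,
    channel_labels,
    feature_names=("lbp",),
    apen_params: ApEnParams = ApEnParams(),
) -> dict:
    """One :class:`FeatureMatrix` per requested feature type."""
    return {
        name: build_feature_matrix(decomposed, name, channel_labels,
                                   apen_params=apen_params)
        for name in feature_names
    }


def run_pipeline(
    recordings: list,
    issues=("I", "II", "III", "IV", "V"),
    feature_names=("lbp",),
    classifier_kinds=("lda",),
    schemes=("kfold", "loso"),
    k: int = 10,
    seed: int = 0,
    epoch_seconds: float = 8.0,
    classifier_overrides=None,
) -> list:
    """Run the full analysis on a cohort and return evaluation records."""
    decomposed, channels = decompose_epochs(recordings, epoch_seconds)
    matrices = extract_features(decomposed, channels, feature_names)
    configs = default_configs(classifier_kinds, seed=seed,
                              overrides=classifier_overrides)
    records = []
    for issue in issues:
        records.extend(
            run_issue(matrices, issue, configs, schemes=schemes, k=k, seed=seed)
        )
    return records
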