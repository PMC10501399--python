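"""Seeded synthetic EEG cohorts with class-dependent spectral structure.

The generator emulates the statistical structure a resting-state EEG
study of Alzheimer's disease relies on, without attempting physiological
realism: each class (neurotypical, mild AD, moderate AD) is defined by
relative power weights over the four classical bands (delta 0.5-4 Hz,
theta 4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz) on top of a 1/f^beta
background.  The default profiles encode the canonical AD spectral
shift — alpha power falls and theta power rises with disease severity —
with monotone weight orderings 3/2/1 (alpha) and 1/2/3 (theta) across
neurotypical / mild / moderate.

Per channel, a signal is a mixture of a subject-level common source and
channel-independent noise (30% shared variance), both built as

    sum_bands sqrt(weight_b) * unit-power band-limited Gaussian noise
    + background 1/f^beta noise at the configured SNR.

Band weights receive a seeded per-subject multiplicative jitter (+-10%)
so that subject-wise cross-validation is non-trivial.  Everything is
driven by ``numpy.random.SeedSequence`` spawned per (class, subject), so
a cohort is a pure function of its spec: identical spec and seed give
bit-identical signals, and distinct subjects differ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .dataio import (
    CLASS_LABELS,
    CohortManifest,
    EEGRecording,
    MONTAGE_1020,
    write_edf,
)

BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

_DEFAULT_ALPHA = {"neurotypical": 3.0, "mild_ad": 2.0, "moderate_ad": 1.0}
_DEFAULT_THETA = {"neurotypical": 1.0, "mild_ad": 2.0, "moderate_ad": 3.0}


class ConfigurationError(ValueError):
    """A cohort spec violates one of its invariants."""


@dataclass(frozen=True)
class ClassSpectralProfile:
    """Relative band-power weights and background for one class."""

    class_label: str
    band_weights: dict            # band name -> linear power weight >= 0
    background_exponent: float = 1.0
    snr_db: float = 20.0

    def __post_init__(self):
        if not self.band_weights or all(w == 0 for w in self.band_weights.values()):
            raise ConfigurationError("at least one band weight must be > 0")
        for name, w in self.band_weights.items():
            if w < 0:
                raise ConfigurationError(f"band weight {name} is negative")
            if name not in BANDS:
                raise ConfigurationError(f"unknown band {name!r}")


def default_profiles(contrast: float = 1.0) -> dict:
    """Class profiles with the canonical AD spectral contrast.

    ``contrast`` interpolates between the default monotone orderings
    (1.0) and completely flat, class-indistinguishable weights (0.0);
    the flat point is the across-class mean of each band's defaults, so
    total power is independent of contrast.
    """
    profiles = {}
    for label in CLASS_LABELS:
        alpha = 2.0 + contrast * (_DEFAULT_ALPHA[label] - 2.0)
        theta = 2.0 + contrast * (_DEFAULT_THETA[label] - 2.0)
        profiles[label] = ClassSpectralProfile(
            class_label=label,
            band_weights={"delta": 1.0, "theta": theta, "alpha": alpha, "beta": 1.0},
        )
    return profiles


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one cohort deterministically."""

    subjects_per_class: int = 5
    trials_per_subject: int = 28
    n_channels: int = 20
    fs: float = 200.0
    epoch_seconds: float = 8.0
    seed: int = 0
    profiles: dict | None = None   # class label -> ClassSpectralProfile
    subject_jitter: float = 0.10   # +-fraction on band weights per subject
    common_source_fraction: float = 0.30

    def __post_init__(self):
        spe = self.fs * self.epoch_seconds
        if abs(spe - round(spe)) > 1e-9:
            raise ConfigurationError(
                f"fs * epoch_seconds = {spe} is not an integer sample count"
            )
        if self.subjects_per_class < 2:
            raise ConfigurationError(
                "subjects_per_class must be >= 2 for cross-validation feasibility"
            )
        if self.trials_per_subject < 1 or self.n_channels < 1:
            raise ConfigurationError("trials_per_subject and n_channels must be >= 1")
        if self.profiles is None:
            object.__setattr__(self, "profiles", default_profiles())

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.fs * self.epoch_seconds))

    @property
    def samples_per_subject(self) -> int:
        return self.trials_per_subject * self.samples_per_epoch


def null_cohort_spec(spec: CohortSpec) -> CohortSpec:
    """The label-uninformative counterpart of ``spec``.

    Class profiles are flattened *and* the per-subject band-weight jitter
    is removed.  Both carry label-correlated information: flat profiles
    remove the class contrast, and zero jitter removes subject signatures
    that pooled-trial cross-validation could otherwise memorize (every
    subject belongs to exactly one class).  A correct pipeline evaluated
    on such a cohort can only score at chance.
    """
    return replace(spec, profiles=default_profiles(0.0), subject_jitter=0.0)


def _structured_noise(rng, n: int, fs: float, weights: dict) -> np.ndarray:
    """Sum over bands of sqrt(weight) x unit-average-power band noise."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    out = np.zeros(n)
    for band, w in weights.items():
        if w == 0:
            continue
        lo, hi = BANDS[band]
        spec = np.fft.rfft(rng.standard_normal(n))
        spec[(freqs < lo) | (freqs >= hi)] = 0.0
        x = np.fft.irfft(spec, n)
        power = np.mean(x * x)
        if power > 0:
            out += np.sqrt(w / power) * x
    return out


def _background_noise(rng, n: int, fs: float, beta: float) -> np.ndarray:
    """Unit-average-power 1/f^beta noise, flat below 0.5 Hz, no DC."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    shaping = np.zeros_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = np.maximum(freqs[nonzero], 0.5) ** (-beta / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    power = np.mean(x * x)
    return x / np.sqrt(power)


def _subject_signal(ss: np.random.SeedSequence, spec: CohortSpec,
                    profile: ClassSpectralProfile) -> np.ndarray:
    rng = np.random.default_rng(ss)
    n = spec.samples_per_subject
    jitter = 1.0 + spec.subject_jitter * rng.uniform(-1.0, 1.0, size=len(profile.band_weights))
    weights = {
        band: w * j
        for (band, w), j in zip(profile.band_weights.items(), jitter)
    }
    total_w = sum(weights.values())
    bg_scale = np.sqrt(total_w * 10.0 ** (-profile.snr_db / 10.0))

    def one_source() -> np.ndarray:
        return (
            _structured_noise(rng, n, spec.fs, weights)
            + bg_scale * _background_noise(rng, n, spec.fs, profile.background_exponent)
        )

    common = one_source()
    c = spec.common_source_fraction
    data = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        data[ch] = np.sqrt(c) * common + np.sqrt(1.0 - c) * one_source()
    return data


def generate_cohort(spec: CohortSpec) -> list:
    """Generate ``subjects_per_class`` recordings per class.

    Returns a list of :class:`~emdad.dataio.EEGRecording`, ordered by
    class then subject index; subject ids are ``<class>-s<k>``.
    """
    root = np.random.SeedSequence(spec.seed)
    channels = tuple(MONTAGE_1020[: spec.n_channels]) if spec.n_channels <= len(
        MONTAGE_1020
    ) else tuple(MONTAGE_1020) + tuple(
        f"X{i}" for i in range(spec.n_channels - len(MONTAGE_1020))
    )
    recordings = []
    for ci, label in enumerate(CLASS_LABELS):
        profile = spec.profiles[label]
        for si in range(spec.subjects_per_class):
            ss = np.random.SeedSequence(
                entropy=spec.seed, spawn_key=(ci, si)
            )
            data = _subject_signal(ss, spec, profile)
            recordings.append(
                EEGRecording(
                    subject_id=f"{label}-s{si}",
                    class_label=label,
                    fs=spec.fs,
                    channel_labels=channels,
                    data=data,
                )
            )
    return recordings


def band_power(x: np.ndarray, fs: float, band: tuple) -> float:
    """Mean periodogram power of ``x`` inside ``band`` (integrated PSD)."""
    lo, hi = band
    freqs, psd = _sig.periodogram(x, fs=fs, window="boxcar", detrend=False)
    mask = (freqs >= lo) & (freqs < hi)
    return float(np.trapezoid(psd[mask], freqs[mask]))


def class_contrast_report(cohort: list, band: tuple) -> dict:
    """Per-class mean band power over all channels of every recording.

    A quick sanity surface for the generator: with the default profiles
    the class ordering of e.g. theta power mirrors the configured band
    weights (moderate AD > mild AD > neurotypical).
    """
    if not cohort:
        raise ValueError("empty cohort")
    lo, hi = band
    fs = cohort[0].fs
    if hi > fs / 2:
        raise ValueError(f"band upper edge {hi} exceeds Nyquist {fs / 2}")
    sums: dict = {}
    counts: dict = {}
    for rec in cohort:
        for ch in range(rec.n_channels):
            p = band_power(rec.data[ch], rec.fs, band)
            sums[rec.class_label] = sums.get(rec.class_label, 0.0) + p
            counts[rec.class_label] = counts.get(rec.class_label, 0) + 1
    return {label: sums[label] / counts[label] for label in sums}


def save_cohort(cohort: list, directory, epoch_seconds: float = 8.0) -> CohortManifest:
    """Write one EDF per subject plus a JSON manifest ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    fs = cohort[0].fs
    spe = int(round(fs * epoch_seconds))
    for rec in cohort:
        fname = f"{rec.subject_id}.edf"
        write_edf(rec, directory / fname, record_seconds=epoch_seconds)
        entries.append(
            {
                "subject_id": rec.subject_id,
                "class_label": rec.class_label,
                "file": fname,
                "n_trials": rec.n_samples // spe,
            }
        )
    manifest = CohortManifest(entries=entries, fs=fs, epoch_seconds=epoch_seconds)
    manifest.save(directory / "manifest.json")
    return manifest
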