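"""Scalar features computed on every IMF/residual component.

Seven operators are supported, each producing one number per component:

========  ==========================================================
apen      approximate entropy (pattern regularity)
energy    sum of squared magnitudes
lbp       logarithmic band power, log of the mean squared magnitude
mf        mean frequency of the periodogram power spectrum
norm      Euclidean norm, sqrt of the energy
ppv       peak-to-peak value, max minus min
zcr       zero-crossing rate, normalized count of sign transitions
========  ==========================================================

A trial's feature vector stacks the chosen operator over all channels and
all components (7 IMFs + residual), channel-major, giving a constant
``n_channels * 8`` width; feature types are never concatenated with each
other — each feature matrix is classified on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .emd import IMFSet

_LBP_FLOOR_EPS = 1e-12

COMPONENT_NAMES = tuple(f"IMF{i}" for i in range(1, 8)) + ("residual",)

FEATURE_NAMES = ("apen", "energy", "lbp", "mf", "norm", "ppv", "zcr")


@dataclass(frozen=True)
class ApEnParams:
    """Approximate-entropy parameters.

    ``r`` is specified as a multiple of the component's standard
    deviation, which makes the statistic invariant to amplitude scaling.
    ``norm_kind`` selects the vector norm used to compare embedded
    patterns: the Chebyshev maximum norm is the standard choice; the
    Euclidean norm is available for comparison.
    """

    e: int = 2
    r: float = 0.2
    norm_kind: str = "max"  # or "euclidean"

    def __post_init__(self):
        if self.e < 1:
            raise ValueError("embedding dimension e must be >= 1")
        if self.r < 0:
            raise ValueError("tolerance multiplier r must be >= 0")
        if self.norm_kind not in ("max", "euclidean"):
            raise ValueError(f"unknown norm_kind {self.norm_kind!r}")


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """All length-m windows of x as rows, shape (N - m + 1, m)."""
    return np.lib.stride_tricks.sliding_window_view(x, m)


def _phi(x: np.ndarray, m: int, r_abs: float, norm_kind: str) -> float:
    """Mean log correlation integral over the N-m+1 embedded patterns.

    Self-comparisons are included (the Heaviside step is 1 at zero
    distance), so every correlation integral is strictly positive and the
    logarithm is always defined.
    """
    windows = _embed(x, m)
    n_vec = windows.shape[0]
    if norm_kind == "max":
        d = np.abs(windows[:, None, 0] - windows[None, :, 0])
        for k in range(1, m):
            np.maximum(d, np.abs(windows[:, None, k] - windows[None, :, k]), out=d)
        within = d <= r_abs
    else:
        sq = np.zeros((n_vec, n_vec))
        for k in range(m):
            diff = windows[:, None, k] - windows[None, :, k]
            sq += diff * diff
        within = sq <= r_abs * r_abs
    c = within.mean(axis=1)
    return float(np.mean(np.log(c)))


def apen(x: np.ndarray, params: ApEnParams = ApEnParams()) -> float:
    """Approximate entropy of a component.

    Computed as the difference of mean log correlation integrals at
    embedding dimensions ``e`` and ``e + 1``; the tolerance is
    ``params.r`` times the population standard deviation of ``x``.  A
    constant component (zero SD) has entropy 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= params.e + 1:
        raise ValueError(f"need more than e+1={params.e + 1} samples, got {n}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r_abs = params.r * sd
    return _phi(x, params.e, r_abs, params.norm_kind) - _phi(
        x, params.e + 1, r_abs, params.norm_kind
    )


def energy(x: np.ndarray) -> float:
    """Sum of the squared magnitudes."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty component")
    return float(np.sum(x * x))


def lbp(x: np.ndarray) -> float:
    """Log (natural) of the mean squared magnitude.

    An identically-zero component has no defined band power; the
    configured floor ``log(1e-12)`` is returned instead.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty component")
    mean_sq = float(np.mean(x * x))
    if mean_sq == 0.0:
        return float(np.log(_LBP_FLOOR_EPS))
    return float(np.log(mean_sq))


def mean_frequency(x: np.ndarray, fs: float) -> float:
    """Power-weighted mean of the periodogram frequencies, in Hz.

    A full-length rectangular-window periodogram is used, so a tone
    aligned to a frequency bin concentrates its power in that single bin
    and the mean frequency recovers it exactly.  Zero total power
    returns 0.
    """
    x = np.asarray(x, dtype=float)
    freqs, power = _sig.periodogram(x, fs=fs, window="boxcar", detrend=False)
    total = float(np.sum(power))
    if total == 0.0:
        return 0.0
    return float(np.sum(freqs * power) / total)


def norm_feature(x: np.ndarray) -> float:
    """Euclidean norm: square root of the sum of squares."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty component")
    return float(np.sqrt(np.sum(x * x)))


def ppv(x: np.ndarray) -> float:
    """Peak-to-peak value |max - min|."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty component")
    return float(np.abs(np.max(x) - np.min(x)))


def zcr(x: np.ndarray) -> float:
    """Zero-crossing rate: (1/N) * sum |sgn(x_n) - sgn(x_{n-1})|.

    The sign convention maps zero to +1, and each crossing contributes 2
    to the sum, so values range over [0, 2).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    s = np.where(x >= 0, 1.0, -1.0)
    return float(np.sum(np.abs(s[1:] - s[:-1])) / x.size)


def compute_feature(name: str, x: np.ndarray, fs: float,
                    apen_params: ApEnParams = ApEnParams()) -> float:
    if name == "apen":
        return apen(x, apen_params)
    if name == "energy":
        return energy(x)
    if name == "lbp":
        return lbp(x)
    if name == "mf":
        return mean_frequency(x, fs)
    if name == "norm":
        return norm_feature(x)
    if name == "ppv":
        return ppv(x)
    if name == "zcr":
        return zcr(x)
    raise ValueError(f"unknown feature {name!r}; choose from {FEATURE_NAMES}")


@dataclass
class FeatureMatrix:
    """Trials x (channels x 8 components) matrix for one feature type."""

    values: np.ndarray
    feature_name: str
    column_labels: tuple
    labels: tuple        # class label per trial
    subject_ids: tuple   # subject id per trial

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x columns)")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("column count does not match column_labels")
        if not (self.values.shape[0] == len(self.labels) == len(self.subject_ids)):
            raise ValueError("row count, labels and subject_ids must agree")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def feature_columns(channel_labels) -> tuple:
    return tuple(
        f"{ch}_{comp}" for ch in channel_labels for comp in COMPONENT_NAMES
    )


def compute_feature_vector(
    imfsets: list,
    feature_name: str,
    fs: float,
    apen_params: ApEnParams = ApEnParams(),
) -> np.ndarray:
    """One trial's feature row: channel-major over IMF1..IMF7, residual.

    ``imfsets`` holds one :class:`~emdad.emd.IMFSet` per channel, in
    channel order.  Placeholder (zero-filled) IMFs are evaluated like any
    other component, through each operator's degenerate-input rule.
    """
    lengths = {imfset.residual.size for imfset in imfsets}
    if len(lengths) != 1:
        raise ValueError("all channels must share the same epoch length")
    row = [
        compute_feature(feature_name, comp, fs, apen_params)
        for imfset in imfsets
        for comp in imfset.components
    ]
    return np.asarray(row)


def build_feature_matrix(
    decomposed_epochs: list,
    feature_name: str,
    channel_labels,
    apen_params: ApEnParams = ApEnParams(),
) -> FeatureMatrix:
    """Stack per-trial feature vectors into a matrix with metadata.

    ``decomposed_epochs`` is a list of ``(epoch, imfsets)`` pairs as
    produced by :func:`emdad.pipeline.decompose_epochs`.  Row order
    follows the input order, so it is a deterministic function of
    (subject order, trial index).
    """
    if not decomposed_epochs:
        raise ValueError("need at least one epoch")
    fs_values = {ep.fs for ep, _ in decomposed_epochs}
    if len(fs_values) != 1:
        raise ValueError(f"mixed sampling rates in input: {sorted(fs_values)}")
    fs = fs_values.pop()
    rows, labels, subjects = [], [], []
    for ep, imfsets in decomposed_epochs:
        rows.append(compute_feature_vector(imfsets, feature_name, fs, apen_params))
        labels.append(ep.class_label)
        subjects.append(ep.subject_id)
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_name=feature_name,
        column_labels=feature_columns(channel_labels),
        labels=tuple(labels),
        subject_ids=tuple(subjects),
    )
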