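"""Empirical Mode Decomposition by envelope sifting.

A signal is decomposed into a fixed number of intrinsic mode functions
(IMFs) plus a residual.  Each IMF is obtained by *sifting*: local maxima
and minima are interpolated with natural cubic splines into an upper and
lower envelope, the envelope mean is subtracted, and the process repeats
until the candidate satisfies a Cauchy-style convergence criterion

    SD = sum((h_prev - h_new)**2) / sum(h_prev**2) < sd_threshold

or a sift-count cap is reached.  Subtracting each IMF from the running
residual telescopes, so

    x == sum(imfs) + residual

holds to floating-point round-off for every input, which the test suite
asserts as an invariant.

The decomposition always returns exactly ``n_imfs`` components: when the
residual becomes monotone before ``n_imfs`` genuine modes are found, the
remaining slots are zero-filled and flagged as placeholders so the
downstream feature-vector width stays constant.

Numerical conventions (all deterministic):

* plateaus in extrema detection are represented by their midpoint sample,
  rounded down — this keeps the decomposition stable on 16-bit quantized
  data, where exact ties are common;
* envelopes are extended by mirroring the two nearest extrema about each
  endpoint before the spline fit, which suppresses end swings on short
  epochs;
* with fewer than 4 spline knots the envelope falls back to linear
  interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline


class MonotoneResidual(Exception):
    """The sequence has too few extrema to support an envelope pair."""


class DegenerateInput(ValueError):
    """Input too short or non-finite for decomposition."""


@dataclass(frozen=True)
class SiftStopCriteria:
    sd_threshold: float = 0.2
    max_sift: int = 10


@dataclass
class ExtremaSet:
    maxima_indices: np.ndarray
    maxima_values: np.ndarray
    minima_indices: np.ndarray
    minima_values: np.ndarray

    @property
    def n_maxima(self) -> int:
        return len(self.maxima_indices)

    @property
    def n_minima(self) -> int:
        return len(self.minima_indices)


@dataclass
class EnvelopePair:
    upper: np.ndarray
    lower: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return (self.upper + self.lower) / 2.0


@dataclass
class IMFSet:
    """Ordered decomposition of one channel epoch."""

    imfs: list            # of ndarray, length n_imfs
    residual: np.ndarray
    sift_counts: list     # iterations used per IMF (0 for placeholders)
    placeholder: list     # True where the slot is a zero-filled pad
    condition_met: list = None  # extrema/zero-crossing condition per IMF

    @property
    def components(self) -> list:
        """IMF1..IMFn followed by the residual (the feature operators run
        over all of these)."""
        return list(self.imfs) + [self.residual]

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.imfs, axis=0) + self.residual


def find_extrema(x: np.ndarray) -> ExtremaSet:
    """Locate interior local maxima and minima, plateau-aware.

    A plateau bounded by a rise and a fall counts as one maximum at its
    midpoint (rounded down); symmetrically for minima.  Endpoints are
    never extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DegenerateInput(f"need at least 3 samples, got {x.size}")
    steps = np.sign(np.diff(x))
    nz = np.flatnonzero(steps)
    if nz.size < 2:
        return ExtremaSet(np.empty(0, int), np.empty(0), np.empty(0, int), np.empty(0))
    s = steps[nz]
    turn = np.flatnonzero(s[:-1] != s[1:])
    # plateau (possibly length-1) spans samples nz[k]+1 .. nz[k+1]
    idx = (nz[turn] + 1 + nz[turn + 1]) // 2
    is_max = s[turn] > 0
    mx, mn = idx[is_max], idx[~is_max]
    return ExtremaSet(mx, x[mx], mn, x[mn])


def _extend_knots(indices: np.ndarray, values: np.ndarray, n: int):
    """Mirror the two extrema nearest each endpoint about the endpoint."""
    k = min(2, len(indices))
    left_i = -indices[:k][::-1]
    left_v = values[:k][::-1]
    right_i = 2 * (n - 1) - indices[-k:][::-1]
    right_v = values[-k:][::-1]
    ti = np.concatenate([left_i, indices, right_i]).astype(float)
    tv = np.concatenate([left_v, values, right_v])
    # mirroring an extremum at the exact endpoint duplicates its knot
    keep = np.concatenate([[True], np.diff(ti) > 0])
    return ti[keep], tv[keep]


def _envelope(indices, values, n: int) -> np.ndarray:
    ti, tv = _extend_knots(indices, values, n)
    grid = np.arange(n, dtype=float)
    if len(ti) < 4:
        return np.interp(grid, ti, tv)
    return CubicSpline(ti, tv, bc_type="natural")(grid)


def interpolate_envelopes(x: np.ndarray, extrema: ExtremaSet | None = None) -> EnvelopePair:
    """Natural cubic-spline upper/lower envelopes on the full sample grid.

    Raises :class:`MonotoneResidual` when fewer than two maxima or two
    minima exist, which :func:`emd_decompose` consumes as the signal to
    stop extracting modes.
    """
    x = np.asarray(x, dtype=float)
    if extrema is None:
        extrema = find_extrema(x)
    if extrema.n_maxima < 2 or extrema.n_minima < 2:
        raise MonotoneResidual(
            f"{extrema.n_maxima} maxima / {extrema.n_minima} minima: "
            "envelope pair undefined"
        )
    n = x.size
    return EnvelopePair(
        upper=_envelope(extrema.maxima_indices, extrema.maxima_values, n),
        lower=_envelope(extrema.minima_indices, extrema.minima_values, n),
    )


def sift_once(h: np.ndarray):
    """One sifting step: subtract the envelope mean.  Returns (h_new, M)."""
    env = interpolate_envelopes(h)
    m = env.mean
    return h - m, m


def zero_crossings(x: np.ndarray) -> int:
    s = np.where(np.asarray(x) >= 0, 1, -1)
    return int(np.count_nonzero(s[1:] != s[:-1]))


def satisfies_imf_condition(x: np.ndarray, tol: int = 1) -> bool:
    """Extrema count and zero-crossing count differ by at most ``tol``."""
    ext = find_extrema(x)
    return abs((ext.n_maxima + ext.n_minima) - zero_crossings(x)) <= tol


def extract_imf(x: np.ndarray, stop: SiftStopCriteria = SiftStopCriteria()):
    """Sift one IMF out of ``x``.  Returns ``(imf, sift_count)``.

    Sifting stops when the Cauchy SD criterion drops below
    ``stop.sd_threshold`` or after ``stop.max_sift`` iterations; if the
    candidate loses its extrema mid-sift, the current candidate is
    returned as-is.
    """
    h = np.asarray(x, dtype=float)
    h_new, _ = sift_once(h)  # raises MonotoneResidual if x admits no sift
    count = 1
    while True:
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < stop.sd_threshold or count >= stop.max_sift:
            break
        try:
            h_new, _ = sift_once(h)
        except MonotoneResidual:
            break
        count += 1
    return h, count


def emd_decompose(
    x: np.ndarray,
    n_imfs: int = 7,
    stop: SiftStopCriteria = SiftStopCriteria(),
) -> IMFSet:
    """Decompose ``x`` into ``n_imfs`` IMFs plus a residual.

    Modes exhausted early leave zero-filled placeholder slots so the
    output width is constant; the residual then carries everything left.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DegenerateInput("input contains non-finite samples")
    residual = x.copy()
    imfs, counts, placeholder, met = [], [], [], []
    for _ in range(n_imfs):
        try:
            imf, cnt = extract_imf(residual, stop)
        except (MonotoneResidual, DegenerateInput):
            break
        imfs.append(imf)
        counts.append(cnt)
        placeholder.append(False)
        try:
            met.append(satisfies_imf_condition(imf))
        except DegenerateInput:
            met.append(False)
        residual = residual - imf
    while len(imfs) < n_imfs:
        imfs.append(np.zeros_like(x))
        counts.append(0)
        placeholder.append(True)
        met.append(False)
    return IMFSet(imfs=imfs, residual=residual, sift_counts=counts,
                  placeholder=placeholder, condition_met=met)
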