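"""Empirical mode decomposition: extrema, envelopes, sifting, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emdad.emd import (
    DegenerateInput,
    MonotoneResidual,
    SiftStopCriteria,
    emd_decompose,
    extract_imf,
    find_extrema,
    interpolate_envelopes,
    sift_once,
    zero_crossings,
)


def brute_force_extrema(x):
    """O(n) neighbor-comparison oracle with plateau-midpoint convention."""
    maxima, minima = [], []
    n = len(x)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        left, right = x[i - 1], x[j + 1] if j + 1 < n else None
        if right is not None:
            if x[i] > left and x[i] > right:
                maxima.append((i + j) // 2)
            elif x[i] < left and x[i] < right:
                minima.append((i + j) // 2)
        i = j + 1
    return maxima, minima


class TestFindExtrema:
    def test_monotone_ramp_has_no_interior_extrema(self):
        ext = find_extrema(np.arange(10.0))
        assert ext.n_maxima == 0 and ext.n_minima == 0

    def test_single_peak(self):
        ext = find_extrema(np.array([0.0, 1.0, 0.0]))
        assert list(ext.maxima_indices) == [1]
        assert ext.n_minima == 0

    def test_plateau_midpoint_rounded_down(self):
        # plateau of 2 at indices 2,3,4 -> representative 3
        x = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        ext = find_extrema(x)
        assert list(ext.maxima_indices) == [3]
        # even-length plateau at indices 2,3 -> midpoint rounds down to 2
        x = np.array([0.0, 1.0, 2.0, 2.0, 1.0, 0.0])
        assert list(find_extrema(x).maxima_indices) == [2]

    def test_matches_brute_force_oracle_on_random_sequences(self, rng):
        for _ in range(20):
            x = rng.standard_normal(500)
            ext = find_extrema(x)
            mx, mn = brute_force_extrema(x)
            assert list(ext.maxima_indices) == mx
            assert list(ext.minima_indices) == mn

    def test_matches_oracle_on_quantized_sequences(self, rng):
        # heavy ties, as on 16-bit quantized data
        for _ in range(10):
            x = np.round(rng.standard_normal(300) * 3)
            ext = find_extrema(x)
            mx, mn = brute_force_extrema(x)
            assert list(ext.maxima_indices) == mx
            assert list(ext.minima_indices) == mn

    def test_alternation_of_merged_extrema(self, rng):
        x = rng.standard_normal(400)
        ext = find_extrema(x)
        kinds = sorted(
            [(i, "max") for i in ext.maxima_indices]
            + [(i, "min") for i in ext.minima_indices]
        )
        for (_, a), (_, b) in zip(kinds, kinds[1:]):
            assert a != b

    def test_too_short_raises(self):
        with pytest.raises(DegenerateInput):
            find_extrema(np.array([1.0, 2.0]))


class TestEnvelopes:
    def test_constant_extrema_give_flat_envelopes(self):
        # triangle wave between peaks at +1 and troughs at -1
        t = np.arange(400)
        x = np.abs((t % 40) - 20) / 10.0 - 1.0
        env = interpolate_envelopes(x)
        peaks = find_extrema(x)
        assert np.allclose(env.upper[peaks.maxima_indices], 1.0, atol=1e-9)
        assert np.allclose(env.lower[peaks.minima_indices], -1.0, atol=1e-9)

    def test_sinusoid_mean_envelope_near_zero_in_center(self):
        t = np.arange(1600) / 200.0
        x = np.sin(2 * np.pi * 10 * t)  # 80 cycles
        env = interpolate_envelopes(x)
        n = len(x)
        center = slice(n // 4, 3 * n // 4)
        assert np.max(np.abs(env.mean[center])) < 0.05

    def test_envelopes_interpolate_their_extrema_exactly(self, rng):
        x = rng.standard_normal(500)
        ext = find_extrema(x)
        env = interpolate_envelopes(x, ext)
        assert np.allclose(env.upper[ext.maxima_indices],
                           ext.maxima_values, atol=1e-9)
        assert np.allclose(env.lower[ext.minima_indices],
                           ext.minima_values, atol=1e-9)
        # spline overshoot can locally invert the pair between knots of the
        # other envelope, but ordering must hold almost everywhere
        assert np.mean(env.upper >= env.lower) > 0.98

    def test_mean_is_half_sum(self, rng):
        x = rng.standard_normal(300)
        env = interpolate_envelopes(x)
        assert np.array_equal(env.mean, (env.upper + env.lower) / 2.0)

    def test_too_few_extrema_signal_monotone_residual(self):
        with pytest.raises(MonotoneResidual):
            interpolate_envelopes(np.array([0.0, 1.0, 0.0, 2.0, 4.0, 8.0, 16.0]))


class TestSifting:
    def test_sift_subtracts_envelope_mean_exactly(self, rng):
        x = rng.standard_normal(400)
        h_new, m = sift_once(x)
        assert np.array_equal(h_new, x - m)

    def test_offset_sinusoid_centers_after_one_sift(self):
        t = np.arange(1600) / 200.0
        x = np.sin(2 * np.pi * 10 * t) + 0.5
        h, _ = sift_once(x)
        center = slice(400, 1200)
        assert abs(np.mean(h[center])) < 0.05

    def test_infinite_threshold_means_exactly_one_sift(self, rng):
        x = rng.standard_normal(400)
        imf, count = extract_imf(x, SiftStopCriteria(sd_threshold=np.inf))
        expected, _ = sift_once(x)
        assert count == 1
        assert np.array_equal(imf, expected)

    def test_sift_count_bounded_by_max_sift(self, rng):
        stop = SiftStopCriteria(sd_threshold=0.0, max_sift=6)
        for _ in range(5):
            _, count = extract_imf(rng.standard_normal(800), stop)
            assert count <= 6

    def test_pure_tone_is_recovered_as_first_imf(self):
        t = np.arange(1600) / 200.0
        x = np.sin(2 * np.pi * 10 * t)
        imf, _ = extract_imf(x)
        center = slice(160, 1440)  # central 80%
        r = np.corrcoef(imf[center], x[center])[0, 1]
        assert r >= 0.99

    def test_monotone_input_raises(self):
        with pytest.raises(MonotoneResidual):
            extract_imf(np.linspace(0.0, 1.0, 100))


class TestDecompose:
    def test_reconstruction_identity(self, rng):
        for _ in range(10):
            x = rng.standard_normal(1600)
            s = emd_decompose(x)
            err = np.max(np.abs(s.reconstruct() - x))
            assert err <= 1e-8 * np.max(np.abs(x))

    def test_two_tone_separation(self):
        t = np.arange(1600) / 200.0
        x = np.sin(2 * np.pi * 20 * t) + np.sin(2 * np.pi * 2 * t)
        s = emd_decompose(x)
        center = slice(160, 1440)
        hi = np.sin(2 * np.pi * 20 * t)[center]
        lo = np.sin(2 * np.pi * 2 * t)[center]
        r1 = np.corrcoef(s.imfs[0][center], hi)[0, 1]
        # the slow tone may appear in IMF2 or (with few slow cycles) IMF3;
        # the stated contract is IMF2
        r2 = np.corrcoef(s.imfs[1][center], lo)[0, 1]
        assert r1 >= 0.95
        assert r2 >= 0.95

    def test_always_seven_imfs_with_placeholders(self):
        ramp = np.linspace(0.0, 5.0, 1600)
        s = emd_decompose(ramp)
        assert len(s.imfs) == 7
        assert all(s.placeholder)
        assert np.array_equal(s.residual, ramp)

    def test_imf_condition_met_or_flagged(self, rng):
        # sifted IMFs either satisfy the extrema/zero-crossing condition
        # (tolerance 1) or ran out of sift budget, and the flag records
        # which; placeholders are always flagged unmet
        from emdad.emd import SiftStopCriteria, satisfies_imf_condition
        stop = SiftStopCriteria()
        x = rng.standard_normal(1600)
        s = emd_decompose(x, stop=stop)
        for imf, ph, cnt, met in zip(s.imfs, s.placeholder, s.sift_counts,
                                     s.condition_met):
            if ph:
                assert not met
                continue
            assert met == satisfies_imf_condition(imf, tol=1)
            assert cnt <= stop.max_sift

    def test_decreasing_zero_crossing_rate(self, rng):
        # characteristic frequency decreases down the IMF ladder; checked
        # statistically over many noise epochs
        wins = 0
        total = 0
        for _ in range(30):
            x = rng.standard_normal(1600)
            s = emd_decompose(x)
            rates = [zero_crossings(imf) for imf, ph in
                     zip(s.imfs, s.placeholder) if not ph]
            for a, b in zip(rates, rates[1:]):
                total += 1
                if a >= b:
                    wins += 1
        assert wins / total > 0.95

    def test_determinism(self, rng):
        x = rng.standard_normal(1600)
        a = emd_decompose(x)
        b = emd_decompose(x.copy())
        for ia, ib in zip(a.imfs, b.imfs):
            assert np.array_equal(ia, ib)
        assert np.array_equal(a.residual, b.residual)

    def test_nonfinite_input_rejected(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(DegenerateInput):
            emd_decompose(x)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_reconstruction_property_random_epochs(seed):
    """sum(IMFs) + residual == input, for arbitrary seeded epochs."""
    x = np.random.default_rng(seed).standard_normal(400)
    s = emd_decompose(x)
    assert np.max(np.abs(s.reconstruct() - x)) <= 1e-8 * np.max(np.abs(x))
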