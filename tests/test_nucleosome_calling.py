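import numpy as np
import pytest

from conftest import make_profile
from nucpos.nucleosome_calling import (
    Peak,
    PeakSet,
    assign_plus_one,
    call_peaks,
    epanechnikov_kernel,
    estimate_nrl,
    ndr_metrics,
    smooth_profile,
)


def brute_force_smooth(values, mask, bandwidth):
    """Independent double-loop Epanechnikov weighted average over valid bins."""
    n = values.size
    out = np.zeros(n)
    for i in range(n):
        num = den = 0.0
        for j in range(max(0, i - bandwidth), min(n, i + bandwidth + 1)):
            if not mask[j]:
                continue
            u = (j - i) / bandwidth
            w = 0.75 * (1 - u * u)
            num += w * values[j]
            den += w
        out[i] = num / den if den > 0 else 0.0
    return out


def brute_force_maxima(values):
    """Walk-based strict local maxima with leftmost-plateau tie rule."""
    out = []
    n = values.size
    for i in range(n):
        if i > 0 and values[i - 1] == values[i]:
            continue  # not the leftmost bin of its plateau
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if i == 0 or j == n - 1:
            continue
        if values[i - 1] < values[i] and values[j + 1] < values[i]:
            out.append(i)
    return out


class TestSmoothing:
    def test_kernel_support_and_shape(self):
        v = np.zeros(101)
        v[50] = 1.0
        sm = smooth_profile(make_profile(v, lo=-50), bandwidth=30)
        assert sm.values.argmax() == 50
        assert np.all(sm.values[:50 - 30] == 0) and np.all(sm.values[50 + 31 :] == 0)
        np.testing.assert_allclose(sm.values[50 - 20], sm.values[50 + 20])

    def test_constant_profile_unchanged(self):
        p = make_profile(np.full(200, 3.3))
        np.testing.assert_allclose(smooth_profile(p, 30).values, 3.3, atol=1e-12)

    def test_matches_direct_convolution(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            v = rng.random(150) * 10
            mask = rng.random(150) > 0.1
            p = make_profile(v, mask=mask)
            sm = smooth_profile(p, 30)
            np.testing.assert_allclose(
                sm.values, brute_force_smooth(v, mask, 30), atol=1e-12
            )

    def test_mass_conserved_away_from_edges(self):
        rng = np.random.default_rng(2)
        v = rng.random(400)
        sm = smooth_profile(make_profile(v), 30)
        assert abs(sm.values[30:-30].sum() - v[30:-30].sum()) < v.sum() * 0.01

    def test_never_exceeds_input_maximum(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            v = rng.random(100)
            sm = smooth_profile(make_profile(v), 15)
            assert sm.values.max() <= v.max() + 1e-12


class TestPeakCalling:
    def test_simple_maxima(self):
        ps = call_peaks(make_profile([0, 1, 0, 2, 0]), noise_frac=0.0)
        assert ps.summits == [1, 3]
        assert [p.rank for p in ps.peaks] == [1, 2]

    def test_plateau_takes_leftmost_bin(self):
        ps = call_peaks(make_profile([0, 2, 2, 2, 0]), noise_frac=0.0)
        assert ps.summits == [1]

    def test_noise_floor_mean_and_max_references(self):
        v = [0, 10, 0, 1, 0, 10, 0]  # mean = 3, max = 10
        assert call_peaks(make_profile(v), 0.5).summits == [1, 5]  # floor 1.5
        assert call_peaks(make_profile(v), 0.2).summits == [1, 3, 5]  # floor 0.6
        assert call_peaks(make_profile(v), 0.2, noise_ref="max").summits == [1, 5]

    def test_matches_bruteforce_scan_on_random_profiles(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            # quantized values provoke plateaus and ties
            v = rng.integers(0, 6, size=rng.integers(3, 80)).astype(float)
            ps = call_peaks(make_profile(v), noise_frac=0.0)
            assert ps.summits == brute_force_maxima(v)

    def test_masked_segment_edges_are_not_peaks(self):
        v = np.array([5.0, 1, 2, 9, 2, 1, 5.0])
        mask = np.array([False, True, True, True, True, True, False])
        ps = call_peaks(make_profile(v, mask=mask), noise_frac=0.0)
        assert ps.summits == [3]


class TestPlusOne:
    def test_first_downstream_peak(self):
        ps = PeakSet(
            peaks=[Peak(-250, 1.0, 1), Peak(60, 2.0, 2), Peak(230, 1.5, 3)],
            noise_threshold=0.0,
        )
        assert assign_plus_one(ps).summit == 60

    def test_no_downstream_peak_flags_gene(self):
        ps = PeakSet(peaks=[Peak(-115, 1.0, 1)], noise_threshold=0.0)
        assert assign_plus_one(ps) is None

    def test_first_peak_even_if_close_to_atg(self):
        ps = PeakSet(peaks=[Peak(5, 1.0, 1), Peak(175, 1.0, 2)], noise_threshold=0.0)
        assert assign_plus_one(ps).summit == 5

    def test_search_limit_and_literal_five_prime_reading(self):
        ps = PeakSet(
            peaks=[Peak(-115, 1.0, 1), Peak(400, 1.0, 2)], noise_threshold=0.0
        )
        assert assign_plus_one(ps, search_limit=300) is None
        assert assign_plus_one(ps, five_prime=True).summit == -115


def _peakset(summits, heights=None):
    heights = heights or [1.0] * len(summits)
    return PeakSet(
        peaks=[Peak(s, h, i + 1) for i, (s, h) in enumerate(zip(summits, heights))],
        noise_threshold=0.0,
    )


class TestNRL:
    def test_exactly_periodic_summits(self):
        est = estimate_nrl(_peakset([0, 170, 340, 510, 680]))
        assert est.nrl == pytest.approx(170.0)
        assert est.r_squared == pytest.approx(1.0)
        assert est.n_peaks_used == 5

    def test_matches_closed_form_ols(self):
        summits = [0, 170, 343, 513, 686]
        est = estimate_nrl(_peakset(summits))
        slope, intercept = np.polyfit(np.arange(5), np.array(summits), 1)
        assert est.nrl == pytest.approx(slope, abs=1e-9)
        assert est.intercept == pytest.approx(intercept, abs=1e-9)

    def test_translation_invariance(self):
        base = [3, 172, 341, 515, 684]
        a = estimate_nrl(_peakset(base))
        b = estimate_nrl(_peakset([s + 500 for s in base]), plus_one=Peak(503, 1.0, 1))
        assert a.nrl == pytest.approx(b.nrl, abs=1e-9)

    def test_too_few_peaks_reports_count(self):
        with pytest.raises(ValueError, match="found 3"):
            estimate_nrl(_peakset([0, 170, 340]))

    def test_height_ranked_variant_uses_tallest_downstream(self):
        ps = _peakset(
            [0, 170, 340, 510, 680, 850],
            heights=[3.0, 2.5, 2.0, 1.8, 1.5, 0.1],
        )
        est = estimate_nrl(ps, n_nucs=5, height_ranked=True)
        assert est.nrl == pytest.approx(170.0)

    def test_jittered_summits_recover_spacing(self):
        rng = np.random.default_rng(6)
        for L in (160, 175, 190):
            summits = sorted(
                int(round(k * L + rng.normal(0, 5))) for k in range(5)
            )
            est = estimate_nrl(_peakset(summits), plus_one=Peak(summits[0], 1.0, 1))
            assert abs(est.nrl - L) < 8  # O(sigma/sqrt(n)) around the truth


class TestNDR:
    def test_run_arithmetic(self):
        offs = np.arange(-600, 601)
        v = np.full(offs.size, 1.2)
        v[(offs >= -200) & (offs <= -30)] = 0.5
        center, width = ndr_metrics(make_profile(v, lo=-600), plus_one_offset=60)
        assert center == pytest.approx(-115.0)
        assert width == 171

    def test_no_depletion_gives_zero_width(self):
        v = np.ones(1201)
        center, width = ndr_metrics(make_profile(v, lo=-600), plus_one_offset=60)
        assert center is None and width == 0

    def test_only_upstream_runs_count(self):
        offs = np.arange(-600, 601)
        v = np.full(offs.size, 1.2)
        v[(offs >= 100) & (offs <= 500)] = 0.1  # downstream of +1: ignored
        v[(offs >= -150) & (offs <= -100)] = 0.5
        center, width = ndr_metrics(make_profile(v, lo=-600), plus_one_offset=60)
        assert width == 51 and center == pytest.approx(-125.0)
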