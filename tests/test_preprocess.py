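"""Spatial filtering, baseline correction, polarity, masking, normalising."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import grey_opening

from cardiomap import (
    FluorescenceMovie,
    SimulationSpec,
    apply_polarity,
    gaussian_spatial_filter,
    normalise_trace,
    segment_tissue,
    simulate_paced_movie,
    tophat_baseline,
)
from cardiomap.preprocess import gaussian_kernel

from conftest import make_movie


def hand_kernel(size, sigma):
    """Independent oracle: evaluate exp(-(dx^2+dy^2)/(2 sigma^2)) and
    normalise by the explicit sum."""
    half = size // 2
    vals = [[np.exp(-(dx * dx + dy * dy) / (2 * sigma ** 2))
             for dx in range(-half, half + 1)]
            for dy in range(-half, half + 1)]
    vals = np.array(vals)
    return vals / vals.sum()


class TestGaussianFilter:
    def test_kernel_matches_hand_normalised_gaussian(self):
        for size, sigma in [(3, 1.5), (5, 1.0), (3, 0.8), (7, 2.5)]:
            np.testing.assert_allclose(gaussian_kernel(size, sigma),
                                       hand_kernel(size, sigma), rtol=1e-12)

    def test_constant_frame_unchanged(self):
        movie = make_movie(np.full((4, 6, 6), 3.7))
        out = gaussian_spatial_filter(movie)
        np.testing.assert_allclose(out.data, movie.data, rtol=1e-12)

    def test_interior_impulse_reproduces_kernel(self):
        data = np.zeros((1, 7, 7))
        data[0, 3, 3] = 1.0
        out = gaussian_spatial_filter(make_movie(data), size=3, sigma=1.5)
        patch = out.data[0, 2:5, 2:5]
        np.testing.assert_allclose(patch, hand_kernel(3, 1.5), rtol=1e-12)
        assert patch[1, 1] == pytest.approx(0.1478, abs=5e-5)

    def test_corner_impulse_renormalised_truncation(self):
        data = np.zeros((1, 5, 5))
        data[0, 0, 0] = 1.0
        out = gaussian_spatial_filter(make_movie(data), size=3, sigma=1.5)
        k = hand_kernel(3, 1.5)
        # per-pixel oracle: weights over in-image offsets, renormalised
        frame = data[0]
        expected = np.zeros_like(frame)
        for r in range(5):
            for c in range(5):
                num = den = 0.0
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        rr, cc = r + dy, c + dx
                        if 0 <= rr < 5 and 0 <= cc < 5:
                            num += k[dy + 1, dx + 1] * frame[rr, cc]
                            den += k[dy + 1, dx + 1]
                expected[r, c] = num / den
        np.testing.assert_allclose(out.data[0], expected, rtol=1e-12)
        # at the corner itself only the 2x2 nearest weights remain
        assert out.data[0, 0, 0] == pytest.approx(k[1, 1] / k[1:, 1:].sum())

    def test_no_bleed_from_outside_mask(self):
        data = np.ones((2, 5, 5))
        data[:, 2, 2] = 100.0  # bright pixel excluded from the mask
        mask = np.ones((5, 5), bool)
        mask[2, 2] = False
        out = gaussian_spatial_filter(make_movie(data), mask=mask)
        assert np.allclose(out.data[:, mask], 1.0)
        assert out.data[0, 2, 2] == 100.0  # out-of-mask pixels untouched

    def test_interior_mean_preserved(self):
        rng = np.random.default_rng(1)
        movie = make_movie(rng.normal(size=(3, 30, 30)))
        out = gaussian_spatial_filter(movie)
        # a normalised kernel redistributes but conserves interior mass
        assert out.data[:, 5:-5, 5:-5].mean() == pytest.approx(
            movie.data[:, 5:-5, 5:-5].mean(), abs=0.02)

    def test_even_size_rejected(self, tiny_movie):
        with pytest.raises(ValueError, match="odd"):
            gaussian_spatial_filter(tiny_movie, size=4)


def brute_opening(trace, k):
    """Independent moving-minimum-then-moving-maximum oracle with edge
    replication, window length k (odd)."""
    half = k // 2
    padded = np.concatenate([np.full(half, trace[0]), trace,
                             np.full(half, trace[-1])])
    eroded = np.array([padded[i:i + k].min() for i in range(len(trace))])
    padded2 = np.concatenate([np.full(half, eroded[0]), eroded,
                              np.full(half, eroded[-1])])
    return np.array([padded2[i:i + k].max() for i in range(len(trace))])


class TestTophatBaseline:
    def test_constant_trace_corrects_to_zero(self):
        movie = make_movie(np.full((50, 2, 2), 7.0))
        out = tophat_baseline(movie, kernel_ms=10)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_narrow_spike_survives(self):
        trace = np.array([0, 0, 5, 0, 0], dtype=float)
        movie = make_movie(trace.reshape(-1, 1, 1), frame_rate=1000.0)
        out = tophat_baseline(movie, kernel_ms=3)
        np.testing.assert_array_equal(out.data[:, 0, 0], trace)

    def test_matches_brute_force_opening_on_random_traces(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(20, 120)
            k_ms = float(rng.integers(3, 21))
            trace = rng.normal(size=n).cumsum()  # wandering baseline
            movie = make_movie(trace.reshape(-1, 1, 1), frame_rate=1000.0)
            out = tophat_baseline(movie, kernel_ms=k_ms)
            k = int(round(k_ms))
            if k % 2 == 0:
                k += 1
            expected = trace - brute_opening(trace, k)
            np.testing.assert_allclose(out.data[:, 0, 0], expected,
                                       atol=1e-10)

    def test_ap_train_on_ramp_flattens_diastole(self):
        # beats much narrower than the kernel on a linear ramp of slope s
        fr, s = 1000.0, 0.01  # per ms
        t = np.arange(1500)
        trace = s * t.astype(float)
        for start in range(100, 1400, 150):
            trace[start:start + 30] += 1.0
        movie = make_movie(trace.reshape(-1, 1, 1), frame_rate=fr)
        out = tophat_baseline(movie, kernel_ms=100)
        corrected = out.data[:, 0, 0]
        diastole = np.ones(len(t), bool)
        for start in range(100, 1400, 150):
            diastole[start - 5:start + 40] = False
        assert np.abs(corrected[diastole]).max() <= 101 * s + 1e-9

    def test_correction_never_negative_under_element_fit(self):
        rng = np.random.default_rng(5)
        trace = rng.random(300)
        movie = make_movie(trace.reshape(-1, 1, 1), frame_rate=1000.0)
        out = tophat_baseline(movie, kernel_ms=21)
        assert out.data.min() >= -1e-12  # opening <= original pointwise

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50))
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(9)
        trace = rng.random(200)
        a = tophat_baseline(make_movie(trace.reshape(-1, 1, 1)), 15)
        b = tophat_baseline(make_movie((trace + shift).reshape(-1, 1, 1)), 15)
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_too_short_kernel_rejected(self):
        movie = make_movie(np.zeros((50, 1, 1)), frame_rate=100.0)
        with pytest.raises(ValueError, match="at least 3"):
            tophat_baseline(movie, kernel_ms=5)  # 0.5 samples at 100 Hz


class TestApplyPolarity:
    def test_inversion_uses_per_pixel_max(self):
        movie = make_movie(np.array([10.0, 2.0, 10.0]).reshape(-1, 1, 1),
                           polarity="inverted_voltage")
        out = apply_polarity(movie)
        np.testing.assert_array_equal(out.data[:, 0, 0], [0.0, 8.0, 0.0])
        assert out.polarity == "upright"

    def test_upright_unchanged(self, tiny_movie):
        out = apply_polarity(tiny_movie)
        np.testing.assert_array_equal(out.data, tiny_movie.data)

    def test_idempotent_once_upright(self):
        movie = make_movie(np.array([10.0, 2.0, 7.0]).reshape(-1, 1, 1),
                           polarity="inverted_voltage")
        once = apply_polarity(movie)
        twice = apply_polarity(once)
        np.testing.assert_array_equal(once.data, twice.data)


class TestSegmentTissue:
    def test_signal_disc_recovered(self):
        rows = cols = 41
        yy, xx = np.mgrid[0:rows, 0:cols]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 12 ** 2
        spec = SimulationSpec(grid=(rows, cols), tissue=disc, noise_sd=0.1,
                              pcl_schedule=((110.0, 3),), seed=2)
        movie, _ = simulate_paced_movie(spec)
        mask = segment_tissue(apply_polarity(movie))
        truly = disc
        hit = (mask.flags & truly).sum() / truly.sum()
        false = (mask.flags & ~truly).sum() / max(1, (~truly).sum())
        assert hit >= 0.99
        assert false <= 0.01

    def test_uniform_movie_full_frame(self):
        t = np.sin(np.linspace(0, 6, 60))
        movie = make_movie(np.tile(t[:, None, None], (1, 8, 8)))
        mask = segment_tissue(movie)
        assert mask.flags.all()

    def test_largest_component_kept(self):
        data = np.zeros((30, 20, 20))
        t = np.sin(np.linspace(0, 12, 30))
        data[:, 2:10, 2:10] = t[:, None, None]      # 64-pixel blob
        data[:, 14:17, 14:17] = t[:, None, None]    # 9-pixel blob
        mask = segment_tissue(make_movie(data))
        assert mask.flags[2:10, 2:10].all()
        assert not mask.flags[14:17, 14:17].any()


class TestNormaliseTrace:
    def test_basic(self):
        np.testing.assert_allclose(normalise_trace([2, 4, 6]), [0, 0.5, 1])

    def test_identity_on_normalised(self):
        t = np.array([0.0, 0.25, 1.0, 0.5])
        np.testing.assert_allclose(normalise_trace(t), t)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(0.01, 100), b=st.floats(-50, 50))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(11)
        t = rng.random(50)
        np.testing.assert_allclose(normalise_trace(a * t + b),
                                   normalise_trace(t), atol=1e-9)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            normalise_trace(np.ones(10))
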