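"""Dominant frequency and optical wave similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomap import (
    SimulationSpec,
    apply_polarity,
    detect_beats,
    df_map,
    dominant_frequency,
    global_signal,
    identify_pcls,
    ows,
    ows_map,
    segment_tissue,
    simulate_irregular_movie,
    simulate_paced_movie,
)
from cardiomap.rhythm import export_spectrum
from cardiomap.simulate import ap_template

from conftest import make_movie


def brute_df(trace, frame_rate, band=(0.5, 50.0), resolution=0.05):
    """Independent oracle: direct DFT sums of the Hann-windowed trace on
    the zero-padded grid, argmax inside the band."""
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / (n - 1))
    x = (trace - trace.mean()) * w
    npad = max(n, int(np.ceil(frame_rate / resolution)))
    freqs = np.arange(npad // 2 + 1) * frame_rate / npad
    sel = (freqs >= band[0]) & (freqs <= band[1])
    t = np.arange(n)
    best_f, best_p = np.nan, -1.0
    for f, k in zip(freqs[sel], np.nonzero(sel)[0]):
        c = np.sum(x * np.exp(-2j * np.pi * k * t / npad))
        p = abs(c) ** 2
        if p > best_p + 1e-12 * max(best_p, 1.0):
            best_p, best_f = p, f
    return best_f


class TestDominantFrequency:
    def test_pure_sine_line(self):
        t = np.arange(5000) / 1000.0
        res = dominant_frequency(np.sin(2 * np.pi * 5.0 * t), 1000.0)
        assert res.df == pytest.approx(5.0, abs=0.05)

    def test_larger_amplitude_component_wins(self):
        t = np.arange(4000) / 1000.0
        sig = 1.0 * np.sin(2 * np.pi * 4.0 * t) + \
            2.0 * np.sin(2 * np.pi * 9.0 * t)
        res = dominant_frequency(sig, 1000.0)
        assert res.df == pytest.approx(9.0, abs=0.05)
        assert res.df == pytest.approx(brute_df(sig, 1000.0), abs=1e-9)

    def test_paced_train_fundamental(self):
        # pacing at 160 ms cycle length -> DF at 1/0.160 = 6.25 Hz
        spec = SimulationSpec(pcl_schedule=((160.0, 20),), apd80=60.0)
        movie, _ = simulate_paced_movie(spec)
        sig = global_signal(apply_polarity(movie))
        res = dominant_frequency(sig, 1000.0)
        assert res.df == pytest.approx(6.25, abs=0.05)

    def test_matches_brute_force_dft_on_random_signals(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(200, 600))
            fr = float(rng.choice([250.0, 500.0, 1000.0]))
            # random mixture of tones plus noise
            t = np.arange(n) / fr
            sig = rng.normal(0, 0.2, n)
            for _k in range(3):
                f = rng.uniform(1.0, 40.0)
                sig += rng.uniform(0.3, 2.0) * np.sin(
                    2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            res = dominant_frequency(sig, fr)
            assert res.df == pytest.approx(brute_df(sig, fr), abs=1e-9)

    def test_grid_spacing_bounded_for_all_table_rates(self):
        for fr in (1000.0, 987.0, 500.0):
            res = dominant_frequency(np.sin(np.arange(300) * 0.2), fr)
            assert np.max(np.diff(res.frequencies)) <= 0.05 + 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(0.01, 100), b=st.floats(-10, 10))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(23)
        t = np.arange(1000) / 1000.0
        sig = np.sin(2 * np.pi * 7.3 * t) + rng.normal(0, 0.1, t.size)
        assert dominant_frequency(a * sig + b, 1000.0).df == \
            dominant_frequency(sig, 1000.0).df

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            dominant_frequency(np.sin(np.arange(100)), 80.0)

    def test_spectrum_export(self, tmp_path):
        res = dominant_frequency(np.sin(np.arange(500) * 0.1), 1000.0)
        export_spectrum(res, tmp_path / "s.csv")
        text = (tmp_path / "s.csv").read_text()
        assert text.startswith("frequency_hz,power")


class TestDfMap:
    def test_paced_movie_uniform_df(self):
        spec = SimulationSpec(grid=(21, 21), pcl_schedule=((125.0, 16),))
        movie, truth = simulate_paced_movie(spec)
        movie = apply_polarity(movie)
        mask = segment_tissue(movie)
        dmap = df_map(movie, mask)
        np.testing.assert_allclose(dmap.defined_values, 8.0, atol=0.05)

    def test_two_domain_movie_bimodal(self):
        grid = (20, 20)
        left = np.zeros(grid, bool)
        left[:, :10] = True
        right = ~left
        movie, truth = simulate_irregular_movie(
            grid, 1000.0, [(left, 8.0), (right, 14.0)], jitter=0.0, seed=1)
        dmap = df_map(movie, np.ones(grid, bool))
        np.testing.assert_allclose(dmap.values[left], 8.0, atol=0.05)
        np.testing.assert_allclose(dmap.values[right], 14.0, atol=0.05)

    def test_constant_movie_undefined(self):
        movie = make_movie(np.ones((300, 4, 4)))
        dmap = df_map(movie, np.ones((4, 4), bool))
        assert np.all(np.isnan(dmap.values))

    def test_single_domain_matches_paced_df(self):
        grid = (10, 10)
        whole = np.ones(grid, bool)
        irr, _ = simulate_irregular_movie(grid, 1000.0, [(whole, 8.0)],
                                          jitter=0.0, seed=2)
        paced, _ = simulate_paced_movie(SimulationSpec(
            grid=grid, pcl_schedule=((125.0, 16),), polarity="upright"))
        df_irr = df_map(irr, whole).defined_values
        df_pac = df_map(paced, whole).defined_values
        np.testing.assert_allclose(df_irr, df_pac, atol=0.05)


class TestOws:
    def test_identical_beats_give_one(self):
        beat = ap_template(3.0, 50.0, 1000.0, 100.0)
        assert ows([beat] * 5) == pytest.approx(1.0)

    def test_orthogonal_beats_give_zero(self):
        a = np.array([1.0, 0.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, 1.0])
        assert ows([a, b]) == pytest.approx(0.0)

    def test_monotone_decrease_with_apd_jitter(self):
        rng_master = np.random.default_rng(31)
        values = []
        for sd in (0.0, 3.0, 8.0, 15.0):
            rng = np.random.default_rng(rng_master.integers(2 ** 31))
            beats = [ap_template(3.0, float(np.clip(50.0 + sd * rng.normal(),
                                                    10.0, 90.0)),
                                 1000.0, 130.0) for _ in range(8)]
            values.append(ows(beats))
        assert values[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_symmetric_under_reordering(self):
        rng = np.random.default_rng(5)
        beats = [ap_template(3.0, 40.0 + 10 * rng.random(), 1000.0, 100.0)
                 for _ in range(6)]
        v1 = ows(beats)
        v2 = ows(beats[::-1])
        assert v1 == pytest.approx(v2, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 20), b=st.floats(-5, 5))
    def test_affine_invariance_applied_uniformly(self, a, b):
        rng = np.random.default_rng(6)
        beats = [ap_template(3.0, 40.0 + 10 * rng.random(), 1000.0, 100.0)
                 for _ in range(4)]
        v1 = ows(beats)
        v2 = ows([a * t + b for t in beats])
        assert v2 == pytest.approx(v1, abs=1e-9)

    def test_noise_degrades_similarity_monotonically(self):
        beat = ap_template(3.0, 50.0, 1000.0, 100.0)
        values = []
        for sd in (0.0, 0.05, 0.15, 0.4):
            rng = np.random.default_rng(43)
            beats = [beat + rng.normal(0, sd, beat.size) for _ in range(6)]
            values.append(ows(beats))
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[-1] < values[0]

    def test_flat_beats_dropped(self):
        beat = ap_template(3.0, 50.0, 1000.0, 100.0)
        assert ows([beat, np.zeros_like(beat), beat]) == pytest.approx(1.0)
        assert np.isnan(ows([np.zeros(50), np.zeros(50)]))

    def test_injectable_weights(self):
        a = ap_template(3.0, 40.0, 1000.0, 100.0)
        b = ap_template(3.0, 70.0, 1000.0, 110.0)[:a.size]
        uniform = ows([a, a, b])
        tilted = ows([a, a, b], weights=[1.0, 1.0, 0.0])
        assert tilted != pytest.approx(uniform)


class TestOwsMap:
    def _analysed(self, spec):
        movie, truth = simulate_paced_movie(spec)
        movie = apply_polarity(movie)
        mask = segment_tissue(movie)
        sig = global_signal(movie, mask)
        table = identify_pcls(detect_beats(sig, movie.frame_rate),
                              movie.frame_rate)
        return movie, mask, table

    def test_stable_pacing_gives_ows_near_one(self):
        movie, mask, table = self._analysed(
            SimulationSpec(grid=(21, 21), pcl_schedule=((140.0, 8),)))
        omap = ows_map(movie, table, 0, mask)
        assert np.nanmin(omap.values) > 0.99

    def test_alternans_confined_to_one_half(self):
        # half the tissue alternates: build two half-movies and join them
        grid = (20, 20)
        stable, _ = simulate_paced_movie(SimulationSpec(
            grid=grid, pcl_schedule=((160.0, 8),), apd80=60.0,
            polarity="upright", speed=1e6))
        alt, _ = simulate_paced_movie(SimulationSpec(
            grid=grid, pcl_schedule=((160.0, 8),), apd80=60.0,
            alternans_delta=40.0, polarity="upright", speed=1e6))
        n = min(stable.n_frames, alt.n_frames)
        data = stable.data[:n].copy()
        data[:, :, 10:] = alt.data[:n, :, 10:]
        movie = make_movie(data)
        table = identify_pcls(detect_beats(global_signal(movie), 1000.0),
                              1000.0)
        omap = ows_map(movie, table, 0, np.ones(grid, bool))
        left = np.nanmean(omap.values[:, :10])
        right = np.nanmean(omap.values[:, 10:])
        assert left > 0.99
        assert right < left - 0.005

    def test_single_beat_group_undefined_with_warning(self):
        movie, mask, table = self._analysed(SimulationSpec(
            grid=(15, 15), pcl_schedule=((140.0, 6), (95.0, 2))))
        single = table.groups[table.groups.beat_count == 1]
        if single.empty:
            pytest.skip("no single-beat group formed")
        g = int(single.pcl_group.iloc[0])
        with pytest.warns(UserWarning, match="fewer than 2 beats"):
            omap = ows_map(movie, table, g, mask)
        assert np.all(np.isnan(omap.values))

    def test_irregular_movie_jitter_lowers_ows(self):
        grid = (12, 12)
        whole = np.ones(grid, bool)
        values = {}
        for jit in (0.0, 0.3):
            movie, _ = simulate_irregular_movie(grid, 1000.0, [(whole, 7.0)],
                                                jitter=jit, seed=11,
                                                duration_s=3.0)
            table = identify_pcls(
                detect_beats(global_signal(movie), 1000.0), 1000.0)
            # group with the most beats
            g = int(table.groups.sort_values("beat_count").pcl_group.iloc[-1])
            omap = ows_map(movie, table, g, whole)
            values[jit] = float(np.nanmean(omap.values))
        assert values[0.0] > 0.98
        assert values[0.3] < values[0.0]
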