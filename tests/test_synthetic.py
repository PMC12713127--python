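"""Synthetic generator: determinism, planted structure, preprocessing."""

import numpy as np
import pytest

from spatiodyn import (ICNTimeSeries, bandpass, generate_background,
                       global_signal_regress, make_traveling_wave, plant_qpp,
                       preprocess, zscore)
from spatiodyn.experiments import random_template


class TestGenerateBackground:
    def test_seeded_determinism(self):
        a = generate_background(105, 140, 3.0, seed=7)
        b = generate_background(105, 140, 3.0, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_independent_icns_without_global_signal(self):
        # Monte-Carlo under independence: mean pairwise correlation near 0
        ts = generate_background(20, 2000, 3.0, global_signal_weight=0.0,
                                 noise_sd=1.0, seed=5)
        c = np.corrcoef(ts.data.T)
        off = c[~np.eye(20, dtype=bool)]
        assert abs(off.mean()) < 0.1

    def test_pure_global_signal_is_rank_one(self):
        ts = generate_background(6, 200, 3.0, global_signal_weight=1.0,
                                 noise_sd=0.0, seed=0)
        c = np.corrcoef(ts.data.T)
        np.testing.assert_allclose(c, 1.0, atol=1e-10)

    @pytest.mark.parametrize("kwargs", [
        dict(n_icn=1, n_timepoints=100, tr_seconds=3.0),
        dict(n_icn=5, n_timepoints=8, tr_seconds=3.0),
        dict(n_icn=5, n_timepoints=100, tr_seconds=-1.0),
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_background(seed=0, **kwargs)


class TestPlantQPP:
    def test_zero_amplitude_is_identity(self):
        bg = generate_background(10, 200, 3.0, seed=1)
        tmpl = random_template(10, 8, seed=2)
        out, _ = plant_qpp(bg, tmpl, 20, 2, amplitude_map=0.0, seed=3)
        np.testing.assert_array_equal(out.data, bg.data)

    def test_injection_is_exactly_additive(self):
        # output - input equals the scheduled template copies, nothing else
        bg = generate_background(6, 300, 3.0, seed=4)
        tmpl = random_template(6, 8, seed=5)
        out, truth = plant_qpp(bg, tmpl, 25, 3, amplitude_map=1.0, seed=6)
        diff = out.data - bg.data
        expected = np.zeros_like(diff)
        for s in truth.occurrence_starts:
            expected[s:s + 8, :] += tmpl.T
        np.testing.assert_allclose(diff, expected, atol=1e-14)

    def test_noise_free_segments_match_template_exactly(self):
        zero = ICNTimeSeries(np.zeros((400, 5)) + 1e-9, 3.0)
        tmpl = random_template(5, 8, seed=7)
        out, truth = plant_qpp(zero, tmpl, 20, 0, amplitude_map=1.0, seed=8)
        for s in truth.occurrence_starts:
            seg = out.data[s:s + 8, :].T
            r = np.corrcoef(seg.ravel(), tmpl.ravel())[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_occurrence_count_matches_schedule_scan(self):
        bg = generate_background(4, 800, 3.0, seed=9)
        tmpl = random_template(4, 8, seed=10)
        out, truth = plant_qpp(bg, tmpl, 20, 2, seed=11)
        starts = np.asarray(truth.occurrence_starts)
        assert starts[0] + 8 <= 800 and starts[-1] + 8 <= 800
        gaps = np.diff(starts)
        assert (gaps >= 8).all()
        # independent scan: every planted window really differs from input
        changed = np.nonzero(np.any(out.data != bg.data, axis=1))[0]
        recovered = np.unique([t - w for t in changed for w in range(8)
                               if 0 <= t - w and t - w in set(starts)])
        assert len(starts) == len(recovered)

    def test_template_wider_than_series_rejected(self):
        bg = generate_background(4, 100, 3.0, seed=0)
        with pytest.raises(ValueError):
            plant_qpp(bg, random_template(4, 60, seed=1), 60, 0, seed=2)


class TestTravelingWave:
    def test_zero_phase_step_gives_identical_columns(self):
        ts = make_traveling_wave(8, 128, 1.0, 0.05, 0.0, noise_sd=0.0)
        for m in range(1, 8):
            np.testing.assert_allclose(ts.data[:, m], ts.data[:, 0])

    def test_sinusoid_moments_over_whole_cycles(self):
        # 0.05 Hz at TR=1: period 20 samples; 200 samples = 10 cycles
        ts = make_traveling_wave(4, 200, 1.0, 0.05, np.pi / 8, noise_sd=0.0)
        assert np.abs(ts.data.mean(axis=0)).max() < 1e-12
        v = ts.data.var(axis=0)
        np.testing.assert_allclose(v, v[0], rtol=1e-12)

    def test_phase_gradient_sets_cross_correlation_lag(self):
        # ICN 8 lags ICN 0 by 8 * (pi/8) = pi, i.e. half a period; the
        # brute-force cross-correlation peak over whole cycles sits there.
        period = 20
        ts = make_traveling_wave(16, 400, 1.0, 1 / period, np.pi / 8,
                                 noise_sd=0.0)
        x, y = ts.data[:, 0], ts.data[:, 8]
        lags = np.arange(period)
        cc = [np.dot(x[:-period], np.roll(y, -k)[:-period]) for k in lags]
        # y = cos(wt - pi) peaks half a period after x
        assert lags[int(np.argmax(cc))] == period // 2

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_traveling_wave(4, 100, 2.0, 0.25, 0.1)


class TestPreprocessingChain:
    def test_passband_amplitude_preserved(self):
        t = np.arange(600) * 3.0
        x = np.cos(2 * np.pi * 0.05 * t)
        ts = ICNTimeSeries(np.column_stack([x, x]), 3.0)
        out = bandpass(ts)
        inner = slice(100, 500)
        ratio = out.data[inner, 0].std() / x[inner].std()
        assert 0.9 < ratio < 1.1

    def test_dc_removed(self):
        ts = ICNTimeSeries(np.full((200, 3), 5.0) + 1e-12, 3.0)
        out = bandpass(ts)
        assert np.abs(out.data).max() < 1e-6 * 5.0

    def test_stopband_attenuation(self):
        t = np.arange(400) * 1.0
        x = np.cos(2 * np.pi * 0.4 * t)
        ts = ICNTimeSeries(np.column_stack([x, x]), 1.0)
        out = bandpass(ts)
        assert out.data[100:300, 0].std() / x[100:300].std() < 0.1

    def test_gsr_output_orthogonal_to_global_mean(self):
        rng = np.random.default_rng(0)
        ts = ICNTimeSeries(rng.standard_normal((300, 8)), 3.0)
        g = ts.data.mean(axis=1)
        out = global_signal_regress(ts)
        for m in range(8):
            assert abs(np.corrcoef(out.data[:, m], g)[0, 1]) < 1e-10

    def test_gsr_idempotent_on_orthogonal_input(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((200, 6))
        y = global_signal_regress(ICNTimeSeries(x, 3.0)).data
        # y's columns are orthogonal to its own global mean (which is
        # therefore numerically zero), so a fresh regression is the identity
        with pytest.warns(UserWarning, match="zero variance"):
            out = global_signal_regress(ICNTimeSeries(y, 3.0))
        np.testing.assert_allclose(out.data, y, atol=1e-12)

    def test_gsr_matches_normal_equations_on_toy_matrix(self):
        x = np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 4.0]])
        ts = ICNTimeSeries(x, 1.0)
        out = global_signal_regress(ts)
        g = x.mean(axis=1)
        gc = g - g.mean()
        expected = x - np.outer(gc, (x - x.mean(0)).T @ gc / (gc @ gc))
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_zscore_moments_and_idempotence(self):
        x = np.column_stack([[1.0, 2.0, 3.0], [10.0, 0.0, 5.0]])
        z = zscore(ICNTimeSeries(x, 1.0))
        np.testing.assert_allclose(z.data.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.data.std(axis=0, ddof=1), 1.0)
        with pytest.warns(UserWarning):
            z2 = zscore(z)
        np.testing.assert_array_equal(z.data, z2.data)

    def test_zscore_zero_variance_names_icn(self):
        x = np.column_stack([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        with pytest.raises(ValueError, match="2"):
            zscore(ICNTimeSeries(x, 1.0, icn_ids=(1, 2)))

    def test_flags_recorded_and_steps_warn_once_applied(self):
        rng = np.random.default_rng(2)
        ts = ICNTimeSeries(rng.standard_normal((300, 5)), 3.0)
        out = preprocess(ts)
        assert out.flags == {"bandpassed", "gsr", "zscored"}
        with pytest.warns(UserWarning):
            again = bandpass(out)
        np.testing.assert_array_equal(again.data, out.data)
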