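"""Eye-movement cleaning, FIR filtering, smoothing and LLE."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from roadhypno.eye_features import (apply_fir, clean_eye, design_fir,
                                    lle_embed, moving_average)
from roadhypno.timeline_io import SampledSignal


def _eye_signal(values, names=None):
    names = names or ["pupil_diameter_left", "valid"]
    return SampledSignal(names, 100.0, 0.0, values)


class TestCleanEye:
    def test_all_valid_identity(self):
        rng = np.random.default_rng(0)
        vals = np.column_stack([4 + 0.1 * rng.normal(size=200), np.ones(200)])
        sig = _eye_signal(vals)
        np.testing.assert_array_equal(clean_eye(sig).values, vals)

    def test_spike_interpolated_to_neighbors(self):
        vals = np.column_stack([np.full(50, 4.0), np.ones(50)])
        vals[25, 0] = 30.0  # far outside the physiological range
        out = clean_eye(_eye_signal(vals))
        assert out.values[25, 0] == pytest.approx(4.0)

    def test_invalid_flag_repaired(self):
        vals = np.column_stack([np.full(50, 4.0), np.ones(50)])
        vals[10, 0], vals[10, 1] = 0.0, 0.0
        out = clean_eye(_eye_signal(vals))
        assert out.values[10, 0] == pytest.approx(4.0)
        assert out.channel("valid").all()

    def test_leading_run_held_at_nearest_valid(self):
        vals = np.column_stack([np.full(50, 4.0), np.ones(50)])
        vals[:3, 0] = 0.5  # below range
        out = clean_eye(_eye_signal(vals))
        np.testing.assert_allclose(out.values[:3, 0], 4.0)

    def test_channel_entirely_out_of_range_error(self):
        vals = np.column_stack([np.full(50, 0.5), np.ones(50)])
        with pytest.raises(ValueError, match="every sample is invalid"):
            clean_eye(_eye_signal(vals))


class TestDesignFir:
    @pytest.mark.parametrize("fc,m,mode", [(8.0, 101, "lowpass"),
                                           (0.1, 201, "highpass"),
                                           (3.0, 31, "lowpass")])
    def test_coefficients_symmetric(self, fc, m, mode):
        fir = design_fir(fc, 100.0, m, mode)
        np.testing.assert_array_equal(fir.coefficients,
                                      fir.coefficients[::-1])

    def test_lowpass_table_design_frequency_response(self):
        fir = design_fir(8.0, 100.0, 101, "lowpass")
        h = fir.frequency_response(np.array([0.0, 50.0]))
        assert abs(h[0]) == pytest.approx(1.0, abs=1e-12)
        assert abs(h[1]) < 1e-3

    def test_highpass_table_design_kills_dc(self):
        fir = design_fir(0.1, 100.0, 201, "highpass")
        assert abs(fir.frequency_response(np.array([0.0]))[0]) < 1e-3
        assert abs(np.sum(fir.coefficients)) < 1e-12

    def test_even_order_and_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            design_fir(8.0, 100.0, 100)
        with pytest.raises(ValueError):
            design_fir(60.0, 100.0, 101)

    def test_center_tap_matches_ideal_value(self):
        # untapered ideal response at the center tap is 2 fc / fs
        fir = design_fir(8.0, 100.0, 101, "lowpass")
        taper = np.hamming(101)
        raw = fir.coefficients / taper
        raw *= (2 * 8.0 / 100.0) / raw[50]  # undo DC normalization
        assert raw[50] == pytest.approx(2 * 8.0 / 100.0)


class TestApplyFir:
    def test_constant_preserved_by_lowpass(self):
        fir = design_fir(8.0, 100.0, 101, "lowpass")
        sig = SampledSignal(["x"], 100.0, 0.0, np.full((500, 1), 2.5))
        out = apply_fir(sig, fir)
        interior = out.values[101:-101, 0]
        np.testing.assert_allclose(interior, 2.5, atol=1e-9)

    def test_impulse_reproduces_coefficients(self):
        fir = design_fir(8.0, 100.0, 31, "lowpass")
        x = np.zeros(200)
        center = 100
        x[center] = 1.0
        sig = SampledSignal(["x"], 100.0, 0.0, x[:, None])
        out = apply_fir(sig, fir)
        # delay-compensated: response centred on the impulse
        got = out.values[center - 15: center + 16, 0]
        np.testing.assert_allclose(got, fir.coefficients, atol=1e-12)

    def test_stopband_tone_attenuated(self):
        fir = design_fir(8.0, 100.0, 101, "lowpass")
        t = np.arange(2000) / 100.0
        sig = SampledSignal(["x"], 100.0, 0.0, np.sin(2 * np.pi * 20 * t)[:, None])
        out = apply_fir(sig, fir)
        assert np.max(np.abs(out.values[200:-200])) < 0.05

    def test_short_signal_error(self):
        fir = design_fir(8.0, 100.0, 101, "lowpass")
        with pytest.raises(ValueError):
            apply_fir(SampledSignal(["x"], 100.0, 0.0, np.zeros((50, 1))), fir)


class TestMovingAverage:
    def test_constant_preserved(self):
        sig = SampledSignal(["x"], 10.0, 0.0, np.full((30, 1), 7.0))
        np.testing.assert_allclose(moving_average(sig, 5).values, 7.0)

    def test_impulse_spreads_quarter(self):
        x = np.zeros(20)
        x[8] = 1.0
        sig = SampledSignal(["x"], 10.0, 0.0, x[:, None])
        out = moving_average(sig, 4).values[:, 0]
        np.testing.assert_allclose(out[8:12], 0.25)
        assert np.all(out[:8] == 0) and np.all(out[12:] == 0)

    def test_n1_identity_and_bad_n(self):
        rng = np.random.default_rng(0)
        sig = SampledSignal(["x"], 10.0, 0.0, rng.normal(size=(40, 1)))
        np.testing.assert_array_equal(moving_average(sig, 1).values, sig.values)
        with pytest.raises(ValueError):
            moving_average(sig, 0)

    def test_variance_reduced_on_noise(self):
        rng = np.random.default_rng(42)
        sig = SampledSignal(["x"], 10.0, 0.0, rng.normal(size=(5000, 1)))
        out = moving_average(sig, 20)
        assert out.values.var() < sig.values.var()


class TestLleEmbed:
    def test_weight_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 5))
        emb = lle_embed(x, n_neighbors=6, n_components=2)
        sums = emb.weights.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)
        assert np.all((emb.weights != 0).sum(axis=1) == 6)

    def test_line_segment_ordering_recovered(self):
        # evenly spaced points on a noiseless line segment in 3-D
        t = np.linspace(0.0, 1.0, 50)
        direction = np.array([1.0, -2.0, 0.5])
        x = np.outer(t, direction)
        emb = lle_embed(x, n_neighbors=5, n_components=1)
        rho = spearmanr(t, emb.coordinates[:, 0]).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_matches_sklearn_on_swiss_curve(self):
        # independent cross-check: same neighbourhood ordering as sklearn's LLE
        from sklearn.manifold import LocallyLinearEmbedding

        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(0, 3, size=80))
        x = np.column_stack([np.cos(t), np.sin(t), 0.1 * t]) \
            + 0.01 * rng.normal(size=(80, 3))
        ours = lle_embed(x, n_neighbors=8, n_components=1).coordinates[:, 0]
        ref = LocallyLinearEmbedding(n_neighbors=8, n_components=1,
                                     eigen_solver="dense").fit_transform(x)[:, 0]
        rho = spearmanr(ours, ref).statistic
        assert abs(rho) > 0.95

    def test_planar_manifold_neighborhood_preservation(self):
        rng = np.random.default_rng(2)
        uv = rng.uniform(-1, 1, size=(120, 2))
        basis = rng.normal(size=(2, 5))
        x = uv @ basis
        k = 8
        emb = lle_embed(x, n_neighbors=k, n_components=2)

        def knn(points, kk):
            d = np.linalg.norm(points[:, None] - points[None], axis=2)
            np.fill_diagonal(d, np.inf)
            return np.argsort(d, axis=1)[:, :kk]

        orig = knn(x, 2 * k)
        new = knn(emb.coordinates, k)
        frac = np.mean([np.isin(new[i], orig[i]).mean() for i in range(len(x))])
        assert frac >= 0.9

    def test_objective_beats_random_orthonormal(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(80, 6))
        emb = lle_embed(x, n_neighbors=7, n_components=2)

        def objective(y):
            resid = y - emb.weights @ y
            return np.sum(resid**2)

        q, _ = np.linalg.qr(rng.normal(size=(80, 2)))
        assert objective(emb.coordinates) <= objective(q * np.sqrt(80))

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            lle_embed(x, n_neighbors=10, n_components=2)
        with pytest.raises(ValueError):
            lle_embed(np.ones((20, 4)), n_neighbors=3, n_components=2)
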