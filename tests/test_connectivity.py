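"""Spectral transfer, DTF/ffDTF/partial coherence/dDTF, and feature assembly."""

import numpy as np
import pytest

from emolink.connectivity import (
    DEFAULT_CHANNELS,
    DEFAULT_FREQS,
    BandScheme,
    ConnectivityTensor,
    band_average,
    baseline_correct,
    build_feature_matrix,
    connection_pairs,
    ddtf,
    dtf,
    ffdtf,
    outflow,
    partial_coherence,
    sliding_ddtf,
    top_fraction_edges,
    transfer_function,
    zscore_standardize,
)
from emolink.synthetic import PlantedEdge, make_band_coupled_var
from emolink.var import VarModel, fit_var_ridge, simulate_var

FS = 250.0


def _model(coeffs, sigma=None):
    coeffs = np.asarray(coeffs, dtype=float)
    n = coeffs.shape[1]
    return VarModel(coeffs=coeffs, sigma=np.eye(n) if sigma is None else sigma, fs=FS)


@pytest.fixture(scope="module")
def unidir_fit():
    """Ridge-fit VAR on data from a planted unidirectional 2-channel system."""
    m = make_band_coupled_var(
        2, [PlantedEdge("ch0", "ch1", "theta", 0.3)], FS
    )
    x = simulate_var(m, 20_000, seed=1)
    return fit_var_ridge(x, order=15, ridge=1e-6, fs=FS)


class TestTransferFunction:
    def test_zero_coefficients_give_identity(self):
        spec = transfer_function(_model(np.zeros((2, 3, 3))), DEFAULT_FREQS)
        assert np.allclose(spec.H, np.eye(3)[None], atol=1e-14)

    def test_univariate_ar1_dc_gain(self):
        # |H(0)|^2 = 1/(1-a)^2 = 4 for a = 0.5
        spec = transfer_function(_model(np.array([[[0.5]]])), np.array([0.0]))
        assert abs(spec.H[0, 0, 0]) ** 2 == pytest.approx(4.0, abs=1e-12)

    def test_conjugate_symmetry_about_nyquist(self):
        m = _model([[[0.4, 0.2], [-0.1, 0.3]]])
        f = 10.0
        spec = transfer_function(m, np.array([f]))
        # brute-force H at fs - f from the defining formula
        ph = np.exp(-2j * np.pi * (FS - f) / FS)
        Abar = np.eye(2) - m.coeffs[0] * ph
        H_mirror = np.linalg.inv(Abar)
        assert np.allclose(spec.H[0], H_mirror.conj(), atol=1e-12)

    def test_frequencies_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            transfer_function(_model(np.zeros((1, 2, 2))), np.array([130.0]))


class TestDtfFamily:
    def test_independent_channels_have_zero_cross_terms(self):
        spec = transfer_function(_model(np.zeros((1, 4, 4))), DEFAULT_FREQS)
        for measure in (dtf, ffdtf, partial_coherence, ddtf):
            vals = measure(spec).values
            off = vals[~np.eye(4, dtype=bool)]
            assert np.all(np.abs(off) < 1e-10)

    def test_dtf_row_normalization(self, unidir_fit):
        vals = dtf(transfer_function(unidir_fit, DEFAULT_FREQS)).values
        sums = vals.sum(axis=1)  # over sources, per sink and frequency
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_ffdtf_global_normalization(self, unidir_fit):
        vals = ffdtf(transfer_function(unidir_fit, DEFAULT_FREQS)).values
        sums = vals.sum(axis=(1, 2))  # over sources and frequencies, per sink
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_single_frequency_ffdtf_equals_dtf(self):
        m = _model([[[0.4, 0.2], [0.1, 0.3]]])
        spec = transfer_function(m, np.array([8.0]))
        assert np.allclose(ffdtf(spec).values, dtf(spec).values, atol=1e-14)

    def test_flat_transfer_gives_frequency_uniform_ffdtf(self):
        spec = transfer_function(_model(np.zeros((1, 2, 2))), DEFAULT_FREQS)
        vals = ffdtf(spec).values
        # diagonal entries identical across frequencies (flat spectrum)
        assert np.allclose(vals[0, 0, :], vals[0, 0, 0], atol=1e-14)

    def test_two_channel_partial_coherence_equals_ordinary_coherence(self):
        m = _model([[[0.4, 0.25], [0.15, 0.3]]])
        spec = transfer_function(m, DEFAULT_FREQS)
        chi2 = partial_coherence(spec).values
        S = spec.S
        ordinary = np.abs(S[:, 0, 1]) ** 2 / (
            S[:, 0, 0].real * S[:, 1, 1].real
        )
        assert np.allclose(chi2[0, 1, :], ordinary, atol=1e-10)

    def test_values_lie_in_unit_interval(self, unidir_fit):
        spec = transfer_function(unidir_fit, DEFAULT_FREQS)
        for measure in (dtf, ffdtf, partial_coherence, ddtf):
            vals = measure(spec).values
            assert vals.min() >= 0.0 and vals.max() <= 1.0 + 1e-12

    def test_planted_direction_dominates_in_coupled_band(self, unidir_fit):
        tensor = band_average(ddtf(transfer_function(unidir_fit, DEFAULT_FREQS)))
        theta = tensor.bands.index("theta")
        forward = tensor.values[1, 0, theta]   # ch0 -> ch1 planted
        reverse = tensor.values[0, 1, theta]
        assert forward / reverse > 10.0


@pytest.fixture(scope="module")
def chain_fit():
    # cascade 0 -> 1 -> 2; the 0 -> 2 influence is purely indirect
    edges = [
        PlantedEdge("ch0", "ch1", "theta", 0.3),
        PlantedEdge("ch1", "ch2", "theta", 0.3),
    ]
    m = make_band_coupled_var(3, edges, FS)
    x = simulate_var(m, 30_000, seed=2)
    return fit_var_ridge(x, order=15, ridge=1e-6, fs=FS)


class TestChainSuppression:
    def test_indirect_pair_partial_coherence_suppressed(self, chain_fit):
        spec = transfer_function(chain_fit, DEFAULT_FREQS)
        chi2 = band_average(partial_coherence(spec))
        theta = chi2.bands.index("theta")
        assert chi2.values[2, 0, theta] < chi2.values[1, 0, theta]
        assert chi2.values[2, 0, theta] < chi2.values[2, 1, theta]

    def test_indirect_ddtf_below_dtf(self, chain_fit):
        spec = transfer_function(chain_fit, DEFAULT_FREQS)
        d = band_average(ddtf(spec))
        g = band_average(dtf(spec))
        theta = d.bands.index("theta")
        ratio = d.values[2, 0, theta] / g.values[2, 0, theta]
        assert ratio < 1.0


class TestSliding:
    def test_single_full_window_equals_static_estimate(self):
        m = make_band_coupled_var(2, [PlantedEdge("ch0", "ch1", "alpha", 0.3)], FS)
        epochs = simulate_var(m, 500, seed=4, n_trials=3)
        times = np.arange(500) / FS
        sliding = sliding_ddtf(
            epochs, FS, times, window_ms=2000.0, step_ms=2000.0,
            order=5, ridge=1e-3,
        )
        static_fit = fit_var_ridge(epochs, order=5, ridge=1e-3, fs=FS)
        static = ddtf(transfer_function(static_fit, DEFAULT_FREQS))
        assert sliding.values.shape[0] == 1
        assert np.allclose(sliding.values[0], static.values, atol=1e-12)

    def test_stationary_data_has_stable_windows(self):
        m = make_band_coupled_var(2, [PlantedEdge("ch0", "ch1", "alpha", 0.3)], FS)
        epochs = simulate_var(m, 1500, seed=5, n_trials=30)
        times = np.arange(1500) / FS
        t = sliding_ddtf(epochs, FS, times, window_ms=500, step_ms=250,
                         order=5, ridge=1e-3)
        t = band_average(t)
        alpha = t.bands.index("alpha")
        series = t.values[:, 1, 0, alpha]
        assert series.std() < 0.2 * series.mean()

    def test_onset_of_coupling_elevates_post_windows(self):
        uncoupled = make_band_coupled_var(2, [], FS)
        coupled = make_band_coupled_var(
            2, [PlantedEdge("ch0", "ch1", "alpha", 0.5)], FS
        )
        pre = simulate_var(uncoupled, 500, seed=6, n_trials=40)
        post = simulate_var(coupled, 500, seed=7, n_trials=40)
        epochs = np.concatenate([pre, post], axis=1)
        times = (np.arange(1000) - 500) / FS
        t = band_average(sliding_ddtf(epochs, FS, times, window_ms=400,
                                      step_ms=100, order=5, ridge=1e-3))
        alpha = t.bands.index("alpha")
        series = t.values[:, 1, 0, alpha]
        pre_mean = series[t.times < -0.3].mean()
        post_mean = series[t.times > 0.3].mean()
        assert post_mean > 3 * pre_mean

    def test_too_short_window_raises_with_formula(self):
        epochs = np.random.default_rng(0).standard_normal((4, 500, 1))
        with pytest.raises(ValueError, match="window"):
            sliding_ddtf(epochs, FS, np.arange(500) / FS,
                         window_ms=100, step_ms=50, order=15)


class TestBandAverage:
    def test_hand_arithmetic_on_theta_grid(self):
        freqs = np.array([4.0, 5.0, 6.0, 7.0])
        vals = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)
        t = ConnectivityTensor(vals, ("a",), "dDTF", freqs=freqs)
        out = band_average(t, BandScheme({"theta": (4.0, 7.0)}))
        assert out.values[0, 0, 0] == pytest.approx(2.5)

    def test_frequency_constant_tensor(self):
        t = ConnectivityTensor(
            np.full((2, 2, len(DEFAULT_FREQS)), 0.37), ("a", "b"), "dDTF",
            freqs=DEFAULT_FREQS,
        )
        out = band_average(t)
        assert np.allclose(out.values, 0.37)

    def test_empty_band_raises(self):
        t = ConnectivityTensor(
            np.zeros((1, 1, 3)), ("a",), "dDTF", freqs=np.array([4.0, 5.0, 6.0])
        )
        with pytest.raises(ValueError, match="delta"):
            band_average(t, BandScheme({"delta": (1.0, 3.0)}))


class TestBaselineAndZscore:
    def _tensor(self, values, times):
        return ConnectivityTensor(
            values, ("a", "b"), "dDTF", bands=("theta",), times=times
        )

    def test_time_constant_tensor_maps_to_zero(self):
        times = np.linspace(-0.25, 1.0, 20)
        t = self._tensor(np.full((20, 2, 2, 1), 0.4), times)
        out = baseline_correct(t, (-0.25, 0.0))
        assert np.allclose(out.values, 0.0)

    def test_step_change_recovered(self):
        times = np.linspace(-0.25, 1.0, 26)
        vals = np.full((26, 2, 2, 1), 0.2)
        vals[times > 0] += 0.1
        out = baseline_correct(self._tensor(vals, times), (-0.25, 0.0))
        assert np.allclose(out.values[times > 0], 0.1, atol=1e-12)

    def test_no_baseline_windows_raises(self):
        times = np.linspace(0.5, 1.0, 5)
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(self._tensor(np.zeros((5, 2, 2, 1)), times),
                             (-0.25, 0.0))

    def test_zscore_moments_and_two_pass_oracle(self, rng):
        vals = rng.random((30, 2, 2, 1))
        t = self._tensor(vals, np.linspace(0, 1, 30))
        z = zscore_standardize(t, axis=0)
        assert np.allclose(z.values.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.values.std(axis=0), 1.0, atol=1e-10)
        # brute-force two-pass oracle on one slice
        col = vals[:, 1, 0, 0]
        expect = (col - col.mean()) / col.std()
        assert np.allclose(z.values[:, 1, 0, 0], expect, atol=1e-12)

    def test_constant_slice_becomes_zero(self):
        vals = np.ones((10, 1, 1, 1))
        z = zscore_standardize(self._tensor(vals, np.linspace(0, 1, 10)), axis=0)
        assert np.allclose(z.values, 0.0)


class TestOutflowAndTopEdges:
    def test_all_ones_offdiagonal_gives_eleven(self):
        conn = np.ones((12, 12)) - np.eye(12)
        assert np.allclose(outflow(conn), 11.0)

    def test_matches_brute_force_summation(self, rng):
        conn = rng.random((12, 12))
        of = outflow(conn)
        for j in range(12):
            brute = sum(conn[i, j] for i in range(12) if i != j)
            assert of[j] == pytest.approx(brute, abs=1e-12)

    def test_zero_matrix(self):
        assert np.allclose(outflow(np.zeros((5, 5))), 0.0)

    def test_full_fraction_returns_all_pairs(self, rng):
        conn = rng.standard_normal((12, 12))
        edges = top_fraction_edges(conn, DEFAULT_CHANNELS, fraction=1.0)
        assert len(edges) == 132

    def test_ten_percent_is_fourteen_edges(self, rng):
        conn = rng.standard_normal((12, 12))
        edges = top_fraction_edges(conn, DEFAULT_CHANNELS, fraction=0.10)
        assert len(edges) == 14  # ceil(13.2)

    def test_tie_break_is_deterministic(self):
        conn = np.ones((12, 12))
        a = top_fraction_edges(conn, DEFAULT_CHANNELS, fraction=0.1)
        b = top_fraction_edges(conn, DEFAULT_CHANNELS, fraction=0.1)
        assert a == b
        # sink-major order: first pair is (CP3, CPz)
        assert (a[0][0], a[0][1]) == ("CP3", "CPz")


class TestFeatureMatrix:
    def test_shape_and_pair_count(self, rng):
        tensors = [rng.random((12, 12, 4)) for _ in range(6)]
        conds = ["attend", "reinterpret"] * 3
        fm = build_feature_matrix(tensors, conds, DEFAULT_CHANNELS,
                                  ("delta", "theta", "alpha", "beta"))
        assert fm.values.shape == (132, 4, 2)
        assert len(fm.pairs) == 132
        assert len(set(fm.pairs)) == 132
        assert all(i != j for i, j in fm.pairs)

    def test_single_trial_equals_its_values(self, rng):
        t_a = rng.random((3, 3, 2))
        t_r = rng.random((3, 3, 2))
        fm = build_feature_matrix([t_a, t_r], ["attend", "reinterpret"],
                                  ("x", "y", "z"), ("theta", "alpha"))
        k = fm.pairs.index((1, 0))
        assert fm.values[k, 0, 0] == pytest.approx(t_a[1, 0, 0])
        assert fm.values[k, 1, 1] == pytest.approx(t_r[1, 0, 1])

    def test_trial_order_invariance(self, rng):
        tensors = [rng.random((3, 3, 1)) for _ in range(4)]
        conds = ["attend", "reinterpret", "attend", "reinterpret"]
        fm1 = build_feature_matrix(tensors, conds, ("x", "y", "z"), ("theta",))
        order = [2, 1, 0, 3]
        fm2 = build_feature_matrix([tensors[k] for k in order],
                                   [conds[k] for k in order],
                                   ("x", "y", "z"), ("theta",))
        assert np.allclose(fm1.values, fm2.values)

    def test_pair_enumeration_is_sink_major(self):
        pairs = connection_pairs(("a", "b", "c"))
        assert pairs == [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
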