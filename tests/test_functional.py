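"""Correlation and SVD activation analysis."""

import numpy as np
import pytest

from fulm.functional import (
    SvdActivation,
    baseline_map,
    correlation_map,
    relative_variation_map,
    select_stim_mode,
    single_trial_variation,
    svd_decompose,
    synthetic_rank_two_movie,
    variation_map,
)
from fulm.grids import default_coarse_grid
from fulm.maps import build_sliding_movie
from fulm.phantom import StimulusProtocol
from fulm.tracking import rasterize_trackset


@pytest.fixture
def rank2():
    movie, truth = synthetic_rank_two_movie(seed=3)
    return movie, truth


class TestCorrelationMap:
    def test_perfect_and_anti_correlated_pixels(self):
        n_t = 70
        t = np.arange(n_t)
        a = ((t >= 30) & (t < 60)).astype(float)
        m = np.zeros((2, 2, n_t))
        m[0, 0] = a  # identical to the stimulus
        m[0, 1] = -a + 5.0  # anti-correlated
        m[1, 0] = 3.0  # zero temporal variance
        m[1, 1] = np.sin(t)  # unrelated
        c = correlation_map(m, a)
        assert np.isclose(c[0, 0], 1.0)
        assert np.isclose(c[0, 1], -1.0)
        assert c[1, 0] == 0.0
        assert -1.0 <= c[1, 1] <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlation_map(np.zeros((2, 2, 10)), np.ones(9))

    def test_activated_pixels_outrank_controls(self, activated_truth, short_protocol):
        """Mean correlation over activated phantom pixels exceeds the mean
        over control-vessel pixels."""
        from fulm.maps import pattern_average_streaming

        grid = default_coarse_grid(16, 16).super_grid(8)
        raster = rasterize_trackset(activated_truth.to_trackset(), grid)
        pm = pattern_average_streaming(raster, grid, short_protocol)
        c = correlation_map(pm, short_protocol.boxcar(pm.phases))
        act = activated_truth.activated_pixel_mask(grid)
        ctl = activated_truth.segment_pixel_mask(grid, segment_ids={1})
        assert c[act].mean() > c[ctl].mean() + 0.1


class TestSvdDecompose:
    def test_rank2_movie_has_two_modes(self, rank2):
        movie, _ = rank2
        svd = svd_decompose(movie)
        assert svd.s[1] > 1e-8
        assert np.all(svd.s[2:] < 1e-10 * svd.s[0])

    def test_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 5, size=(6, 7, 20))
        svd = svd_decompose(m)
        np.testing.assert_allclose(svd.reconstruct(), m, atol=1e-10 * np.abs(m).max())
        k = svd.n_modes
        uf = svd.u.reshape(-1, k)
        np.testing.assert_allclose(uf.T @ uf, np.eye(k), atol=1e-10)
        np.testing.assert_allclose(svd.vt @ svd.vt.T, np.eye(k), atol=1e-10)

    def test_zero_movie_rejected(self):
        with pytest.raises(ValueError):
            svd_decompose(np.zeros((3, 3, 5)))


class TestSelectStimMode:
    def test_rank2_selects_second_mode_with_positive_sign(self, rank2):
        movie, truth = rank2
        svd = svd_decompose(movie)
        i = select_stim_mode(svd, truth["a_t"])
        assert i == 1 and svd.mode_number == 2
        assert svd.p[i] > 0.99

    def test_orthogonal_stimulus_yields_no_mode(self, rank2):
        movie, truth = rank2
        svd = svd_decompose(movie)
        rng = np.random.default_rng(1)
        # a stimulus orthogonal to both temporal modes by construction
        a = rng.normal(size=movie.shape[2])
        for v in svd.vt[:2]:
            a -= (a @ v) * v
        a -= a.mean()
        with pytest.warns(UserWarning, match="no stimulus-locked mode"):
            assert select_stim_mode(svd, a) is None

    def test_global_sign_invariance(self, rank2):
        """Flipping any (U_i, V_i) pair leaves the output maps unchanged."""
        movie, truth = rank2
        svd1 = svd_decompose(movie)
        svd2 = svd_decompose(movie)
        svd2.u[:, :, 1] *= -1
        svd2.vt[1] *= -1
        select_stim_mode(svd1, truth["a_t"])
        select_stim_mode(svd2, truth["a_t"])
        w = truth["stim_window"]
        m1 = variation_map(svd1, truth["phases"], w, (0.0, 30.0))
        m2 = variation_map(svd2, truth["phases"], w, (0.0, 30.0))
        np.testing.assert_allclose(m1, m2, atol=1e-12)


class TestVariationMap:
    def test_planted_amplitude_recovered_exactly(self, rank2):
        """MB_svd equals activation amplitude x stimulus duration on the
        activated pixels and 0 elsewhere (rank-2 construction)."""
        movie, truth = rank2
        svd = svd_decompose(movie)
        select_stim_mode(svd, truth["a_t"])
        m = variation_map(svd, truth["phases"], truth["stim_window"], (0.0, 30.0))
        expected = truth["activation_amp"] * truth["t_stim"] * truth["activation_map"]
        np.testing.assert_allclose(m, expected, atol=1e-8 * expected.max())

    def test_unequal_windows_rejected(self, rank2):
        movie, truth = rank2
        svd = svd_decompose(movie)
        select_stim_mode(svd, truth["a_t"])
        with pytest.raises(ValueError, match="equal duration"):
            variation_map(svd, truth["phases"], (30.0, 60.0), (0.0, 20.0))

    def test_applies_to_velocity_style_movies(self):
        """The same machinery yields speed-variation maps from a velocity
        movie (values in mm/s instead of counts)."""
        movie, truth = synthetic_rank_two_movie(
            baseline_level=8.0, activation_amp=0.5, seed=9
        )
        svd = svd_decompose(movie)
        select_stim_mode(svd, truth["a_t"])
        m = variation_map(svd, truth["phases"], truth["stim_window"], (0.0, 30.0))
        np.testing.assert_allclose(
            m, 0.5 * truth["t_stim"] * truth["activation_map"], atol=1e-8
        )


class TestRelativeVariationMap:
    def _handmade_svd(self):
        """Direct formula oracle on an explicitly constructed decomposition."""
        nz = nx = 4
        n_t = 10
        phases = np.arange(n_t, dtype=float)
        u = np.zeros((nz, nx, 2))
        u[:, :, 0] = 1.0 / np.sqrt(nz * nx)
        u[1, 2, 1] = 1.0
        vt = np.zeros((2, n_t))
        vt[0] = 1.0 / np.sqrt(n_t)
        vt[1, 5:] = 1.0 / np.sqrt(5)
        svd = SvdActivation(s=np.array([20.0, 4.0]), u=u, vt=vt, step_t=1.0)
        svd.i_stim = 1
        svd.p = np.array([0.0, 1.0])
        return svd, phases

    def test_matches_direct_formula(self):
        svd, phases = self._handmade_svd()
        stim_w, base_w = (5.0, 10.0), (0.0, 5.0)
        out = relative_variation_map(svd, phases, stim_w, base_w)
        num = 4.0 * svd.u[:, :, 1] * (vsum := (svd.vt[1, 5:].sum() - svd.vt[1, :5].sum()))
        den = 20.0 * svd.u[:, :, 0] * svd.vt[0, :5].sum()
        expected = num / den
        assert np.isclose(out[1, 2], expected[1, 2])
        # pixels without activation: numerator 0 -> ratio 0
        assert np.isclose(out[0, 0], 0.0)

    def test_zero_baseline_pixels_masked(self, rank2):
        movie, truth = rank2
        svd = svd_decompose(movie)
        select_stim_mode(svd, truth["a_t"])
        out = relative_variation_map(svd, truth["phases"], truth["stim_window"], (0.0, 30.0))
        # disjoint supports: activated pixels have no baseline -> masked
        assert np.isnan(out[truth["activation_map"] > 0]).all()

    def test_overlapping_supports_match_perturbative_closed_form(self):
        """With baseline under the activated pixels, the ratio approaches
        (a * T_stim) / (b * T_base)."""
        movie, truth = synthetic_rank_two_movie(
            baseline_level=10.0,
            activation_amp=0.5,
            n_baseline_pixels=120,
            n_activated_pixels=3,
            overlap=True,
            seed=5,
        )
        svd = svd_decompose(movie)
        select_stim_mode(svd, truth["a_t"])
        out = relative_variation_map(svd, truth["phases"], truth["stim_window"], (0.0, 30.0))
        expected = (0.5 * truth["t_stim"]) / (10.0 * 30.0)
        act = truth["activation_map"] > 0
        np.testing.assert_allclose(out[act], expected, rtol=0.05)

    def test_first_mode_stimulus_warns_and_masks(self):
        svd, phases = self._handmade_svd()
        svd.i_stim = 0
        with pytest.warns(UserWarning, match="first mode"):
            base = baseline_map(svd, phases, (0.0, 5.0))
        assert np.all(base == 0.0)

    def test_baseline_map_reproduces_basal_image(self, rank2):
        movie, truth = rank2
        svd = svd_decompose(movie)
        select_stim_mode(svd, truth["a_t"])
        base = baseline_map(svd, truth["phases"], (0.0, 30.0))
        np.testing.assert_allclose(base, truth["baseline_map"] * 30.0, atol=1e-8)


class TestSingleTrial:
    def _movie_from(self, truth, protocol, grid_factor=8):
        grid = default_coarse_grid(16, 16).super_grid(grid_factor)
        raster = rasterize_trackset(truth.to_trackset(), grid)
        return build_sliding_movie(raster, grid, acq_t=protocol.acq_t), grid

    def test_strong_activation_found_without_pattern_summation(
        self, activated_truth, short_protocol
    ):
        movie, grid = self._movie_from(activated_truth, short_protocol)
        total, per_trial, courses = single_trial_variation(movie, short_protocol, p_min=0.3)
        assert per_trial.shape[0] == short_protocol.n_patterns
        act = activated_truth.activated_pixel_mask(grid)
        ctl = activated_truth.segment_pixel_mask(grid, segment_ids={1})
        assert total[act].mean() > total[ctl].mean()

    def test_null_phantom_selects_no_mode(self, null_truth, short_protocol):
        movie, _ = self._movie_from(null_truth, short_protocol)
        with pytest.warns(UserWarning, match="no stimulus-locked mode"):
            total, per_trial, _ = single_trial_variation(movie, short_protocol)
        assert per_trial.shape[0] == 0
        assert np.all(total == 0.0)


class TestBolusDiscrimination:
    def test_injection_and_activation_in_distinct_modes(self):
        """With a bolus-like global concentration oscillation plus a
        stimulus-locked activation, the two signals land in different
        singular modes and the scalar products pick the activation."""
        rng = np.random.default_rng(7)
        nz = nx = 12
        n_t = 140  # two 70-s patterns
        t = np.arange(n_t, dtype=float)
        proto = StimulusProtocol(rest_pre=30, stim=30, rest_post=10, n_patterns=2)
        a = proto.boxcar(t)
        vasc = (rng.uniform(size=(nz, nx)) < 0.3).astype(float)
        act = np.zeros((nz, nx))
        act[4:6, 4:6] = vasc[4:6, 4:6]
        bolus = 1.0 + 0.5 * np.sin(2 * np.pi * t / 35.0)  # injections every 35 s
        m = 5.0 * vasc[:, :, None] * bolus[None, None, :] + 2.0 * act[:, :, None] * (
            a - a.mean()
        )[None, None, :]
        svd = svd_decompose(m)
        i_stim = select_stim_mode(svd, a, p_min=0.3)
        assert i_stim is not None
        # the bolus oscillation dominates another, different mode
        bol_scores = np.abs(svd.vt @ ((bolus - bolus.mean()) / np.linalg.norm(bolus - bolus.mean())))
        i_bolus = int(np.argmax(bol_scores))
        assert i_bolus != i_stim
        assert i_stim in (1, 2) and i_bolus in (0, 1)
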