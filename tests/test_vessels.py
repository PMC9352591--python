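"""Compartment segmentation, vessel profiles, perfusion areas and the
rest-versus-stimulation statistics."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from fulm.grids import Grid, default_coarse_grid
from fulm.maps import MapSet, accumulate_maps, split_rest_stim_maps
from fulm.phantom import StimulusProtocol
from fulm.tracking import rasterize_polyline, rasterize_trackset
from fulm.vessels import (
    LABELS,
    PerfusionArea,
    dilation_constriction_map,
    dynamic_velocity_histogram,
    flow_angle,
    half_max_diameter,
    neighbor_velocity_discrimination,
    paired_depth_stats,
    perfusion_area,
    profile_metrics,
    rest_stim_stats,
    segment_compartments,
    transversal_profile,
    velocity_samples_across_section,
)

GRID = Grid(nz=96, nx=96, pitch_z_um=6.25, pitch_x_um=6.875)


def _mapset(count, vz=None, vx=None, velocity=None, grid=GRID):
    count = np.asarray(count, float)
    z = np.zeros_like(count)
    return MapSet(
        count=count,
        velocity=velocity if velocity is not None else z,
        vz=vz if vz is not None else z,
        vx=vx if vx is not None else z,
        valid_mask=count >= 1,
        grid=grid,
    )


def _vessel_maps(cols, amp=20.0, vz_val=5.0, grid=GRID):
    """Vertical vessel spanning the given columns with downward flow."""
    count = np.zeros(grid.shape)
    vz = np.zeros(grid.shape)
    for c in cols:
        count[:, c] = amp
        vz[:, c] = vz_val
    return _mapset(count, vz=vz, velocity=np.abs(vz), grid=grid)


class TestSegmentCompartments:
    def test_two_vessel_phantom_labels(self, null_truth):
        """One descending and one ascending vessel are labelled arteriole
        and venule with >= 95 % pixel accuracy."""
        grid = default_coarse_grid(16, 16).super_grid(8)
        raster = rasterize_trackset(null_truth.to_trackset(), grid)
        maps = accumulate_maps(raster, grid)
        labels = segment_compartments(maps)
        art_true = null_truth.segment_pixel_mask(grid, segment_ids={0})
        ven_true = null_truth.segment_pixel_mask(grid, segment_ids={1})
        got = labels[art_true & (labels > 0)]
        assert len(got) > 50
        assert (got == LABELS["penetrating_arteriole"]).mean() >= 0.95
        got_v = labels[ven_true & (labels > 0)]
        assert (got_v == LABELS["venule"]).mean() >= 0.95

    def test_pial_seed_overrides_flow_split(self):
        maps = _vessel_maps([40, 41, 42])
        pial = np.zeros(GRID.shape, bool)
        pial[:, :] = True  # everything declared pial
        labels = segment_compartments(maps, pial_mask=pial)
        assert set(np.unique(labels)) <= {LABELS["none"], LABELS["pial"]}

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            segment_compartments(_mapset(np.zeros(GRID.shape)))


class TestDynamicVelocityHistogram:
    proto = StimulusProtocol(rest_pre=3, stim=3, rest_post=1, n_patterns=3)

    def _raster(self, speed=10.0):
        t = np.arange(0.0, self.proto.acq_t, 0.25)
        return pd.DataFrame(
            {
                "track_id": 0,
                "iz": 10,
                "ix": 10,
                "t_s": t,
                "vz_mm_s": speed,
                "vx_mm_s": 0.0,
                "speed_mm_s": speed,
            }
        )

    def _labels(self):
        labels = np.zeros(GRID.shape, dtype=np.int8)
        labels[10, 10] = LABELS["penetrating_arteriole"]
        return labels

    def test_single_speed_single_hot_bin(self):
        hist, edges, phases = dynamic_velocity_histogram(
            self._raster(10.0), self._labels(), "penetrating_arteriole", self.proto, w_t=2.0, step_t=1.0
        )
        assert hist.max() == 1.0
        hot = np.nonzero(hist.sum(axis=1))[0]
        assert hot.tolist() == [10]  # 1 mm/s bins: all mass in [10, 11)
        assert hist.shape == (len(edges) - 1, len(phases))

    def test_direction_filter_for_arterioles(self):
        """Upward-flowing bubbles are excluded from the arteriolar
        compartment even inside its pixels."""
        r = self._raster(10.0)
        r["vz_mm_s"] = -10.0  # ascending
        with pytest.raises(ValueError, match="no detections"):
            dynamic_velocity_histogram(r, self._labels(), "penetrating_arteriole", self.proto)

    def test_empty_compartment_rejected(self):
        with pytest.raises(ValueError):
            dynamic_velocity_histogram(
                self._raster(), np.zeros(GRID.shape, np.int8), "venule", self.proto
            )


class TestProfilesAndDiameter:
    def test_half_max_diameter_exact_on_rectangle(self):
        offs = np.arange(-40.0, 40.5, 1.0)
        profile = np.where(np.abs(offs) <= 12.0, 8.0, 0.0)
        # crossings interpolate to the rectangle edges at threshold 4
        d = half_max_diameter(offs, profile, 4.0)
        assert abs(d - 25.0) <= 1.0  # edges at +-12.5 after interpolation

    def test_gaussian_fwhm_closed_form(self):
        offs = np.arange(-60.0, 60.5, 0.5)
        sigma = 9.0
        profile = 5.0 * np.exp(-0.5 * (offs / sigma) ** 2)
        d = half_max_diameter(offs, profile, 2.5)
        assert abs(d - 2.355 * sigma) < 1.0

    def test_profile_never_reaching_threshold_is_nan(self):
        offs = np.arange(-10.0, 10.5, 1.0)
        assert np.isnan(half_max_diameter(offs, np.ones_like(offs), 5.0))

    def test_rectangular_vessel_metrics_exact(self):
        """A vertical vessel of rectangular cross-section measures its
        true width, max count and centre speed."""
        cols = list(range(40, 48))  # 8 super-pixels wide = 55 um
        maps = _vessel_maps(cols, amp=20.0, vz_val=6.0)
        center = GRID.index_center(48, 43)
        rest, stim = profile_metrics(maps, maps, (float(center[0]), float(center[1])), (6.0, 0.0))
        width_true = len(cols) * GRID.pitch_x_um
        assert abs(rest.diameter_um - width_true) <= GRID.pitch_x_um
        assert np.isclose(rest.max_count, 20.0)
        assert np.isclose(rest.velocity_at_max, 6.0)
        assert rest.diameter_um == stim.diameter_um

    def test_rest_threshold_semantics(self):
        """The diameter threshold comes from the REST profile: pure
        amplitude scaling leaves the rest diameter unchanged but widens the
        stim diameter of a Gaussian profile."""
        sigma_px = 4.0
        count = np.zeros(GRID.shape)
        xs = np.arange(GRID.nx)
        count[:, :] = 10.0 * np.exp(-0.5 * ((xs - 43) / sigma_px) ** 2)[None, :]
        vz = np.full(GRID.shape, 5.0)
        rest_maps = _mapset(count, vz=vz, velocity=np.abs(vz))
        stim_maps = _mapset(2.0 * count, vz=vz, velocity=np.abs(vz))
        center = GRID.index_center(48, 43)
        rest, stim = profile_metrics(
            rest_maps, stim_maps, (float(center[0]), float(center[1])), (5.0, 0.0)
        )
        fwhm_um = 2.355 * sigma_px * GRID.pitch_x_um
        assert abs(rest.diameter_um - fwhm_um) < 2 * GRID.pitch_x_um
        assert stim.diameter_um > 1.2 * rest.diameter_um

    def test_transversal_profile_matches_point_metrics(self):
        cols = list(range(40, 48))
        maps = _vessel_maps(cols, amp=20.0, vz_val=6.0)
        seg = np.array([[300.0, 150.0], [300.0, 500.0]])
        rest, stim = transversal_profile(maps, maps, seg, slice_width_um=50.0, smooth_um=0.0)
        assert abs(rest.diameter_um - len(cols) * GRID.pitch_x_um) <= GRID.pitch_x_um
        assert np.isclose(rest.max_count, 20.0)

    def test_no_vessel_in_segment_flagged(self):
        maps = _vessel_maps([40], amp=0.0)
        seg = np.array([[300.0, 150.0], [300.0, 500.0]])
        rest, stim = transversal_profile(maps, maps, seg)
        assert np.isnan(rest.diameter_um) and np.isnan(stim.max_count)

    def test_flow_angle_two_argument_form(self):
        assert flow_angle(1.0, 0.0) == 0.0
        assert np.isclose(flow_angle(1.0, 1.0), np.pi / 4)
        assert np.isclose(abs(flow_angle(-1.0, 0.0)), np.pi)  # no division by zero


class TestPerfusionArea:
    def _raster_from_tracks(self, tracks):
        rows = []
        for tid, pts in enumerate(tracks):
            pix = rasterize_polyline(np.asarray(pts, float), GRID)
            for iz, ix in pix:
                rows.append((tid, iz, ix, 0.0, 1.0, 0.0, 1.0))
        return pd.DataFrame(
            rows, columns=["track_id", "iz", "ix", "t_s", "vz_mm_s", "vx_mm_s", "speed_mm_s"]
        )

    seed = np.array([[100.0, 100.0], [100.0, 400.0]])

    def test_area_equals_independent_rasterization(self):
        track = [[50.0, 200.0], [550.0, 200.0]]
        raster = self._raster_from_tracks([track])
        area = perfusion_area(raster, self.seed, GRID)
        oracle_pixels = {tuple(p) for p in rasterize_polyline(np.asarray(track), GRID)}
        assert area.n_pixels == len(oracle_pixels)
        assert np.isclose(area.area_um2, len(oracle_pixels) * 6.25 * 6.875)

    def test_duplicate_track_does_not_enlarge(self):
        track = [[50.0, 200.0], [550.0, 200.0]]
        one = perfusion_area(self._raster_from_tracks([track]), self.seed, GRID)
        two = perfusion_area(self._raster_from_tracks([track, track]), self.seed, GRID)
        assert one.area_um2 == two.area_um2

    def test_monotone_under_track_addition(self):
        t1 = [[50.0, 200.0], [550.0, 200.0]]
        t2 = [[50.0, 200.0], [550.0, 300.0]]
        t3 = [[50.0, 500.0], [550.0, 500.0]]  # does not pass the seed
        a1 = perfusion_area(self._raster_from_tracks([t1]), self.seed, GRID)
        a12 = perfusion_area(self._raster_from_tracks([t1, t2]), self.seed, GRID)
        a123 = perfusion_area(self._raster_from_tracks([t1, t2, t3]), self.seed, GRID)
        assert a1.area_um2 <= a12.area_um2
        assert a12.area_um2 == a123.area_um2  # non-passing track ignored

    def test_no_passing_tracks_warns_zero(self):
        t3 = [[50.0, 500.0], [550.0, 500.0]]
        with pytest.warns(UserWarning, match="no tracks pass"):
            area = perfusion_area(self._raster_from_tracks([t3]), self.seed, GRID)
        assert area.area_um2 == 0.0


class TestDilationMap:
    def test_identical_conditions_all_zero(self):
        count = np.zeros(GRID.shape)
        count[:, 40:44] = 10.0
        out = dilation_constriction_map(count, count)
        assert np.all(out == 0)

    def test_widened_vessel_ring_of_dilation(self):
        rest = np.zeros(GRID.shape)
        rest[:, 40:44] = 10.0
        stim = np.zeros(GRID.shape)
        stim[:, 36:48] = 10.0  # clearly dilated vessel
        out = dilation_constriction_map(rest, stim)
        assert set(np.unique(out)) <= {-1, 0, 1}
        assert (out == 1).sum() > 0
        # dilation pixels hug the old vessel on both sides
        dil_cols = np.unique(np.nonzero(out == 1)[1])
        assert dil_cols.min() < 40 and dil_cols.max() >= 44


class TestRestStimStats:
    def _exact_two_sided_p(self, rel):
        """Exhaustive signed-rank enumeration oracle (no ties)."""
        n = len(rel)
        ranks = stats.rankdata(np.abs(rel))
        w_obs = ranks[np.asarray(rel) > 0].sum()
        ws = []
        for signs in product([0, 1], repeat=n):
            ws.append(sum(r for r, s in zip(ranks, signs) if s))
        ws = np.asarray(ws)
        mean_w = n * (n + 1) / 4
        p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
        return p

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        rest = np.full(10, 100.0)
        stim = rest * (1 + rng.normal(0.05, 0.08, size=10))
        out = rest_stim_stats(rest, stim)
        rel = (stim - rest) / rest
        assert np.isclose(out["p_value"], self._exact_two_sided_p(rel), atol=1e-12)

    def test_all_positive_variations_minimal_p(self):
        rest = np.full(10, 50.0)
        stim = rest * np.linspace(1.1, 1.5, 10)
        out = rest_stim_stats(rest, stim)
        assert np.isclose(out["p_value"], 2 / 2**10)
        assert out["mean_rel"] > 0

    def test_symmetric_differences_p_near_one(self):
        rest = np.full(8, 10.0)
        deltas = np.array([1, -1, 2, -2, 3, -3, 4, -4], float)
        out = rest_stim_stats(rest, rest + deltas)
        assert out["p_value"] > 0.9

    def test_zero_differences_reported_undefined(self):
        rest = np.full(6, 5.0)
        with pytest.warns(UserWarning):
            out = rest_stim_stats(rest[:4], rest[:4])
        assert np.isnan(out["p_value"])

    def test_paired_depth_comparison(self):
        shallow = np.array([0.10, 0.12, 0.11, 0.13, 0.09, 0.14, 0.12, 0.10])
        deep = shallow - 0.07
        out = paired_depth_stats(shallow, deep)
        assert out["p_value"] < 0.01


class TestNeighborVelocityDiscrimination:
    def test_distinct_populations_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(8.0, 0.5, 20)
        b = rng.normal(12.0, 0.5, 20)
        out = neighbor_velocity_discrimination([a, b])
        assert out.significant.iloc[0]
        # closed-form check of the Welch statistic
        t_direct = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 20 + b.var(ddof=1) / 20)
        assert np.isclose(out.t.iloc[0], t_direct)

    def test_identical_populations_rarely_significant(self):
        n_sig = 0
        for s in range(40):
            rng = np.random.default_rng(100 + s)
            a = rng.normal(10.0, 0.5, 20)
            b = rng.normal(10.0, 0.5, 20)
            n_sig += int(neighbor_velocity_discrimination([a, b]).significant.iloc[0])
        assert n_sig <= 2  # alpha = 0.01: >= 95 % of seeds non-significant

    def test_small_bins_skipped(self):
        out = neighbor_velocity_discrimination([np.array([1.0]), np.array([2.0, 3.0])])
        assert len(out) == 0

    def test_sample_collection_by_phase(self):
        proto = StimulusProtocol(rest_pre=3, stim=3, rest_post=1, n_patterns=2)
        raster = pd.DataFrame(
            {
                "track_id": [0, 1, 2],
                "iz": [5, 5, 6],
                "ix": [7, 7, 7],
                "t_s": [1.0, 8.0, 4.0],
                "vz_mm_s": [3.0, 4.0, 9.0],
                "vx_mm_s": 0.0,
                "speed_mm_s": [3.0, 4.0, 9.0],
            }
        )
        samples = velocity_samples_across_section(
            raster, [(5, 7), (6, 7)], protocol=proto, phase_window=(0.0, 3.0)
        )
        assert samples[0].tolist() == [3.0, 4.0]  # both rest-phase detections
        assert samples[1].tolist() == []


class TestLongitudinalProfile:
    def _rect_vessel_maps(self, amp, cols):
        count = np.zeros(GRID.shape)
        vz = np.zeros(GRID.shape)
        for c in cols:
            count[:, c] = amp
            vz[:, c] = 5.0
        return _mapset(count, vz=vz, velocity=np.where(count > 0, 5.0, 0.0))

    def test_centerline_extraction_prunes_to_vessel_axis(self):
        from fulm.vessels import extract_centerline

        mask = np.zeros(GRID.shape, bool)
        mask[:, 40:48] = True
        mask[30:33, 48:58] = True  # short spur branch
        pts = extract_centerline(mask, min_branch_px=12)
        assert len(pts) > 80
        # axis runs down the middle; skeleton ends may fan out by a pixel
        on_axis = np.abs(pts[:, 1] - 43.5) <= 1.0
        assert on_axis.mean() >= 0.95
        assert (np.diff(pts[:, 0]) >= 0).all()

    def test_rectangular_vessel_constant_diameter(self):
        from fulm.vessels import longitudinal_profile

        cols = list(range(40, 48))
        rest = self._rect_vessel_maps(20.0, cols)
        stim = self._rect_vessel_maps(30.0, cols)
        centerline = np.array([(z, 43) for z in range(8, 88)])
        df = longitudinal_profile(rest, stim, centerline)
        width = len(cols) * GRID.pitch_x_um
        inner = df[(df.iz > 15) & (df.iz < 80)]
        np.testing.assert_allclose(inner.rest_diameter_um, width, atol=GRID.pitch_x_um)
        # amplitude-only change: same width at the rest half-max threshold
        np.testing.assert_allclose(inner.stim_diameter_um, width, atol=GRID.pitch_x_um)
        np.testing.assert_allclose(inner.rest_max_count, 20.0, rtol=1e-6)
        np.testing.assert_allclose(inner.stim_max_count, 30.0, rtol=1e-6)

    def test_short_centerline_warns_unsmoothed(self):
        from fulm.vessels import longitudinal_profile

        rest = self._rect_vessel_maps(20.0, [40, 41])
        centerline = np.array([(z, 40) for z in range(40, 44)])
        with pytest.warns(UserWarning, match="unsmoothed"):
            df = longitudinal_profile(rest, rest, centerline, depth_smooth_um=200.0)
        assert len(df) == 4


class TestCompartmentTimecourse:
    def test_activated_compartment_shows_flux_increase(self, activated_truth, short_protocol):
        from fulm.maps import accumulate_maps as acc
        from fulm.vessels import compartment_timecourse

        grid = default_coarse_grid(16, 16).super_grid(8)
        ts = activated_truth.to_trackset()
        raster = rasterize_trackset(ts, grid)
        rest, _ = split_rest_stim_maps(raster, grid, short_protocol)
        labels = segment_compartments(rest, vz_min_mm_s=0.5)
        tc_art = compartment_timecourse(
            ts, grid, labels, "penetrating_arteriole", short_protocol, n_splits=3
        )
        tc_ven = compartment_timecourse(ts, grid, labels, "venule", short_protocol, n_splits=3)
        stim = (tc_art.phase_s >= 32) & (tc_art.phase_s < 58)
        art_rise = tc_art.loc[stim, "rel_flux"].mean()
        ven_rise = tc_ven.loc[stim, "rel_flux"].mean()
        assert art_rise > 0.2  # activated: ~+50 % plateau
        # the activated compartment rises well above the (noisy, 3-pattern)
        # control compartment
        assert art_rise > ven_rise + 0.2
        base = tc_ven.phase_s < short_protocol.rest_pre
        assert abs(tc_ven.loc[base, "rel_flux"].mean()) < 0.1

    def test_speed_gain_shifts_velocity_histogram(self, activated_truth, short_protocol):
        grid = default_coarse_grid(16, 16).super_grid(8)
        raster = rasterize_trackset(activated_truth.to_trackset(), grid)
        rest, _ = split_rest_stim_maps(raster, grid, short_protocol)
        labels = segment_compartments(rest, vz_min_mm_s=0.5)
        hist, edges, phases = dynamic_velocity_histogram(
            raster, labels, "penetrating_arteriole", short_protocol
        )
        centers = 0.5 * (edges[:-1] + edges[1:])
        w = hist.sum(axis=0)
        mean_v = np.where(w > 0, (hist * centers[:, None]).sum(axis=0) / np.maximum(w, 1e-12), np.nan)
        stim = (phases >= 34) & (phases < 58)
        base = phases < 28
        # speed_gain 1.2 during stimulation: phase-wise mean speed rises
        assert np.nanmean(mean_v[stim]) > 1.1 * np.nanmean(mean_v[base])
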