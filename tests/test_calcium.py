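"""Kymograph extraction, ΔF/F0, transient detection and per-site read-outs."""

import numpy as np
import pytest

from synaptodev import (
    CalciumSimParams,
    DFFKymograph,
    Kymograph,
    LineROI,
    SynapticSite,
    TransientEvent,
    average_site_transients,
    compute_dff,
    detect_transients,
    diffusion_distance,
    extract_kymograph,
    gen_calcium_movie,
    identify_sites,
    site_auc,
    split_before_after,
    synchrony,
    transient_frequency,
)
from synaptodev.calcium import SiteProfile
from synaptodev.exceptions import BaselineError, GeometryError, ParameterError

PX = 10.0 / 65.0


def _dff(matrix: np.ndarray) -> DFFKymograph:
    """Wrap a bare ΔF/F0 matrix for functions that take a DFFKymograph."""
    m = np.asarray(matrix, dtype=float)
    return DFFKymograph(dff=m, f0=np.ones(m.shape[1]), baseline_frames=None)


class TestExtractKymograph:
    def test_uniform_movie_gives_constant_kymograph(self):
        movie = np.full((4, 30, 40), 7.5)
        roi = LineROI([(5.0, 15.0), (34.0, 15.0)], width_px=5)
        kymo = extract_kymograph(movie, roi)
        np.testing.assert_allclose(kymo.values, 7.5)

    def test_width_one_horizontal_line_equals_raster_row(self):
        rng = np.random.default_rng(0)
        movie = rng.random((3, 20, 50))
        roi = LineROI([(0.0, 8.0), (49.0, 8.0)], width_px=1)
        kymo = extract_kymograph(movie, roi)
        np.testing.assert_array_equal(kymo.values, movie[:, 8, :])

    def test_width_three_perpendicular_mean(self):
        movie = np.zeros((1, 9, 20))
        movie[0, 3, :] = 1.0
        movie[0, 4, :] = 2.0
        movie[0, 5, :] = 3.0
        roi = LineROI([(2.0, 4.0), (17.0, 4.0)], width_px=3)
        kymo = extract_kymograph(movie, roi)
        np.testing.assert_allclose(kymo.values, 2.0)

    def test_roi_outside_image_is_geometry_error(self):
        movie = np.zeros((2, 10, 10))
        with pytest.raises(GeometryError):
            extract_kymograph(movie, LineROI([(0.0, 5.0), (20.0, 5.0)], width_px=1))

    def test_empty_frame_range_rejected(self):
        movie = np.zeros((5, 10, 10))
        roi = LineROI([(1.0, 5.0), (8.0, 5.0)], width_px=1)
        with pytest.raises(ParameterError):
            extract_kymograph(movie, roi, frame_range=(3, 3))


class TestComputeDff:
    def test_static_movie_gives_zero_dff(self):
        kymo = Kymograph(np.full((20, 10), 50.0))
        dff = compute_dff(kymo)
        np.testing.assert_allclose(dff.dff, 0.0)

    def test_doubling_gives_dff_of_one(self):
        values = np.full((20, 10), 50.0)
        values[10, 4] = 100.0
        dff = compute_dff(Kymograph(values), baseline=np.arange(5))
        assert dff.dff[10, 4] == pytest.approx(1.0)

    def test_recovers_generator_amplitude(self):
        # seed chosen so events at each site are separated by > 6 decay
        # constants; overlapping tails would stack above the single-event peak
        p = CalciumSimParams(n_frames=400, transient_rate=4.0, amplitude=1.5,
                             noise_sd=0.0, n_sites=2, seed=3)
        movie, roi, truth = gen_calcium_movie(p)
        kymo = extract_kymograph(movie, roi)
        dff = compute_dff(kymo)
        sites = truth.latent["site_positions"]
        peaks = [dff.dff[:, s].max() for s in sites]
        for pk in peaks:
            assert pk == pytest.approx(1.5, rel=0.02)

    def test_nonpositive_baseline_is_error(self):
        with pytest.raises(BaselineError):
            compute_dff(Kymograph(np.zeros((10, 5))))


class TestIdentifySites:
    def test_flat_dff_gives_no_sites(self):
        assert identify_sites(_dff(np.zeros((50, 100)))) == []

    def test_two_separated_bumps(self):
        m = np.zeros((50, 100))
        x = np.arange(100)
        m[10] = np.exp(-((x - 30) ** 2) / 8.0) + np.exp(-((x - 60) ** 2) / 8.0)
        sites = identify_sites(_dff(m), min_separation=10)
        assert [s.center for s in sites] == [30, 60]

    def test_recovers_generator_site_centers(self):
        p = CalciumSimParams(n_frames=300, transient_rate=8.0, noise_sd=0.0,
                             n_sites=3, seed=2)
        movie, roi, truth = gen_calcium_movie(p)
        dff = compute_dff(extract_kymograph(movie, roi))
        sites = identify_sites(dff, min_separation=20)
        found = sorted(s.center for s in sites)
        np.testing.assert_allclose(found, truth.latent["site_positions"], atol=1)


class TestDetectTransients:
    def test_zero_trace_no_events(self):
        site = SynapticSite(center=5, halfwidth=2, id=0)
        assert detect_transients(_dff(np.zeros((100, 11))), site) == []

    def test_rectangular_pulse_edges(self):
        m = np.zeros((60, 11))
        m[20:25, 5] = 1.0  # 5-frame pulse
        site = SynapticSite(center=5, halfwidth=2, id=0)
        events = detect_transients(_dff(m), site, k_sd=3.0, min_frames=3)
        assert len(events) == 1
        assert (events[0].onset, events[0].offset) == (20, 24)
        assert events[0].peak_dff == pytest.approx(1.0)

    def test_short_blips_below_min_frames_ignored(self):
        m = np.zeros((60, 11))
        m[20, 5] = 1.0
        site = SynapticSite(center=5, halfwidth=2, id=0)
        assert detect_transients(_dff(m), site, min_frames=2) == []


class TestSiteProfilesAndMetrics:
    def test_single_event_profile_is_peak_frame_profile(self):
        m = np.zeros((30, 20))
        m[10] = np.linspace(0, 1, 20)
        ev = TransientEvent(site_id=0, onset=9, offset=11, peak_frame=10, peak_dff=1.0)
        prof = average_site_transients(_dff(m), [ev])
        np.testing.assert_array_equal(prof.profile, m[10])

    def test_mean_of_p_and_3p_is_2p(self):
        base = np.exp(-((np.arange(40) - 20.0) ** 2) / 18.0)
        m = np.zeros((30, 40))
        m[5] = base
        m[15] = 3 * base
        evs = [
            TransientEvent(0, 4, 6, 5, 1.0),
            TransientEvent(0, 14, 16, 15, 3.0),
        ]
        prof = average_site_transients(_dff(m), evs)
        np.testing.assert_allclose(prof.profile, 2 * base)

    def test_auc_zero_profile(self):
        prof = SiteProfile(np.zeros(50), n_events=1, peak_position=0)
        assert site_auc(prof) == 0.0

    def test_auc_rectangular_plateau(self):
        profile = np.zeros(30)
        profile[10:20] = 1.0  # 10-px plateau
        prof = SiteProfile(profile, n_events=1, peak_position=12)
        assert site_auc(prof, baseline_level=0.0) == pytest.approx(10.0)

    def test_auc_gaussian_closed_form(self):
        x = np.arange(2000, dtype=float)
        a, sigma = 0.8, 60.0
        prof = SiteProfile(a * np.exp(-((x - 1000) ** 2) / (2 * sigma**2)), 1, 1000)
        assert site_auc(prof) == pytest.approx(a * sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_diffusion_distance_single_pixel(self):
        profile = np.zeros(21)
        profile[10] = 1.0
        prof = SiteProfile(profile, 1, 10)
        assert diffusion_distance(prof) == pytest.approx(10.0 / 65.0)

    def test_diffusion_distance_65px_is_10um(self):
        profile = np.zeros(100)
        profile[10:75] = 1.0  # 65 px above threshold
        prof = SiteProfile(profile, 1, 40)
        assert diffusion_distance(prof) == pytest.approx(10.0)

    def test_diffusion_distance_gaussian_fwhm(self):
        x = np.arange(200, dtype=float)
        prof = SiteProfile(np.exp(-((x - 100) ** 2) / (2 * 25.0)), 1, 100)
        got_px = diffusion_distance(prof, px_size=1.0, fraction=0.5)
        assert got_px == pytest.approx(2.355 * 5.0, abs=1.0)

    def test_diffusion_monotone_in_profile_width(self):
        x = np.arange(400, dtype=float)
        widths = []
        for sigma in (2.0, 6.0, 20.0):
            prof = SiteProfile(np.exp(-((x - 200) ** 2) / (2 * sigma**2)), 1, 200)
            widths.append(diffusion_distance(prof))
        assert widths[0] < widths[1] < widths[2]

    def test_frequency_normalization(self):
        evs = [TransientEvent(0, i, i + 1, i, 1.0) for i in range(10)]
        assert transient_frequency(evs, 1000) == pytest.approx(5.0)
        assert transient_frequency([], 1000) == 0.0


class TestSynchrony:
    def test_identical_traces_give_unity(self):
        t = np.sin(np.linspace(0, 20, 500))
        m = np.tile(t[:, None], (1, 10))
        sites = [SynapticSite(center=i, halfwidth=1, id=i) for i in range(10)]
        res = synchrony(_dff(m), sites, frame_window=(0, 500))
        for v in res["per_site"].values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_inverted_pair_gives_minus_one(self):
        t = np.sin(np.linspace(0, 20, 500))
        m = np.stack([t, -t], axis=1)
        sites = [SynapticSite(0, 1, 0), SynapticSite(1, 1, 1)]
        res = synchrony(_dff(m), sites, frame_window=(0, 500))
        for v in res["per_site"].values():
            assert v == pytest.approx(-1.0, abs=1e-9)

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(123)
        m = rng.normal(size=(500, 20))
        sites = [SynapticSite(i, 1, i) for i in range(20)]
        res = synchrony(_dff(m), sites, frame_window=(0, 500), seed=0)
        assert all(abs(v) < 0.1 for v in res["per_site"].values())

    def test_constant_trace_dropped_with_warning(self):
        t = np.sin(np.linspace(0, 20, 500))
        m = np.stack([t, np.zeros(500), t], axis=1)
        sites = [SynapticSite(i, 1, i) for i in range(3)]
        with pytest.warns(UserWarning, match="constant"):
            res = synchrony(_dff(m), sites, frame_window=(0, 500))
        assert set(res["per_site"]) == {0, 2}


class TestSplitBeforeAfter:
    def test_all_before(self):
        evs = [TransientEvent(0, i, i + 2, i + 1, 1.0) for i in range(0, 50, 10)]
        before, after = split_before_after(evs, 100)
        assert len(before) == 5 and after == []

    def test_boundary_at_zero(self):
        evs = [TransientEvent(0, 5, 8, 6, 1.0)]
        before, after = split_before_after(evs, 0)
        assert before == [] and len(after) == 1

    def test_partition_counts_match_hand_count(self):
        rng = np.random.default_rng(4)
        peaks = rng.integers(0, 200, size=30)
        evs = [TransientEvent(0, int(p), int(p) + 2, int(p) + 1, 1.0) for p in peaks]
        before, after = split_before_after(evs, 100)
        assert len(before) == int((peaks + 1 < 100).sum())
        assert len(before) + len(after) == 30

    def test_spanning_event_flagged(self):
        evs = [TransientEvent(0, 98, 105, 99, 1.0)]
        with pytest.warns(UserWarning, match="spans"):
            before, after = split_before_after(evs, 100)
        assert len(before) == 1
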