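import numpy as np
import pytest
from skimage.restoration import richardson_lucy as skimage_rl

from fluorkit.synth import gen_movie
from fluorkit.twophoton import (BinarizedMovie, ImagingMovie,
                                MostActiveWindow, RoiSet, binarize_window,
                                find_most_active_minute,
                                first_last_minute_delta, fov_dff_trace,
                                gaussian_psf, identify_rois,
                                richardson_lucy_stack,
                                roi_correlation_analysis,
                                smooth_and_deconvolve)

SMALL_MOVIE_KW = dict(shape=(128, 128), duration=210.0,
                      anesthesia_off_s=30.0, frame_rate=4.9,
                      ramp_center_s=150.0, ramp_width_s=8.0,
                      hot_window=(60.0, 120.0), n_hotspots=12,
                      hotspot_sigma_px=6.0, n_vessels=1,
                      vessel_radius_px=7.0)
SEARCH_KW = dict(search_start_s=45.0, search_end_s=165.0)


def flat_movie(value=3.0, t=40, h=8, w=8, fr=0.1):
    return ImagingMovie(frames=np.full((t, h, w), value), frame_rate=fr)


class TestFovDff:
    def test_constant_movie_zero(self):
        dff = fov_dff_trace(flat_movie())
        assert np.allclose(dff.values, 0.0)

    def test_median_baseline_arithmetic(self):
        # first-minute frame means {1, 1, 2}: median 1; later mean 1.5
        frames = np.stack([np.full((4, 4), v)
                           for v in (1.0, 1.0, 2.0, 1.5, 1.5)])
        movie = ImagingMovie(frames=frames, frame_rate=0.05)  # 3 frames/min
        dff = fov_dff_trace(movie)
        assert dff.baseline_value == pytest.approx(1.0)
        assert dff.values[-1] == pytest.approx(0.5)

    def test_ramp_raises_late_dff(self):
        t = np.linspace(1.0, 2.0, 40)
        frames = t[:, None, None] * np.ones((40, 6, 6))
        movie = ImagingMovie(frames=frames, frame_rate=0.1)
        dff = fov_dff_trace(movie)
        n = 6
        assert dff.values[-n:].mean() > dff.values[:n].mean()

    def test_short_movie_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            fov_dff_trace(flat_movie(t=3))


class TestFirstLastMinuteDelta:
    def test_flat_zero(self):
        assert first_last_minute_delta(fov_dff_trace(flat_movie())) == 0.0

    def test_step_recovered(self):
        frames = np.ones((40, 4, 4))
        frames[20:] *= 1.3
        movie = ImagingMovie(frames=frames, frame_rate=0.1)
        delta = first_last_minute_delta(fov_dff_trace(movie))
        assert delta == pytest.approx(0.3, rel=1e-6)

    def test_generator_ramp_recovered(self):
        movie, truth = gen_movie(5, **SMALL_MOVIE_KW)
        delta = first_last_minute_delta(fov_dff_trace(movie))
        assert delta == pytest.approx(truth["ramp_amplitude"], abs=0.05)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            first_last_minute_delta(fov_dff_trace(flat_movie(t=8)))


class TestMostActiveMinute:
    def test_constant_movie_earliest_window(self):
        movie = flat_movie(t=40)
        win = find_most_active_minute(movie, 60.0, 400.0)
        assert win.start_frame == 6
        assert win.n_frames == 6

    def test_contrast_burst_selected(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(10.0, 1.0, size=(40, 8, 8))
        frames[24:30] += rng.normal(0.0, 6.0, size=(6, 8, 8))
        movie = ImagingMovie(frames=np.maximum(frames, 0),
                             frame_rate=0.1)
        win = find_most_active_minute(movie, 60.0, 400.0)
        assert 19 <= win.start_frame <= 29

    def test_search_exactly_one_minute(self):
        movie = flat_movie(t=40)
        win = find_most_active_minute(movie, 100.0, 160.0)
        assert win.start_frame == 10

    def test_short_search_raises(self):
        with pytest.raises(ValueError, match="minute"):
            find_most_active_minute(flat_movie(t=40), 100.0, 130.0)

    def test_hot_window_found_in_generator_movie(self):
        movie, truth = gen_movie(8, **SMALL_MOVIE_KW)
        win = find_most_active_minute(movie, **SEARCH_KW)
        t_start = win.start_frame / movie.frame_rate
        lo, hi = truth["hot_window"]
        assert lo - 15.0 <= t_start <= hi


class TestBinarize:
    def test_constant_movie_all_zero(self):
        movie = flat_movie()
        win = MostActiveWindow(start_frame=0, n_frames=40,
                               mean_spatial_sd=0.0)
        assert not binarize_window(movie, win).frames.any()

    def test_hand_arithmetic_single_pixel(self):
        # {1,1,1,1,10}: median 1, sample s.d. 4.0249, threshold 5.0249
        vals = np.array([1.0, 1.0, 1.0, 1.0, 10.0])
        movie = ImagingMovie(frames=vals[:, None, None],
                             frame_rate=1.0)
        win = MostActiveWindow(0, 5, 0.0)
        b = binarize_window(movie, win).frames[:, 0, 0]
        assert np.array_equal(b, [0, 0, 0, 0, 1])

    def test_matches_bruteforce_loop(self, rng):
        frames = rng.uniform(0, 100, size=(30, 6, 6))
        movie = ImagingMovie(frames=frames, frame_rate=1.0)
        win = MostActiveWindow(4, 20, 0.0)
        b = binarize_window(movie, win).frames
        for i in range(6):
            for j in range(6):
                px = frames[4:24, i, j]
                thr = np.median(px) + np.std(px, ddof=1)
                assert np.array_equal(b[:, i, j], (px > thr).astype(int))

    @pytest.mark.parametrize("a,b_off", [(2.0, 10.0), (0.3, -1.0)])
    def test_affine_intensity_invariance(self, rng, a, b_off):
        frames = rng.uniform(10, 100, size=(25, 8, 8))
        win = MostActiveWindow(0, 25, 0.0)
        m1 = ImagingMovie(frames=frames, frame_rate=1.0)
        m2 = ImagingMovie(frames=np.maximum(a * frames + b_off, 0.0),
                          frame_rate=1.0)
        assert np.array_equal(binarize_window(m1, win).frames,
                              binarize_window(m2, win).frames)


class TestDeconvolution:
    def test_zero_input_zero_output(self):
        out = richardson_lucy_stack(np.zeros((3, 50, 50)), gaussian_psf())
        assert np.allclose(out, 0.0)

    def test_uniform_is_fixed_point(self):
        out = richardson_lucy_stack(np.full((2, 60, 60), 0.4),
                                    gaussian_psf(), iterations=1)
        assert np.allclose(out, 0.4, atol=1e-9)

    def test_symmetric_kernel_no_shift(self):
        frame = np.zeros((1, 64, 64))
        frame[0, 30, 33] = 1.0
        from scipy.ndimage import gaussian_filter
        blurred = gaussian_filter(frame, (0, 3, 3))
        dec = richardson_lucy_stack(blurred, gaussian_psf(19, 3.0),
                                    iterations=20)
        peak = np.unravel_index(np.argmax(dec[0]), dec[0].shape)
        assert peak == (30, 33)

    def test_matches_skimage_in_interior(self, rng):
        # boundary conditions differ (reflective vs zero padding), and
        # their influence travels ~ iterations x kernel half-width, so
        # compare deep interior pixels only
        obs = rng.uniform(0.05, 1.0, size=(2, 96, 96))
        psf = gaussian_psf(11, 2.0)
        ours = richardson_lucy_stack(obs, psf, iterations=5)
        ref = np.stack([skimage_rl(o, psf, num_iter=5, clip=False)
                        for o in obs])
        m = 32
        assert np.allclose(ours[:, m:-m, m:-m], ref[:, m:-m, m:-m],
                           rtol=1e-3, atol=1e-4)

    def test_kernel_larger_than_frame_raises(self):
        with pytest.raises(ValueError, match="PSF"):
            richardson_lucy_stack(np.ones((1, 20, 20)), gaussian_psf())

    def test_smoothed_values_bounded(self):
        b = BinarizedMovie(frames=np.random.default_rng(0).integers(
            0, 2, size=(10, 50, 50)).astype(np.uint8), window=(0, 10))
        dec, proj = smooth_and_deconvolve(b)
        assert proj.shape == (50, 50)
        assert np.all(dec >= 0.0)


class TestIdentifyRois:
    def blob_projection(self, n_blobs=12, h=160, w=160, seed=0):
        rng = np.random.default_rng(seed)
        rr, cc = np.mgrid[0:h, 0:w]
        proj = np.full((h, w), 0.1) + rng.normal(0, 0.002, size=(h, w))
        peaks = []
        k = 0
        while len(peaks) < n_blobs:
            r0, c0 = rng.integers(15, h - 15, size=2)
            if any((r0 - r) ** 2 + (c0 - c) ** 2 < 28 ** 2
                   for r, c in peaks):
                k += 1
                assert k < 10000
                continue
            peaks.append((r0, c0))
            amp = 0.2 + 0.01 * len(peaks)
            proj += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                                 / (2 * 8.0 ** 2))
        return proj, peaks

    def test_active_rois_on_brightest_blobs(self):
        proj, peaks = self.blob_projection()
        roiset = identify_rois([proj])[0]
        active = [r for r in roiset.rois if r.roi_class == "active"]
        assert len(active) == 10
        # the ten brightest blobs (highest amplitude = last placed)
        brightest = peaks[2:]
        hits = 0
        for r in active:
            if any(abs(r.center[0] - p[0]) < 10
                   and abs(r.center[1] - p[1]) < 10 for p in brightest):
                hits += 1
        assert hits >= 8

    def test_total_count_twenty(self):
        proj, _ = self.blob_projection()
        roiset = identify_rois([proj])[0]
        assert len(roiset.rois) == 20
        assert len(roiset.by_class("active")) == 10
        assert len(roiset.by_class("inactive")) == 10

    def test_vessel_stripe_never_in_roi(self):
        proj, _ = self.blob_projection()
        proj[:, 60:66] = 0.0  # zero-valued vessel stripe, below p5
        roiset = identify_rois([proj])[0]
        for r in roiset.rois:
            assert not np.any((r.pixels[:, 1] >= 60)
                              & (r.pixels[:, 1] < 66))

    def test_rois_disjoint_and_in_band(self):
        proj, _ = self.blob_projection(seed=3)
        roiset = identify_rois([proj])[0]
        taken = np.zeros(proj.shape, dtype=bool)
        p5, p69, p70 = np.percentile(proj, [5.0, 69.0, 70.0])
        for r in roiset.rois:
            vals = proj[r.pixels[:, 0], r.pixels[:, 1]]
            if r.roi_class == "active":
                assert np.all(vals >= p70)
            else:
                assert np.all((vals >= p5) & (vals < p69))
            assert not taken[r.pixels[:, 0], r.pixels[:, 1]].any()
            taken[r.pixels[:, 0], r.pixels[:, 1]] = True

    def test_diameter_spans_12_pixels(self):
        proj, _ = self.blob_projection()
        roi = identify_rois([proj])[0].rois[0]
        rows = roi.pixels[:, 0]
        cols = roi.pixels[:, 1]
        assert rows.max() - rows.min() + 1 == 12
        assert cols.max() - cols.min() + 1 == 12

    def test_insufficient_area_warns(self):
        proj = np.zeros((40, 40))
        proj[:20, :20] = np.random.default_rng(0).uniform(1, 2, (20, 20))
        with pytest.warns(UserWarning, match="ROIs"):
            roiset = identify_rois([proj])[0]
        assert len(roiset.rois) < 20

    def test_pooled_percentiles_across_fovs(self):
        # bands come from the pooled distribution: a dim FOV next to a
        # bright FOV gets few/no active ROIs
        dim = np.full((100, 100), 0.1)
        bright, _ = self.blob_projection(seed=4, n_blobs=6, h=120, w=120)
        bright += 1.0
        with pytest.warns(UserWarning):
            roisets = identify_rois([dim, bright])
        assert len(roisets[0].by_class("active")) == 0
        assert len(roisets[1].by_class("active")) == 10


class TestRoiCorrelations:
    def make_roiset_with_traces(self, traces, classes):
        rois = []
        for i, c in enumerate(classes):
            rois.append(type("R", (), {
                "roi_class": c, "center": (i, i), "radius_px": 6.0,
                "pixels": np.array([[i, i]])})())
        rs = RoiSet(rois=rois, percentile_bands={})
        rs.traces = np.asarray(traces, dtype=float)
        return rs

    def test_identical_traces_r_one(self):
        t = np.sin(np.linspace(0, 10, 200))
        rs = self.make_roiset_with_traces([t, t], ["active", "active"])
        corr = roi_correlation_analysis(rs)
        assert corr.matrix[0, 1] == pytest.approx(1.0)
        assert corr.mean_active_r == pytest.approx(1.0)

    def test_shared_latent_beats_noise(self, rng):
        latent = rng.normal(size=300).cumsum()
        active = [latent + rng.normal(0, 1.0, 300) for _ in range(5)]
        inactive = [rng.normal(0, 3.0, 300) for _ in range(5)]
        rs = self.make_roiset_with_traces(active + inactive,
                                          ["active"] * 5 + ["inactive"] * 5)
        corr = roi_correlation_analysis(rs)
        assert corr.mean_active_r > corr.mean_inactive_r

    def test_constant_trace_pairs_nan_and_excluded(self, rng):
        traces = [rng.normal(size=100), np.full(100, 2.0),
                  rng.normal(size=100)]
        rs = self.make_roiset_with_traces(traces, ["active"] * 3)
        corr = roi_correlation_analysis(rs)
        assert np.isnan(corr.matrix[0, 1])
        assert np.isfinite(corr.mean_active_r)

    def test_shuffled_traces_null(self, rng):
        means = []
        base = rng.normal(size=(6, 250))
        for _ in range(100):
            shuffled = np.stack([row[rng.permutation(250)] for row in base])
            rs = self.make_roiset_with_traces(shuffled, ["active"] * 6)
            means.append(roi_correlation_analysis(rs).mean_active_r)
        assert abs(np.mean(means)) < 0.02

    def test_matrix_properties(self, rng):
        rs = self.make_roiset_with_traces(rng.normal(size=(8, 120)),
                                          ["active"] * 4 + ["inactive"] * 4)
        corr = roi_correlation_analysis(rs)
        m = corr.matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert np.nanmax(np.abs(m)) <= 1.0 + 1e-12


class TestEndToEnd:
    def test_hotspot_movie_pipeline(self):
        movie, truth = gen_movie(42, **SMALL_MOVIE_KW)
        win = find_most_active_minute(movie, **SEARCH_KW)
        binarized = binarize_window(movie, win)
        _, proj = smooth_and_deconvolve(binarized)
        roiset = identify_rois([proj])[0]
        assert len(roiset.rois) == 20
        corr = roi_correlation_analysis(roiset, movie, win)
        assert corr.mean_active_r > corr.mean_inactive_r
        hits = sum(
            1 for r in roiset.rois if r.roi_class == "active"
            and truth["hotspot_mask"][r.pixels[:, 0], r.pixels[:, 1]].mean()
            > 0.5)
        assert hits >= 8
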