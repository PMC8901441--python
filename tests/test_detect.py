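"""Spot detection, Gaussian fitting and quality filters."""

import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from smstoich import (
    ImageStack,
    ParticleFit,
    SimConfig,
    analyze_image,
    detect_spots,
    filter_particles,
    fit_particle,
    generate_particle_field,
    max_z_project,
)
from smstoich.detect import fits_to_frame

from conftest import render_gaussian


class TestMaxProjection:
    def test_matches_bruteforce_max(self, rng):
        stack = ImageStack(rng.poisson(50, (8, 30, 30)).astype(float))
        proj, argmax = max_z_project(stack)
        # brute-force oracle: per-pixel loop over planes
        for r in range(30):
            for c in range(0, 30, 7):
                vals = stack.data[:, r, c]
                assert proj[r, c] == vals.max()
                assert argmax[r, c] == int(np.argmax(vals))

    def test_ties_resolve_to_lowest_plane(self):
        stack = ImageStack(np.ones((4, 5, 5)))
        _, argmax = max_z_project(stack)
        assert np.all(argmax == 0)

    def test_single_bright_plane_wins(self):
        data = np.ones((3, 6, 6))
        data[1] = 9.0
        proj, argmax = max_z_project(ImageStack(data))
        assert np.all(proj == 9.0)
        assert np.all(argmax == 1)

    def test_single_plane_identity_with_warning(self):
        stack = ImageStack(np.ones((1, 5, 5)))
        with pytest.warns(UserWarning, match="single-plane"):
            proj, _ = max_z_project(stack)
        assert np.array_equal(proj, stack.data[0])


class TestDetectSpots:
    def test_blank_image_at_5sigma_yields_nothing(self, rng):
        blank = rng.poisson(100, (150, 150)).astype(float)
        assert detect_spots(blank, threshold_sd=5.0).size == 0

    def test_single_spot_detected_within_one_pixel(self, rng):
        noise_sd = 10.0
        img = render_gaussian((60, 60), 30.4, 25.7, 10 * noise_sd, 1.3, background=100.0)
        img = rng.poisson(img).astype(float)
        peaks = detect_spots(img, threshold_sd=5.0)
        assert len(peaks) == 1
        assert np.hypot(peaks[0, 0] - 30.4, peaks[0, 1] - 25.7) <= 1.0

    def test_two_separated_spots_both_found(self, rng):
        img = render_gaussian((60, 60), 20.0, 20.0, 120.0, 1.3, background=100.0)
        img += render_gaussian((60, 60), 20.0, 30.0, 120.0, 1.3)
        img = rng.poisson(img).astype(float)
        peaks = detect_spots(img, threshold_sd=5.0)
        assert len(peaks) == 2

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((10, 10)), dog_sigma_small=2.0, dog_sigma_large=1.0)


class TestFitParticle:
    def test_noiseless_parameter_recovery(self):
        img = render_gaussian((21, 21), 10.2, 9.8, 500.0, 1.3, background=100.0)
        fit = fit_particle(img, (10, 10))
        assert fit.amplitude == pytest.approx(500.0, rel=0.01)
        assert fit.sigma == pytest.approx(1.3, rel=0.01)
        assert fit.row == pytest.approx(10.2, abs=0.02)
        assert fit.col == pytest.approx(9.8, abs=0.02)
        expected_ip = 2 * np.pi * 500.0 * 1.3**2
        assert fit.brightness == pytest.approx(expected_ip, rel=0.02)
        assert fit.retained

    def test_flat_image_fits_to_zero_brightness(self):
        fit = fit_particle(np.full((21, 21), 80.0), (10, 10))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)
        assert fit.brightness == pytest.approx(0.0, abs=1e-3)

    def test_brightness_agrees_with_pixel_sum_oracle(self):
        # background-subtracted pixel sum over the ROI vs fitted volume
        img = render_gaussian((21, 21), 10.0, 10.0, 400.0, 1.1, background=50.0)
        fit = fit_particle(img, (10, 10))
        rr, cc = np.mgrid[0:21, 0:21].astype(float)
        disc = (rr - 10) ** 2 + (cc - 10) ** 2 <= 3**2
        pixel_sum = (img - 50.0)[disc].sum()
        # the fitted volume integrates the tails beyond the 3-px ROI; a
        # sigma=1.1 Gaussian holds ~97% of its volume inside 3 px
        assert fit.brightness == pytest.approx(pixel_sum, rel=0.05)

    def test_roi_outside_image_flags_fit_fail(self):
        fit = fit_particle(np.ones((21, 21)), (2, 2))
        assert "fit_fail" in fit.qc_flags

    def test_brightness_linearity(self, rng):
        # doubling true brightness doubles median fitted Ip within 2%
        def field(scale, seed):
            cfg = SimConfig(
                n_particles=40,
                monomer_intensity=400.0 * scale,
                monomer_cv=0.0,
                labeling_efficiency=1.0,
                min_separation_px=12.0,
                shot_noise=False,
                read_noise_sd=1.0,
                seed=seed,
            )
            stack, _ = generate_particle_field(cfg)
            fits, _ = analyze_image(stack.data[0])
            return np.median([f.brightness for f in fits])

        m1 = field(1.0, 5)
        m2 = field(2.0, 5)
        assert m2 / m1 == pytest.approx(2.0, rel=0.02)


def _make_fits(sigmas, spacing=20.0):
    return [
        ParticleFit(row=spacing * (i % 40), col=spacing * (i // 40), sigma=float(s))
        for i, s in enumerate(sigmas)
    ]


class TestFilters:
    def test_sigma_percentile_retains_95_percent(self, rng):
        fits = _make_fits(rng.normal(1.3, 0.2, 10_000), spacing=9.0)
        retained, report = filter_particles(fits, min_center_separation_px=7.0)
        frac = sum("sigma_outlier" not in f.qc_flags for f in fits) / len(fits)
        assert frac == pytest.approx(0.95, abs=0.005)

    def test_close_pair_both_flagged(self):
        fits = [
            ParticleFit(row=10.0, col=10.0, sigma=1.3),
            ParticleFit(row=10.0, col=12.0, sigma=1.3),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained, _ = filter_particles(fits, min_center_separation_px=7.0)
        assert retained == []
        assert all("overlap" in f.qc_flags for f in fits)

    def test_edge_plane_particles_discarded(self):
        fits = _make_fits(np.full(30, 1.3))
        fits[0].frame_of_max = 0
        fits[1].frame_of_max = 7
        fits[2].frame_of_max = 3
        filter_particles(fits, n_planes=8)
        assert "edge_frame" in fits[0].qc_flags
        assert "edge_frame" in fits[1].qc_flags
        assert "edge_frame" not in fits[2].qc_flags

    def test_filtering_is_idempotent_and_order_independent(self, rng):
        fits = _make_fits(rng.normal(1.3, 0.2, 200), spacing=9.0)
        fits[0].row, fits[0].col = fits[1].row + 1, fits[1].col
        r1, _ = filter_particles(fits)
        set1 = {id(f) for f in r1}
        r2, _ = filter_particles(fits)
        assert {id(f) for f in r2} == set1

    def test_few_fits_skip_sigma_filter_with_warning(self):
        fits = _make_fits([1.0, 1.1, 5.0])
        with pytest.warns(UserWarning, match="sigma-percentile"):
            retained, _ = filter_particles(fits)
        assert all("sigma_outlier" not in f.qc_flags for f in fits)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_particles([])


class TestEndToEnd:
    def _pr(self, fits, truth, tol=1.5):
        det = np.array([[f.row, f.col] for f in fits])
        tru = truth.loc[truth["visible"], ["row", "col"]].to_numpy()
        d_det, _ = cKDTree(tru).query(det)
        d_tru, _ = cKDTree(det).query(tru)
        return (d_det <= tol).mean(), (d_tru <= tol).mean()

    def test_detection_precision_recall_at_snr5(self):
        noise_sd = np.sqrt(104.0)
        brightness = 5 * noise_sd * 2 * np.pi * 1.3**2
        cfg = SimConfig(
            field_size_px=(200, 200),
            n_particles=400,  # 0.01 spots / px^2
            monomer_intensity=brightness,
            monomer_cv=0.0,
            labeling_efficiency=1.0,
            background_level=100.0,
            read_noise_sd=2.0,
            min_separation_px=5.2,
            seed=17,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, truth = generate_particle_field(cfg)
        centers = detect_spots(stack.data[0])
        det = [ParticleFit(row=r, col=c) for r, c in centers]
        precision, recall = self._pr(det, truth)
        assert precision >= 0.95
        assert recall >= 0.95

    def test_noiseless_pipeline_brightness_error_below_5pct(self):
        cfg = SimConfig(
            n_particles=50,
            monomer_intensity=800.0,
            monomer_cv=0.1,
            labeling_efficiency=1.0,
            shot_noise=False,
            read_noise_sd=0.5,
            min_separation_px=12.0,
            seed=18,
        )
        stack, truth = generate_particle_field(cfg)
        fits, _ = analyze_image(stack.data[0])
        tru = truth[["row", "col"]].to_numpy()
        tree = cKDTree(tru)
        errs = []
        for f in fits:
            d, i = tree.query([f.row, f.col])
            if d < 1.0:
                errs.append(abs(f.brightness - truth["brightness"].iloc[i]) / truth["brightness"].iloc[i])
        assert len(errs) >= 30
        assert np.median(errs) < 0.05

    def test_table_serialization_roundtrip(self):
        fits = [ParticleFit(row=1.0, col=2.0, sigma=1.3, brightness=500.0)]
        fits[0].qc_flags.add("overlap")
        tab = fits_to_frame(fits)
        assert tab.loc[0, "qc_flags"] == "overlap"
        assert tab.loc[0, "brightness"] == 500.0
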