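import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memprobe import synthetic
from memprobe.gp_pipeline import (
    cluster_vesicles,
    delta_gp,
    detect_vesicles,
    eccentricity,
    gp_map,
    gp_value,
    internalization_index,
    membrane_profile,
    otsu_mask,
    vesicle_gp_stats,
)
from memprobe.image_model import SpectralImage


class TestGPValue:
    @pytest.mark.parametrize(
        "ib, ir, expected",
        [(100, 100, 0.0), (100, 0, 1.0), (0, 100, -1.0), (3, 1, 0.5)],
    )
    def test_examples(self, ib, ir, expected):
        assert gp_value(ib, ir) == pytest.approx(expected)

    def test_zero_sum_is_undefined(self):
        assert math.isnan(gp_value(0, 0))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            gp_value(-1, 5)

    @given(
        ib=st.floats(0, 1e6),
        ir=st.floats(0, 1e6),
    )
    @settings(derandomize=True, max_examples=200)
    def test_bounded(self, ib, ir):
        gp = gp_value(ib, ir)
        assert math.isnan(gp) or -1.0 <= gp <= 1.0

    @given(
        ib=st.floats(0.1, 1e4),
        ir=st.floats(0.1, 1e4),
        scale=st.floats(0.01, 100),
    )
    @settings(derandomize=True, max_examples=200)
    def test_scale_invariant(self, ib, ir, scale):
        assert gp_value(scale * ib, scale * ir) == pytest.approx(gp_value(ib, ir))

    def test_strictly_decreasing_in_red_intensity(self):
        vals = [gp_value(10.0, ir) for ir in np.linspace(0, 50, 25)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestGPMap:
    def make_two_channel(self, plane_b, plane_r, lo=557.0, ld=664.0):
        # pad planes into an NR-style 22-channel stack
        centers = np.linspace(503, 700, 22)
        data = np.zeros((22, *np.shape(plane_b)))
        i_b = int(np.argmin(np.abs(centers - lo)))
        i_r = int(np.argmin(np.abs(centers - ld)))
        data[i_b] = plane_b
        data[i_r] = plane_r
        return SpectralImage(data, centers)

    def test_uniform_planes_give_zero(self, nr_config):
        img = self.make_two_channel(np.full((4, 4), 10.0), np.full((4, 4), 10.0))
        gm = gp_map(img, nr_config)
        assert np.all(gm.defined_mask)
        np.testing.assert_allclose(gm.values, 0.0)

    def test_ratio_two_to_one(self, nr_config):
        plane_r = np.full((3, 3), 7.0)
        gm = gp_map(self.make_two_channel(2 * plane_r, plane_r), nr_config)
        np.testing.assert_allclose(gm.values, 1 / 3)

    def test_undefined_where_dark(self, nr_config):
        plane = np.zeros((2, 2))
        plane[0, 0] = 5.0
        gm = gp_map(self.make_two_channel(plane, np.zeros((2, 2))), nr_config)
        assert gm.defined_mask[0, 0]
        assert not gm.defined_mask[1, 1]


class TestOtsu:
    def test_bimodal_ring(self):
        rng = np.random.default_rng(0)
        field = rng.normal(10, 1, (100, 100))
        ring = np.zeros((100, 100), dtype=bool)
        yy, xx = np.mgrid[0:100, 0:100]
        ring[np.abs(np.hypot(yy - 50, xx - 50) - 30) < 3] = True
        field[ring] = rng.normal(200, 5, ring.sum())
        mask = otsu_mask(field)
        false_pos = (mask & ~ring).sum() / (~ring).sum()
        assert false_pos < 0.01
        assert (mask & ring).sum() / ring.sum() > 0.99

    def test_two_level_field(self):
        field = np.zeros((10, 10))
        field[5:, :] = 255.0
        mask = otsu_mask(field)
        assert mask.sum() == 50
        assert np.all(mask[5:, :])

    def test_constant_field_rejected(self):
        with pytest.raises(ValueError):
            otsu_mask(np.full((5, 5), 3.0))

    def test_matches_brute_force_between_class_variance(self):
        """The Otsu threshold attains the exhaustive maximum of between-class
        variance on the same 256-bin histogram (maximizers can tie across
        empty bins between the modes, so the objective is compared)."""
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(42)
        for _ in range(20):
            field = np.concatenate(
                [
                    rng.normal(rng.uniform(5, 50), rng.uniform(1, 10), 500),
                    rng.normal(rng.uniform(100, 250), rng.uniform(1, 20), 500),
                ]
            ).reshape(50, 20)
            thr = threshold_otsu(field, nbins=256)
            hist, edges = np.histogram(field.ravel(), bins=256)
            centers = 0.5 * (edges[:-1] + edges[1:])
            p = hist / hist.sum()

            def objective(threshold):
                sel = centers <= threshold
                w0, w1 = p[sel].sum(), p[~sel].sum()
                if w0 <= 0 or w1 <= 0:
                    return 0.0
                mu0 = (p[sel] * centers[sel]).sum() / w0
                mu1 = (p[~sel] * centers[~sel]).sum() / w1
                return w0 * w1 * (mu0 - mu1) ** 2

            best = max(objective(c) for c in centers[:-1])
            assert objective(thr) == pytest.approx(best, rel=1e-10)
            # and the module mask is exactly the thresholded field
            np.testing.assert_array_equal(otsu_mask(field), field > thr)


class TestClustering:
    @staticmethod
    def ring_mask(shape, center, radius, thickness=3):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return np.abs(np.hypot(yy - center[0], xx - center[1]) - radius) < thickness / 2

    def test_two_separated_rings(self):
        mask = self.ring_mask((120, 120), (30, 30), 18) | self.ring_mask(
            (120, 120), (85, 85), 18
        )
        clusters = cluster_vesicles(mask, eps=3, min_samples=8)
        assert len(clusters) == 2

    def test_single_ring_keeps_all_pixels(self):
        mask = self.ring_mask((80, 80), (40, 40), 20)
        clusters = cluster_vesicles(mask)
        assert len(clusters) == 1
        assert len(clusters[0]) == mask.sum()

    def test_empty_mask_yields_no_objects(self):
        assert cluster_vesicles(np.zeros((10, 10), dtype=bool)) == []

    def test_agrees_with_connected_components_for_solid_objects(self):
        """For solid, well-separated objects DBSCAN reproduces plain
        connected-component labeling."""
        from scipy.ndimage import label

        mask = np.zeros((100, 100), dtype=bool)
        mask[10:30, 10:30] = True
        mask[60:80, 50:90] = True
        mask[40:45, 5:9] = True
        clusters = cluster_vesicles(mask, eps=3, min_samples=8)
        labelled, n = label(mask)
        assert len(clusters) == n
        got = {frozenset(map(tuple, c)) for c in clusters}
        want = {
            frozenset(map(tuple, np.argwhere(labelled == k))) for k in range(1, n + 1)
        }
        assert got == want


class TestEccentricity:
    @staticmethod
    def filled(shape_fn, size=101):
        yy, xx = np.mgrid[0:size, 0:size] - size // 2
        return np.argwhere(shape_fn(yy, xx))

    def test_disc_is_round(self):
        pixels = self.filled(lambda y, x: y**2 + x**2 <= 40**2)
        assert eccentricity(pixels) < 0.1

    def test_two_to_one_ellipse(self):
        # a = 2b: eccentricity sqrt(1 - 1/4) = sqrt(0.75)
        pixels = self.filled(lambda y, x: (x / 40) ** 2 + (y / 20) ** 2 <= 1)
        assert eccentricity(pixels) == pytest.approx(math.sqrt(0.75), abs=0.01)

    def test_cutoff_separates_circle_from_ellipse(self):
        disc = self.filled(lambda y, x: y**2 + x**2 <= 30**2)
        ellipse = self.filled(lambda y, x: (x / 40) ** 2 + (y / 20) ** 2 <= 1)
        assert eccentricity(disc) < 0.5 <= eccentricity(ellipse)

    def test_collinear_degenerates_to_one(self):
        with pytest.warns(UserWarning):
            assert eccentricity([[0, i] for i in range(10)]) == 1.0


class TestVesicleStats:
    def make_gp(self, values):
        from memprobe.gp_pipeline import GPMap

        values = np.asarray(values, dtype=float)
        return GPMap(values, np.isfinite(values))

    def test_constant(self):
        gp = self.make_gp([[0.2, 0.2, 0.2]])
        med, sd = vesicle_gp_stats(gp, [[0, 0], [0, 1], [0, 2]])
        assert med == 0.2
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_median_symmetric(self):
        gp = self.make_gp([[-1.0, 0.0, 1.0]])
        med, _ = vesicle_gp_stats(gp, [[0, 0], [0, 1], [0, 2]])
        assert med == 0.0

    def test_undefined_pixels_excluded(self):
        gp = self.make_gp([[0.5, np.nan]])
        med, sd = vesicle_gp_stats(gp, [[0, 0], [0, 1]])
        assert med == 0.5

    def test_no_defined_pixels_errors(self):
        gp = self.make_gp([[np.nan]])
        with pytest.raises(ValueError):
            vesicle_gp_stats(gp, [[0, 0]])


class TestDeltaGP:
    def test_ordered_minus_disordered(self):
        assert delta_gp(0.5, -0.26) == pytest.approx(0.76)

    def test_equal_is_zero(self):
        assert delta_gp(0.3, 0.3) == 0.0

    def test_recovery_from_synthetic_phases(self, vesicle_scene, nr_config):
        """Planted two-phase vesicle: ordered-disordered GP difference
        recovered within +/-0.03 of the analytic value."""
        spec, img, truth = vesicle_scene
        records = detect_vesicles(img, nr_config)
        janus = [t for t in truth["vesicles"] if len(t["phase_gp"]) == 2][0]
        target = min(
            (r for r in records if r.retained),
            key=lambda r: np.hypot(
                r.centroid[0] - janus["center"][0], r.centroid[1] - janus["center"][1]
            ),
        )
        from memprobe.image_model import ROI, subtract_background

        corrected = subtract_background(
            img, ROI.from_mask(truth["label_map"] == -1, "background")
        )
        gm = gp_map(corrected, nr_config)
        phase_map, label_map = truth["phase_map"], truth["label_map"]
        vlabel = label_map[int(janus["center"][0]) + 30, int(janus["center"][1])]
        measured = []
        for pi in (0, 1):
            mask = (label_map == vlabel) & (phase_map == pi)
            med, _ = vesicle_gp_stats(gm, np.argwhere(mask))
            measured.append(med)
        expected = delta_gp(*sorted(janus["phase_gp"], reverse=True))
        got = delta_gp(*sorted(measured, reverse=True))
        assert got == pytest.approx(expected, abs=0.03)


class TestMembraneProfile:
    def test_uniform_vesicle_constant_profile(self, nr_config):
        spec = synthetic.VesicleSceneSpec(
            image_size=(128, 128),
            vesicles=[
                synthetic.VesicleSpec(
                    center=(64, 64), radius=30,
                    phases=[(0, 360, synthetic.GaussianSpectrum(600, 30, 2000))],
                )
            ],
            noise="none",
            seed=0,
        )
        img, truth = synthetic.make_vesicle_image(spec)
        rec = detect_vesicles(img, nr_config)[0]
        prof = membrane_profile(img, nr_config, rec)
        vals = prof.gp_values[np.isfinite(prof.gp_values)]
        assert vals.std() < 0.02
        assert vals.mean() == pytest.approx(truth["vesicles"][0]["phase_gp"][0], abs=0.02)

    def test_janus_vesicle_two_level_step(self, nr_config):
        """Hemisphere phases appear as a two-level step function along the rim."""
        spec = synthetic.VesicleSceneSpec(
            image_size=(128, 128),
            vesicles=[
                synthetic.VesicleSpec(
                    center=(64, 64), radius=30,
                    phases=[
                        (0, 180, synthetic.GaussianSpectrum(580, 30, 2000)),
                        (180, 360, synthetic.GaussianSpectrum(650, 30, 2000)),
                    ],
                )
            ],
            noise="none",
            seed=0,
        )
        img, truth = synthetic.make_vesicle_image(spec)
        rec = detect_vesicles(img, nr_config)[0]
        prof = membrane_profile(img, nr_config, rec)
        g1, g2 = truth["vesicles"][0]["phase_gp"]
        first = prof.gp_values[(prof.positions > 10) & (prof.positions < 170)]
        second = prof.gp_values[(prof.positions > 190) & (prof.positions < 350)]
        assert np.nanmedian(first) == pytest.approx(g1, abs=0.03)
        assert np.nanmedian(second) == pytest.approx(g2, abs=0.03)

    def test_rotation_shifts_profile(self, nr_config):
        """Rotating the phase boundary rotates the profile accordingly."""
        def scene(offset):
            return synthetic.VesicleSceneSpec(
                image_size=(128, 128),
                vesicles=[
                    synthetic.VesicleSpec(
                        center=(64, 64), radius=30,
                        phases=[
                            (offset, offset + 180, synthetic.GaussianSpectrum(580, 30, 2000)),
                            (offset + 180, offset + 360, synthetic.GaussianSpectrum(650, 30, 2000)),
                        ],
                    )
                ],
                noise="none",
                seed=0,
            )

        img0, _ = synthetic.make_vesicle_image(scene(0))
        img90, _ = synthetic.make_vesicle_image(scene(90))
        rec0 = detect_vesicles(img0, nr_config)[0]
        rec90 = detect_vesicles(img90, nr_config)[0]
        p0 = membrane_profile(img0, nr_config, rec0)
        p90 = membrane_profile(img90, nr_config, rec90)
        shifted = np.roll(p90.gp_values, -90)
        ok = np.isfinite(p0.gp_values) & np.isfinite(shifted)
        # agree away from the transition edges
        disagree = np.abs(p0.gp_values[ok] - shifted[ok]) > 0.1
        assert disagree.mean() < 0.05


class TestInternalization:
    @pytest.mark.parametrize("internal, expected", [(100.0, 1.0), (50.0, 0.5), (0.0, 0.0)])
    def test_ratio(self, internal, expected):
        profile = np.zeros(50)
        profile[[10, 40]] = 100.0
        profile[20:31] = internal
        idx = internalization_index(profile, [10, 40], np.arange(20, 31))
        assert idx == pytest.approx(expected)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            internalization_index(np.ones(10), [2, 8], np.arange(2, 5))

    def test_zero_membrane_errors(self):
        with pytest.raises(ValueError):
            internalization_index(np.zeros(10), [1, 8], np.arange(3, 6))

    def test_noisy_synthetic_profile(self):
        profile, peaks, internal, truth = synthetic.make_internalization_profile(
            0.4, noise_sigma=0.02, seed=7
        )
        idx = internalization_index(profile, peaks, internal)
        assert idx == pytest.approx(truth["fraction"], abs=0.05)


class TestDetection:
    def test_recovers_planted_layout(self, vesicle_scene, nr_config):
        """3 circles retained, 2:1 ellipses (ecc ~0.87 >= 0.5) discarded,
        uniform-phase GP medians within +/-0.02 of analytic truth."""
        spec, img, truth = vesicle_scene
        records = detect_vesicles(img, nr_config)
        retained = [r for r in records if r.retained]
        assert len(retained) == truth["n_true_vesicles"] == 3
        for t in truth["vesicles"]:
            if t["is_decoy"] or len(t["phase_gp"]) != 1:
                continue
            rec = min(
                retained,
                key=lambda r: np.hypot(
                    r.centroid[0] - t["center"][0], r.centroid[1] - t["center"][1]
                ),
            )
            assert rec.gp_median == pytest.approx(t["phase_gp"][0], abs=0.02)
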