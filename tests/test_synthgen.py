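"""Generator correctness: known-truth scenes, determinism, conservation."""

import numpy as np
import pytest

import cocscreen as cs
from cocscreen.errors import ParameterError, PlacementError


class TestOocyteScene:
    def test_uniform_disc_has_unit_ratio(self):
        scene, truth = cs.make_oocyte_scene(radius_px=60, true_ratio=1.0,
                                            noise_sd=0.0, seed=0)
        plane = scene.plane("mito", 0)
        inside = plane > 0
        assert truth.true_ratio == 1.0
        assert np.unique(plane[inside]).size == 1  # one intensity level

    def test_ratio_by_analytic_mask_averaging(self):
        # oracle: per-pixel means over the analytically defined annulus/disc
        r, ratio = 100, 3.0
        scene, _ = cs.make_oocyte_scene(radius_px=r, true_ratio=ratio,
                                        noise_sd=0.0, seed=0)
        plane = scene.plane("mito", 0)
        size = plane.shape[0]
        c = (size - 1) / 2
        yy, xx = np.mgrid[0:size, 0:size]
        dist = np.hypot(yy - c, xx - c)
        center = dist <= 0.8 * r
        cortex = (dist <= r) & ~center
        measured = plane[cortex].mean() / plane[center].mean()
        assert measured == pytest.approx(ratio, rel=0.05)

    def test_vehicle_default_truth(self):
        _, truth = cs.make_oocyte_scene(seed=0)
        assert truth.true_ratio == 1.4

    def test_equator_is_largest_plane(self):
        scene, _ = cs.make_oocyte_scene(radius_px=50, true_ratio=2.0,
                                        noise_sd=0.0, n_z=7, seed=0)
        areas = [(scene.plane("mito", z) > 0).sum() for z in range(7)]
        assert int(np.argmax(areas)) == 3

    def test_small_radius_rejected(self):
        with pytest.raises(ParameterError):
            cs.make_oocyte_scene(radius_px=10)

    def test_seeded_determinism(self):
        a, _ = cs.make_oocyte_scene(noise_sd=8.0, seed=5)
        b, _ = cs.make_oocyte_scene(noise_sd=8.0, seed=5)
        c, _ = cs.make_oocyte_scene(noise_sd=8.0, seed=6)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)


class TestExpansionPair:
    def test_areas_match_request_within_1pct(self):
        (_, _), truth = cs.make_expansion_pair(13231, fold=2.877, seed=1)
        before, after = truth.true_area_px
        assert before == pytest.approx(13231, rel=0.01)
        assert after == pytest.approx(round(2.877 * 13231), rel=0.01)

    def test_unit_fold_gives_equal_areas(self):
        (_, _), truth = cs.make_expansion_pair(9000, fold=1.0, seed=2)
        before, after = truth.true_area_px
        assert after == pytest.approx(before, rel=0.01)

    def test_zero_irregularity_is_a_disc(self):
        (scene, _), truth = cs.make_expansion_pair(12000, fold=1.5,
                                                   irregularity=0.0, seed=3)
        before, _ = truth.true_area_px
        # analytic: pi r^2 with r from the requested area
        assert before == pytest.approx(12000, rel=0.01)
        mask = scene.plane("brightfield") > 100
        # oracle: the analytic disc of the same area, IoU ~ 1
        size = mask.shape[0]
        c = (size - 1) / 2
        yy, xx = np.mgrid[0:size, 0:size]
        disc = np.hypot(yy - c, xx - c) <= np.sqrt(12000 / np.pi)
        iou = (mask & disc).sum() / (mask | disc).sum()
        assert iou > 0.98

    def test_frame_too_small_rejected(self):
        with pytest.raises(ParameterError):
            cs.make_expansion_pair(13231, fold=3.0, frame=50)


class TestNucleusScene:
    def test_truth_composition(self, worked_nucleus_scene):
        _, truth = worked_nucleus_scene
        counts = truth.class_counts()
        assert sum(counts.values()) == 227
        assert counts["apoptotic"] == 7
        assert counts["secondary"] == 10
        assert counts["necrotic_only"] == 0

    def test_all_healthy_means_blank_marker_channels(self):
        scene, truth = cs.make_coc_nucleus_scene(n_total=40, noise_sd=0.0,
                                                 bg_level=0.0, seed=1)
        assert all(c == "healthy" for _, c in truth.nucleus_truth)
        assert scene.plane("tunel").max() == 0
        assert scene.plane("ethd1").max() == 0

    def test_touching_spots_connected_before_watershed(self):
        from skimage.measure import label
        from cocscreen.synthgen import _render_spots
        img = _render_spots((80, 80), np.array([[40.0, 36.0], [40.0, 45.0]]),
                            3.0, 150.0)
        # oracle: connected-component count on the noiseless binary render
        assert label(img > 40).max() == 1
        # the two spots are still resolvable peaks
        assert label(img > 120).max() == 2

    def test_min_separation_honored(self):
        _, truth = cs.make_coc_nucleus_scene(n_total=60, min_sep_px=14.0, seed=2)
        pts = np.array([c for c, _ in truth.nucleus_truth])
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                     pts[:, None, 1] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 14.0

    def test_infeasible_packing_raises(self):
        with pytest.raises(PlacementError):
            cs.make_coc_nucleus_scene(n_total=500, min_sep_px=40.0,
                                      frame=(256, 256), seed=0)

    def test_class_counts_cannot_exceed_total(self):
        with pytest.raises(ParameterError):
            cs.make_coc_nucleus_scene(n_total=5, n_tunel_only=3, n_double=3)


class TestOutcomeTables:
    def test_multinomial_rows_conserve_n(self):
        counts = cs.simulate_experiment_counts(
            {"a": (0.84, 0.16), "b": (0.5, 0.5)}, n_per_group=90, seed=0
        )
        assert (counts.sum(axis=1) == 90).all()

    def test_degenerate_probs(self):
        counts = cs.simulate_experiment_counts({"a": (1.0, 0.0)}, 50,
                                               categories=["x", "y"], seed=0)
        assert counts.loc["a", "x"] == 50 and counts.loc["a", "y"] == 0

    def test_multinomial_mean_matches_probability(self):
        # binomial SE oracle: fraction over 10,000 draws within 3 SE of p
        p, n, reps = 0.84, 90, 10_000
        fracs = [
            cs.simulate_experiment_counts({"g": (p, 1 - p)}, n, seed=s).iloc[0, 0] / n
            for s in range(reps // 100)
        ]
        # 100 independent draws (seeds); SE of the mean fraction
        se = np.sqrt(p * (1 - p) / n / len(fracs))
        assert np.mean(fracs) == pytest.approx(p, abs=3 * se)

    def test_negative_probability_rejected(self):
        with pytest.raises(ParameterError):
            cs.simulate_experiment_counts({"a": (-0.1, 1.1)}, 10)

    def test_steroid_sd_zero_is_exact(self):
        tab = cs.simulate_steroid_table(
            group_means={("progesterone", "vehicle"): 6.40},
            group_sds={("progesterone", "vehicle"): 0.0},
            n_reps=3, seed=0,
        )
        assert (tab["concentration_ng_ml"] == 6.40).all()

    def test_steroid_unknown_analyte_rejected(self):
        with pytest.raises(ParameterError):
            cs.simulate_steroid_table(group_means={("cortisol", "vehicle"): 1.0})

    def test_steroid_nonnegative_and_deterministic(self):
        a = cs.simulate_steroid_table(seed=3)
        b = cs.simulate_steroid_table(seed=3)
        assert (a["concentration_ng_ml"] >= 0).all()
        assert a.equals(b)
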