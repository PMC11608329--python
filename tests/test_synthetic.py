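"""Ground-truthed scene generation, presets and detection scoring."""

import dataclasses

import numpy as np
import pytest

from mitonuc import (InputError, SceneParams, expected_empty_fraction,
                     generate_scene, preset_params,
                     preset_target_empty_fraction, score_detection,
                     simulate_counts)
from mitonuc.segmentation import ClusterRecord

PRESETS = ["wt_like", "opa1_null_like", "rescue_like", "opa1_oe_like",
           "mut_870_like", "mut_2713_like"]


class TestGenerateScene:
    def test_same_seed_bit_identical(self):
        p = SceneParams(n_organelles=8, seed=17)
        s1 = generate_scene(p)
        s2 = generate_scene(p)
        for name in s1.channels:
            np.testing.assert_array_equal(s1.channels[name].pixels,
                                          s2.channels[name].pixels)
        assert s1.truth.n_clusters == s2.truth.n_clusters

    def test_forced_empty_limit_has_no_clusters(self):
        p = SceneParams(n_organelles=5, empty_excess=1.0, seed=3)
        scene = generate_scene(p)
        assert scene.truth.n_clusters == 0
        # nucleoid channel holds only diffuse background and noise
        assert scene.channels["nucleoid"].pixels.max() < 200.0

    def test_poisson_mean_recovered_over_200_draws(self):
        base = SceneParams(n_organelles=1, length_median_um=4.0,
                           length_sigma_log=0.3, length_clip_um=(4.0, 4.0))
        counts = []
        for seed in range(200):
            p = dataclasses.replace(base, seed=seed)
            truth = generate_scene(p, render=False).truth
            counts.append(truth.n_clusters)
        assert np.mean(counts) == pytest.approx(4.0, rel=0.1)

    def test_clusters_lie_on_midline_inside_mask(self):
        scene = generate_scene(SceneParams(n_organelles=15, seed=9))
        px = scene.truth.params.pixel_size_um
        for org in scene.truth.organelles:
            p0, p1 = org.midline_um
            d = p1 - p0
            for (x, y) in org.cluster_xy_um:
                if float(d @ d) > 0:
                    t = ((x - p0[0]) * d[0] + (y - p0[1]) * d[1]) / float(d @ d)
                    proj = p0 + np.clip(t, 0, 1) * d
                    assert np.hypot(x - proj[0], y - proj[1]) < 1e-9
                r, c = int(round(y / px)), int(round(x / px))
                assert scene.truth.mito_mask.pixels[r, c]

    def test_cluster_count_conservation_in_expectation(self):
        p = SceneParams(empty_excess=0.2, seed=0)
        lengths, counts = simulate_counts(p, 5000)
        expect = (1 - 0.2) * p.lambda_per_um * lengths.mean()
        assert counts.mean() == pytest.approx(expect, rel=0.1)

    def test_overcrowded_field_raises_helpful_error(self):
        p = SceneParams(field_um=(4.0, 4.0), n_organelles=200,
                        max_place_tries=30, seed=0)
        with pytest.raises(InputError, match="density"):
            generate_scene(p, render=False)

    def test_nucleus_mode_adds_blob_and_truth_mask(self):
        p = SceneParams(n_organelles=5, nucleus=True, seed=2)
        scene = generate_scene(p)
        assert scene.truth.nucleus_mask is not None
        assert scene.truth.nucleus_mask.pixels.sum() > 1000

    def test_mic60_mode_emits_striped_channel(self):
        p = SceneParams(n_organelles=5, mic60_mode=True, seed=2)
        scene = generate_scene(p)
        assert "mic60" in scene.channels
        inside = scene.channels["mic60"].pixels[scene.truth.mito_mask.pixels]
        assert np.ptp(inside) > 100.0  # stripes, not a flat fill

    @pytest.mark.parametrize("bad", [
        {"empty_excess": 1.5}, {"diffuse_fraction": -0.1},
        {"pixel_size_um": 0.0}, {"n_organelles": 0},
        {"length_clip_um": (0.0, 3.0)},
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(InputError):
            SceneParams(**bad)


class TestPresets:
    @pytest.mark.parametrize("name", PRESETS)
    def test_expected_empty_fraction_matches_target(self, name):
        params = preset_params(name)
        target = preset_target_empty_fraction(name)
        assert expected_empty_fraction(params) == pytest.approx(target, abs=1e-9)

    @pytest.mark.parametrize("name", PRESETS)
    def test_sampled_empty_fraction_within_binomial_interval(self, name):
        params = preset_params(name, seed=101)
        target = preset_target_empty_fraction(name)
        _, counts = simulate_counts(params, 10000)
        phat = float(np.mean(counts == 0))
        half = 1.96 * np.sqrt(target * (1 - target) / 1000)
        assert abs(phat - target) < half

    def test_null_preset_is_short_and_diffuse(self):
        p = preset_params("opa1_null_like")
        assert p.length_clip_um[1] <= 3.0
        assert p.diffuse_fraction > preset_params("wt_like").diffuse_fraction

    def test_lambda_is_one_per_um_in_all_presets(self):
        assert all(preset_params(n).lambda_per_um == 1.0 for n in PRESETS)

    def test_unknown_preset_error_lists_valid_names(self):
        with pytest.raises(InputError, match="wt_like"):
            preset_params("mystery")


def _fake_cluster(x, y):
    return ClusterRecord(centroid_um=(x, y), centroid_px=(y / 0.04, x / 0.04),
                         peak_intensity=1.0, integrated_intensity=1.0,
                         equiv_diameter_um=0.1, area_px=1)


class TestScoreDetection:
    def test_perfect_detection_scores_unity(self, noiseless_scene):
        detected = [_fake_cluster(x, y)
                    for (x, y) in noiseless_scene.truth.cluster_xy_um]
        s = score_detection(detected, [], noiseless_scene.truth)
        assert s["precision"] == 1.0 and s["recall"] == 1.0 and s["f1"] == 1.0

    def test_missing_detections_lower_recall_not_precision(self, noiseless_scene):
        truth = noiseless_scene.truth
        detected = [_fake_cluster(x, y)
                    for (x, y) in truth.cluster_xy_um[:-7]]  # miss the last 7
        s = score_detection(detected, [], truth)
        assert s["n_matched"] == truth.n_clusters - 7
        assert s["precision"] == 1.0
        assert s["recall"] == pytest.approx((truth.n_clusters - 7) / truth.n_clusters)

    def test_greedy_competition_matches_exactly_one(self, noiseless_scene):
        (x, y) = noiseless_scene.truth.cluster_xy_um[0]
        detected = [_fake_cluster(x + 0.02, y), _fake_cluster(x - 0.02, y)]
        truth = noiseless_scene.truth
        s = score_detection(detected, [], truth)
        assert s["n_matched"] == 1
        assert s["n_detected_clusters"] == 2

    def test_end_to_end_noiseless_f1_is_one(self, noiseless_scene,
                                            analyzed_noiseless):
        s = score_detection(analyzed_noiseless.clusters,
                            analyzed_noiseless.organelles,
                            noiseless_scene.truth)
        assert s["f1"] == 1.0
        assert s["n_detected_clusters"] == s["n_true_clusters"]
        assert s["organelle_count_error"] == 0
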