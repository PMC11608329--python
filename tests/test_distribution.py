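"""Cluster-to-organelle assignment and the two-level distribution model."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from mitonuc import (BinaryMask, InputError, SceneParams, assign_clusters,
                     compare_groups, generate_scene, label_and_measure,
                     longitudinal_stats, population_array_stats,
                     simulate_counts)
from mitonuc.cli import analyze_images
from mitonuc.segmentation import ClusterRecord

from conftest import PX, make_bar_mask


def _cluster(x_um, y_um, px=PX):
    return ClusterRecord(centroid_um=(x_um, y_um),
                         centroid_px=(y_um / px, x_um / px),
                         peak_intensity=100.0, integrated_intensity=100.0,
                         equiv_diameter_um=0.2, area_px=4)


class TestAssignClusters:
    def test_single_owner_gets_all_clusters(self):
        mask = make_bar_mask(3.0, pixel_size_um=PX)
        orgs, labels = label_and_measure(mask, min_area_um2=0.0)
        clusters = [_cluster(1.0, 0.6), _cluster(2.0, 0.6), _cluster(3.0, 0.6)]
        assign_clusters(clusters, orgs, labels)
        assert orgs[0].cluster_count == 3
        assert all(c.organelle_label == orgs[0].label for c in clusters)

    def test_mask_membership_decides_between_close_neighbors(self):
        # two bars separated by a 3-px gap; centroid inside bar A
        m = np.zeros((40, 120), dtype=bool)
        m[10:18, 5:60] = True
        m[21:29, 5:60] = True
        orgs, labels = label_and_measure(BinaryMask(m, PX), min_area_um2=0.0)
        c = _cluster(1.0, 17 * PX)  # last row of bar A
        assign_clusters([c], orgs, labels)
        assert c.organelle_label == orgs[0].label

    def test_midpoint_cluster_has_central_arc_position(self):
        mask = make_bar_mask(4.0, width_um=0.3, pixel_size_um=PX, pad_px=12)
        orgs, labels = label_and_measure(mask, min_area_um2=0.0)
        x_mid = 12 * PX + 2.0
        y_mid = (12 + 4) * PX  # vertical center of the bar
        c = _cluster(x_mid, y_mid)
        assign_clusters([c], orgs, labels)
        assert c.arc_position == pytest.approx(0.5, abs=0.05)

    def test_off_mask_centroid_snaps_within_2px_else_unassigned(self):
        mask = make_bar_mask(2.0, pixel_size_um=PX)
        orgs, labels = label_and_measure(mask, min_area_um2=0.0)
        near = _cluster(1.0, 8 * PX)   # 2 px above the bar (rows 10..)
        far = _cluster(1.0, 2 * PX)    # 8 px above the bar
        assign_clusters([near, far], orgs, labels)
        assert near.organelle_label == orgs[0].label and not near.unassigned
        assert far.organelle_label is None and far.unassigned

    def test_inconsistent_labeled_mask_rejected(self):
        mask = make_bar_mask(2.0, pixel_size_um=PX)
        orgs, labels = label_and_measure(mask, min_area_um2=0.0)
        bogus = labels.copy()
        bogus[0, 0] = 99
        with pytest.raises(InputError, match="label"):
            assign_clusters([], orgs, bogus)


class TestArrayStats:
    def _stats_for_counts(self, counts):
        mask = BinaryMask(np.ones((10, 10), bool), 1.0)
        orgs, labels = label_and_measure(mask, min_area_um2=0.0)
        base = orgs[0]
        all_orgs = []
        for i, k in enumerate(counts, start=1):
            o = dataclasses.replace(base, label=i, cluster_count=k)
            all_orgs.append(o)
        return population_array_stats(all_orgs, [], mask)

    def test_histogram_and_mean_by_definition(self):
        s = self._stats_for_counts([0, 1, 2])
        assert s.count_histogram == pytest.approx((1 / 3, 1 / 3, 1 / 3, 0, 0))
        assert s.empty_fraction == pytest.approx(1 / 3)
        assert s.mean_clusters_per_mito == pytest.approx(1.0)

    def test_histogram_caps_at_4_plus(self):
        s = self._stats_for_counts([4, 5, 9])
        assert s.count_histogram[4] == pytest.approx(1.0)

    def test_density_is_total_clusters_over_total_area(self):
        # single 100-px organelle at 1 um/px -> 100 um^2; rescale to 10 um^2
        mask = BinaryMask(np.ones((10, 10), bool), np.sqrt(0.1))
        orgs, labels = label_and_measure(mask, min_area_um2=0.0)
        orgs[0].cluster_count = 4
        s = population_array_stats(orgs, [], mask)
        assert s.total_area_um2 == pytest.approx(10.0)
        assert s.clusters_per_total_area == pytest.approx(0.4)

    def test_zero_organelles_rejected(self):
        mask = BinaryMask(np.ones((4, 4), bool), 1.0)
        with pytest.raises(InputError):
            population_array_stats([], [], mask)

    def test_conservation_identity_on_analyzed_scene(self, analyzed_noiseless):
        a = analyzed_noiseless.array_stats
        assert a.clusters_per_total_area * a.total_area_um2 == pytest.approx(
            a.n_assigned_clusters, abs=1e-9)
        assert sum(a.count_histogram) == pytest.approx(1.0, abs=1e-12)

    def test_empty_fraction_matches_filter_exclusions(self, analyzed_noiseless):
        from mitonuc import filter_organelles
        a = analyzed_noiseless.array_stats
        _, excluded = filter_organelles(analyzed_noiseless.organelles,
                                        require_clusters=True)
        assert a.empty_fraction == pytest.approx(
            len(excluded) / a.n_organelles)


class TestLongitudinalStats:
    def _org(self, label, length, count):
        from test_organelles import _record
        return _record(label, length, count)

    def test_exact_collinearity_recovered(self):
        orgs = [self._org(1, 1.0, 1), self._org(2, 2.0, 2), self._org(3, 4.0, 4)]
        lg = longitudinal_stats(orgs)
        assert lg.regression.slope == pytest.approx(1.0)
        assert lg.regression.intercept == pytest.approx(0.0, abs=1e-12)
        assert lg.regression.r2 == pytest.approx(1.0)

    def test_single_organelle_density_defined_regression_not(self):
        lg = longitudinal_stats([self._org(1, 2.0, 2)])
        assert lg.mean_clusters_per_um == pytest.approx(1.0)
        assert lg.regression is None

    def test_arc_positions_uniform_on_noiseless_scenes(self):
        params = SceneParams(length_median_um=3.0, length_sigma_log=0.35,
                             length_clip_um=(1.5, 6.0), empty_excess=0.0,
                             poisson_scale=0.0, gaussian_sd=0.0)
        arcs = []
        seed = 11
        while len(arcs) < 300:
            p = dataclasses.replace(params, seed=seed)
            scene = generate_scene(p)
            res = analyze_images(scene.channels["mito"],
                                 scene.channels["nucleoid"],
                                 require_clusters=True)
            lg = longitudinal_stats(res.kept, res.clusters)
            arcs.extend(lg.arc_positions)
            seed += 1
        d, p_value = sps.kstest(arcs, "uniform")
        assert p_value > 0.01

    def test_empty_excess_monotonically_raises_empty_fraction(self):
        fracs = []
        for i, e in enumerate((0.0, 0.25, 0.5)):
            params = SceneParams(empty_excess=e, seed=100 + i)
            _, counts = simulate_counts(params, 1000)
            fracs.append(np.mean(counts == 0))
        assert fracs[0] < fracs[1] < fracs[2]


class TestCompareGroups:
    def _stats(self, empty_fraction):
        from mitonuc import ArrayStats
        h0 = empty_fraction
        return ArrayStats(
            n_organelles=10,
            count_histogram=(h0, 1 - h0, 0.0, 0.0, 0.0),
            empty_fraction=h0, mean_clusters_per_mito=1.0,
            mean_clusters_per_area=0.5, clusters_per_total_area=0.5,
            total_area_um2=20.0, n_assigned_clusters=10,
            n_unassigned_clusters=0)

    def test_mean_and_sem(self):
        table = compare_groups({"wt": [self._stats(0.1), self._stats(0.2)]})
        row = table.iloc[0]
        assert row["empty_fraction_mean"] == pytest.approx(0.15)
        assert row["empty_fraction_sem"] == pytest.approx(0.05)
        assert row["n_cells"] == 2

    def test_identical_conditions_identical_rows(self):
        cells = [self._stats(0.1), self._stats(0.3)]
        table = compare_groups({"a": cells, "b": list(cells)})
        a = table[table.condition == "a"].drop(columns="condition").iloc[0]
        b = table[table.condition == "b"].drop(columns="condition").iloc[0]
        assert a.equals(b)

    def test_single_cell_condition_has_undefined_sem(self):
        table = compare_groups({"solo": [self._stats(0.1)]})
        row = table.iloc[0]
        assert not row["sem_defined"]
        assert np.isnan(row["empty_fraction_sem"])

    def test_empty_condition_rejected(self):
        with pytest.raises(InputError):
            compare_groups({"none": []})
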