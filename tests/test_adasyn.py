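import numpy as np
import pytest

import zoocnn as z
from zoocnn.data import ClusterSet

from conftest import brute_force_knn_difficulty


class TestComputePlan:
    def test_balanced_classes_yield_empty_plan(self):
        pts = np.random.default_rng(0).normal(size=(100, 2))
        labels = np.array([0] * 50 + [1] * 50)
        plan = z.compute_plan(ClusterSet(pts, labels), 1, k=5, beta=1.0)
        assert plan.G == 0
        assert plan.counts.sum() == 0

    def test_total_synthesis_count_formula(self):
        """G = round(beta * (m_l - m_s)) for several betas."""
        pts = np.random.default_rng(1).normal(size=(150, 2))
        labels = np.array([0] * 100 + [1] * 50)
        for beta in (1.0, 0.5, 0.25):
            plan = z.compute_plan(ClusterSet(pts, labels), 1, k=5, beta=beta)
            assert plan.G == round(beta * 50)
            assert plan.counts.sum() == plan.G

    def test_one_dimensional_toy_against_enumeration(self):
        """k-NN difficulty on a tiny 1-D set matches brute-force enumeration."""
        pts = np.array([[0.0], [10.0], [0.1], [0.2], [0.3]])
        labels = np.array([1, 1, 0, 0, 0])  # minority 1, majority 0
        plan = z.compute_plan(ClusterSet(pts, labels), 1, k=2, beta=1.0)
        assert plan.G == 1
        oracle = brute_force_knn_difficulty(pts, labels, 1, 2)
        np.testing.assert_allclose(plan.ratios, oracle / oracle.sum())
        assert plan.counts.sum() == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_difficulty_ratios_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(60, 3))
        labels = rng.integers(0, 2, size=60)
        labels[:40] = 0  # make 1 the minority
        cs = ClusterSet(pts, labels)
        plan = z.compute_plan(cs, 1, k=4, beta=1.0)
        raw = brute_force_knn_difficulty(pts, labels, 1, 4)
        expected = raw / raw.sum() if raw.sum() else np.full(len(raw), 1 / len(raw))
        np.testing.assert_allclose(plan.ratios, expected)

    def test_ratio_normalization_and_proportionality(self, gaussian_clusters):
        plan = z.compute_plan(gaussian_clusters, 1, k=5, beta=1.0)
        assert plan.G == 140
        assert np.all(plan.ratios >= 0) and np.all(plan.ratios <= 1)
        assert plan.ratios.sum() == pytest.approx(1.0)
        # largest-remainder apportionment stays proportional
        corr = np.corrcoef(plan.ratios, plan.counts / plan.G)[0, 1]
        assert corr >= 0.99

    def test_k_too_large_rejected(self):
        pts = np.zeros((4, 2))
        with pytest.raises(ValueError):
            z.compute_plan(ClusterSet(pts, [0, 0, 0, 1]), 1, k=4)


class TestSynthesize:
    def test_empty_plan_gives_empty_output(self):
        pts = np.random.default_rng(0).normal(size=(100, 2))
        labels = np.array([0] * 50 + [1] * 50)
        cs = ClusterSet(pts, labels)
        plan = z.compute_plan(cs, 1, k=5, beta=1.0)
        assert z.synthesize_samples(cs, plan, seed=0).shape == (0, 2)

    def test_identical_minority_points_reproduce_themselves(self):
        v = np.array([2.5, -1.0])
        pts = np.vstack([np.tile(v, (10, 1)),
                         np.random.default_rng(0).normal(5, 1, size=(40, 2))])
        labels = np.array([1] * 10 + [0] * 40)
        cs = ClusterSet(pts, labels)
        plan = z.compute_plan(cs, 1, k=3, beta=1.0)
        synth = z.synthesize_samples(cs, plan, seed=3)
        assert len(synth) == plan.G == 30
        np.testing.assert_allclose(synth, np.tile(v, (30, 1)))

    def test_every_point_inside_parent_neighbor_bounding_box(self, gaussian_clusters):
        """Each synthetic point is a convex combination along one segment."""
        cs = gaussian_clusters
        plan = z.compute_plan(cs, 1, k=5, beta=1.0)
        synth = z.synthesize_samples(cs, plan, seed=11)
        minority = cs.points[plan.minority_indices]
        # recover the parent of each output row from the allocation order
        parents = np.repeat(np.arange(len(plan.counts)), plan.counts)
        for s, p in zip(synth, parents):
            x_i = minority[p]
            d = np.linalg.norm(minority - x_i, axis=1)
            nbrs = np.argsort(d, kind="stable")[1 : plan.k + 1]
            in_some_box = any(
                np.all(s >= np.minimum(x_i, minority[nb]) - 1e-9)
                and np.all(s <= np.maximum(x_i, minority[nb]) + 1e-9)
                for nb in nbrs
            )
            assert in_some_box

    def test_mismatched_plan_rejected(self, gaussian_clusters):
        plan = z.compute_plan(gaussian_clusters, 1, k=5, beta=1.0)
        shrunk = ClusterSet(gaussian_clusters.points[:10], gaussian_clusters.labels[:10])
        with pytest.raises(ValueError):
            z.synthesize_samples(shrunk, plan, seed=0)

    def test_boundary_focus_exceeds_uniform_allocation(self, gaussian_clusters):
        """Parents of synthetic points are harder than the average minority
        point: adaptive allocation concentrates on the class boundary."""
        cs = gaussian_clusters
        plan = z.compute_plan(cs, 1, k=5, beta=1.0)
        raw = brute_force_knn_difficulty(cs.points, cs.labels, 1, 5)
        weighted = np.average(raw, weights=plan.counts)
        assert weighted >= raw.mean()


class TestBalanceDataset:
    def test_full_balance_within_one(self, small_imageset):
        balanced = z.balance_dataset(small_imageset, beta=1.0, seed=0)
        counts = balanced.class_counts()
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_beta_zero_is_identity(self, small_imageset):
        assert z.balance_dataset(small_imageset, beta=0.0) is small_imageset

    def test_partial_balance(self):
        ds = z.generate_images({0: 100, 1: 50, 2: 0}, side=16, seed=2)
        balanced = z.balance_dataset(ds, beta=0.5, seed=0)
        assert balanced.class_counts()[1] == 75

    def test_originals_preserved_and_synthetics_flagged(self, small_imageset):
        balanced = z.balance_dataset(small_imageset, beta=1.0, seed=0)
        n = len(small_imageset)
        assert np.array_equal(balanced.images[:n], small_imageset.images)
        assert np.array_equal(balanced.labels[:n], small_imageset.labels)
        assert all(p == "real" for p in balanced.provenance[:n])
        assert all(p == "synthetic" for p in balanced.provenance[n:])
        assert balanced.images.min() >= 0 and balanced.images.max() <= 1

    def test_single_class_rejected(self):
        ds = z.generate_images({0: 20, 1: 0, 2: 0}, side=16, seed=0)
        with pytest.raises(ValueError):
            z.balance_dataset(ds)

    def test_plan_exports_to_json(self, gaussian_clusters, tmp_path):
        plan = z.compute_plan(gaussian_clusters, 1, k=5, beta=1.0)
        text = plan.to_json(tmp_path / "plan.json")
        import json

        payload = json.loads(text)
        assert payload["G"] == plan.G
        assert sum(payload["counts"]) == plan.G
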