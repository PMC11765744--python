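import numpy as np
import pytest

import zoocnn as z
from zoocnn.space import decode_vector, denormalize_vector
from zoocnn.sracos import learn_sampling_region, sracos_minimize


def sphere(cfg: z.HyperConfig) -> float:
    """2-active-dimension surrogate with optimum near the tuned point."""
    return (np.log10(cfg.learning_rate) + 4) ** 2 + (cfg.dropout - 0.44) ** 2


class TestSchedule:
    @pytest.mark.parametrize(
        "iteration, total, expected",
        [(0, 300, 0.6), (300, 300, 0.3), (150, 300, 0.45)],
    )
    def test_linear_interpolation(self, iteration, total, expected):
        assert z.exploration_probability(iteration, total) == pytest.approx(expected)


class TestRegionLearning:
    def test_no_negatives_gives_step_size_box(self):
        rng = np.random.default_rng(0)
        anchor = np.full(8, 0.5)
        lo, hi = learn_sampling_region([anchor], [], None, 0.1, rng)
        np.testing.assert_allclose(lo, 0.4)
        np.testing.assert_allclose(hi, 0.6)

    def test_anchor_always_inside(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            anchor = rng.random(8)
            negatives = [rng.random(8) for _ in range(5)]
            lo, hi = learn_sampling_region(
                [anchor], negatives, None, 0.2, rng, anchor_index=0
            )
            assert np.all(lo <= anchor) and np.all(anchor <= hi)

    def test_retained_negatives_excluded_from_region(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            anchor = rng.random(4)
            negatives = [
                np.clip(anchor + rng.normal(0, 0.05, 4), 0, 1) for _ in range(6)
            ]
            lo, hi = learn_sampling_region(
                [anchor], negatives, None, 0.3, rng, anchor_index=0
            )
            for n in negatives:
                if np.array_equal(n, anchor):
                    continue
                assert not (np.all(n >= lo) and np.all(n <= hi))


class TestSracos:
    def test_flat_landscape_early_stops_at_patience(self):
        trace = z.sracos_optimize(
            lambda c: 1.0,
            z.default_space(),
            z.OptimizerConfig(budget=100, population=50, patience=30, seed=0),
        )
        assert trace.best_value == 1.0
        assert trace.evaluations_used == 80  # population + patience

    def test_best_so_far_monotone_and_budget_respected(self):
        calls = 0

        def noisy(cfg):
            nonlocal calls
            calls += 1
            if calls % 7 == 0:
                raise RuntimeError("simulated evaluation failure")
            return sphere(cfg)

        trace = z.sracos_optimize(
            noisy, z.default_space(), z.OptimizerConfig(budget=150, seed=3)
        )
        bests = [r.best_so_far for r in trace.records]
        assert all(b2 <= b1 for b1, b2 in zip(bests, bests[1:]))
        assert trace.evaluations_used <= 150
        assert trace.evaluations_used == len(trace.records)
        assert any(np.isinf(r.value) for r in trace.records)

    def test_deterministic_under_seed(self):
        opt = z.OptimizerConfig(budget=120, seed=11)
        t1 = z.sracos_optimize(sphere, z.default_space(), opt)
        t2 = z.sracos_optimize(sphere, z.default_space(), opt)
        assert t1.best_value == t2.best_value
        assert [r.value for r in t1.records] == [r.value for r in t2.records]

    def test_full_exploration_equals_uniform_random_search(self):
        """With explore probability pinned at 1 the candidate stream is the
        seeded uniform stream."""
        opt = z.OptimizerConfig(
            budget=80, population=20, explore_start=1.0, explore_end=1.0,
            patience=10**9, seed=5,
        )
        space = z.default_space()
        trace = z.sracos_optimize(sphere, space, opt)
        rng = np.random.default_rng(5)
        expected = []
        for i in range(80):
            if i >= 20:
                rng.random()  # the explore/exploit coin
            expected.append(
                decode_vector(denormalize_vector(rng.random(8), space), space)
            )
        assert [r.candidate for r in trace.records] == expected

    def test_beats_random_search_on_sphere(self):
        space = z.default_space()
        s_vals, r_vals = [], []
        for seed in range(10):
            trace = z.sracos_optimize(
                sphere, space, z.OptimizerConfig(budget=300, seed=seed)
            )
            rng = np.random.default_rng(seed + 10_000)
            r_vals.append(
                min(sphere(z.sample_config(space, rng)) for _ in range(300))
            )
            s_vals.append(trace.best_value)
        assert np.median(s_vals) <= np.median(r_vals)

    def test_consistency_on_sphere_large_budget(self):
        hits = sum(
            z.sracos_optimize(
                sphere, z.default_space(), z.OptimizerConfig(budget=2000, seed=s)
            ).best_value
            <= 0.05
            for s in range(20)
        )
        assert hits >= 18

    def test_re_evaluations_average_noisy_objectives(self):
        calls = []

        def stub(cfg):
            calls.append(cfg)
            return float(len(calls) % 3)  # deterministic pseudo-noise

        trace = z.sracos_optimize(
            stub,
            z.default_space(),
            z.OptimizerConfig(budget=12, population=12, re_evaluations=3, seed=0),
        )
        assert len(calls) == 36  # 3 calls per recorded evaluation
        assert trace.evaluations_used == 12
        assert trace.records[0].value == pytest.approx((1 + 2 + 0) / 3)

    def test_trace_csv_export(self, tmp_path):
        trace = z.sracos_optimize(
            sphere, z.default_space(), z.OptimizerConfig(budget=60, seed=0)
        )
        trace.to_csv(tmp_path / "trace.csv")
        lines = (tmp_path / "trace.csv").read_text().splitlines()
        assert lines[0] == "iteration,candidate,value,best_so_far"
        assert len(lines) == trace.evaluations_used + 1


class TestRandomEmbedding:
    def test_same_seed_same_matrix(self):
        a = z.make_random_embedding(z.default_space(), 3, seed=9)
        b = z.make_random_embedding(z.default_space(), 3, seed=9)
        np.testing.assert_array_equal(a.A, b.A)

    def test_bad_target_dim_rejected(self):
        with pytest.raises(ValueError):
            z.make_random_embedding(z.default_space(), 8, seed=0)
        with pytest.raises(ValueError):
            z.make_random_embedding(z.default_space(), 0, seed=0)

    def test_truncated_identity_freezes_coordinates(self):
        emb = z.make_random_embedding(z.default_space(), 2, seed=0)
        emb.A = np.zeros((8, 2))
        emb.A[6, 0] = 1.0  # free: learning-rate slot
        emb.A[7, 1] = 1.0  # free: dropout slot
        rng = np.random.default_rng(0)
        lifted = [emb.lift(rng.random(2)) for _ in range(50)]
        frozen = np.array(lifted)[:, :6]
        assert np.all(frozen == 0.5)

    def test_linear_objective_optimum_recovered(self):
        """On a linear objective the embedded optimum matches the full-space
        optimum (both push the free coordinate to its bound)."""
        space = z.default_space()

        def linear(cfg):
            return np.log10(cfg.learning_rate)  # minimized at lr lower bound

        emb, lifted = z.make_random_embedding(space, 7, seed=1, objective=linear)
        trace = sracos_minimize(
            lifted, 7, z.OptimizerConfig(budget=400, population=50, seed=1)
        )
        assert trace.best_value == pytest.approx(np.log10(1e-5), abs=0.1)
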