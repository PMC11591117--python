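"""Binary-enhanced WOA: pool, strategies, binarization, and main loop."""

import numpy as np
import pytest

from ccawoa import (
    Pool,
    binarize,
    enriched_encircle,
    migrate,
    preferential_select,
    run_bewoa,
    run_binary_woa,
    update_pool,
)


class TestPool:
    def test_capacity_held_after_many_updates(self, rng):
        pool = Pool(5)
        for i in range(20):
            update_pool(pool, np.zeros(3), np.ones(3), rng, np.full(3, -1.0), np.full(3, 1.0))
            assert len(pool) <= 5
        assert len(pool) == 5

    def test_capacity_validation(self):
        with pytest.raises(ValueError):
            Pool(0)

    def test_crossover_extremes(self, rng):
        # all-ones binary vector keeps only the perturbed-best part
        ybest, yworst = np.array([1.0, 2.0]), np.array([-5.0, -6.0])
        lo, hi = np.full(2, -10.0), np.full(2, 10.0)
        pool = Pool(4)
        update_pool(pool, ybest, yworst, rng, lo, hi, perturb_scale=0.0,
                    binary_vector=np.ones(2, dtype=int))
        assert np.array_equal(pool.members[0], ybest)
        update_pool(pool, ybest, yworst, rng, lo, hi,
                    binary_vector=np.zeros(2, dtype=int))
        assert np.array_equal(pool.members[1], yworst)


class TestMigrate:
    def test_degenerate_bounds_deterministic(self, rng):
        out = migrate(np.full(3, 2.0), np.full(3, 2.0), np.full(3, 0.5), np.full(3, 0.5), rng)
        assert np.allclose(out, 1.5)

    def test_output_range_monte_carlo(self):
        rng = np.random.default_rng(0)
        lo, hi = np.array([-2.0]), np.array([3.0])
        bl, bu = np.array([0.0]), np.array([1.0])
        draws = np.array([migrate(lo, hi, bl, bu, rng)[0] for _ in range(10_000)])
        assert draws.min() >= lo[0] - bu[0]
        assert draws.max() <= hi[0] - bl[0]

    def test_inverted_bounds_raise(self, rng):
        with pytest.raises(ValueError):
            migrate(np.array([1.0]), np.array([0.0]), np.array([0.0]), np.array([1.0]), rng)

    def test_seeded_reproducibility(self):
        args = (np.zeros(4), np.ones(4), np.zeros(4), np.full(4, 0.5))
        a = migrate(*args, np.random.default_rng(5))
        b = migrate(*args, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestPreferentialSelect:
    def test_hand_value_with_injected_pool(self, rng):
        pool = Pool(2)
        pool.members = [np.array([3.0]), np.array([2.0])]
        # members differ so the draw is one of the two orderings
        out = preferential_select(np.array([1.0]), W=1.0, U=2.0, pool=pool, rng=rng)
        assert out[0] in (3.0, -1.0)  # 1 + 2*(3-2) or 1 + 2*(2-3)

    def test_zero_w_returns_position(self, rng):
        pool = Pool(3)
        pool.members = [np.array([9.0]), np.array([-4.0])]
        yj = np.array([1.5])
        assert np.array_equal(preferential_select(yj, 0.0, 1.3, pool, rng), yj)

    def test_identical_members_no_move(self, rng):
        pool = Pool(3)
        pool.members = [np.array([2.0]), np.array([2.0])]
        yj = np.array([0.5])
        assert np.array_equal(preferential_select(yj, 1.0, 1.0, pool, rng), yj)

    def test_small_pool_falls_back(self, rng):
        out = preferential_select(np.array([1.0]), 1.0, 1.0, Pool(3), rng)
        assert np.all(np.isfinite(out))


class TestEnrichedEncircle:
    def test_hand_value(self, rng):
        pool = Pool(1)
        pool.members = [np.array([2.0])]
        out = enriched_encircle(np.array([4.0]), W=0.5, C=1.0, pool=pool, rng=rng)
        assert out[0] == pytest.approx(3.0)

    def test_zero_w_returns_best(self, rng):
        pool = Pool(1)
        pool.members = [np.array([-7.0])]
        ybest = np.array([4.0])
        assert np.array_equal(enriched_encircle(ybest, 0.0, 1.9, pool, rng), ybest)

    def test_empty_pool_falls_back_to_encircle(self, rng):
        ybest = np.array([4.0])
        out = enriched_encircle(ybest, 0.0, 1.0, Pool(2), rng, fallback_yj=np.array([1.0]))
        assert np.array_equal(out, ybest)


class TestBinarize:
    def test_strictly_binary_and_saturation(self, rng):
        y = rng.normal(0, 3, size=200)
        bits = binarize(y, "sigmoid", rng)
        assert set(np.unique(bits)) <= {0, 1}
        assert np.all(binarize(np.full(50, 20.0), "sigmoid", rng) == 1)
        assert np.all(binarize(np.full(50, -20.0), "sigmoid", rng) == 0)

    def test_sigmoid_at_zero_is_fair_coin(self):
        rng = np.random.default_rng(123)
        freq = np.mean([binarize(np.zeros(100), "sigmoid", rng).mean() for _ in range(100)])
        assert freq == pytest.approx(0.5, abs=0.02)

    def test_vshape_zero_never_activates(self, rng):
        assert np.all(binarize(np.zeros(100), "vshape", rng) == 0)

    def test_seeded_reproducibility_and_validation(self):
        y = np.linspace(-2, 2, 30)
        a = binarize(y, "sigmoid", np.random.default_rng(9))
        b = binarize(y, "sigmoid", np.random.default_rng(9))
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            binarize(np.array([np.inf]), "sigmoid", np.random.default_rng(0))
        with pytest.raises(ValueError):
            binarize(y, "sshape", np.random.default_rng(0))


def popcount_fitness(bits):
    return float(np.sum(bits)) / len(bits)


class TestRunBEWOA:
    def test_size_penalty_objective_shrinks_masks(self):
        res = run_bewoa(popcount_fitness, dim=40, n_whales=10, max_it=40, seed=2)
        assert res.best_fitness <= 0.5  # at or below a typical random mask
        assert res.n_selected == int(res.best_mask.sum())
        assert res.n_selected < 20

    def test_history_non_increasing_any_seed(self):
        for seed in range(3):
            res = run_bewoa(popcount_fitness, dim=25, n_whales=6, max_it=20, seed=seed)
            assert np.all(np.diff(res.fitness_history) <= 0)

    def test_fixed_seed_reproduces_trajectory(self):
        a = run_bewoa(popcount_fitness, dim=30, n_whales=8, max_it=25, seed=7)
        b = run_bewoa(popcount_fitness, dim=30, n_whales=8, max_it=25, seed=7)
        assert a.fitness_history == b.fitness_history
        assert np.array_equal(a.best_mask, b.best_mask)

    def test_greedy_update_never_worsens_stored_fitness(self):
        # track every evaluation; the running best must equal the minimum
        # over all masks evaluated so far (global-best contract)
        evals = []

        def spy(bits):
            f = popcount_fitness(bits)
            evals.append(f)
            return f

        res = run_bewoa(spy, dim=30, n_whales=8, max_it=25, seed=1)
        assert res.best_fitness == min(evals)
        assert res.n_evaluations == len(evals)

    def test_masks_strictly_binary(self):
        res = run_bewoa(popcount_fitness, dim=15, n_whales=5, max_it=10, seed=3)
        assert set(np.unique(res.best_mask)) <= {0, 1}

    def test_pool_capacity_respected_in_log(self):
        res = run_bewoa(popcount_fitness, dim=20, n_whales=6, max_it=30,
                        pool_capacity=4, seed=0)
        assert max(rec["pool_size"] for rec in res.log) <= 4

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            run_bewoa(popcount_fitness, dim=10, n_whales=3, max_it=5)
        with pytest.raises(ValueError):
            run_bewoa(popcount_fitness, dim=10, n_whales=6, max_it=5, migrate_fraction=0.0)


class TestRunBinaryWOA:
    def test_converges_on_size_penalty_and_reproduces(self):
        a = run_binary_woa(popcount_fitness, dim=30, n_whales=8, max_it=30, seed=4)
        b = run_binary_woa(popcount_fitness, dim=30, n_whales=8, max_it=30, seed=4)
        assert a.best_fitness <= 0.5
        assert np.all(np.diff(a.fitness_history) <= 0)
        assert np.array_equal(a.best_mask, b.best_mask)
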