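"""Swarm core: pheromone dynamics, communication, phases, and full runs."""

import numpy as np
import pytest

from mabc.core import (
    Bee,
    MabcGeneSelector,
    PheromoneField,
    _SwarmState,
    communicate,
    deposit_pheromone,
    evaporate,
    init_random,
    run,
    sigmoid,
    update_best,
    update_inertia,
    update_tmax,
)
from mabc.params import MabcParams, get_preset
from mabc.synthetic import SyntheticSpec, generate_dataset


class FixedFitness:
    """Deterministic stand-in evaluator: fitness = fraction of genes selected."""

    def __init__(self, n):
        self._n = n

    def fitness(self, mask):
        m = np.asarray(mask)
        if m.sum() == 0:
            raise ValueError("empty mask")
        return float(m.sum()) / self._n

    def evaluate(self, mask):
        f = self.fitness(mask)
        return f, f


class TestSigmoidAndInit:
    def test_sigmoid_fixed_points(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(5.0) == pytest.approx(1.0 / (1.0 + np.exp(-5.0)))

    def test_init_never_returns_empty_mask(self):
        field = PheromoneField.initialize(10, tmax=5.0)
        field.p[:] = 0.0  # worst case: zero selection probability everywhere
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert init_random(field, rng, 10, alpha=0.01).sum() >= 1

    def test_empirical_selection_rate_matches_closed_form(self):
        """With uniform pheromone tmax=5 and alpha=0.05 the per-gene selection
        rate is alpha * sigmoid(5), up to Monte-Carlo error and the
        empty-mask repair."""
        field = PheromoneField.initialize(50, tmax=5.0)
        rng = np.random.default_rng(1)
        draws = 20_000
        total = sum(init_random(field, rng, 50, alpha=0.05).sum() for _ in range(draws))
        rate = total / (draws * 50)
        expected = 0.05 * sigmoid(5.0)
        # repair adds at most P(all zero)/n per gene
        assert rate == pytest.approx(expected, abs=0.004)


class TestPheromoneUpdates:
    def test_unselected_gene_only_decays(self):
        field = PheromoneField.initialize(3, tmax=5.0)
        field.p[:] = 2.0
        bee = Bee(
            position=np.array([1, 0, 1], np.uint8), fit=1.0,
            pbest=np.array([1, 0, 1], np.uint8), pbest_fit=1.0,
        )
        gbest = np.array([1, 0, 0], np.uint8)
        params = MabcParams(c0=0.6)
        deposit_pheromone(bee, gbest, 1.0, field, w=0.5, params=params,
                          rng=np.random.default_rng(0))
        assert field.p[1] == pytest.approx(2.0 * 0.5)  # all indicator terms vanish

    def test_deposition_arithmetic_with_unit_randoms(self, monkeypatch):
        field = PheromoneField.initialize(1, tmax=5.0)
        field.p[:] = 1.0
        bee = Bee(
            position=np.ones(1, np.uint8), fit=1.0,
            pbest=np.ones(1, np.uint8), pbest_fit=1.0,
        )

        class UnitRng:
            def random(self, k):
                return np.ones(k)

        deposit_pheromone(bee, np.ones(1, np.uint8), 1.0, field, w=1.0,
                          params=MabcParams(c0=0.6), rng=UnitRng())
        # 1*1 + 0.6 + 0.2 + 0.2 = 2 with c1 = c2 = 0.2
        assert field.p[0] == pytest.approx(2.0)

    def test_deposition_clamps_to_tmax(self):
        field = PheromoneField.initialize(1, tmax=1.5)
        field.p[:] = 1.4
        bee = Bee(
            position=np.ones(1, np.uint8), fit=1.0,
            pbest=np.ones(1, np.uint8), pbest_fit=1.0,
        )
        deposit_pheromone(bee, np.ones(1, np.uint8), 1.0, field, w=1.0,
                          params=MabcParams(c0=0.6), rng=np.random.default_rng(1))
        assert field.p[0] <= 1.5

    def test_evaporation(self):
        field = PheromoneField.initialize(2, tmax=5.0)
        evaporate(field, 0.8)
        np.testing.assert_allclose(field.p, 4.0)
        evaporate(field, 1.0)
        np.testing.assert_allclose(field.p, 4.0)  # rho = 1 is a no-op
        field.p[:] = 0.0
        evaporate(field, 0.5)
        np.testing.assert_allclose(field.p, 0.0)  # floor is a fixed point

    def test_tmax_growth(self):
        field = PheromoneField.initialize(1, tmax=5.0)
        update_tmax(field, gf=1.0, rho=0.8)
        assert field.tmax == pytest.approx(9.0)
        update_tmax(field, gf=0.0, rho=0.8)
        assert field.tmax == pytest.approx(9.0)  # gf = 0 leaves it unchanged
        for gf in (0.5, 0.9, 1.0):
            before = field.tmax
            update_tmax(field, gf, 0.8)
            assert field.tmax > before


class TestInertia:
    def test_decay_rule_hits_zero_at_final_iteration(self):
        params = MabcParams(wt_rule="eq5", max_iter=20)
        assert update_inertia(1.4, 20, params, np.random.default_rng(0)) == 0.0

    def test_decay_rule_printed_denominator(self):
        params = MabcParams(wt_rule="eq5", max_iter=20)
        w = update_inertia(1.4, 5, params, np.random.default_rng(0))
        assert w == pytest.approx((1.4 - 0.4) * 15 / 20.4)

    def test_corrected_decay_variant(self):
        params = MabcParams(wt_rule="eq5", eq5_corrected=True, max_iter=20)
        w = update_inertia(1.4, 5, params, np.random.default_rng(0))
        assert w == pytest.approx((1.4 - 0.4) * 15 / 20 + 0.4)

    def test_random_rule_bounds(self):
        params = MabcParams(wt_rule="eq6")
        rng = np.random.default_rng(0)
        ws = [update_inertia(1.4, i, params, rng) for i in range(200)]
        assert all(0.5 <= w <= 1.0 for w in ws)
        assert max(ws) > 0.9 and min(ws) < 0.6


class TestCommunicate:
    def make_bees(self, masks, ev):
        return [
            Bee(position=np.array(m, np.uint8), fit=ev.fitness(m),
                pbest=np.array(m, np.uint8), pbest_fit=ev.fitness(m))
            for m in masks
        ]

    def test_copies_predecessor_when_all_pheromone_high(self):
        ev = FixedFitness(4)
        bees = self.make_bees([[1, 0, 1, 0], [0, 1, 0, 1]], ev)
        field = PheromoneField.initialize(4, tmax=5.0)  # all at tmax > tmax/2
        communicate(1, bees, field, ev, np.random.default_rng(0))
        np.testing.assert_array_equal(bees[1].position, bees[0].position)

    def test_intersection_with_strong_pheromone_set(self):
        rng = np.random.default_rng(0)
        n = 30
        pred = (rng.random(n) < 0.5).astype(np.uint8)
        pred[0] = 1  # guarantee non-empty result
        ev = FixedFitness(n)
        bees = self.make_bees([pred, np.ones(n, np.uint8)], ev)
        field = PheromoneField.initialize(n, tmax=5.0)
        strong = rng.random(n) < 0.5
        strong[0] = True
        field.p[:] = np.where(strong, 4.0, 1.0)  # threshold is tmax/2 = 2.5
        communicate(1, bees, field, ev, rng)
        expected = set(np.flatnonzero(pred)) & set(np.flatnonzero(strong))
        assert set(np.flatnonzero(bees[1].position)) == expected

    def test_empty_predecessor_triggers_repair(self):
        ev = FixedFitness(4)
        bees = self.make_bees([[1, 0, 0, 0], [0, 1, 1, 0]], ev)
        bees[0].position = np.zeros(4, np.uint8)
        field = PheromoneField.initialize(4, tmax=5.0)
        communicate(1, bees, field, ev, np.random.default_rng(0))
        assert bees[1].position.sum() == 1

    def test_first_bee_has_no_predecessor(self):
        ev = FixedFitness(2)
        bees = self.make_bees([[1, 0]], ev)
        with pytest.raises(ValueError):
            communicate(0, bees, PheromoneField.initialize(2, 5.0), ev,
                        np.random.default_rng(0))


class TestUpdateBest:
    def setup_method(self):
        self.field = PheromoneField.initialize(3, tmax=5.0)
        mask = np.array([1, 1, 0], np.uint8)
        self.bee = Bee(position=mask, fit=0.5, pbest=mask.copy(), pbest_fit=0.5,
                       trial=3)
        self.state = _SwarmState(gbest=mask.copy(), gf=0.6, field=self.field)

    def test_improvement_replaces_pbest_and_resets_trial(self):
        cand = np.array([1, 0, 0], np.uint8)
        update_best(self.bee, cand, 0.7, self.state, rho=0.8)
        assert self.bee.pbest_fit == 0.7
        assert self.bee.trial == 0
        np.testing.assert_array_equal(self.bee.position, cand)

    def test_non_improvement_keeps_everything_and_increments_trial(self):
        cand = np.array([0, 1, 1], np.uint8)
        update_best(self.bee, cand, 0.4, self.state, rho=0.8)
        assert self.bee.fit == 0.5 and self.bee.pbest_fit == 0.5
        assert self.bee.trial == 4

    def test_tie_keeps_incumbent(self):
        incumbent = self.bee.position.copy()
        update_best(self.bee, np.array([0, 0, 1], np.uint8), 0.5, self.state, rho=0.8)
        np.testing.assert_array_equal(self.bee.position, incumbent)

    def test_new_global_best_grows_tmax(self):
        tmax_before = self.field.tmax
        update_best(self.bee, np.array([1, 0, 0], np.uint8), 0.9, self.state, rho=0.8)
        assert self.state.gf == 0.9
        assert self.field.tmax == pytest.approx(tmax_before * (1 + 0.8 * 0.9))


class TestScoutBias:
    def test_reinitialized_mask_favors_high_pheromone_gene(self):
        """With one gene at tmax and the rest at the floor, scout re-inits
        select that gene far more often than any other."""
        field = PheromoneField.initialize(10, tmax=5.0)
        field.p[:] = 0.0
        field.p[3] = 5.0
        rng = np.random.default_rng(0)
        counts = np.zeros(10)
        for _ in range(10_000):
            counts += init_random(field, rng, 10, alpha=0.05)
        assert counts[3] > counts[np.arange(10) != 3].max()


def small_search_setup(seed=0, n_genes=60, n_samples=24):
    spec = SyntheticSpec(n_samples=n_samples, n_genes=n_genes, n_informative=3,
                        effect_size=4.0, seed=seed)
    ds, planted = generate_dataset(spec)
    model = MabcGeneSelector(ds, params=get_preset("table2"))
    return model, planted


class TestRun:
    def test_trace_is_non_decreasing_and_seeded_runs_identical(self):
        model, _ = small_search_setup()
        res1 = model.fit(seed=5)
        res2 = MabcGeneSelector(model.dataset, params=model.params).fit(seed=5)
        fits = [f for f, _ in res1.trace]
        assert fits == sorted(fits)
        assert res1.selected_indices == res2.selected_indices
        assert res1.fitness == res2.fitness
        assert res1.trace == res2.trace

    def test_single_iteration_run_is_valid(self):
        model, _ = small_search_setup()
        params = get_preset("table2")
        params.max_iter = 1
        res = run(model.search_dataset_, params, seed=0, evaluator=model.evaluator_)
        assert res.n_selected >= 1
        assert len(res.trace) == 1

    def test_pheromone_bounds_hold_throughout(self):
        model, _ = small_search_setup()
        seen = []

        def observer(it, state):
            seen.append(
                (state.field.p.min(), state.field.p.max(), state.field.tmax)
            )

        model.fit(seed=2, observer=observer)
        tmaxes = [t for _, _, t in seen]
        assert all(lo >= 0.0 and hi <= t + 1e-12 for lo, hi, t in seen)
        assert tmaxes == sorted(tmaxes)

    def test_ablation_keeps_pheromone_frozen(self):
        model, _ = small_search_setup()
        states = []

        def observer(it, state):
            states.append((state.field.p.copy(), state.field.tmax))

        run(model.search_dataset_, model.params, seed=1,
            evaluator=model.evaluator_, ablation=True, observer=observer)
        first_p, first_tmax = states[0]
        for p, tmax in states[1:]:
            np.testing.assert_array_equal(p, first_p)
            assert tmax == first_tmax
        np.testing.assert_allclose(first_p, model.params.tmax)

    def test_selected_indices_refer_to_original_matrix(self):
        model, planted = small_search_setup()
        res = model.fit(seed=3)
        assert all(0 <= j < model.dataset.n_genes for j in res.selected_indices)
        assert all(
            model.dataset.gene_ids[j] == g
            for j, g in zip(res.selected_indices, res.selected_genes)
        )

    def test_degenerate_phase_configuration_still_improves(self):
        # probLS = 0 and r4 = 0: pure neighborhood + greedy selection
        model, _ = small_search_setup()
        params = get_preset("table2")
        params.prob_ls = 0.0
        params.r4 = 0.0
        res = run(model.search_dataset_, params, seed=4, evaluator=model.evaluator_)
        fits = [f for f, _ in res.trace]
        assert fits == sorted(fits)
        assert res.fitness >= fits[0]
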