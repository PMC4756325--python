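import numpy as np
import pytest

from rcgsim import (
    ConfigurationError,
    InteractionGraph,
    ModelParams,
    advance,
    detect_fixation,
    elementary_step,
    fermi_probability,
    imitate_profile,
    initialize_population,
    make_square_lattice,
    mc_generation,
    punish,
    run,
)


class TestFermiProbability:
    def test_closed_form_values(self):
        assert fermi_probability(1.0, 1.0, 0.1) == pytest.approx(0.5)
        # P_j - P_i = 0.2 at K = 0.1: 1 / (1 + e^-2)
        assert fermi_probability(0.0, 0.2, 0.1) == pytest.approx(0.8807970779778823)
        # P_j - P_i = -1 at K = 0.1: 1 / (1 + e^10)
        assert fermi_probability(0.0, -1.0, 0.1) == pytest.approx(4.5397868702434395e-05)

    def test_overflow_safe(self):
        assert fermi_probability(1e6, 0.0, 0.1) == 0.0
        assert fermi_probability(0.0, 1e6, 0.1) == 1.0

    def test_symmetry_and_monotonicity(self):
        # grid kept within |dP|/K <= 20 so float64 can still resolve the
        # tails (beyond that W saturates to exactly 0 or 1)
        grid = np.linspace(-2, 2, 101)
        w = np.array([fermi_probability(0.0, x, 0.1) for x in grid])
        np.testing.assert_allclose(w + w[::-1], 1.0, atol=1e-12)
        assert np.all(np.diff(w) > 0)
        assert np.all((w > 0) & (w < 1))

    def test_invalid_noise(self):
        with pytest.raises(ConfigurationError):
            fermi_probability(0.0, 0.0, 0.0)


class TestPunish:
    def test_reduces_to_population_minima(self, make_pop):
        pop = make_pop([0.5, 0.6, 0.7], [0.2, 0.05, 0.9], [0.7, 0.3, 0.4])
        punish(pop, 2)
        np.testing.assert_allclose(pop.alpha, [0.2, 0.05, 0.05])
        np.testing.assert_allclose(pop.beta, [0.7, 0.3, 0.3])
        assert pop.gamma[2] == 0.7  # real capability untouched

    def test_beta_example(self, make_pop):
        pop = make_pop([0.5] * 3, [0.5, 0.5, 0.5], [0.7, 0.3, 0.4])
        punish(pop, 0)
        np.testing.assert_allclose(pop.beta, [0.3, 0.3, 0.4])

    def test_idempotent_at_minimum(self, make_pop):
        pop = make_pop([0.5] * 3, [0.1, 0.4, 0.9], [0.2, 0.6, 0.8])
        before = (pop.alpha.copy(), pop.beta.copy())
        punish(pop, 0)  # player 0 already holds both minima
        np.testing.assert_array_equal(pop.alpha, before[0])
        np.testing.assert_array_equal(pop.beta, before[1])

    def test_never_increases_traits(self, make_pop, rng):
        for _ in range(50):
            pop = make_pop(rng.uniform(0, 1, 5), rng.uniform(0, 1, 5), rng.uniform(0, 1, 5))
            i = int(rng.integers(5))
            a0, b0 = pop.alpha[i], pop.beta[i]
            punish(pop, i)
            assert pop.alpha[i] <= a0 and pop.beta[i] <= b0


class TestImitateProfile:
    def test_certain_and_impossible_adoption(self, make_pop):
        pop = make_pop([0.5, 0.5], [0.1, 0.9], [0.2, 0.8])
        assert imitate_profile(pop, 0, 1, 1.0) == (True, True)
        assert pop.alpha[0] == 0.9 and pop.beta[0] == 0.8
        pop2 = make_pop([0.5, 0.5], [0.1, 0.9], [0.2, 0.8])
        assert imitate_profile(pop2, 0, 1, 0.0) == (False, False)
        assert pop2.alpha[0] == 0.1 and pop2.beta[0] == 0.2

    def test_independent_draws(self, make_pop):
        # With W = 1/2 the chance of adopting exactly one of the two traits
        # is 2 W (1 - W) = 1/2; check against 3 binomial standard errors.
        rng = np.random.default_rng(77)
        pop = make_pop([0.5, 0.5], [0.1, 0.9], [0.2, 0.8])
        n = 100_000
        exactly_one = 0
        for _ in range(n):
            a, b = imitate_profile(pop, 0, 1, 0.5, rng)
            exactly_one += a != b
            pop.alpha[0], pop.beta[0] = 0.1, 0.2
        se = (0.25 / n) ** 0.5
        assert abs(exactly_one / n - 0.5) < 3 * se


class TestElementaryStep:
    @staticmethod
    def _two_player_pop(make_pop, p):
        graph = InteractionGraph.from_edges(2, [(0, 1)])
        # delta = 2 forces mutual claims; gamma_0 < gamma_1 so player 0
        # always loses the conflict.
        pop = make_pop([0.2, 0.8], [0.6, 0.3], [0.5, 0.9], graph=graph, seed=5)
        params = ModelParams(r=2.5, c=1.0, delta=2.0, p=p)
        return pop, params

    def test_forced_punishment(self, make_pop):
        pop, params = self._two_player_pop(make_pop, p=1.0)
        for _ in range(60):
            event = elementary_step(pop, params)
            if event.focal == 0:
                assert event.punished
                assert not event.adopted_alpha and not event.adopted_beta
            else:
                assert not event.punished  # the winner is never punished
        # punished player's profile sits at the population minima
        assert pop.alpha[0] == pop.alpha.min()
        assert pop.beta[0] == pop.beta.min()

    def test_punishment_disabled(self, make_pop):
        pop, params = self._two_player_pop(make_pop, p=0.0)
        events = [elementary_step(pop, params) for _ in range(60)]
        assert not any(e.punished for e in events)

    def test_large_payoff_gap_forces_adoption(self, make_pop):
        # model neighbour richer by >= 1 with K = 0.1: adoption probability
        # per trait exceeds 0.9999
        graph = InteractionGraph.from_edges(2, [(0, 1)])
        pop = make_pop([0.2, 0.9], [0.0, 0.5], [0.0, 0.9], graph=graph, seed=8)
        params = ModelParams(r=2.5, c=1.0, delta=0.0, p=0.0)
        adopted = [e for e in (elementary_step(pop, params) for _ in range(40)) if e.focal == 0]
        assert all(e.adopted_alpha and e.adopted_beta for e in adopted[:1])
        assert pop.alpha[0] == pop.alpha[1] and pop.beta[0] == pop.beta[1]


class TestGenerationAndFixation:
    def test_generation_counts_and_time(self, lattice5):
        params = ModelParams(p=0.3, delta=0.5, seed=3)
        pop = initialize_population(params, lattice5)
        events = mc_generation(pop, params)
        assert len(events) == 25
        assert pop.time == 1

    def test_reference_path_deterministic(self, lattice5):
        params = ModelParams(p=0.5, delta=0.5, seed=3)
        results = []
        for _ in range(2):
            pop = initialize_population(params, lattice5)
            for _ in range(3):
                mc_generation(pop, params)
            results.append((pop.alpha.copy(), pop.beta.copy()))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        np.testing.assert_array_equal(results[0][1], results[1][1])

    def test_detect_fixation(self, make_pop):
        fixed = make_pop([0.1, 0.5, 0.9], [0.4] * 3, [0.7] * 3)
        assert detect_fixation(fixed)
        deviant = make_pop([0.1, 0.5, 0.9], [0.4, 0.4, 0.41], [0.7] * 3)
        assert not detect_fixation(deviant)

    def test_fixation_absorbing(self, make_pop, lattice5):
        # all players share one profile: no punishment or imitation event
        # can create a new value, so nothing ever changes
        pop = make_pop([0.0] * 25, [0.6] * 25, [0.8] * 25, graph=lattice5, seed=6)
        pop.gamma[:] = np.random.default_rng(1).uniform(0, 1, 25)
        params = ModelParams(p=0.0, r=3.0, delta=0.0)
        _, fixated = advance(pop, params, 100, kernel_seed=11)
        assert fixated is not None
        assert np.all(pop.alpha == 0.6) and np.all(pop.beta == 0.8)

    def test_value_set_closure_and_bounds(self, lattice5):
        # alpha/beta values only propagate by copying: the sets of distinct
        # values can only shrink, and gamma is conserved exactly
        params = ModelParams(p=0.5, delta=0.5, seed=12)
        pop = initialize_population(params, lattice5)
        alpha0, beta0 = np.sort(pop.alpha), np.sort(pop.beta)
        gamma0 = np.sort(pop.gamma)
        for _ in range(30):
            mc_generation(pop, params)
            assert np.isin(pop.alpha, alpha0).all()
            assert np.isin(pop.beta, beta0).all()
            np.testing.assert_array_equal(np.sort(pop.gamma), gamma0)
            assert np.all((pop.alpha >= 0) & (pop.alpha <= 1))
            assert np.all((pop.beta >= 0) & (pop.beta <= 1))


class TestCompiledPath:
    def test_kernel_matches_reference_distribution(self):
        # same model, two independent implementations (interpreted reference
        # vs compiled kernel): stationary levels must agree within a few
        # replicate standard errors under strong sanction
        graph = make_square_lattice(10)
        params = ModelParams(r=2.5, c=1.0, delta=1.0, p=1.0, seed=0)
        ref, fast = [], []
        for seed in range(8):
            pop = initialize_population(ModelParams(delta=1.0, p=1.0, seed=seed), graph)
            for _ in range(120):
                mc_generation(pop, params)
            ref.append((pop.alpha.mean(), pop.beta.mean()))
            pop = initialize_population(ModelParams(delta=1.0, p=1.0, seed=seed), graph)
            advance(pop, params, 120, kernel_seed=seed * 7 + 1)
            fast.append((pop.alpha.mean(), pop.beta.mean()))
        ref, fast = np.array(ref), np.array(fast)
        assert abs(ref[:, 0].mean() - fast[:, 0].mean()) < 0.12
        assert abs(ref[:, 1].mean() - fast[:, 1].mean()) < 0.12

    def test_run_reproducible_and_bounded(self):
        graph = make_square_lattice(5)
        params = ModelParams(
            p=0.5, delta=0.5, relax_steps=10, measure_steps=10, n_runs=2, seed=21
        )
        a = run(params, graph)
        b = run(params, graph)
        assert a.levels == b.levels
        series = a.replicates[0]
        assert series.n_generations == 10
        assert np.all((series.mean_alpha >= 0) & (series.mean_alpha <= 1))
        assert np.all((series.mean_beta >= 0) & (series.mean_beta <= 1))
        assert np.all(series.punish_count <= 25)

    def test_run_snapshots(self):
        graph = make_square_lattice(5)
        params = ModelParams(
            p=0.0, delta=0.2, relax_steps=20, measure_steps=5, n_runs=1, seed=4
        )
        result = run(params, graph, snapshot_gens=[0, 10, 20])
        snaps = result.replicates[0].snapshots
        assert set(snaps) == {0, 10, 20}
        assert all(a.shape == (25,) and b.shape == (25,) for a, b in snaps.values())

    def test_early_fixation_reported(self):
        graph = make_square_lattice(3)
        params = ModelParams(
            p=0.0, r=3.0, delta=0.0, relax_steps=2000, measure_steps=50,
            n_runs=1, seed=2,
        )
        result = run(params, graph)
        # 9 players without punishment coalesce quickly; the frozen profile
        # is reported as a constant measurement trace
        if result.fixated_fraction == 1.0:
            series = result.replicates[0]
            assert series.mean_alpha.std() == 0.0
            assert detect_fixation(result.population)
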