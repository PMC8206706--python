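import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitwalk.pairs import pair_labels
from traitwalk.sim import (
    Individual,
    Population,
    SimConfig,
    fitness,
    init_population,
    run,
    select,
    step_generation,
    trait_and_corr_change,
    trait_change,
)


class TestSimConfig:
    def test_defaults(self):
        cfg = SimConfig()
        assert cfg.n_individuals == 1000
        assert cfg.generations == 2000
        assert cfg.replicates == 100
        assert cfg.p_corr == pytest.approx(0.10)
        assert cfg.step_sd == pytest.approx(0.05)
        assert cfg.propagation == "replace"

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            SimConfig.from_dict({"n_individuals": 10, "bogus": 1})

    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(p_corr=1.5)
        with pytest.raises(ValueError):
            SimConfig(propagation="sideways")
        with pytest.raises(ValueError):
            SimConfig(mode="A9never")

    def test_start_spec_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="weights"):
            SimConfig(start_spec=[(0.5, np.zeros(4)), (0.2, np.ones(4))])

    def test_config_hash_stable(self):
        assert SimConfig().config_hash() == SimConfig().config_hash()
        assert SimConfig().config_hash() != SimConfig(step_sd=0.01).config_hash()


class TestInitPopulation:
    def test_mixed_mode_uniform_moments(self, ref_scape, rng):
        cfg = SimConfig(n_individuals=20000, mode="mixed")
        pop = init_population(cfg, ref_scape, rng=rng)
        # Uniform(-1, 1): mean 0, variance 1/3
        assert np.all(np.abs(pop.corr.mean(axis=0)) < 0.02)
        np.testing.assert_allclose(pop.corr.var(axis=0), 1 / 3, atol=0.01)
        assert np.all(pop.traits == ref_scape.start_traits[None, :])

    def test_a2_pins_top_two_ancestral_pairs(self, ref_scape, ref_corr, rng):
        cfg = SimConfig(n_individuals=500, mode="A2")
        pop = init_population(cfg, ref_scape, ref_corr, rng=rng)
        pinned = ref_corr.top_ranked("ancestral", 2)
        for pair_idx, r in pinned:
            np.testing.assert_allclose(pop.corr[:, pair_idx], r)
        free = [i for i in range(6) if i not in [i for i, _ in pinned]]
        for i in free:
            assert pop.corr[:, i].std() > 0.1  # varies across individuals

    def test_e_mode_pins_evolved_values(self, ref_scape, ref_corr, rng):
        cfg = SimConfig(n_individuals=200, mode="E1")
        pop = init_population(cfg, ref_scape, ref_corr, rng=rng)
        pair_idx, r = ref_corr.top_ranked("evolved", 1)[0]
        np.testing.assert_allclose(pop.corr[:, pair_idx], r)

    def test_bias_mode_without_table_rejected(self, ref_scape, rng):
        with pytest.raises(ValueError, match="correlation table"):
            init_population(SimConfig(mode="A1"), ref_scape, rng=rng)

    def test_uncorrelated_mode_zero_corr(self, ref_scape, rng):
        cfg = SimConfig(n_individuals=100, mode="uncorrelated")
        pop = init_population(cfg, ref_scape, rng=rng)
        np.testing.assert_allclose(pop.corr, 0.0)

    def test_multi_start_exact_quarters(self, ref_scape, rng):
        starts = [(0.25, np.full(4, float(i))) for i in range(4)]
        cfg = SimConfig(n_individuals=1000, start_spec=starts)
        pop = init_population(cfg, ref_scape, rng=rng)
        for i in range(4):
            assert np.sum(np.all(pop.traits == float(i), axis=1)) == 250


class TestTraitChange:
    def test_replace_with_zero_corr_zeroes_other_traits(self, rng):
        ind = Individual(np.array([0.5, 0.7, -0.3]), np.zeros(3))
        out = trait_change(ind, rng, step_sd=0.05, propagation="replace")
        changed = np.flatnonzero(out.traits != 0.0)
        assert changed.size == 1  # all non-focal traits replaced by 0

    def test_replace_hand_computation(self):
        # K=2, traits (0.5, 0), corr=1, focal trait 1, delta=+0.1 -> (0.6, 0.6)
        ind = Individual(np.array([0.5, 0.0]), np.array([1.0]))
        out = _forced_trait_change(ind, k=0, delta=0.1, propagation="replace")
        np.testing.assert_allclose(out.traits, [0.6, 0.6])

    def test_delta_hand_computation(self):
        ind = Individual(np.array([0.5, 0.0]), np.array([1.0]))
        out = _forced_trait_change(ind, k=0, delta=0.1, propagation="delta")
        np.testing.assert_allclose(out.traits, [0.6, 0.1])

    def test_uncorrelated_only_delta_applied(self, rng):
        ind = Individual(np.array([0.5, 0.7]), np.array([0.9]))
        out = trait_change(ind, rng, step_sd=0.05, propagation="replace",
                           uncorrelated=True)
        assert np.sum(out.traits != ind.traits) == 1

    def test_corr_untouched(self, rng):
        ind = Individual(np.zeros(4), np.linspace(-1, 1, 6))
        out = trait_change(ind, rng)
        np.testing.assert_array_equal(out.corr, ind.corr)


def _forced_trait_change(ind, k, delta, propagation):
    """Deterministic helper: inject the focal index and step by rigging rng."""

    class Rigged:
        def integers(self, *a, **k2):
            return k

        def normal(self, *a, **k2):
            return delta

    return trait_change(ind, Rigged(), propagation=propagation)


class TestTraitAndCorrChange:
    def test_clipping_at_plus_one(self):
        ind = Individual(np.zeros(2), np.array([0.98]))

        class Rigged:
            calls = 0

            def integers(self, *a, **k):
                return 0

            def normal(self, *a, **k):
                Rigged.calls += 1
                return 0.10 if Rigged.calls == 1 else 0.0

        out = trait_and_corr_change(ind, Rigged())
        assert out.corr[0] == pytest.approx(1.0)

    def test_hand_computation_four_traits(self):
        # pair 1v2, corr_new = 0.5, first = trait 1, delta = 0.2
        ind = Individual(np.zeros(4), np.zeros(6))

        class Rigged:
            normals = iter([0.5, 0.2])

            def integers(self, *a, **k):
                return 0  # pair index 0 = (1,2); endpoint choice 0 = first

            def normal(self, *a, **k):
                return next(Rigged.normals)

        out = trait_and_corr_change(ind, Rigged())
        np.testing.assert_allclose(out.traits, [0.2, 0.1, 0.0, 0.0])
        assert out.corr[0] == pytest.approx(0.5)

    def test_pair_choice_uniform(self, rng):
        # chi-square on the chosen-pair frequencies vs Uniform(1/6)
        n = 120_000
        ind = Individual(np.zeros(4), np.zeros(6))
        counts = np.zeros(6)
        for _ in range(n):
            out = trait_and_corr_change(ind, rng, step_sd=0.5)
            changed = np.flatnonzero(out.corr != 0.0)
            counts[changed[0]] += 1
        expected = n / 6
        chi2 = np.sum((counts - expected) ** 2 / expected)
        # df = 5; P(chi2 > 20.5) ~ 0.001
        assert chi2 < 20.5

    def test_only_selected_pair_and_traits_move(self, rng):
        ind = Individual(np.ones(4), np.full(6, 0.5))
        out = trait_and_corr_change(ind, rng)
        assert np.sum(out.corr != ind.corr) <= 1
        assert np.sum(out.traits != ind.traits) <= 2


class TestFitness:
    def test_at_endpoint_is_one(self, ref_scape):
        traits = ref_scape.loadings[:, :2] @ ref_scape.end
        assert fitness(traits, ref_scape) == pytest.approx(1.0)

    def test_unit_distance(self, ref_scape):
        off = ref_scape.end + np.array([1.0, 0.0])
        traits = ref_scape.loadings[:, :2] @ off
        assert fitness(traits, ref_scape) == pytest.approx(np.exp(-0.5))

    def test_distance_ten(self, ref_scape):
        off = ref_scape.end + np.array([10.0, 0.0])
        traits = ref_scape.loadings[:, :2] @ off
        w = fitness(traits, ref_scape)
        assert w == pytest.approx(np.exp(-50.0))
        assert w > 0

    def test_strictly_decreasing_in_distance(self, ref_scape):
        zs = np.linspace(0, 5, 40)
        ws = [
            fitness(ref_scape.loadings[:, :2] @ (ref_scape.end + [z, 0.0]), ref_scape)
            for z in zs
        ]
        assert np.all(np.diff(ws) < 0)


class TestSelect:
    def test_all_zero_weights_rejected(self, rng):
        pop = Population(np.zeros((3, 2)), np.zeros((3, 1)))
        with pytest.raises(ValueError, match="zero"):
            select(pop, np.zeros(3), rng)

    def test_near_fixation_of_dominant_weight(self, rng):
        pop = Population(np.arange(8, dtype=float).reshape(4, 2), np.zeros((4, 1)))
        w = np.array([1.0, 1e-300, 1e-300, 1e-300])
        new, idx = select(pop, w, rng)
        assert np.all(idx == 0)

    def test_binomial_offspring_share(self, rng):
        # weights (0.8, 0.2), N = 1e5: parent-1 share within 3 binomial sigma
        n = 100_000
        pop = Population(
            np.repeat(np.array([[0.0], [1.0]]), [n // 2, n // 2], axis=0),
            np.zeros((n, 1)),
        )
        w = np.where(pop.traits[:, 0] == 0.0, 0.8 / (n // 2), 0.2 / (n // 2))
        new, idx = select(pop, w, rng)
        share = np.mean(new.traits[:, 0] == 0.0)
        sigma = np.sqrt(0.8 * 0.2 / n)
        assert abs(share - 0.8) < 3 * sigma

    def test_offspring_are_exact_copies(self, rng):
        traits = rng.normal(size=(10, 4))
        corr = rng.uniform(-1, 1, size=(10, 6))
        pop = Population(traits, corr)
        new, idx = select(pop, np.ones(10), rng)
        np.testing.assert_array_equal(new.traits, traits[idx])
        np.testing.assert_array_equal(new.corr, corr[idx])


class TestStepGeneration:
    def test_exact_ninety_ten_split(self, ref_scape, ref_corr):
        # With step_sd tiny but nonzero, count which individuals got a corr
        # change by watching the corr matrix.
        cfg = SimConfig(n_individuals=1000, p_corr=0.1, step_sd=1e-6, mode="mixed")
        rng = np.random.default_rng(0)
        pop = init_population(cfg, ref_scape, rng=rng)
        before = pop.corr.copy()
        from traitwalk.sim import _mutate_population
        from traitwalk.pairs import pair_index_matrix

        _mutate_population(pop, cfg, pair_index_matrix(4), rng)
        changed = np.sum(np.any(pop.corr != before, axis=1))
        assert changed == 100

    def test_step_sd_zero_is_identity_mutation(self, ref_scape):
        cfg = SimConfig(n_individuals=200, step_sd=0.0, mode="mixed")
        rng = np.random.default_rng(1)
        pop = init_population(cfg, ref_scape, rng=rng)
        before_t, before_c = pop.traits.copy(), pop.corr.copy()
        from traitwalk.sim import _mutate_population
        from traitwalk.pairs import pair_index_matrix

        _mutate_population(pop, cfg, pair_index_matrix(4), rng)
        np.testing.assert_array_equal(pop.traits, before_t)
        np.testing.assert_array_equal(pop.corr, before_c)

    def test_population_size_preserved(self, ref_scape):
        cfg = SimConfig(n_individuals=57, mode="mixed", generations=3, replicates=1)
        rng = np.random.default_rng(2)
        pop = init_population(cfg, ref_scape, rng=rng)
        new, fit = step_generation(pop, cfg, ref_scape, rng)
        assert new.size == 57
        assert fit.shape == (57,)


class TestRun:
    def test_same_seed_bit_identical(self, ref_scape, ref_corr):
        cfg = SimConfig(n_individuals=40, generations=20, replicates=2,
                        base_seed=99, mode="mixed")
        a = run(cfg, ref_scape, ref_corr)
        b = run(cfg, ref_scape, ref_corr)
        for ra, rb in zip(a, b):
            assert ra.summary.equals(rb.summary)
            assert ra.final.equals(rb.final)

    def test_zero_generations_only_initial_state(self, ref_scape):
        cfg = SimConfig(n_individuals=30, generations=0, replicates=1, mode="mixed")
        res = run(cfg, ref_scape)[0]
        assert len(res.summary) == 1
        assert res.summary.loc[0, "generation"] == 0

    def test_generation_axis_length(self, ref_scape):
        cfg = SimConfig(n_individuals=30, generations=15, replicates=1, mode="mixed")
        res = run(cfg, ref_scape)[0]
        assert len(res.summary) == 16

    def test_replicate_seeds_offset_from_base(self, ref_scape):
        cfg = SimConfig(n_individuals=20, generations=2, replicates=3,
                        base_seed=7, mode="mixed")
        res = run(cfg, ref_scape)
        assert [r.seed for r in res] == [7, 8, 9]

    def test_correlations_bounded_over_trajectory(self, ref_scape, ref_corr):
        cfg = SimConfig(n_individuals=60, generations=150, replicates=2,
                        base_seed=3, mode="mixed", step_sd=0.3)
        for res in run(cfg, ref_scape, ref_corr):
            corr_cols = [c for c in res.summary.columns if c.startswith("mean_corr_")]
            assert (res.summary[corr_cols].abs() <= 1.0 + 1e-12).all().all()
            assert np.all(np.abs(res.final_corr()) <= 1.0)

    def test_fitness_in_unit_interval(self, ref_scape):
        cfg = SimConfig(n_individuals=50, generations=50, replicates=1,
                        base_seed=1, mode="mixed")
        res = run(cfg, ref_scape)[0]
        f = res.final["fitness"].to_numpy()
        assert np.all((f > 0) & (f <= 1))
        assert np.all((res.summary["mean_fitness"] > 0)
                      & (res.summary["mean_fitness"] <= 1))

    def test_frozen_correlations_without_corr_channel(self, ref_scape):
        cfg = SimConfig(n_individuals=40, generations=30, replicates=1,
                        base_seed=4, mode="mixed", p_corr=0.0)
        res = run(cfg, ref_scape)[0]
        # every final corr vector must equal one of the initial vectors
        rng = np.random.default_rng(4)
        init = init_population(cfg, ref_scape, rng=rng)
        init_set = {tuple(np.round(r, 12)) for r in init.corr}
        for row in res.final_corr():
            assert tuple(np.round(row, 12)) in init_set


class TestSelectionResponse:
    def test_doubling_weight_increases_offspring_share(self, rng):
        # multinomial oracle: share ratio tracks the weight ratio
        n = 200_000
        w1 = np.array([1.0, 1.0, 1.0, 1.0])
        w2 = np.array([2.0, 1.0, 1.0, 1.0])
        s1 = np.mean(rng.choice(4, size=n, p=w1 / w1.sum()) == 0)
        s2 = np.mean(rng.choice(4, size=n, p=w2 / w2.sum()) == 0)
        assert s2 > s1
        assert s2 == pytest.approx(0.4, abs=0.01)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_property_corr_always_bounded(seed):
    ind = Individual(np.zeros(4), np.random.default_rng(seed).uniform(-1, 1, 6))
    out = trait_and_corr_change(ind, np.random.default_rng(seed + 1), step_sd=2.0)
    assert np.all(np.abs(out.corr) <= 1.0)
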