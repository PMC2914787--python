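import numpy as np
import pytest
from scipy.stats import kstest

from speciesim.landscape import FitnessGrid, Landscape, LandscapeConfig, init_grid
from speciesim.population import (
    ExtinctionError,
    Organism,
    PopulationState,
    ReproductionConfig,
    _death_mask,
    _draw_normal_coords,
    _draw_uniform_coords,
    _thin_mask,
    assign_mates,
    draw_offspring_coord_normal,
    draw_offspring_coord_uniform,
    init_population,
    nearest_neighbors,
    random_death,
    reproduce,
    step_generation,
    thin_overcrowded,
)

from oracles import brute_nearest_two, greedy_thin

RCFG = ReproductionConfig()


def constant_landscape(value, mode="static"):
    cfg = LandscapeConfig(mode=mode)
    return Landscape(
        FitnessGrid(np.full((cfg.coarse_size, cfg.coarse_size), float(value))), cfg
    )


class TestInitPopulation:
    def test_size_generation_and_bounds(self, rng):
        state = init_population(300, rng, RCFG)
        assert state.size == 300 and state.generation == 0
        assert np.all(state.coords >= 0) and np.all(state.coords <= 45)
        assert np.all(state.mu == RCFG.mu)

    def test_determinism(self):
        a = init_population(50, np.random.default_rng(9), RCFG)
        b = init_population(50, np.random.default_rng(9), RCFG)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_competition_mu_uniform_on_unit_interval(self, rng):
        cfg = ReproductionConfig(competition_mode=True)
        state = init_population(10_000, rng, cfg)
        se = np.sqrt(1 / 12 / 10_000)
        assert abs(state.mu.mean() - 0.5) < 3 * se
        assert state.mu.min() >= 0 and state.mu.max() <= 1

    def test_rejects_empty(self, rng):
        with pytest.raises(ValueError):
            init_population(0, rng, RCFG)


class TestAssignMates:
    def test_two_organisms_are_mutual(self):
        orgs = [Organism(0, (1.0, 1.0)), Organism(1, (5.0, 5.0))]
        assert assign_mates(orgs) == {0: 1, 1: 0}

    def test_three_collinear(self):
        # x = 0, 1, 3: organism 2 is nearer to 1 than to 0
        orgs = [Organism(i, (x, 10.0)) for i, x in enumerate([0.0, 1.0, 3.0])]
        assert assign_mates(orgs) == {0: 1, 1: 0, 2: 1}

    def test_never_self(self, rng):
        orgs = [
            Organism(i, tuple(c)) for i, c in enumerate(rng.uniform(0, 45, (40, 2)))
        ]
        mates = assign_mates(orgs)
        assert all(oid != mate for oid, mate in mates.items())

    def test_single_organism_signals_extinction(self):
        with pytest.raises(ExtinctionError):
            assign_mates([Organism(0, (1.0, 1.0))])

    @pytest.mark.parametrize("n", [5, 60, 300])
    def test_matches_brute_force(self, n, rng):
        # n spans the brute-force and KD-tree paths
        coords = rng.uniform(0, 45, size=(n, 2))
        nn, nn2 = nearest_neighbors(coords)
        onn, onn2 = brute_nearest_two(coords)
        np.testing.assert_array_equal(nn, onn)
        np.testing.assert_array_equal(nn2, onn2)


class TestUniformKernel:
    def test_degenerate_interval(self, rng):
        out = draw_offspring_coord_uniform((10.0, 10.0), (10.0, 10.0), 0.0, rng)
        np.testing.assert_array_equal(out, [10.0, 10.0])

    def test_zero_mu_confined_to_parent_box(self, rng):
        for _ in range(200):
            out = draw_offspring_coord_uniform((10.0, 10.0), (12.0, 14.0), 0.0, rng)
            assert 10.0 <= out[0] <= 12.0
            assert 10.0 <= out[1] <= 14.0

    def test_distribution_uniform_over_extended_interval(self, rng):
        # parents at x = 10 and 12 with mu = 1: x uniform on [9, 13]
        m = 100_000
        p1 = np.tile([10.0, 20.0], (m, 1))
        p2 = np.tile([12.0, 20.0], (m, 1))
        out = _draw_uniform_coords(p1, p2, np.ones(m), rng, 45.0)
        assert kstest(out[:, 0], "uniform", args=(9.0, 4.0)).pvalue > 0.001

    def test_mu_extended_bound(self, rng):
        p1 = rng.uniform(0, 45, (500, 2))
        p2 = rng.uniform(0, 45, (500, 2))
        mu = rng.uniform(0, 2, 500)
        out = _draw_uniform_coords(p1, p2, mu, rng, 45.0)
        lo = np.minimum(p1, p2) - mu[:, None]
        hi = np.maximum(p1, p2) + mu[:, None]
        assert np.all(out >= np.maximum(lo, 0.0) - 1e-12)
        assert np.all(out <= np.minimum(hi, 45.0) + 1e-12)
        assert np.all(out >= 0) and np.all(out <= 45)


class TestNormalKernel:
    def test_degenerate_interval(self, rng):
        out = draw_offspring_coord_normal((10.0, 10.0), (10.0, 10.0), 0.0, 0.1581, rng)
        np.testing.assert_array_equal(out, [10.0, 10.0])

    def test_truncation_contract(self, rng):
        p1 = rng.uniform(0, 45, (500, 2))
        p2 = rng.uniform(0, 45, (500, 2))
        mu = rng.uniform(0, 2, 500)
        out = _draw_normal_coords(p1, p2, mu, 0.1581, rng, 45.0)
        lo = np.maximum(np.minimum(p1, p2) - mu[:, None], 0.0)
        hi = np.minimum(np.maximum(p1, p2) + mu[:, None], 45.0)
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_spread_matches_rejection_oracle(self, rng):
        # coincident parents at 20 with mu = 1: compare to a scalar rejection
        # sampler with identical parameters
        from oracles import rejection_normal_axis

        m = 100_000
        p = np.tile([20.0, 20.0], (m, 1))
        out = _draw_normal_coords(p, p, np.ones(m), 0.1581, rng, 45.0)
        oracle = rejection_normal_axis(
            20.0, 20.0, 1.0, 0.1581, 45.0, np.random.default_rng(77), m
        )
        assert out[:, 0].std() == pytest.approx(oracle.std(), rel=0.01)


class TestReproduce:
    def _pair_state(self, mu=0.35, competition=False, mus=(0.35, 0.35)):
        orgs = [
            Organism(0, (10.0, 10.0), mu=mus[0]),
            Organism(1, (10.5, 10.0), mu=mus[1]),
        ]
        return PopulationState.from_organisms(orgs)

    def test_brood_size_from_fitness(self, rng):
        state = self._pair_state()
        land = constant_landscape(3.0)
        kids = reproduce(state, land, RCFG, rng)
        assert len(kids) == 6  # 3 offspring per organism
        assert {k.parent_ids for k in kids} == {(0, 1), (1, 0)}

    def test_label_propagation(self, rng):
        state = self._pair_state()
        land = constant_landscape(2.0)
        kids = reproduce(state, land, RCFG, rng)
        assert not any(k.labeled for k in kids)
        state.labeled[0] = True
        kids = reproduce(state, land, RCFG, rng)
        assert all(k.labeled for k in kids)  # either-parent descent

    def test_competition_inheritance_fair_coin(self, rng):
        # far-apart pairs with mu 0.2 / 0.8; fitness 4 -> 10^4 offspring
        cfg = ReproductionConfig(competition_mode=True)
        n_pairs = 1250
        centers = np.column_stack(
            [
                2.0 + 40.0 * (np.arange(n_pairs) % 36) / 36.0,
                2.0 + 40.0 * (np.arange(n_pairs) // 36) / 36.0,
            ]
        )
        orgs = []
        for k, (cx, cy) in enumerate(centers):
            orgs.append(Organism(2 * k, (cx, cy), mu=0.2))
            orgs.append(Organism(2 * k + 1, (cx + 0.05, cy), mu=0.8))
        state = PopulationState.from_organisms(orgs)
        kids = reproduce(state, constant_landscape(4.0), cfg, rng)
        mus = np.array([k.mu for k in kids])
        frac = (mus == 0.2).mean()
        se = 0.5 / np.sqrt(len(mus))
        assert abs(frac - 0.5) < 3 * se
        assert set(np.unique(mus)) == {0.2, 0.8}

    def test_single_parent_is_extinction(self, rng):
        state = PopulationState.from_organisms([Organism(0, (5.0, 5.0))])
        with pytest.raises(ExtinctionError):
            reproduce(state, constant_landscape(2.0), RCFG, rng)


class TestRandomDeath:
    def test_zero_max_keeps_everyone(self, rng):
        cfg = ReproductionConfig(death_fraction_max=0.0)
        orgs = [Organism(i, (1.0 + i, 1.0)) for i in range(30)]
        assert random_death(orgs, rng, cfg) == orgs

    def test_forced_rho_removes_exact_count(self, rng):
        orgs = [Organism(i, (1.0 + 0.01 * i, 1.0)) for i in range(100)]
        assert len(random_death(orgs, rng, RCFG, rho=0.5)) == 50

    def test_mean_removed_fraction(self, rng):
        # rho ~ U(0, 0.70) has mean 0.35
        n = 1000
        fracs = [1 - _death_mask(n, rng, 0.70).mean() for _ in range(2000)]
        se = 0.70 / np.sqrt(12) / np.sqrt(2000)
        assert abs(np.mean(fracs) - 0.35) < 3 * se


class TestThinning:
    def test_conflicting_pair_keeps_exactly_one(self, rng):
        orgs = [Organism(0, (10.0, 10.0)), Organism(1, (10.1, 10.0))]
        assert len(thin_overcrowded(orgs, 0.25, rng)) == 1

    def test_spaced_input_unchanged(self, rng):
        orgs = [Organism(i, (10.0 + 0.3 * i, 10.0)) for i in range(10)]
        assert thin_overcrowded(orgs, 0.25, rng) == orgs

    def test_line_of_five_identity_order(self, rng):
        orgs = [Organism(i, (10.0 + 0.2 * i, 10.0)) for i in range(5)]
        out = thin_overcrowded(orgs, 0.25, rng, order=np.arange(5))
        assert [o.id for o in out] == [0, 2, 4]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_greedy_oracle_and_spacing(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 3, size=(120, 2))  # dense -> many conflicts
        order = rng.permutation(120)
        mask = _thin_mask(coords, 0.25, rng, order=order)
        kept = sorted(np.flatnonzero(mask))
        assert kept == greedy_thin(coords, 0.25, order)
        survivors = coords[mask]
        diff = survivors[:, None] - survivors[None, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.25


class TestStepGeneration:
    def test_extinction_signal(self, rng):
        state = PopulationState.from_organisms([Organism(0, (5.0, 5.0))])
        with pytest.raises(ExtinctionError):
            step_generation(state, constant_landscape(2.0), RCFG, rng)

    def test_zero_mu_offspring_confined_to_parent_box(self, rng):
        cfg = ReproductionConfig(mu=0.0)
        orgs = [Organism(0, (10.0, 10.0)), Organism(1, (10.5, 10.3))]
        state = PopulationState.from_organisms(orgs)
        new, _ = step_generation(state, constant_landscape(4.0), cfg, rng)
        assert np.all(new.coords[:, 0] >= 10.0) and np.all(new.coords[:, 0] <= 10.5)
        assert np.all(new.coords[:, 1] >= 10.0) and np.all(new.coords[:, 1] <= 10.3)

    def test_bitwise_deterministic_trajectory(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            cfg = LandscapeConfig(mode="shifting")
            land = Landscape(init_grid(rng, cfg), cfg)
            state = init_population(100, rng, RCFG)
            for _ in range(10):
                state, land = step_generation(state, land, RCFG, rng)
                if state.extinct:
                    break
            return state

        a, b = run(42), run(42)
        assert a.generation == b.generation
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.ids, b.ids)

    def test_coords_always_in_bounds_and_ids_unique(self, rng):
        cfg = LandscapeConfig(mode="shifting")
        land = Landscape(init_grid(rng, cfg), cfg)
        state = init_population(100, rng, RCFG)
        for _ in range(15):
            state, land = step_generation(state, land, RCFG, rng)
            assert np.all(state.coords >= 0) and np.all(state.coords <= 45)
            assert len(np.unique(state.ids)) == state.size
            if state.extinct:
                break


class TestMutationBoundInvariant:
    @pytest.mark.parametrize("kernel", ["uniform", "normal"])
    def test_offspring_within_mu_extended_parent_interval(self, kernel, rng):
        cfg = ReproductionConfig(mu=0.4, kernel=kernel)
        orgs = [
            Organism(i, tuple(c)) for i, c in enumerate(rng.uniform(0, 45, (30, 2)))
        ]
        state = PopulationState.from_organisms(orgs)
        by_id = {o.id: np.array(o.coords) for o in orgs}
        kids = reproduce(state, constant_landscape(4.0), cfg, rng)
        for kid in kids:
            pa, pb = (by_id[p] for p in kid.parent_ids)
            lo = np.maximum(np.minimum(pa, pb) - cfg.mu, 0.0)
            hi = np.minimum(np.maximum(pa, pb) + cfg.mu, 45.0)
            assert np.all(np.array(kid.coords) >= lo - 1e-12)
            assert np.all(np.array(kid.coords) <= hi + 1e-12)


class TestCompetitionMuClosure:
    def test_no_new_mu_values_ever_appear(self, rng):
        cfg = ReproductionConfig(competition_mode=True)
        lcfg = LandscapeConfig(mode="shifting")
        land = Landscape(init_grid(rng, lcfg), lcfg)
        state = init_population(200, rng, cfg)
        founder_values = set(state.mu.tolist())
        previous = founder_values
        for _ in range(12):
            state, land = step_generation(state, land, cfg, rng)
            if state.extinct:
                break
            current = set(state.mu.tolist())
            assert current <= previous  # values can vanish, never (re)appear
            previous = current
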