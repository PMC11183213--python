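"""Per-process and whole-run behaviour of the lattice engine."""

import numpy as np
import pytest
from scipy import stats

from psfsim.engine import (
    EMPTY,
    GridState,
    SimConfig,
    establishment_rate,
    initialise,
    introduce_invader,
    run_simulation,
    step_growth,
    step_immigration,
    step_mortality,
    step_recruitment,
)
from psfsim.networks import (
    ScenarioSpec,
    apply_conspecific,
    build_null,
    build_scenario_table,
)


def small_config(**kw):
    defaults = dict(grid_side=20, n_steps=50, invasion_step=40, n_invaders=10,
                    record_every=10, rng_seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture
def null_table():
    return build_null(100)


@pytest.fixture
def populated(null_table):
    """A partially filled 20x20 grid after a few steps of dynamics."""
    cfg = small_config(p_immigration=0.05)
    rng = np.random.default_rng(42)
    state = initialise(cfg, null_table)
    for step in range(1, 11):
        step_immigration(state, cfg, null_table, rng)
        if step > 1:
            step_recruitment(state, cfg, null_table, rng)
        step_growth(state, cfg, rng)
        step_mortality(state, cfg, rng)
    assert state.n_occupied > 0
    return state, cfg


class TestInitialise:
    def test_grid_starts_empty_and_unconditioned(self, null_table):
        cfg = small_config()
        state = initialise(cfg, null_table)
        assert state.n_occupied == 0
        assert np.all(state.soil == null_table.unconditioned)
        assert state.biomass.sum() == 0.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(p_immigration=1.5)
        with pytest.raises(ValueError):
            SimConfig(p_mortality=-0.1)
        with pytest.raises(ValueError):
            SimConfig(n_steps=0)
        with pytest.raises(ValueError):
            SimConfig(cap_mode="bogus")


class TestImmigration:
    def test_zero_probability_is_identity(self, null_table):
        cfg = small_config(p_immigration=0.0)
        state = initialise(cfg, null_table)
        step_immigration(state, cfg, null_table, np.random.default_rng(1))
        assert state.n_occupied == 0

    def test_immigrants_establish_at_standard_rate_on_virgin_soil(
        self, null_table
    ):
        cfg = small_config(p_immigration=1.0)
        state = initialise(cfg, null_table)
        step_immigration(state, cfg, null_table, np.random.default_rng(1))
        assert state.n_occupied == cfg.n_cells
        assert np.all(state.growth_rate == 1.65)
        assert np.array_equal(state.soil, state.occupant)

    def test_count_matches_binomial_law(self, null_table):
        cfg = small_config(p_immigration=0.01)
        rng = np.random.default_rng(7)
        counts = []
        for _ in range(300):
            state = initialise(cfg, null_table)
            step_immigration(state, cfg, null_table, rng)
            counts.append(state.n_occupied)
        total = sum(counts)
        n_trials = 300 * cfg.n_cells
        p = stats.binomtest(total, n_trials, cfg.p_immigration).pvalue
        assert p > 1e-3

    def test_species_uniform_and_never_invader(self, null_table):
        cfg = small_config(p_immigration=1.0)
        rng = np.random.default_rng(3)
        draws = []
        for _ in range(30):
            state = initialise(cfg, null_table)
            step_immigration(state, cfg, null_table, rng)
            draws.append(state.occupant.ravel().copy())
        draws = np.concatenate(draws)
        assert draws.max() < 100  # the invader never immigrates
        freq = np.bincount(draws, minlength=100)
        p = stats.chisquare(freq).pvalue
        assert p > 1e-3


class TestRecruitment:
    def test_empty_community_no_recruits(self, null_table):
        cfg = small_config()
        state = initialise(cfg, null_table)
        step_recruitment(state, cfg, null_table, np.random.default_rng(0))
        assert state.n_occupied == 0

    def test_fills_every_empty_cell(self, populated, null_table):
        state, cfg = populated
        step_recruitment(state, cfg, null_table, np.random.default_rng(5))
        assert state.n_occupied == cfg.n_cells

    def test_species_proportional_to_biomass(self, null_table):
        # seed three species with biomass 60/30/10 and count recruit draws
        cfg = small_config(grid_side=50)
        rng = np.random.default_rng(11)
        counts = np.zeros(101)
        for _ in range(5):
            state = initialise(cfg, null_table)
            state.occupant[0, :3] = [0, 1, 2]
            state.biomass[0, :3] = [60.0, 30.0, 10.0]
            state.growth_rate[0, :3] = 1.65
            state.soil[0, :3] = [0, 1, 2]
            before = state.occupant.copy()
            step_recruitment(state, cfg, null_table, rng)
            new = state.occupant[before == EMPTY]
            counts += np.bincount(new, minlength=101)
        observed = counts[:3]
        p = stats.chisquare(observed, counts.sum() * np.array([0.6, 0.3, 0.1])).pvalue
        assert p > 1e-3
        assert counts[3:].sum() == 0

    def test_recruit_rate_follows_soil(self):
        table = apply_conspecific(build_null(100))
        cfg = small_config()
        rng = np.random.default_rng(2)
        state = initialise(cfg, table)
        # monoculture of species 7 conditions everything it touches
        state.occupant[5, 5] = 7
        state.biomass[5, 5] = 50.0
        state.growth_rate[5, 5] = 1.65
        state.soil[:, :] = 7
        step_recruitment(state, cfg, table, rng)
        recruits = (state.occupant == 7) & (state.biomass == cfg.initial_biomass)
        # conspecific soil + negative conspecific feedback -> slow
        assert np.all(state.growth_rate[recruits] == 1.49)


class TestEstablishmentRate:
    def test_table_lookup_values(self, null_table):
        table = apply_conspecific(build_null(100))
        inv, unc = table.invader, table.unconditioned
        assert establishment_rate(inv, inv, table) == 1.82
        assert establishment_rate(inv, 3, table) == 1.65  # no heterospecifics
        assert establishment_rate(5, unc, table) == 1.65
        assert establishment_rate(5, 5, table) == 1.49

    def test_unknown_species_raises(self, null_table):
        with pytest.raises(KeyError):
            establishment_rate(500, 0, null_table)
        with pytest.raises(KeyError):
            establishment_rate(0, 500, null_table)


class TestGrowth:
    def make_single(self, cfg, biomass, rate):
        state = initialise(cfg, build_null(100))
        state.occupant[10, 10] = 0
        state.biomass[10, 10] = biomass
        state.growth_rate[10, 10] = rate
        state.soil[10, 10] = 0
        return state

    @pytest.mark.parametrize("mode", ["rescale", "share", "clip"])
    def test_isolated_plant_grows_multiplicatively(self, mode):
        cfg = small_config(neighbourhood_cap=100.0, cap_mode=mode)
        state = self.make_single(cfg, 1.0, 1.65)
        step_growth(state, cfg)
        assert state.biomass[10, 10] == pytest.approx(1.65)

    @pytest.mark.parametrize("mode", ["rescale", "share"])
    def test_saturated_neighbourhood_cannot_grow_past_cap(self, mode):
        cfg = small_config(neighbourhood_cap=10.0, cap_mode=mode)
        state = self.make_single(cfg, 4.0, 1.65)
        for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            state.occupant[10 + dr, 10 + dc] = 1
            state.biomass[10 + dr, 10 + dc] = 1.5
            state.growth_rate[10 + dr, 10 + dc] = 1.65
            state.soil[10 + dr, 10 + dc] = 1
        step_growth(state, cfg)
        total = state.biomass[9:12, 9:12].sum()
        assert total <= 10.0 + 1e-9

    @pytest.mark.parametrize("mode", ["rescale", "share", "clip"])
    def test_cap_invariant_on_random_states(self, mode):
        cfg = small_config(neighbourhood_cap=8.0, cap_mode=mode)
        rng = np.random.default_rng(9)
        for _ in range(20):
            state = initialise(cfg, build_null(100))
            occ = rng.random((20, 20)) < 0.7
            state.occupant[occ] = rng.integers(0, 100, occ.sum())
            state.biomass[occ] = rng.uniform(0.1, 1.6, occ.sum())
            state.growth_rate[occ] = rng.choice([1.49, 1.65, 1.82], occ.sum())
            state.soil[occ] = state.occupant[occ]
            pre = state.biomass.copy()
            step_growth(state, cfg)
            b = state.biomass
            assert np.all(b >= 0)
            if mode in ("rescale", "share"):
                # five-cell sums respect the cap after a synchronous update
                s5 = b.copy()
                s5[1:, :] += b[:-1, :]
                s5[:-1, :] += b[1:, :]
                s5[:, 1:] += b[:, :-1]
                s5[:, :-1] += b[:, 1:]
                assert np.all(s5 <= cfg.neighbourhood_cap + 1e-9)
            else:
                # clip bounds each focal plant against pre-step neighbours
                npre = np.zeros_like(pre)
                npre[1:, :] += pre[:-1, :]
                npre[:-1, :] += pre[1:, :]
                npre[:, 1:] += pre[:, :-1]
                npre[:, :-1] += pre[:, 1:]
                bound = np.maximum(pre, cfg.neighbourhood_cap - npre)
                assert np.all(b <= bound + 1e-9)
            if mode in ("share", "clip"):
                # these mechanics never shrink a plant
                assert np.all(b >= pre - 1e-12)

    def test_clip_cap_binding_freezes_biomass(self):
        cfg = small_config(neighbourhood_cap=5.0, cap_mode="clip")
        state = self.make_single(cfg, 2.0, 1.82)
        state.occupant[9, 10] = 1
        state.biomass[9, 10] = 3.0
        state.growth_rate[9, 10] = 1.65
        state.soil[9, 10] = 1
        step_growth(state, cfg)
        assert state.biomass[10, 10] == pytest.approx(2.0)


class TestMortality:
    def test_zero_probability_no_deaths(self, populated, null_table):
        state, _ = populated
        cfg = small_config(p_mortality=0.0)
        n = state.n_occupied
        step_mortality(state, cfg, np.random.default_rng(0))
        assert state.n_occupied == n

    def test_death_leaves_soil_conditioning(self, populated):
        state, cfg = populated
        before_occ = state.occupant.copy()
        step_mortality(state, SimConfig(grid_side=20, p_mortality=1.0),
                       np.random.default_rng(0))
        assert state.n_occupied == 0
        died = before_occ != EMPTY
        assert np.array_equal(state.soil[died], before_occ[died])
        assert np.all(state.biomass == 0.0)

    def test_death_count_matches_binomial_law(self, null_table):
        cfg = small_config(grid_side=50, p_mortality=0.1)
        rng = np.random.default_rng(13)
        total_deaths = 0
        trials = 0
        for _ in range(50):
            state = initialise(cfg, null_table)
            state.occupant[:, :] = 0
            state.biomass[:, :] = 1.0
            state.growth_rate[:, :] = 1.65
            state.soil[:, :] = 0
            trials += cfg.n_cells
            step_mortality(state, cfg, rng)
            total_deaths += cfg.n_cells - state.n_occupied
        p = stats.binomtest(total_deaths, trials, 0.1).pvalue
        assert p > 1e-3


class TestInvasion:
    def test_invaders_fill_distinct_empty_cells(self, populated, null_table):
        state, cfg = populated
        empty_before = (state.occupant == EMPTY)
        introduce_invader(state, cfg, null_table, np.random.default_rng(1))
        inv_cells = state.occupant == null_table.invader
        assert inv_cells.sum() == cfg.n_invaders
        assert np.all(empty_before[inv_cells])
        assert np.all(state.biomass[inv_cells] == cfg.initial_biomass)

    def test_invader_standard_rate_on_resident_soil(self, null_table):
        cfg = small_config(n_invaders=5)
        state = initialise(cfg, null_table)
        state.soil[:, :] = 3  # everything conditioned by resident 3
        introduce_invader(state, cfg, null_table, np.random.default_rng(1))
        inv = state.occupant == null_table.invader
        assert np.all(state.growth_rate[inv] == 1.65)

    def test_full_grid_places_none(self, null_table, caplog):
        cfg = small_config(n_invaders=5)
        state = initialise(cfg, null_table)
        state.occupant[:, :] = 0
        state.biomass[:, :] = 1.0
        introduce_invader(state, cfg, null_table, np.random.default_rng(1))
        assert not np.any(state.occupant == null_table.invader)


class TestRunSimulation:
    def test_same_seed_reproduces_trajectory(self):
        spec = ScenarioSpec.from_name("Neg.Mod.5.NC", invasion=True)
        cfg = small_config(p_immigration=0.01, rng_seed=77)
        a = run_simulation(spec, cfg)
        b = run_simulation(spec, cfg)
        assert np.array_equal(a.biomass, b.biomass)
        assert np.array_equal(a.abundance, b.abundance)

    def test_no_invasion_means_no_invader_ever(self):
        spec = ScenarioSpec.from_name("Null")
        cfg = small_config(p_immigration=0.01)
        res = run_simulation(spec, cfg)
        assert np.all(res.biomass[:, -1] == 0.0)
        assert np.all(res.abundance[:, -1] == 0)

    def test_zero_immigration_grid_stays_empty(self):
        spec = ScenarioSpec.from_name("Null")
        cfg = small_config(p_immigration=0.0)
        res = run_simulation(spec, cfg)
        assert res.biomass.sum() == 0.0

    def test_community_persists_across_seeds(self):
        spec = ScenarioSpec.from_name("Null")
        for seed in range(5):
            cfg = small_config(p_immigration=0.01, n_steps=200,
                               record_every=200, rng_seed=seed)
            res = run_simulation(spec, cfg)
            assert res.biomass[-1].sum() > 0.0

    def test_records_mandatory_steps(self):
        spec = ScenarioSpec.from_name("Null")
        cfg = SimConfig(grid_side=10, n_steps=5_200, record_every=5_000,
                        p_immigration=0.01, rng_seed=1)
        res = run_simulation(spec, cfg)
        assert 5_000 in res.steps and 5_200 in res.steps

    def test_invasion_step_after_end_rejected(self):
        spec = ScenarioSpec.from_name("Null", invasion=True)
        cfg = small_config(n_steps=30, invasion_step=40)
        with pytest.raises(ValueError):
            run_simulation(spec, cfg)

    def test_occupancy_biomass_consistency_and_soil_monotone(self):
        table = build_null(100)
        cfg = small_config(p_immigration=0.02)
        rng = np.random.default_rng(4)
        state = initialise(cfg, table)
        prev_unconditioned = cfg.n_cells
        for step in range(1, 30):
            step_immigration(state, cfg, table, rng)
            if step > 1:
                step_recruitment(state, cfg, table, rng)
            step_growth(state, cfg, rng)
            step_mortality(state, cfg, rng)
            occ = state.occupant != EMPTY
            assert np.all((state.biomass > 0) == occ)
            assert np.all(state.biomass >= 0)
            # occupied cells always carry their occupant's conditioning
            assert np.array_equal(state.soil[occ], state.occupant[occ])
            n_unc = int(np.count_nonzero(state.soil == table.unconditioned))
            assert n_unc <= prev_unconditioned
            prev_unconditioned = n_unc

    def test_species_label_exchangeability(self):
        """Consistently permuting species labels in the interaction table
        leaves aggregate community behaviour statistically unchanged."""
        from psfsim.networks import build_modular

        base = build_modular(100, 5, "negative")
        perm = np.random.default_rng(0).permutation(100)
        permuted = base.copy()
        permuted.classes[:100, :100] = base.classes[perm][:, perm]
        spec = ScenarioSpec.from_name("Neg.Mod.5")

        def mean_total(table):
            totals = []
            for seed in (1, 2, 3, 4):
                cfg = small_config(p_immigration=0.05, n_steps=150,
                                   record_every=150, rng_seed=seed)
                res = run_simulation(spec, cfg, table=table)
                totals.append(res.biomass[-1].sum())
            return np.mean(totals)

        a, b = mean_total(base), mean_total(permuted)
        assert abs(a - b) / max(a, b) < 0.25


class TestExports:
    def test_result_time_series_frame(self):
        spec = ScenarioSpec.from_name("Null")
        cfg = small_config(p_immigration=0.05, n_steps=40, record_every=20)
        res = run_simulation(spec, cfg)
        df = res.to_frame()
        assert set(df.columns) == {"step", "species", "biomass", "abundance"}
        assert len(df) == len(res.steps) * 101
        total = df[df.step == 40]["biomass"].sum()
        assert total == pytest.approx(res.summary_at(40).biomass_by_species.sum())

    def test_grid_snapshot_frame(self, populated):
        state, cfg = populated
        df = state.to_frame()
        assert len(df) == cfg.n_cells
        occupied = df[df.occupant >= 0]
        assert (occupied.biomass > 0).all()
        assert (occupied.occupant == occupied.soil).all()
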