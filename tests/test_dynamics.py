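import dataclasses

import numpy as np
import pytest

from coexsim.dynamics import (
    SimulationConfig,
    Trajectory,
    apply_adaptation,
    apply_primary_extinctions,
    apply_recruitment,
    attempt_colonization,
    latitude_amplification,
    run_paired,
    run_simulation,
    sample_cumulative_change,
    step_temperature,
)
from coexsim.foodweb import FoodWeb
from coexsim.world import World, instantaneous_extinction_probability


def make_locality_world(pool, temps=(0.0, 20.0), members=None, lat=10.5, n_loc=1,
                        adj=None):
    """Hand-built world around the given pool for step-operator tests."""
    from coexsim.world import Locality

    n = len(pool)
    locs = []
    for k in range(n_loc):
        member = np.zeros(n, dtype=bool)
        ids = np.asarray(members if members is not None else np.arange(min(20, n)))
        member[ids] = True
        loc = Locality(
            id=k, lat=lat, lon=float(k), loc_t=temps[0], loc_T=temps[1],
            loc_t0=temps[0], loc_T0=temps[1],
            member=member, sp_t=pool.sp_t.copy(), sp_T=pool.sp_T.copy(),
            est=np.zeros(n, dtype=np.int64), p_prev=np.zeros(n),
            integral=np.zeros(n), cum_p=np.zeros(n),
            web=None, initial_diversity=int(member.sum()),
        )
        locs.append(loc)
    return World(locs, pool, adj)


class TestTrajectory:
    def test_latitude_amplification(self):
        assert latitude_amplification(0.0) == 1.0
        assert latitude_amplification(60.0) == 1.0
        assert latitude_amplification(90.0) == 2.0
        assert latitude_amplification(-75.0) == 1.5

    def test_cumulative_change_calibration(self):
        # Monte-Carlo over 1000 replicate 5000-step trajectories at low latitude
        total = sample_cumulative_change("heating", n_steps=5000, n_reps=1000, seed=0)
        se = total.std() / np.sqrt(len(total))
        assert abs(total.mean() - 50.0) < 3 * se + 0.2

    def test_per_100_step_rate(self):
        total = sample_cumulative_change("heating", n_steps=100, n_reps=2000, seed=1)
        assert total.mean() == pytest.approx(1.0, abs=0.02)

    def test_cooling_sign(self, small_pool):
        world = make_locality_world(small_pool)
        t0 = world.localities[0].loc_T
        for step in range(1, 50):
            step_temperature(world, Trajectory("cooling", 50), step, key_seed=3)
        assert world.localities[0].loc_T < t0

    def test_polar_amplification_in_world(self, small_pool):
        w_eq = make_locality_world(small_pool, lat=10.5)
        w_po = make_locality_world(small_pool, lat=90.0)
        for step in range(1, 200):
            step_temperature(w_eq, Trajectory("heating"), step, key_seed=5)
            step_temperature(w_po, Trajectory("heating"), step, key_seed=5)
        d_eq = w_eq.localities[0].loc_T - w_eq.localities[0].loc_T0
        d_po = w_po.localities[0].loc_T - w_po.localities[0].loc_T0
        assert d_po == pytest.approx(2 * d_eq)

    def test_invalid(self):
        with pytest.raises(ValueError):
            Trajectory("sideways")
        with pytest.raises(ValueError):
            Trajectory("heating", n_steps=0)


class TestAdaptation:
    def test_zero_probability_noop(self, small_pool):
        world = make_locality_world(small_pool)
        before = world.localities[0].sp_T.copy()
        apply_adaptation(world, 0.0, "heating", 1, key_seed=2)
        assert np.array_equal(world.localities[0].sp_T, before)

    def test_heating_only_raises_upper_limit(self, small_pool):
        world = make_locality_world(small_pool, members=np.arange(len(small_pool)))
        loc = world.localities[0]
        t_before, T_before = loc.sp_t.copy(), loc.sp_T.copy()
        for step in range(1, 300):
            apply_adaptation(world, 0.05, "heating", step, key_seed=4)
        assert np.array_equal(loc.sp_t, t_before)
        assert np.all(loc.sp_T >= T_before) and (loc.sp_T > T_before).any()

    def test_mean_shift_near_three_quarters(self, small_pool):
        # probability 1: every population adapts exactly once this step
        world = make_locality_world(small_pool, members=np.arange(len(small_pool)))
        loc = world.localities[0]
        apply_adaptation(world, 1.0, "cooling", 1, key_seed=6)
        shifts = world.pool.sp_t - loc.sp_t
        assert shifts.mean() == pytest.approx(0.75, abs=0.05)
        assert shifts.std() == pytest.approx(0.25, abs=0.05)


class TestPrimaryExtinction:
    def test_negative_margin_is_certain_death(self, small_pool):
        world = make_locality_world(small_pool, temps=(100.0, 120.0),
                                    members=np.arange(50))
        removed = apply_primary_extinctions(world, 1, key_seed=7)
        assert world.localities[0].richness == 0
        assert len(removed[0]) == 50

    def test_wide_margin_never_dies(self, small_pool):
        # all species tolerate far beyond the local extremes
        world = make_locality_world(small_pool, temps=(0.0, 10.0), members=np.arange(50))
        loc = world.localities[0]
        loc.sp_t[:] = -100.0
        loc.sp_T[:] = 100.0
        for step in range(1, 200):
            apply_primary_extinctions(world, step, key_seed=8)
        assert loc.richness == 50

    def test_constant_margin_hazard_matches_closed_form(self, pools):
        # populations at fixed margin m: the integrated probability is the
        # constant p = 1/(1+m), so the eventual removal fraction converges to p
        from coexsim.species import generate_species_pool

        pool = generate_species_pool(pools, n_total=10_000, tardigrade_count=0, seed=9)
        world = make_locality_world(pool, temps=(0.0, 20.0),
                                    members=np.arange(10_000))
        loc = world.localities[0]
        margin = 1.5
        loc.sp_t[:] = -50.0
        loc.sp_T[:] = 20.0 + margin
        told = margin
        p = instantaneous_extinction_probability(told)
        loc.p_prev[:] = p
        for step in range(1, 300):
            apply_primary_extinctions(world, step, key_seed=10)
        removed_frac = 1.0 - loc.richness / 10_000
        assert removed_frac == pytest.approx(p, abs=0.02)


class TestRecruitment:
    def _recruit_world(self, small_pool):
        world = make_locality_world(small_pool, n_loc=2, members=np.arange(10))
        web = FoodWeb(len(small_pool), [5], [0], [1.0], basal_ids=[0])
        web.w[0] = 0.5  # degraded link
        world.localities[0].web = web
        return world, web

    def test_weight_gain_is_inverse_distance_capped(self, small_pool, rng):
        world, web = self._recruit_world(small_pool)
        world.distance[0, 1] = world.distance[1, 0] = 4.0
        apply_recruitment(world, rng, probability=1.0)
        assert web.w[0] == pytest.approx(0.75)  # 0.5 + 1.0/4
        for _ in range(10):
            apply_recruitment(world, rng, probability=1.0)
        assert web.w[0] == pytest.approx(1.0)  # capped at initial weight

    def test_absent_resource_not_recruited(self, small_pool, rng):
        world, web = self._recruit_world(small_pool)
        world.remove_from(world.localities[1], np.array([0]))  # source loses resource
        apply_recruitment(world, rng, probability=1.0)
        assert web.w[0] == pytest.approx(0.5)


class TestColonization:
    def test_dispersal_probability_is_inverse_distance(self, small_pool, adj):
        world = make_locality_world(small_pool, n_loc=2, members=np.arange(30))
        world.distance[:] = 2.0
        np.fill_diagonal(world.distance, 0.0)
        rng = np.random.default_rng(0)
        outcomes = [
            attempt_colonization(world.copy(), "tolerance", adj, rng).outcome
            for _ in range(600)
        ]
        frac_dispersed = np.mean([o != "failed_dispersal" for o in outcomes])
        assert frac_dispersed == pytest.approx(0.5, abs=0.07)

    def _one_vs_one_world(self, small_pool, strong_colonizer: bool):
        """Locality 0 hosts resident a, locality 1 hosts b (identical phenotype,
        same trophic level); whoever has the wider margins wins displacement."""
        import dataclasses as dc

        pool = dc.replace(small_pool,
                          phenotype_counts=small_pool.phenotype_counts.copy())
        cons = np.flatnonzero(pool.trophic_level == 1)[:2]
        a, b = int(cons[0]), int(cons[1])
        pool.phenotype_counts[b] = pool.phenotype_counts[a]
        world = make_locality_world(pool, n_loc=2, temps=(0.0, 20.0), members=[a])
        src = world.localities[1]
        world.remove_from(src, src.community)
        world.add_to(src, b)
        world.distance[:] = 1.0
        np.fill_diagonal(world.distance, 0.0)
        strong, weak = ((-30.0, 60.0), (-1.0, 21.0))
        for loc in world.localities:
            loc.sp_t[a], loc.sp_T[a] = weak if strong_colonizer else strong
            loc.sp_t[b], loc.sp_T[b] = strong if strong_colonizer else weak
        return world, a, b

    def test_identical_stronger_colonizer_displaces(self, small_pool, adj):
        # engagement is certain (similarity 1); the better margin must win
        world, a, b = self._one_vs_one_world(small_pool, strong_colonizer=True)
        displaced = 0
        for seed in range(40):
            w2 = world.copy()
            ev = attempt_colonization(w2, "tolerance", adj, np.random.default_rng(seed))
            if ev.target == 0:  # b invades a's locality
                displaced += 1
                assert ev.outcome == "displaced"
                assert ev.displaced == (a,)
                assert ev.delta == 0  # one-for-one replacement
                assert w2.localities[0].member[b] and not w2.localities[0].member[a]
            else:  # weak a attacks strong b
                assert ev.outcome == "failed_outcompeted"
        assert displaced > 0

    def test_weaker_colonizer_fails(self, small_pool, adj):
        world, a, b = self._one_vs_one_world(small_pool, strong_colonizer=False)
        for seed in range(30):
            ev = attempt_colonization(world.copy(), "tolerance", adj,
                                      np.random.default_rng(seed))
            if ev.target == 0:
                assert ev.outcome == "failed_outcompeted"

    def test_colonization_diversity_deltas_enumerated(self, adj):
        cfg = SimulationConfig.desk_scale(seed=21, n_localities=(8, 8), n_steps=150,
                                          preliminary_colonization_events=400,
                                          log_events=True)
        result = run_simulation(cfg)
        deltas = {ev.delta for ev in result.events if ev.outcome.startswith("estab")
                  or ev.outcome == "displaced"}
        assert deltas <= set(range(-30, 2))
        failed = [ev for ev in result.events if ev.outcome.startswith("failed")]
        assert all(ev.delta == 0 for ev in failed)


class TestFullRuns:
    def test_run_simulation_curve_shape(self):
        cfg = SimulationConfig.desk_scale(seed=31, n_localities=(6, 6), n_steps=200,
                                          preliminary_colonization_events=100)
        result = run_simulation(cfg)
        c = result.curve
        assert len(c.step) == 201
        assert c.richness[0] == c.initial_richness > 0
        assert np.all(c.richness >= 0)
        assert np.all(np.diff(c.abs_delta_t) >= 0)

    def test_richness_non_increasing_without_migration(self):
        cfg = SimulationConfig.desk_scale(seed=32, n_localities=(6, 6), n_steps=300,
                                          preliminary_colonization_events=0,
                                          per_step_colonization_attempts=0)
        result = run_simulation(cfg)
        assert np.all(np.diff(result.curve.richness) <= 0)

    def test_scenario_dominance_paired_seeds(self):
        # with migration off, co-extinction can only add removals
        cfg = SimulationConfig.desk_scale(
            seed=33, n_localities=(8, 8), n_steps=600,
            preliminary_colonization_events=0, per_step_colonization_attempts=0,
            recruitment_probability=0.0,
        )
        res_tol, res_co = run_paired(cfg)
        assert np.all(res_co.curve.richness <= res_tol.curve.richness)

    def test_invalid_config_rejected_before_running(self):
        with pytest.raises(ValueError):
            SimulationConfig(coextinction_threshold=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(scenario="both").validate()
        with pytest.raises(ValueError):
            dataclasses.replace(SimulationConfig(), per_step_colonization_attempts=-1).validate()

    def test_annihilation_pads_curve(self):
        cfg = SimulationConfig.desk_scale(seed=34, n_localities=(5, 5), n_steps=4000,
                                          coextinction_threshold=0.0,
                                          preliminary_colonization_events=0,
                                          per_step_colonization_attempts=0)
        result = run_simulation(cfg)
        c = result.curve
        zero = np.flatnonzero(c.richness == 0)
        if len(zero):
            assert np.all(c.richness[zero[0]:] == 0)
            assert len(c.richness) == cfg.n_steps + 1
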