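"""Per-step simulation loop: temperature trajectories, adaptation, primary
extinctions, co-extinction cascades, community rescue and colonization.

Temperature shifts each locality's extremes by |N(0.01, 0.0025)| °C per step
(sign set by the trajectory), amplified by 1 + (|lat| - 60)/30 poleward of
60°, for 5000 steps (≈ 50 °C cumulative change at low latitudes).  At every
step, species whose tolerance margin turns negative are removed outright and
the others face a conditional hazard derived from the integrated extinction
probability; in the co-extinction scenario primary losses then trigger
cascades through the local food web, partially offset by recruitment from
neighbouring localities and by dispersal/colonization.

Randomness that both paired scenarios must share (climate, adaptation,
extinction hazards) is drawn from counter-based streams keyed on
(seed, step, locality, species); scenario-specific randomness (colonization,
recruitment) uses ordinary per-scenario generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _rand
from .calibration import default_pools
from .coextinction import cascade
from .foodweb import connectance
from .species import (
    SpeciesPool,
    TraitAdjacency,
    build_trait_adjacency,
    generate_species_pool,
    rescaled_accessibility_matrix,
)
from .world import (
    World,
    WorldConfig,
    build_world,
    instantaneous_extinction_probability,
    tolerance_margin,
)
from .calibration import generate_climate_grid

__all__ = [
    "Trajectory",
    "SimulationConfig",
    "DiversityCurve",
    "SimulationResult",
    "ColonizationEvent",
    "step_temperature",
    "apply_adaptation",
    "apply_primary_extinctions",
    "apply_recruitment",
    "attempt_colonization",
    "run_simulation",
    "run_paired",
    "prepare_world",
    "sample_cumulative_change",
]


@dataclass(frozen=True)
class Trajectory:
    direction: str = "heating"  # or "cooling"
    n_steps: int = 5000
    step_delta_mean: float = 0.01  # °C per step at |lat| <= 60
    step_delta_sd: float = 0.0025

    def __post_init__(self):
        if self.direction not in ("heating", "cooling"):
            raise ValueError("direction must be 'heating' or 'cooling'")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.step_delta_sd < 0:
            raise ValueError("step_delta_sd must be >= 0")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "heating" else -1.0


def latitude_amplification(lat) -> np.ndarray:
    """1 below 60° absolute latitude, rising linearly to 2 at the poles."""
    return 1.0 + np.maximum(0.0, np.abs(np.asarray(lat, dtype=float)) - 60.0) / 30.0


@dataclass
class SimulationConfig:
    """Concrete parameter set for one simulation run.

    Defaults follow the full-scale study conditions; :meth:`desk_scale` gives
    the reduced configuration used for laptop-sized experiments.
    """

    scenario: str = "coextinction"  # or "tolerance"
    direction: str = "heating"
    n_steps: int = 5000
    coextinction_threshold: float = 0.5
    reallocation_ratio: float = 0.5
    adaptation_probability: float = 0.00005
    preliminary_colonization_events: int = 10_000
    per_step_colonization_attempts: int = 10
    recruitment_probability: float = 0.01
    pool_size: int = 100_000
    tardigrade_count: int = 100
    grid_cells: int = 2000
    n_localities: tuple[int, int] | int = (100, 500)
    n_candidates: tuple[int, int] | int = (100, 1000)
    adjacency_pairs: int = 1_000_000
    basal_fraction: float = 0.35
    max_trophic_level: int = 5
    log_events: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in ("tolerance", "coextinction"):
            raise ValueError("scenario must be 'tolerance' or 'coextinction'")
        Trajectory(self.direction, self.n_steps)
        for name in ("coextinction_threshold", "reallocation_ratio",
                     "recruitment_probability", "adaptation_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.preliminary_colonization_events < 0:
            raise ValueError("preliminary_colonization_events must be >= 0")
        if self.per_step_colonization_attempts < 0:
            raise ValueError("per_step_colonization_attempts must be >= 0")
        if self.tardigrade_count > self.pool_size:
            raise ValueError("tardigrade_count cannot exceed pool_size")

    @classmethod
    def desk_scale(cls, **overrides) -> "SimulationConfig":
        """Reduced problem size for interactive use and testing."""
        base = dict(
            pool_size=2000,
            tardigrade_count=4,
            grid_cells=1500,
            n_localities=(20, 50),
            n_candidates=(100, 1000),
            preliminary_colonization_events=2000,
            adjacency_pairs=200_000,
        )
        base.update(overrides)
        return cls(**base)

    def snapshot(self) -> dict:
        return asdict(self)


@dataclass
class ColonizationEvent:
    step: int
    source: int
    target: int
    species: int
    outcome: str  # established / displaced / failed_<reason>
    delta: int = 0
    displaced: tuple[int, ...] = ()


@dataclass
class DiversityCurve:
    """Per-step global and extremophile richness along a trajectory."""

    step: np.ndarray
    delta_t: np.ndarray  # mean signed ΔT across localities, °C
    abs_delta_t: np.ndarray  # mean |ΔT| across localities, °C
    richness: np.ndarray
    tardigrade_richness: np.ndarray
    scenario: str
    direction: str
    config: dict = field(default_factory=dict)

    @property
    def initial_richness(self) -> int:
        return int(self.richness[0])

    def surviving_fraction(self) -> np.ndarray:
        if self.initial_richness == 0:
            raise ValueError("curve starts at zero richness")
        return self.richness / self.initial_richness

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "delta_t_c": self.delta_t,
                "abs_delta_t_c": self.abs_delta_t,
                "richness": self.richness,
                "tardigrade_richness": self.tardigrade_richness,
            }
        )

    def collapse_delta_t(self, which: str = "tardigrade") -> float:
        """Mean |ΔT| at the first step where (tardigrade) richness hits zero.

        NaN if the tracked richness never reaches zero or was zero initially.
        """
        r = self.tardigrade_richness if which == "tardigrade" else self.richness
        if r[0] == 0:
            return float("nan")
        zero = np.flatnonzero(r == 0)
        if len(zero) == 0:
            return float("nan")
        return float(self.abs_delta_t[zero[0]])


@dataclass
class SimulationResult:
    curve: DiversityCurve
    world: World
    events: list[ColonizationEvent]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# step operators
# ---------------------------------------------------------------------------

def step_temperature(world: World, trajectory: Trajectory, step: int, key_seed: int) -> World:
    """Shift every locality's temperature extremes by this step's increment."""
    ids = np.arange(len(world))
    key = _rand.key_from(key_seed, _rand.TAG_TEMP, step)
    delta = _rand.normals(key, ids, trajectory.step_delta_mean, trajectory.step_delta_sd)
    amp = getattr(world, "_lat_amp", None)
    if amp is None:
        amp = latitude_amplification([loc.lat for loc in world.localities])
        world._lat_amp = amp
    shifts = trajectory.sign * delta * amp
    for loc, s in zip(world.localities, shifts):
        loc.loc_t += s
        loc.loc_T += s
    return world


def _entity_ids(world: World, per_loc_ids: list[np.ndarray]) -> np.ndarray:
    """Combined (locality, species) entity ids for counter-based draws.

    A population keeps the same entity id for the whole run, so paired
    scenario runs see identical draws for every population they share.
    """
    n = len(world.pool)
    return np.concatenate(
        [loc.id * n + ids for loc, ids in zip(world.localities, per_loc_ids)]
    )


def apply_adaptation(
    world: World, probability: float, direction: str, step: int, key_seed: int,
    _communities: list[np.ndarray] | None = None,
) -> World:
    """Let each resident population, with the given probability, extend the
    trajectory-relevant thermal limit by N(0.75, 0.25) °C in the direction of
    the change (upper limit under heating, lower under cooling)."""
    if probability <= 0:
        return world
    per_loc = _communities or [loc.community for loc in world.localities]
    eids = _entity_ids(world, per_loc)
    if len(eids) == 0:
        return world
    sel = _rand.uniforms(_rand.key_from(key_seed, _rand.TAG_ADAPT_SEL, step), eids)
    if not (sel < probability).any():
        return world
    offset = 0
    for loc, ids in zip(world.localities, per_loc):
        k = len(ids)
        hit = sel[offset:offset + k] < probability
        if hit.any():
            adapting = ids[hit]
            shift = _rand.normals(
                _rand.key_from(key_seed, _rand.TAG_ADAPT_SHIFT, step),
                eids[offset:offset + k][hit], 0.75, 0.25,
            )
            if direction == "heating":
                loc.sp_T[adapting] += shift
            else:
                loc.sp_t[adapting] -= shift
        offset += k
    return world


def apply_primary_extinctions(
    world: World, step: int, key_seed: int,
    _communities: list[np.ndarray] | None = None,
) -> dict[int, np.ndarray]:
    """Remove climatically doomed populations; return removed ids per locality.

    Populations with a negative tolerance margin go deterministically.  The
    rest face the incremental hazard h = (P_k - P_{k-1}) / (1 - P_{k-1}),
    where P_k is the integrated (time-averaged) extinction probability since
    establishment — so the integrated curve acts as the cumulative extinction
    CDF and per-step draws never double-count exposure.
    """
    locs = world.localities
    per_loc = _communities or [loc.community for loc in locs]
    eids = _entity_ids(world, per_loc)
    if len(eids) == 0:
        return {}
    u = _rand.uniforms(_rand.key_from(key_seed, _rand.TAG_HAZARD, step), eids)

    # gather all populations into flat arrays; one pass of hazard math
    sp_t = np.concatenate([loc.sp_t[ids] for loc, ids in zip(locs, per_loc)])
    sp_T = np.concatenate([loc.sp_T[ids] for loc, ids in zip(locs, per_loc)])
    lt = np.concatenate([np.full(len(ids), loc.loc_t) for loc, ids in zip(locs, per_loc)])
    lT = np.concatenate([np.full(len(ids), loc.loc_T) for loc, ids in zip(locs, per_loc)])
    est = np.concatenate([loc.est[ids] for loc, ids in zip(locs, per_loc)])
    p_prev = np.concatenate([loc.p_prev[ids] for loc, ids in zip(locs, per_loc)])
    integral = np.concatenate([loc.integral[ids] for loc, ids in zip(locs, per_loc)])
    prev = np.concatenate([loc.cum_p[ids] for loc, ids in zip(locs, per_loc)])

    told = tolerance_margin(sp_t, sp_T, lt, lT)
    p = instantaneous_extinction_probability(told)
    # running trapezoid of the instantaneous curve, unit step width
    integral = integral + 0.5 * (p_prev + p)
    age = step - est
    P = np.where(age > 0, np.clip(integral / np.maximum(age, 1), 0, 1), 0.0)
    h = np.where(prev < 1.0, np.clip((P - prev) / (1.0 - prev), 0.0, 1.0), 1.0)
    cum = np.maximum(prev, P)
    doomed = (told < 0) | (u < h)

    removed: dict[int, np.ndarray] = {}
    offset = 0
    for loc, ids in zip(locs, per_loc):
        k = len(ids)
        if k == 0:
            continue
        sl = slice(offset, offset + k)
        offset += k
        loc.integral[ids] = integral[sl]
        loc.p_prev[ids] = p[sl]
        loc.cum_p[ids] = cum[sl]
        gone = ids[doomed[sl]]
        if len(gone):
            world.remove_from(loc, gone)
            removed[loc.id] = gone
    return removed


def apply_recruitment(
    world: World, rng: np.random.Generator, probability: float = 0.01
) -> World:
    """Community rescue: each (target, source) pair fires with the given
    probability; links whose resource also lives in the source locality regain
    1/d of their initial weight, capped at the initial weight."""
    n = len(world)
    for i, tgt in enumerate(world.localities):
        web = tgt.web
        if web is None or web.n_links == 0:
            continue
        fire = rng.random(n) < probability
        fire[i] = False
        for j in np.flatnonzero(fire):
            src = world.localities[j]
            if src.richness == 0:
                continue
            mask = web.alive & src.member[web.res]
            if mask.any():
                web.w[mask] = np.minimum(
                    web.w0[mask], web.w[mask] + web.w0[mask] / world.distance[i, j]
                )
    return world


def _establish(world: World, tgt, migrant: int, m_t: float, m_T: float, step: int) -> None:
    tgt.sp_t[migrant] = m_t
    tgt.sp_T[migrant] = m_T
    tgt.est[migrant] = step
    tgt.integral[migrant] = 0.0
    tgt.cum_p[migrant] = 0.0
    tgt.p_prev[migrant] = instantaneous_extinction_probability(
        tolerance_margin(m_t, m_T, tgt.loc_t, tgt.loc_T)
    )
    world.add_to(tgt, migrant)


def attempt_colonization(
    world: World,
    scenario: str,
    adj: TraitAdjacency,
    rng: np.random.Generator,
    step: int = 0,
    threshold: float = 0.5,
    ratio: float = 0.5,
) -> ColonizationEvent:
    """One dispersal/colonization attempt between a random pair of localities.

    Dispersal succeeds with probability 1/d; colonization then fails outright
    with one minus the target's invasion susceptibility (connectance of the
    local web in the co-extinction scenario; the initial-to-current diversity
    ratio, clamped to 1, in the tolerance scenario).  A surviving candidate
    must then beat same-trophic-level competitors (tolerance scenario) or
    claim links in the local food web (co-extinction scenario).
    """
    pool = world.pool
    n = len(world)
    if n < 2:
        raise ValueError("colonization needs at least two localities")
    i, j = rng.choice(n, size=2, replace=False)
    src, tgt = world.localities[i], world.localities[j]
    ev = ColonizationEvent(step=step, source=int(i), target=int(j), species=-1,
                           outcome="failed_empty_source")
    if src.richness == 0:
        return ev
    migrant = int(rng.choice(src.community))
    ev.species = migrant
    if rng.random() >= 1.0 / world.distance[i, j]:
        ev.outcome = "failed_dispersal"
        return ev
    if tgt.member[migrant]:
        ev.outcome = "failed_already_present"
        return ev

    if scenario == "tolerance":
        p_s = 1.0 if tgt.richness == 0 else min(1.0, tgt.initial_diversity / tgt.richness)
    else:
        p_s = connectance(tgt.web, n_nodes=tgt.richness) if tgt.richness else 0.0
    if rng.random() >= p_s:
        ev.outcome = "failed_susceptibility"
        return ev

    m_t, m_T = float(src.sp_t[migrant]), float(src.sp_T[migrant])
    told_mig = float(tolerance_margin(m_t, m_T, tgt.loc_t, tgt.loc_T))
    tl_m = float(pool.trophic_level[migrant])
    mig_counts = pool.phenotype_counts[migrant][None, :]

    if scenario == "tolerance":
        ids = tgt.community
        same = ids[pool.trophic_level[ids] == tl_m]
        if len(same):
            m = np.minimum(pool.phenotype_counts[same], mig_counts).sum(axis=1)
            t = pool.phenotype_counts[same].sum(axis=1) + mig_counts.sum()
            similarity = 2.0 * m / t
            engaged = same[rng.random(len(same)) < similarity]
        else:
            engaged = np.array([], dtype=np.int64)
        if len(engaged) == 0:
            suit = 1.0 - instantaneous_extinction_probability(told_mig)
            if rng.random() < suit:
                _establish(world, tgt, migrant, m_t, m_T, step)
                ev.outcome, ev.delta = "established_empty_niche", 1
            else:
                ev.outcome = "failed_unsuitable"
            return ev
        told_res = tolerance_margin(tgt.sp_t[engaged], tgt.sp_T[engaged], tgt.loc_t, tgt.loc_T)
        if np.all(told_mig >= told_res):
            world.remove_from(tgt, engaged)
            _establish(world, tgt, migrant, m_t, m_T, step)
            ev.outcome = "displaced"
            ev.displaced = tuple(int(s) for s in engaged)
            ev.delta = 1 - len(engaged)
        else:
            ev.outcome = "failed_outcompeted"
        return ev

    # --- co-extinction scenario: enter the food web ---
    web = tgt.web
    if web is None or web.n_links == 0:
        ev.outcome = "failed_no_web"
        return ev
    if tl_m > 0:
        eligible = np.flatnonzero(web.alive & (pool.trophic_level[web.cons] == tl_m))
        if len(eligible) == 0:
            ev.outcome = "failed_no_web_entry"
            return ev
        res_ids = web.res[eligible]
        told_res = tolerance_margin(
            tgt.sp_t[web.cons[eligible]], tgt.sp_T[web.cons[eligible]], tgt.loc_t, tgt.loc_T
        )
        access = rescaled_accessibility_matrix(adj, mig_counts, pool.phenotype_counts[res_ids])[0]
        win = eligible[(told_mig >= told_res) & (rng.random(len(eligible)) < access)]
        if len(win) == 0:
            ev.outcome = "failed_no_web_entry"
            return ev
        losers = np.unique(web.cons[win])
        web.cons[win] = migrant
        web.present[migrant] = True
        web.stock0[migrant] = float(web.w[win].sum())
        _establish(world, tgt, migrant, m_t, m_T, step)

        # residents stripped of their last resource link go extinct, with cascades
        fully_lost = [
            int(c) for c in losers if not np.any(web.alive & (web.cons == c))
        ]
        extinct_total: list[int] = []
        if fully_lost:
            result = cascade(web, fully_lost, threshold, ratio, inplace=True)
            extinct_total = result.extinct_ids
            world.remove_from(tgt, np.asarray(extinct_total, dtype=np.int64))

        # the colonizer may enrol as an additional resource for local consumers
        cand = np.flatnonzero(
            web.alive
            & (pool.trophic_level[web.res] == tl_m)
            & (web.cons != migrant)
        )
        if len(cand):
            suit = 1.0 - instantaneous_extinction_probability(told_mig)
            acc = rescaled_accessibility_matrix(
                adj, pool.phenotype_counts[web.cons[cand]], mig_counts
            )[:, 0]
            sel = cand[(rng.random(len(cand)) < acc) & (rng.random(len(cand)) < suit)]
            if len(sel):
                frac = rng.random(len(sel))
                taken = frac * web.w[sel]
                web.w[sel] -= taken  # conserved: the colonizer takes a share
                web.add_links(web.cons[sel], np.full(len(sel), migrant), taken)
        ev.outcome = "established_web"
        ev.displaced = tuple(extinct_total)
        ev.delta = 1 - len(extinct_total)
        return ev

    # basal colonizer: may replace local basal species as resources
    cand = np.flatnonzero(web.alive & web.basal_mask[web.res] & (web.res != migrant))
    if len(cand) == 0:
        ev.outcome = "failed_no_basal_links"
        return ev
    acc = rescaled_accessibility_matrix(
        adj, pool.phenotype_counts[web.cons[cand]], mig_counts
    )[:, 0]
    win = cand[rng.random(len(cand)) < acc]
    if len(win) == 0:
        ev.outcome = "failed_no_web_entry"
        return ev
    web.res[win] = migrant
    web.present[migrant] = True
    web.basal_mask[migrant] = True
    _establish(world, tgt, migrant, m_t, m_T, step)
    ev.outcome, ev.delta = "established_basal", 1
    return ev


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def prepare_world(config: SimulationConfig):
    """Build calibration pools, species pool, trait adjacency, climate grid and
    a populated world from a simulation config."""
    config.validate()
    s = [int(x) for x in np.random.SeedSequence(config.seed).generate_state(6) % 2**31]
    pools = default_pools(seed=s[0], basal_fraction=config.basal_fraction,
                          max_level=config.max_trophic_level)
    pool = generate_species_pool(
        pools,
        n_total=config.pool_size,
        tardigrade_count=config.tardigrade_count,
        trajectory=config.direction,
        seed=s[1],
    )
    adj = build_trait_adjacency(s[2], n_calibration_pairs=config.adjacency_pairs)
    grid = generate_climate_grid(config.grid_cells, seed=s[3])
    wc = WorldConfig(
        n_localities=config.n_localities
        if not np.isscalar(config.n_localities)
        else (config.n_localities, config.n_localities),
        n_candidates=config.n_candidates
        if not np.isscalar(config.n_candidates)
        else (config.n_candidates, config.n_candidates),
    )
    world = build_world(grid, pool, adj, wc, seed=s[4])
    return world, adj


class _Engine:
    """Drives one scenario's change phase on a prepared world."""

    def __init__(self, world: World, config: SimulationConfig, scenario: str,
                 hazard_seed: int, rng: np.random.Generator):
        self.world = world
        self.config = config
        self.scenario = scenario
        self.hazard_seed = hazard_seed
        self.rng = rng
        self.events: list[ColonizationEvent] = []
        self.trajectory = Trajectory(config.direction, config.n_steps)

    def colonize(self, n_events: int, step: int) -> None:
        if len(self.world) < 2:
            return
        for _ in range(n_events):
            ev = attempt_colonization(
                self.world, self.scenario, self.world.adj, self.rng, step=step,
                threshold=self.config.coextinction_threshold,
                ratio=self.config.reallocation_ratio,
            )
            if self.config.log_events:
                self.events.append(ev)

    def run_change_phase(self) -> DiversityCurve:
        cfg, world = self.config, self.world
        n = cfg.n_steps
        rec = {
            "step": np.arange(n + 1),
            "delta_t": np.zeros(n + 1),
            "abs_delta_t": np.zeros(n + 1),
            "richness": np.zeros(n + 1, dtype=np.int64),
            "tardigrade_richness": np.zeros(n + 1, dtype=np.int64),
        }
        rec["richness"][0] = world.richness
        rec["tardigrade_richness"][0] = world.tardigrade_richness

        last = n
        for step in range(1, n + 1):
            step_temperature(world, self.trajectory, step, self.hazard_seed)
            communities = [loc.community for loc in world.localities]
            apply_adaptation(world, cfg.adaptation_probability, cfg.direction,
                             step, self.hazard_seed, _communities=communities)
            removed = apply_primary_extinctions(world, step, self.hazard_seed,
                                                _communities=communities)
            if self.scenario == "coextinction":
                for loc in world.localities:
                    gone = removed.get(loc.id)
                    if gone is None or loc.web is None:
                        continue
                    result = cascade(
                        loc.web, gone, cfg.coextinction_threshold,
                        cfg.reallocation_ratio, inplace=True,
                    )
                    victims = [s for g, s in result.extinct if g > 0]
                    if victims:
                        world.remove_from(loc, np.asarray(victims, dtype=np.int64))
                if cfg.recruitment_probability > 0:
                    apply_recruitment(world, self.rng, cfg.recruitment_probability)
            self.colonize(cfg.per_step_colonization_attempts, step)

            rec["delta_t"][step] = world.mean_dT()
            rec["abs_delta_t"][step] = world.mean_abs_dT()
            rec["richness"][step] = world.richness
            rec["tardigrade_richness"][step] = world.tardigrade_richness
            if world.richness == 0:
                last = step
                break

        if last < n:  # annihilation: pad the remaining record
            per_step = self.trajectory.step_delta_mean
            tail = np.arange(1, n - last + 1)
            rec["delta_t"][last + 1:] = rec["delta_t"][last] + self.trajectory.sign * per_step * tail
            rec["abs_delta_t"][last + 1:] = rec["abs_delta_t"][last] + per_step * tail
            rec["richness"][last + 1:] = 0
            rec["tardigrade_richness"][last + 1:] = 0

        return DiversityCurve(
            step=rec["step"], delta_t=rec["delta_t"], abs_delta_t=rec["abs_delta_t"],
            richness=rec["richness"], tardigrade_richness=rec["tardigrade_richness"],
            scenario=self.scenario, direction=cfg.direction, config=cfg.snapshot(),
        )


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(x) for x in np.random.SeedSequence([seed, 0xC0E7]).generate_state(n) % 2**31]


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Build a world and run one scenario end to end (preliminary
    colonization phase, then the environmental-change phase)."""
    config.validate()
    world, adj = prepare_world(config)
    hz, rng_seed = _child_seeds(config.seed, 2)
    eng = _Engine(world, config, config.scenario, hz, np.random.default_rng(rng_seed))
    eng.colonize(config.preliminary_colonization_events, step=0)
    curve = eng.run_change_phase()
    return SimulationResult(curve=curve, world=world, events=eng.events, config=config)


def run_paired(config: SimulationConfig) -> tuple[SimulationResult, SimulationResult]:
    """Run the tolerance and co-extinction scenarios on the same prepared world.

    The preliminary colonization phase runs once (web-aware mechanics, since
    the webs exist) before the world is duplicated; both change phases then
    share the same climate/adaptation/hazard randomness, so any richness gap
    is attributable to scenario mechanics alone.
    """
    config.validate()
    world, adj = prepare_world(config)
    hz, prep_seed, tol_seed, co_seed = _child_seeds(config.seed, 4)

    prep = _Engine(world, config, "coextinction", hz, np.random.default_rng(prep_seed))
    prep.colonize(config.preliminary_colonization_events, step=0)

    world_tol = world.copy(drop_webs=True)
    world_co = world

    results = []
    for scenario, w, s in (("tolerance", world_tol, tol_seed), ("coextinction", world_co, co_seed)):
        import dataclasses

        cfg = dataclasses.replace(config, scenario=scenario)
        eng = _Engine(w, cfg, scenario, hz, np.random.default_rng(s))
        curve = eng.run_change_phase()
        results.append(SimulationResult(curve=curve, world=w, events=eng.events, config=cfg))
    return results[0], results[1]


def sample_cumulative_change(
    direction: str = "heating",
    n_steps: int = 5000,
    n_reps: int = 1000,
    seed: int = 0,
    lat: float = 0.0,
) -> np.ndarray:
    """Cumulative |ΔT| after ``n_steps`` for ``n_reps`` replicate trajectories
    at a given latitude (Monte-Carlo check of the trajectory calibration)."""
    traj = Trajectory(direction, n_steps)
    amp = float(latitude_amplification(lat))
    ids = np.arange(n_reps)
    total = np.zeros(n_reps)
    for step in range(1, n_steps + 1):
        key = _rand.key_from(seed, _rand.TAG_TEMP, step)
        total += _rand.normals(key, ids, traj.step_delta_mean, traj.step_delta_sd) * amp
    return total
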