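"""Localities, communities and species–locality climatic compatibility.

A locality is a 1°×1° cell with current and initial temperature extremes and
a resident community drawn from the global species pool.  Compatibility is
the tolerance margin Tol_d = min(loc_t − sp_t, sp_T − loc_T): the narrower of
the two buffers between a species' thermal limits and the local extremes.
The extinction hazard is a piecewise function of that margin, integrated over
the time a population has been established.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ClimateGrid
from .foodweb import FoodWeb, assemble_food_web, prune_unconnected
from .species import Species, SpeciesPool, TraitAdjacency

__all__ = [
    "Locality",
    "World",
    "CompatibilityResult",
    "WorldConfig",
    "tolerance_distance",
    "tolerance_margin",
    "instantaneous_extinction_probability",
    "integrated_extinction_probability",
    "populate_locality",
    "build_world",
    "locality_distance",
]


def tolerance_margin(sp_t, sp_T, loc_t, loc_T):
    """Vectorized Tol_d = min(loc_t − sp_t, sp_T − loc_T)."""
    return np.minimum(loc_t - sp_t, sp_T - loc_T)


def tolerance_distance(species: Species, locality: "Locality") -> float:
    """Tolerance margin (°C) of a species in a locality; negative = incompatible."""
    return float(tolerance_margin(species.sp_t, species.sp_T, locality.loc_t, locality.loc_T))


def instantaneous_extinction_probability(tol_d):
    """Piecewise hazard: 0 for Tol_d >= 5, 1 for Tol_d < 0, else 1/(1 + Tol_d)."""
    tol_d = np.asarray(tol_d, dtype=float)
    p = np.where(tol_d < 0.0, 1.0, np.where(tol_d >= 5.0, 0.0, 1.0 / (1.0 + tol_d)))
    return float(p) if p.ndim == 0 else p


def integrated_extinction_probability(
    sp_t: float,
    sp_T: float,
    loc_t_start: float,
    loc_T_start: float,
    loc_t_now: float,
    loc_T_now: float,
    n_points: int = 100,
) -> float:
    """Extinction probability integrated since establishment.

    Local temperatures are reconstructed linearly between their values at
    establishment and now (temperature change is linear in time, 1 °C per
    time unit), the instantaneous probability is evaluated at ``n_points``
    equally spaced times, and the normalized (trapezoidal mean) area under
    that curve is returned, clamped to [0, 1].  If the current margin is
    already negative the probability is 1.
    """
    if tolerance_margin(sp_t, sp_T, loc_t_now, loc_T_now) < 0:
        return 1.0
    f = np.linspace(0.0, 1.0, n_points)
    lt = loc_t_start + f * (loc_t_now - loc_t_start)
    lT = loc_T_start + f * (loc_T_now - loc_T_start)
    p = instantaneous_extinction_probability(tolerance_margin(sp_t, sp_T, lt, lT))
    return float(np.clip(np.trapezoid(p, f), 0.0, 1.0))


@dataclass
class CompatibilityResult:
    tol_d: float
    instantaneous_p: float
    integrated_p: float


@dataclass
class Locality:
    """Grid cell with its resident community and (optionally) a food web.

    Community state is stored in dense pool-length arrays: ``member`` flags
    residency; ``sp_t``/``sp_T`` are per-population thermal limits (they drift
    under adaptation independently of the global pool); ``est`` is the step a
    population established; ``p_prev``/``integral``/``cum_p`` hold the running
    trapezoidal integral of the instantaneous extinction probability and the
    cumulative (integrated) extinction probability reached so far.
    """

    id: int
    lat: float
    lon: float
    loc_t: float
    loc_T: float
    loc_t0: float
    loc_T0: float
    member: np.ndarray
    sp_t: np.ndarray
    sp_T: np.ndarray
    est: np.ndarray
    p_prev: np.ndarray
    integral: np.ndarray
    cum_p: np.ndarray
    web: FoodWeb | None = None
    initial_diversity: int = 0
    _comm_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def community(self) -> np.ndarray:
        if self._comm_cache is None:
            self._comm_cache = np.flatnonzero(self.member)
        return self._comm_cache

    def invalidate_community(self) -> None:
        self._comm_cache = None

    @property
    def richness(self) -> int:
        return int(self.member.sum())

    @property
    def establishment_time(self) -> dict[int, int]:
        return {int(s): int(self.est[s]) for s in self.community}

    def copy(self, drop_web: bool = False) -> "Locality":
        return Locality(
            id=self.id, lat=self.lat, lon=self.lon,
            loc_t=self.loc_t, loc_T=self.loc_T, loc_t0=self.loc_t0, loc_T0=self.loc_T0,
            member=self.member.copy(), sp_t=self.sp_t.copy(), sp_T=self.sp_T.copy(),
            est=self.est.copy(), p_prev=self.p_prev.copy(),
            integral=self.integral.copy(), cum_p=self.cum_p.copy(),
            web=None if (drop_web or self.web is None) else self.web.copy(),
            initial_diversity=self.initial_diversity,
        )


def locality_distance(a: Locality, b: Locality) -> float:
    """Euclidean distance in degree coordinates (no wraparound)."""
    return float(np.hypot(a.lat - b.lat, a.lon - b.lon))


@dataclass
class WorldConfig:
    """Sampling ranges for world construction (inclusive integer ranges)."""

    n_localities: tuple[int, int] = (100, 500)
    n_candidates: tuple[int, int] = (100, 1000)
    build_webs: bool = True
    #: admit candidates whose tolerance margin is non-negative (the literal
    #: "niche compatibility" reading); set False to admit stochastically with
    #: probability 1 - instantaneous extinction probability instead.
    threshold_admission: bool = True
    max_attempts_factor: int = 200
    min_community: int = 5
    min_basal_share: float = 0.2


class World:
    """The virtual Earth: localities plus pairwise distances and diversity counts."""

    def __init__(self, localities: list[Locality], pool: SpeciesPool, adj: TraitAdjacency):
        if not localities:
            raise ValueError("a world needs at least one locality")
        ids = [loc.id for loc in localities]
        if len(set(ids)) != len(ids):
            raise ValueError("locality ids must be unique")
        self.localities = localities
        self.pool = pool
        self.adj = adj
        lat = np.array([l.lat for l in localities])
        lon = np.array([l.lon for l in localities])
        d = np.hypot(lat[:, None] - lat[None, :], lon[:, None] - lon[None, :])
        # distances below one cell width are clamped so 1/d stays a probability
        self.distance = np.maximum(d, 1.0)
        np.fill_diagonal(self.distance, 0.0)
        self.counts = np.zeros(len(pool), dtype=np.int64)
        for loc in localities:
            self.counts[loc.member] += 1

    def __len__(self) -> int:
        return len(self.localities)

    @property
    def richness(self) -> int:
        return int((self.counts > 0).sum())

    @property
    def tardigrade_richness(self) -> int:
        return int(((self.counts > 0) & self.pool.is_tardigrade).sum())

    def remove_from(self, loc: Locality, ids: np.ndarray) -> None:
        ids = np.asarray(ids, dtype=np.int64)
        actually = ids[loc.member[ids]]
        if len(actually):
            loc.member[actually] = False
            loc.invalidate_community()
            self.counts[actually] -= 1

    def add_to(self, loc: Locality, sp: int) -> None:
        if not loc.member[sp]:
            loc.member[sp] = True
            loc.invalidate_community()
            self.counts[sp] += 1

    def mean_abs_dT(self) -> float:
        return float(np.mean([abs(l.loc_T - l.loc_T0) for l in self.localities]))

    def mean_dT(self) -> float:
        return float(np.mean([l.loc_T - l.loc_T0 for l in self.localities]))

    def copy(self, drop_webs: bool = False) -> "World":
        new = object.__new__(World)
        new.localities = [l.copy(drop_web=drop_webs) for l in self.localities]
        new.pool = self.pool
        new.adj = self.adj
        new.distance = self.distance
        new.counts = self.counts.copy()
        return new

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [l.id for l in self.localities],
                "lat": [l.lat for l in self.localities],
                "lon": [l.lon for l in self.localities],
                "loc_t": [l.loc_t for l in self.localities],
                "loc_T": [l.loc_T for l in self.localities],
                "loc_t0": [l.loc_t0 for l in self.localities],
                "loc_T0": [l.loc_T0 for l in self.localities],
                "richness": [l.richness for l in self.localities],
                "initial_diversity": [l.initial_diversity for l in self.localities],
            }
        )

    def to_json(self, path) -> None:
        payload = {
            "localities": self.to_frame().to_dict(orient="records"),
            "communities": {int(l.id): [int(s) for s in l.community] for l in self.localities},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def populate_locality(
    cell: tuple[float, float, float, float],
    pool: SpeciesPool,
    n_candidates: int,
    rng: np.random.Generator,
    adj: TraitAdjacency | None = None,
    loc_id: int = 0,
    config: WorldConfig | None = None,
) -> Locality | None:
    """Try to found a community in a grid cell; return None on rejection.

    ``n_candidates`` species are drawn uniformly from the pool; each is
    admitted with probability equal to its climatic suitability
    (1 − instantaneous extinction probability, so a margin >= 5 °C always
    admits and a negative margin never does), or by a hard margin >= 0 check
    in threshold mode.  The locality is rejected if fewer than 5 species are
    admitted or basal species make up under 20% of them; when webs are built,
    assembly failure is also a rejection and species left without trophic
    links are dropped before finalizing.
    """
    config = config or WorldConfig()
    lat, lon, t_min, t_max = cell
    if n_candidates > len(pool):
        raise ValueError("n_candidates exceeds the species pool size")
    cand = rng.choice(len(pool), size=n_candidates, replace=False)
    told = tolerance_margin(pool.sp_t[cand], pool.sp_T[cand], t_min, t_max)
    if config.threshold_admission:
        admit = told >= 0
    else:
        suit = 1.0 - instantaneous_extinction_probability(told)
        admit = rng.random(n_candidates) < suit
    community = np.unique(cand[admit])
    if len(community) < config.min_community:
        return None
    basal = pool.trophic_level[community] == 0
    if basal.mean() < config.min_basal_share:
        return None

    web = None
    if config.build_webs:
        if adj is None:
            raise ValueError("building webs requires a trait adjacency")
        web = assemble_food_web(community, pool, adj, rng)
        prune_unconnected(web)
        # drop species left without any trophic link
        degree = web.consumers_supported() + web.resources_held()
        linkless = web.present & (degree == 0)
        if linkless.any():
            web.remove_species(np.flatnonzero(linkless))
        community = web.nodes
        if len(community) < config.min_community or not (
            pool.trophic_level[community] == 0
        ).any():
            return None
        web.compact()
        web.stock0 = web.stock_vector()  # stocks at the start of the simulation

    n = len(pool)
    member = np.zeros(n, dtype=bool)
    member[community] = True
    loc = Locality(
        id=loc_id, lat=float(lat), lon=float(lon),
        loc_t=float(t_min), loc_T=float(t_max), loc_t0=float(t_min), loc_T0=float(t_max),
        member=member,
        sp_t=pool.sp_t.copy(), sp_T=pool.sp_T.copy(),
        est=np.zeros(n, dtype=np.int64),
        p_prev=np.zeros(n), integral=np.zeros(n), cum_p=np.zeros(n),
        web=web,
        initial_diversity=len(community),
    )
    told_all = tolerance_margin(loc.sp_t, loc.sp_T, loc.loc_t, loc.loc_T)
    loc.p_prev = np.asarray(instantaneous_extinction_probability(told_all), dtype=float)
    return loc


def build_world(
    grid: ClimateGrid,
    pool: SpeciesPool,
    adj: TraitAdjacency,
    config: WorldConfig | None = None,
    seed: int = 0,
) -> World:
    """Populate a world: draw the target locality count and per-simulation
    candidate size from their uniform ranges, then fill cells until the target
    is met, replacing rejected localities with fresh random cells."""
    config = config or WorldConfig()
    rng = np.random.default_rng(seed)

    def _draw(rng_, rangeval):
        lo, hi = (rangeval, rangeval) if np.isscalar(rangeval) else rangeval
        return int(rng_.integers(lo, hi + 1))

    target = _draw(rng, config.n_localities)
    n_cand = _draw(rng, config.n_candidates)

    localities: list[Locality] = []
    attempts = 0
    max_attempts = config.max_attempts_factor * target
    while len(localities) < target:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not populate {target} localities after {attempts} attempts "
                f"({len(localities)} succeeded); the climate grid or calibration "
                "pools may be too hostile"
            )
        attempts += 1
        cell = grid.cells[int(rng.integers(0, len(grid)))]
        loc = populate_locality(
            cell, pool, n_cand, rng, adj=adj, loc_id=len(localities), config=config
        )
        if loc is not None:
            localities.append(loc)
    return World(localities, pool, adj)
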