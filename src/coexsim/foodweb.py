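"""Local food webs: assembly, basal-path pruning, connectance, export.

Links run consumer → resource and carry a weight in [0, 1] equal to the
rescaled trait accessibility of the pair; the weight is a proxy for how much
of the resource the consumer uses.  Webs keep a snapshot of the initial link
weights and of each consumer's initial resource stock (the cumulative weight
of its resource links), which anchors the co-extinction threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .species import SpeciesPool, TraitAdjacency, rescaled_accessibility_matrix

__all__ = [
    "FoodWeb",
    "expected_resource_count",
    "assemble_food_web",
    "prune_unconnected",
    "connectance",
]


class FoodWeb:
    """Weighted directed resource-use graph stored as flat link arrays.

    Node identifiers are global species ids (pool indices); per-species state
    (membership, basal flag, initial stock) lives in dense pool-length arrays
    so that cascades and recruitment vectorize.
    """

    def __init__(self, pool_size: int, cons=(), res=(), weights=(), basal_ids=()):
        self.pool_size = int(pool_size)
        self.cons = np.asarray(cons, dtype=np.int64)
        self.res = np.asarray(res, dtype=np.int64)
        self.w = np.asarray(weights, dtype=float).copy()
        self.w0 = self.w.copy()
        self.alive = np.ones(len(self.cons), dtype=bool)
        self.present = np.zeros(self.pool_size, dtype=bool)
        self.basal_mask = np.zeros(self.pool_size, dtype=bool)
        self.basal_mask[np.asarray(basal_ids, dtype=np.int64)] = True
        nodes = np.union1d(self.cons, self.res) if len(self.cons) else np.array([], int)
        self.present[nodes] = True
        self.present |= self.basal_mask
        self.stock0 = np.zeros(self.pool_size)
        np.add.at(self.stock0, self.cons, self.w)

    # -- basic queries -------------------------------------------------

    @property
    def n_links(self) -> int:
        return int(self.alive.sum())

    @property
    def nodes(self) -> np.ndarray:
        return np.flatnonzero(self.present)

    @property
    def n_nodes(self) -> int:
        return int(self.present.sum())

    def resource_ids(self, consumer: int) -> np.ndarray:
        return self.res[self.alive & (self.cons == consumer)]

    def resource_stock(self, consumer: int) -> float:
        if not self.present[consumer]:
            raise KeyError(f"species {consumer} not in web")
        return float(self.w[self.alive & (self.cons == consumer)].sum())

    def stock_vector(self) -> np.ndarray:
        """Current resource stock per species id (dense, pool-length)."""
        s = np.zeros(self.pool_size)
        np.add.at(s, self.cons[self.alive], self.w[self.alive])
        return s

    def consumers_supported(self) -> np.ndarray:
        """Number of consumers each species supports as a resource (dense)."""
        c = np.zeros(self.pool_size, dtype=np.int64)
        np.add.at(c, self.res[self.alive], 1)
        return c

    def resources_held(self) -> np.ndarray:
        """Number of resources each species holds as a consumer (dense)."""
        c = np.zeros(self.pool_size, dtype=np.int64)
        np.add.at(c, self.cons[self.alive], 1)
        return c

    # -- mutation ------------------------------------------------------

    def add_links(self, cons, res, weights, initial=None) -> None:
        cons = np.asarray(cons, dtype=np.int64)
        weights = np.asarray(weights, dtype=float)
        initial = weights if initial is None else np.asarray(initial, dtype=float)
        self.cons = np.concatenate([self.cons, cons])
        self.res = np.concatenate([self.res, np.asarray(res, dtype=np.int64)])
        self.w = np.concatenate([self.w, weights])
        self.w0 = np.concatenate([self.w0, initial])
        self.alive = np.concatenate([self.alive, np.ones(len(cons), dtype=bool)])
        self.present[cons] = True
        self.present[np.asarray(res, dtype=np.int64)] = True

    def remove_species(self, ids) -> None:
        ids = np.asarray(ids, dtype=np.int64)
        self.present[ids] = False
        gone = np.zeros(self.pool_size, dtype=bool)
        gone[ids] = True
        self.alive &= ~(gone[self.cons] | gone[self.res])

    def compact(self) -> None:
        """Drop dead link rows (bookkeeping only; no semantic change)."""
        keep = self.alive
        self.cons, self.res = self.cons[keep], self.res[keep]
        self.w, self.w0 = self.w[keep], self.w0[keep]
        self.alive = np.ones(len(self.cons), dtype=bool)

    def copy(self) -> "FoodWeb":
        new = object.__new__(FoodWeb)
        new.pool_size = self.pool_size
        for name in ("cons", "res", "w", "w0", "alive", "present", "basal_mask", "stock0"):
            setattr(new, name, getattr(self, name).copy())
        return new

    # -- export --------------------------------------------------------

    def to_edge_list(self) -> pd.DataFrame:
        a = self.alive
        return pd.DataFrame(
            {
                "consumer_id": self.cons[a],
                "resource_id": self.res[a],
                "weight": self.w[a],
                "initial_weight": self.w0[a],
            }
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(int(i) for i in self.nodes)
        for c, r, w, w0 in zip(
            self.cons[self.alive], self.res[self.alive], self.w[self.alive], self.w0[self.alive]
        ):
            g.add_edge(int(c), int(r), weight=float(w), initial_weight=float(w0))
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_edge_list(cls, df: pd.DataFrame, pool_size: int, basal_ids=()) -> "FoodWeb":
        web = cls(
            pool_size,
            df["consumer_id"].to_numpy(),
            df["resource_id"].to_numpy(),
            df["weight"].to_numpy(),
            basal_ids=basal_ids,
        )
        if "initial_weight" in df:
            web.w0 = df["initial_weight"].to_numpy(float).copy()
            web.stock0 = np.zeros(pool_size)
            np.add.at(web.stock0, web.cons, web.w0)
        return web


def expected_resource_count(specificity: float, local_richness: int) -> int:
    """Link quota for a consumer: round(specificity × richness), floored at 1.

    The floor keeps ultra-specialists from being guaranteed victims of the
    basal-path pruning step.
    """
    if local_richness < 1:
        raise ValueError("local_richness must be >= 1")
    return max(1, int(np.floor(specificity * local_richness + 0.5)))


def assemble_food_web(
    community: np.ndarray,
    pool: SpeciesPool,
    adj: TraitAdjacency,
    rng: np.random.Generator,
) -> FoodWeb:
    """Three-step linking of a locality's community into a food web.

    For each consumer (processed in random order, candidates presented in
    random order, each link forming with probability equal to the pair's
    rescaled accessibility, stopping at the consumer's expected resource
    count): (1) resources one trophic level below; (2) if the quota is unmet,
    same-level species with a smaller intra-level score; (3) if still unmet
    and TL > 1, resources two levels below.  Link weight = accessibility.
    """
    community = np.asarray(community, dtype=np.int64)
    if len(community) == 0:
        raise ValueError("community must be non-empty")
    S = len(community)
    tl = pool.trophic_level[community]
    intra = pool.intra_level_score[community]
    counts = pool.phenotype_counts[community]
    access = rescaled_accessibility_matrix(adj, counts, counts)  # (S, S) consumer x resource

    links_c: list[int] = []
    links_r: list[int] = []
    links_w: list[float] = []

    order = rng.permutation(S)
    for i in order:
        if tl[i] == 0:
            continue
        quota = expected_resource_count(float(pool.specificity[community[i]]), S)
        got: list[int] = []

        def try_candidates(mask: np.ndarray) -> None:
            need = quota - len(got)
            if need <= 0:
                return
            cand = np.flatnonzero(mask)
            if len(cand) == 0:
                return
            cand = rng.permutation(cand)
            accept = rng.random(len(cand)) < access[i, cand]
            got.extend(cand[accept][:need].tolist())

        # step 1: TL_j < TL_i <= TL_j + 1  (one level below, continuous-safe)
        try_candidates((tl < tl[i]) & (tl[i] <= tl + 1))
        # step 2: same level, smaller intra-level score
        if len(got) < quota:
            chosen = np.zeros(S, dtype=bool)
            chosen[got] = True
            try_candidates((tl == tl[i]) & (intra < intra[i]) & ~chosen)
        # step 3: two levels below
        if len(got) < quota and tl[i] > 1:
            chosen = np.zeros(S, dtype=bool)
            chosen[got] = True
            try_candidates((tl[i] - 2 <= tl) & (tl < tl[i] - 1) & ~chosen)

        for j in got:
            links_c.append(int(community[i]))
            links_r.append(int(community[j]))
            links_w.append(float(access[i, j]))

    basal_ids = community[tl == 0]
    web = FoodWeb(len(pool), links_c, links_r, links_w, basal_ids=basal_ids)
    web.present[community] = True
    return web


def prune_unconnected(web: FoodWeb) -> FoodWeb:
    """Remove consumers lacking a directed resource path to any basal species.

    Removal cascades to a fixpoint (in place) — dropping an unsupported
    consumer can orphan the species that fed on it.
    """
    supported = web.basal_mask & web.present
    while True:
        reach = supported[web.res[web.alive]]
        newly = np.zeros(web.pool_size, dtype=bool)
        newly[web.cons[web.alive][reach]] = True
        newly &= ~supported
        if not newly.any():
            break
        supported |= newly
    doomed = web.present & ~supported
    if doomed.any():
        web.remove_species(np.flatnonzero(doomed))
    return web


def connectance(web: FoodWeb, n_nodes: int | None = None) -> float:
    """Links over squared node count (the theoretical maximum link number)."""
    n = web.n_nodes if n_nodes is None else int(n_nodes)
    if n < 1:
        raise ValueError("connectance undefined for an empty web")
    return web.n_links / n**2
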