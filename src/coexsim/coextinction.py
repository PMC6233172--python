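"""Threshold-triggered co-extinction cascades with proportional reallocation.

A consumer dies when the fraction of its *initial* resource stock it has lost
reaches the co-extinction threshold (strictly positive loss required, so a
threshold of 0 kills on any loss and a threshold of 1 only on complete
depletion).  Weight freed by the extinction of consumers is redistributed —
scaled by the reallocation ratio — among the surviving consumers of each
freed resource, proportionally to their current use of it.  Removal,
re-evaluation and reallocation iterate until no new co-extinctions occur.
Basal species are never co-extinction victims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .foodweb import FoodWeb

__all__ = ["CascadeResult", "resource_stock", "reallocate", "cascade"]


@dataclass
class CascadeResult:
    """Outcome of one cascade: who died in which generation, and the survivors.

    Generation 0 holds the primary removals; generation g > 0 the consumers
    co-extinct in the g-th sweep.
    """

    extinct: list[tuple[int, int]]  # (generation, species id)
    web: FoodWeb
    lost_fraction: dict[int, float]

    @property
    def extinct_ids(self) -> list[int]:
        return [s for _, s in self.extinct]

    @property
    def n_coextinct(self) -> int:
        return sum(1 for g, _ in self.extinct if g > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [g for g, _ in self.extinct],
                "species_id": [s for _, s in self.extinct],
                "lost_fraction": [self.lost_fraction.get(s, np.nan) for _, s in self.extinct],
            }
        )


def resource_stock(web: FoodWeb, consumer: int) -> float:
    """Cumulative current weight of the consumer's resource links."""
    return web.resource_stock(consumer)


def reallocate(web: FoodWeb, freed: dict[int, float] | np.ndarray, ratio: float) -> FoodWeb:
    """Redistribute freed resource weight to surviving consumers (in place).

    For each resource with freed weight w, every remaining link on it gains
    ``ratio * w * u / sum(u)`` where u is the link's current weight.  Resources
    with no remaining consumers redistribute nothing.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    if isinstance(freed, dict):
        dense = np.zeros(web.pool_size)
        for r, w in freed.items():
            dense[r] = w
        freed = dense
    if ratio == 0.0 or not np.any(freed > 0):
        return web
    use = np.zeros(web.pool_size)
    a = web.alive
    np.add.at(use, web.res[a], web.w[a])
    share = np.zeros(len(web.w))
    res_use = use[web.res]
    ok = a & (res_use > 0)
    share[ok] = ratio * freed[web.res[ok]] * web.w[ok] / res_use[ok]
    web.w = web.w + share
    return web


def cascade(
    web: FoodWeb,
    primary_removals,
    threshold: float,
    ratio: float,
    inplace: bool = False,
) -> CascadeResult:
    """Run the co-extinction cascade triggered by a set of primary removals.

    Each sweep: remove the newly extinct species and their links, pool the
    weight their consumption freed per resource, reallocate it, then mark any
    surviving non-basal consumer whose lost fraction of initial stock is
    strictly positive and >= threshold.  Stops when a sweep adds no victims
    (or the web is empty).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    if not inplace:
        web = web.copy()

    primary = np.asarray(list(primary_removals), dtype=np.int64)
    extinct: list[tuple[int, int]] = [(0, int(s)) for s in primary]
    newly = np.zeros(web.pool_size, dtype=bool)
    newly[primary] = True
    newly &= web.present

    generation = 0
    lost_now = np.zeros(web.pool_size)
    while newly.any():
        # freed weight: consumption by dying consumers, per resource
        dying_links = web.alive & newly[web.cons]
        freed = np.zeros(web.pool_size)
        np.add.at(freed, web.res[dying_links], web.w[dying_links])

        web.remove_species(np.flatnonzero(newly))
        reallocate(web, freed, ratio)

        stock = web.stock_vector()
        consumers = web.present & ~web.basal_mask & (web.stock0 > 0)
        lost_now = np.zeros(web.pool_size)
        lost_now[consumers] = (
            web.stock0[consumers] - stock[consumers]
        ) / web.stock0[consumers]
        # strict-positive-loss guard uses a small epsilon so float noise in the
        # stock sums cannot kill a consumer at threshold 0
        victims = consumers & (lost_now > 1e-12) & (lost_now >= threshold)

        generation += 1
        newly = victims
        extinct.extend((generation, int(s)) for s in np.flatnonzero(victims))

    lost_fraction = {int(s): float(lost_now[s]) for s in np.flatnonzero(web.present)}
    return CascadeResult(extinct=extinct, web=web, lost_fraction=lost_fraction)
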