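"""Global species pool: phenotypes, trait adjacency, accessibility, similarity.

Every virtual species carries thermal tolerance limits, a trophic level with
an intra-level score, a resource specificity, and a phenotype — a multiset of
1–9 letters over a 26-trait alphabet.  A consumer's ability to use a resource
(its "accessibility") is the sum of trait-versus-trait scores in a shared
26×26 adjacency matrix, rescaled to [0,1] against Monte-Carlo-calibrated
extremes.  A small fraction of species are tardigrade-like extremophiles with
extreme tolerance limits and a grazer/micro-predator trophic position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .calibration import CalibrationPools, Guild

N_TRAITS = 26
_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

__all__ = [
    "SpeciesGuild",
    "Phenotype",
    "TraitAdjacency",
    "Species",
    "SpeciesPool",
    "build_trait_adjacency",
    "sample_phenotype_counts",
    "raw_accessibility",
    "rescaled_accessibility",
    "rescaled_accessibility_matrix",
    "trait_similarity",
    "generate_species_pool",
]


class SpeciesGuild(str, Enum):
    PLANT = "plant"
    ECTOTHERM = "ectotherm"
    ENDOTHERM = "endotherm"
    TARDIGRADE = "tardigrade"


_GUILD_CODES = {g: i for i, g in enumerate(SpeciesGuild)}
_CODE_GUILDS = {i: g for g, i in _GUILD_CODES.items()}


@dataclass(frozen=True)
class Phenotype:
    """Multiset of functional-trait letters, stored as per-trait counts."""

    counts: np.ndarray  # shape (26,), small non-negative ints

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.shape != (N_TRAITS,) or c.min() < 0:
            raise ValueError("phenotype counts must be a length-26 non-negative vector")
        if not 1 <= int(c.sum()) <= 9:
            raise ValueError("phenotype size must be between 1 and 9 traits")

    @classmethod
    def from_letters(cls, letters: str) -> "Phenotype":
        counts = np.zeros(N_TRAITS, dtype=np.int64)
        for ch in letters.upper():
            i = _ALPHABET.find(ch)
            if i < 0:
                raise ValueError(f"trait letter {ch!r} outside A–Z alphabet")
            counts[i] += 1
        return cls(counts)

    @property
    def letters(self) -> str:
        return "".join(_ALPHABET[i] * int(n) for i, n in enumerate(self.counts))

    @property
    def size(self) -> int:
        return int(self.counts.sum())


@dataclass
class TraitAdjacency:
    """26×26 trait-consumption score matrix with calibrated accessibility bounds.

    ``x[i, j]`` is the degree to which consumer trait *i* grants access to a
    resource bearing trait *j* (negative values protect the resource).
    ``ca_min``/``ca_max`` are the empirical extremes of raw accessibility over
    many random phenotype pairs, used to rescale raw sums to [0, 1].
    """

    x: np.ndarray
    ca_min: float | None = None
    ca_max: float | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (N_TRAITS, N_TRAITS):
            raise ValueError("trait adjacency must be 26×26")
        if np.abs(self.x).max() > 1.0:
            raise ValueError("trait adjacency entries must lie in [-1, 1]")

    @property
    def calibrated(self) -> bool:
        return (
            self.ca_min is not None
            and self.ca_max is not None
            and self.ca_min < self.ca_max
        )

    def to_frame(self) -> pd.DataFrame:
        letters = list(_ALPHABET)
        return pd.DataFrame(self.x, index=letters, columns=letters)


def sample_phenotype_counts(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 26) trait-count matrix; sizes uniform on 1..9, letters uniform A–Z."""
    sizes = rng.integers(1, 10, size=n)
    counts = np.zeros((n, N_TRAITS), dtype=np.int16)
    p = np.full(N_TRAITS, 1.0 / N_TRAITS)
    for s in range(1, 10):
        mask = sizes == s
        k = int(mask.sum())
        if k:
            counts[mask] = rng.multinomial(s, p, size=k)
    return counts


def build_trait_adjacency(seed: int, n_calibration_pairs: int = 1_000_000) -> TraitAdjacency:
    """Random uniform(-1,1) trait matrix with Monte-Carlo accessibility bounds.

    The bounds are the observed extremes of raw accessibility across
    ``n_calibration_pairs`` random consumer/resource phenotype pairs
    (1 million by default).
    """
    if n_calibration_pairs < 1000:
        raise ValueError("n_calibration_pairs must be >= 1000")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1.0, 1.0, size=(N_TRAITS, N_TRAITS))
    adj = TraitAdjacency(x)
    cons = sample_phenotype_counts(n_calibration_pairs, rng).astype(float)
    res = sample_phenotype_counts(n_calibration_pairs, rng).astype(float)
    ca = np.einsum("ij,jk,ik->i", cons, x, res, optimize=True)
    adj.ca_min = float(ca.min())
    adj.ca_max = float(ca.max())
    return adj


def raw_accessibility(adj: TraitAdjacency, consumer: Phenotype, resource: Phenotype) -> float:
    """Sum of x[i, j] over consumer traits i and resource traits j (with multiplicity)."""
    return float(consumer.counts @ adj.x @ resource.counts)


def rescaled_accessibility(
    adj: TraitAdjacency, consumer: Phenotype, resource: Phenotype
) -> float:
    """Accessibility mapped to [0, 1]: 1 - (ca_max - ca) / (ca_max - ca_min).

    Raw values outside the calibrated extremes (possible: the bounds are
    Monte-Carlo estimates) are clamped.
    """
    if not adj.calibrated:
        raise ValueError("trait adjacency is not calibrated (ca_min/ca_max unset)")
    ca = raw_accessibility(adj, consumer, resource)
    val = 1.0 - (adj.ca_max - ca) / (adj.ca_max - adj.ca_min)
    return float(np.clip(val, 0.0, 1.0))


def rescaled_accessibility_matrix(
    adj: TraitAdjacency, consumer_counts: np.ndarray, resource_counts: np.ndarray
) -> np.ndarray:
    """Vectorized rescaled accessibility: rows = consumers, cols = resources."""
    if not adj.calibrated:
        raise ValueError("trait adjacency is not calibrated (ca_min/ca_max unset)")
    ca = consumer_counts.astype(float) @ adj.x @ resource_counts.astype(float).T
    val = 1.0 - (adj.ca_max - ca) / (adj.ca_max - adj.ca_min)
    return np.clip(val, 0.0, 1.0)


def trait_similarity(p1: Phenotype | np.ndarray, p2: Phenotype | np.ndarray) -> float:
    """2·M/T similarity of two phenotypes (1 identical, 0 disjoint).

    M is the number of letter matches counted with multiplicity and T the total
    number of traits in both phenotypes.
    """
    c1 = p1.counts if isinstance(p1, Phenotype) else np.asarray(p1)
    c2 = p2.counts if isinstance(p2, Phenotype) else np.asarray(p2)
    m = np.minimum(c1, c2).sum()
    t = c1.sum() + c2.sum()
    return float(2.0 * m / t)


@dataclass(frozen=True)
class Species:
    id: int
    guild: SpeciesGuild
    sp_t: float  # lower thermal limit, °C
    sp_T: float  # upper thermal limit, °C
    trophic_level: float
    intra_level_score: float
    specificity: float
    phenotype: Phenotype

    def __post_init__(self):
        if not self.sp_t < self.sp_T:
            raise ValueError("sp_t must be below sp_T")


@dataclass
class SpeciesPool:
    """Columnar container for the global species pool (pool index = species id)."""

    sp_t: np.ndarray
    sp_T: np.ndarray
    trophic_level: np.ndarray
    intra_level_score: np.ndarray
    specificity: np.ndarray
    guild_code: np.ndarray  # int8 codes into SpeciesGuild order
    phenotype_counts: np.ndarray  # (n, 26) int16

    def __len__(self) -> int:
        return len(self.sp_t)

    def __getitem__(self, i: int) -> Species:
        return Species(
            id=int(i),
            guild=_CODE_GUILDS[int(self.guild_code[i])],
            sp_t=float(self.sp_t[i]),
            sp_T=float(self.sp_T[i]),
            trophic_level=float(self.trophic_level[i]),
            intra_level_score=float(self.intra_level_score[i]),
            specificity=float(self.specificity[i]),
            phenotype=Phenotype(self.phenotype_counts[i].astype(np.int64)),
        )

    @property
    def is_basal(self) -> np.ndarray:
        return self.trophic_level == 0

    @property
    def is_tardigrade(self) -> np.ndarray:
        return self.guild_code == _GUILD_CODES[SpeciesGuild.TARDIGRADE]

    def species(self) -> list[Species]:
        return [self[i] for i in range(len(self))]

    def to_frame(self) -> pd.DataFrame:
        letters = [
            Phenotype(c.astype(np.int64)).letters for c in self.phenotype_counts
        ]
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "guild": [_CODE_GUILDS[int(g)].value for g in self.guild_code],
                "sp_t": self.sp_t,
                "sp_T": self.sp_T,
                "trophic_level": self.trophic_level,
                "intra_level_score": self.intra_level_score,
                "specificity": self.specificity,
                "phenotype": letters,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_species_pool(
    pools: CalibrationPools,
    n_total: int = 100_000,
    tardigrade_count: int = 100,
    trajectory: str = "heating",
    seed: int = 0,
    endotherm_probability: float = 0.001,
) -> SpeciesPool:
    """Draw the global species pool from the calibration pools.

    Each species gets a trophic record; basal species (TL = 0) take plant
    tolerance limits, consumers take endotherm limits with probability
    ``endotherm_probability`` (endotherms are ~3 orders of magnitude rarer
    than ectotherms) and ectotherm limits otherwise.  ``tardigrade_count``
    species are overridden as extremophiles: trophic level drawn from {1, 2},
    and, per trajectory, upper limit a uniform integer in [50, 100] (heating,
    lower limit -20 °C) or lower limit a uniform integer in [-80, -50]
    (cooling, upper limit 40 °C).
    """
    if trajectory not in ("heating", "cooling"):
        raise ValueError("trajectory must be 'heating' or 'cooling'")
    if tardigrade_count > n_total:
        raise ValueError("tardigrade_count cannot exceed n_total")
    for name in ("plant_lower", "ectotherm_lower", "endotherm_lower", "trophic_level"):
        if len(getattr(pools, name)) == 0:
            raise ValueError(f"calibration pool {name!r} is empty")

    rng = np.random.default_rng(seed)
    n = int(n_total)

    tro_idx = rng.integers(0, len(pools.trophic_level), size=n)
    tl = pools.trophic_level[tro_idx].copy()
    spec = pools.specificity[tro_idx].copy()
    basal = tl == 0

    sp_t = np.empty(n)
    sp_T = np.empty(n)
    guild = np.empty(n, dtype=np.int8)

    k = int(basal.sum())
    pick = rng.integers(0, len(pools.plant_lower), size=k)
    sp_t[basal] = pools.plant_lower[pick]
    sp_T[basal] = pools.plant_upper[pick]
    guild[basal] = _GUILD_CODES[SpeciesGuild.PLANT]

    cons = ~basal
    k = int(cons.sum())
    endo = rng.random(k) < endotherm_probability
    for mask_local, lower, upper, code in (
        (endo, pools.endotherm_lower, pools.endotherm_upper, SpeciesGuild.ENDOTHERM),
        (~endo, pools.ectotherm_lower, pools.ectotherm_upper, SpeciesGuild.ECTOTHERM),
    ):
        idx = np.flatnonzero(cons)[mask_local]
        pick = rng.integers(0, len(lower), size=len(idx))
        sp_t[idx] = lower[pick]
        sp_T[idx] = upper[pick]
        guild[idx] = _GUILD_CODES[code]

    intra = rng.random(n)
    intra[basal] = 0.0
    spec[basal] = 1.0

    # tardigrade-like extremophiles override a random subset
    tard = rng.choice(n, size=tardigrade_count, replace=False)
    if tardigrade_count:
        guild[tard] = _GUILD_CODES[SpeciesGuild.TARDIGRADE]
        tl[tard] = rng.choice([1.0, 2.0], size=tardigrade_count)
        nb = pools.trophic_level > 0
        if nb.any():
            spec[tard] = rng.choice(pools.specificity[nb], size=tardigrade_count)
        intra[tard] = rng.random(tardigrade_count)
        if trajectory == "heating":
            sp_T[tard] = rng.integers(50, 101, size=tardigrade_count).astype(float)
            sp_t[tard] = -20.0
        else:
            sp_t[tard] = rng.integers(-80, -49, size=tardigrade_count).astype(float)
            sp_T[tard] = 40.0

    counts = sample_phenotype_counts(n, rng)
    return SpeciesPool(
        sp_t=sp_t,
        sp_T=sp_T,
        trophic_level=tl,
        intra_level_score=intra,
        specificity=spec,
        guild_code=guild,
        phenotype_counts=counts,
    )
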