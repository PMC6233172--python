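"""Robustness metrics, scenario comparison and food-web disassembly.

Robustness is the area under the curve of surviving diversity fraction versus
normalized environmental change (1 = no loss, 0 = instant collapse).  The
headline statistic is the percentage by which a tolerance-only scenario
overestimates that robustness relative to the co-extinction scenario:
100 · (AUC_tol − AUC_co) / AUC_co.

Disassembly probes a single web's robustness by removing species in a given
order (thermal-tolerance order, importance order, or random) and cascading
co-extinctions after every removal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coextinction import cascade
from .dynamics import DiversityCurve, SimulationConfig, run_paired
from .foodweb import FoodWeb
from .species import SpeciesPool

__all__ = [
    "RobustnessResult",
    "DisassemblyCurve",
    "ExperimentConfig",
    "ExperimentResult",
    "robustness_auc",
    "underestimation_pct",
    "disassemble",
    "run_experiment",
]

DISASSEMBLY_ORDERS = ("heat_tolerance", "cold_tolerance", "best", "worst", "random")


@dataclass
class RobustnessResult:
    auc: float
    scenario: str
    direction: str
    config: dict = field(default_factory=dict)


@dataclass
class DisassemblyCurve:
    removed: np.ndarray  # species removed so far (directly)
    surviving_fraction: np.ndarray
    order: str
    initial_richness: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"removed": self.removed, "surviving_fraction": self.surviving_fraction}
        )


def robustness_auc(curve: DiversityCurve | DisassemblyCurve) -> float:
    """Trapezoidal area of surviving fraction vs normalized progress, in [0, 1].

    Progress is step/n_steps for a trajectory curve and direct removals over
    initial richness for a disassembly curve.
    """
    if isinstance(curve, DisassemblyCurve):
        y = curve.surviving_fraction
        x = curve.removed / max(curve.initial_richness, 1)
    else:
        y = curve.surviving_fraction()
        x = curve.step / curve.step[-1]
    if len(y) == 0:
        raise ValueError("empty curve")
    return float(np.clip(np.trapezoid(y, x), 0.0, 1.0))


def underestimation_pct(r_tolerance: float, r_coextinction: float) -> float:
    """How much ignoring co-extinctions inflates robustness, in percent."""
    if r_coextinction <= 0:
        raise ValueError("co-extinction robustness must be positive (undefined otherwise)")
    return 100.0 * (r_tolerance - r_coextinction) / r_coextinction


def disassemble(
    web: FoodWeb,
    pool: SpeciesPool,
    order: str,
    threshold: float,
    ratio: float,
    seed: int = 0,
    importance: str = "consumers",
) -> DisassemblyCurve:
    """Remove species one by one per the order, cascading after each removal.

    Orders: ``heat_tolerance`` — ascending upper thermal limit (least
    heat-tolerant first); ``cold_tolerance`` — descending lower limit (least
    cold-tolerant first); ``best``/``worst`` — ascending/descending importance
    (number of consumers supported by default, resources held with
    ``importance='resources'``), computed once on the intact web; ``random``.
    """
    if order not in DISASSEMBLY_ORDERS:
        raise ValueError(f"order must be one of {DISASSEMBLY_ORDERS}")
    web = web.copy()
    nodes = web.nodes
    n0 = len(nodes)
    if n0 == 0:
        raise ValueError("web is empty")
    rng = np.random.default_rng(seed)

    if order == "heat_tolerance":
        sequence = nodes[np.argsort(pool.sp_T[nodes], kind="stable")]
    elif order == "cold_tolerance":
        sequence = nodes[np.argsort(-pool.sp_t[nodes], kind="stable")]
    elif order in ("best", "worst"):
        score = (
            web.consumers_supported() if importance == "consumers" else web.resources_held()
        )[nodes]
        sequence = nodes[np.argsort(score, kind="stable")]
        if order == "worst":
            sequence = sequence[::-1]
    else:
        sequence = rng.permutation(nodes)

    removed = [0]
    frac = [1.0]
    k = 0
    for sp in sequence:
        if not web.present[sp]:
            continue  # already gone through an earlier cascade
        k += 1
        cascade(web, [int(sp)], threshold, ratio, inplace=True)
        removed.append(k)
        frac.append(web.n_nodes / n0)
        if web.n_nodes == 0:
            break
    return DisassemblyCurve(
        removed=np.asarray(removed), surviving_fraction=np.asarray(frac),
        order=order, initial_richness=n0,
    )


@dataclass
class ExperimentConfig:
    """Replicated paired-scenario experiment with per-replicate random parameters.

    Each replicate samples the co-extinction threshold, reallocation ratio,
    adaptation probability, locality count, candidate sample size and
    colonization frequencies from their uniform ranges, builds one world, and
    runs the tolerance and co-extinction change phases on it.
    """

    n_replicates: int = 50
    direction: str = "heating"
    seed: int = 0
    base: SimulationConfig = field(default_factory=SimulationConfig.desk_scale)
    threshold_range: tuple[float, float] = (0.0, 1.0)
    ratio_range: tuple[float, float] = (0.0, 1.0)
    adaptation_range: tuple[float, float] = (0.0, 0.0001)
    per_step_attempts_range: tuple[int, int] = (1, 20)
    preliminary_events_range: tuple[int, int] = (1000, 5000)


@dataclass
class ExperimentResult:
    table: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_experiment(config: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Run paired simulations over randomly parametrized replicates.

    Emits one row per replicate (sampled parameters, both AUCs, the
    underestimation percentage and the tardigrade collapse ΔT of the
    co-extinction run) plus min/mean/median/max summaries.
    """
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(config.n_replicates):
        cfg = dataclasses.replace(
            config.base,
            direction=config.direction,
            coextinction_threshold=float(rng.uniform(*config.threshold_range)),
            reallocation_ratio=float(rng.uniform(*config.ratio_range)),
            adaptation_probability=float(rng.uniform(*config.adaptation_range)),
            per_step_colonization_attempts=int(
                rng.integers(config.per_step_attempts_range[0],
                             config.per_step_attempts_range[1] + 1)
            ),
            preliminary_colonization_events=int(
                rng.integers(config.preliminary_events_range[0],
                             config.preliminary_events_range[1] + 1)
            ),
            seed=int(rng.integers(0, 2**31)),
        )
        res_tol, res_co = run_paired(cfg)
        auc_tol = robustness_auc(res_tol.curve)
        auc_co = robustness_auc(res_co.curve)
        rows.append(
            {
                "replicate": rep,
                "direction": config.direction,
                "threshold": cfg.coextinction_threshold,
                "ratio": cfg.reallocation_ratio,
                "adaptation_probability": cfg.adaptation_probability,
                "per_step_attempts": cfg.per_step_colonization_attempts,
                "preliminary_events": cfg.preliminary_colonization_events,
                "initial_richness": res_co.curve.initial_richness,
                "auc_tolerance": auc_tol,
                "auc_coextinction": auc_co,
                "underestimation_pct": underestimation_pct(auc_tol, auc_co)
                if auc_co > 0
                else np.nan,
                "tardigrade_collapse_dt": res_co.curve.collapse_delta_t("tardigrade"),
            }
        )
        if progress:
            print(f"replicate {rep + 1}/{config.n_replicates} done", flush=True)

    table = pd.DataFrame(rows)
    under = table["underestimation_pct"].dropna()
    collapse = table["tardigrade_collapse_dt"].dropna()
    summary = {
        "direction": config.direction,
        "n_replicates": config.n_replicates,
        "underestimation_min": float(under.min()) if len(under) else np.nan,
        "underestimation_median": float(under.median()) if len(under) else np.nan,
        "underestimation_mean": float(under.mean()) if len(under) else np.nan,
        "underestimation_max": float(under.max()) if len(under) else np.nan,
        "tardigrade_collapse_mean_dt": float(collapse.mean()) if len(collapse) else np.nan,
        "auc_tolerance_mean": float(table["auc_tolerance"].mean()),
        "auc_coextinction_mean": float(table["auc_coextinction"].mean()),
    }
    return ExperimentResult(table=table, summary=summary)
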