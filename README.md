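# coexsim

A virtual-Earth simulator for quantifying how **co-extinctions** — consumers
starving after the loss of their resources — amplify climate-driven
biodiversity collapse.

Ecologists and network scientists can use it to ask: if you subject a planet
of interconnected food webs to relentless heating (or a nuclear-winter style
cooling), how much faster does life disappear than single-species thermal
tolerances alone would predict?

## The model

A global pool of virtual species carries empirically plausible traits:

- **thermal limits** `sp_t < sp_T` (°C), drawn from synthetic pools calibrated
  so that plant lower/upper limits have medians 1.3 / 23.7 °C and animal
  limits 23.4 / 35.0 °C (with published 1σ spreads);
- a **trophic level** (0 = basal producer), an intra-level score, and a
  **specificity** that scales its expected number of resource links;
- a **phenotype** — a multiset of 1–9 letters over a 26-trait alphabet. A
  consumer's accessibility to a resource is the sum of trait-pair scores in a
  shared random 26×26 matrix, rescaled to [0, 1] against Monte-Carlo extremes:
  `ca̅ = 1 − (ca_max − ca) / (ca_max − ca_min)`.

Species are dropped into 1°×1° localities with Earth-like temperature extremes
(`loc_t`, `loc_T`) and admitted when compatible; each community is wired into
a weighted food web (links form with probability `ca̅`, weights equal `ca̅`,
consumers stop at `round(specificity × richness)` resources, and species
without a path to a basal resource are pruned).

Climate change shifts each locality's extremes by N(0.01, 0.0025) °C per step
for 5000 steps (~50 °C total; amplified up to 2× poleward of 60°). A species'
compatibility margin is

```
Tol_d = min(loc_t − sp_t, sp_T − loc_T)
```

with instantaneous extinction probability 0 for `Tol_d ≥ 5`, 1 for
`Tol_d < 0`, else `1/(1 + Tol_d)`, integrated over each population's residence
time. Two scenarios run on identical worlds and climate draws:

- **tolerance** — only these primary extinctions;
- **co-extinction** — primary losses additionally trigger cascades: a consumer
  dies when the lost fraction of its initial resource stock reaches a
  threshold θ ∈ [0, 1]; freed resource weight is redistributed to surviving
  consumers (reallocation ratio ∈ [0, 1]). Dispersal/colonization and
  distance-weighted recruitment rescue communities in between.

Robustness is the area under the surviving-fraction vs normalized-change
curve; the headline statistic is the **underestimation percentage**
`100 · (AUC_tol − AUC_co) / AUC_co`. Tardigrade-like extremophiles (huge
thermal margins, trophic level 1–2) probe whether tolerance alone predicts
survival — it does not: they die with their webs.

## Worked example

```python
from coexsim import SimulationConfig, run_paired, robustness_auc, underestimation_pct

cfg = SimulationConfig.desk_scale(seed=42)   # 2000 species, 20-50 localities
res_tol, res_co = run_paired(cfg)            # same world, same climate draws
a_tol, a_co = robustness_auc(res_tol.curve), robustness_auc(res_co.curve)
print(f"AUC tolerance     {a_tol:.3f}")
print(f"AUC co-extinction {a_co:.3f}")
print(f"underestimation   {underestimation_pct(a_tol, a_co):.0f}%")
print(f"tardigrade collapse at {res_co.curve.collapse_delta_t():.1f} °C")
```

prints (exact values vary with the seed):

```
AUC tolerance     0.055
AUC co-extinction 0.021
underestimation   162%
tardigrade collapse at 2.1 °C
```

Ignoring co-extinctions makes planetary life look ~2.6× more robust than it
is in this replicate, and the extremophiles — individually tolerant up to
50–100 °C — vanish after only ~2 °C of heating, when the webs feeding them
have collapsed.

The same machinery is scriptable from the shell:

```bash
coexsim simulate --trajectory heating --scenario coextinction --seed 1 --out run/
coexsim experiment --trajectory cooling --reps 20 --out exp/
coexsim disassemble --orders heat_tolerance,cold_tolerance,best,worst --reps 10
```

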