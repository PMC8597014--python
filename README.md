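# acetylkinetics

Kinetic modelling of acetyl-group migration and hydrolysis in mannan
oligo- and polysaccharides.

Acetyl esters on β-(1→4)-mannans wander: under mildly alkaline, aqueous
conditions they migrate between the O2 and O3 hydroxyls of a mannose unit,
hop across the glycosidic bond to the primary O6 of the neighbouring unit,
and are slowly hydrolysed. Because O-acetylation controls the physical and
biological properties of hemicelluloses such as spruce galactoglucomannan
(GGM), the rates of these processes matter to anyone studying plant cell
walls, hemicellulose-based materials, or acetylated-polysaccharide
pharmacology.

This package implements the two base-catalysed pseudo-first-order reaction
networks used to quantify those processes from ¹H-NMR time courses:

* a **7-species trisaccharide scheme** (species `1a`–`1g`, every
  acetylation pattern of a doubly acetylated manno-trisaccharide down to
  the deacetylated product), and
* a **4-unit GGM scheme** (mannose units `A` = O3-Ac, `B` = O2-Ac,
  `C` = O6-Ac, `D` = deacetylated),

both parameterised by five tied rate constants (h⁻¹ at pH 8):
`k_O2→O6`, `k_O3→O2`, `k_O2→O3`, `k_prim.hydr`, `k_sec.hydr`. Every rate
carries the hydroxide correction `10^(pH−8)`, so a drifting pH only
reparametrises time: with `τ(t) = ∫₀ᵗ 10^(pH(s)−8) ds`, the model is the
linear system `c(t) = expm(K·τ(t))·c₀` for a mass-conserving generator
matrix `K`. Rate constants are estimated by minimising

```
SSQ = Σ_t Σ_i (c_model(i,t) − c_observed(i,t))²
```

with a simplex + Levenberg–Marquardt-style staged optimiser wrapped around
the forward simulation, and reported with linearised standard errors
`s²(JᵀJ)⁻¹` and an R²-style degree of explanation. A synthetic-data module
generates realistic noisy time courses (geometric sampling over four
weeks, pH drift 7.95 → 7.75, Gaussian integral noise) so the entire
pipeline is testable by parameter recovery without any external data. See
`docs/methods.md` for the full model description and numerical choices.

## Worked example

Jointly fit the five constants to two synthetic migration experiments
(starting from the doubly acetylated `1a` and from the O6-acetylated `1b`),
generated with the published trisaccharide constants, a pH drift from 7.95
to 7.75 over four weeks, and σ = 0.005 noise on the fractions:

```python
import numpy as np
from acetylkinetics import (
    FitConfig, GeneratorConfig, NoiseModel, PhDriftModel,
    constants_preset, fit_rate_constants, generate_dataset,
)

truth = constants_preset("table1")
datasets = [
    generate_dataset(GeneratorConfig(
        constants=truth, start=start,
        ph_model=PhDriftModel(kind="linear", ph_start=7.95, ph_end=7.75, horizon=672.0),
        noise=NoiseModel(sigma=0.005, seed=i),
    ))
    for i, start in enumerate(("from_1a", "from_1b"))
]
result = fit_rate_constants(datasets, FitConfig(initial_guess=truth.as_dict(),
                                                multistart_count=1))
print(f"SSQ = {result.ssq:.4g}, degree of explanation = {result.degree_of_explanation:.2f} %")
for name, value in result.estimates.as_dict().items():
    print(f"{name:12s} {value:.3e} +- {result.standard_errors[name]:.2e} h^-1")
```

prints

```
SSQ = 0.007117, degree of explanation = 99.96 %
k_O2_O6      2.057e-03 +- 1.93e-05 h^-1
k_O3_O2      1.878e+00 +- 4.22e-02 h^-1
k_O2_O3      1.019e+00 +- 2.43e-02 h^-1
k_prim_hydr  1.913e-03 +- 1.43e-05 h^-1
k_sec_hydr   1.560e-03 +- 8.13e-06 h^-1
```

i.e. all five generating constants are recovered well within their
standard errors despite the pH drift — the hydroxide correction removes
the confounding exactly. The fast-exchange pair implies an O2:O3
quasi-equilibrium of `k_O3→O2/(k_O3→O2 + k_O2→O3) ≈ 65:35` for the
trisaccharide (and ≈ 61:39 for GGM, where `k_O2→O3` is locked at 1 h⁻¹
because the polysaccharide is already at migration equilibrium).

The same workflow is scriptable from the shell:

```sh
acetylkinetics generate --model tri --constants-preset table1 --seed 1 --out run/
acetylkinetics fit run/dataset.csv --ph-log run/ph_log.csv \
    --constants-preset table1 --out run/fit
acetylkinetics recover --model ggm --constants-preset table2-2mg \
    --replicates 20 --sigma 0.005 --seed 1 --out run/recovery
```

## Layout

* `src/acetylkinetics/kinetics.py` — networks, pH correction, rate matrix,
  stiff (BDF) and exact (matrix-exponential) simulation
* `src/acetylkinetics/fitting.py` — SSQ objective, staged fitting,
  standard errors, degree of explanation
* `src/acetylkinetics/timecourse_io.py` — time-course / pH-log / peak-
  integral CSV formats
* `src/acetylkinetics/synthetic.py` — dataset generator and
  parameter-recovery experiments
* `src/acetylkinetics/cli.py` — `acetylkinetics simulate|generate|fit|recover`
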