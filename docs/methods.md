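# Methods

## The model

Acetyl esters on partially acetylated mannans migrate between hydroxyl
positions and are slowly hydrolysed under mildly alkaline conditions. The
package implements two base-catalysed pseudo-first-order reaction networks:

**Trisaccharide scheme (7 species).** A β-(1→4)-linked manno-trisaccharide
carrying two acetyls is tracked through every acetylation pattern:

| species | acetylation |
|---|---|
| 1a | central-unit O2-Ac + O3-Ac |
| 1b | reducing-end O6-Ac + central O3-Ac |
| 1c | reducing-end O6-Ac + central O2-Ac |
| 1d | O3-Ac only |
| 1e | O2-Ac only |
| 1f | O6-Ac only |
| 1g | deacetylated |

Five tied constants parameterise all transitions: the slow trans-glycosidic
migration `k_O2→O6` (1a→1b, 1e→1f), the fast intra-unit exchange pair
`k_O3→O2` (1b→1c, 1d→1e) and `k_O2→O3` (reverse), hydrolysis from the
primary position `k_prim.hydr` (1b→1d, 1c→1e, 1f→1g) and from the secondary
positions `k_sec.hydr` (1a→1d, 1a→1e, 1b→1f, 1c→1f, 1d→1g, 1e→1g). The
doubly acetylated 1a loses either of its two secondary acetyls, giving the
factor 2 in its own loss term. The back-migration O6→O2 (1b→1a) is
experimentally negligible and is omitted from the scheme; the transition
table is the single place to add it for sensitivity studies. One tie in the
published constant list is internally inconsistent with the rate laws
(`k_prim.hydr` listed for a transition that already carries `k_O2→O6`);
the network follows the rate laws, assigning `k_prim.hydr` to 1f→1g.

**GGM scheme (4 units).** For galactoglucomannan the state is the
acetylation pattern of a mannose unit: A (O3-Ac) ⇌ B (O2-Ac) → C (O6-Ac)
→ D (deacetylated), with A→D and B→D at `k_sec.hydr` and C→D at
`k_prim.hydr`, using the same five-constant vocabulary.

Both networks are linear: `dc/dt = f(t) · K · c`, where `K` is a generator
matrix (non-negative off-diagonals, zero column sums — mass is conserved
exactly) and `f(t)` is the hydroxide correction below.

## pH correction and transformed time

All rates are proportional to [OH⁻]. The correction factor
`f = 10^(pH − 8)` normalises to the hydroxide concentration at pH 8
(10⁻⁶ M), so all reported constants are "at pH 8"; `f` is exactly 1 at
pH 8 and, e.g., a drop from 7.95 to 7.75 multiplies every rate by
`10^(−0.2) ≈ 0.63`, a 37 % decrease. A start-referenced variant (factor 1
at the initial pH) is available through `PhProfile.reference_ph`.

Because the same scalar multiplies every rate, a drifting pH is exactly a
time reparametrisation: with `τ(t) = ∫₀ᵗ 10^(pH(s) − 8) ds`, the solution is
`c(t) = expm(K · τ(t)) · c₀`. pH logs are linearly interpolated in pH
between samples and held constant outside the logged span (weekly pH-meter
readings are sparse; linear-in-pH is smooth and adequate); `τ` is integrated
analytically on each linear segment (the integrand is an exponential).

## Forward simulation

Two routes are implemented and cross-checked:

* `simulate` — SciPy's BDF (backward-differentiation) stiff integrator with
  analytic Jacobian `f(t)·K`, rtol 1e-8 / atol 1e-10. The constants span
  ~3 orders of magnitude (1.88 vs 1.56e-3 h⁻¹), so the system is stiff on
  the month-long horizons of interest.
* `simulate_closed_form` — the exact matrix-exponential solution in
  transformed time, evaluated by eigendecomposition of `K` (with an
  incremental `expm` fallback when the eigenbasis is ill-conditioned or the
  decomposition does not reconstruct `K` to 1e-10).

The property suite asserts agreement within 1e-6 per component over 100
randomised instances (constants uniform in [0, 2] h⁻¹, Dirichlet initial
states, random two-point pH drifts), mass conservation to 1e-8 over
1000 h, and monotone growth of the absorbing deacetylated species.
Round-off negatives are clipped to zero only on output, never inside the
integrator. The fitting objective uses the closed-form route by default
(exact and ~10× faster for this linear system); `FitConfig(simulator="bdf")
` selects the stiff integrator.

## Fitting

The objective is the unweighted sum of squares
`SSQ = Σ_t Σ_i (c_model − c_observed)²` pooled over datasets, time points
and observed species, with missing observations (NaN) excluded. Several
datasets (e.g. the 1a-start and 1b-start experiments) share one constant
vector in a joint fit; single-dataset fits are possible but weakly identify
the fast-exchange pair.

Optimisation runs in log10-parameter space (conditioning across the three
decades), with default bounds [1e-8, 1e2] h⁻¹, staged as Nelder-Mead
simplex (robustness) followed by a Levenberg-Marquardt-style trust-region
least-squares refinement; bounds force the `trf` variant rather than plain
LM. Multistart (default 5 starts, deterministic from the config seed)
perturbs the initial guess multiplicatively by uniform factors in
[0.5, 1.5]. Accepted steps never increase SSQ; a fit started at the optimum
stays there. Locked constants (e.g. `k_O2→O3 = 1.00 h⁻¹` in the GGM fits,
where the pre-equilibrated O2:O3 ratio leaves only the ratio identifiable)
are held bit-exactly.

Standard errors are the linearised `s²(JᵀJ)⁻¹` with `s² = SSQ/(n − p)` and
`J` the sensitivity of the simulated observations to each free constant by
central differences with relative step 1e-4 in log space (robust to solver
noise at the configured tolerances). A rank-deficient `J` triggers an
identifiability warning and undefined errors for the affected parameters.
The degree of explanation is `100·(1 − SSQ/Σ(c_obs − mean)²)`; the mean is
the grand mean pooled over all observed values by default (per-species
centring is available), and the statistic is undefined (NaN) for
zero-variance data.

## Synthetic data generator

The generator emulates the measurement process: ¹H-NMR acetyl-peak-derived
species fractions over a four-week experiment. Defaults:

* **Sampling** — 25 points geometrically spaced from 1 h to 672 h: the
  O2⇌O3 exchange equilibrates within hours while hydrolysis takes weeks, so
  early density is what identifies the fast pair.
* **pH** — linear drift 7.95 → 7.75 over 672 h, matching the observed
  dissolution pH and end-of-run readings; constant and
  exponential-approach drifts are available.
* **Noise** — additive Gaussian, σ = 0.005 absolute mole fraction, a
  plausible ¹H-integral precision (synthetic; the experimental integration
  error is not reported). Noisy fractions are clipped to [0, 1] and, by
  default, rows are rescaled to the conserved clean total.
* **Starts** — `from_1a`/`from_1b` (pure starting compound; an
  `initial_hydrolyzed_fraction`, e.g. the ~10 % already hydrolysed at the
  first measurement, is moved into 1d/1e at the O2:O3 equilibrium split) and
  `ggm_default` = (A, B, C, D) = (0.39, 0.61, 0, 0): acetyl-bearing units
  normalised to 1 with the 61:39 O2:O3 ratio and no O6 signal at t₀.
  Never-acetylated mannose units are invisible to acetyl-peak NMR and are
  excluded from the state.

What the generator does **not** emulate: peak overlap and baseline error
(noise is i.i.d. Gaussian, real integral errors are correlated), free-
acetate interference, the mechanism behind the concentration dependence in
GGM (each concentration is an independent constant set), and temperature
effects. Passing recovery tests therefore demonstrate estimator
correctness and calibration under the stated noise model, not robustness
to structured NMR artefacts.

`recovery_experiment` repeats generate-fit cycles (replicate seeds spawned
from a master seed) and reports per-parameter relative bias, relative RMSE,
median absolute relative error and ±2-SE coverage. With the default joint
1a/1b design at σ = 0.005, the migration constants are recovered with
median absolute relative error of a few percent and ~95 % nominal ±2-SE
coverage; noise-free round trips recover the generating constants to well
below 0.1 %.

## Numerical and design choices

* Problem sizes in the test and acceptance workflows (25 sample times,
  20 replicates, 100 randomised oracle instances) are chosen so the full
  self-consistency study runs in seconds while leaving all estimates
  well-resolved.
* Species orderings (1a…1g, A…D) are fixed everywhere, including CSV
  headers, for reproducible matrices and byte-stable files (values printed
  with 10 significant digits).
* Dataset row sums may exceed 1 by up to 0.05 to admit unnormalised noisy
  fractions; grossly misnormalised files (row sum 1.2) are rejected.
* Peak integrals: a doubly acetylated species' two singlets are averaged
  (each is an independent 3H reporter of the same molar concentration).
  The deacetylated species is only reconstructible by difference under the
  "normalise to t₀ total" convention, which is provided but not asserted
  as the historical quantification method.
* τ = 0 returns the initial state exactly (identity propagator short-cut).

## Known limitations

* Rate constants are condition-specific (100 mM phosphate, 25 °C);
  no ionic-strength or temperature dependence is modelled.
* The GGM model treats units independently (mean-field over the chain);
  inter-chain interactions that likely cause the concentration dependence
  are out of scope.
* Linearised standard errors understate uncertainty for strongly nonlinear
  or near-unidentifiable fits; no profile likelihood or Bayesian intervals
  are provided.
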