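# Methods

This note documents the statistical models implemented in `healthdea`,
the defaults of the synthetic-data generator, the numerical choices, and
what the test suite does and does not establish.

## Inequality measurement

**Gini.** `gini` implements the share formula
`G = Σ P_i Y_i + 2 Σ P_i (1 − V_i) − 1` on cities ranked ascending by
per-capita (or per-km²) holdings. This is algebraically identical to the
trapezoid Lorenz-area formula `1 − Σ P_i (V_i + V_{i−1})`, which the
tests use as an independent oracle (agreement to 1e−12 on random share
vectors). Ties in the ranking are broken by city id; `G` itself is
invariant to tie order, the reported ranking is just made deterministic.
Cities with zero resource are allowed (they sort first). Fairness band
labels use the conventional cutoffs 0.2 / 0.3 / 0.4 / 0.5 with boundary
values assigned to the fairer band.

**Theil.** `theil` uses the natural logarithm throughout,
`T = Σ P_i ln(P_i/Y_i)`; the same base is used by the entropy weights,
which keeps the two internally consistent. A `log` argument exposes
base-10 for sensitivity checks. Note that with this definition `T` is
*not* bounded by 1 for extreme concentration; no clamping is applied.
Zero resource shares with positive population shares are a domain error
(the logarithm is undefined), reported rather than smoothed. The
decomposition `T = Σ_g P_g T_g + Σ_g P_g ln(P_g/Y_g)` is an exact
identity; within-region indices `T_g` are computed on shares
renormalised inside each region.

**HRDI.** The geometric mean of resource per 1000 persons and resource
per km². Population is carried as end-of-year residents; the package
does not enforce a mid-year versus end-of-year convention.

## Entropy weights and the composite indicator

Min-max normalisation per criterion; entropies
`e_j = −Σ p_ij ln p_ij / ln m` with `p ln p → 0` at `p = 0`; weights
`w_j = (1 − e_j)/(n − Σ e_j)`. A constant criterion is undefined under
min-max scaling; it is assigned `e_j = 1`, hence weight 0, with a
warning — a criterion that does not discriminate between cities should
not influence the composite. The composite indicator defaults to the
weighted sum of the *raw* indicator values (`C_i = Σ w_j a_ij`); because
raw indicators carry incommensurable units, a `normalized` mode that
weights the min-max-scaled values is provided as well (that mode is
invariant to affine rescaling of any criterion). Weights are computed
per year across cities; a pooled computation is a caller-side choice
(pass multiple years' rows as one matrix).

## DEA programs

All three programs are input-oriented and assume constant returns to
scale. They are solved as linear programs with HiGHS
(`scipy.optimize.linprog`).

* **CCR (two-phase).** Phase I minimises the radial contraction θ;
  phase II maximises the residual slacks at fixed θ. The reported
  *total* slack per input is observed minus frontier target, i.e.
  radial plus non-radial reduction — the quantity the stage-2 regression
  explains. (`CCRResult.input_targets` lets a caller recover the
  radial-only decomposition if wanted.)
* **SBM (standard).** `δ = min (1/m) Σ x̄_i/x_io` over reference points
  `X λ ≤ x̄ ≤ x_o` with `Y λ ≥ y_o`; δ ∈ (0, 1] and δ ≤ θ always.
* **Super-efficiency SBM.** Same objective with the evaluated DMU
  excluded from the reference set and `x̄ ≥ x_o`; δ ≥ 1. Because the
  output bundle is fixed at `y_o`, the objective is already linear — no
  Charnes–Cooper transform is needed. If no combination of the other
  DMUs can produce `y_o` (a sole producer of some output), the program
  is infeasible and the score is reported as `inf`.

`efficiency_score` composes the two the way results are reported:
standard SBM below 1, super-SBM at or above 1. The classification
tolerance is 1e−6 (a score ≥ 1 − 1e−6 counts as efficient), safely
below the 3-decimal reporting precision and safely above LP solver
noise (feasibility tolerance 1e−9). Zero outputs are permitted; zero
or negative inputs are rejected at validation, since the SBM ratios
require strictly positive inputs. Multiple optimal λ are possible;
only scores, slacks and targets are contractual, not λ.

## Stage-2 stochastic frontier

Each input's slack vector is regressed on the six environmental
variables (standardised, plus an intercept) with the composed error of
a cost frontier, `ε = v + u`, `v ~ N(0, σ_v²)`, `u ~ N⁺(0, σ_u²)`:

    ln L = Σ [ ln 2 − ln σ + ln φ(ε/σ) + ln Φ(ε λ/σ) ],
    σ² = σ_u² + σ_v²,  λ = σ_u/σ_v,  γ = σ_u²/σ².

An intercept is always included: slacks have positive mean by
construction. The likelihood is maximised over `(β, ln σ², logit γ)` —
the logit keeps γ inside (0, 1) — from three starts (γ₀ ∈ {0.1, 0.5,
0.9}) seeded at the OLS solution with the intercept shifted by the
implied mean inefficiency `σ_u √(2/π)`; each start runs BFGS then a
Nelder–Mead polish. The Gaussian OLS fit is the exact γ → 0 limit and
is always retained as a candidate, so the reported log-likelihood never
falls below the OLS log-likelihood and the LR statistic is never
negative. Identification caveat: the frontier *intercept* trades off
against the mean of the one-sided error, so its sampling error is much
larger than that of the slope coefficients; recovery checks therefore
target the slopes and γ.

**JLMS.** `E[u|ε] = (λσ/(1+λ²)) [φ(z)/Φ(z) + z]` with `z = ελ/σ`. The
Mills ratio is evaluated via `log_ndtr`, so the formula stays finite for
arbitrarily negative residuals. Noise is recovered as the complement
`v̂ = ε̂ − û`, which conserves residuals exactly. At γ = 0 the
estimates degenerate to `û = 0`, `v̂ = ε̂`.

**LR test.** `LR = 2(lnL − lnL_OLS)` is compared with the equal mixture
`½χ²₀ + ½χ²₁` appropriate for a parameter on the boundary; the critical
value at level α is the upper-2α quantile of χ²₁ (5.412 at 1%). The
mixture is asymptotic; in simulations at n ≈ 150 the empirical size
runs somewhat above nominal, which the size test acknowledges by
accepting up to 2.5× the nominal level.

**Adjustment.** `X^A_ij = X_ij + [max_j Z_j β̂_i − Z_j β̂_i] +
[max_j v̂_ij − v̂_ij]`. The first bracket is written here with the
max over DMUs of the *fitted environmental slack*; both brackets are
non-negative, so adjusted inputs never fall below observed inputs and
the city facing the worst environment and worst luck is left untouched.
An input whose slacks are all (numerically) zero — every city efficient
in that input — is carried through unadjusted with an audit note, as is
any input whose frontier regression fails.

## Synthetic province generator

The generator emulates a province of 21 cities in four development
regions (9/4/3/5), one dominant high-development region, observed over
several years. It is the test oracle: no published data-generating
process exists for this setting, so the generator documents its own.

* **Outputs first, frontier inputs derived.** Per-capita output rates
  (visits 2.0, discharges 0.11, examinations 0.30 per person; revenue
  1.6e−6 billion per person) are shifted by a city development index δ
  (region effect plus city noise) with elasticities 0.15–0.25 and mild
  year growth. Frontier inputs follow the constant-returns Cobb–Douglas
  inverse `x*_i = A_i Π_r y_r^{α_ir}` with row-stochastic elasticities;
  the constants `A_i` are calibrated so a baseline five-million-person
  city uses 45 hospitals, 16 000 beds and 20 000 technicians.
* **Observed inputs** exceed the frontier by three multiplicative
  factors: an environment-driven slack `exp(Z̃ β)` (default β small and
  negative on GDP, urbanisation, education, insurance and health
  spending — better environments waste less), half-normal managerial
  inefficiency `u` (σ_u = 0.25, shared by a city's three inputs:
  management is a city trait) whose scale can drift with the
  environment index (`u_env_scale` = 0.2), and log-normal noise `v`
  (σ_v = 0.10). True efficiency is `exp(−u)`; γ_true = σ_u²/(σ_u²+σ_v²).
* **City sizes are deliberately comparable** (log-normal, sd 0.08,
  region means 5.5 vs 4.8 million). The stage-2 regression explains
  slack *levels* with environmental variables; with strongly
  heterogeneous city sizes those levels are dominated by scale rather
  than environment and the additive adjustment is not meaningful. Real
  provinces are more size-heterogeneous than this; see Limitations.
* **`inequality_level`** rescales every log-deviation of the four
  resource indicators from exact population-proportionality; at 0 the
  per-capita allocation is identical everywhere (every
  population-basis Gini is exactly 0), at 1 the calibrated dispersion
  applies. The applied `u` and `v` recorded in the ground truth are
  scaled consistently.
* Randomness is split deterministically by (variable, city, year) with
  `SeedSequence`, so adding a variable does not perturb earlier draws
  and a fixed seed reproduces the panel bit for bit.

The recovery experiments freeze one "strong environmental confounding"
condition: 42 cities (so the seven-parameter slack regressions are well
identified), σ_u = 0.4, σ_v = 0.05, environmental slack coefficients
three times the default, and no environment-dependence of σ_u (the
confounding runs purely through the additive slack channel that the
stage-2 model is built to remove). Under this condition, across 25
seeded replicates, stage-3 scores rank-correlate with true efficiency
better than stage-1 scores, and the environment explains less stage-3
than stage-1 score variance, in at least 80% of replicates.

## Aggregation and quadrants

Provincial and regional means are unweighted arithmetic means of city
scores; a city is efficient when its composite score is ≥ 1 − 1e−6;
the efficient share is reported in percent. Pooled multi-year region
means equal means of the yearly region means for balanced panels.
Quadrant thresholds are the unweighted means of the supplied cities;
a coordinate exactly on a threshold counts as "high", consistent with
the right-inclusive ≥ 1 efficiency rule. Two endowment axes are
supported: the HRDI of the entropy-weighted composite indicator, and
per-thousand-person government subsidies. Report tables round scores to
3 decimals, inequality indices and densities to 4, percentages to 2.

## Problem sizes used in tests

Oracle agreement uses 1000 random share vectors (Gini), 200 random
panels (Theil) and 100 random DEA instances with at most 6 DMUs; SFA
recovery uses 50 replicates at n = 500; LR size and power use 150
replicates at n = 150 and 30 at n = 200; the pipeline recovery
experiment uses 25 replicates of the 42-city condition above. The full
suite runs in about two minutes on one CPU.

## Limitations

* The stage-2 regression models slack levels linearly in the
  environmental variables, as is conventional; it carries no size
  offset. On panels with realistic (order-of-magnitude) city-size
  heterogeneity the adjustment degrades instead of helping — the
  pipeline runs, but stage-3 scores should then be interpreted with
  care. The generator's comparable-size default reflects the conditions
  under which the method's own logic is coherent.
* Slacks are censored at zero (efficient cities), which the Gaussian
  plus half-normal error structure ignores; this is inherited from the
  method, not resolved.
* The LR test's mixed-χ² reference is asymptotic; at n ≈ 21 (one year
  of one province) its size is appreciably distorted, so stage-2 test
  decisions on real-sized panels are indicative only.
* Efficiency scores depend on the chosen input/output set; undesirable
  outputs, quality indicators and variable returns to scale are out of
  scope, as are bootstrap confidence intervals for Gini and Theil.
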