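# healthdea

Equity and efficiency analysis of regional public-hospital resource
allocation, built for health-systems researchers who work with
city-by-year panels of resource stocks (hospitals, beds, health
technicians, government subsidies), service outputs (visits, discharges,
examinations, medical revenue) and environmental covariates.

The package puts both questions — *is the allocation fair?* and *is it
used efficiently?* — into one framework:

**Equity.** For a resource with city amounts `Y_i` and population (or
area) shares `P_i`, the Gini coefficient is computed directly from the
Lorenz ranking,

    G = Σ P_i Y_i + 2 Σ P_i (1 − V_i) − 1,

with `V_i` the cumulative resource share after sorting cities by
per-capita (or per-km²) holdings. The Theil index
`T = Σ P_i ln(P_i/Y_i)` is decomposed into within- and between-region
parts, `T = Σ_g P_g T_g + Σ_g P_g ln(P_g/Y_g)`, with contribution rates
per region. The health resource density index (HRDI) is the geometric
mean of a resource's density per thousand persons and per km². An
entropy-weight scheme turns the four resource indicators into one
comprehensive endowment indicator per city.

**Efficiency.** An improved three-stage DEA under constant returns to
scale:

1. *Stage 1* — input-oriented CCR programs give each city's total input
   slacks; a composite SBM / super-efficiency SBM score ranks all cities
   (inefficient ones score < 1 by the slack-based measure, efficient
   ones ≥ 1 by the super-efficiency program that excludes them from
   their own reference set).
2. *Stage 2* — each input's slack vector is regressed on six
   environmental variables with a half-normal stochastic frontier,
   `S_j = Z_j β + v_j + u_j`, `v ~ N(0, σ_v²)`, `u ~ N⁺(0, σ_u²)`;
   the JLMS conditional expectation `E[u|ε]` separates managerial
   inefficiency from noise, and every city's inputs are raised to the
   worst observed environment and worst observed luck:
   `X^A = X + [max f(Z;β̂) − f(Z;β̂)] + [max v̂ − v̂]`.
3. *Stage 3* — the SBM / super-SBM scores are recomputed on the
   adjusted inputs, so the final ranking reflects management rather than
   environment or chance.

Finally, cities are placed in a two-dimensional **coordination matrix**
(resource endowment × stage-3 efficiency, thresholds at the all-city
means), separating "adequate and efficient" from the three problem
quadrants.

A seeded synthetic-province generator (`simulate_panel`) produces
21-city, 4-region panels with a known production frontier, known
inefficiency and known environmental confounding, so every stage is
testable with ground truth.

## Worked example

```bash
healthdea simulate --seed 4 --years 2020 --outdir out
healthdea equity out/panel.csv --outdir out
healthdea three-stage out/panel.csv --outdir out
```

The synthetic province (seed 4) prints, in `out/gini.csv`:

| resource    | basis      | G      | band            |
|-------------|------------|--------|-----------------|
| hospitals   | population | 0.1217 | absolutely fair |
| beds        | population | 0.0973 | absolutely fair |
| technicians | population | 0.1159 | absolutely fair |
| subsidies   | population | 0.3620 | relatively fair |
| subsidies   | area       | 0.5496 | very unfair     |

i.e. staff and beds are allocated nearly proportionally to population,
government subsidies much less so, and every resource is distributed
less equitably over geography than over population. `out/theil.csv`
attributes 77.0% of subsidy inequality to between-region differences.
`out/three_stage_summary.csv` reports the adjusted efficiency summary

```
year  provincial_mean  efficient_count  efficient_share_pct  ...
2020  0.835            3                14.29
```

with per-city stage-1/stage-3 scores in `out/three_stage_scores.csv`
and the SFA audit (γ̂, log-likelihoods, convergence) in
`out/three_stage_audit.csv`.

The same operations are available as a library:

```python
import healthdea as hd

panel, truth = hd.simulate_panel(hd.SimConfig(seed=4, years=(2020,)))
result = hd.run_three_stage(panel, 2020)
summary = hd.summarize_scores(result.cities, result.stage3_scores,
                              dict(zip(result.cities, result.regions)))
```

## Layout

| module                  | contents                                             |
|-------------------------|------------------------------------------------------|
| `healthdea.panel`       | panel CSV reading/validation, result-table writing   |
| `healthdea.simulate`    | synthetic province generator with ground truth       |
| `healthdea.equity`      | Lorenz, Gini, Theil decomposition, HRDI              |
| `healthdea.weighting`   | entropy weights and composite indicator              |
| `healthdea.dea`         | CCR, SBM and super-efficiency SBM linear programs    |
| `healthdea.sfa`         | half-normal frontier MLE, JLMS, LR test, adjustment  |
| `healthdea.pipeline`    | three-stage orchestration, summaries, quadrants      |
| `healthdea.guangdong`   | published Guangdong reference aggregates             |
| `healthdea.cli`         | `healthdea` command-line interface                   |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
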