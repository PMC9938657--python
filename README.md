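# compgrowth

Analysis toolkit for **compensatory growth** trials in juvenile whiteleg
shrimp (*Litopenaeus vannamei*): after a short period of feed restriction,
shrimp returned to satiation feeding grow faster than continuously fed
controls, often catching up completely while consuming less feed. This
package quantifies that response on three fronts:

1. **Nitrogen turnover kinetics.** After a diet switch, muscle δ¹⁵N relaxes
   exponentially from its baseline toward equilibrium with the new diet:

   C(t) = Cₙ + (C₀ − Cₙ) · e^−(k+m)t

   where *k* (day⁻¹) is the exponential growth rate (isotopic change through
   tissue accretion) and *m* (day⁻¹) the metabolic turnover rate (replacement
   of existing tissue nitrogen). *k* is measured from weights,
   k = ln(W_final/W_initial)/days; *m* is estimated by bounded nonlinear
   least squares. Derived summaries: the residence half-time
   t₅₀ = ln 2/(k + m) and the percentage split of isotopic change between
   growth (100·k/(k+m)) and metabolism (100·m/(k+m)).
2. **Zootechnical performance.** WG (%) = 100·(FW − IW)/IW,
   SGR (% day⁻¹) = 100·(ln FW − ln IW)/days, cumulative feed intake per
   shrimp (FI), FCR = FI/(FW − IW), survival, and per-window interval SGRs.
3. **Group comparisons and community summaries.** One-way ANOVA with Tukey
   HSD and compact-letter displays; Shannon diversity (nats) and
   bias-corrected Chao1 richness on OTU count tables, with rank-level
   relative abundances.

A seeded synthetic-data module simulates whole cohorts (weights, feed,
δ¹⁵N series, Dirichlet-multinomial OTU tables) with the structure of a
35-day trial — initial weight 0.44 ± 0.03 g, treatments Control / T3
(70% restriction, 3 d) / T6 (70% restriction, 6 d), δ¹⁵N from 8.53‰
toward 14.31‰ — so the full pipeline runs and is tested without any
external data. The turnover fitter is a scikit-learn estimator
(`NitrogenTurnoverModel`) and composes with sklearn tooling.

## Worked example

```bash
compgrowth run --out-dir demo --seed 7
```

simulates the default three-treatment cohort and writes the report bundle.
`demo/turnover.tsv` (abridged):

| treatment | k | m | k–m contribution (%) | t50 | letters (m) |
|-----------|--------|--------|-----|------|---|
| Control | 0.0584 | 0.0308 | 65 – 35 | 7.8 | a |
| T3 | 0.0627 | 0.0146 | 81 – 19 | 9.0 | b |
| T6 | 0.0649 | 0.0000 | 100 – 0 | 10.7 | c |

Reading: restricted shrimp grow faster during recovery (higher *k*), and
their isotopic change is driven almost entirely by tissue accretion — the
metabolic turnover rate *m* drops from 0.0308 day⁻¹ (Control) toward zero
under the longest restriction, so dietary nitrogen resides longer in
muscle (t₅₀ rises from 7.8 to 10.7 days). The T6 estimate sits on the
m ≥ 0 bound and is flagged (`at_boundary`). Letters come from Tukey tests
on per-replicate fits: treatments sharing no letter differ at p < 0.05.
`demo/performance.tsv` shows the catch-up growth (WG 670 ± 5% Control vs
691 ± 12% T3 and 636 ± 14% T6 with lower FCR in the restricted groups),
and `demo/diversity.tsv` the per-sample Shannon/Chao1 values.

The same stages are available piecewise (`compgrowth simulate`,
`performance`, `turnover`, `compare`, `diversity`) and as library calls
(`compgrowth.run_pipeline`, `fit_metabolic_turnover`, `one_way_anova`, …).

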