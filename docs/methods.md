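# Methods

## The incorporation model and what it assumes

Tissue δ¹⁵N after a diet switch is modelled as a single well-mixed
nitrogen pool approaching equilibrium with the new diet:

C(t) = Cₙ + (C₀ − Cₙ)·e^−(k+m)t,

with C₀ the baseline value fixed by the pre-switch diet, Cₙ the
asymptotic value in equilibrium with the new diet, k the exponential
growth rate and m the metabolic turnover rate, both in day⁻¹ and both
assumed constant over the fitted window. The model ignores isotopic
routing, discrimination drift, and multi-pool (fast/slow) dynamics;
consequently it is fitted only over the post-restriction window where
growth is close to a single exponential. k is not a free parameter: it
is measured from weights over the same window (natural logarithm — the
rate that appears in the model's exponent), leaving m as the only
kinetic unknown. Derived quantities are t₅₀ = ln 2/(k+m) and the
growth/metabolism split (100·k/(k+m), 100·m/(k+m)), which sums to 100
by construction.

## Fitting

`NitrogenTurnoverModel` minimises the residual sum of squares of the
model over the observations inside the fit window (default days 7–35,
inclusive), with m constrained to [0, m_max] (default m_max = 0.2 day⁻¹,
far above any plausible muscle turnover rate in juvenile penaeids).
Replicate observations at a time point enter the SSE individually — no
pre-averaging — which preserves within-day variance for the bootstrap.
The optimiser is a bounded trust-region least-squares solve restarted
from a fixed grid of initial values (0, 0.005, 0.02, 0.05, 0.1 day⁻¹);
the best SSE wins, making the fit deterministic in its inputs. Estimates
within solver tolerance (1e−8) of a bound are snapped onto the bound and
flagged `at_boundary` rather than reported as spuriously interior; a
negative m is never reported. If every start fails the model falls back
to a coarse grid minimum and sets `converged_ = False` with a warning —
never silently. The standard error of m comes from the scaled covariance
of the fit, with a Gauss–Newton curvature fallback when the covariance
is degenerate (e.g. at the boundary). The asymptote Cₙ is fixed at the
observed equilibrium value by default; co-estimating it is supported
(`fit_cn`), changes the residual degrees of freedom, and is flagged in
every output. At least three distinct time points inside the window are
required; fewer raise `FitError`.

Uncertainty beyond the curvature SE comes from a case-resampling
bootstrap that resamples observations with replacement *within* each
time point (preserving the sampling design) and refits; percentile
intervals are reported. Because no per-tank isotope series exist (three
individuals per treatment per day, unpaired), significance letters on m
and t₅₀ are derived from per-replicate-index pseudo-fits: the r-th
pseudo-series takes the r-th observation at every day. The pairing is
arbitrary and is documented as such; it supplies the replicate structure
a letters display needs, not a claim about how any particular trial
computed its dispersions.

## Synthetic cohorts

The generator emulates a 35-day trial on juvenile *L. vannamei*
(12 shrimp × 3 tanks per treatment, initial weight 0.44 ± 0.03 g,
sampling days 0, 3, 6, 9, 14, 21, 28, 35 with 3 individuals per
treatment per day; δ¹⁵N baseline 8.53‰, asymptote 14.31‰).

* **Growth** is piecewise exponential with three phase rates. Defaults:
  Control grows at 0.0583 day⁻¹ throughout (0.44 g → ≈3.38 g at day 35);
  T3 and T6 grow at 0.020 day⁻¹ during 3 or 6 days of 70% restriction,
  then compensate at 0.0639 / 0.0666 day⁻¹ until day 28, reaching full
  catch-up (≈3.47 g / ≈3.23 g). Individual noise is multiplicative
  lognormal (sd 0.05 on the log scale) on top of the drawn initial
  weight.
* **Isotopes** follow the incorporation model with the *piecewise*
  cumulative growth exponent, C(t) = Cₙ + (C₀−Cₙ)·exp(−(K(t) + m·t)),
  so restriction slows the growth-driven part of the enrichment exactly
  as it slows growth. Per-treatment m defaults are 0.033 / 0.018 / 0.008
  day⁻¹. Gaussian noise, default sd 0.2‰ — a design choice between the
  reported day-0 (±0.1‰) and asymptotic (±0.26‰) dispersions, since
  within-day replicate sds are otherwise unreported. An optional additive
  enrichment offset during restriction (default 0) emulates the δ¹⁵N
  enrichment that nutrient recycling under restriction can cause.
* **Feed** is ration-fraction × tank biomass per day: baseline 11% of
  biomass, cut by the restriction fraction while restricting, elevated
  to 13% (T3) / 14% (T6) during the hyperphagia window (end of
  restriction to day 14). Tank biomass starts from the tank's simulated
  day-0 total and grows along the treatment trajectory, giving realistic
  between-tank FI variance.
* **Microbiome** counts are Dirichlet-multinomial around a fixed
  ~60-OTU profile dominated by Proteobacteria/Rhodobacteraceae (~88%),
  with Actinobacteria (~8%) and minor phyla, at configurable depth.

One integer seed drives named substreams per component and treatment;
identical configuration + seed reproduces every table byte for byte.

What the generator does **not** emulate: mortality as a process
(survival is a configuration constant), the mid-trial redistribution of
a fourth replicate tank, satiation feeding that declines with body size
(the ration fraction is constant by design, so simulated FI and FCR are
higher in absolute terms than a real trial's, though their ordering
across treatments is preserved), day-to-day environmental variation, and
sequence-level read error. Passing tests therefore demonstrate that the
estimators recover known generating values under the trial's design and
noise levels — not that real data meet the model's assumptions.

A consequence worth knowing: the pipeline fits a *constant* k (measured
over the window) to series generated with the *piecewise* exponent, the
same approximation an analysis of real restricted cohorts makes. For
long restrictions this mismatch biases m toward zero — the default T6
fit lands on the m = 0 bound and is flagged — while the treatment
ordering of m and t₅₀ is preserved. Parameter-recovery claims are
therefore made with the constant-rate generator
(`simulate_isotope_observations`), where the fit is unbiased (mean bias
≲ 1e−4 day⁻¹ at the trial's noise level).

## Performance metrics

Computed per tank (IW/FW = tank mean individual weight at the first and
last sampled day; FI = cumulative feed per day-0 head count), then
summarised as mean ± SD across tanks (n = number of tanks). A pooled
alternative recomputes the metrics from treatment-level mean weights;
the two conventions legitimately disagree at printed precision (e.g.
634% vs 640% weight gain from the same data), which is why both are
exposed and the per-tank convention is the default. Survival excludes
individuals removed for scheduled sampling from the denominator.

## Group statistics

One-way ANOVA (F from the classical between/within decomposition, p
from the F distribution) and Tukey HSD delegate to scipy; unequal group
sizes use the Tukey–Kramer standard error. The compact-letter display is
computed by insert-and-absorb: start with one letter set holding all
groups, split any set containing a significantly different pair, absorb
subsets. Letters are ordered by descending group mean with ties broken
by label, so displays are reproducible; minimality of the letter count
is verified against exhaustive search for up to five groups. Groups with
fewer than two observations are rejected by name.

## Diversity

Shannon entropy is reported in nats (the log base is an option, since
conventions differ), over OTUs with nonzero count. Chao1 uses the
bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) by default so
doubleton-free samples are defined; the classic form is a flag. No
rarefaction is applied by default; a seeded rarefaction utility is
provided. All-zero samples are rejected, never silently scored.

## Numerical and reporting choices

* Presentation rounding in TSV reports mirrors the field's tables (WG
  integer, contributions integer, t₅₀ one decimal); JSON twins always
  carry full precision.
* The run log echoes the fully resolved configuration and every seed, so
  a run is reproducible from its log alone; logs contain no timestamps,
  keeping outputs byte-stable.
* Problem sizes used by the shipped studies — 200 simulations per
  treatment for parameter recovery, bootstrap resamples of 100–500,
  20 000 label permutations for the Tukey oracle — were chosen as the
  smallest sizes at which the Monte-Carlo error is comfortably below the
  effects being checked.

## Known limitations

Single-pool, single-element (¹⁵N) kinetics only; no trophic
discrimination modelling; no two-pool or time-varying-m models. The
ANOVA letters on turnover parameters rest on pseudo-replicate fits (see
above). The CLI reads whole tables into memory and is sized for
trial-scale data, not sequencing-scale matrices.
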