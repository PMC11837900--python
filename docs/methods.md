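# Methods

## Isotope quantification

Delta values are relative isotope abundances, `δ = (R_sample/R_standard −
1) × 1000 ‰`, referenced to Vienna PeeDee Belemnite (carbon) and
atmospheric N₂ (nitrogen). Raw machine deltas are recalibrated with a
two-point linear map anchored on two laboratory standards per element
(glycine and threonine reference materials); the fitted line reproduces
both standards exactly (interpolation, checked to 1e-12), and fitting
fails loudly if the two measured values coincide. Calibration is fit
independently for C and N.

Enrichment factors are `ε = δ_specimen − mean δ of the plot's autotrophic
references`. The plot baseline is the arithmetic mean over the reference
plants of the same 2 m × 2 m quadrat; fewer than three usable references
is an error, not a warning, because the baseline's sampling error
propagates directly into every focal ε of that plot. Reference plants
receive diagnostic ε values against their own plot mean, which therefore
average to exactly zero within each plot. Specimens in plots without a
baseline raise rather than being silently dropped.

The linear two-source mixing model estimates percent fungal-derived
carbon as `%Cdf = (ε¹³C / ε¹³C_fmh) × 100`, where `ε¹³C_fmh` is the mean
carbon enrichment of protocorms — the obligately mycoheterotrophic stage
— pooled over all protocorm records (one global endpoint). Design
choices:

- Only the carbon channel enters the model; ε¹⁵N is computed identically
  for reporting but never used in `%Cdf`.
- Estimates are not clamped to [0, 100]; negative values (specimens more
  depleted than their references) and values above 100 keep their sign
  and carry an out-of-range flag, consistent with the unconstrained
  linear model.
- When no protocorms are available the model refuses to guess and asks
  for an explicit `endpoint=` value (e.g. from the literature).
- Protocorms are whole-plant tissue while adult values come from leaves;
  no tissue correction is applied. Incorporated fungal biomass likely
  biases protocorm ¹⁵N low, one reason the nitrogen channel stays out of
  the mixing model.
- Summary statistics report the sample SD (n−1 denominator); SD is
  reported missing for n = 1 rather than zero.

## Community profiling

OTUs are assigned to coarse trophic guilds through a family → guild map
with per-OTU overrides (for families straddling guilds, e.g. an
ECM-forming clade inside an otherwise rhizoctonia family). Only guilds in
a whitelist — rhizoctonia, saprotrophic non-rhizoctonia, ectomycorrhizal
and other orchid-mycorrhizal fungi — are retained before abundance
computation; the map must cover every family present or it errors naming
the gap.

Relative abundances are computed on reads pooled within each stratum
(fraction = taxon reads / stratum reads), not as means of per-sample
fractions; this matches the "X reads, Y % of all reads" reporting
convention and weights samples by depth. The denominator is the total of
*retained* OTUs within the stratum being described. Because published
percentage sets of this kind are not always mutually consistent across
strata, the filtering step is separate and skippable (`--no-filter`), so
either denominator convention can be reproduced. No rarefaction or depth
normalization is applied — outputs are raw read sums alongside fractions.
Dominance summaries sort by fraction with lexicographic tie-breaks, so
ordering is deterministic.

## Group inference

Isotope metrics are compared among the four specimen categories with a
linear mixed model: category as fixed term (cell-means coding), a random
intercept for population, and plot as a nested variance component, fitted
by REML (statsmodels MixedLM, L-BFGS with a Powell fallback). Degenerate
designs are handled by dropping unidentifiable random terms: a factor
with a single level contributes nothing and its variance is reported as
the boundary value 0; with no random structure left, the fit collapses to
OLS on group means (and a constant response short-circuits to OLS, where
all variance components are exactly zero).

Post hoc comparisons use the Tukey–Kramer studentized-range procedure,
valid for unequal group sizes:

    q_ab = |m_a − m_b| / sqrt((MSE/2)(1/n_a + 1/n_b)),  p = P(Q_{k,df} ≥ q_ab)

with residual degrees of freedom `n − k`. Model-based df corrections
(Satterthwaite, Kenward–Roger) would widen intervals slightly at these
sample sizes but are deliberately not used: the n − k convention is
simple, reproducible, and its family-wise error calibration is verified
by simulation (10 000 null replicates give a rejection rate within
[0.04, 0.06] at α = 0.05). At k = 2 the adjusted p-value reduces exactly
to the pooled two-sample t-test p-value (q = √2·|t|), which is how the
per-trait morph comparison is implemented. Phenotypic traits are analyzed
per individual with no random terms.

## Synthetic data

The generator reproduces the study conditions: three populations, five
quadrats each, three autotrophic references per quadrat; per-population
focal counts 4/8, 4/5 and 8/6 plants with/without coralloid rhizomes, and
five protocorms confined to the third population. Group enrichment
offsets default to the reported statistics — ε¹³C (mean/SD, ‰) 3.9/1.7
for coralloid plants, 1.3/1.7 without, 6.7/0.2 for protocorms; ε¹⁵N
3.8/1.1, 3.1/1.5 and 1.1/0.7 — around autotroph bases of δ¹³C −31.5 ±
1.5‰ and δ¹⁵N −1.8 ± 1.3‰. The protocorm ε¹⁵N default is *derived* from
group δ¹⁵N means (−0.7 − (−1.8) = 1.1‰), not itself a reported value.
Plot and population intercept SDs (0.5‰ each) are design assumptions:
no within/between-plot variance decomposition for reference plants is
available to pin them.

Noise placement is deliberate: focal offsets are added to the plot's
*true* reference mean, while the pipeline estimates that mean from the
sampled references — so estimated ε carries realistic baseline-estimation
error (≈ SD/√3 per plot, shared by plot-mates). Consequently the
realized SD of estimated protocorm ε exceeds the configured 0.2‰ draw
SD; parameter-recovery tests account for this by using empirical standard
errors. With all SDs zeroed the design collapses to its fixed point:
every coralloid specimen has ε¹³C = 3.9‰ and %Cdf = 3.9/6.7 × 100 =
58.2 %.

OTU counts are Dirichlet-multinomial: per sample, taxon proportions are
drawn from a Dirichlet centred on the (morph, organ) composition profile
with concentration 50 — visible but non-degenerate compositional
variation (no dispersion estimate exists to calibrate against) — then
reads are multinomial at 20 000 per sample. Dominant-family fractions of
the default profiles are pinned to the observed per-stratum dominance
(92.17 % / 85.14 % saprotroph share in rhizomes and roots of coralloid
plants; 45.78 % rhizoctonia and 28.58 % saprotroph share without); the
split of the remainder over minor families is an assumption. Families are
split into two OTUs with 4:1 within-family weights. Traits are truncated
normals (at 0) with counts rounded to integers and Fv/Fm clipped to
[0, 1].

Randomness: one root seed, spawned into independent substreams per
dataset (isotopes, OTUs, traits), so each dataset is reproducible on its
own and identical seeds give identical draws.

What the generator does **not** emulate: spatial covariance between
quadrats, depth variation between samples, index hopping/chimeras or any
sequence-level artifact, correlation between a plant's isotope signature
and its community profile, and measurement-device drift. Passing tests
therefore demonstrate the estimators' correctness under the stated
sampling model, not robustness to those real-data features.

## Problem sizes and numerical choices

The default suite runs the full design (~85 specimens, ~50 samples) plus
a 600-specimen parameter-recovery run, a 200-replicate power check
(coralloid vs non-coralloid ε¹³C difference detected in ≥95 % of runs at
default effect sizes), and the 10 000-replicate null calibration; the
whole suite completes in well under a minute. REML convergence tolerance
follows statsmodels defaults with variances implicitly initialized from
the response scale; the family-wise error simulation compares the maximal
q statistic against the studentized-range critical value (identical to
"any adjusted p < α", avoiding 60 000 survival-function evaluations).
Ties in dominance ranking, row ordering after grouping, and report column
order are all deterministic.

## Known limitations

- The linear mixing model assumes the protocorm endpoint transfers across
  sites and tissues; with rhizoctonia partners (weak ¹³C enrichers) it
  likely *underestimates* fungal carbon in the non-coralloid morph.
- Exact published P-values depend on an unstated df convention and are
  not reproduced; the package's own convention is documented above and
  calibration-tested instead.
- The mixed model assumes Gaussian residuals; count-like responses
  (flower numbers) are treated as continuous in the trait comparison.
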