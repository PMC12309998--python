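# Methods

## Data model

The unit of observation is a replicate-level trait value: one pot of four
plants averaged into one replicate, four replicates per genotype × treatment
cell.  Tables are long-format (`genotype, row_type, treatment, replicate,
trait, value`) with a closed treatment set `{C, Ds, Dd}` (aliases
`control/single/double` are resolved on read).  Missing values are explicit
(NaN), never zero-filled, and the balanced-design estimators refuse
unbalanced cells rather than impute: the closed-form variance-component
formulas below are only valid under balance, and silent imputation would
invalidate them without warning.

Eighteen traits are pre-registered.  Fourteen are measured; four are
computed at replicate level:

| code | formula | note |
|------|---------|------|
| MTKW | 1000·MSW/MSN | thousand-kernel weight, main ear |
| ATKW | 1000·(MSW+SSW)/(MSN+SSN) | thousand-kernel weight, all ears |
| ASN  | (MSN+SSN)/RT | grains per spike harvested |
| ASW  | (MSW+SSW)/RT | grain weight per spike harvested |

The trait names alone do not pin down the denominators (e.g. whether "per
spikes harvested" counts the main spike); the formulas above are this
package's documented reconstruction and can be overridden by passing custom
formulas to `derive_traits`.  Zero denominators yield explicit missing
values.  Main-ear density (DENS) is treated as a measured trait rather than
as SPS/EaL.

## Tolerance indices

Indices are computed for any trait but default to grain yield (GY), the
convention in drought-tolerance screening.  The stress mean `Ys` is the
equal-weight average of the Ds and Dd cell means; grand means are unweighted
over genotypes (identical to pooled means under balance, but explicit about
genotype weighting).  Numerical conventions:

- `SI = 0` (no detectable stress) makes DSI undefined; it is returned
  missing with a warning rather than raising, so a control-vs-control run
  degrades gracefully.
- Boundary values: `DSI = 1` classifies as *sensitive* (strict `<`),
  `STI = 1` and `YSI = 0.75` classify as tolerant (`≥`), mirroring the
  direction of the published inequalities.
- "Lowest/highest TOL" in the joint most-tolerant/most-susceptible rules is
  operationalized as the bottom/top quartile of the panel's TOL
  distribution.  No numeric TOL cut-off exists in the source convention;
  the quantile (default 0.25) is explicit configuration.
- The consensus rank averages the four per-index ranks (DSI and TOL
  ascending, STI and YSI descending, average ranks for ties) and breaks
  ties on the average by genotype name, so the ordering is deterministic.

## Response profiling

Change% = 100 · (stress cell mean)/(control cell mean) per trait and
genotype.  Clustering uses Euclidean distance and complete linkage on raw
change% values — the defaults of the heatmap tooling common in this
literature — with both choices exposed as parameters; no per-trait
standardization is applied because change% is already scale-free.  The cut
at `k` clusters (default 3) is renumbered by descending group-mean GY
change%, so "group 3" is always the most affected group regardless of
dendrogram orientation.

Group profiles re-express a group's mean change% as a percentage of the
unweighted grand-mean change% of all genotypes; with one group every value
is 100 by construction.  Separation letters come from Tukey HSD pairwise
tests after a one-way ANOVA across groups: letters are assigned to the
maximal cliques of the not-significantly-different graph (groups ordered by
descending mean), which is the standard compact-letter-display construction.
The post-hoc test is a package choice; the source convention states only
"P = 0.05".  Degenerate input (all values identical) shares one letter.

The two-way ANOVA is the balanced fixed-effects decomposition computed in
closed form (genotype, treatment, interaction, residual), reported as SS% of
the total with F-tests against the residual mean square and stars at
0.05/0.01/0.001.  The closed form is shared with the variance-component
estimators and is cross-checked against a general linear-model fit in the
test suite.

## Variance components and BLUP

Model: `y_ijk = μ + τ_j + g_i + (gτ)_ij + e_ijk` with treatment fixed and
genotype and interaction random.  One upstream description states the
genotype was fixed, but genotype-mean BLUPs (which exist only for random
effects) are the analysis's centrepiece, so genotype-as-random is the
interpretation implemented.  All three treatments enter the model.

On the balanced design the expected-mean-squares estimators
(`Vr = MS_e`, `Vge = (MS_g×t − MS_e)/r`, `Vg = (MS_g − MS_g×t)/(rt)`) equal
REML whenever interior; negative solutions are truncated at zero and
flagged.  No general unbalanced REML is claimed — unbalanced input is an
error, keeping the numerics exactly verifiable.  An independent Henderson
mixed-model-equation solve (dense assembly) lives in the test suite and
agrees with the closed-form BLUPs to 1e-8 on interior draws.

Derived quantities: `Vph = Vg + Vge + Vr` (the interaction variance is
included; definitions that omit it exist, but the sum is the standard
phenotypic variance of one plot), `h² = Vg/Vph`,
`h²mg = Vg/(Vg + Vge/t + Vr/(tr))`, accuracy `√h²mg`,
`CVg = 100√Vg/μ`, `CVr = 100√Vr/μ` (undefined at zero grand mean, flagged).
The genotype-mean BLUP is `μ + h²mg(ȳᵢ − μ)`; its 95% interval uses the
prediction-error variance of the genotype effect, `PEV = (1 − h²mg)·Vg`,
with the ANOVA error degrees of freedom:
`BLUP ± t(0.975, df_e)·√PEV`.  Shrinkage preserves the ranking of observed
means, so Spearman correlation between means and BLUPs is 1 on balanced
data.

`rank_stability` joins the BLUP above/below-mean flag with the index
consensus rank; *high-yield tolerant* requires above-mean BLUP and a rank in
the best third, *low-yield susceptible* below-mean BLUP and a rank in the
worst third (the tertile is a parameter).

## Multivariate summaries

Correlations and PCA operate on genotype × trait matrices of treatment
means: replicate-level input would mix residual noise into structures that
are interpreted at the genotype level.  Pearson P values use the exact
t transform, pairwise-complete, unadjusted by default (a Benjamini–Hochberg
pass can be applied downstream; no adjustment is imposed because the
screening convention reports raw P).  Network edges keep the signed r for
all pairs with `|r| ≥ threshold`; edge sets are monotone in the threshold.

PCA is an eigen-decomposition of the correlation matrix (covariance
optionally).  The sign of each component is fixed by making its
largest-magnitude loading positive, so scores and loadings are reproducible
across eigen-solvers.  Variance explained sums to 100 over all components.

## Synthetic cohort generator

The generator defines the study conditions for every recovery experiment:
28 genotypes (14 two-rowed, 14 six-rowed, interleaved), 3 treatments, 4
replicates, 14 measured traits (the 4 computed traits are then derived from
the simulated components, so their noise structure is the realistic ratio
noise).

Deterministic part per cell: row-type baseline × archetype vigor ×
treatment multiplier × archetype stress modifier (stress treatments only) ×
genotype priming factor (Dd only).  Latent structure: a lognormal genotype
effect `g_i` (shared across traits — genotypes are globally larger or
smaller), a lognormal genotype × treatment interaction `u_ij`, and
proportional Gaussian replicate noise, mean-corrected so every cell's
expectation equals its deterministic part; values truncate at zero.  With
the `additive` variance declaration the effects enter additively — exactly
the model the EMS estimators assume — which is what the parameter-recovery
experiments use (`Vg = 1.0, Vge = 0.5, Vr = 0.25` at the study design gives
mean relative bias under 10% across 500 replicates).

Default magnitudes (log-scale `Vg = 0.0064`, `Vge = 0.0025`, residual CV
12%) are chosen as realistic pot-trial values: per-genotype variance
estimates were not published, so these are calibrated only against the
group-level printed percentages, which the generator anchors exactly:
two-rowed control GY 4.7 g falling to 2.45 g (Ds) and 2.2 g (Dd); six-rowed
GY reductions 47.52%/44.24%; MSW reductions 53.12%/54.42%; MSN medians
24 → 14.13/14.25 (2R) and 40.63 → 25.13/20.5 (6R).  Because archetype
modifiers multiply on top, the baked treatment multiplier is the target
divided by the vigor-weighted archetype-modifier mixture mean, making the
row-type expectation equal the target exactly.  The double-stress level is
tied to the single-stress response through a genotype-specific priming
factor (mean 1, SD 0.15), reproducing the reported pattern that the
panel-mean Dd/Ds yield ratio is ≈98% with half the genotypes above 100%.

Three planted archetypes give the clustering and classification something
true to recover:

- *main_ear_preserver* (n = 6): keeps main-ear grain number/weight and
  reproductive tillers under stress; vigor 1.18 (stable, high-yielding).
- *side_ear_compensator* (n = 14): compensates through side-ear grain.
- *susceptible* (n = 8): main-ear parameters collapse toward zero while
  vegetative biomass increases; vigor 0.865.

Vigor multiplies the yield traits under every treatment (mixture mean
exactly 1, so panel means are unbiased) and cancels from all change%
statistics; it exists because joint tolerance typing (STI ≥ 1 in
particular) requires tolerant genotypes to be above-average yielders under
control conditions as well, which matches how such genotypes are described
in practice.  Vegetative biomass is deliberately outside the vigor set so
the stress-treatment biomass-vs-grain antagonism of the susceptible type
survives in the correlation structure.

What the generator does **not** emulate: integer-valued counts, within-pot
plant-to-plant correlation, treatment-specific variance heterogeneity,
genotype-specific trait correlations beyond the shared size factor and the
archetype contrasts, and any physiological dynamics (soil water, phenology).
The archetype contrasts are also stylized — sharper than real cultivar
panels, where tolerance grades continuously — so a perfect Rand index here
shows the machinery recovers separable structure, not that real panels
separate this cleanly.  A handful of preserver genotypes can exceed their
control yield under stress in a given draw, which real drought data would
rarely show; the margin is deliberate so that tolerance typing has
unambiguous planted positives.

## Problem sizes and numerics

The test suite runs the recovery Monte-Carlo at 500 replicates of the full
(28 × 3 × 4) design, the calibration experiments at 1,000 null simulations
(letter displays, correlation P) and 500 (ANOVA SS% against df shares,
exact under independent chi-squares), sizes at which Monte-Carlo error is
well inside the asserted tolerances.  Tolerances: oracle equivalences at
1e-8 absolute; exact identities at machine-precision `allclose`; stochastic
recoveries at the thresholds stated in the tests (Rand ≥ 0.9, bias < 10%,
calibration ±1.5 percentage points).  Ties in consensus ranking and letter
assignment are broken deterministically (genotype name; descending group
mean).  Degenerate inputs — zero variance anywhere, zero denominators,
SI = 0, empty groups — return flagged missing values or single letters
rather than raising, except where the result would be statistically
meaningless (unbalanced variance-component input, missing entries in PCA),
which raise with instructions.
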