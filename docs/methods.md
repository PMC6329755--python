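# Methods

This note records the models, defaults, and numerical choices behind each
module, what the synthetic data does and does not emulate, and the known
limitations.

## Pooled screen model and hit calling

The screen design pairs each replicate's treated arm with its own vehicle
arm (the infected pool is split), so the unit of replication is the paired
log ratio log₂(CPTM_treated+1) − log₂(CPTM_vehicle+1), one per replicate.
CPTM is (nᵢ/N_total)·10⁶; the +1 pseudocount is applied after normalization
and the base is 2 throughout, so downstream fold changes are log₂ units.

The moderated t follows the standard empirical-Bayes construction: with
per-shRNA sample variance s²_g on d_g = n−1 df, the prior (d₀, s₀²) is
moment-matched on e_g = ln s²_g − ψ(d_g/2) + ln(d_g/2), solving
ψ′(d₀/2) = var(e) − mean ψ′(d_g/2) by monotone bisection on d₀ ∈ (0.1, 10⁶]
(relative tolerance 10⁻¹⁰) and s₀² = exp(mean(e) + ψ(d₀/2) − ln(d₀/2)). When
the empirical var(e) does not exceed the trigamma term — homogeneous
variances — d₀ is +∞ and every posterior variance equals s₀² (the t
reference distribution then has effectively infinite df; scipy handles
df = inf directly). A zero-variance ensemble falls back to the ordinary t
with a warning; prior_df=0 can be forced to recover the unmoderated test.
BH adjustment runs across all shRNAs as one family (not per gene). Gene
scores are plain means of member-shRNA log fold changes; waterfall ties
break lexicographically by symbol so ranking is total and deterministic.
Gene *hits* (used by recovery tests) require ≥ 2 member shRNAs significant
with the dropout sign — a deliberate conservative rule, since the study
design treats a single significant hairpin as unconfirmed.

Barcode counting matches a fixed read window exactly against the library;
an optional Hamming-1 rescue assigns uniquely-nearest barcodes and discards
ambiguous reads. Fixed-position exact matching replaces short-read
alignment because screen barcodes are positionally determined; the
simulator writes reads as prefix+barcode+suffix so the counter is testable
losslessly end to end.

## Dose-response metrics

Metrics follow the two-regime growth-inhibition/lethality convention
anchored at the day-0 signal: GI metrics reference vehicle growth (C − T0),
LD50 and Emax reference T0 alone. Replicate wells are averaged per dose
before fitting; the 4PL is fit by least squares on log dose with loose
positivity bounds, and fits with R² < 0.8 (or < 4 distinct doses, or
optimizer failure) fall back to flagged monotone piecewise-linear
interpolation using the first bracketing dose pair. Crossings on the fitted
curve are found by scanning a 512-point log-dose grid for the first sign
change and bisecting to 10⁻⁶ relative tolerance; crossings are never
reported outside the tested dose range. Emax uses the minimum *observed*
per-dose mean rather than the fitted minimum, so the two printed anchor
values (−100 % for a zero-signal top dose, 0 % for exact stasis) are
reproduced exactly rather than to fit tolerance; Emax is clamped to
[−100, 0] so net growth under drug reports 0. Z′ uses sample standard
deviations (ddof = 1). Caliper volume sorts the two measures so the squared
term always takes the smaller dimension.

## Biomarker ranking

Pearson R per gene is computed vectorized on the expression/Emax overlap
(complete case on missing Emax), with p from the exact t transform on n−2
df and BH across genes. Quartiles use linear interpolation between order
statistics (numpy's default), and group membership is strict (> Q3, < Q1);
the group test defaults to Welch's unequal-variance t with a
pooled-variance flag for strict replication of a plain Student test. No
lineage adjustment is attempted; a per-lineage five-number summary supports
box-plot style comparisons instead.

## Loewe surface and synergy score

Margins are fitted with a bottom-zero monotone 4PL (isotonic running-max
interpolation as fallback for non-monotone margins — implemented directly
as a cumulative maximum rather than a full isotonic regression, which the
margin inversion does not need). The additive effect per cell solves the
dose-equivalence condition by plain bisection on the effect scale
(tolerance 10⁻⁶), capped at the lower margin plateau when the combined dose
exceeds what either agent can reach (flagged per cell). The score is the
dilution-weighted positive-excess volume gated by data positivity
(`gate="both"`; `gate="excess"` switches the gating, since the exact gating
of the original vendor software is not public). Excess below 10⁻⁵ — the
solver's resolution of the additive surface — counts as zero, so exactly
additive data scores exactly 0. Published per-matrix scores from the
original instrument software are not bit-reproducible without the raw
matrices; the implementation preserves the additive-null behavior
(self-cross scores ≈ 1 at 3 pp noise, < 5 bound) and ordering under planted
synergy, which is what the property suite asserts.

The simulator builds its additive grids with an independent construction:
closed-form margin inverses and Brent's method at 10⁻¹³ tolerance, so the
analyzer is never checked against its own solver.

## Isoform classes

Class abundances are exact transcript sums (conservation is tested).
Contrasts use the unweighted two-sample moderated t on
logCPM = log₂((count+0.5)/(libsize+1)·10⁶); mean–variance precision
weighting (voom-style) is deliberately not implemented — a documented
fidelity gap that does not affect sign/ordering recovery, which is what the
tests assert. Significance tiers sit at adjusted p < 0.01 and < 0.001.
Event flags combine significance with a median log₂(TPM+1) > 2 gate
evaluated in the arm where the class is expressed (treated for inductions,
control for reductions); the class→direction map (CDS-L antiapoptotic,
CDS-S/AS proapoptotic) is a configurable argument.

## Synthetic data: what it emulates and what it does not

Generator defaults are the study conditions: 841 genes across 6500
barcodes (~8 hairpins per gene) in duplicate at 10⁷ reads per sample;
11-point three-fold dilution from 10 µM in triplicate with a separate-plate
T0; a 478-line panel with a rho = 0.6 planted insensitivity marker over
1000 background genes (a desk-scale stand-in for a transcriptome — the
top-rank recovery statistic only sharpens with more null genes); 8×8
three-fold dose matrices with EC50 at the grid midpoint; triplicate
transcript tables with an MCL1-like sensitive gene (CDS-L −1, CDS-S +2,
AS +3 log₂) next to a splicing-resistant highly expressed gene.

Counts are negative binomial via a gamma–Poisson mixture
(var = μ + φμ², φ = 0.05 by default; φ = 0 is the deterministic
expectation limit). The NB choice is a modeling convention — the original
screen does not state a count noise model. Baseline barcode abundances are
lognormal (σ_ln = 0.5). The simulators do not model sequencing error, PCR
bias, plate-position effects, lineage structure in the panel, or
transcript-length effects in counts; passing recovery tests therefore
demonstrates the statistics under clean sampling noise, not robustness to
those artifacts. All randomness flows from one config seed through named
substreams (crc32-keyed SeedSequence children), so outputs are
byte-identical per seed and adding a draw site never perturbs existing
streams.

## Problem sizes

The test suite runs screens at 40–60 genes for per-module checks and at the
full 6500-barcode scale for the 25-seed recovery suite; panel recovery uses
the full 478 lines over 25 seeds; the Loewe null uses 10 seeded 8×8
matrices. These sizes were chosen so every property is exercised at the
design's stated scale while the whole suite completes in well under a
minute.

## Known limitations

* Unweighted moderated t (no voom precision weights) for count contrasts.
* The synergy-score gating convention is a documented choice, not a
  reproduction of the vendor formula; absolute scores are comparable only
  within this implementation.
* GI/LD metrics assume a monotone-decreasing response; biphasic curves land
  in the interpolation fallback and report first crossings.
* The expression panel is lineage-free; per-lineage correlation modes
  operate on user-supplied labels.
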