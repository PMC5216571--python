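# Methods

## Normalization and group means

Expression is quantified as RPKM = 10⁹·C/(N·L). The library size N
defaults to the per-sample column sum of the count matrix (floored at 1),
because the pipeline's entry point is a count matrix over a shared
transcript set and the original total of mapped reads is generally not
recoverable from it; an explicit per-sample override is accepted wherever a
matrix is constructed. Replicates are averaged on the RPKM scale — the
genotype-level quantity of interest is mean expression per transcript, and
averaging RPKM keeps it independent of per-replicate depth differences.
Counts are summed across replicates only inside the statistical tests,
which operate on two pooled libraries. No pseudocount is added anywhere in
normalization; zeros are handled explicitly by the classifier's routing
rules.

## Differential expression

Both exact engines condition on observed totals:

* **binomial** (default): conditional on t = c₁+c₂, c₁ ~ Binomial(t,
  n₁/(n₁+n₂)) under the null of equal relative expression. The two-sided
  p-value is the sum of point probabilities ≤ that of the observed count
  (point-probability method). This is the small-count-safe exact form of
  the MA-plot random-sampling model; the normal approximation variant is
  deliberately not implemented, as the exact test dominates it at every
  count size.
* **fisher**: two-sided Fisher's exact test on [[c₁, n₁−c₁], [c₂, n₂−c₂]].

The two are near-identical at sequencing depth (measured: ≤ 0.0125
absolute p-value difference at pooled depths of a few thousand) and
asymptotically equivalent; both are exposed because both are in common
use for two-library designs.

Benjamini–Hochberg adjustment runs across all tested genes (genes with at
least one nonzero pooled count); calls require q < 0.001 **and**
|M| > 1 (both strict), where M is the log2 ratio of pooled-count RPKM.
A gene with a zero pooled count on exactly one side has M = ±∞ and can
still be called; its A value is recorded as missing. An optional raw-p
mode (`adjust=False` / `--no-fdr`) gates on the unadjusted p-value
instead, for designs where the p-threshold convention is preferred.

**Known property — overdispersion.** Pooling replicates discards
biological variability: the exact tests are calibrated for sampling
(Poisson) noise only and are anti-conservative when counts are
negative-binomially dispersed (measured on synthetic nulls: ~1% of genes
falsely called at dispersion 0.05, 0 at dispersion 0). This is inherent
to the two-library method; dispersion-modelling GLMs are out of scope by
design. Null-calibration tests therefore use Poisson noise, which is the
model's own null.

## Dosage model

PT-ELV = ½χ_paternal + χ_maternal and PD-ELV = ½χ_paternal + ½χ_maternal,
with the genome doses parameterized (default 1 paternal : 2 maternal
chromosome sets) so reciprocal triploids can be analysed. The invariant
PT − PD = χ_maternal/2 ≥ 0 is the conserved extra maternal dose.

Because predictions carry no replicate structure, the default comparison
is threshold-only: call up/down when |log2(AT/prediction)| > 1. A
statistical mode for count input forms predicted pseudo-counts as the
dose-weighted combination of pooled parental counts (rounded to nearest
integer, with a matching pseudo library size) and applies the chosen exact
engine; its p-values inherit the pseudo-observation caveat and are logged
as such.

Note a structural fact of the model: PD/PT = (b+g)/(b+2g) ∈ (½, 1], so a
hybrid sitting exactly at the diploid state is never more than one log2
unit below the additive expectation — threshold-mode PT comparisons flag
only genes suppressed beyond full compensation. Observed down-calls
against PD therefore indicate mechanisms beyond pure dosage arithmetic.

## Twelve-category classifier

Pairwise equality is |log2 ratio| ≤ τ (non-strict, default τ = 1);
difference is strict. This reconciles the mixed "> 1"/"≤ 1" threshold
conventions and is validated by the bundled panel, which contains
borderline parent ratios of 0.986 (classified equal) and hybrid/parent
ratios of 1.075 (classified different).

The decision table uses the exclusive geometric patterns — e.g.
transgressive up (V/VI) requires the hybrid above *both* parents, not
merely above the higher one. In threshold mode the patterns are exhaustive
over reachable call triples (totality is property-tested over random
triples); in statistical mode the three independent tests can produce
geometrically impossible triples (e.g. hybrid above the higher parent yet
below the lower one), which are reported as **Unresolved** rather than
silently merged into a numbered category.

Routing order per gene: Silenced (hybrid mean 0, both parents above the
10-RPKM floor) → Novel (both parents 0, hybrid above the floor) →
Excluded (any remaining zero group mean) → ratio classification. The
silencing/novel floor is applied on the RPKM scale and is configurable.
Zero-expression genes are Excluded rather than pseudocounted because the
category geometry is meaningful only for genes expressed in all three
genotypes.

**Ambiguous** labels the geometrically possible case where the parents
differ (τ < |log2(b/g)| ≤ 2τ) while the hybrid is within τ of both. An
optional tie-break (`ambiguous_tiebreak`) assigns ELD toward the parent
with the smaller absolute log2 ratio, with exact ties kept Ambiguous; the
default keeps the label, since merging it would overstate dominance
counts.

Mirror symmetry under parental-role exchange
({I↔II, V↔VI, VII↔X, VIII↔IX, XI↔XII}, fixing III/IV/NoChange/Ambiguous)
and scale invariance are enforced as property tests.

## Enrichment and reporting

Subset enrichment is a Fisher exact test on (subset vs rest) ×
(in grouping vs not), one-sided toward over-representation by default
because the claims it supports are directional; a two-sided alternative
and a whole-set comparator margin are available by flag. The sample odds
ratio gets a 0.5 continuity correction when any cell is zero. Percentages
in reports are computed at full precision and rounded to one decimal only
for display; a denominator override supports gene sets whose unchanged
members are known only by count.

## qPCR

2^−ΔΔCt with technical triplicates averaged on the Ct scale before the
delta is taken, and fold changes averaged across biological replicates
(spread = sample SD). This is the conventional reading of
"average threshold cycle"; no amplification-efficiency correction is
applied.

## Synthetic-data generator

The generator emulates the target study design: three genotypes × 3
replicate libraries at 10⁶ mapped reads, ~20 RPKM median log-normal
baseline expression (σ = 1), gene lengths uniform on 400–4000 bp,
negative-binomial counts with variance μ + 0.05·μ² (dispersion 0 →
Poisson), planted effects of 3 log2 units, and category proportions of
3% per numbered category, 60% NoChange, 2% Silenced, 2% Novel.

Geometry per planted category: parents separated by ±effect_lfc (or
equal); dominance genes put the hybrid exactly at the matching parent;
transgressive genes put it effect_lfc beyond the extreme parent;
mid-parent genes put it at the **geometric** mean of the parents, i.e.
effect_lfc/2 from each on the log scale — the arithmetic mid-parent value
would sit within τ of the higher parent whenever effect_lfc ≤ ~2.7 and
the planted class would be unrecoverable by construction. Silenced genes
set the hybrid mean to exactly 0 with both parents ≥ 40 RPKM (safely
above the detection floor under noise); Novel genes mirror this.

`dosage_factor` rescales every hybrid mean relative to the additive
expectation under equal parental expression: hybrid = geometry ×
dosage_factor × 3/2. The default 2/3 — full compensation to the diploid
state, the regime the classifier is designed for — makes the scale
exactly 1 and preserves planted geometry; 1.0 simulates an uncompensated
triploid whose every gene is shifted +log2(1.5) against both parents.
Configurations with effect_lfc ≤ 2τ are flagged infeasible (warning +
truth metadata): mid-parent genes cannot then be separated from both
parents.

RPKM → expected count conversion is μ = RPKM·N·L/10⁹ per replicate, used
directly as the (real-valued) NB/Poisson mean; the matrix's library sizes
are fixed at the nominal depth so that planted RPKM is exact in
expectation. Everything is deterministic given the seed
(`numpy.random.default_rng`).

**What passing recovery tests show — and don't.** At the default
conditions (2,000 genes, effects of 3 log2 units, dispersion 0.05),
threshold-mode classification recovers ≈ 95% of planted categories, with
losses concentrated where they should be: deeply down-regulated
transgressive genes whose hybrid counts stochastically hit all-zero
(routed to Excluded), low-baseline genes, and mid-parent genes whose
margin to the equality band is effect_lfc/2 − τ. The generated matrix
carries the nominal depths as library sizes; if they are discarded and
column sums used instead, the planted transgressive genes shift each
group's total differently and RPKM ratios acquire a composition bias —
which is why the serialized outputs include a library-size table and the
CLI accepts `--library-sizes`. The generator does not emulate length
biases, correlated replicates, or homoeolog-level read assignment, so
recovery here bounds performance only under the stated noise model, not
on real data.

## Problem sizes in tests

Unit tests run at 50–1,500 genes; the acceptance suite uses the
spec-level conditions (2,000 genes × 5 seeds) for recovery, exhaustive
enumeration up to totals of 50 (binomial) and margins of 60 (Fisher) for
oracle equivalence, and 10⁴ random triples for classifier invariants.
The full suite completes in well under a minute.
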