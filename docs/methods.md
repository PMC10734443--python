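# Methods

## Differential expression

The DE stage is a deliberately transparent negative-binomial Wald
pipeline on a genes × samples count matrix with exactly two conditions
(wild type `wt`, mutant `mut`) and ≥ 2 replicates each.

**Normalization.** Median-of-ratios size factors: for each sample,
the median over genes (restricted to genes with nonzero counts in every
sample) of count / geometric-mean. Scaling one library by a constant c
moves its factor by c^(k−1)/k relative to the others (k samples) and
leaves fold-change estimates unchanged up to the pseudocount term.

**Dispersion.** Per-gene method of moments under Var K = μ + d·μ²:
on normalized counts, d = (pooled within-condition variance −
μ·mean(1/s)) / μ², residuals pooled across both conditions after
removing each condition's mean. Negative estimates floor at 1e−8. No
trend or shrinkage fitting: at the scales this package targets the
planted effects are large and the floor-plus-moments estimate is
adequate; parity with shrinkage-based DE tools is explicitly not
claimed.

**Wald test.** lfc = log2((μ̄_mut + pc)/(μ̄_wt + pc)) with pseudocount
pc = 0.5 (configurable) on normalized condition means; the standard
error comes from the delta method with the NB variance evaluated at the
estimated means and dispersion. The statistic lfc/se is referred to a
Student-t distribution with n₁ + n₂ − 2 degrees of freedom rather than
the standard normal. This is a small-sample correction: the plug-in
variance is estimated from the same handful of replicates as the mean
difference, and with 3+3 replicates a normal reference rejects the null
at roughly 12% instead of 5%, while the t reference holds the type-I
error at ~4.5% (measured by the null benchmark in
`redoxreg.benchmark`). At large replicate numbers the two coincide.

**Signed fold change.** fc = 2^lfc for lfc ≥ 0 and −2^(−lfc)
otherwise, so downregulation appears as a negative multiple (fc = −23
is 23-fold down), the null is +1, and |fc| ≥ 1 always. Thresholds in
this convention: the magnitude threshold is inclusive (|fc| ≥ 2), the
p-value thresholds strict (p < 0.05).

**Multiple testing.** Step-up Benjamini–Hochberg over the tested genes
only; genes with zero counts in every sample are flagged untested
(p = 1 by convention) and excluded from the family size m.

## Transcriptional-cluster calling

Candidates are DE records with |fc| ≥ 2 and raw p < 0.05. Within each
(contig, strand), candidates sorted by start are chained greedily:
a candidate joins the open chain iff the intergenic gap to the previous
candidate (next.start − prev.end − 1, 1-based inclusive coordinates) is
strictly below the threshold (default 250 bp) and the regulation
direction matches. Maximal chains of ≥ 2 genes become TCs; singletons
are reported as "isolated". Because the chain predicate is pairwise,
greedy left-to-right chaining returns exactly the maximal valid runs
and is order-independent; the test suite checks this against an
exhaustive enumeration oracle on random layouts.

Two deliberate semantics: (i) the gap is measured between consecutive
*candidates* — an intervening non-candidate gene on the same strand
does not break a chain unless it stretches the distance past the
threshold; (ii) the chromosome is treated as linear, with no wraparound
join between the last and first gene.

**Rescue rule.** The affected set is {candidates with BH p < 0.05} ∪
{candidates belonging to a TC with ≥ 1 BH-significant member}. Rescued
genes therefore always pass the raw filters (they are drawn from the
candidate set); TCs with no significant member are dropped from
reporting. Summary percentages are rounded to integers, ties away from
zero.

## Region profiles and categories

Region membership is interval overlap by ≥ 1 bp (or an explicit gene
list). Average fold changes are taken over *affected* genes only:
unaffected genes sit near fc = ±1 and would dilute the quantity of
interest. The profile also counts TCs lying fully inside the region and
affected genes belonging to no reported TC (transcriptional
fragmentation). The biological-process breakdown uses a user-supplied
curated map; unmapped genes fall into "Unknown". No automated
functional annotation or enrichment statistic is attempted.

## Phenotype metrics

PMP = OD₈₈₀/OD₆₆₀ (pigment absorbance per unit biomass); ΔPMP = PMP of
a condition minus PMP of the unpigmented aerobic control, computed at
the endpoint (final time point) of each growth curve — an
end-of-culture measurement, not a maximum over time. Optical densities
can be corrected to a 1 cm path-length equivalent by dividing by the
instrument's effective path length; the factor is geometry-specific and
has no default. The correction cancels in PMP. The group comparison is
a plain unpaired two-tailed equal-variance t test; degenerate input
(both groups constant and equal) returns (t, p) = (0, 1) by convention.

## Variant screen

Calls are kept when coverage ≥ 10 reads and alt-allele frequency
> 60% (strict); kept calls are treated as true strain differences.
Uniqueness is key-based on (contig, position, ref, alt); when a
reference sequence is supplied, 1-bp homopolymer deletions are
left-aligned before comparison so the same physical deletion called at
different positions of a run compares equal. Frameshift prediction
applies the edit, translates with the bacterial genetic code (table 11,
stop set TAA/TAG/TGA, alternative starts read as formyl-Met → Met) from
codon 1 to the first in-frame stop, and reports the mutant protein
length, the percent size reduction, and the 1-based nt position of the
new stop. A 1-bp deletion inside a homopolymer run ≥ 2 is flagged
ambiguous — every choice of deleted position yields the same sequence,
which the tests verify exhaustively on a 7-G run. ORF arithmetic:
an ORF of L nt (L divisible by 3) encodes L/3 − 1 amino acids.

## Synthetic data: what it emulates, and what not

The generators emulate the *shape* of the study's data, not its
biology: a linear chromosome with genes on both strands, planted
co-strand gene blocks whose internal gaps are drawn below the TC
threshold and whose flanking gaps are drawn at or above it (so planted
blocks satisfy the TC predicate by construction and never merge);
NB counts with log-uniform baseline means, per-sample library factors,
and condition effects equal to the planted signed fold changes; variant
tables with shared background calls, planted passing mutant-unique
calls and decoys failing one filter each; and logistic growth with
OD₈₈₀ = OD₆₆₀ × (basal PMP + pigment effect in pigmented wild-type
cultures) plus Gaussian noise. Everything is deterministic under the
configured seed.

Not emulated: read-level artefacts (mapping bias, rRNA carry-over, GC
effects), dispersion trends with expression level, operon-internal
promoters, overlapping same-strand genes, condition-dependent growth
rates, and spectral overlap between pigments. Passing the planted-truth
suite therefore demonstrates the pipeline's logic is correct under the
stated model, not that the statistical stage matches any particular
production DE tool on real libraries.

**Default study conditions.** 3 replicates per condition (the working
scale of bacterial RNA-seq designs), NB dispersion 0.05 (typical for
biological replicates), baseline means log-uniform on [50, 1000],
library factors log-uniform on [0.7, 1.4], logistic growth to OD 1.2
with rate 0.25 h⁻¹ and midpoint 12 h, basal PMP 1.0, pigment effect
0.5, measurement noise SD 0.01 (0 = exact mode for recovery tests).

## Benchmarks and problem sizes

`redoxreg.benchmark` fixes two reference datasets. The *recovery*
benchmark — 2,000 genes on 20 Mbp, 40 planted TCs (ten per signed fc in
{−83, −23, −4, +4}, sizes 3–5, alternating strands), 6+6 replicates,
dispersion 0.01, means on [200, 2000] — is sized so the whole
DE→TC→rescue run takes well under a second while leaving ~1,850 null
genes to exercise the filters. Its first (fc = −4) cluster carries one
member planted at baseline mean 3.5: weak enough that its BH-adjusted p
tends to fail while its raw evidence passes the candidate filters,
which makes the rescue rule observable rather than vacuous. The deep
mean range keeps the pseudocount bias on the fc = −83 group inside the
25% recovery tolerance. The *null* benchmark (2,000 genes, 3+3,
defaults) measures type-I error of the Wald stage.

## Known limitations

- The DE stage is intentionally minimal: no dispersion shrinkage, no
  GLM covariates, no independent filtering; it is calibrated for the
  desk-scale designs above, not for production RNA-seq analysis.
- TC calling assumes a gap-and-direction definition only; it does not
  model promoters, terminators or polycistronic mRNA evidence.
- Variant comparison does no general indel normalization beyond the
  1-bp homopolymer left-alignment.
- The growth model is logistic with additive noise; lag-phase
  asymmetries and condition-dependent growth rates are out of scope.
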