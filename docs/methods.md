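# Methods

This note documents the models, defaults and numerical conventions behind
`termsignal`, and what its synthetic benchmarks do and do not demonstrate.

## Gene records and annotation

Coordinates are 0-based half-open internally; GenBank and feature-table
input (1-based inclusive) is converted at the parser boundary. Every CDS
is verified against the genome: length divisible by three and a
genetic-code-11 stop codon (TAA/TAG/TGA) as the final triplet; violations
are skipped with a logged warning rather than repaired. Downstream
(+4 onward) and upstream context windows default to 20 bases, read
strand-aware and wrapping the origin on circular replicons; on a linear
replicon a +4 base beyond the end is recorded as missing and the gene is
excluded from +4 statistics (but kept for stop-codon usage). The +4 base
of a gene overlapping another feature is simply the next genomic base in
coding orientation — overlap is not conditioned on. Genes are flagged
*hypothetical* by a case-insensitive substring match on the product
qualifier and *pseudo* from the pseudo qualifier; *ribosomal* means the
product contains "ribosomal protein". Ambiguity codes (N, …) in a CDS or
its +4 base exclude the gene from context statistics, logged. tRNA
anticodons come from the anticodon qualifier when present, else from
positions 34–36 of the annotated tRNA sequence (flagged as inferred).

## Reference sets and codon-usage indices

HEGs are the k = 40 ribosomal-protein genes with the highest protein
abundance (ppm); LEGs are the k = 40 genes with the lowest strictly
positive abundance among all non-pseudo, non-hypothetical genes (not
restricted to non-ribosomal genes; configurable). Abundance ties at the
selection boundary break by ascending gene id, making the partition
deterministic and order-invariant.

I_TE weights: within each synonymous family, with a pseudocount (default
0.5) added to every count, `r(c) = f_HEG(c)/f_LEG(c)` on within-family
frequencies and `w(c) = r(c)/max_family r`. The six-fold families (Leu,
Ser, Arg) are split by default into their four-codon subfamily (constant
first two bases) and two-codon subfamily, keeping ratios within groups
read by the same isoacceptor pools. A gene's score is
`exp(mean(ln w))` over its codons, excluding the start codon (whatever
its triplet), the stop, and the single-codon families Met and Trp whose
weight is 1 by construction; whether to exclude start codons is
configurable since conventions differ among published implementations.
CAI uses the same family scheme and scoring path with
`w = f_HEG / max_family f_HEG`. The pseudocount makes weights defined for
families unobserved in one reference set; exact scale invariance of the
weights holds at pseudocount 0.

Species where HEG and LEG codon usage barely differ make an HEG/LEG
contrast index meaningless; the distinctness check reports the Pearson
correlation of HEG vs LEG RSCU over families observed in both (≥ 10
families required), with "not distinct" at r ≥ 0.8 by default. The
threshold is a configurable operationalisation of what is otherwise an
inspection call.

Expression deciles: genes are stably sorted by (score, gene id) and split
into 10 bins, remainder genes going to the lowest bins; each bin is
summarised by its mean score (mean rather than median — an arbitrary but
fixed choice).

## Stop-context statistics

All proportions are exact count ratios, so `p × n` reconstructs integer
counts. In decile trends, P_U (and P_A/P_C/P_G) is the +4-base fraction
unconditional on the stop codon; per-stop variants (P_U.UAA, …) are also
emitted. Trend regressions are ordinary least squares of each per-bin
series on bin mean score, with two-tailed t p-values (df = 8 for 10
bins). The Table-2-style per-species contrast takes the 100 highest- and
100 lowest-scoring genes ending in each stop codon (all of them, with a
recorded shortfall, if fewer exist).

Dependence of the +4 distribution on the stop codon is tested by
likelihood-ratio G statistics: independence on one 3×4 table (df 6;
zero-margin rows/columns dropped with the df adjusted and a warning); for
two species, the species × stop × base interaction is tested against the
no-three-way-interaction log-linear model fitted by iterative
proportional fitting (tolerance 1e-10, ≤ 1000 sweeps, df 6).

The shuffle control permutes each gene's 20-base 5′ window with a seeded
generator (exactly preserving per-gene composition) and regresses the
U-fraction at the shuffled window's first base on bin mean score. Since
the 5′ window carries no stop-context information, any +4-specific signal
must vanish; with 10 bins a *single* null regression has E[R²] ≈ 1/9 and
exceeds 0.2 about a fifth of the time, so the benchmarks report the mean
R² over a replicate set rather than one draw.

## Near-cognate tRNAs

Decoding is strict Watson–Crick: the decoded codon is the reverse
complement of the anticodon, and a near-cognate of a stop codon differs
from it at exactly one position (the mismatch position indexes
nc_tRNA1/2/3). Wobble rules are deliberately not applied: the
classification is a bookkeeping definition, not a kinetic model.
Anticodons that decode a stop exactly (suppressors) are excluded by the
single-mismatch rule. Abundance fractions divide near-cognate gene-copy
sums by the species' total tRNA gene copies (initiator and special tRNAs
included in the denominator). `p_nc1_minus_gln` removes the
glutamine-decoding anticodon (for UAA: 5′-TTG-3′), the dominant known
read-through contributor, to expose the remaining signal.

## Independent contrasts

Felsenstein's pruning: at a node joining children with values x1, x2 and
(pruned) branch lengths v1, v2, the standardized contrast is
`(x1 − x2)/√(v1 + v2)`, the ancestral value the 1/v-weighted mean, and
the parent edge is lengthened by `v1·v2/(v1 + v2)`. A zero-length sibling
pair (v1 + v2 = 0) is an error naming the node. Child order — hence
contrast sign — is fixed alphabetically by smallest descendant tip name;
polytomies are resolved to a deterministic ladder of zero-length
bifurcations in the same order. Contrast regressions are forced through
the origin, as the method requires, with R² measured about zero and the
slope t-test on n − 1 df; published contrast R² values computed with an
intercept are therefore not exactly comparable. On a star phylogeny with
equal branch lengths the through-origin contrast correlation reduces to
the ordinary Pearson correlation of tip values (verified to 1e-10 in the
tests). Batch mode applies the same machinery across bootstrap trees and
summarises the spread of R² and p.

The rank-sum test mirrors mainstream statistical practice: exact null
enumeration (dynamic-programming count of the Mann–Whitney U
distribution) when there are no ties and min(n) < 25, otherwise the
normal approximation with midranks, tie-corrected variance and a ±0.5
continuity correction; this reproduces R's `wilcox.test` to ≥ 10 decimal
places on tied data. p-values are reported raw, with no multiple-testing
correction. The saturating curve fit uses the two-parameter power form
`y = a·xᵇ` (initialised from a log-log regression); the true functional
form for stop-usage/+4U saturation is not identified, so this fit is
descriptive only.

## Synthetic data generator

The generator's defaults are the study conditions for all benchmarks.
Each species has 2000 genes of 90–150 codons — the scale of a typical
bacterial genome, so decile bins carry realistic counts. Gene i has a
log-normal protein abundance (location log 500 for the
highly-expressed class, 12% of genes, else log 5; σ = 1), and its
expression percentile q mixes a HEG and a LEG codon profile. The LEG
profile is the mutation-background expectation (codon probability ∝
product of base probabilities); the HEG profile multiplies one
deterministically preferred codon per family by 4. The underlying base
composition is calibrated by root-finding so mean coding GC hits the
genomic target (realized GC within 0.03 of target at ≥ 500 genes, by
construction checked at generation). 50 of the high-class genes are
annotated as ribosomal proteins; 5% of genes are "hypothetical" and 2%
pseudo to exercise the filters.

Stop-codon usage interpolates between class distributions (HEG:
0.70/0.12/0.18 for TAA/TAG/TGA; LEG: 0.45/0.25/0.30) by q, and the
+4 distribution likewise (TAA: +4U 0.62 in HEGs vs 0.30 in LEGs, with
smaller contrasts for UAG/UGA) — effect sizes taken from the observed
range in enteric bacteria. Across a cohort, GC drives stop usage through
a logistic link (GC-rich species shift away from UAA), and a species'
UAA-nc_tRNA1 copy fraction shifts its UAA-HEG +4U probability with slope
β = 2 (β = 0 and the structureless +4 model give exact null conditions).
Brownian traits are simulated along the tree with exact bivariate
increment covariance. Identical specs and seeds give byte-identical
outputs including serialisations, and every generated bundle re-parses
with zero warnings.

What the generator does *not* emulate: operon structure, real intergenic
architecture, amino-acid composition differences between genes,
GC-skew, wobble-decoding kinetics, or empirical abundance distributions.
Passing recovery benchmarks therefore shows the pipeline's estimators are
correct and calibrated under the assumed generative structure, not that
real genomes satisfy that structure.

## Benchmarks and problem sizes

The parameter-recovery benchmarks run 200 planted-effect replicates and
100 zero-effect replicates at the default generator settings (positive
P_U decile slope at p < 0.05 expected in ≥ 95% of planted replicates;
null slopes centered at zero), 20 shuffle-control replicates (mean R²
expected below 0.2), and contrast calibration on a random 19-tip tree:
pooled variance of standardized unit-rate contrasts over 1000 replicates
(expected in [0.9, 1.1]) and mean recovered contrast correlation over
500 replicates at simulated ρ = 0.8 (expected within ±0.05). These sizes
give stable estimates in a few minutes on one CPU.

## Known limitations

* The shipped 19-species +4U table is reproduced as printed in its
  source; printed tables can carry transcription errors (two of its rows
  share an accession and GC value), which limits agreement with
  statistics computed on the original underlying data.
* The distinctness threshold (0.8) and the near-cognate definition are
  conventions, exposed as configuration, not biological claims.
* The log-linear machinery covers only the 3×4 and 2×3×4 designs the
  analysis needs; it is not a general hierarchical model fitter.
* Contrast regressions assume the tree's branch lengths are in units
  proportional to expected trait variance; no branch-length
  transformation (Grafen, Pagel's λ, …) is offered.
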