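# Methods

This note documents the models, defaults and design choices behind
`scsnpkit`, in the order the pipeline runs.

## Filter cascade

The cascade is order-sensitive and fixed: sample QC → nonsynonymous →
per-cell read support → cross-cell site coverage. Reports telescope (each
rule's output count is the next rule's input count) and the cascade is
idempotent on its own output.

* **Sample QC.** Two cutoffs, minimum covered sites (default 100 000) and
  minimum mean depth (default 5×). The thresholds are tunable, not
  canonical; the defaults cleanly separate the synthetic generator's
  planted low-quality cells (which sit well below both) from good cells.
  The retained-cell count is the `AS` denominator of every downstream
  sample ratio.
* **Effect class.** The pipeline is annotator-agnostic: it consumes a
  configurable VCF INFO key with values `synonymous` / `nonsynonymous` /
  anything-else→`unknown`. Unknown effects are dropped by default
  (counted separately); a keep-unknown mode exists.
* **Read support.** "At least 5 reads" is an inclusive bound (depth ≥ 5).
* **Site coverage.** "More than 95% of samples" is a strict inequality:
  79/83 = 0.9518 passes, 78/83 fails. "Covered" at a site means depth ≥ 1
  in that cell, deliberately distinct from the 5-read support rule, and
  the denominator is the retained-cell count. Coverage is supplied as a
  per-site sidecar table because variant files only witness sites where a
  variant was called.
* **Multiallelic sites** become one record per ALT allele; the coverage
  rule acts at the position level.

## Frequency statistics

`SNP-Freq_c` and `SNP-Freq_g` normalise counts per megabase of chromosome
or gene length so values are comparable across features; gene length
defaults to the genomic span (end − start + 1, 1-based inclusive) because
that is reproducible from any gene-model file. Percentages print half-up
at two decimals (50/83 → 60.24). Dispersion uses the unbiased (n−1)
variance; CV and Fano are undefined at mean 0 and such genes are excluded
from correlations. Correlations default to Spearman (the frequency
distributions are heavy-tailed); Pearson is selectable. The
chromosome-enrichment test is Welch's t on target-vs-other per-Mb values
pooled over cells; chrY is included unless excluded in configuration.

## GO-slim analysis

Each SNP on a gene adds one count to every GO term annotated to that gene
("the more SNPs, the more likely the function is altered" heuristic).
Back-tracing collapses a term onto every slim-set member on any is_a path
to the root, with **set semantics** (a slim counts once per term regardless
of path multiplicity); a path-count weighting variant sits behind a flag.
Slim × cell matrices are exported as log2(count+1) — natural log is used
only for chromosome matrix exports. K-means (scikit-learn, fixed seed,
10 restarts) groups slim rows with per-category defaults k = {BP: 2,
MF: 3, CC: 2}; groups are relabelled by decreasing mean so group 0 is the
most enriched, making the labelling invariant to row permutation. Each
group is tested against the pooled remainder with Welch's t. Rows may
optionally be z-scored before clustering (off by default; recorded in
output metadata).

## Cancer-gene enrichment

The group test is a one-sided Wilcoxon rank-sum (cancer group greater) on
pooled per-cell `SNP-Freq_g` values. Outlier handling is automated for
reproducibility: values beyond 3× IQR above the pooled 75th percentile are
removed before testing (a manual exclusion list is also accepted). No
variance-stabilising transform is applied by default — the rank-sum is
rank-based — but a log1p flag exists.

The per-cell bootstrap threshold is the 95% quantile of pooled resamples
(replicates × n draws with replacement) of the cell's non-cancer-gene
frequencies; this is the resampled-value distribution itself, the simplest
monotone reading of a "bootstrap density" null. Entries of the binary
matrix are 1 iff the gene's frequency strictly exceeds the bound (zero
frequencies are never enriched). Replicates default to 10 000; every cell
draws from an independent RNG stream spawned from the master seed, so the
matrix is bit-exact reproducible and independent of cell order. Genes
enriched in strictly more than 50% of all cells are "recurrent".

## Pathway analysis

Fisher's exact test uses a gene-level 2×2 table (mutated = MS ≥ 1 after
filtering × pathway membership); a SNP-level variant is available behind a
flag. Sample ratios are compared in-vs-out with a one-sided rank-sum.

The expression-matched bootstrap defines its null as: draw, per pathway
gene, one non-pathway gene from the same mean-expression decile
(relaxing to the nearest non-empty bin), and compare the resampled mean
`SNP-Freq_g` with the pathway's; p = (1 + #{resample ≥ observed}) /
(R + 1), so p ∈ [1/(R+1), 1] and decreases monotonically as the pathway
mean rises. This matching direction is a design choice: the alternative
readings of "matched on expression" do not yield a well-defined test.

Ranking sorts pathway genes by mean frequency (desc), then SR (desc), then
symbol (asc) for determinism; selection takes SR strictly above 50%, plus
reason-tagged manual additions (`high_freq_manual`, `kegg_documented`).
Selected vs unselected frequencies get a Welch t-test.

## Fusion filtering

Four drop rules in fixed order per cell: (1) ribosomal partner (gene-set
file; the synthetic annotation uses RPL*/RPS*/MRPL* symbols), (2) either
partner intronic or intraexonic, (3) either partner gene having more than
one distinct partner **among the survivors of rules 1–2** in that cell,
(4) same-chromosome breakpoints strictly less than 100 kbp apart (strand
ignored). The rule-3 timing matters — a gene sharing a partner only with a
ribosomal record is not promiscuous — and a regression test pins one such
discriminating case. Drops plus retained always equal the input, per cell.
Recurrence counts an unordered partner pair once per cell.

## Ka/Ks estimation

The estimator is an in-repo pairwise counting method in the Nei–Gojobori
(1986) style: synonymous site counts per codon average the fraction of the
three possible changes per position that preserve the amino acid (changes
to stop codons count as nonsynonymous); sites are averaged over the two
sequences; multi-difference codons average substitution counts with equal
weight over mutational pathways that avoid stop-codon intermediates; and
proportions are Jukes–Cantor corrected (d = −¾ ln(1 − 4p/3)). ω is
undefined (never infinite) when Ks = 0, and such orthologs are excluded
from correlations and tallied separately. Gap, ambiguity and stop codon
columns are dropped by default. The implementation is cross-checked in the
test suite against an independent reference implementation
(`Bio.codonalign`) to 10⁻⁴.

This is a deliberate methodological simplification: tree-based maximum
likelihood ω estimation over ortholog sets is a different (heavier)
procedure, and no per-ortholog reference values exist to match, so the
package asserts classification-level behaviour (ω > 1 positive, ω < 1
purifying, |ω − 1| ≤ 10⁻⁹ neutral) and estimator recovery on pairs with
planted substitution counts. Ortholog screening applies record-level
filters first (expression rate ≥ 0.95, mutated fraction ≥ 0.05), then
drops slims with fewer than 10 surviving orthologs and orthologs left with
no retained slim.

## Synthetic cohort: what it emulates, and what it does not

Defaults describe a 96-cell single-cell cohort with 4 bulk-cancer and
1 bulk-normal companions; 13 of 96 cells are planted low-quality so QC
retains 83. 500 genes are placed on hg19-length chromosomes proportionally
to length (at least two per chromosome), with log-normal lengths (median
30 kb).

* **Clonal mutation model.** A gene either carries cohort-wide SNPs
  (probability 0.35) or none; mutated genes draw per-cell counts from a
  Poisson whose chromosome-level total is fixed at 1.0 raw SNP/Mb/cell
  (scaled 3× on chr11 and chr17, the planted enrichment). Distributing
  each chromosome's quota over its mutated genes keeps per-Mb chromosome
  density exactly flat when no enrichment is planted — this is what makes
  the chromosome t-test's null calibration meaningful. The density itself
  is a design choice set so the planted 5× cancer-gene excess is
  detectable at the 95% bootstrap bound; a sparser cohort would starve the
  per-cell frequency null of counts.
* **Exact planted counts.** Twenty genes carry exact mutated-cell
  membership (counts mirroring a published mutation table, e.g. 50, 81
  and 82 of 83 retained cells); their SNPs are written filter-clean
  (nonsynonymous, depth ≥ 5, fully covered sites) so the cascade recovers
  the planted counts exactly.
* **Attribute noise.** Background SNPs are nonsynonymous with probability
  0.75, low-depth with probability 0.08, and sit at low-coverage sites
  with probability 0.05, exercising every cascade rule at known rates.
* **Cancer genes.** A 175-symbol list (20 planted + 155 synthetic
  symbols); 10 are planted "enriched" with a 5× rate multiplier. Truth
  records the enriched set; recovery is assessed entry-wise over retained
  cells (low-quality cells carry no usable signal by construction).
* **Expression.** Negative-binomial counts with var = μ + 0.3 μ², i.e.
  Fano = 1 + 0.3 μ > 1, reproducing the qualitative CV–mean (negative)
  and Fano–mean (positive) relationships of single-cell data.
* **Fusions and orthologs.** Fusion tables contain recurrent surviving
  pairs plus noise records each constructed to trigger exactly one drop
  rule (or none), so survival flags are known without running the filter.
  Ortholog pairs (300 codons) plant substitution counts that invert the
  NG86 arithmetic for target ω ∈ {0.2, 1.0, 2.0}, with mean expression
  drawn inversely related to ω.
* **Determinism.** All randomness flows from one master seed through named
  `SeedSequence` spawn keys; a cohort is byte-identical given its seed.

Not emulated: read-level error profiles, allelic expression, amplification
bias, caller disagreement structure, linkage between SNPs, and realistic
per-cell dropout of clonal SNPs (background mutated genes therefore show
near-unit sample ratios; SR structure is carried by the planted genes).
Passing tests demonstrate the pipeline's arithmetic, contracts and power
on planted effects — not calling accuracy on real reads.

## Numerical and testing choices

Problem sizes in the test suite are scaled for a single-CPU run: null
calibrations use 10-cell/120-gene cohorts over 200 seeds (the band
[0.02, 0.09] at α = 0.05 brackets the Monte-Carlo and discreteness error
of 200 draws); oracle-equivalence suites use ≤ 100-record toys over 100
seeds; the full 96-cell cohort is generated once per session. The
acceptance script uses 2 000 bootstrap replicates for the matrix target —
its reported quantity (column count) is replicate-independent — while the
in-suite structural test runs the full 10 000. Ties in rankings and
recurrence tables break lexicographically so outputs are stable across
runs; percentage formatting uses decimal half-up rounding, matching how
two-decimal percentages are conventionally printed.
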