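# scsnpkit

Downstream interpretation of SNP calls from single-cell RNA-seq, built for
cohorts like a 96-cell colon-cancer (HCT116-style) experiment with a few
bulk companion samples. Upstream tools (aligner, variant callers, fusion
caller, effect annotator) are out of scope: this package starts from
per-cell VCFs and candidate tables, applies the filtering and statistics a
single-cell SNP study needs, and ends at interpretable gene, pathway and
selection-level summaries.

## What it computes

**Filter cascade.** Sample-level QC (sequencing depth and covered sites)
removes low-quality cells; variants are then kept only if nonsynonymous,
supported by ≥ 5 reads in their cell, and located at sites covered in more
than 95% of the retained cells.

**Frequency statistics.** With `SNP_count` per chromosome of length `L_c`
and `SC` SNPs on a gene of length `GL` (bases):

    SNP-Freq_c = SNP_count / (L_c / 10^6)        (SNPs per Mb of chromosome)
    SNP-Freq_g = SC / (GL / 10^6)                (SNPs per Mb of gene)
    SR         = MS / AS                         (mutated cells / retained cells)

plus per-gene dispersion (CV = σ/μ, Fano = σ²/μ), Spearman/Pearson
correlations, a Welch t-test for chromosome-level enrichment (e.g.
chr11 + chr17 against the rest), and caller-set comparisons.

**GO-slim burden.** SNP counts propagate from genes to their GO terms,
terms are collapsed to a slim vocabulary by is_a back-tracing, and the
resulting slim × cell matrices (log2(count+1)) are k-means-grouped with
group-vs-rest Welch t-tests.

**Cancer-gene enrichment.** One-sided Wilcoxon rank-sum of cancer-gene vs
other-gene `SNP-Freq_g`; then, per cell, a bootstrap of the non-cancer-gene
frequencies yields an upper 95% bound, producing a binary cells × genes
enrichment matrix and a ">50% of cells" recurrence selection.

**Pathways.** Fisher's exact test on mutated-gene membership, rank-sum on
sample ratios, an expression-matched resampling null for the pathway's mean
frequency, and a two-step ranking (frequency, then SR) with a strict
SR > 50% selection plus reason-tagged manual additions.

**Fusions.** A deFuse-style candidate table passes four drop rules in
order: ribosomal partner; intronic/intraexonic breakpoint; promiscuous
partner within the cell; same-chromosome breakpoints < 100 kbp apart.

**Selection (Ka/Ks).** A pairwise Nei–Gojobori-style counting estimator
with Jukes–Cantor correction gives ω = Ka/Ks per ortholog pair; slims are
screened (≥ 10 orthologs, ≥ 95% expression rate, ≥ 5% mutated cells),
classified (ω > 1 positive, ω < 1 purifying), and associated with
expression.

**Synthetic cohorts.** `scsnpkit.synthetic` generates a full on-disk cohort
(VCFs, gene models, GO files, expression, fusion tables, codon-aligned
ortholog pairs) with recorded ground truth — planted chromosome enrichment,
exact per-gene mutated-cell counts, cancer-gene frequency excess, fusion
cases for every rule, and known ω — so the whole pipeline is testable
without any external data.

## Worked example

```sh
scsnpkit simulate --outdir cohort --seed 3 --cells 24 --genes 200
scsnpkit run-all --cohort cohort --outdir results --seed 3
```

prints, among other stage summaries:

```
84169 records retained across 21 cells
chr11/chr17 enrichment: p=9.38e-48 (greater)
rank-sum p=0.944; matrix 21x175; 28 recurrent genes
analyzed 5 pathways
              n_samples   mean_raw  mean_retained  retained_ratio
sample_class
single_cell          24   4.708333          2.625        0.557522
bulk_cancer           4  12.500000          1.000        0.080000
bulk_normal           1  22.000000          0.000        0.000000
omega-expression correlation rho=-0.877 p=2.32e-12
36 orthologs retained across 3 slims
```

Reading this: 3 of 24 simulated cells fail QC (the generator plants the
13/96 low-quality fraction); the planted 3× excess on chr11/chr17 is
recovered with overwhelming significance; the bootstrap procedure returns
the binary 21 × 175 cell-by-cancer-gene matrix; fusion candidates shrink
from ~4.7 to ~2.6 per cell (bulk samples lose proportionally more); and the
planted inverse relation between ω and expression appears as a strong
negative Spearman correlation.

In Python, the frequency primitives are plain functions:

```python
>>> from scsnpkit import sample_ratio, format_percent
>>> format_percent(sample_ratio(50, 83))   # gene mutated in 50 of 83 cells
'60.24'
```

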