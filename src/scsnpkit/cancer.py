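"""Cancer-gene SNP enrichment: group rank-sum test, per-cell bootstrap
thresholds, the binary cells x cancer-genes enrichment matrix, and
recurrence selection.

For each cell, the SNP-Freq_g values of all *non*-cancer genes form the null
pool; resampling that pool with replacement builds a one-sided 95% bound,
and a cancer gene is called enriched in the cell when its own frequency
exceeds that bound.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .statistics import TestResult


def cancer_group_test(
    gene_freq: pd.DataFrame,
    cancer_genes: list[str],
    outlier_iqr_multiple: float = 3.0,
    manual_exclude: set[str] | None = None,
    log1p: bool = False,
) -> TestResult:
    """One-sided Wilcoxon rank-sum: are cancer-gene SNP-Freq_g values larger
    than other genes'? Upper outliers are removed from the pooled values
    before testing (the rule is applied to both groups)."""
    exclude = manual_exclude or set()
    cancer = [g for g in gene_freq.columns if g in set(cancer_genes) and g not in exclude]
    other = [g for g in gene_freq.columns if g not in set(cancer_genes) and g not in exclude]
    a = gene_freq[cancer].to_numpy(dtype=float).ravel()
    b = gene_freq[other].to_numpy(dtype=float).ravel()
    pooled = np.concatenate([a, b])
    q1, q3 = np.percentile(pooled, [25, 75])
    cut = q3 + outlier_iqr_multiple * (q3 - q1)
    a, b = a[a <= cut], b[b <= cut]
    if a.size == 0 or b.size == 0:
        raise ValueError("outlier removal emptied a group")
    if log1p:
        a, b = np.log1p(a), np.log1p(b)
    u, p = stats.mannwhitneyu(a, b, alternative="greater")
    return TestResult(
        method="wilcoxon_rank_sum_one_sided",
        statistic=float(u),
        p_value=float(p),
        n_group1=a.size,
        n_group2=b.size,
        direction="greater",
    )


def bootstrap_threshold(
    other_values: np.ndarray,
    replicates: int = 10_000,
    seed: int | np.random.Generator = 0,
    ci: float = 0.95,
) -> float:
    """Upper one-sided bound of the bootstrap distribution of resampled
    other-gene frequencies: the ``ci`` quantile of ``replicates`` pooled
    resamples (each of the original size), deterministic given the seed."""
    values = np.asarray(other_values, dtype=float)
    if values.size < 20:
        raise ValueError(f"need >= 20 other-gene values, got {values.size}")
    if replicates < 1000:
        raise ValueError("replicates must be >= 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # one flat resample of replicates * n draws is the pooled bootstrap sample
    idx = rng.integers(0, values.size, size=replicates * values.size)
    return float(np.quantile(values[idx], ci))


@dataclass
class EnrichmentMatrix:
    """Binary cells x cancer-genes matrix plus the bootstrap parameters."""

    matrix: pd.DataFrame  # rows cell ids, columns cancer genes, values {0,1}
    replicates: int
    seed: int
    ci: float
    thresholds: pd.Series  # per-cell bootstrap bound


def build_enrichment_matrix(
    gene_freq: pd.DataFrame,
    cancer_genes: list[str],
    replicates: int = 10_000,
    seed: int = 0,
    ci: float = 0.95,
) -> EnrichmentMatrix:
    """Entry (cell, gene) = 1 iff the gene's SNP-Freq_g in that cell exceeds
    the cell's bootstrap upper bound built from all non-cancer genes.

    Genes absent from the frequency table count as frequency 0 and are never
    enriched. Per-cell RNG streams are spawned from the master seed, so the
    matrix is reproducible bit-exact and independent of cell order.
    """
    cancer = list(dict.fromkeys(cancer_genes))
    other_cols = [g for g in gene_freq.columns if g not in set(cancer)]
    if not other_cols:
        raise ValueError("no non-cancer genes available for the null pool")
    freq = gene_freq.reindex(columns=cancer, fill_value=0.0)
    out = pd.DataFrame(0, index=gene_freq.index, columns=cancer, dtype=int)
    thresholds = {}
    for i, cell in enumerate(gene_freq.index):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        thr = bootstrap_threshold(
            gene_freq.loc[cell, other_cols].to_numpy(), replicates, rng, ci
        )
        thresholds[cell] = thr
        vals = freq.loc[cell].to_numpy(dtype=float)
        out.loc[cell] = ((vals > thr) & (vals > 0)).astype(int)
    return EnrichmentMatrix(
        matrix=out,
        replicates=replicates,
        seed=seed,
        ci=ci,
        thresholds=pd.Series(thresholds, name="bootstrap_threshold"),
    )


def select_recurrent(matrix: pd.DataFrame, fraction: float = 0.5) -> pd.DataFrame:
    """Genes enriched in strictly more than ``fraction`` of all cells,
    ordered by decreasing column mean."""
    if matrix.empty:
        raise ValueError("enrichment matrix is empty")
    means = matrix.mean(axis=0)
    selected = means[means > fraction]
    order = sorted(selected.index, key=lambda g: (-selected[g], str(g)))
    return pd.DataFrame({"enriched_fraction": selected.loc[order]}).rename_axis("gene_id")
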