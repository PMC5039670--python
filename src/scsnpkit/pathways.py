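"""Per-pathway SNP enrichment: Fisher's exact test on mutated-gene counts,
rank-sum on sample ratios, an expression-matched resampling null for the
pathway's mean SNP-Freq_g, and the two-step gene ranking/selection."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PathwayDef
from .statistics import TestResult

log = logging.getLogger(__name__)


def pathway_fisher(
    mutated: pd.Series, pathway: PathwayDef
) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 table
    {mutated, not mutated} x {in pathway, out}.

    ``mutated`` is a boolean Series over all genes (MS >= 1 after filtering).
    """
    genes = mutated.index
    in_path = genes.isin(pathway.genes)
    if not in_path.any() or in_path.all():
        raise ValueError(f"pathway {pathway.name} is empty (or universal) after intersection")
    m = mutated.astype(bool).to_numpy()
    if m.all() or not m.any():
        raise ValueError("degenerate margin: all genes mutated or none")
    table = [
        [int((m & in_path).sum()), int((m & ~in_path).sum())],
        [int((~m & in_path).sum()), int((~m & ~in_path).sum())],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(
        method="fisher_exact",
        statistic=float(odds),
        p_value=float(p),
        n_group1=int(in_path.sum()),
        n_group2=int((~in_path).sum()),
        direction="greater" if odds > 1 else "less",
    )


def pathway_sr_wilcoxon(sr_in, sr_out) -> TestResult:
    """One-sided rank-sum (in-pathway sample ratios greater), ties mid-ranked."""
    a = np.asarray(sr_in, dtype=float)
    b = np.asarray(sr_out, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need >= 1 value")
    u, p = stats.mannwhitneyu(a, b, alternative="greater")
    return TestResult(
        method="wilcoxon_rank_sum_one_sided",
        statistic=float(u),
        p_value=float(p),
        n_group1=a.size,
        n_group2=b.size,
        direction="greater",
    )


def expression_matched_bootstrap(
    pathway_genes: list[str],
    other_genes: list[str],
    mean_freq: pd.Series,
    mean_expression: pd.Series,
    replicates: int = 1000,
    seed: int = 0,
    n_bins: int = 10,
) -> float:
    """Resampling p value for the pathway's mean SNP-Freq_g against
    expression-matched draws of non-pathway genes.

    Candidate genes are binned into expression quantile bins; each replicate
    draws, per pathway gene, one candidate from the same bin (relaxing to
    the nearest non-empty bin). p = (1 + #{replicate mean >= pathway mean})
    / (replicates + 1).
    """
    if replicates < 100:
        raise ValueError("replicates must be >= 100")
    path = [g for g in pathway_genes if g in mean_freq.index]
    cand = [g for g in other_genes if g in mean_freq.index]
    if not path or not cand:
        raise ValueError("pathway or candidate gene set empty after intersection")
    missing = [g for g in path + cand if g not in mean_expression.index]
    if missing:
        raise ValueError(f"expression missing for gene(s): {missing[:5]}")
    expr = mean_expression
    edges = np.quantile(expr[cand].to_numpy(), np.linspace(0, 1, n_bins + 1))
    edges[-1] = np.inf

    def bin_of(v: float) -> int:
        return int(np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_bins - 1))

    cand_by_bin: dict[int, np.ndarray] = {}
    cand_bins = np.array([bin_of(expr[g]) for g in cand])
    freq_cand = mean_freq[cand].to_numpy()
    for b in range(n_bins):
        cand_by_bin[b] = np.flatnonzero(cand_bins == b)
    # nearest non-empty bin fallback
    resolved: dict[int, np.ndarray] = {}
    for b in range(n_bins):
        if cand_by_bin[b].size:
            resolved[b] = cand_by_bin[b]
        else:
            for d in range(1, n_bins):
                for nb in (b - d, b + d):
                    if 0 <= nb < n_bins and cand_by_bin[nb].size:
                        resolved[b] = cand_by_bin[nb]
                        break
                if b in resolved:
                    log.warning("expression bin %d empty; relaxed to nearest bin", b)
                    break

    path_bins = [bin_of(expr[g]) for g in path]
    rng = np.random.default_rng(seed)
    draws = np.column_stack(
        [resolved[b][rng.integers(0, resolved[b].size, size=replicates)] for b in path_bins]
    )
    rep_means = freq_cand[draws].mean(axis=1)
    observed = float(mean_freq[path].mean())
    exceed = int((rep_means >= observed).sum())
    return (1 + exceed) / (replicates + 1)


@dataclass
class PathwayReport:
    name: str
    fisher: TestResult
    sr_wilcoxon: TestResult
    bootstrap_p: float
    gene_table: pd.DataFrame  # ranked: gene, mean_snp_freq, sample_ratio, selected, reason
    selection_test: TestResult | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)


def rank_and_select(
    pathway: PathwayDef,
    mean_freq: pd.Series,
    sr: pd.Series,
    sr_threshold: float = 0.5,
    manual_additions: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, TestResult | None]:
    """Rank pathway genes by mean SNP-Freq_g (desc), tie-break by SR (desc)
    then symbol (asc); select genes with SR strictly above the threshold,
    union reason-tagged manual additions; Welch t-test of selected vs
    unselected genes' frequencies."""
    manual = manual_additions or {}
    genes = sorted(g for g in pathway.genes if g in mean_freq.index)
    bad = [g for g in manual if g not in genes]
    if bad:
        raise ValueError(f"manual addition(s) not in pathway {pathway.name}: {bad}")
    tbl = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_snp_freq": [float(mean_freq[g]) for g in genes],
            "sample_ratio": [float(sr.get(g, 0.0)) for g in genes],
        }
    )
    tbl = tbl.sort_values(
        by=["mean_snp_freq", "sample_ratio", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    reasons = []
    for row in tbl.itertuples(index=False):
        if row.sample_ratio > sr_threshold:
            reasons.append("sr_threshold")
        elif row.gene_id in manual:
            reasons.append(manual[row.gene_id])
        else:
            reasons.append("")
    tbl["selected"] = [bool(r) for r in reasons]
    tbl["reason"] = reasons
    sel = tbl.loc[tbl["selected"], "mean_snp_freq"].to_numpy()
    unsel = tbl.loc[~tbl["selected"], "mean_snp_freq"].to_numpy()
    test = None
    if sel.size >= 2 and unsel.size >= 2:
        t, p = stats.ttest_ind(sel, unsel, equal_var=False)
        test = TestResult(
            "welch_t", float(t), float(p), sel.size, unsel.size,
            direction="greater" if sel.mean() > unsel.mean() else "less",
        )
    return tbl, test


def analyze_pathway(
    pathway: PathwayDef,
    gene_freq: pd.DataFrame,
    sr_table: pd.DataFrame,
    expression: pd.DataFrame,
    replicates: int = 1000,
    seed: int = 0,
    sr_threshold: float = 0.5,
    manual_additions: dict[str, str] | None = None,
) -> PathwayReport:
    """Run all four pathway analyses and assemble one report."""
    mutated = sr_table["mutated_samples"] >= 1
    fisher = pathway_fisher(mutated, pathway)
    in_mask = sr_table.index.isin(pathway.genes)
    wil = pathway_sr_wilcoxon(
        sr_table.loc[in_mask, "sample_ratio"], sr_table.loc[~in_mask, "sample_ratio"]
    )
    mean_freq = gene_freq.mean(axis=0)
    mean_expr = expression.mean(axis=1)  # expression is genes x cells
    others = [g for g in gene_freq.columns if g not in pathway.genes]
    boot_p = expression_matched_bootstrap(
        sorted(pathway.genes), others, mean_freq, mean_expr, replicates, seed
    )
    tbl, sel_test = rank_and_select(
        pathway, mean_freq, sr_table["sample_ratio"], sr_threshold, manual_additions
    )
    return PathwayReport(
        name=pathway.name,
        fisher=fisher,
        sr_wilcoxon=wil,
        bootstrap_p=boot_p,
        gene_table=tbl,
        selection_test=sel_test,
        seed=seed,
    )
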