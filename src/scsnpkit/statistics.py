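"""Per-megabase SNP frequency statistics, sample ratios, dispersion and
enrichment tests.

Frequencies are normalised per megabase of the feature's length so values
are comparable across chromosomes and across genes of different sizes:

    SNP-Freq_c = SNP_count / (chromosome_length / 1e6)
    SNP-Freq_g = SC / (GL / 1e6)
    SR         = MS / AS      (mutated samples over all retained samples)
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .records import SnpRecord

MB = 1e6


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_group1: int
    n_group2: int
    direction: str = ""  # "greater" when group1 mean/rank exceeds group2

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


def snp_freq_c(snp_count: int, chrom_length_bases: int) -> float:
    """SNPs per megabase of one chromosome in one cell."""
    if chrom_length_bases < 1:
        raise ValueError("chromosome length must be >= 1")
    if snp_count < 0:
        raise ValueError("snp_count must be >= 0")
    return snp_count / (chrom_length_bases / MB)


def snp_freq_g(sc: int, gl: int) -> float:
    """SNPs per megabase of one gene's length (GL) in one cell."""
    if gl < 1:
        raise ValueError("gene length must be >= 1")
    if sc < 0:
        raise ValueError("SNP count must be >= 0")
    return sc / (gl / MB)


def sample_ratio(ms: int, as_: int) -> float:
    """Fraction of retained cells in which a gene carries >= 1 SNP."""
    if as_ < 1:
        raise ValueError("AS must be >= 1")
    if not 0 <= ms <= as_:
        raise ValueError("MS must satisfy 0 <= MS <= AS")
    return ms / as_


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Render a fraction as a percentage, half-up rounded (0.6024.. -> '60.24')."""
    q = Decimal(1).scaleb(-decimals)
    return str((Decimal(repr(float(fraction))) * 100).quantize(q, rounding=ROUND_HALF_UP))


def _count_matrix(
    pairs: list[tuple[str, str]], row_ids: list[str], col_ids: list[str]
) -> pd.DataFrame:
    rows = {c: i for i, c in enumerate(row_ids)}
    cols = {c: j for j, c in enumerate(col_ids)}
    counts = np.zeros((len(row_ids), len(col_ids)), dtype=np.int64)
    idx = [
        (rows[r], cols[c]) for r, c in pairs if r in rows and c in cols
    ]
    if idx:
        i, j = zip(*idx)
        np.add.at(counts, (np.fromiter(i, int), np.fromiter(j, int)), 1)
    return pd.DataFrame(counts, index=list(row_ids), columns=list(col_ids))


def chromosome_profile(
    records: list[SnpRecord], chrom_lengths: dict[str, int], cell_ids: list[str]
) -> pd.DataFrame:
    """Cells x chromosomes matrix of SNP-Freq_c (SNPs per Mb)."""
    counts = _count_matrix(
        [(r.cell_id, r.chrom) for r in records], list(cell_ids), list(chrom_lengths)
    )
    lengths = pd.Series(chrom_lengths, dtype=float)
    return counts / (lengths / MB)


def gene_profile(
    records: list[SnpRecord], gene_lengths: dict[str, int], cell_ids: list[str]
) -> pd.DataFrame:
    """Cells x genes matrix of SNP-Freq_g; genes with no SNP have frequency 0."""
    counts = _count_matrix(
        [(r.cell_id, r.gene_id) for r in records], list(cell_ids), list(gene_lengths)
    )
    lengths = pd.Series(gene_lengths, dtype=float)
    return counts / (lengths / MB)


def sample_ratios(gene_freq: pd.DataFrame) -> pd.DataFrame:
    """Per-gene MS, AS and SR from a cells x genes frequency (or count) matrix."""
    ms = (gene_freq > 0).sum(axis=0).astype(int)
    as_ = len(gene_freq.index)
    return pd.DataFrame(
        {"mutated_samples": ms, "all_samples": as_, "sample_ratio": ms / as_}
    ).rename_axis("gene_id")


@dataclass(frozen=True)
class DispersionRecord:
    gene_id: str
    mean: float
    sd: float
    variance: float
    cv: float  # sd / mean
    fano: float  # variance / mean
    defined: bool


def dispersion_stats(gene_id: str, values) -> DispersionRecord:
    """CV and Fano factor across cells (unbiased n-1 variance).

    Undefined (mean == 0) records are flagged and must be excluded from
    correlation analyses by the caller.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.isfinite(x).all():
        raise ValueError("need >= 2 finite values")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    sd = float(np.sqrt(var))
    if mean == 0.0:
        return DispersionRecord(gene_id, mean, sd, var, np.nan, np.nan, defined=False)
    return DispersionRecord(gene_id, mean, sd, var, sd / mean, var / mean, defined=True)


def dispersion_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`dispersion_stats` to every column of a cells x genes matrix."""
    rows = [dispersion_stats(g, matrix[g].to_numpy()) for g in matrix.columns]
    return pd.DataFrame(rows).set_index("gene_id")


def correlate(x, y, method: str = "spearman") -> TestResult:
    """Correlation between paired vectors with a two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in one vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return TestResult(
        method=f"{method}_correlation",
        statistic=float(r),
        p_value=float(p),
        n_group1=x.size,
        n_group2=y.size,
        direction="negative" if r < 0 else "positive",
    )


def chromosome_enrichment_test(
    profile: pd.DataFrame, target_chroms: list[str]
) -> TestResult:
    """Welch t-test of target-chromosome SNP-Freq_c values against all other
    chromosomes, pooled over cells."""
    targets = [c for c in profile.columns if c in set(target_chroms)]
    others = [c for c in profile.columns if c not in set(target_chroms)]
    if not targets or not others:
        raise ValueError("target chromosomes must be a non-empty proper subset")
    a = profile[targets].to_numpy().ravel()
    b = profile[others].to_numpy().ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        method="welch_t",
        statistic=float(t),
        p_value=float(p),
        n_group1=a.size,
        n_group2=b.size,
        direction="greater" if a.mean() > b.mean() else "less",
    )


def compare_callsets(records_by_caller: dict[str, list[SnpRecord]]) -> pd.DataFrame:
    """Cross-caller consistency: per-cell mean SNP counts, pairwise site-set
    Jaccard, and targeted-gene overlap."""
    if len(records_by_caller) < 2:
        raise ValueError("need >= 2 callers to compare")
    rows = []
    sites = {
        name: {(r.cell_id, r.chrom, r.pos) for r in recs}
        for name, recs in records_by_caller.items()
    }
    genes = {
        name: {r.gene_id for r in recs if r.gene_id}
        for name, recs in records_by_caller.items()
    }
    for name, recs in records_by_caller.items():
        n_cells = len({r.cell_id for r in recs}) or 1
        rows.append({"caller": name, "pair": "", "mean_snps_per_cell": len(recs) / n_cells,
                     "site_jaccard": np.nan, "gene_overlap": len(genes[name])})
    for a, b in combinations(sorted(records_by_caller), 2):
        union = sites[a] | sites[b]
        jac = len(sites[a] & sites[b]) / len(union) if union else 1.0
        rows.append({"caller": "", "pair": f"{a}|{b}", "mean_snps_per_cell": np.nan,
                     "site_jaccard": jac, "gene_overlap": len(genes[a] & genes[b])})
    return pd.DataFrame(rows)
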