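"""GO-slim summarisation of SNP burden.

Each SNP on a gene contributes one count to every GO term annotated to that
gene; terms are then collapsed onto a reduced "slim" vocabulary by tracing
is_a ancestry (a term maps to every slim on a path from it to the root, set
semantics). Per category (BP/CC/MF) this yields a slim x cell count matrix
whose rows are clustered with k-means and tested group-vs-rest.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .io import GoAnnotations
from .records import SnpRecord
from .statistics import TestResult

log = logging.getLogger(__name__)

CATEGORIES = ("BP", "CC", "MF")


def snp_weight_per_term(
    records: list[SnpRecord], annotations: GoAnnotations
) -> tuple[dict[str, dict[str, int]], set[str]]:
    """Per cell, add each SNP's gene count to every GO term of that gene.

    Returns ``{cell_id: {term: count}}`` plus the set of genes that carried
    SNPs but no annotation.
    """
    counts: dict[str, dict[str, int]] = {}
    unannotated: set[str] = set()
    for r in records:
        terms = annotations.gene_to_terms.get(r.gene_id)
        if not terms:
            unannotated.add(r.gene_id)
            continue
        per_cell = counts.setdefault(r.cell_id, {})
        for t in terms:
            per_cell[t] = per_cell.get(t, 0) + 1
    if unannotated:
        log.info("%d SNP-bearing genes had no GO annotation", len(unannotated))
    return counts, unannotated


def backtrace_to_slims(
    term: str, annotations: GoAnnotations, path_count_weighting: bool = False
) -> dict[str, int]:
    """Slim terms reachable from ``term`` by is_a ancestry (term included).

    Returns slim -> multiplicity. With set semantics (default) every
    multiplicity is 1; with ``path_count_weighting`` a slim counts once per
    distinct is_a path from the term to it.
    """
    if term not in annotations.graph:
        log.warning("unknown GO term %s; back-trace empty", term)
        return {}
    hits = {term} | annotations.ancestors(term)
    slims = hits & annotations.slim_terms
    if not path_count_weighting:
        return {s: 1 for s in slims}
    import networkx as nx

    out = {}
    for s in slims:
        if s == term:
            out[s] = 1
        else:
            out[s] = len(list(nx.all_simple_paths(annotations.graph, term, s))) or 1
    return out


@dataclass
class SlimCountMatrix:
    """Slim terms x cells count matrix for one GO category."""

    category: str
    counts: pd.DataFrame  # rows slim terms, columns cell ids, int
    unslimmed_terms: set[str]

    @property
    def transformed(self) -> pd.DataFrame:
        """log2(count + 1), the scale used for clustering and export."""
        return np.log2(self.counts + 1)


def build_slim_matrix(
    term_counts: dict[str, dict[str, int]],
    annotations: GoAnnotations,
    category: str,
    cell_ids: list[str] | None = None,
    path_count_weighting: bool = False,
) -> SlimCountMatrix:
    """Collapse per-term counts onto slims for one category."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    cells = list(cell_ids) if cell_ids is not None else sorted(term_counts)
    slim_rows = sorted(
        t for t in annotations.slim_terms if annotations.term_category.get(t) == category
    )
    mat = pd.DataFrame(0, index=slim_rows, columns=cells, dtype=int)
    unslimmed: set[str] = set()
    backtrace_cache: dict[str, dict[str, int]] = {}
    for cell, counts in term_counts.items():
        if cell not in mat.columns:
            continue
        for term, n in counts.items():
            if annotations.term_category.get(term) != category:
                continue
            if term not in backtrace_cache:
                backtrace_cache[term] = backtrace_to_slims(
                    term, annotations, path_count_weighting
                )
            slims = backtrace_cache[term]
            if not slims:
                unslimmed.add(term)
                continue
            for s, mult in slims.items():
                mat.loc[s, cell] += n * mult
    if mat.empty:
        log.warning("category %s produced an empty slim matrix", category)
    return SlimCountMatrix(category=category, counts=mat, unslimmed_terms=unslimmed)


@dataclass
class SlimGrouping:
    category: str
    assignment: pd.Series  # slim term -> group index (0 = highest mean)
    group_tests: dict[int, TestResult]
    degenerate: bool = False


def cluster_and_test(
    matrix: SlimCountMatrix, k: int, seed: int, zscore_rows: bool = False
) -> SlimGrouping:
    """K-means on log2-transformed slim rows, then per-group Welch t-test of
    the group's values against all remaining groups pooled.

    Groups are relabelled by decreasing group mean so group 0 is the most
    SNP-enriched; the labelling (and hence the result) is invariant to row
    permutation of the input.
    """
    X = matrix.transformed
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} rows < k={k}")
    vals = X.to_numpy()
    fit_vals = vals
    if zscore_rows:
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        fit_vals = np.where(sd > 0, (vals - mu) / np.where(sd == 0, 1, sd), 0.0)
    degenerate = len(np.unique(fit_vals, axis=0)) < k
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(fit_vals)
    # relabel by decreasing mean of the (untransformed-scale log) values
    means = {lab: vals[labels == lab].mean() for lab in np.unique(labels)}
    order = sorted(means, key=lambda lab: -means[lab])
    relabel = {old: new for new, old in enumerate(order)}
    assignment = pd.Series([relabel[lab] for lab in labels], index=X.index, name="group")
    tests: dict[int, TestResult] = {}
    for g in sorted(set(assignment)):
        a = vals[(assignment == g).to_numpy()].ravel()
        b = vals[(assignment != g).to_numpy()].ravel()
        if a.size < 2 or b.size < 2:
            tests[g] = TestResult("welch_t", np.nan, np.nan, a.size, b.size)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        tests[g] = TestResult(
            "welch_t", float(t), float(p), a.size, b.size,
            direction="greater" if a.mean() > b.mean() else "less",
        )
    if degenerate:
        log.warning("category %s: fewer distinct rows than k; clustering degenerate", matrix.category)
    return SlimGrouping(matrix.category, assignment, tests, degenerate=degenerate)
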