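"""Pathway Fisher / rank-sum / expression-matched bootstrap and the
two-step gene ranking."""
from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from scsnpkit.io import PathwayDef
from scsnpkit.pathways import (
    analyze_pathway,
    expression_matched_bootstrap,
    pathway_fisher,
    pathway_sr_wilcoxon,
    rank_and_select,
)


def hypergeom_two_sided_p(table):
    """Exact two-sided Fisher p by enumerating the hypergeometric support."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c

    def prob(k):
        return comb(c1, k) * comb(n - c1, r1 - k) / comb(n, r1)

    p_obs = prob(a)
    return sum(prob(k) for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


class TestPathwayFisher:
    def _inputs(self, table):
        (a, b), (c, d) = table
        genes = [f"g{i}" for i in range(a + b + c + d)]
        pw = PathwayDef("pw", frozenset(genes[:a] + genes[a + b: a + b + c]))
        mutated = pd.Series([True] * (a + b) + [False] * (c + d), index=genes)
        return mutated, pw

    def test_balanced_table_shows_no_association(self):
        mutated, pw = self._inputs([[10, 10], [10, 10]])
        res = pathway_fisher(mutated, pw)
        assert res.statistic == 1.0 and res.p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        table = [[9, 1], [1, 9]]
        mutated, pw = self._inputs(table)
        res = pathway_fisher(mutated, pw)
        assert res.statistic == pytest.approx(81.0)
        assert res.p_value == pytest.approx(hypergeom_two_sided_p(table))

    def test_swapping_rows_and_columns_preserves_p(self):
        table = [[12, 3], [5, 20]]
        res1 = pathway_fisher(*self._inputs(table))
        swapped = [[20, 5], [3, 12]]  # both rows and both columns swapped
        res2 = pathway_fisher(*self._inputs(swapped))
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_degenerate_margin_rejected(self):
        genes = [f"g{i}" for i in range(10)]
        mutated = pd.Series(True, index=genes)
        with pytest.raises(ValueError, match="degenerate"):
            pathway_fisher(mutated, PathwayDef("pw", frozenset(genes[:4])))

    def test_empty_pathway_after_intersection_rejected(self):
        mutated = pd.Series([True, False], index=["g1", "g2"])
        with pytest.raises(ValueError, match="empty"):
            pathway_fisher(mutated, PathwayDef("pw", frozenset({"x1", "x2"})))

    def test_null_calibration(self):
        """Mutation status independent of membership rejects at ~5%."""
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(400)]
        rejections, n_seeds = 0, 200
        for _ in range(n_seeds):
            mutated = pd.Series(rng.random(400) < 0.5, index=genes)
            members = rng.choice(genes, size=80, replace=False)
            pw = PathwayDef("pw", frozenset(members))
            rejections += pathway_fisher(mutated, pw).p_value < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.09


class TestSrWilcoxon:
    def test_separable_groups_hit_minimal_p(self):
        """4 vs 4 fully separated values reach the smallest one-sided p the
        group sizes allow: 1 / C(8,4)."""
        res = pathway_sr_wilcoxon([0.9, 0.8, 0.85, 0.95], [0.1, 0.2, 0.15, 0.05])
        assert res.p_value == pytest.approx(1 / comb(8, 4))

    def test_identically_distributed_groups_near_half(self):
        """Groups drawn from one distribution: the one-sided p sits near its
        symmetric centre rather than either tail."""
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(50):
            pooled = rng.random(80)
            ps.append(pathway_sr_wilcoxon(pooled[:40], pooled[40:]).p_value)
        assert 0.35 < float(np.median(ps)) < 0.65

    def test_null_calibration(self):
        rng = np.random.default_rng(21)
        rejections, n_seeds = 0, 200
        for _ in range(n_seeds):
            pooled = rng.random(60)
            rejections += pathway_sr_wilcoxon(pooled[:20], pooled[20:]).p_value < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.09


class TestExpressionMatchedBootstrap:
    def _tables(self, rng, n=220):
        genes = [f"g{i}" for i in range(n)]
        freq = pd.Series(rng.lognormal(2, 0.6, size=n), index=genes)
        expr = pd.Series(rng.lognormal(1, 1.0, size=n), index=genes)
        return genes, freq, expr

    def test_far_above_candidates_gives_floor_p(self):
        rng = np.random.default_rng(0)
        genes, freq, expr = self._tables(rng)
        pathway = genes[:15]
        freq[pathway] = freq.max() * 50
        p = expression_matched_bootstrap(pathway, genes[15:], freq, expr,
                                         replicates=500, seed=0)
        assert p == pytest.approx(1 / 501)

    def test_p_bounded_and_monotone_in_pathway_mean(self):
        rng = np.random.default_rng(1)
        genes, freq, expr = self._tables(rng)
        pathway = genes[:15]
        p0 = expression_matched_bootstrap(pathway, genes[15:], freq, expr,
                                          replicates=300, seed=2)
        boosted = freq.copy()
        boosted[pathway] *= 20
        p1 = expression_matched_bootstrap(pathway, genes[15:], boosted, expr,
                                          replicates=300, seed=2)
        assert 1 / 301 <= p1 <= p0 <= 1.0

    def test_too_few_replicates_rejected(self):
        rng = np.random.default_rng(2)
        genes, freq, expr = self._tables(rng)
        with pytest.raises(ValueError, match="replicates"):
            expression_matched_bootstrap(genes[:5], genes[5:], freq, expr,
                                         replicates=0, seed=0)

    def test_null_calibration(self):
        """Pathway drawn from the same population: p is uniform, so the 5%
        rejection rate stays in band over 200 seeds."""
        rng = np.random.default_rng(3)
        rejections, n_seeds = 0, 200
        for seed in range(n_seeds):
            genes, freq, expr = self._tables(rng, n=160)
            members = [genes[i] for i in rng.choice(160, size=12, replace=False)]
            others = [g for g in genes if g not in set(members)]
            p = expression_matched_bootstrap(members, others, freq, expr,
                                             replicates=199, seed=seed)
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_seeds <= 0.09


class TestRankAndSelect:
    def _pathway(self):
        return PathwayDef("pw", frozenset({"a", "b", "c"}))

    def test_sr_threshold_is_strict(self):
        freq = pd.Series({"a": 5.0, "b": 4.0, "c": 3.0})
        sr = pd.Series({"a": 0.9, "b": 0.5, "c": 0.2})
        tbl, _ = rank_and_select(self._pathway(), freq, sr, sr_threshold=0.5)
        assert tbl.loc[tbl["selected"], "gene_id"].tolist() == ["a"]

    def test_sr_breaks_frequency_ties(self):
        freq = pd.Series({"a": 5.0, "b": 5.0, "c": 1.0})
        sr = pd.Series({"a": 0.3, "b": 0.8, "c": 0.1})
        tbl, _ = rank_and_select(self._pathway(), freq, sr)
        assert tbl["gene_id"].tolist() == ["b", "a", "c"]

    def test_ordering_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(12)]
        freq = pd.Series(rng.choice([1.0, 2.0, 3.0], size=12), index=genes)
        sr = pd.Series(rng.choice([0.2, 0.5, 0.8], size=12), index=genes)
        pw = PathwayDef("pw", frozenset(genes))
        tbl, _ = rank_and_select(pw, freq, sr)
        expected = sorted(genes, key=lambda g: (-freq[g], -sr[g], g))
        assert tbl["gene_id"].tolist() == expected

    def test_manual_addition_outside_pathway_rejected(self):
        freq = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        sr = pd.Series({"a": 0.1, "b": 0.1, "c": 0.1})
        with pytest.raises(ValueError, match="zzz"):
            rank_and_select(self._pathway(), freq, sr, manual_additions={"zzz": "kegg_documented"})

    def test_manual_addition_reason_tagged(self):
        freq = pd.Series({"a": 9.0, "b": 2.0, "c": 3.0})
        sr = pd.Series({"a": 0.9, "b": 0.1, "c": 0.1})
        tbl, _ = rank_and_select(self._pathway(), freq, sr,
                                 manual_additions={"c": "high_freq_manual"})
        row = tbl.set_index("gene_id").loc["c"]
        assert row["selected"] and row["reason"] == "high_freq_manual"


def test_default_cohort_pathway_reports(filtered_cohort, default_cohort):
    """Full pathway analysis runs on the generated cohort and is seed-stable."""
    from scsnpkit import io
    from scsnpkit.statistics import sample_ratios

    data, outdir = default_cohort
    freq = filtered_cohort["gene_freq"].loc[data.truth.retained_cells]
    sr = sample_ratios(freq)
    expr = io.read_expression(outdir / "expression.tsv")
    pw = next(p for p in io.read_gene_sets(outdir / "pathways.gmt")
              if p.name == "mismatch_repair")
    rep1 = analyze_pathway(pw, freq, sr, expr, replicates=200, seed=5)
    rep2 = analyze_pathway(pw, freq, sr, expr, replicates=200, seed=5)
    assert rep1.bootstrap_p == rep2.bootstrap_p
    assert 0 < rep1.fisher.p_value <= 1
    # planted RPA1 has MS=50 of 83: SR 0.602 > 0.5 so it is auto-selected
    row = rep1.gene_table.set_index("gene_id").loc["RPA1"]
    assert row["selected"] and row["reason"] == "sr_threshold"
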