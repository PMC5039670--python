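"""Fusion filter cascade: rule semantics, order dependence, conservation
and recurrence percentages."""
from __future__ import annotations

import numpy as np
import pytest

from scsnpkit.fusions import (
    filter_fusion_cascade,
    recurrent_fusions,
    summarize_fusions,
)
from scsnpkit.records import FusionRecord, Location

RIBO = {"RPL7", "RPS3"}


def fusion(cell="c1", g5="A", g3="B", c5="chr1", c3="chr2", b5=1_000_000,
           b3=5_000_000, l5=Location.EXONIC, l3=Location.EXONIC):
    return FusionRecord(cell_id=cell, gene5=g5, gene3=g3, chrom5=c5, chrom3=c3,
                        breakpoint5=b5, breakpoint3=b3, location5=l5, location3=l3,
                        supporting_reads=3)


def brute_force_survivors(records, ribosomal):
    """Independent reimplementation of the cascade's retained set."""
    out = {}
    cells = {r.cell_id for r in records}
    for cell in cells:
        recs = [r for r in records if r.cell_id == cell]
        stage = [
            r for r in recs
            if r.gene5 not in ribosomal and r.gene3 not in ribosomal
            and r.location5 not in (Location.INTRONIC, Location.INTRAEXONIC)
            and r.location3 not in (Location.INTRONIC, Location.INTRAEXONIC)
        ]
        survivors = []
        for r in stage:
            partners5 = {x.gene3 for x in stage if x.gene5 == r.gene5}
            partners5 |= {x.gene5 for x in stage if x.gene3 == r.gene5}
            partners3 = {x.gene3 for x in stage if x.gene5 == r.gene3}
            partners3 |= {x.gene5 for x in stage if x.gene3 == r.gene3}
            if len(partners5) > 1 or len(partners3) > 1:
                continue
            if r.chrom5 == r.chrom3 and abs(r.breakpoint5 - r.breakpoint3) < 100_000:
                continue
            survivors.append(r)
        out[cell] = survivors
    return out


class TestCascadeRules:
    def test_ribosomal_partner_dropped_first(self):
        reports = filter_fusion_cascade([fusion(g5="RPL7")], RIBO)
        assert reports["c1"].drops["ribosomal_partner"] == 1
        assert not reports["c1"].retained

    def test_close_same_chromosome_pair_dropped(self):
        """Breakpoints 40 kbp apart on one chromosome fall below the 100 kbp
        read-through cutoff."""
        rec = fusion(c3="chr1", b5=1_000_000, b3=1_040_000)
        reports = filter_fusion_cascade([rec], RIBO)
        assert reports["c1"].drops["close_breakpoints"] == 1

    def test_intron_or_intraexonic_partner_dropped(self):
        recs = [fusion(g5="A", g3="B", l3=Location.INTRONIC),
                fusion(g5="C", g3="D", l5=Location.INTRAEXONIC, b5=2_000_000)]
        reports = filter_fusion_cascade(recs, RIBO)
        assert reports["c1"].drops["intron_or_intraexonic"] == 2

    def test_multi_partner_rule_counts_survivors_of_earlier_rules(self):
        """A ribosomal record sharing a gene with a clean record must not
        trigger the multi-partner rule: partner counting happens after the
        ribosomal and location rules (order-dependence pin)."""
        recs = [
            fusion(g5="A", g3="RPL7"),  # dropped at rule 1
            fusion(g5="A", g3="B"),  # A has one surviving partner -> kept
        ]
        reports = filter_fusion_cascade(recs, RIBO)
        assert [r.gene3 for r in reports["c1"].retained] == ["B"]
        # same pair evaluated without the ribosomal rule would be dropped:
        alt = brute_force_survivors(recs, set())
        assert alt["c1"] == []

    def test_multi_partner_pair_both_dropped(self):
        recs = [fusion(g5="A", g3="B"), fusion(g5="A", g3="C", b5=9_000_000)]
        reports = filter_fusion_cascade(recs, RIBO)
        assert reports["c1"].drops["multiple_partners"] == 2

    def test_conservation_per_cell(self):
        rng = np.random.default_rng(0)
        recs = [
            fusion(cell=f"c{rng.integers(0, 4)}", g5=f"X{i}", g3=f"Y{i}",
                   b5=int(rng.integers(1, 10**7)))
            for i in range(40)
        ]
        for rep in filter_fusion_cascade(recs, RIBO).values():
            assert sum(rep.drops.values()) + len(rep.retained) == rep.n_input

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        locations = list(Location)
        genes = [f"g{i}" for i in range(8)] + ["RPL7"]
        recs = []
        for i in range(int(rng.integers(5, 40))):
            g5, g3 = rng.choice(genes, size=2, replace=False)
            same = rng.random() < 0.4
            c5 = "chr1"
            c3 = "chr1" if same else "chr2"
            recs.append(
                fusion(cell=f"c{rng.integers(0, 3)}", g5=str(g5), g3=str(g3), c5=c5, c3=c3,
                       b5=int(rng.integers(1, 3 * 10**5)), b3=int(rng.integers(1, 3 * 10**5)),
                       l5=locations[rng.integers(0, 4)], l3=locations[rng.integers(0, 4)])
            )
        reports = filter_fusion_cascade(recs, RIBO)
        expected = brute_force_survivors(recs, RIBO)
        for cell, rep in reports.items():
            assert rep.retained == expected[cell]

    def test_planted_truth_flags_matched_exactly(self, default_cohort):
        data, _ = default_cohort
        reports = filter_fusion_cascade(data.fusion_records, set(data.ribosomal_genes))
        survived = {
            (cell, r.gene5, r.gene3)
            for cell, rep in reports.items()
            for r in rep.retained
        }
        truth = data.truth.fusion_truth
        expected = {
            (row.cell_id, row.gene5, row.gene3)
            for row in truth.itertuples(index=False)
            if row.should_survive
        }
        assert survived == expected


class TestSummaries:
    def test_class_means(self):
        reports = filter_fusion_cascade(
            [fusion(cell="c1", g5=f"A{i}", g3=f"B{i}") for i in range(4)]
            + [fusion(cell="c2", g5=f"C{i}", g3=f"D{i}") for i in range(6)],
            RIBO,
        )
        summary = summarize_fusions({"single_cell": reports})
        assert summary.loc["single_cell", "mean_raw"] == 5.0

    def test_everything_filtered_gives_zero_mean(self):
        reports = filter_fusion_cascade(
            [fusion(cell="c1", g5="RPL7"), fusion(cell="c2", g5="RPS3")], RIBO
        )
        summary = summarize_fusions({"single_cell": reports})
        assert summary.loc["single_cell", "mean_retained"] == 0.0

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="bulk_cancer"):
            summarize_fusions({"bulk_cancer": {}})


class TestRecurrence:
    def test_five_of_96_cells_prints_5_21_percent(self):
        recs = [fusion(cell=f"c{i}", g5="UBB", g3="UBC") for i in range(5)]
        table = recurrent_fusions(recs, n_samples=96)
        assert table.loc[0, "n_cells"] == 5
        assert table.loc[0, "percent"] == 5.21

    def test_every_cell_gives_100_percent(self):
        recs = [fusion(cell=f"c{i}") for i in range(12)]
        assert recurrent_fusions(recs, 12).loc[0, "percent"] == 100.00

    def test_duplicate_rows_count_once_per_cell(self):
        rng = np.random.default_rng(1)
        recs = []
        for i in range(40):
            cell = f"c{rng.integers(0, 6)}"
            recs.append(fusion(cell=cell, g5="A", g3="B"))
            if rng.random() < 0.5:  # duplicate row, same pair, same cell
                recs.append(fusion(cell=cell, g5="B", g3="A", b5=999))
        table = recurrent_fusions(recs, n_samples=6).set_index("pair")
        expected = len({r.cell_id for r in recs})  # brute-force set oracle
        assert table.loc["A-B", "n_cells"] == expected
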