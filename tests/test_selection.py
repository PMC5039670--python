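"""NG86 Ka/Ks estimator, ortholog filters, selection classification and the
omega-expression association."""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from scsnpkit.selection import (
    OrthologRecord,
    classify_selection,
    filter_orthologs,
    ng86_kaks,
    slim_selection_summary,
)
from scsnpkit.synthetic import plant_codon_pair


class TestNg86:
    def test_identical_sequences(self):
        seq = "ATGGGACCCTTT"
        res = ng86_kaks(seq, seq)
        assert res.ka == 0.0 and res.ks == 0.0 and res.omega is None

    def test_single_fourfold_synonymous_change(self):
        """GGA <-> GGG (Gly, 4-fold site) among identical codons:
        ka = 0, ks > 0, omega = 0."""
        res = ng86_kaks("ATGGGATTTAAACCCGTA", "ATGGGGTTTAAACCCGTA")
        assert res.ka == 0.0 and res.ks > 0.0 and res.omega == 0.0

    def test_hand_computed_ten_codon_example(self):
        """Worked example counted by hand before implementation.

        seq1 codons: TTT GGA CTT ATG AAA CCC GTA TAC GAT AGC
        seq2 differs by GGA->GGG (synonymous) and ATG->ATA (nonsynonymous).
        Synonymous sites per codon (seq1): 1/3,1,1,0,1/3,1,1,1/3,1/3,1/3
        -> S1 = 17/3; seq2 replaces ATG(0) with ATA(2/3) and keeps GGG(1)
        -> S2 = 19/3; averaged S = 6, N = 24. sd = nd = 1, so
        ps = 1/6, pn = 1/24; Jukes-Cantor gives
        ks = -0.75 ln(1 - 4/18) = 0.1884856, ka = -0.75 ln(1 - 4/72)
        = 0.0428687, omega = 0.227437.
        """
        seq1 = "TTTGGACTTATGAAACCCGTATACGATAGC"
        seq2 = "TTTGGGCTTATAAAACCCGTATACGATAGC"
        res = ng86_kaks(seq1, seq2)
        assert res.syn_sites == pytest.approx(6.0, abs=1e-12)
        assert res.nonsyn_sites == pytest.approx(24.0, abs=1e-12)
        assert res.ks == pytest.approx(0.1884856, abs=1e-6)
        assert res.ka == pytest.approx(0.0428687, abs=1e-6)
        assert res.omega == pytest.approx(0.227437, abs=1e-5)

    def test_matches_independent_reference_implementation(self):
        """Cross-check against Bio.codonalign's NG86 on random pairs."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(17)
        for target in (0.2, 0.5, 1.0, 2.0):
            s1, s2 = plant_codon_pair(rng, 200, target)
            res = ng86_kaks(s1, s2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
            assert res.ka == pytest.approx(dn, abs=1e-4)
            assert res.ks == pytest.approx(ds, abs=1e-4)

    def test_symmetric_in_sequence_order(self):
        rng = np.random.default_rng(3)
        s1, s2 = plant_codon_pair(rng, 120, 1.5)
        a, b = ng86_kaks(s1, s2), ng86_kaks(s2, s1)
        assert a.ka == pytest.approx(b.ka, abs=1e-12)
        assert a.ks == pytest.approx(b.ks, abs=1e-12)

    def test_length_errors(self):
        with pytest.raises(ValueError, match="divisible"):
            ng86_kaks("ATGC", "ATGC")
        with pytest.raises(ValueError, match="equal length"):
            ng86_kaks("ATGATG", "ATG")

    def test_gap_and_stop_columns_dropped(self):
        # middle codon gapped in seq2, final codon is a stop in seq1
        res = ng86_kaks("ATGGGATAA", "ATG---TGG")
        assert res.n_codons == 1 and res.ka == 0.0

    def test_planted_omega_recovered_within_band(self):
        """Planted omega in {0.2, 1.0, 2.0} at 300 codons is recovered
        within +-0.3 (median over 100 seeded pairs)."""
        for target in (0.2, 1.0, 2.0):
            estimates = []
            for seed in range(100):
                rng = np.random.default_rng(10_000 + seed)
                s1, s2 = plant_codon_pair(rng, 300, target)
                estimates.append(ng86_kaks(s1, s2).omega)
            assert abs(float(np.median(estimates)) - target) <= 0.3

    def test_synonymous_only_pair_has_zero_ka(self):
        # target omega 0 plants no nonsynonymous substitutions at all
        rng = np.random.default_rng(4)
        s1, s2 = plant_codon_pair(rng, 50, 0.0)
        res = ng86_kaks(s1, s2)
        assert res.ka == 0.0 and res.omega == 0.0


class TestFilters:
    def _rec(self, oid, slims, expr=1.0, mut=0.3):
        return OrthologRecord(ortholog_id=oid, go_slims=frozenset(slims),
                              expression_rate=expr, mutated_fraction=mut, omega=0.5)

    def test_expression_rate_boundary(self):
        kept, _ = filter_orthologs(
            [self._rec("a", {"s"}, expr=0.94)] + [self._rec(f"b{i}", {"s"}) for i in range(10)]
        )
        assert all(r.ortholog_id != "a" for r in kept)

    def test_slim_below_ten_orthologs_dropped(self):
        records = [self._rec(f"x{i}", {"small"}) for i in range(9)]
        records += [self._rec(f"y{i}", {"big"}) for i in range(10)]
        kept, slims = filter_orthologs(records)
        assert slims == {"big"} and len(kept) == 10

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_two_pass_oracle(self, seed):
        rng = np.random.default_rng(seed)
        slims = ["s1", "s2", "s3"]
        records = [
            self._rec(
                f"o{i}",
                set(rng.choice(slims, size=int(rng.integers(1, 3)), replace=False)),
                expr=float(rng.uniform(0.9, 1.0)),
                mut=float(rng.uniform(0.0, 0.2)),
            )
            for i in range(int(rng.integers(10, 60)))
        ]
        kept, kept_slims = filter_orthologs(records)
        # oracle: explicit two-pass
        stage = [r for r in records if r.expression_rate >= 0.95 and r.mutated_fraction >= 0.05]
        counts: dict = {}
        for r in stage:
            for s in r.go_slims:
                counts[s] = counts.get(s, 0) + 1
        exp_slims = {s for s, n in counts.items() if n >= 10}
        exp_ids = [r.ortholog_id for r in stage if r.go_slims & exp_slims]
        assert kept_slims == exp_slims
        assert [r.ortholog_id for r in kept] == exp_ids


class TestClassification:
    @pytest.mark.parametrize(
        "omega,expected",
        [(2.0, "positive"), (0.3, "negative"), (1.0, "neutral"),
         (1.0 + 1e-12, "neutral"), (None, "undefined"), (float("nan"), "undefined")],
    )
    def test_omega_classes(self, omega, expected):
        assert classify_selection(omega) == expected


class TestSlimSummary:
    def test_medians_match_brute_force(self):
        recs = [
            OrthologRecord("a", omega=0.5, go_slims=frozenset({"s1"})),
            OrthologRecord("b", omega=1.5, go_slims=frozenset({"s1", "s2"})),
            OrthologRecord("c", omega=None, go_slims=frozenset({"s2"})),
        ]
        summary, _ = slim_selection_summary(recs)
        assert summary.loc["s1", "median_omega"] == pytest.approx(1.0)
        assert summary.loc["s2", "median_omega"] == pytest.approx(1.5)
        assert summary.loc["s2", "n_undefined"] == 1

    def test_degenerate_correlation_surfaces_as_warning(self, caplog):
        recs = [
            OrthologRecord(f"o{i}", omega=1.0, go_slims=frozenset({"s"}))
            for i in range(5)
        ]
        expr = pd.Series({f"o{i}": float(i) for i in range(5)})
        _, corr = slim_selection_summary(recs, expression=expr)
        assert corr is None

    def test_planted_cohort_shows_negative_association(self, default_cohort):
        """Generator plants expression inversely related to omega: the
        estimated omega vs expression correlation is negative."""
        data, _ = default_cohort
        records = [r.estimate() for r in data.ortholog_records]
        kept, _ = filter_orthologs(records)
        assert len(kept) >= 30  # three planted slims survive
        summary, corr = slim_selection_summary(kept, expression=data.ortholog_expression)
        assert corr is not None
        assert corr.statistic < 0 and corr.p_value < 0.05
        # planted positive-selection orthologs dominate the omega=2 group
        assert (summary["n_positive"] > 0).any()
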