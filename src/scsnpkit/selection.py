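"""Selection-stress screen: ortholog/GO-slim filtering, a pairwise NG86-style
Ka/Ks estimator with Jukes-Cantor correction, omega-based selection
classification, and the Ka/Ks-expression association.

The estimator counts synonymous and nonsynonymous *sites* by averaging, per
codon position, the fraction of the three possible single-base changes that
are synonymous (changes creating a stop codon count as nonsynonymous), and
counts *substitutions* between codon pairs by equal-weight averaging over
all single-step mutational pathways that avoid stop-codon intermediates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .statistics import TestResult, correlate

log = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
_BASES = "ACGT"
_STOPS = set(_TABLE.stop_codons)


def _aa(codon: str) -> str | None:
    """Amino acid for a codon, None for stop codons."""
    return None if codon in _STOPS else _TABLE.forward_table[codon]


def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3)."""
    aa = _aa(codon)
    s = 0.0
    for i in range(3):
        n_syn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut not in _STOPS and _aa(mut) == aa:
                n_syn += 1
        s += n_syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two codons,
    averaged with equal weight over stop-free mutational pathways."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    any_path: list[tuple[int, int]] = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if cur not in _STOPS and nxt not in _STOPS and _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        any_path.append((sd, nd))
        if not through_stop:
            valid.append((sd, nd))
    paths = valid if valid else any_path
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    omega: float | None  # None when ks == 0 (or a distance is undefined)
    n_codons: int
    syn_sites: float
    nonsyn_sites: float


def ng86_kaks(seq1: str, seq2: str, drop_bad_codons: bool = True) -> KaKsResult:
    """Pairwise Ka/Ks for a codon-aligned sequence pair.

    Codon columns containing gaps, ambiguity characters or stop codons are
    dropped before counting (the default); omega is None when Ks is 0.
    """
    s1, s2 = seq1.upper(), seq2.upper()
    if len(s1) != len(s2):
        raise ValueError("sequences must be aligned to equal length")
    if len(s1) % 3:
        raise ValueError("aligned length must be divisible by 3")
    codons = []
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        bad = (
            any(b not in _BASES for b in c1 + c2)
            or c1 in _STOPS
            or c2 in _STOPS
        )
        if bad:
            if not drop_bad_codons:
                raise ValueError(f"unusable codon column at {i}: {c1}/{c2}")
            continue
        codons.append((c1, c2))
    if not codons:
        raise ValueError("no usable codon columns left")
    S = sum((_syn_sites(c1) + _syn_sites(c2)) / 2.0 for c1, c2 in codons)
    N = 3 * len(codons) - S
    sd = nd = 0.0
    for c1, c2 in codons:
        s, n = _pathway_counts(c1, c2)
        sd += s
        nd += n
    # degenerate alignments (no synonymous or no nonsynonymous sites left)
    # have a zero proportion only when no substitutions of that class exist
    ps = sd / S if S > 0 else (0.0 if sd == 0 else float("nan"))
    pn = nd / N if N > 0 else (0.0 if nd == 0 else float("nan"))
    ks, ka = _jukes_cantor(ps), _jukes_cantor(pn)
    omega: float | None
    if np.isnan(ka) or np.isnan(ks) or ks == 0.0:
        omega = None
    else:
        omega = ka / ks
    return KaKsResult(ka=ka, ks=ks, omega=omega, n_codons=len(codons), syn_sites=S, nonsyn_sites=N)


@dataclass
class OrthologRecord:
    ortholog_id: str
    seq1: str = ""
    seq2: str = ""
    ka: float = float("nan")
    ks: float = float("nan")
    omega: float | None = None
    go_slims: frozenset[str] = field(default_factory=frozenset)
    expression_rate: float = 0.0  # fraction of cells with detected expression
    mutated_fraction: float = 0.0  # fraction of cells with >= 1 SNP

    def estimate(self) -> "OrthologRecord":
        res = ng86_kaks(self.seq1, self.seq2)
        self.ka, self.ks, self.omega = res.ka, res.ks, res.omega
        return self


def filter_orthologs(
    records: list[OrthologRecord],
    min_orthologs_per_slim: int = 10,
    min_expression_rate: float = 0.95,
    min_mutated_fraction: float = 0.05,
) -> tuple[list[OrthologRecord], set[str]]:
    """Two-pass filter: drop orthologs below the expression / mutation rates,
    then drop slim terms with fewer than ``min_orthologs_per_slim`` surviving
    orthologs and orthologs left with no retained slim."""
    stage = [
        r
        for r in records
        if r.expression_rate >= min_expression_rate
        and r.mutated_fraction >= min_mutated_fraction
    ]
    slim_counts: dict[str, int] = {}
    for r in stage:
        for s in r.go_slims:
            slim_counts[s] = slim_counts.get(s, 0) + 1
    kept_slims = {s for s, n in slim_counts.items() if n >= min_orthologs_per_slim}
    kept = []
    for r in stage:
        retained_slims = r.go_slims & kept_slims
        if retained_slims:
            kept.append(
                OrthologRecord(
                    ortholog_id=r.ortholog_id,
                    seq1=r.seq1,
                    seq2=r.seq2,
                    ka=r.ka,
                    ks=r.ks,
                    omega=r.omega,
                    go_slims=frozenset(retained_slims),
                    expression_rate=r.expression_rate,
                    mutated_fraction=r.mutated_fraction,
                )
            )
    return kept, kept_slims


def classify_selection(omega: float | None, tol: float = 1e-9) -> str:
    """omega > 1 positive, < 1 negative (purifying), == 1 neutral."""
    if omega is None or (isinstance(omega, float) and np.isnan(omega)):
        return "undefined"
    if abs(omega - 1.0) <= tol:
        return "neutral"
    return "positive" if omega > 1.0 else "negative"


def slim_selection_summary(
    records: list[OrthologRecord],
    expression: pd.Series | None = None,
    method: str = "spearman",
) -> tuple[pd.DataFrame, TestResult | None]:
    """Per-slim median omega and classification tally, plus the gene-level
    omega vs mean-expression correlation (None with a warning when fewer
    than 3 defined pairs, or when the correlation is degenerate)."""
    rows = []
    slims = sorted({s for r in records for s in r.go_slims})
    for s in slims:
        omegas = [r.omega for r in records if s in r.go_slims and r.omega is not None]
        classes = [classify_selection(r.omega) for r in records if s in r.go_slims]
        rows.append(
            {
                "slim": s,
                "n_orthologs": sum(1 for r in records if s in r.go_slims),
                "median_omega": float(np.median(omegas)) if omegas else float("nan"),
                "n_positive": classes.count("positive"),
                "n_negative": classes.count("negative"),
                "n_neutral": classes.count("neutral"),
                "n_undefined": classes.count("undefined"),
            }
        )
    summary = pd.DataFrame(rows, columns=[
        "slim", "n_orthologs", "median_omega", "n_positive", "n_negative",
        "n_neutral", "n_undefined",
    ]).set_index("slim")

    corr = None
    if expression is not None:
        pairs = [
            (r.omega, float(expression[r.ortholog_id]))
            for r in records
            if r.omega is not None and r.ortholog_id in expression.index
        ]
        if len(pairs) < 3:
            log.warning("fewer than 3 (omega, expression) pairs; correlation skipped")
        else:
            x, y = zip(*pairs)
            try:
                corr = correlate(x, y, method=method)
            except ValueError as exc:
                log.warning("omega-expression correlation undefined: %s", exc)
    return summary, corr
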