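"""Fusion-transcript filter cascade and cohort summaries.

Candidates (a deFuse-style table, one row per fusion per cell) pass four
drop rules, in order, per cell:

1. either partner is a ribosomal gene;
2. either partner's breakpoint is intronic or intraexonic;
3. either partner gene appears with multiple distinct partners in the same
   cell (evaluated on the survivors of rules 1-2);
4. both partners on one chromosome with breakpoints < 100 kbp apart
   (likely read-through rather than rearrangement).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .records import FusionRecord, Location
from .statistics import format_percent

READTHROUGH_DISTANCE = 100_000
_DROP_LOCATIONS = {Location.INTRONIC, Location.INTRAEXONIC}

RULES = ("ribosomal_partner", "intron_or_intraexonic", "multiple_partners", "close_breakpoints")


@dataclass
class FusionFilterReport:
    """Per-cell cascade accounting; drops + retained always equal the input."""

    cell_id: str
    n_input: int
    drops: dict[str, int] = field(default_factory=dict)
    retained: list[FusionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.drops.values()) + len(self.retained)
        if self.drops and total != self.n_input:
            raise ValueError("fusion report does not conserve records")


def filter_fusion_cascade(
    records: list[FusionRecord], ribosomal_genes: set[str]
) -> dict[str, FusionFilterReport]:
    """Apply the four-rule cascade per cell; returns reports keyed by cell."""
    if not ribosomal_genes:
        raise ValueError("ribosomal gene set must be non-empty")
    by_cell: dict[str, list[FusionRecord]] = {}
    for r in records:
        if not isinstance(r.location5, Location) or not isinstance(r.location3, Location):
            raise ValueError(f"unknown location class on record {r.gene5}-{r.gene3}")
        by_cell.setdefault(r.cell_id, []).append(r)

    reports: dict[str, FusionFilterReport] = {}
    for cell, recs in by_cell.items():
        drops = {rule: 0 for rule in RULES}
        stage = []
        for r in recs:
            if r.gene5 in ribosomal_genes or r.gene3 in ribosomal_genes:
                drops["ribosomal_partner"] += 1
            elif r.location5 in _DROP_LOCATIONS or r.location3 in _DROP_LOCATIONS:
                drops["intron_or_intraexonic"] += 1
            else:
                stage.append(r)
        # rule 3 on the survivors of rules 1-2: a gene with >1 distinct partner
        partners: dict[str, set[str]] = {}
        for r in stage:
            partners.setdefault(r.gene5, set()).add(r.gene3)
            partners.setdefault(r.gene3, set()).add(r.gene5)
        promiscuous = {g for g, ps in partners.items() if len(ps) > 1}
        retained = []
        for r in stage:
            if r.gene5 in promiscuous or r.gene3 in promiscuous:
                drops["multiple_partners"] += 1
            elif (
                r.chrom5 == r.chrom3
                and abs(r.breakpoint5 - r.breakpoint3) < READTHROUGH_DISTANCE
            ):
                drops["close_breakpoints"] += 1
            else:
                retained.append(r)
        reports[cell] = FusionFilterReport(
            cell_id=cell, n_input=len(recs), drops=drops, retained=retained
        )
    return reports


def summarize_fusions(
    reports_by_class: dict[str, dict[str, FusionFilterReport]]
) -> pd.DataFrame:
    """Per sample class: mean raw count, mean retained count and their ratio."""
    rows = []
    for cls, reports in reports_by_class.items():
        if not reports:
            raise ValueError(f"no fusion reports for sample class {cls}")
        raw = [r.n_input for r in reports.values()]
        kept = [len(r.retained) for r in reports.values()]
        mean_raw = sum(raw) / len(raw)
        mean_kept = sum(kept) / len(kept)
        rows.append(
            {
                "sample_class": cls,
                "n_samples": len(reports),
                "mean_raw": mean_raw,
                "mean_retained": mean_kept,
                "retained_ratio": mean_kept / mean_raw if mean_raw else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("sample_class")


def recurrent_fusions(retained: list[FusionRecord], n_samples: int) -> pd.DataFrame:
    """Carrier-cell counts per unordered partner pair (a pair counts once per
    cell regardless of duplicate rows), with half-up 2-decimal percentages."""
    carrier: Counter = Counter()
    seen: set[tuple[frozenset, str]] = set()
    for r in retained:
        key = (r.pair, r.cell_id)
        if key not in seen:
            seen.add(key)
            carrier[r.pair] += 1
    rows = [
        {
            "pair": "-".join(sorted(pair)),
            "n_cells": n,
            "percent": float(format_percent(n / n_samples)),
        }
        for pair, n in carrier.items()
    ]
    return (
        pd.DataFrame(rows, columns=["pair", "n_cells", "percent"])
        .sort_values(["n_cells", "pair"], ascending=[False, True])
        .reset_index(drop=True)
    )
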