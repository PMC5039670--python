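"""Sample-level QC and the four-rule SNP filter cascade.

The cascade order is fixed: (1) sample QC on sequencing depth/coverage,
(2) keep nonsynonymous variants, (3) keep variants supported by at least
``min_depth`` reads in the cell, (4) keep variant sites covered (depth >= 1)
in more than ``coverage_fraction`` of the retained cells. Reports telescope:
the output count of each rule is the input count of the next.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .records import CohortManifest, Effect, SnpRecord

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-rule accounting of the cascade."""

    rule_names: list[str] = field(default_factory=list)
    input_counts: list[int] = field(default_factory=list)
    output_counts: list[int] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)  # (cell_id, reason)

    def add(self, rule: str, n_in: int, n_out: int) -> None:
        if self.output_counts and self.output_counts[-1] != n_in:
            raise ValueError(
                f"rule counts do not telescope: {self.output_counts[-1]} != {n_in}"
            )
        self.rule_names.append(rule)
        self.input_counts.append(n_in)
        self.output_counts.append(n_out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": self.rule_names,
                "records_in": self.input_counts,
                "records_out": self.output_counts,
                "records_dropped": [
                    i - o for i, o in zip(self.input_counts, self.output_counts)
                ],
            }
        )


def qc_samples(
    manifest: CohortManifest,
    qc_summary: pd.DataFrame,
    min_covered_sites: int = 100_000,
    min_mean_depth: float = 5.0,
) -> tuple[CohortManifest, list[tuple[str, str]]]:
    """Remove low-quality cells from the manifest.

    ``qc_summary`` must be indexed by (or contain a column) ``cell_id`` with
    columns ``covered_sites`` and ``mean_depth``. Cells below either cutoff
    are removed. The retained-cell count is the AS denominator of all
    downstream sample ratios.
    """
    qc = qc_summary.set_index("cell_id") if "cell_id" in qc_summary.columns else qc_summary
    removed: list[tuple[str, str]] = []
    kept = []
    for entry in manifest:
        if entry.cell_id not in qc.index:
            raise KeyError(f"cell {entry.cell_id} missing from QC summary")
        row = qc.loc[entry.cell_id]
        if row["covered_sites"] < min_covered_sites:
            removed.append((entry.cell_id, f"covered_sites {row['covered_sites']:.0f} < {min_covered_sites}"))
        elif row["mean_depth"] < min_mean_depth:
            removed.append((entry.cell_id, f"mean_depth {row['mean_depth']:.2f} < {min_mean_depth}"))
        else:
            kept.append(entry)
    if not kept:
        raise ValueError("sample QC removed every cell; thresholds too strict for this cohort")
    log.info("sample QC: retained %d of %d cells", len(kept), len(manifest))
    return CohortManifest(kept), removed


def filter_nonsynonymous(
    records: list[SnpRecord], keep_unknown: bool = False
) -> list[SnpRecord]:
    """Keep nonsynonymous variants; ``unknown`` effects are dropped by default."""
    allowed = {Effect.NONSYNONYMOUS}
    if keep_unknown:
        allowed.add(Effect.UNKNOWN)
    n_unknown = sum(1 for r in records if r.effect is Effect.UNKNOWN)
    if n_unknown and not keep_unknown:
        log.debug("dropping %d records with unknown effect class", n_unknown)
    return [r for r in records if r.effect in allowed]


def filter_min_depth(records: list[SnpRecord], min_depth: int = 5) -> list[SnpRecord]:
    """Keep variants covered by at least ``min_depth`` reads in their cell."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return [r for r in records if r.depth >= min_depth]


def filter_site_coverage(
    records: list[SnpRecord],
    site_coverage: dict[tuple[str, int], int],
    n_retained: int,
    fraction: float = 0.95,
) -> list[SnpRecord]:
    """Keep variant sites covered in strictly more than ``fraction`` of cells.

    ``site_coverage`` maps (chrom, pos) to the number of retained cells with
    at least one read at that position; coverage here is independent of
    whether the cell carries the variant. Records at dropped sites are
    removed from every cell.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if n_retained < 1:
        raise ValueError("n_retained must be >= 1")
    kept = []
    for r in records:
        if r.site not in site_coverage:
            raise KeyError(f"site {r.chrom}:{r.pos} absent from coverage table")
        if site_coverage[r.site] / n_retained > fraction:
            kept.append(r)
    return kept


def apply_snp_cascade(
    records: list[SnpRecord],
    site_coverage: dict[tuple[str, int], int],
    n_retained: int,
    min_depth: int = 5,
    coverage_fraction: float = 0.95,
    keep_unknown: bool = False,
    report: FilterReport | None = None,
) -> tuple[list[SnpRecord], FilterReport]:
    """Run rules 2-4 of the cascade (sample QC is applied beforehand on the
    manifest) and return the surviving records plus a telescoping report."""
    rep = report if report is not None else FilterReport()
    n0 = len(records)
    records = filter_nonsynonymous(records, keep_unknown=keep_unknown)
    rep.add("nonsynonymous", n0, len(records))
    n1 = len(records)
    records = filter_min_depth(records, min_depth=min_depth)
    rep.add(f"min_depth>={min_depth}", n1, len(records))
    n2 = len(records)
    records = filter_site_coverage(
        records, site_coverage, n_retained, fraction=coverage_fraction
    )
    rep.add(f"site_coverage>{coverage_fraction:g}", n2, len(records))
    return records, rep
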