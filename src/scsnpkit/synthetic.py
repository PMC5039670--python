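"""Synthetic cohort generator with planted, recorded ground truth.

Emulates a 96-single-cell RNA-seq SNP cohort (plus 4 bulk cancer and 1 bulk
normal sample): per-cell VCFs with a planted chromosome-level enrichment,
exact planted per-gene mutated-sample counts, cancer genes with a planted
SNP-frequency excess, an expression matrix with negative-binomial
mean-dispersion structure, fusion candidate tables containing cases for
every filter rule, and codon-aligned ortholog pairs with known omega.

All randomness flows from one master seed through named SeedSequence
spawn keys, so a cohort is byte-identical given its seed. Planted SNPs are
written clean (nonsynonymous, depth >= 5, fully covered site) so they
survive the filter cascade and the planted mutated-sample counts are
recovered exactly; background SNPs carry realistic attribute noise that the
cascade removes at known rates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import CHROMOSOMES, Caller, Effect, FusionRecord, Location, SnpRecord
from .selection import _STOPS, _TABLE, _jukes_cantor, _syn_sites, OrthologRecord

log = logging.getLogger(__name__)

#: hg19 chromosome lengths (bases)
CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}

#: default planted per-gene mutated-sample counts (of the retained cells)
PLANTED_COUNTS: dict[str, int] = {
    "RPA1": 50, "CYCS": 81, "YWHAE": 82, "PERP": 57, "MSH3": 4, "RPA3": 80,
    "YWHAQ": 70, "YWHAB": 82, "YWHAZ": 80, "CSNK2B": 81, "RBX1": 80,
    "BMP7": 35, "SMURF2": 13, "ID2": 80, "ATR": 13, "CCNB1": 21, "CDK4": 13,
    "ATM": 8, "HSP90AB1": 79, "GNB4": 27,
}
#: SNPs written per carrier cell for planted genes (default 1)
PLANTED_SNPS_PER_CELL: dict[str, int] = {"BMP7": 4, "RPA1": 3, "ATR": 3, "HSP90AB1": 2}

_SLIM_NAMES = {
    "BP": ["signal.transduction", "transport", "biosynthetic.process",
           "response.to.stress", "immune.system.process", "homeostatic.process",
           "cell.cycle", "small.molecule.metabolic.process"],
    "CC": ["cytosol", "nucleoplasm", "nucleolus", "organelle",
           "plasma.membrane", "protein.complex", "cytoplasm", "nucleus"],
    "MF": ["RNA.binding", "DNA.binding", "ion.binding", "enzyme.binding",
           "oxidoreductase.activity", "structural.constituent.of.ribosome",
           "kinase.activity", "transporter.activity"],
}

_BASES = "ACGT"
_CODONS = [c for c in (a + b + d for a in _BASES for b in _BASES for d in _BASES) if c not in _STOPS]


@dataclass
class SyntheticConfig:
    """Study conditions of the default synthetic cohort."""

    seed: int = 0
    n_cells: int = 96
    n_low_quality: int = 13
    n_bulk_cancer: int = 4
    n_bulk_normal: int = 1
    n_genes: int = 500
    snp_rate_per_mb: float = 1.0  # raw SNPs per megabase per cell
    p_gene_mutated: float = 0.35  # fraction of genes carrying clonal SNPs
    chrom_enrichment: dict[str, float] = field(
        default_factory=lambda: {"chr11": 3.0, "chr17": 3.0}
    )
    cancer_multiplier: float = 5.0
    n_enriched_cancer: int = 10
    n_cancer_genes: int = 175
    planted_counts: dict[str, int] = field(default_factory=lambda: dict(PLANTED_COUNTS))
    planted_snps_per_cell: dict[str, int] = field(
        default_factory=lambda: dict(PLANTED_SNPS_PER_CELL)
    )
    p_nonsynonymous: float = 0.75
    p_synonymous: float = 0.20  # remainder written as "other" -> unknown
    p_low_depth: float = 0.08
    p_low_coverage_site: float = 0.05
    bulk_cancer_rate_factor: float = 3.0
    bulk_normal_rate_factor: float = 0.5
    low_quality_rate_factor: float = 0.05
    expression_log_mean: float = 1.6
    expression_log_sd: float = 1.2
    expression_dispersion: float = 0.3  # var = mu + phi * mu^2
    fusion_noise_mean: float = 3.0
    bulk_fusion_noise_mean: float = 15.0
    ortholog_codons: int = 300
    ortholog_targets: tuple = (0.2, 1.0, 2.0)
    orthologs_per_slim: int = 12

    def __post_init__(self) -> None:
        if self.n_low_quality >= self.n_cells:
            raise ValueError("n_low_quality must be < n_cells")
        for g, m in self.planted_counts.items():
            if m > self.n_cells - self.n_low_quality:
                raise ValueError(
                    f"planted count {m} for {g} exceeds the retained cell count"
                )
        if self.ortholog_codons % 1:
            raise ValueError("ortholog_codons must be an integer")

    @property
    def n_retained(self) -> int:
        return self.n_cells - self.n_low_quality

    @classmethod
    def scaled(cls, n_cells: int, n_genes: int = 500, seed: int = 0, **kwargs) -> "SyntheticConfig":
        """Default study conditions rescaled to a smaller cohort: the
        low-quality fraction (13/96) and planted mutated-sample counts keep
        their proportions of the retained-cell count."""
        n_low = max(1, round(13 * n_cells / 96)) if n_cells < 96 else 13
        retained = n_cells - n_low
        counts = {
            g: max(1, round(m * retained / 83)) for g, m in PLANTED_COUNTS.items()
        }
        kwargs.setdefault("n_cancer_genes", min(175, max(len(counts) + 5, n_genes // 2)))
        kwargs.setdefault("n_enriched_cancer", min(10, kwargs["n_cancer_genes"] // 6))
        return cls(
            seed=seed, n_cells=n_cells, n_low_quality=n_low, n_genes=n_genes,
            planted_counts=counts, **kwargs,
        )


@dataclass
class CohortTruth:
    seed: int
    n_cells: int
    retained_cells: list[str]
    low_quality_cells: list[str]
    planted_counts: dict[str, int]
    chrom_enrichment: dict[str, float]
    cancer_multiplier: float
    enriched_cancer_genes: list[str]
    cancer_genes: list[str]
    fusion_truth: pd.DataFrame  # cell_id, gene5, gene3, should_survive
    ortholog_targets: dict[str, float]

    def to_yaml(self) -> str:
        payload = {
            "seed": self.seed,
            "n_cells": self.n_cells,
            "retained_cells": self.retained_cells,
            "low_quality_cells": self.low_quality_cells,
            "planted_counts": self.planted_counts,
            "chrom_enrichment": self.chrom_enrichment,
            "cancer_multiplier": self.cancer_multiplier,
            "enriched_cancer_genes": self.enriched_cancer_genes,
            "ortholog_targets": self.ortholog_targets,
        }
        return yaml.safe_dump(payload, sort_keys=True)


@dataclass
class CohortData:
    """In-memory cohort: everything generate_cohort writes to disk."""

    config: SyntheticConfig
    truth: CohortTruth
    cell_ids: list[str]
    bulk_ids: list[str]
    records: list[SnpRecord]
    site_coverage: dict[tuple[str, int], int]
    qc_summary: pd.DataFrame
    genes: pd.DataFrame  # indexed by gene_id
    expression: pd.DataFrame  # genes x samples
    fusion_records: list[FusionRecord]
    ortholog_records: list[OrthologRecord]
    ortholog_expression: pd.Series
    pathways: dict[str, list[str]]
    ribosomal_genes: list[str]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------- gene models


def _make_genes(cfg: SyntheticConfig) -> pd.DataFrame:
    rng = _rng(cfg.seed, 0)
    planted = sorted(cfg.planted_counts)
    n_cg = cfg.n_cancer_genes - len(planted)
    cg = [f"CG{i:03d}" for i in range(1, n_cg + 1)]
    n_bg = cfg.n_genes - len(planted) - n_cg
    if n_bg < 1:
        raise ValueError("n_genes too small for the planted + cancer gene lists")
    bg = [f"G{i:04d}" for i in range(1, n_bg + 1)]
    symbols = planted + cg + bg

    total_len = sum(CHROM_LENGTHS.values())
    # genes assigned to chromosomes proportional to length -> uniform genic
    # density; every chromosome gets at least two genes so per-chromosome
    # profiles are defined on the whole declared set
    probs = np.array([CHROM_LENGTHS[c] for c in CHROMOSOMES], dtype=float) / total_len
    if len(symbols) < 2 * len(CHROMOSOMES):
        raise ValueError(f"n_genes must be >= {2 * len(CHROMOSOMES)}")
    chrom_idx = np.concatenate(
        [
            np.repeat(np.arange(len(CHROMOSOMES)), 2),
            rng.choice(len(CHROMOSOMES), size=len(symbols) - 2 * len(CHROMOSOMES), p=probs),
        ]
    )
    chrom_idx = rng.permutation(chrom_idx)
    lengths = np.round(np.exp(rng.normal(np.log(30_000), 0.4, size=len(symbols)))).astype(int)
    lengths = np.clip(lengths, 2_000, None)
    rows = []
    for sym, ci, gl in zip(symbols, chrom_idx, lengths):
        chrom = CHROMOSOMES[int(ci)]
        start = int(rng.integers(1, CHROM_LENGTHS[chrom] - int(gl)))
        rows.append(
            {"gene_id": sym, "symbol": sym, "chrom": chrom, "start": start,
             "end": start + int(gl) - 1, "gene_length_bases": int(gl)}
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    df.attrs["cancer_genes"] = planted + cg
    return df


# ------------------------------------------------------------------ SNP layer


def _per_gene_rates(
    cfg: SyntheticConfig, genes: pd.DataFrame, enriched: set[str], mutated: np.ndarray
) -> np.ndarray:
    """Raw expected SNP count per gene per cell.

    SNPs are clonal: only cohort-mutated genes carry them. The chromosome
    quota (rate_per_mb x length x enrichment) is split among the
    chromosome's mutated genes proportional to gene length, so per-Mb
    chromosome density is flat whenever every enrichment factor is 1,
    independent of which genes happen to be mutated."""
    lam = np.zeros(len(genes))
    gl = genes["gene_length_bases"].to_numpy(dtype=float)
    for chrom in CHROMOSOMES:
        mask = (genes["chrom"] == chrom).to_numpy() & mutated
        if not mask.any():
            continue
        factor = cfg.chrom_enrichment.get(chrom, 1.0)
        quota = cfg.snp_rate_per_mb * CHROM_LENGTHS[chrom] / 1e6 * factor
        lam[mask] = quota * gl[mask] / gl[mask].sum()
    enriched_mask = genes.index.isin(enriched)
    lam[enriched_mask] *= cfg.cancer_multiplier
    return lam


def simulate_cohort(cfg: SyntheticConfig) -> CohortData:
    """Draw the full cohort in memory (no disk I/O)."""
    genes = _make_genes(cfg)
    cancer_genes: list[str] = genes.attrs["cancer_genes"]
    planted = sorted(cfg.planted_counts)

    rng_struct = _rng(cfg.seed, 8)
    cg_pool = [g for g in cancer_genes if g not in planted]
    enriched = sorted(
        str(g)
        for g in rng_struct.choice(
            cg_pool, size=min(cfg.n_enriched_cancer, len(cg_pool)), replace=False
        )
    )

    cell_ids = [f"sc{i:03d}" for i in range(1, cfg.n_cells + 1)]
    low_quality = sorted(
        str(c) for c in rng_struct.choice(cell_ids, size=cfg.n_low_quality, replace=False)
    )
    retained = [c for c in cell_ids if c not in set(low_quality)]
    bulk_ids = [f"bulkC{i}" for i in range(1, cfg.n_bulk_cancer + 1)] + [
        f"bulkN{i}" for i in range(1, cfg.n_bulk_normal + 1)
    ]

    # clonal mutation status per gene: enriched cancer genes always mutated,
    # planted genes handled by exact membership, at least one mutated gene
    # per chromosome so every chromosome profile is populated
    rng_mut = _rng(cfg.seed, 11)
    mutated = rng_mut.random(len(genes)) < cfg.p_gene_mutated
    mutated |= genes.index.isin(enriched)
    is_planted = genes.index.isin(planted)
    mutated &= ~is_planted
    for chrom in CHROMOSOMES:
        cmask = (genes["chrom"] == chrom).to_numpy() & ~is_planted
        if cmask.any() and not (mutated & cmask).any():
            mutated[int(rng_mut.choice(np.flatnonzero(cmask)))] = True

    lam = _per_gene_rates(cfg, genes, set(enriched), mutated)
    planted_idx = genes.index.get_indexer(planted)
    lam[planted_idx] = 0.0  # planted genes get exact membership, no background

    gene_ids = genes.index.to_numpy()
    chroms = genes["chrom"].to_numpy()
    starts = genes["start"].to_numpy()
    gl = genes["gene_length_bases"].to_numpy()

    # planted membership: exactly m retained cells per planted gene
    membership: dict[str, set[str]] = {}
    for j, g in enumerate(planted):
        rngm = _rng(cfg.seed, 7, j)
        membership[g] = set(rngm.choice(retained, size=cfg.planted_counts[g], replace=False))

    records: list[SnpRecord] = []
    clean_sites: set[tuple[str, int]] = set()
    background_sites: set[tuple[str, int]] = set()

    def cell_rate_factor(sample: str) -> float:
        if sample in set(low_quality):
            return cfg.low_quality_rate_factor
        if sample.startswith("bulkC"):
            return cfg.bulk_cancer_rate_factor
        if sample.startswith("bulkN"):
            return cfg.bulk_normal_rate_factor
        return 1.0

    all_samples = cell_ids + bulk_ids
    for si, sample in enumerate(all_samples):
        rng = _rng(cfg.seed, 1, si)
        counts = rng.poisson(lam * cell_rate_factor(sample))
        for gi in np.flatnonzero(counts):
            k = int(counts[gi])
            span = int(gl[gi])
            pos = starts[gi] + rng.choice(span, size=min(k, span), replace=False)
            for p in np.sort(pos):
                ref, alt = rng.choice(4, size=2, replace=False)
                u = rng.random()
                if u < cfg.p_nonsynonymous:
                    eff = Effect.NONSYNONYMOUS
                elif u < cfg.p_nonsynonymous + cfg.p_synonymous:
                    eff = Effect.SYNONYMOUS
                else:
                    eff = Effect.UNKNOWN
                depth = (
                    int(rng.integers(0, 5))
                    if rng.random() < cfg.p_low_depth
                    else 5 + int(rng.poisson(15))
                )
                site = (chroms[gi], int(p))
                background_sites.add(site)
                records.append(
                    SnpRecord(
                        cell_id=sample, chrom=chroms[gi], pos=int(p),
                        ref=_BASES[ref], alt=_BASES[alt], depth=depth,
                        gene_id=str(gene_ids[gi]), effect=eff, caller=Caller.GATK,
                    )
                )
        # planted genes: exact membership, clean attributes, shared grid sites
        for g in planted:
            if sample not in membership[g]:
                continue
            row = genes.loc[g]
            n_snps = cfg.planted_snps_per_cell.get(g, 1)
            for j in range(n_snps):
                p = int(row["start"]) + 13 + 17 * j
                site = (row["chrom"], p)
                clean_sites.add(site)
                records.append(
                    SnpRecord(
                        cell_id=sample, chrom=row["chrom"], pos=p,
                        ref="A", alt="G", depth=5 + int(rng.poisson(15)),
                        gene_id=g, effect=Effect.NONSYNONYMOUS, caller=Caller.GATK,
                    )
                )

    # per-site coverage across retained cells (clean sites fully covered)
    rng_cov = _rng(cfg.seed, 2)
    n_ret = len(retained)
    pass_lo = int(np.floor(0.96 * n_ret))
    fail_hi = max(1, int(np.floor(0.94 * n_ret)))
    site_coverage: dict[tuple[str, int], int] = {}
    for site in sorted(background_sites - clean_sites):
        if rng_cov.random() < cfg.p_low_coverage_site:
            site_coverage[site] = int(rng_cov.integers(n_ret // 2, fail_hi + 1))
        else:
            site_coverage[site] = int(rng_cov.integers(pass_lo, n_ret + 1))
    for site in sorted(clean_sites):
        site_coverage[site] = n_ret

    # QC summaries: low-quality cells fall below both default cutoffs
    rng_qc = _rng(cfg.seed, 3)
    qc_rows = []
    for sample in all_samples:
        if sample in set(low_quality):
            covered = int(rng_qc.integers(5_000, 50_000))
            depth = float(rng_qc.uniform(0.2, 2.0))
        else:
            covered = int(rng_qc.integers(800_000, 1_200_000))
            depth = float(rng_qc.uniform(8.0, 25.0))
        qc_rows.append({"cell_id": sample, "covered_sites": covered,
                        "mean_depth": round(depth, 3)})
    qc_summary = pd.DataFrame(qc_rows)

    # expression: NB counts with var = mu + phi mu^2 (Fano = 1 + phi mu > 1)
    rng_ex = _rng(cfg.seed, 4)
    mu = np.exp(rng_ex.normal(cfg.expression_log_mean, cfg.expression_log_sd, size=len(genes)))
    phi = cfg.expression_dispersion
    n_param = 1.0 / phi
    p_param = n_param / (n_param + mu)
    expr = rng_ex.negative_binomial(
        n_param, p_param[:, None], size=(len(genes), len(all_samples))
    )
    expression = pd.DataFrame(expr, index=genes.index, columns=all_samples)

    pathways = _make_pathways(cfg, genes)
    ribosomal = [f"RPL{i}" for i in range(1, 21)] + [f"RPS{i}" for i in range(1, 16)] + [
        f"MRPL{i}" for i in range(1, 6)
    ]
    fusion_records, fusion_truth = plant_fusion_events(cfg, cell_ids, bulk_ids, ribosomal)
    ortho_records, ortho_expr, ortho_targets = plant_ortholog_alignments(cfg)

    truth = CohortTruth(
        seed=cfg.seed,
        n_cells=cfg.n_cells,
        retained_cells=retained,
        low_quality_cells=low_quality,
        planted_counts=dict(cfg.planted_counts),
        chrom_enrichment=dict(cfg.chrom_enrichment),
        cancer_multiplier=cfg.cancer_multiplier,
        enriched_cancer_genes=list(enriched),
        cancer_genes=list(cancer_genes),
        fusion_truth=fusion_truth,
        ortholog_targets=ortho_targets,
    )
    return CohortData(
        config=cfg, truth=truth, cell_ids=cell_ids, bulk_ids=bulk_ids,
        records=records, site_coverage=site_coverage, qc_summary=qc_summary,
        genes=genes, expression=expression, fusion_records=fusion_records,
        ortholog_records=ortho_records, ortholog_expression=ortho_expr,
        pathways=pathways, ribosomal_genes=ribosomal,
    )


def _make_pathways(cfg: SyntheticConfig, genes: pd.DataFrame) -> dict[str, list[str]]:
    rng = _rng(cfg.seed, 5)
    fillers = [g for g in genes.index if g.startswith("G")]
    cores = {
        "p53_signaling": ["PERP", "CYCS", "ATR", "CCNB1", "CDK4", "ATM"],
        "tgf_beta_signaling": ["BMP7", "SMURF2", "ID2", "RBX1"],
        "mismatch_repair": ["RPA1", "MSH3", "RPA3"],
        "pi3k_akt_signaling": ["YWHAQ", "YWHAE", "YWHAB", "YWHAZ", "HSP90AB1", "GNB4"],
        "wnt_signaling": ["CSNK2B", "RBX1"],
    }
    out = {}
    for name, core in cores.items():
        core = [g for g in core if g in genes.index]
        extra = sorted(rng.choice(fillers, size=10, replace=False))
        out[name] = core + [g for g in extra if g not in core]
    return out


# -------------------------------------------------------------------- fusions


def plant_fusion_events(
    cfg: SyntheticConfig, cell_ids: list[str], bulk_ids: list[str], ribosomal: list[str]
) -> tuple[list[FusionRecord], pd.DataFrame]:
    """Emit fusion candidates whose survival under the filter cascade is
    known by construction: recurrent surviving pairs, plus noise records
    each deliberately triggering one drop rule (or none)."""
    rng = _rng(cfg.seed, 6)
    records: list[FusionRecord] = []
    truth_rows: list[dict] = []
    counter = 0

    def add(cell, g5, g3, c5, c3, b5, b3, l5, l3, survive):
        records.append(
            FusionRecord(
                cell_id=cell, gene5=g5, gene3=g3, chrom5=c5, chrom3=c3,
                breakpoint5=int(b5), breakpoint3=int(b3),
                location5=l5, location3=l3,
                supporting_reads=int(rng.integers(2, 60)),
            )
        )
        truth_rows.append(
            {"cell_id": cell, "gene5": g5, "gene3": g3, "should_survive": bool(survive)}
        )

    recurrent = [
        ("EML4", "ALK", "chr2", "chr2", 42_396_490, 29_446_394, 11),
        ("VTI1A", "TCF7L2", "chr10", "chr10", 114_206_756, 114_710_009, 33),
        ("PTPRK", "RSPO3", "chr6", "chr6", 128_290_003, 127_439_749, 5),
        ("UBB", "UBC", "chr17", "chr12", 16_285_933, 125_396_194, 5),
    ]
    for g5, g3, c5, c3, b5, b3, n_carriers in recurrent:
        carriers = rng.choice(cell_ids, size=min(n_carriers, len(cell_ids)), replace=False)
        survive = not (c5 == c3 and abs(b5 - b3) < 100_000)
        for cell in sorted(carriers):
            add(cell, g5, g3, c5, c3, b5, b3, Location.EXONIC, Location.EXONIC, survive)

    def noise_record(cell: str, kind: int) -> None:
        nonlocal counter
        counter += 1
        ga, gb = f"FUS{counter:04d}A", f"FUS{counter:04d}B"
        ca, cb = rng.choice(CHROMOSOMES, size=2, replace=False)
        ba = rng.integers(1_000_000, 40_000_000)
        bb = rng.integers(1_000_000, 40_000_000)
        if kind == 0:  # ribosomal partner
            add(cell, str(rng.choice(ribosomal)), gb, ca, cb, ba, bb,
                Location.EXONIC, Location.EXONIC, False)
        elif kind == 1:  # intronic / intraexonic partner
            loc = Location.INTRONIC if rng.random() < 0.5 else Location.INTRAEXONIC
            add(cell, ga, gb, ca, cb, ba, bb, Location.EXONIC, loc, False)
        elif kind == 2:  # same-chromosome close breakpoints
            dist = int(rng.integers(5_000, 95_000))
            add(cell, ga, gb, ca, ca, ba, ba + dist, Location.EXONIC, Location.EXONIC, False)
        elif kind == 3:  # multi-partner: one 5' gene, two distinct 3' partners
            counter += 1
            gc = f"FUS{counter:04d}C"
            add(cell, ga, gb, ca, cb, ba, bb, Location.EXONIC, Location.EXONIC, False)
            add(cell, ga, gc, ca, cb, ba + 500, bb + 500, Location.EXONIC, Location.EXONIC, False)
        else:  # clean inter-chromosomal candidate, unique partners
            add(cell, ga, gb, ca, cb, ba, bb, Location.EXONIC, Location.EXONIC, True)

    kinds = np.array([0, 1, 2, 3, 4])
    sc_probs = np.array([0.25, 0.25, 0.15, 0.10, 0.25])
    bulk_probs = np.array([0.35, 0.30, 0.20, 0.10, 0.05])
    for cell in cell_ids:
        for _ in range(int(rng.poisson(cfg.fusion_noise_mean))):
            noise_record(cell, int(rng.choice(kinds, p=sc_probs)))
    for cell in bulk_ids:
        for _ in range(int(rng.poisson(cfg.bulk_fusion_noise_mean))):
            noise_record(cell, int(rng.choice(kinds, p=bulk_probs)))

    return records, pd.DataFrame(truth_rows)


# ------------------------------------------------------------------ orthologs


def _codon_variants(codon: str, synonymous: bool) -> list[str]:
    aa = _TABLE.forward_table[codon]
    out = []
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut in _STOPS:
                continue
            if (aa == _TABLE.forward_table[mut]) == synonymous:
                out.append(mut)
    return out


def plant_codon_pair(
    rng: np.random.Generator, n_codons: int, target_omega: float | None,
    syn_fraction: float = 0.08,
) -> tuple[str, str]:
    """Codon-aligned pair with substitution counts chosen so the NG86
    estimate of omega is close to ``target_omega`` (None -> identical pair).

    One substitution per codon at most, so pathway averaging is exact.
    """
    if n_codons % 1:
        raise ValueError("codon count must be integral")
    codons = [str(rng.choice(_CODONS)) for _ in range(n_codons)]
    seq1 = "".join(codons)
    if target_omega is None:
        return seq1, seq1
    S = sum(_syn_sites(c) for c in codons)
    N = 3 * n_codons - S
    n_syn = max(1, round(syn_fraction * S))
    ds = _jukes_cantor(n_syn / S)
    pn = 0.75 * (1.0 - np.exp(-4.0 * target_omega * ds / 3.0))
    n_nonsyn = round(pn * N)
    syn_ok = [i for i, c in enumerate(codons) if _codon_variants(c, True)]
    non_ok = [i for i, c in enumerate(codons) if _codon_variants(c, False)]
    syn_pick = rng.choice(syn_ok, size=n_syn, replace=False)
    remaining = [i for i in non_ok if i not in set(syn_pick)]
    non_pick = rng.choice(remaining, size=n_nonsyn, replace=False)
    mutated = list(codons)
    for i in syn_pick:
        mutated[int(i)] = str(rng.choice(_codon_variants(codons[int(i)], True)))
    for i in non_pick:
        mutated[int(i)] = str(rng.choice(_codon_variants(codons[int(i)], False)))
    return seq1, "".join(mutated)


def plant_ortholog_alignments(
    cfg: SyntheticConfig,
) -> tuple[list[OrthologRecord], pd.Series, dict[str, float]]:
    """Ortholog pairs with planted omega, slim links and filter metadata.

    Three well-populated slims carry ``orthologs_per_slim`` orthologs each
    with target omegas cycling through ``ortholog_targets``; one small slim
    (< 10 orthologs) and a handful of low-expression / low-mutation
    orthologs are planted to exercise the filters. Mean expression is drawn
    inversely related to omega so the omega-expression association is
    negative by construction.
    """
    if cfg.ortholog_codons < 30:
        raise ValueError("need >= 30 codons per pair")
    rng = _rng(cfg.seed, 9)
    slims = ["signal.transduction", "response.to.stress", "transport"]
    records: list[OrthologRecord] = []
    expr: dict[str, float] = {}
    targets: dict[str, float] = {}
    idx = 0

    def make(slim_set, omega, expr_rate, mut_frac):
        nonlocal idx
        idx += 1
        oid = f"ORTH{idx:03d}"
        s1, s2 = plant_codon_pair(rng, cfg.ortholog_codons, omega)
        rec = OrthologRecord(
            ortholog_id=oid, seq1=s1, seq2=s2, go_slims=frozenset(slim_set),
            expression_rate=expr_rate, mutated_fraction=mut_frac,
        )
        records.append(rec)
        targets[oid] = float(omega) if omega is not None else float("nan")
        base = 60.0 / (0.5 + (omega if omega is not None else 1.0))
        expr[oid] = float(base * np.exp(rng.normal(0.0, 0.25)))

    for slim in slims:
        for j in range(cfg.orthologs_per_slim):
            omega = cfg.ortholog_targets[j % len(cfg.ortholog_targets)]
            make({slim}, omega, float(rng.uniform(0.96, 1.0)), float(rng.uniform(0.10, 0.60)))
    for _ in range(5):  # slim below the 10-ortholog floor
        make({"small.slim.term"}, 1.0, float(rng.uniform(0.96, 1.0)), 0.3)
    for _ in range(4):  # fails the expression-rate filter
        make({slims[0]}, 0.2, float(rng.uniform(0.5, 0.94)), 0.3)
    for _ in range(3):  # fails the mutated-fraction filter
        make({slims[1]}, 2.0, 1.0, float(rng.uniform(0.0, 0.04)))
    return records, pd.Series(expr, name="mean_expression"), targets


# ------------------------------------------------------------------- writers


def _write_vcf(path: Path, records: list[SnpRecord]) -> None:
    order = {c: i for i, c in enumerate(CHROMOSOMES)}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">',
        '##INFO=<ID=EFFCLASS,Number=1,Type=String,Description="Coding effect class">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Overlapping gene symbol">',
        '##INFO=<ID=CALLER,Number=1,Type=String,Description="Variant caller">',
    ]
    lines += [f"##contig=<ID={c},length={CHROM_LENGTHS[c]}>" for c in CHROMOSOMES]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    eff_out = {Effect.NONSYNONYMOUS: "nonsynonymous", Effect.SYNONYMOUS: "synonymous",
               Effect.UNKNOWN: "other"}
    for r in sorted(records, key=lambda r: (order[r.chrom], r.pos, r.alt)):
        info = (
            f"DP={r.depth};EFFCLASS={eff_out[r.effect]};GENE={r.gene_id};"
            f"CALLER={r.caller.value}"
        )
        lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}")
    path.write_text("\n".join(lines) + "\n")


def _write_obo_gaf(cfg: SyntheticConfig, genes: pd.DataFrame, outdir: Path) -> None:
    """Toy three-category ontology, slim list and GAF annotations."""
    ns_long = {"BP": "biological_process", "CC": "cellular_component", "MF": "molecular_function"}
    terms: list[str] = []
    slim_ids: list[str] = []
    leaf_ids: list[str] = []
    leaf_meta: list[tuple[str, str]] = []  # (leaf id, aspect letter)
    aspect_letter = {"BP": "P", "CC": "C", "MF": "F"}
    tid = 0

    def new_id() -> str:
        nonlocal tid
        tid += 1
        return f"GO:{tid:07d}"

    blocks = ["format-version: 1.2", "ontology: synthetic-go"]
    for cat in ("BP", "CC", "MF"):
        root = new_id()
        blocks.append(f"\n[Term]\nid: {root}\nname: {ns_long[cat]}\nnamespace: {ns_long[cat]}")
        for slim_name in _SLIM_NAMES[cat]:
            sid = new_id()
            slim_ids.append(sid)
            blocks.append(
                f"\n[Term]\nid: {sid}\nname: {slim_name}\nnamespace: {ns_long[cat]}\n"
                f"is_a: {root} ! {ns_long[cat]}"
            )
            for k in range(4):
                lid = new_id()
                leaf_ids.append(lid)
                leaf_meta.append((lid, aspect_letter[cat]))
                blocks.append(
                    f"\n[Term]\nid: {lid}\nname: {slim_name}.leaf{k}\n"
                    f"namespace: {ns_long[cat]}\nis_a: {sid} ! {slim_name}"
                )
    (outdir / "ontology.obo").write_text("\n".join(blocks) + "\n")
    (outdir / "slim_terms.txt").write_text(
        "# synthetic GO slim subset\n" + "\n".join(slim_ids) + "\n"
    )
    rng = _rng(cfg.seed, 10)
    gaf_lines = ["!gaf-version: 2.2"]
    aspects = dict(leaf_meta)
    for sym in genes.index:
        n_terms = int(rng.integers(1, 4))
        chosen = rng.choice(leaf_ids, size=n_terms, replace=False)
        for term in sorted(map(str, chosen)):
            gaf_lines.append(
                "\t".join(
                    ["SYN", sym, sym, "", term, "PMID:0000001", "IEA", "",
                     aspects[term], sym, "", "protein", "taxon:9606",
                     "20160101", "SYN", "", ""]
                )
            )
    (outdir / "annotations.gaf").write_text("\n".join(gaf_lines) + "\n")


def generate_cohort(cfg: SyntheticConfig, outdir: str | Path) -> CohortData:
    """Write the full on-disk cohort (deterministic, byte-identical per seed)
    and return the in-memory data plus truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_cohort(cfg)

    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    by_cell: dict[str, list[SnpRecord]] = {s: [] for s in data.cell_ids + data.bulk_ids}
    for r in data.records:
        by_cell[r.cell_id].append(r)
    manifest_rows = []
    for sample in data.cell_ids + data.bulk_ids:
        _write_vcf(vcf_dir / f"{sample}.vcf", by_cell[sample])
        cls = (
            "bulk_cancer" if sample.startswith("bulkC")
            else "bulk_normal" if sample.startswith("bulkN")
            else "single_cell"
        )
        manifest_rows.append(
            {"cell_id": sample, "vcf_path": f"vcf/{sample}.vcf", "sample_class": cls}
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    genes_bed = data.genes.reset_index()
    bed = pd.DataFrame(
        {
            "chrom": genes_bed["chrom"],
            "start": genes_bed["start"] - 1,  # BED is 0-based half-open
            "end": genes_bed["end"],
            "name": genes_bed["gene_id"],
        }
    )
    bed.to_csv(outdir / "genes.bed", sep="\t", index=False, header=False)

    data.qc_summary.to_csv(outdir / "qc_summary.tsv", sep="\t", index=False)
    cov = pd.DataFrame(
        [(c, p, n) for (c, p), n in sorted(data.site_coverage.items())],
        columns=["chrom", "pos", "covered_cells"],
    )
    cov.to_csv(outdir / "site_coverage.tsv", sep="\t", index=False)
    data.expression.rename_axis("gene_id").to_csv(outdir / "expression.tsv", sep="\t")

    _write_obo_gaf(cfg, data.genes, outdir)

    gmt_lines = [
        "\t".join([name, "synthetic pathway"] + members)
        for name, members in data.pathways.items()
    ]
    (outdir / "pathways.gmt").write_text("\n".join(gmt_lines) + "\n")
    (outdir / "cancer_genes.txt").write_text(
        "# curated cancer-related genes (synthetic cohort)\n"
        + "\n".join(data.truth.cancer_genes) + "\n"
    )
    (outdir / "ribosomal_genes.txt").write_text("\n".join(data.ribosomal_genes) + "\n")

    fus = pd.DataFrame(
        [
            {
                "cell_id": r.cell_id, "gene5": r.gene5, "gene3": r.gene3,
                "chrom5": r.chrom5, "chrom3": r.chrom3,
                "breakpoint5": r.breakpoint5, "breakpoint3": r.breakpoint3,
                "location5": r.location5.value, "location3": r.location3.value,
                "supporting_reads": r.supporting_reads,
            }
            for r in data.fusion_records
        ]
    )
    fus.to_csv(outdir / "fusions.tsv", sep="\t", index=False)

    ortho_dir = outdir / "orthologs"
    ortho_dir.mkdir(exist_ok=True)
    meta_rows = []
    for rec in data.ortholog_records:
        fasta = ortho_dir / f"{rec.ortholog_id}.fasta"
        fasta.write_text(
            f">{rec.ortholog_id}_a\n{rec.seq1}\n>{rec.ortholog_id}_b\n{rec.seq2}\n"
        )
        meta_rows.append(
            {
                "ortholog_id": rec.ortholog_id,
                "fasta": f"orthologs/{rec.ortholog_id}.fasta",
                "go_slims": ";".join(sorted(rec.go_slims)),
                "expression_rate": round(rec.expression_rate, 4),
                "mutated_fraction": round(rec.mutated_fraction, 4),
                "mean_expression": round(float(data.ortholog_expression[rec.ortholog_id]), 4),
                "target_omega": data.truth.ortholog_targets[rec.ortholog_id],
            }
        )
    pd.DataFrame(meta_rows).to_csv(ortho_dir / "orthologs.tsv", sep="\t", index=False)

    (outdir / "truth.yaml").write_text(data.truth.to_yaml())
    pd.DataFrame(
        sorted(data.truth.planted_counts.items()), columns=["gene_id", "mutated_samples"]
    ).to_csv(outdir / "truth_planted_counts.tsv", sep="\t", index=False)
    data.truth.fusion_truth.to_csv(outdir / "truth_fusions.tsv", sep="\t", index=False)
    log.info("cohort written to %s (%d samples, %d SNP records)",
             outdir, len(data.cell_ids) + len(data.bulk_ids), len(data.records))
    return data
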