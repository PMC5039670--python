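"""Run configuration: thresholds, input paths and the master seed."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    min_site_depth: int = 5
    site_coverage_fraction: float = 0.95
    min_covered_sites: int = 100_000
    min_mean_depth: float = 5.0
    sr_selection_threshold: float = 0.5
    bootstrap_replicates: int = 10_000
    keep_unknown_effect: bool = False
    k_per_category: dict = field(default_factory=lambda: {"BP": 2, "MF": 3, "CC": 2})

    def validate(self) -> None:
        if self.min_site_depth < 1:
            raise ValueError("min_site_depth must be >= 1")
        if not 0.0 <= self.site_coverage_fraction <= 1.0:
            raise ValueError("site_coverage_fraction must be in [0, 1]")
        if not 0.0 <= self.sr_selection_threshold <= 1.0:
            raise ValueError("sr_selection_threshold must be in [0, 1]")
        if self.bootstrap_replicates < 100:
            raise ValueError("bootstrap_replicates must be >= 100")
        for cat, k in self.k_per_category.items():
            if k < 2:
                raise ValueError(f"k for category {cat} must be >= 2")


@dataclass
class RunConfig:
    """Everything a pipeline run needs: paths, thresholds, seed."""

    cohort_dir: str = "."
    outdir: str = "results"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    # input file names relative to cohort_dir (the synthetic generator's layout)
    manifest: str = "manifest.tsv"
    gene_models: str = "genes.bed"
    qc_summary: str = "qc_summary.tsv"
    site_coverage: str = "site_coverage.tsv"
    expression: str = "expression.tsv"
    gaf: str = "annotations.gaf"
    obo: str = "ontology.obo"
    slim: str = "slim_terms.txt"
    gmt: str = "pathways.gmt"
    cancer_genes: str = "cancer_genes.txt"
    ribosomal_genes: str = "ribosomal_genes.txt"
    fusion_table: str = "fusions.tsv"
    ortholog_dir: str = "orthologs"

    def path(self, name: str) -> Path:
        return Path(self.cohort_dir) / getattr(self, name)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__}, )
        cfg.thresholds = thr
        cfg.thresholds.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
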