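"""Readers for every external format the pipeline consumes.

VCF via pysam, BED/GTF via pyranges, OBO via obonet; GAF 2.x and the simple
line formats (GMT, plain gene lists, fusion TSV) via pandas. All coordinates
are converted to 1-based inclusive on read.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd
import pyranges
import pysam

from .records import (
    Caller,
    CohortManifest,
    Effect,
    FusionRecord,
    GeneModel,
    Location,
    ManifestEntry,
    SampleClass,
    SnpRecord,
    normalize_chrom,
)

log = logging.getLogger(__name__)

#: INFO keys the synthetic cohort writes and the reader consumes by default
DEFAULT_EFFECT_KEY = "EFFCLASS"
DEFAULT_GENE_KEY = "GENE"
DEFAULT_CALLER_KEY = "CALLER"

FUSION_COLUMNS = [
    "cell_id",
    "gene5",
    "gene3",
    "chrom5",
    "chrom3",
    "breakpoint5",
    "breakpoint3",
    "location5",
    "location3",
    "supporting_reads",
]


class InputError(Exception):
    """Missing or unusable input file."""


class ParseError(Exception):
    """Malformed content inside an input file."""


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest TSV (cell_id, vcf_path, sample_class).

    Relative VCF paths are resolved against the manifest's directory; every
    path must resolve to an existing file.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for row in df.itertuples(index=False):
        vcf = Path(row.vcf_path)
        if not vcf.is_absolute():
            vcf = path.parent / vcf
        if not vcf.exists():
            raise InputError(f"VCF for cell {row.cell_id} not found: {vcf}")
        entries.append(
            ManifestEntry(
                cell_id=row.cell_id,
                vcf_path=str(vcf),
                sample_class=SampleClass(row.sample_class),
            )
        )
    return CohortManifest(entries)


def read_cell_vcf(
    path: str | Path,
    cell_id: str,
    effect_key: str = DEFAULT_EFFECT_KEY,
    gene_key: str = DEFAULT_GENE_KEY,
    caller_key: str = DEFAULT_CALLER_KEY,
) -> list[SnpRecord]:
    """Read one cell's VCF into SnpRecords, one record per ALT allele.

    Read depth comes from INFO/DP (0 with a warning when absent); the effect
    class from a configurable INFO key with values synonymous /
    nonsynonymous / other (anything else maps to ``unknown``).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"VCF not found: {path}")
    records: list[SnpRecord] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # pysam warns on minimal headers
            vcf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - pysam error text varies
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    def info_get(rec, key):
        # pysam raises on keys absent from the header; treat as missing
        try:
            val = rec.info.get(key)
        except (KeyError, ValueError):
            return None
        return val[0] if isinstance(val, tuple) else val

    with vcf:
        for rec in vcf:
            depth = info_get(rec, "DP")
            if depth is None:
                log.warning("%s:%s:%d has no DP field; depth set to 0", cell_id, rec.chrom, rec.pos)
                depth = 0
            try:
                effect = Effect(str(info_get(rec, effect_key)))
            except ValueError:
                effect = Effect.UNKNOWN
            try:
                caller = Caller(str(info_get(rec, caller_key)))
            except ValueError:
                caller = Caller.GATK
            gene = info_get(rec, gene_key)
            gene = str(gene) if gene is not None else ""
            for alt in rec.alts or ():
                records.append(
                    SnpRecord(
                        cell_id=cell_id,
                        chrom=normalize_chrom(rec.chrom),
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        depth=int(depth),
                        gene_id=gene,
                        effect=effect,
                        caller=caller,
                    )
                )
    return records


def read_cohort_vcfs(manifest: CohortManifest, **kwargs) -> list[SnpRecord]:
    """Read every cell VCF in a manifest into one flat record list."""
    out: list[SnpRecord] = []
    for entry in manifest:
        out.extend(read_cell_vcf(entry.vcf_path, entry.cell_id, **kwargs))
    return out


def _gene_models_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"duplicate gene_id(s) in gene models: {sorted(dup)}")
    return df


def read_gene_models(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read gene models from BED (4+ columns, 0-based half-open) or GTF.

    Returns a DataFrame indexed by gene_id with columns symbol, chrom,
    start, end (1-based inclusive) and gene_length_bases (genomic span).
    For GTF, transcripts of one gene are merged to their union span.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene model file not found: {path}")
    if dialect is None:
        dialect = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    if path.stat().st_size == 0:
        log.warning("gene model file %s is empty", path)
        return pd.DataFrame(
            columns=["symbol", "chrom", "start", "end", "gene_length_bases"]
        ).rename_axis("gene_id")
    if dialect == "bed":
        gr = pyranges.read_bed(str(path))
        df = gr.df
        if "Name" not in df.columns:
            raise ParseError("BED gene models need at least 4 columns (name)")
        out = pd.DataFrame(
            {
                "gene_id": df["Name"].astype(str),
                "symbol": df["Name"].astype(str),
                "chrom": df["Chromosome"].map(normalize_chrom),
                "start": df["Start"].astype(int) + 1,  # 0-based half-open -> 1-based
                "end": df["End"].astype(int),
            }
        )
    else:
        gr = pyranges.read_gtf(str(path))
        df = gr.df
        df = df[df["Feature"].isin(["gene", "transcript", "exon"])]
        symbol = (
            df.groupby("gene_id")["gene_name"].first()
            if "gene_name" in df.columns
            else None
        )
        agg = df.groupby("gene_id").agg(
            chrom=("Chromosome", "first"), start=("Start", "min"), end=("End", "max")
        )
        out = pd.DataFrame(
            {
                "gene_id": agg.index.astype(str),
                "symbol": (
                    symbol.fillna(pd.Series(agg.index, index=agg.index)).astype(str)
                    if symbol is not None
                    else agg.index.astype(str)
                ),
                "chrom": agg["chrom"].map(normalize_chrom).values,
                "start": agg["start"].astype(int).values + 1,
                "end": agg["end"].astype(int).values,
            }
        )
    if (out["end"] < out["start"]).any():
        bad = out.loc[out["end"] < out["start"], "gene_id"].tolist()
        raise ParseError(f"end < start for gene(s): {bad}")
    out["gene_length_bases"] = out["end"] - out["start"] + 1
    return _gene_models_from_frame(out.set_index("gene_id"))


def gene_models_to_records(df: pd.DataFrame) -> dict[str, GeneModel]:
    return {
        gid: GeneModel(
            gene_id=gid,
            symbol=row["symbol"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            gene_length_bases=int(row["gene_length_bases"]),
        )
        for gid, row in df.iterrows()
    }


_GAF_ASPECTS = {"P": "BP", "F": "MF", "C": "CC"}

#: GAF 2.x column indices used here
_GAF_SYMBOL, _GAF_TERM, _GAF_ASPECT = 2, 4, 8


@dataclass
class GoAnnotations:
    """Gene->GO mapping plus the ontology index used for slim back-tracing."""

    gene_to_terms: dict[str, set[str]]
    term_category: dict[str, str]  # GO id -> BP/CC/MF
    graph: nx.MultiDiGraph  # obonet graph; edges child -> parent
    slim_terms: set[str]
    unannotated: set[str] = field(default_factory=set)

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of ``term`` (term itself excluded)."""
        if term not in self.graph:
            return set()
        return set(nx.descendants(self.graph, term))


def read_go_annotations(
    gaf_path: str | Path,
    obo_path: str | Path,
    slim_path: str | Path,
    all_genes: set[str] | None = None,
) -> GoAnnotations:
    """Load a GAF 2.x annotation file, an OBO ontology and a slim term list.

    Obsolete terms are dropped (with a count logged); GAF rows with an
    unknown aspect are skipped with a warning. Every slim term must exist in
    the ontology.
    """
    for p in (gaf_path, obo_path, slim_path):
        if not Path(p).exists():
            raise InputError(f"GO input not found: {p}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = obonet.read_obo(str(obo_path))
    n_obsolete = sum(1 for _, d in graph.nodes(data=True) if d.get("is_obsolete") == "true")
    if n_obsolete:
        log.info("dropping %d obsolete ontology terms", n_obsolete)
        graph.remove_nodes_from(
            [n for n, d in graph.nodes(data=True) if d.get("is_obsolete") == "true"]
        )
    # keep only is_a edges for the back trace
    drop = [
        (u, v, k)
        for u, v, k in graph.edges(keys=True)
        if k != "is_a"
    ]
    graph.remove_edges_from(drop)

    ns_map = {"biological_process": "BP", "cellular_component": "CC", "molecular_function": "MF"}
    term_category = {
        n: ns_map[d["namespace"]]
        for n, d in graph.nodes(data=True)
        if d.get("namespace") in ns_map
    }

    slim_terms = set(read_gene_list(slim_path))
    missing = slim_terms - set(graph.nodes)
    if missing:
        raise InputError(f"slim term(s) absent from ontology: {sorted(missing)}")

    gaf = pd.read_csv(gaf_path, sep="\t", comment="!", header=None, dtype=str)
    gene_to_terms: dict[str, set[str]] = {}
    for row in gaf.itertuples(index=False):
        symbol, term, aspect = row[_GAF_SYMBOL], row[_GAF_TERM], row[_GAF_ASPECT]
        if aspect not in _GAF_ASPECTS:
            log.warning("GAF row for %s has unknown aspect %r; skipped", symbol, aspect)
            continue
        if term not in graph:
            continue
        gene_to_terms.setdefault(symbol, set()).add(term)
    unannotated = (all_genes - set(gene_to_terms)) if all_genes else set()
    if unannotated:
        log.info("%d genes carry no GO annotation", len(unannotated))
    return GoAnnotations(
        gene_to_terms=gene_to_terms,
        term_category=term_category,
        graph=graph,
        slim_terms=slim_terms,
        unannotated=unannotated,
    )


def read_fusion_table(path: str | Path) -> list[FusionRecord]:
    """Read a deFuse-style fusion candidate TSV; no filtering happens here."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"fusion table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"fusion table missing column(s): {missing}")
    return [
        FusionRecord(
            cell_id=row.cell_id,
            gene5=row.gene5,
            gene3=row.gene3,
            chrom5=normalize_chrom(row.chrom5),
            chrom3=normalize_chrom(row.chrom3),
            breakpoint5=int(row.breakpoint5),
            breakpoint3=int(row.breakpoint3),
            location5=Location(row.location5),
            location3=Location(row.location3),
            supporting_reads=int(row.supporting_reads),
        )
        for row in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class PathwayDef:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"pathway {self.name} has < 2 members; cannot test enrichment")


def read_gene_sets(gmt_path: str | Path) -> list[PathwayDef]:
    """Read pathway gene sets from a GMT file (name, description, members)."""
    gmt_path = Path(gmt_path)
    if not gmt_path.exists():
        raise InputError(f"GMT file not found: {gmt_path}")
    sets = []
    for i, line in enumerate(gmt_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"GMT line {i}: expected name, description and members")
        name, members = fields[0], fields[2:]
        uniq = frozenset(members)
        if len(uniq) < len(members):
            log.warning("pathway %s: %d duplicate member(s) removed", name, len(members) - len(uniq))
        sets.append(PathwayDef(name=name, genes=uniq))
    return sets


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain symbol-per-line list; '#' starts a comment."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene list not found: {path}")
    symbols = []
    for line in path.read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            symbols.append(entry)
    if not symbols:
        raise ParseError(f"{path}: no genes (only comments/blank lines)")
    return symbols


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x cells expression matrix TSV (first column gene symbol)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"expression matrix not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=0)


def read_site_coverage(path: str | Path) -> dict[tuple[str, int], int]:
    """Read the per-site coverage sidecar (chrom, pos, covered_cells)."""
    df = pd.read_csv(path, sep="\t")
    return {
        (normalize_chrom(c), int(p)): int(n)
        for c, p, n in zip(df["chrom"], df["pos"], df["covered_cells"])
    }
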