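"""Shared fixtures: one full-size synthetic cohort (written to disk and read
back through the package's own readers) and one small cohort for fast tests.
"""
from __future__ import annotations

import pytest

from scsnpkit import io
from scsnpkit.filtering import apply_snp_cascade
from scsnpkit.records import SampleClass
from scsnpkit.statistics import gene_profile
from scsnpkit.synthetic import SyntheticConfig, generate_cohort

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """Full default cohort (96 cells) on disk, seed fixed for the session."""
    outdir = tmp_path_factory.mktemp("cohort96")
    data = generate_cohort(SyntheticConfig(seed=COHORT_SEED), outdir)
    return data, outdir


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Scaled-down cohort (24 cells, 200 genes) for I/O and CLI tests."""
    outdir = tmp_path_factory.mktemp("cohort24")
    data = generate_cohort(SyntheticConfig.scaled(24, n_genes=200, seed=7), outdir)
    return data, outdir


@pytest.fixture(scope="session")
def cohort_records(default_cohort):
    """Single-cell records of the default cohort, read back from its VCFs."""
    data, outdir = default_cohort
    manifest = io.read_manifest(outdir / "manifest.tsv")
    sc = manifest.of_class(SampleClass.SINGLE_CELL)
    return io.read_cohort_vcfs(sc)


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort, cohort_records):
    """Records surviving the full SNP cascade, plus the 96-cell SNP-Freq_g
    matrix (genes with no SNP have frequency zero)."""
    data, _ = default_cohort
    n_ret = len(data.truth.retained_cells)
    filtered, report = apply_snp_cascade(
        cohort_records, data.site_coverage, n_retained=n_ret
    )
    gl = data.genes["gene_length_bases"].to_dict()
    freq = gene_profile(filtered, gl, data.cell_ids)
    return {"records": filtered, "report": report, "gene_freq": freq, "data": data}


@pytest.fixture()
def toy_go(tmp_path):
    """Three-term is_a chain (leaf -> slim -> slim/root-adjacent) with two
    annotated genes, written in the on-disk dialects and loaded back."""
    obo = tmp_path / "toy.obo"
    obo.write_text(
        "format-version: 1.2\nontology: toy\n\n"
        "[Term]\nid: GO:0000001\nname: biological_process\nnamespace: biological_process\n\n"
        "[Term]\nid: GO:0000002\nname: t1\nnamespace: biological_process\n"
        "is_a: GO:0000001 ! root\n\n"
        "[Term]\nid: GO:0000003\nname: t2\nnamespace: biological_process\n"
        "is_a: GO:0000002 ! t1\n\n"
        "[Term]\nid: GO:0000004\nname: t3\nnamespace: biological_process\n"
        "is_a: GO:0000003 ! t2\n\n"
        "[Term]\nid: GO:0000005\nname: lonely\nnamespace: biological_process\n"
        "is_a: GO:0000001 ! root\n"
    )
    slim = tmp_path / "slim.txt"
    slim.write_text("GO:0000002\nGO:0000003\n")
    gaf = tmp_path / "toy.gaf"
    rows = [
        ["SYN", "G1", "G1", "", "GO:0000004", "PMID:1", "IEA", "", "P", "G1", "",
         "protein", "taxon:9606", "20160101", "SYN", "", ""],
        ["SYN", "G1", "G1", "", "GO:0000003", "PMID:1", "IEA", "", "P", "G1", "",
         "protein", "taxon:9606", "20160101", "SYN", "", ""],
        ["SYN", "G2", "G2", "", "GO:0000005", "PMID:1", "IEA", "", "P", "G2", "",
         "protein", "taxon:9606", "20160101", "SYN", "", ""],
    ]
    gaf.write_text("!gaf-version: 2.2\n" + "\n".join("\t".join(r) for r in rows) + "\n")
    return io.read_go_annotations(gaf, obo, slim)
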