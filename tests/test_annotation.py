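"""Genome-model windows and hierarchical feature annotation."""

import numpy as np
import pandas as pd
import pytest

from tsratlas.annotation import (
    DEFAULT_HIERARCHY,
    annotate_tsr,
    annotate_tsrs,
    build_genome_model,
    summarize_categories,
)

from conftest import make_tsr

CHROM_LEN = 50_000


def write_gff3(path, rows, chrom="chrX", length=CHROM_LEN):
    """rows: (ftype, start0, end0, strand, id, parent) in 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for ftype, s, e, strand, fid, parent in rows:
            attrs = f"ID={fid}"
            if parent:
                attrs += f";Parent={parent}"
            phase = "0" if ftype == "CDS" else "."
            fh.write(
                f"{chrom}\ttest\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t{phase}\t{attrs}\n"
            )


def overlap_fixture_rows():
    """Hand-crafted constructs where adjacent hierarchy categories overlap."""
    rows = []
    n = [0]

    def add(ftype, s, e, strand, fid=None, parent=None):
        if fid is None:
            n[0] += 1
            fid = f"f{n[0]:03d}"
        rows.append((ftype, s, e, strand, fid, parent))
        return fid

    def tx(gid, tid, s, e, strand, exons=None, cds=(), utr5=(), utr3=()):
        add("mRNA", s, e, strand, tid, gid)
        for a, b in exons or [(s, e)]:
            add("exon", a, b, strand, parent=tid)
        for a, b in cds:
            add("CDS", a, b, strand, parent=tid)
        for a, b in utr5:
            add("five_prime_UTR", a, b, strand, parent=tid)
        for a, b in utr3:
            add("three_prime_UTR", a, b, strand, parent=tid)

    # A: promoter (P1) over proximal (P2)
    add("gene", 10_000, 11_450, "+", "geneP")
    tx("geneP", "P1", 10_000, 11_150, "+")
    tx("geneP", "P2", 10_300, 11_450, "+")
    # B: proximal (Q2) over 5UTR (Q1)
    add("gene", 20_000, 21_150, "+", "geneQ1")
    tx("geneQ1", "Q1", 20_000, 21_150, "+",
       cds=[(20_250, 20_550)], utr5=[(20_000, 20_250)])
    add("gene", 20_700, 21_850, "+", "geneQ2")
    tx("geneQ2", "Q2", 20_700, 21_850, "+")
    # C: 5UTR (R1) over CDS (R2)
    add("gene", 30_000, 30_600, "+", "geneR")
    tx("geneR", "R1", 30_000, 30_600, "+",
       cds=[(30_300, 30_600)], utr5=[(30_000, 30_300)])
    tx("geneR", "R2", 30_000, 30_600, "+",
       cds=[(30_150, 30_600)], utr5=[(30_000, 30_150)])
    # D: CDS (S1) over intron (S2)
    add("gene", 32_000, 33_200, "+", "geneS")
    tx("geneS", "S1", 32_000, 33_200, "+",
       exons=[(32_000, 32_500), (32_700, 33_200)],
       cds=[(32_100, 32_500), (32_700, 33_000)])
    tx("geneS", "S2", 32_000, 33_200, "+",
       exons=[(32_000, 32_200), (32_900, 33_200)],
       cds=[(32_100, 32_200), (32_900, 33_000)])
    # E: intron (T1) over 3UTR (T2)
    add("gene", 35_000, 36_200, "+", "geneT")
    tx("geneT", "T1", 35_000, 36_200, "+",
       exons=[(35_000, 35_200), (35_800, 36_200)],
       cds=[(35_100, 35_200), (35_800, 35_900)])
    tx("geneT", "T2", 35_000, 36_200, "+",
       cds=[(35_100, 35_500)])
    # F/G: 3UTR (U) over antisense (V); antisense over intergenic
    add("gene", 38_000, 38_700, "+", "geneU")
    tx("geneU", "U1", 38_000, 38_700, "+", cds=[(38_100, 38_400)])
    add("gene", 38_300, 39_400, "-", "geneV")
    tx("geneV", "V1", 38_300, 39_400, "-")
    # H: two overlapping promoters -> nearest annotated TSS
    add("gene", 42_000, 43_150, "+", "geneW1")
    tx("geneW1", "W1", 42_000, 43_150, "+")
    add("gene", 42_150, 43_300, "+", "geneW2")
    tx("geneW2", "W2", 42_150, 43_300, "+")
    return rows


OVERLAP_CASES = [
    # (peak, strand, expected category, expected gene)
    (9_950, "+", "promoter", "geneP"),
    (20_220, "+", "proximal", "geneQ2"),
    (30_200, "+", "5UTR", "geneR"),
    (32_300, "+", "CDS", "geneS"),
    (35_600, "+", "intron", "geneT"),
    (38_500, "+", "3UTR", "geneU"),
    (39_000, "+", "antisense", "geneV"),
    (42_100, "+", "promoter", "geneW2"),
    (45_000, "+", "intergenic", None),
]

# with the winning category removed from the hierarchy, the runner-up wins
RUNNER_UP_CASES = [
    (9_950, "+", "promoter", "proximal", "geneP"),
    (20_220, "+", "proximal", "5UTR", "geneQ1"),
    (30_200, "+", "5UTR", "CDS", "geneR"),
    (32_300, "+", "CDS", "intron", "geneS"),
    (35_600, "+", "intron", "3UTR", "geneT"),
    (38_500, "+", "3UTR", "antisense", "geneV"),
    (39_000, "+", "antisense", "intergenic", None),
]


@pytest.fixture(scope="module")
def overlap_model(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "overlap.gff3"
    write_gff3(path, overlap_fixture_rows())
    return build_genome_model(path)


def test_window_geometry_plus(tmp_path):
    path = tmp_path / "g.gff3"
    rows = [("gene", 1000, 2000, "+", "g1", None), ("mRNA", 1000, 2000, "+", "m1", "g1")]
    write_gff3(path, rows)
    tx = build_genome_model(path).transcripts["m1"]
    assert tx.tss == 1000
    assert tx.promoter == (900, 1101)
    assert tx.promoter[1] - tx.promoter[0] == 201
    assert tx.proximal == (500, 900)


def test_window_geometry_minus(tmp_path):
    path = tmp_path / "g.gff3"
    rows = [("gene", 1000, 2000, "-", "g1", None), ("mRNA", 1000, 2000, "-", "m1", "g1")]
    write_gff3(path, rows)
    tx = build_genome_model(path).transcripts["m1"]
    assert tx.tss == 1999
    assert tx.promoter == (1899, 2100)
    assert tx.proximal == (2100, 2500)


def test_windows_clipped_at_chromosome_edges(tmp_path):
    path = tmp_path / "g.gff3"
    rows = [("gene", 50, 1200, "+", "g1", None), ("mRNA", 50, 1200, "+", "m1", "g1")]
    write_gff3(path, rows, length=1500)
    tx = build_genome_model(path).transcripts["m1"]
    assert tx.promoter[0] == 0
    assert tx.proximal == (0, 0)  # fully upstream of the chromosome start


def test_intron_and_utr_derivation(tmp_path):
    path = tmp_path / "g.gff3"
    rows = [
        ("gene", 1000, 2150, "+", "g1", None),
        ("mRNA", 1000, 2150, "+", "m1", "g1"),
        ("exon", 1000, 1550, "+", "e1", "m1"),
        ("exon", 1700, 2150, "+", "e2", "m1"),
        ("CDS", 1250, 1550, "+", "c1", "m1"),
        ("CDS", 1700, 2000, "+", "c2", "m1"),
    ]
    write_gff3(path, rows)
    tx = build_genome_model(path).transcripts["m1"]
    assert tx.introns == [(1550, 1700)]
    assert tx.utr5 == [(1000, 1250)]
    assert tx.utr3 == [(2000, 2150)]


def test_orphan_parent_is_an_error(tmp_path):
    path = tmp_path / "g.gff3"
    rows = [
        ("gene", 1000, 2000, "+", "g1", None),
        ("mRNA", 1000, 2000, "+", "m1", "missing_gene"),
    ]
    write_gff3(path, rows)
    with pytest.raises(ValueError, match="orphan"):
        build_genome_model(path)


def test_hierarchy_overlaps(overlap_model):
    for i, (peak, strand, category, gene) in enumerate(OVERLAP_CASES):
        t = make_tsr(f"t{i}", "chrX", strand, [peak])
        a = annotate_tsr(t, overlap_model)
        assert (a.category, a.gene_id) == (category, gene), (peak, a)


def test_hierarchy_runner_up(overlap_model):
    for i, (peak, strand, winner, runner_up, gene) in enumerate(RUNNER_UP_CASES):
        reduced = tuple(c for c in DEFAULT_HIERARCHY if c != winner)
        t = make_tsr(f"t{i}", "chrX", strand, [peak])
        a = annotate_tsr(t, overlap_model, hierarchy=reduced)
        assert (a.category, a.gene_id) == (runner_up, gene), (peak, a)


def mirror_rows(rows, length=CHROM_LEN):
    flip = {"+": "-", "-": "+"}
    return [
        (ftype, length - e, length - s, flip[strand], fid, parent)
        for ftype, s, e, strand, fid, parent in rows
    ]


def test_annotation_strand_symmetry(tmp_path):
    """Mirroring the genome (and the peaks) must not change any category."""
    rows = overlap_fixture_rows()
    fwd = tmp_path / "fwd.gff3"
    rev = tmp_path / "rev.gff3"
    write_gff3(fwd, rows)
    write_gff3(rev, mirror_rows(rows))
    m_fwd = build_genome_model(fwd)
    m_rev = build_genome_model(rev)
    flip = {"+": "-", "-": "+"}
    for i, (peak, strand, category, gene) in enumerate(OVERLAP_CASES):
        a = annotate_tsr(make_tsr(f"a{i}", "chrX", strand, [peak]), m_fwd)
        b = annotate_tsr(
            make_tsr(f"b{i}", "chrX", flip[strand], [CHROM_LEN - 1 - peak]), m_rev
        )
        assert a.category == b.category == category
        assert a.gene_id == b.gene_id == gene


def test_summarize_categories_counts(overlap_model):
    tsrs = [make_tsr(f"t{i}", "chrX", s, [p]) for i, (p, s, _, _) in enumerate(OVERLAP_CASES)]
    assignments = annotate_tsrs(tsrs, overlap_model)
    presence = pd.DataFrame(
        {"leaf": [True] * len(tsrs), "root": [False] * len(tsrs)},
        index=[t.id for t in tsrs],
    )
    summary = summarize_categories(assignments, presence)
    leaf = summary[summary["tissue"] == "leaf"].set_index("category")
    assert leaf.loc["promoter", "count"] == 2
    assert leaf.loc["intergenic", "count"] == 1
    assert leaf["proportion"].sum() == pytest.approx(1.0)
    root = summary[summary["tissue"] == "root"]
    assert root["count"].sum() == 0
    assert root["proportion"].isna().all()


def test_noiseless_sim_categories_all_correct(noiseless_sim):
    """On clean data, every planted TSR gets its intended category."""
    from tsratlas.evaluate import recovery_report

    sg = noiseless_sim["sg"]
    result = noiseless_sim["result"]
    report = recovery_report(sg, result["tsrs"], assignments=result["assignments"])
    assert report.n_recovered == report.n_planted
    assert report.n_category_correct == report.n_planted
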