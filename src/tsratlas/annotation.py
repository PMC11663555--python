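"""Genome model construction and hierarchical TSR feature annotation.

The model is built from a GFF3 (gene -> mRNA -> exon/CDS/UTR).  For each
transcript we derive, strand-aware:

* ``annotated_tss`` — the transcript's 5' end;
* ``promoter`` — 100 bp upstream through 100 bp downstream of the
  annotated TSS (a 201-bp window);
* ``proximal`` — the 400 bp immediately upstream of the promoter window;
* introns — the transcript span minus its exons;
* 5'/3' UTRs — taken from the annotation when present, otherwise
  derived as exonic sequence outside the CDS, split by side.

A TSR is assigned exactly one category by testing its PEAK position
against same-strand windows in a configurable priority order
(promoter > proximal > 5UTR > CDS > intron > 3UTR), then against
opposite-strand gene bodies (antisense), and finally intergenic.  Among
several candidate transcripts in the winning category, the one whose
annotated TSS is nearest the peak wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Transcript",
    "Gene",
    "GenomeModel",
    "FeatureAssignment",
    "DEFAULT_HIERARCHY",
    "build_genome_model",
    "annotate_tsr",
    "annotate_tsrs",
    "summarize_categories",
]

DEFAULT_HIERARCHY = (
    "promoter",
    "proximal",
    "5UTR",
    "CDS",
    "intron",
    "3UTR",
    "antisense",
    "intergenic",
)

GENIC_CATEGORIES = ("promoter", "proximal", "5UTR", "CDS", "intron", "3UTR")
INTRAGENIC_CATEGORIES = frozenset({"5UTR", "CDS", "intron", "3UTR", "antisense"})

PROMOTER_UP = 100
PROMOTER_DOWN = 100
PROXIMAL_LEN = 400


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)
    tss: int = -1
    promoter: tuple[int, int] = (0, 0)
    proximal: tuple[int, int] = (0, 0)

    @property
    def coding(self) -> bool:
        return bool(self.cds)


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GenomeModel:
    genes: dict[str, Gene]
    transcripts: dict[str, Transcript]
    chrom_lengths: dict[str, int]
    # (chrom, strand, category) -> IntervalTree of (gene_id, transcript_id, tss)
    _feature_index: dict = field(default_factory=dict, repr=False)
    # (chrom, strand) -> IntervalTree of gene bodies
    _gene_index: dict = field(default_factory=dict, repr=False)

    def feature_hits(self, chrom: str, strand: str, pos: int, category: str):
        tree = self._feature_index.get((chrom, strand, category))
        if tree is None:
            return []
        return [iv.data for iv in tree[pos]]

    def gene_hits(self, chrom: str, strand: str, pos: int):
        tree = self._gene_index.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree[pos]]


@dataclass
class FeatureAssignment:
    tsr_id: str
    category: str
    gene_id: str | None = None
    transcript_id: str | None = None


def _subtract(span: tuple[int, int], blocks: list[tuple[int, int]]):
    """Intervals of ``span`` not covered by ``blocks`` (assumed sorted, disjoint)."""
    out = []
    cursor = span[0]
    for s, e in sorted(blocks):
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return out


def _derive_utrs(tx: Transcript) -> None:
    """Fill missing UTRs as exonic minus CDS, split by side of the CDS."""
    if not tx.cds or (tx.utr5 and tx.utr3):
        return
    cds_lo = min(s for s, _ in tx.cds)
    cds_hi = max(e for _, e in tx.cds)
    left, right = [], []
    for es, ee in tx.exons:
        for s, e in _subtract((es, ee), [(max(es, cds_lo), min(ee, cds_hi))]):
            (left if e <= cds_lo else right).append((s, e))
    if tx.strand == "+":
        tx.utr5 = tx.utr5 or left
        tx.utr3 = tx.utr3 or right
    else:
        tx.utr5 = tx.utr5 or right
        tx.utr3 = tx.utr3 or left


def build_genome_model(gff3_path, chrom_lengths: dict[str, int] | None = None) -> GenomeModel:
    """Parse a GFF3 into a GenomeModel with derived windows and indices.

    ``chrom_lengths`` clips promoter/proximal windows at chromosome
    bounds; when omitted it is taken from ``##sequence-region`` pragmas
    if present, else windows are clipped at 0 only.
    """
    if chrom_lengths is None:
        chrom_lengths = _sequence_regions(gff3_path)
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    known_ids = {f.id for f in db.all_features()}
    orphans = []
    for f in db.all_features():
        for parent in f.attributes.get("Parent", []):
            if parent not in known_ids:
                orphans.append(f"{f.id or f.featuretype}->{parent}")
    if orphans:
        raise ValueError(f"orphan Parent references in GFF3: {sorted(set(orphans))}")

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    for g in db.features_of_type("gene"):
        gene = Gene(id=g.id, chrom=g.seqid, strand=g.strand, start=g.start - 1, end=g.end)
        for m in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            tx = Transcript(
                id=m.id,
                gene_id=g.id,
                chrom=m.seqid,
                strand=m.strand,
                start=m.start - 1,
                end=m.end,
                exons=[(c.start - 1, c.end) for c in db.children(m, featuretype="exon", order_by="start")],
                cds=[(c.start - 1, c.end) for c in db.children(m, featuretype="CDS", order_by="start")],
                utr5=[(c.start - 1, c.end) for c in db.children(m, featuretype="five_prime_UTR", order_by="start")],
                utr3=[(c.start - 1, c.end) for c in db.children(m, featuretype="three_prime_UTR", order_by="start")],
            )
            if not tx.exons:
                tx.exons = [(tx.start, tx.end)]
            tx.introns = _subtract((tx.start, tx.end), tx.exons)
            _derive_utrs(tx)
            chrom_len = chrom_lengths.get(tx.chrom)
            if tx.strand == "+":
                tx.tss = tx.start
                prom = (tx.tss - PROMOTER_UP, tx.tss + PROMOTER_DOWN + 1)
                prox = (prom[0] - PROXIMAL_LEN, prom[0])
            else:
                tx.tss = tx.end - 1
                prom = (tx.tss - PROMOTER_DOWN, tx.tss + PROMOTER_UP + 1)
                prox = (prom[1], prom[1] + PROXIMAL_LEN)
            tx.promoter = _clip(prom, chrom_len)
            tx.proximal = _clip(prox, chrom_len)
            gene.transcripts.append(tx)
            transcripts[tx.id] = tx
        genes[gene.id] = gene

    model = GenomeModel(genes=genes, transcripts=transcripts, chrom_lengths=chrom_lengths or {})
    _build_indices(model)
    return model


def _clip(window: tuple[int, int], chrom_len: int | None) -> tuple[int, int]:
    s, e = window
    s = max(0, s)
    if chrom_len is not None:
        e = min(e, chrom_len)
    return (s, max(s, e))  # empty (s, s) when the window is fully off-chromosome


def _sequence_regions(gff3_path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    return lengths


def _build_indices(model: GenomeModel) -> None:
    feat: dict = {}
    gene_idx: dict = {}

    def add(chrom, strand, category, s, e, data):
        if e <= s:
            return
        feat.setdefault((chrom, strand, category), IntervalTree()).addi(s, e, data)

    for gene in model.genes.values():
        gene_idx.setdefault((gene.chrom, gene.strand), IntervalTree()).addi(
            gene.start, gene.end, gene.id
        )
        for tx in gene.transcripts:
            data = (gene.id, tx.id, tx.tss)
            add(tx.chrom, tx.strand, "promoter", *tx.promoter, data)
            add(tx.chrom, tx.strand, "proximal", *tx.proximal, data)
            for s, e in tx.utr5:
                add(tx.chrom, tx.strand, "5UTR", s, e, data)
            for s, e in tx.cds:
                add(tx.chrom, tx.strand, "CDS", s, e, data)
            for s, e in tx.introns:
                add(tx.chrom, tx.strand, "intron", s, e, data)
            for s, e in tx.utr3:
                add(tx.chrom, tx.strand, "3UTR", s, e, data)
    model._feature_index = feat
    model._gene_index = gene_idx


def annotate_tsr(tsr, model: GenomeModel, hierarchy=DEFAULT_HIERARCHY) -> FeatureAssignment:
    """Assign one feature category to a TSR by peak position and priority."""
    peak = tsr.peak
    other = "-" if tsr.strand == "+" else "+"
    for category in hierarchy:
        if category == "antisense":
            hits = model.gene_hits(tsr.chrom, other, peak)
            if hits:
                gene_id = min(
                    hits,
                    key=lambda g: (
                        min(
                            abs(tx.tss - peak)
                            for tx in model.genes[g].transcripts
                        )
                        if model.genes[g].transcripts
                        else 1 << 60,
                        g,
                    ),
                )
                return FeatureAssignment(tsr.id, "antisense", gene_id, None)
        elif category == "intergenic":
            return FeatureAssignment(tsr.id, "intergenic", None, None)
        else:
            hits = model.feature_hits(tsr.chrom, tsr.strand, peak, category)
            if hits:
                gene_id, tx_id, _ = min(
                    hits, key=lambda h: (abs(h[2] - peak), h[0], h[1])
                )
                return FeatureAssignment(tsr.id, category, gene_id, tx_id)
    return FeatureAssignment(tsr.id, "intergenic", None, None)


def annotate_tsrs(tsrs, model: GenomeModel, hierarchy=DEFAULT_HIERARCHY) -> dict[str, FeatureAssignment]:
    return {t.id: annotate_tsr(t, model, hierarchy) for t in tsrs}


def summarize_categories(
    assignments: dict[str, FeatureAssignment],
    presence: pd.DataFrame,
    categories=DEFAULT_HIERARCHY,
) -> pd.DataFrame:
    """Per-tissue TSR counts and proportions by category.

    ``presence`` is a boolean TSR x tissue frame (index = tsr_id).
    Tissues with no present TSRs get NaN proportions (flagged, not 0/0).
    """
    rows = []
    cat = pd.Series({tid: a.category for tid, a in assignments.items()})
    for tissue in presence.columns:
        present_ids = presence.index[presence[tissue]]
        counts = cat.loc[cat.index.intersection(present_ids)].value_counts()
        total = int(counts.sum())
        for c in categories:
            n = int(counts.get(c, 0))
            rows.append(
                {
                    "tissue": tissue,
                    "category": c,
                    "count": n,
                    "proportion": (n / total) if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)
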