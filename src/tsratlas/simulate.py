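"""Synthetic genome, annotation and multi-tissue CTSS tracks with ground truth.

The generator builds a toy genome in which every downstream stage has a
machine-readable truth: genes with a fixed exon/intron architecture are
placed sparsely on random sequence, TSRs of controlled width/shape are
planted in chosen feature categories, divergent (bidirectional) pairs
are planted within the pairing span, TATA-box (TATAWAWR, match starting
30 bp upstream of the peak) and PyPu initiator dinucleotides are written
into the sequence of canonical TSRs, coding-region TSRs carry a planted
first downstream AUG with a known truncation/frameshift consequence,
and a uniform low-level background of single 5'-end counts mimics
degradation noise.

Gene architecture (sense coordinates from the annotated TSS):

    5'UTR [0,250) | CDS-1 [250,550) | intron [550,700)
    | CDS-2 [700,1000) | 3'UTR [1000,1150)

so exon 1 = [0,550), exon 2 = [700,1150), span 1150 bp.  An ATG is
written at the annotated CDS start.  All outputs are fully determined
by the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from tsratlas.util import revcomp

__all__ = [
    "SimConfig",
    "SimGene",
    "SimTsr",
    "SyntheticGenome",
    "generate_genome",
    "generate_ctss",
]

# gene geometry (sense offsets from the TSS)
UTR5_LEN = 250
CDS1 = (250, 550)
INTRON = (550, 700)
CDS2 = (700, 1000)
UTR3 = (1000, 1150)
EXON1 = (0, 550)
EXON2 = (700, 1150)
GENE_SPAN = 1150

_HOSTED = ("promoter", "5UTR", "CDS", "intron", "3UTR")


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults emulate the data regime of a multi-tissue 5'-end atlas:
    a shape mix dominated by single-base TSRs (64.8/16.3/18.9 S/N/B),
    a category mix with a promoter-heavy canonical fraction and a
    CDS-dominant intragenic fraction, strong tissue specificity, and a
    sparse uniform degradation background.
    """

    genome_length: int = 250_000  # bp per chromosome
    n_chromosomes: int = 2
    n_genes: int = 40
    n_tsrs: int | None = None  # default: 1.5 x n_genes
    tissue_names: tuple[str, ...] = ("leaf", "root", "nodule", "flower")
    tsr_width_distribution: dict = field(
        default_factory=lambda: {"single": 0.648, "narrow": 0.163, "broad": 0.189}
    )
    feature_mix: dict = field(
        default_factory=lambda: {
            "promoter": 0.30,
            "5UTR": 0.15,
            "CDS": 0.32,
            "intron": 0.05,
            "3UTR": 0.04,
            "antisense": 0.06,
            "intergenic": 0.08,
        }
    )
    fraction_bidirectional: float = 0.25
    bidirectional_span: int = 600
    tissue_presence_model: dict = field(
        default_factory=lambda: {"specific_fraction": 0.6, "presence_prob": 0.7}
    )
    background_rate: float = 0.2  # expected noise 5' counts per kb per tissue
    tata_plant_rate: float = 0.8
    pypu_plant_rate: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name, dist in (
            ("tsr_width_distribution", self.tsr_width_distribution),
            ("feature_mix", self.feature_mix),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if self.n_genes > 0:
            total_bp = self.genome_length * self.n_chromosomes
            if total_bp < 10 * self.n_genes * GENE_SPAN:
                raise ValueError(
                    "genome too small: total length must be >= 10 x n_genes x gene span"
                )
        if len(set(self.tissue_names)) != len(self.tissue_names):
            raise ValueError("tissue names must be unique")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def total_tsrs(self) -> int:
        if self.n_genes == 0:
            return 0
        return self.n_tsrs if self.n_tsrs is not None else int(round(1.5 * self.n_genes))


@dataclass
class SimGene:
    id: str
    chrom: str
    strand: str
    tss: int  # genomic position of the annotated TSS (0-based)
    paired_with: str | None = None  # head-to-head partner gene

    def sense_to_genomic(self, off: int) -> int:
        return self.tss + off if self.strand == "+" else self.tss - off

    @property
    def start(self) -> int:
        return self.tss if self.strand == "+" else self.tss - GENE_SPAN + 1

    @property
    def end(self) -> int:
        return self.start + GENE_SPAN


@dataclass
class SimTsr:
    id: str
    chrom: str
    strand: str
    positions: list[int]  # genomic, ascending
    counts: list[int]  # aligned with positions
    peak: int
    shape: str  # intended S/N/B under the pooled-profile IQR operator
    category: str  # intended feature annotation
    gene_id: str | None
    tissues: list[str]  # intended presence set
    tissue_scale: dict = field(default_factory=dict)
    partner_id: str | None = None
    pair_category: str | None = None
    tata_planted: bool = False
    pypu_planted: bool = False
    orf_outcome: str | None = None
    orf_delta_aa: int | None = None
    orf_new_start: int | None = None

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1] + 1

    @property
    def total_count(self) -> int:
        return int(sum(self.counts))

    def peak_sense_offset(self, gene: "SimGene") -> int:
        """Sense-coordinate offset of the peak from the host gene's TSS."""
        return self.peak - gene.tss if gene.strand == "+" else gene.tss - self.peak


@dataclass
class SyntheticGenome:
    config: SimConfig
    sequences: dict[str, str]
    genes: list[SimGene]
    tsrs: list[SimTsr]

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "annotation.gff3",
            "manifest_json": outdir / "manifest.json",
            "manifest_tsv": outdir / "manifest.tsv",
        }
        _write_fasta(self.sequences, paths["fasta"])
        _write_gff3(self, paths["gff3"])
        with open(paths["manifest_json"], "w") as fh:
            json.dump(
                {
                    "config": _jsonable(asdict(self.config)),
                    "genes": [asdict(g) for g in self.genes],
                    "tsrs": [asdict(t) for t in self.tsrs],
                },
                fh,
                indent=1,
            )
        _manifest_frame(self).to_csv(paths["manifest_tsv"], sep="\t", index=False)
        return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def _manifest_frame(sg: SyntheticGenome) -> pd.DataFrame:
    rows = []
    for t in sg.tsrs:
        rows.append(
            {
                "id": t.id,
                "chrom": t.chrom,
                "strand": t.strand,
                "start": t.start,
                "end": t.end,
                "peak": t.peak,
                "shape": t.shape,
                "category": t.category,
                "gene_id": t.gene_id or "",
                "tissues": ",".join(t.tissues),
                "partner_id": t.partner_id or "",
                "pair_category": t.pair_category or "",
                "tata_planted": t.tata_planted,
                "pypu_planted": t.pypu_planted,
                "orf_outcome": t.orf_outcome or "",
                "orf_delta_aa": "" if t.orf_delta_aa is None else t.orf_delta_aa,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "chrom", "strand", "start", "end", "peak", "shape", "category",
            "gene_id", "tissues", "partner_id", "pair_category", "tata_planted",
            "pypu_planted", "orf_outcome", "orf_delta_aa",
        ],
    )


# ---------------------------------------------------------------------------
# profiles


def _draw_profile(kind: str, rng) -> tuple[np.ndarray, int]:
    """Count profile (ascending sense offsets, contiguous) and peak index."""
    if kind == "single":
        return np.array([int(rng.integers(20, 81))]), 0
    if kind == "narrow":
        w = int(rng.choice([3, 5]))
        a = int(rng.integers(5, 16))
        ramp = np.arange(1, w // 2 + 2)
        counts = np.concatenate([ramp, ramp[-2::-1]]) * a
        return counts, w // 2
    if kind == "broad":
        w = int(rng.integers(10, 31))
        c = int(rng.integers(3, 9))
        counts = np.full(w, c)
        counts[w // 2] += 2
        return counts, w // 2
    raise ValueError(kind)


def _profile_shape(counts: np.ndarray) -> str:
    """Shape label of a contiguous profile under the step-CDF IQR rule."""
    w = len(counts)
    if w == 1:
        return "S"
    frac = np.cumsum(counts) / counts.sum()
    q25 = int(np.searchsorted(frac, 0.25 - 1e-12))
    q75 = int(np.searchsorted(frac, 0.75 - 1e-12))
    return "N" if (q75 - q25) <= 4 else "B"


def _place_profile(
    strand: str, peak_genomic: int, counts: np.ndarray, peak_idx: int
) -> tuple[list[int], list[int]]:
    """Map a sense-offset profile onto genomic coordinates (ascending)."""
    rel = np.arange(len(counts)) - peak_idx
    if strand == "+":
        pos = peak_genomic + rel
        return pos.tolist(), counts.tolist()
    pos = peak_genomic - rel
    order = np.argsort(pos)
    return pos[order].tolist(), counts[order].tolist()


# ---------------------------------------------------------------------------
# genome generation


def _write_sense(seq_arrays, chrom, strand, peak, rel_start, motif):
    """Write ``motif`` so that it reads 5'->3' on ``strand`` starting at the
    given sense offset relative to ``peak``."""
    arr = seq_arrays[chrom]
    L = len(motif)
    if strand == "+":
        g0 = peak + rel_start
        arr[g0 : g0 + L] = list(motif)
    else:
        g0 = peak - (rel_start + L - 1)
        arr[g0 : g0 + L] = list(revcomp(motif))


def generate_genome(config: SimConfig, outdir=None) -> SyntheticGenome:
    """Build the synthetic genome, annotation and truth manifest.

    When ``outdir`` is given the FASTA, GFF3 and manifest files are
    written there as well.  Identical configs produce byte-identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    seq_arrays = {
        c: rng.choice(np.array(list("ACGT")), size=config.genome_length)
        for c in config.chrom_names
    }

    n_tsrs = config.total_tsrs()
    categories = (
        list(
            rng.choice(
                list(config.feature_mix),
                size=n_tsrs,
                p=list(config.feature_mix.values()),
            )
        )
        if n_tsrs
        else []
    )
    n_promoter = categories.count("promoter")
    n_mm_pairs = int(config.fraction_bidirectional * n_promoter / 2)
    n_mm_pairs = min(n_mm_pairs, config.n_genes // 4)
    n_prompt = int(round(config.fraction_bidirectional * n_promoter / 2))

    genes = _place_genes(config, rng, n_mm_pairs)
    for gene in genes:
        _write_sense(seq_arrays, gene.chrom, gene.strand, gene.tss, CDS1[0], "ATG")

    tsrs = _plant_tsrs(config, rng, genes, categories, n_mm_pairs, n_prompt, seq_arrays)
    _assign_presence(config, rng, tsrs)

    sg = SyntheticGenome(
        config=config,
        sequences={c: "".join(a) for c, a in seq_arrays.items()},
        genes=genes,
        tsrs=tsrs,
    )
    if outdir is not None:
        sg.write(outdir)
    return sg


def _place_genes(config: SimConfig, rng, n_mm_pairs: int) -> list[SimGene]:
    margin = 900
    items = ["pair"] * n_mm_pairs + ["single"] * (config.n_genes - 2 * n_mm_pairs)
    genes: list[SimGene] = []
    idx = 0
    chrom_iter = iter(config.chrom_names)
    chrom = next(chrom_iter, None)
    cursor = margin
    per_chrom = -(-len(items) // max(1, config.n_chromosomes))
    placed_on_chrom = 0
    for item in items:
        while True:
            if chrom is None:
                raise ValueError(
                    "placement error: genes cannot be placed without same-strand "
                    "overlap (genome too short for the requested gene count)"
                )
            need = 2 * GENE_SPAN + 700 if item == "pair" else GENE_SPAN
            if placed_on_chrom < per_chrom and cursor + need + margin <= config.genome_length:
                break
            chrom = next(chrom_iter, None)
            cursor = margin
            placed_on_chrom = 0
        if item == "single":
            strand = "+" if rng.random() < 0.5 else "-"
            tss = cursor if strand == "+" else cursor + GENE_SPAN - 1
            genes.append(SimGene(id=f"G{idx + 1:04d}", chrom=chrom, strand=strand, tss=tss))
            idx += 1
            cursor += GENE_SPAN + int(rng.integers(1700, 2601))
        else:
            # head-to-head: minus-strand gene, then plus-strand gene downstream
            tss_l = cursor + GENE_SPAN - 1
            d = int(rng.integers(180, 341))
            tss_r = tss_l + d
            left = SimGene(id=f"G{idx + 1:04d}", chrom=chrom, strand="-", tss=tss_l)
            right = SimGene(id=f"G{idx + 2:04d}", chrom=chrom, strand="+", tss=tss_r)
            left.paired_with = right.id
            right.paired_with = left.id
            genes.extend([left, right])
            idx += 2
            cursor = tss_r + GENE_SPAN + int(rng.integers(1700, 2601))
        placed_on_chrom += 1
    return genes


def _pick(rng, pool: list):
    return pool[int(rng.integers(len(pool)))]


def _plant_tsrs(config, rng, genes, categories, n_mm_pairs, n_prompt, seq_arrays):
    tsrs: list[SimTsr] = []
    counter = [0]

    def new_id():
        counter[0] += 1
        return f"T{counter[0]:04d}"

    def make_tsr(strand, chrom, peak, category, gene_id, width_kind=None) -> SimTsr:
        kind = width_kind or rng.choice(
            list(config.tsr_width_distribution),
            p=list(config.tsr_width_distribution.values()),
        )
        counts, peak_idx = _draw_profile(str(kind), rng)
        positions, placed = _place_profile(strand, peak, counts, peak_idx)
        return SimTsr(
            id=new_id(),
            chrom=chrom,
            strand=strand,
            positions=positions,
            counts=placed,
            peak=peak,
            shape=_profile_shape(counts),
            category=category,
            gene_id=gene_id,
            tissues=[],
        )

    paired_genes = [g for g in genes if g.paired_with]
    single_genes = [g for g in genes if not g.paired_with]
    hosted_by_gene: dict[str, dict[str, SimTsr]] = {g.id: {} for g in genes}

    # promoter TSRs: paired genes first (one each), rest on singles
    promoter_budget = categories.count("promoter")
    mm_genes = paired_genes[: 2 * n_mm_pairs]
    for gene in mm_genes:
        off = int(rng.integers(-20, 21))
        t = make_tsr(gene.strand, gene.chrom, gene.sense_to_genomic(off), "promoter", gene.id)
        hosted_by_gene[gene.id]["promoter"] = t
        tsrs.append(t)
    promoter_budget -= len(mm_genes)
    if promoter_budget < 0:
        raise ValueError("placement error: more head-to-head promoters than promoter draws")
    for _ in range(promoter_budget):
        pool = [g for g in single_genes if "promoter" not in hosted_by_gene[g.id]]
        if not pool:
            raise ValueError("placement error: not enough genes to host promoter TSRs")
        gene = _pick(rng, pool)
        off = int(rng.integers(-50, 51))
        t = make_tsr(gene.strand, gene.chrom, gene.sense_to_genomic(off), "promoter", gene.id)
        hosted_by_gene[gene.id]["promoter"] = t
        tsrs.append(t)

    # record the planted mRNA-mRNA pairs
    for i in range(n_mm_pairs):
        a = hosted_by_gene[mm_genes[2 * i].id]["promoter"]
        b = hosted_by_gene[mm_genes[2 * i + 1].id]["promoter"]
        a.partner_id, b.partner_id = b.id, a.id
        a.pair_category = b.pair_category = "mRNA-mRNA"

    # other sense categories on single genes only
    off_ranges = {"5UTR": (125, 216), "intron": (575, 676), "3UTR": (1025, 1126)}
    for category in ("5UTR", "CDS", "intron", "3UTR"):
        for _ in range(categories.count(category)):
            pool = [g for g in single_genes if category not in hosted_by_gene[g.id]]
            if not pool:
                raise ValueError(f"placement error: not enough genes to host {category} TSRs")
            gene = _pick(rng, pool)
            if category == "CDS":
                t = _plant_cds_tsr(config, rng, gene, make_tsr, seq_arrays)
            else:
                lo, hi = off_ranges[category]
                off = int(rng.integers(lo, hi))
                kind = None
                if category == "intron":
                    # keep intron TSRs inside the 150-bp intron
                    kind = rng.choice(
                        list(config.tsr_width_distribution),
                        p=list(config.tsr_width_distribution.values()),
                    )
                    if kind == "broad":
                        off = int(rng.integers(580, 670))
                t = make_tsr(
                    gene.strand, gene.chrom, gene.sense_to_genomic(off), category, gene.id,
                    width_kind=kind,
                )
            hosted_by_gene[gene.id][category] = t
            tsrs.append(t)

    # antisense TSRs: only on singles without intron/3UTR TSRs (keeps pairing truth clean)
    n_antisense = categories.count("antisense")
    n_other_div = n_antisense // 2
    for k in range(n_antisense):
        want_pair = k < n_other_div
        pool = [
            g
            for g in single_genes
            if "antisense" not in hosted_by_gene[g.id]
            and "intron" not in hosted_by_gene[g.id]
            and "3UTR" not in hosted_by_gene[g.id]
            and (not want_pair or "CDS" in hosted_by_gene[g.id])
        ]
        if want_pair:
            pool = [
                g
                for g in pool
                if hosted_by_gene[g.id]["CDS"].peak_sense_offset(g) >= 310
            ]
        if not pool:
            want_pair = False
            pool = [
                g
                for g in single_genes
                if "antisense" not in hosted_by_gene[g.id]
                and "intron" not in hosted_by_gene[g.id]
                and "3UTR" not in hosted_by_gene[g.id]
            ]
            if not pool:
                break  # saturated; fewer antisense TSRs than drawn
        gene = _pick(rng, pool)
        anti_strand = "-" if gene.strand == "+" else "+"
        if want_pair:
            cds_tsr = hosted_by_gene[gene.id]["CDS"]
            cds_off = cds_tsr.peak_sense_offset(gene)
            a_off = int(rng.integers(260, cds_off - 39))
        elif "CDS" in hosted_by_gene[gene.id]:
            a_off = int(rng.integers(620, 901))
        else:
            a_off = int(rng.integers(300, 901))
        t = make_tsr(anti_strand, gene.chrom, gene.sense_to_genomic(a_off), "antisense", gene.id)
        hosted_by_gene[gene.id]["antisense"] = t
        tsrs.append(t)
        if want_pair:
            cds_tsr = hosted_by_gene[gene.id]["CDS"]
            cds_tsr.partner_id, t.partner_id = t.id, cds_tsr.id
            cds_tsr.pair_category = t.pair_category = "other-divergence"

    # PROMPT partners for single-gene promoter TSRs
    prompt_pool = [
        g for g in single_genes if "promoter" in hosted_by_gene[g.id]
    ]
    for gene in prompt_pool[:n_prompt]:
        prom = hosted_by_gene[gene.id]["promoter"]
        d_p = int(rng.integers(220, 481))
        anti_strand = "-" if gene.strand == "+" else "+"
        t = make_tsr(
            anti_strand,
            gene.chrom,
            gene.sense_to_genomic(-d_p),
            "intergenic",
            None,
            width_kind=str(rng.choice(["single", "narrow"])),
        )
        tsrs.append(t)
        prom.partner_id, t.partner_id = t.id, prom.id
        prom.pair_category = t.pair_category = "mRNA-PROMPT"

    # intergenic TSRs in zones clear of any gene influence
    n_intergenic = categories.count("intergenic")
    zones = _free_zones(config, genes)
    placed_positions: list[tuple[str, int]] = []
    for _ in range(n_intergenic):
        spot = _pick_intergenic(rng, zones, placed_positions)
        if spot is None:
            break
        chrom, pos = spot
        placed_positions.append(spot)
        strand = "+" if rng.random() < 0.5 else "-"
        tsrs.append(make_tsr(strand, chrom, pos, "intergenic", None))

    _plant_motifs(config, rng, tsrs, seq_arrays)
    tsrs.sort(key=lambda t: (t.chrom, t.start, t.strand))
    return tsrs


def _plant_cds_tsr(config, rng, gene: SimGene, make_tsr, seq_arrays) -> SimTsr:
    """CDS TSR with a controlled first downstream AUG.

    Sequence between the peak (a purine base) and the planted AUG is
    rewritten with pyrimidines so the planted AUG is guaranteed to be
    the first one scanned; its coding-frame offset fixes the intended
    truncation/frameshift outcome.
    """
    off = int(rng.integers(270, 481))
    d1 = off - CDS1[0]
    truncating = rng.random() < 0.5
    d2 = int(rng.integers(9, 46))
    rem = (d1 + d2) % 3
    if truncating and rem != 0:
        d2 += 3 - rem
    elif not truncating and rem == 0:
        d2 += 1
    t = make_tsr(gene.strand, gene.chrom, gene.sense_to_genomic(off), "CDS", gene.id)
    fill = "".join(rng.choice(list("CT"), size=d2 - 1))
    _write_sense(seq_arrays, gene.chrom, gene.strand, t.peak, 0, "G" + fill + "ATG")
    t.orf_outcome = "truncation" if (d1 + d2) % 3 == 0 else "frameshift"
    t.orf_delta_aa = (d1 + d2) // 3 if t.orf_outcome == "truncation" else None
    t.orf_new_start = gene.sense_to_genomic(off + d2)
    return t


def _plant_motifs(config, rng, tsrs: list[SimTsr], seq_arrays) -> None:
    for t in tsrs:
        if t.category == "promoter":
            if rng.random() < config.tata_plant_rate:
                w1, w2 = rng.choice(list("AT"), size=2)
                r = str(rng.choice(list("AG")))
                motif = f"TATA{w1}A{w2}{r}"
                _write_sense(seq_arrays, t.chrom, t.strand, t.peak, -30, motif)
                t.tata_planted = True
        if t.category in ("promoter", "5UTR"):
            if rng.random() < config.pypu_plant_rate:
                dinuc = str(
                    rng.choice(["CA", "TG", "CG", "TA"], p=[0.4, 0.4, 0.1, 0.1])
                )
                _write_sense(seq_arrays, t.chrom, t.strand, t.peak, -1, dinuc)
                t.pypu_planted = True


def _free_zones(config: SimConfig, genes: list[SimGene]):
    clearance = 700
    zones = []
    for chrom in config.chrom_names:
        blocks = sorted(
            (g.start - clearance, g.end + clearance)
            for g in genes
            if g.chrom == chrom
        )
        cursor = 100
        for s, e in blocks:
            if s - cursor >= 200:
                zones.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if config.genome_length - 100 - cursor >= 200:
            zones.append((chrom, cursor, config.genome_length - 100))
    return zones


def _pick_intergenic(rng, zones, placed, min_sep: int = 700, tries: int = 200):
    if not zones:
        return None
    weights = np.array([e - s for _, s, e in zones], dtype=float)
    weights /= weights.sum()
    for _ in range(tries):
        chrom, s, e = zones[int(rng.choice(len(zones), p=weights))]
        pos = int(rng.integers(s + 40, e - 40))
        if all(c != chrom or abs(pos - p) >= min_sep for c, p in placed):
            return chrom, pos
    return None


def _assign_presence(config: SimConfig, rng, tsrs: list[SimTsr]) -> None:
    tissues = list(config.tissue_names)
    model = config.tissue_presence_model
    for t in tsrs:
        if rng.random() < model["specific_fraction"]:
            present = [tissues[int(rng.integers(len(tissues)))]]
        else:
            present = [x for x in tissues if rng.random() < model["presence_prob"]]
            if not present:
                present = [tissues[int(rng.integers(len(tissues)))]]
        t.tissues = sorted(present, key=tissues.index)
        t.tissue_scale = {x: int(rng.integers(1, 4)) for x in t.tissues}


# ---------------------------------------------------------------------------
# CTSS emission


def generate_ctss(
    sg: SyntheticGenome, outdir=None, tissues: list[str] | None = None
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Per-tissue CTSS tables (chrom, pos, strand, count) plus a background log.

    Planted TSRs contribute their profile (times the tissue scale
    factor) in tissues where they are present; background positions
    receive single counts at ``background_rate`` per kb per tissue.
    Duplicate positions are summed.  Returns ``(tracks, background_log)``
    where the log records the number of background events drawn per
    tissue, so emitted totals can be reconciled with planted totals.
    """
    config = sg.config
    if tissues is None:
        tissues = list(config.tissue_names)
    unknown = set(tissues) - set(config.tissue_names)
    if unknown:
        raise ValueError(f"unknown tissue name(s): {sorted(unknown)}")
    rng = np.random.default_rng([config.seed, 1])
    genome_kb = config.genome_length * config.n_chromosomes / 1000.0
    tracks: dict[str, pd.DataFrame] = {}
    bg_log: dict[str, int] = {}
    for tissue in tissues:
        rows = []
        for t in sg.tsrs:
            if tissue not in t.tissues:
                continue
            scale = t.tissue_scale.get(tissue, 1)
            for pos, count in zip(t.positions, t.counts):
                rows.append((t.chrom, pos, t.strand, count * scale))
        n_bg = int(rng.poisson(config.background_rate * genome_kb))
        bg_log[tissue] = n_bg
        for _ in range(n_bg):
            chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
            pos = int(rng.integers(config.genome_length))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, pos, strand, 1))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
        if len(df):
            df = (
                df.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
                .sum()
                .sort_values(["chrom", "pos", "strand"])
                .reset_index(drop=True)
            )
        tracks[tissue] = df
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tissue, df in tracks.items():
            bed = pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["pos"],
                    "end": df["pos"] + 1,
                    "name": ".",
                    "score": df["count"],
                    "strand": df["strand"],
                }
            )
            bed.to_csv(outdir / f"{tissue}.ctss.bed", sep="\t", header=False, index=False)
        with open(outdir / "background_log.json", "w") as fh:
            json.dump(bg_log, fh, indent=1)
    return tracks, bg_log


# ---------------------------------------------------------------------------
# file writers


def _write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _gene_intervals(gene: SimGene):
    """Genomic (0-based half-open) intervals for each feature of a gene."""
    def span(a, b):
        if gene.strand == "+":
            return (gene.tss + a, gene.tss + b)
        return (gene.tss - b + 1, gene.tss - a + 1)

    return {
        "five_prime_UTR": [span(0, UTR5_LEN)],
        "CDS": [span(*CDS1), span(*CDS2)],
        "three_prime_UTR": [span(*UTR3)],
        "exon": [span(*EXON1), span(*EXON2)],
    }


def _write_gff3(sg: SyntheticGenome, path) -> None:
    config = sg.config
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in config.chrom_names:
            fh.write(f"##sequence-region {chrom} 1 {config.genome_length}\n")
        for gene in sg.genes:
            s, e = gene.start + 1, gene.end  # 1-based inclusive
            mrna_id = f"{gene.id}.1"
            fh.write(
                f"{gene.chrom}\ttsratlas_sim\tgene\t{s}\t{e}\t.\t{gene.strand}\t.\tID={gene.id}\n"
            )
            fh.write(
                f"{gene.chrom}\ttsratlas_sim\tmRNA\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={mrna_id};Parent={gene.id}\n"
            )
            intervals = _gene_intervals(gene)
            for ftype in ("exon", "five_prime_UTR", "CDS", "three_prime_UTR"):
                for i, (fs, fe) in enumerate(sorted(intervals[ftype])):
                    phase = "0" if ftype == "CDS" else "."
                    fh.write(
                        f"{gene.chrom}\ttsratlas_sim\t{ftype}\t{fs + 1}\t{fe}\t.\t"
                        f"{gene.strand}\t{phase}\tID={mrna_id}.{ftype}.{i + 1};Parent={mrna_id}\n"
                    )
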