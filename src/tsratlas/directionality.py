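"""Bidirectional (divergent) TSR pairing and antisense/sense pairing.

Two opposite-strand TSRs form a bidirectional pair when they are
divergently oriented (the minus-strand TSR lies 5' of -- i.e. left of --
the plus-strand TSR in reference coordinates, so transcription points
away on both sides) and their outermost boundaries are within
``max_span`` bp (600 by default).  Each TSR joins at most one pair; the
nearest partner wins, with ties resolved toward the larger pooled
abundance.

Pairs are classified against the gene model:

* ``mRNA-mRNA`` — both members are promoter TSRs of two distinct genes;
* ``mRNA-PROMPT`` — exactly one member is a promoter TSR; the other
  initiates within ``max_span`` upstream of that same gene's annotated
  TSS and is not itself another gene's promoter (a promoter upstream
  transcript);
* ``other-divergence`` — both members are intragenic for one and the
  same gene;
* anything else is reported as ``uncategorized``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tsratlas.annotation import FeatureAssignment, GenomeModel, INTRAGENIC_CATEGORIES
from tsratlas.calling import Tsr

__all__ = [
    "BidirectionalPair",
    "AntisensePair",
    "find_bidirectional",
    "classify_bidirectional",
    "pair_antisense_sense",
    "abundance_correlation",
]


@dataclass
class BidirectionalPair:
    plus_tsr_id: str
    minus_tsr_id: str
    span: int
    category: str = "uncategorized"
    plus_abundance: dict | None = None
    minus_abundance: dict | None = None


@dataclass
class AntisensePair:
    sense_tsr_id: str
    antisense_tsr_id: str
    gene_id: str
    sense_abundance: dict
    antisense_abundance: dict
    correlation: float | None = None


def _divergent_span(minus: Tsr, plus: Tsr) -> int | None:
    """Outermost-boundary span of a divergent (minus left of plus) pair."""
    if minus.peak > plus.peak:
        return None  # convergent or crossed arrangement
    return plus.end - minus.start


def find_bidirectional(tsrs: list[Tsr], max_span: int = 600) -> list[BidirectionalPair]:
    """All divergent opposite-strand pairs within ``max_span``, greedily matched."""
    by_chrom: dict[str, dict[str, list[Tsr]]] = {}
    for t in tsrs:
        by_chrom.setdefault(t.chrom, {"+": [], "-": []})[t.strand].append(t)
    candidates = []
    for chrom, strands in by_chrom.items():
        for minus in strands["-"]:
            for plus in strands["+"]:
                span = _divergent_span(minus, plus)
                if span is not None and 0 < span <= max_span:
                    candidates.append((span, minus, plus))
    # nearest partner wins; ties toward larger combined pooled abundance
    candidates.sort(
        key=lambda c: (c[0], -(c[1].pooled_abundance + c[2].pooled_abundance), c[1].id, c[2].id)
    )
    used: set[str] = set()
    pairs = []
    for span, minus, plus in candidates:
        if minus.id in used or plus.id in used:
            continue
        used.update((minus.id, plus.id))
        pairs.append(
            BidirectionalPair(
                plus_tsr_id=plus.id,
                minus_tsr_id=minus.id,
                span=span,
                plus_abundance=dict(plus.abundance),
                minus_abundance=dict(minus.abundance),
            )
        )
    pairs.sort(key=lambda p: (p.plus_tsr_id, p.minus_tsr_id))
    return pairs


def _upstream_distance(peak: int, tx) -> int:
    """Distance from ``peak`` to the transcript's TSS, positive when upstream."""
    return tx.tss - peak if tx.strand == "+" else peak - tx.tss


def classify_bidirectional(
    pair: BidirectionalPair,
    model: GenomeModel,
    assignments: dict[str, FeatureAssignment],
    tsr_by_id: dict[str, Tsr],
    max_span: int = 600,
) -> str:
    """Assign one of mRNA-mRNA / mRNA-PROMPT / other-divergence / uncategorized."""
    a = assignments[pair.plus_tsr_id]
    b = assignments[pair.minus_tsr_id]
    if a.category == "promoter" and b.category == "promoter":
        if a.gene_id != b.gene_id:
            pair.category = "mRNA-mRNA"
            return pair.category
    elif (a.category == "promoter") != (b.category == "promoter"):
        prom, other = (a, b) if a.category == "promoter" else (b, a)
        tx = model.transcripts[prom.transcript_id]
        other_tsr = tsr_by_id[other.tsr_id]
        d = _upstream_distance(other_tsr.five_prime_boundary(), tx)
        if 0 < d <= max_span:
            pair.category = "mRNA-PROMPT"
            return pair.category
    elif (
        a.category in INTRAGENIC_CATEGORIES
        and b.category in INTRAGENIC_CATEGORIES
        and a.gene_id is not None
        and a.gene_id == b.gene_id
    ):
        pair.category = "other-divergence"
        return pair.category
    pair.category = "uncategorized"
    return pair.category


def pair_antisense_sense(
    tsrs: list[Tsr], assignments: dict[str, FeatureAssignment]
) -> tuple[list[AntisensePair], list[str]]:
    """Pair each antisense TSR with its host gene's most abundant sense TSR.

    Returns (pairs, unpaired antisense TSR ids) — an antisense TSR over a
    gene with no detected sense TSR stays unpaired but is still listed.
    """
    by_id = {t.id: t for t in tsrs}
    sense_by_gene: dict[str, list[Tsr]] = {}
    for tid, a in assignments.items():
        if a.gene_id is not None and a.category not in ("antisense", "intergenic"):
            sense_by_gene.setdefault(a.gene_id, []).append(by_id[tid])
    pairs, unpaired = [], []
    for tid, a in sorted(assignments.items()):
        if a.category != "antisense":
            continue
        senses = sense_by_gene.get(a.gene_id, [])
        if not senses:
            unpaired.append(tid)
            continue
        best = max(senses, key=lambda t: (t.pooled_abundance, t.id))
        anti = by_id[tid]
        pairs.append(
            AntisensePair(
                sense_tsr_id=best.id,
                antisense_tsr_id=tid,
                gene_id=a.gene_id,
                sense_abundance=dict(best.abundance),
                antisense_abundance=dict(anti.abundance),
                correlation=abundance_correlation(best.abundance, anti.abundance),
            )
        )
    return pairs, unpaired


def abundance_correlation(
    a: dict[str, float], b: dict[str, float], tissues: list[str] | None = None
) -> float | None:
    """Pearson r of two per-tissue abundance vectors; None when undefined
    (< 3 tissues, or either vector constant)."""
    if tissues is None:
        tissues = sorted(set(a) & set(b))
    if len(tissues) < 3:
        return None
    x = np.array([a[t] for t in tissues], dtype=float)
    y = np.array([b[t] for t in tissues], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])
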