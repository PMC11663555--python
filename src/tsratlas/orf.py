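"""ORF consequences of coding-region transcription initiation.

For a TSR whose peak lies within (or downstream of) the annotated start
codon of a transcript, the downstream spliced sequence is scanned for
the first AUG.  If its offset from the annotated start codon, measured
in coding (spliced) coordinates, is a multiple of 3 the predicted
product is an N-terminally truncated protein (delta_aa = offset / 3);
otherwise the first downstream AUG is out of frame with the annotated
CDS (frameshift).  Peaks at or 5' of the annotated start are reported
as ``upstream_equivalent``; an AUG-free downstream sequence yields
``no_start``.  Scanning looks for AUG only — intervening stop codons do
not end the scan — but a truncated ORF that terminates before the
annotated stop is flagged with its own length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from tsratlas.annotation import Transcript

__all__ = [
    "OrfConsequence",
    "transcript_sequence",
    "downstream_transcript",
    "predict_orf_change",
]


@dataclass
class OrfConsequence:
    tsr_id: str
    gene_id: str
    transcript_id: str
    outcome: str  # truncation | frameshift | no_start | upstream_equivalent
    delta_aa: int | None = None
    new_start_genomic: int | None = None
    premature_stop: bool = False
    new_protein_len: int | None = None


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    return str(genome[chrom][start:end]).upper()


def transcript_sequence(tx: Transcript, genome) -> tuple[str, np.ndarray]:
    """Spliced transcript sequence (5'->3') and the matching genomic positions."""
    parts, pos = [], []
    for s, e in tx.exons:
        parts.append(_fetch(genome, tx.chrom, s, e))
        pos.append(np.arange(s, e))
    seq = "".join(parts)
    posmap = np.concatenate(pos) if pos else np.array([], dtype=int)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        posmap = posmap[::-1]
    return seq, posmap


def _transcript_index(tx: Transcript, posmap: np.ndarray, genomic_pos: int) -> int:
    """Transcript coordinate of a genomic position; intronic positions snap
    to the first exonic base downstream (strand-aware).

    Raises ValueError when the position is 3' of the last exonic base.
    """
    hits = np.nonzero(posmap == genomic_pos)[0]
    if hits.size:
        return int(hits[0])
    # intronic: next exonic base in the direction of transcription
    if tx.strand == "+":
        downstream = np.nonzero(posmap > genomic_pos)[0]
    else:
        downstream = np.nonzero(posmap < genomic_pos)[0]
    if downstream.size == 0:
        raise ValueError(
            f"position {genomic_pos} is 3' of the last exon of {tx.id}: empty downstream sequence"
        )
    return int(downstream[0])


def downstream_transcript(peak: int, tx: Transcript, genome) -> str:
    """Spliced exonic sequence from the peak (inclusive) to the transcript 3' end."""
    seq, posmap = transcript_sequence(tx, genome)
    return seq[_transcript_index(tx, posmap, peak):]


def _cds_start_index(tx: Transcript, posmap: np.ndarray) -> int:
    if tx.strand == "+":
        genomic_start = min(s for s, _ in tx.cds)
    else:
        genomic_start = max(e for _, e in tx.cds) - 1
    return int(np.nonzero(posmap == genomic_start)[0][0])


def predict_orf_change(tsr, tx: Transcript, genome) -> OrfConsequence:
    """Predicted protein-level consequence of initiating at the TSR peak."""
    if not tx.coding:
        raise ValueError(f"transcript {tx.id} is noncoding; ORF consequence undefined")
    seq, posmap = transcript_sequence(tx, genome)
    s0 = _cds_start_index(tx, posmap)
    p = _transcript_index(tx, posmap, tsr.peak)
    base = dict(tsr_id=tsr.id, gene_id=tx.gene_id, transcript_id=tx.id)
    if p <= s0:
        return OrfConsequence(outcome="upstream_equivalent", **base)
    i = seq.find("ATG", p)
    if i < 0:
        return OrfConsequence(outcome="no_start", **base)
    offset = i - s0
    new_start_genomic = int(posmap[i])
    if offset % 3 != 0:
        return OrfConsequence(
            outcome="frameshift", new_start_genomic=new_start_genomic, **base
        )
    # in frame: check whether the truncated ORF reaches the annotated stop
    annotated_len = _protein_length(seq, s0)
    new_len = _protein_length(seq, i)
    premature = (annotated_len is not None and new_len is not None
                 and new_len + offset // 3 != annotated_len)
    return OrfConsequence(
        outcome="truncation",
        delta_aa=offset // 3,
        new_start_genomic=new_start_genomic,
        premature_stop=bool(premature),
        new_protein_len=new_len,
        **base,
    )


def _protein_length(seq: str, start: int) -> int | None:
    """Residues from ``start`` to the first in-frame stop (None if no stop)."""
    frame = seq[start : start + (len(seq) - start) // 3 * 3]
    aa = str(Seq(frame).translate())
    stop = aa.find("*")
    return stop if stop >= 0 else None
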