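"""Sequence and signal context around TSR peaks.

Windows are strand-aware: minus-strand windows are reverse-complemented
so that "upstream" is always to the left.  Offsets follow the promoter
convention: the peak base is +1, the first upstream base is -1, and
there is no offset 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tsratlas.util import PURINES, PYRIMIDINES, iupac_regex, revcomp

__all__ = [
    "PositionalProfile",
    "extract_windows",
    "offset_labels",
    "pypu_profile",
    "tata_profile",
    "signal_metaprofile",
]


@dataclass
class PositionalProfile:
    offsets: np.ndarray
    values: np.ndarray
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values})

    def argmax_offset(self, lo: int | None = None, hi: int | None = None) -> int:
        """Offset of the maximal value, optionally restricted to [lo, hi]."""
        mask = np.ones(len(self.offsets), dtype=bool)
        if lo is not None:
            mask &= self.offsets >= lo
        if hi is not None:
            mask &= self.offsets <= hi
        idx = np.nonzero(mask)[0]
        return int(self.offsets[idx[np.argmax(self.values[idx])]])


def offset_labels(upstream: int, n: int) -> np.ndarray:
    """Peak-relative labels for window indices 0..n-1 (peak=+1, no zero)."""
    raw = np.arange(n) - upstream
    return np.where(raw >= 0, raw + 1, raw)


def extract_windows(
    peaks, genome, upstream: int, downstream: int
) -> tuple[list[str], int]:
    """Fixed-width sequence windows around peaks.

    ``peaks`` is an iterable of (chrom, position, strand).  Each window
    has length upstream+downstream+1 with the peak base at index
    ``upstream``; minus-strand windows are reverse-complemented.  Peaks
    whose window would be clipped at a chromosome edge are dropped and
    counted in the returned total.
    """
    seqs, dropped = [], 0
    for chrom, pos, strand in peaks:
        if strand == "+":
            s, e = pos - upstream, pos + downstream + 1
        else:
            s, e = pos - downstream, pos + upstream + 1
        chrom_seq = genome[chrom]
        if s < 0 or e > len(chrom_seq):
            dropped += 1
            continue
        seq = str(chrom_seq[s:e]).upper()
        if strand == "-":
            seq = revcomp(seq)
        seqs.append(seq)
    return seqs, dropped


def pypu_profile(sequences: list[str], upstream: int):
    """Initiator dinucleotide composition and positional PyPu frequency.

    Returns ``(dinucleotide_table, profile)``: a 16-entry frequency
    table for the (-1, +1) dinucleotide flanking the peak, and a
    per-offset frequency of pyrimidine-then-purine dinucleotides across
    the window (labelled by the first base's offset).  Windows with
    ambiguous bases at a position are excluded from that denominator.
    """
    if not sequences:
        raise ValueError("no sequences")
    length = len(sequences[0])
    table: dict[str, int] = {}
    valid_init = 0
    for seq in sequences:
        dinuc = seq[upstream - 1 : upstream + 1]
        if set(dinuc) <= set("ACGT"):
            table[dinuc] = table.get(dinuc, 0) + 1
            valid_init += 1
    freq_table = pd.Series(
        {
            a + b: table.get(a + b, 0) / valid_init if valid_init else np.nan
            for a in "ACGT"
            for b in "ACGT"
        }
    )
    offsets = offset_labels(upstream, length - 1)
    values = np.zeros(length - 1)
    for i in range(length - 1):
        ok = hit = 0
        for seq in sequences:
            a, b = seq[i], seq[i + 1]
            if a in "ACGT" and b in "ACGT":
                ok += 1
                hit += a in PYRIMIDINES and b in PURINES
        values[i] = hit / ok if ok else np.nan
    return freq_table, PositionalProfile(offsets, values, len(sequences))


def tata_profile(
    sequences: list[str], upstream: int, consensus: str = "TATAWAWR"
) -> PositionalProfile:
    """Per-offset frequency of IUPAC consensus matches beginning there.

    The summary statistic of interest is the argmax offset within the
    upstream core-promoter region (use ``argmax_offset(-50, -10)``); a
    planted TATA-box 30 bp upstream of the peak shows up at -30.
    """
    if not sequences:
        raise ValueError("no sequences")
    pattern = re.compile(iupac_regex(consensus))
    length = len(sequences[0])
    n_offsets = length - len(consensus) + 1
    # per-position match tests (finditer would skip overlapping matches)
    hits = np.zeros(n_offsets)
    for seq in sequences:
        for i in range(n_offsets):
            if pattern.match(seq, i):
                hits[i] += 1
    offsets = offset_labels(upstream, n_offsets)
    return PositionalProfile(offsets, hits / len(sequences), len(sequences))


def _bedgraph_arrays(track, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    arrays = {c: np.zeros(l) for c, l in chrom_lengths.items()}
    if isinstance(track, dict):
        items = track
        for chrom, arr in items.items():
            arrays[chrom] = np.asarray(arr, dtype=float)
        return arrays
    bg = pd.read_csv(
        track,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
    )
    for row in bg.itertuples(index=False):
        if row.chrom in arrays:
            arrays[row.chrom][row.start : row.end] = row.value
    return arrays


def signal_metaprofile(
    peaks,
    signal,
    chrom_lengths: dict[str, int],
    flank: int = 2000,
    bin_size: int = 50,
) -> PositionalProfile:
    """Mean per-bin signal around peaks, strand-flipped so upstream is left.

    ``signal`` is a bedGraph path or a dict chrom -> value array; bases
    without data count as 0.  The window covers [-flank, +flank) around
    each peak in bins of ``bin_size``.
    """
    arrays = _bedgraph_arrays(signal, chrom_lengths)
    width = 2 * flank
    n_bins = width // bin_size
    acc = np.zeros(n_bins)
    n_sites = 0
    for chrom, pos, strand in peaks:
        arr = arrays.get(chrom)
        if arr is None:
            continue
        s, e = pos - flank, pos + flank
        window = np.zeros(width)
        lo, hi = max(0, s), min(len(arr), e)
        if hi > lo:
            window[lo - s : hi - s] = arr[lo:hi]
        if strand == "-":
            window = window[::-1]
        acc += window[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
        n_sites += 1
    if n_sites == 0:
        raise ValueError("no usable peaks for metaprofile")
    offsets = np.arange(n_bins) * bin_size - flank + bin_size // 2
    return PositionalProfile(offsets, acc / n_sites, n_sites)
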