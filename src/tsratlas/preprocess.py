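"""Read-structure preprocessing for 5'-cap-selective libraries.

Read 1 of such a library begins with a UMI followed by the literal
template-switching signature TATAGGG.  The stage mirrors the standard
processing order: (1) drop reads shorter than ``min_length`` or lacking
the pattern near the read start, (2) collapse byte-identical sequences
(which subsumes UMI identity), (3) trim everything through the first
in-window pattern occurrence, appending the removed UMI to the read
name.  Quality strings are trimmed in lockstep; collapsed duplicates
keep the first-seen representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from tsratlas.util import open_text

__all__ = [
    "ReadFilterConfig",
    "ReadFateReport",
    "filter_reads",
    "collapse_duplicates",
    "trim_prefix",
    "preprocess_reads",
]


@dataclass
class ReadFilterConfig:
    min_length: int = 50
    pattern: str = "TATAGGG"
    umi_length: int = 8
    pattern_search_window: int | None = None  # default: umi_length + 3

    def __post_init__(self) -> None:
        if self.pattern_search_window is None:
            self.pattern_search_window = self.umi_length + 3
        if self.min_length <= self.umi_length + len(self.pattern):
            raise ValueError("min_length must exceed umi_length + pattern length")
        if self.pattern_search_window < self.umi_length:
            raise ValueError("pattern_search_window must be >= umi_length")


@dataclass
class ReadFateReport:
    input_reads: int = 0
    removed_short: int = 0
    removed_no_pattern: int = 0
    collapsed_duplicates: int = 0
    surviving_reads: int = 0

    def check(self) -> None:
        total = (
            self.surviving_reads
            + self.removed_short
            + self.removed_no_pattern
            + self.collapsed_duplicates
        )
        if total != self.input_reads:
            raise AssertionError("read-fate conservation identity violated")


def _parse(fastq_in):
    with open_text(fastq_in) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
            yield i, rec


def _pattern_start(seq: str, config: ReadFilterConfig) -> int:
    idx = seq.find(config.pattern)
    if 0 <= idx <= config.pattern_search_window:
        return idx
    return -1


def filter_reads(fastq_in, fastq_out, config: ReadFilterConfig | None = None) -> ReadFateReport:
    """Keep reads >= min_length that contain the pattern within the window."""
    config = config or ReadFilterConfig()
    report = ReadFateReport()
    with open_text(fastq_out, "wt") as out:
        for _, rec in _parse(fastq_in):
            report.input_reads += 1
            seq = str(rec.seq)
            if len(seq) < config.min_length:
                report.removed_short += 1
            elif _pattern_start(seq, config) < 0:
                report.removed_no_pattern += 1
            else:
                report.surviving_reads += 1
                SeqIO.write(rec, out, "fastq")
    return report


def collapse_duplicates(fastq_in, fastq_out) -> int:
    """One representative (first occurrence) per distinct sequence.

    Returns the number of reads removed as duplicates.
    """
    seen: set[str] = set()
    collapsed = 0
    with open_text(fastq_out, "wt") as out:
        for _, rec in _parse(fastq_in):
            seq = str(rec.seq)
            if seq in seen:
                collapsed += 1
                continue
            seen.add(seq)
            SeqIO.write(rec, out, "fastq")
    return collapsed


def trim_prefix(fastq_in, fastq_out, config: ReadFilterConfig | None = None) -> int:
    """Remove everything through the first in-window pattern occurrence.

    The removed UMI (bases before the pattern) is appended to the read
    name after an underscore; qualities are trimmed in lockstep.  A read
    without an in-window pattern is a hard error (should not occur after
    filtering).
    """
    config = config or ReadFilterConfig()
    n = 0
    with open_text(fastq_out, "wt") as out:
        for i, rec in _parse(fastq_in):
            seq = str(rec.seq)
            idx = _pattern_start(seq, config)
            if idx < 0:
                raise ValueError(f"read {i} ({rec.id}) lacks in-window pattern; run filter_reads first")
            cut = idx + len(config.pattern)
            umi = seq[:idx]
            quals = rec.letter_annotations["phred_quality"][cut:]
            trimmed = SeqRecord(
                rec.seq[cut:],
                id=f"{rec.id}_{umi}",
                description="",
                letter_annotations={"phred_quality": quals},
            )
            SeqIO.write(trimmed, out, "fastq")
            n += 1
    return n


def preprocess_reads(
    fastq_in, fastq_out, config: ReadFilterConfig | None = None, workdir=None
) -> ReadFateReport:
    """filter -> collapse -> trim, reporting read fates across all stages."""
    import tempfile
    from pathlib import Path

    config = config or ReadFilterConfig()
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        filtered = Path(tmp) / "filtered.fastq"
        collapsed = Path(tmp) / "collapsed.fastq"
        report = filter_reads(fastq_in, filtered, config)
        report.collapsed_duplicates = collapse_duplicates(filtered, collapsed)
        report.surviving_reads -= report.collapsed_duplicates
        trim_prefix(collapsed, fastq_out, config)
    report.check()
    return report
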