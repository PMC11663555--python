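"""Small shared helpers: strand arithmetic, IUPAC codes, transparent IO."""

from __future__ import annotations

import gzip
import io
from typing import IO

_COMPLEMENT = str.maketrans("ACGTRYKMWSNacgtrykmwsn", "TGCAYRMKWSNtgcayrmkwsn")

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(consensus: str) -> str:
    """Translate an IUPAC consensus into a regular expression.

    Raises ValueError on characters outside the IUPAC nucleotide alphabet.
    """
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code in consensus: {ch!r}")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def open_text(path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return io.open(path, mode)
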