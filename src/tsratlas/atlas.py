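"""Tissue atlas: presence calls, dominant TSRs, and pairwise ATI groups.

A TSR is "present" in a tissue when its per-tissue abundance is at least
``presence_min_tpm`` (1 TPM by default).  For a gene and an ordered pair
of tissues, let A and B be its present TSR sets; the gene is classified:

* Group 1 — a single TSR in each tissue, shared (A = B, |A| = 1);
* Group 2 — a single TSR in each tissue, not shared;
* Group 3 — multiple TSRs, all shared (A = B, |A| > 1);
* Group 4 — multiple TSRs, dominant TSR shared but >= 1 TSR unshared;
* Group 5 — multiple TSRs, the two tissues' dominant TSRs not shared;
* Group 6 — TSRs present in exactly one of the two tissues.

Group 2*/5* are the subsets of Groups 2/5 whose unshared coding-region
TSRs are predicted to truncate or frameshift the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from tsratlas.annotation import FeatureAssignment
from tsratlas.calling import Tsr

__all__ = [
    "GenePairClass",
    "presence_matrix",
    "presence_histogram",
    "dominant_tsr",
    "classify_gene_pairwise",
    "classify_all_genes",
    "star_subset",
    "group_summary",
]


@dataclass
class GenePairClass:
    gene_id: str
    tissue_a: str
    tissue_b: str
    group: int
    star: bool = False
    unshared_tsrs: list[str] = field(default_factory=list)


def presence_matrix(tsrs: list[Tsr], presence_min_tpm: float = 1.0) -> pd.DataFrame:
    """Boolean TSR x tissue matrix: present iff abundance >= threshold."""
    tissues = sorted(tsrs[0].abundance) if tsrs else []
    data = {
        t.id: [t.abundance.get(tissue, 0.0) >= presence_min_tpm for tissue in tissues]
        for t in tsrs
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=tissues)


def presence_histogram(presence: pd.DataFrame) -> pd.Series:
    """Number of TSRs present in a given number of tissues (index = n tissues)."""
    row_sums = presence.sum(axis=1).astype(int)
    return row_sums.value_counts().sort_index()


def _five_prime_key(tsr: Tsr) -> int:
    # ordering key so that min() picks the 5'-most peak on either strand
    return tsr.peak if tsr.strand == "+" else -tsr.peak


def dominant_tsr(
    gene_tsrs: list[Tsr], tissue: str, presence: pd.DataFrame
) -> str | None:
    """The gene's present TSR with maximal abundance in ``tissue``.

    Ties break toward the 5'-most peak (strand-aware).  None when the
    gene has no present TSR in the tissue.
    """
    present = [t for t in gene_tsrs if bool(presence.loc[t.id, tissue])]
    if not present:
        return None
    best = max(t.abundance.get(tissue, 0.0) for t in present)
    tied = [t for t in present if t.abundance.get(tissue, 0.0) == best]
    return min(tied, key=_five_prime_key).id


def classify_gene_pairwise(
    gene_id: str,
    tissue_a: str,
    tissue_b: str,
    gene_tsrs: list[Tsr],
    presence: pd.DataFrame,
) -> GenePairClass | None:
    """Group 1-6 label for one gene and one tissue pair (None if no TSR in either)."""
    set_a = {t.id for t in gene_tsrs if bool(presence.loc[t.id, tissue_a])}
    set_b = {t.id for t in gene_tsrs if bool(presence.loc[t.id, tissue_b])}
    if not set_a and not set_b:
        return None
    unshared = sorted(set_a ^ set_b)
    if not set_a or not set_b:
        group = 6
    elif len(set_a) == 1 and len(set_b) == 1:
        group = 1 if set_a == set_b else 2
    elif set_a == set_b:
        group = 3
    else:
        dom_a = dominant_tsr(gene_tsrs, tissue_a, presence)
        dom_b = dominant_tsr(gene_tsrs, tissue_b, presence)
        group = 4 if dom_a == dom_b else 5
    return GenePairClass(gene_id, tissue_a, tissue_b, group, unshared_tsrs=unshared)


def classify_all_genes(
    tsrs: list[Tsr],
    assignments: dict[str, FeatureAssignment],
    presence: pd.DataFrame,
    tissue_pairs: list[tuple[str, str]] | None = None,
) -> list[GenePairClass]:
    """Classify every gene with sense TSRs over every tissue pair."""
    by_gene: dict[str, list[Tsr]] = {}
    by_id = {t.id: t for t in tsrs}
    for tid, a in assignments.items():
        if a.gene_id is not None and a.category not in ("antisense", "intergenic"):
            by_gene.setdefault(a.gene_id, []).append(by_id[tid])
    if tissue_pairs is None:
        tissue_pairs = list(combinations(presence.columns, 2))
    out = []
    for ta, tb in tissue_pairs:
        for gene_id in sorted(by_gene):
            cls = classify_gene_pairwise(gene_id, ta, tb, by_gene[gene_id], presence)
            if cls is not None:
                out.append(cls)
    return out


def star_subset(
    cls: GenePairClass,
    assignments: dict[str, FeatureAssignment],
    orf_records: dict[str, "object"],
) -> bool:
    """Star flag for Group 2/5: an unshared CDS-category TSR whose predicted
    ORF consequence is a truncation or frameshift."""
    if cls.group not in (2, 5):
        cls.star = False
        return False
    star = False
    for tid in cls.unshared_tsrs:
        a = assignments.get(tid)
        if a is None or a.category != "CDS":
            continue
        rec = orf_records.get(tid)
        if rec is not None and rec.outcome in ("truncation", "frameshift"):
            star = True
            break
    cls.star = star
    return star


def group_summary(classes: list[GenePairClass]) -> pd.DataFrame:
    """Per-tissue-pair percentages for Groups 1-6 plus 2*/5*.

    Group 1-6 percentages are over all classified genes of the pair;
    2*/5* percentages are relative to the Group 2/5 totals.
    """
    rows = []
    by_pair: dict[tuple[str, str], list[GenePairClass]] = {}
    for c in classes:
        by_pair.setdefault((c.tissue_a, c.tissue_b), []).append(c)
    for (ta, tb), group in sorted(by_pair.items()):
        total = len(group)
        counts = {g: sum(1 for c in group if c.group == g) for g in range(1, 7)}
        stars = {g: sum(1 for c in group if c.group == g and c.star) for g in (2, 5)}
        row = {"tissue_a": ta, "tissue_b": tb, "n_genes": total}
        for g in range(1, 7):
            row[f"group{g}_pct"] = 100.0 * counts[g] / total if total else np.nan
        for g in (2, 5):
            row[f"group{g}star_pct"] = (
                100.0 * stars[g] / counts[g] if counts[g] else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
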