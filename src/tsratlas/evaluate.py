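"""Recovery metrics: called TSRs versus the synthetic truth manifest.

A planted TSR counts as recovered when some called TSR on the same
chromosome and strand contains its peak.  Shape, category, presence and
pair recovery are all evaluated on that matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from tsratlas.calling import Tsr
from tsratlas.simulate import SimTsr, SyntheticGenome


@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int
    n_span_exact: int
    n_shape_correct: int
    n_category_correct: int | None = None
    presence_correct: int = 0
    presence_total: int = 0

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")

    @property
    def shape_accuracy(self) -> float:
        return self.n_shape_correct / self.n_recovered if self.n_recovered else float("nan")

    @property
    def presence_accuracy(self) -> float:
        return (
            self.presence_correct / self.presence_total
            if self.presence_total
            else float("nan")
        )


def match_planted(planted: list[SimTsr], called: list[Tsr]) -> dict[str, Tsr | None]:
    """Map each planted TSR id to the called TSR containing its peak (or None)."""
    by_key: dict[tuple[str, str], list[Tsr]] = {}
    for t in called:
        by_key.setdefault((t.chrom, t.strand), []).append(t)
    out: dict[str, Tsr | None] = {}
    for p in planted:
        hit = None
        for t in by_key.get((p.chrom, p.strand), []):
            if t.start <= p.peak < t.end:
                hit = t
                break
        out[p.id] = hit
    return out


def recovery_report(
    sg: SyntheticGenome,
    called: list[Tsr],
    assignments: dict | None = None,
    presence: pd.DataFrame | None = None,
    presence_min_tpm: float = 1.0,
) -> RecoveryReport:
    matches = match_planted(sg.tsrs, called)
    n_rec = sum(1 for m in matches.values() if m is not None)
    n_span = 0
    n_shape = 0
    n_cat = 0 if assignments is not None else None
    pres_ok = pres_tot = 0
    by_id = {p.id: p for p in sg.tsrs}
    for pid, m in matches.items():
        p = by_id[pid]
        if m is None:
            continue
        if (m.start, m.end) == (p.start, p.end):
            n_span += 1
        if m.shape == p.shape:
            n_shape += 1
        if assignments is not None:
            a = assignments.get(m.id)
            if a is not None and a.category == p.category:
                n_cat += 1
        if presence is not None:
            for tissue in presence.columns:
                pres_tot += 1
                truth = tissue in p.tissues
                if bool(presence.loc[m.id, tissue]) == truth:
                    pres_ok += 1
    return RecoveryReport(
        n_planted=len(sg.tsrs),
        n_recovered=n_rec,
        n_span_exact=n_span,
        n_shape_correct=n_shape,
        n_category_correct=n_cat,
        presence_correct=pres_ok,
        presence_total=pres_tot,
    )


def planted_pairs(sg: SyntheticGenome) -> list[tuple[str, str, str]]:
    """Unique planted divergent pairs as (id_a, id_b, category), a < b."""
    seen = set()
    out = []
    for t in sg.tsrs:
        if t.partner_id is None:
            continue
        key = tuple(sorted((t.id, t.partner_id)))
        if key in seen:
            continue
        seen.add(key)
        out.append((key[0], key[1], t.pair_category))
    return out
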