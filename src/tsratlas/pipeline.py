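"""End-to-end pipeline: CTSS tracks -> TSRs -> annotation -> pairs -> groups -> ORF -> motifs.

Stages run in a fixed order with one config; every threshold is echoed
into the output manifest together with input checksums and stage row
counts, so a rerun with identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from pyfaidx import Fasta

from tsratlas.annotation import (
    DEFAULT_HIERARCHY,
    annotate_tsrs,
    build_genome_model,
    summarize_categories,
)
from tsratlas.atlas import (
    classify_all_genes,
    group_summary,
    presence_histogram,
    presence_matrix,
    star_subset,
)
from tsratlas.calling import cluster_tsrs, tsrs_to_frame
from tsratlas.context import extract_windows, pypu_profile, tata_profile
from tsratlas.ctss import filter_tss, read_ctss
from tsratlas.directionality import (
    classify_bidirectional,
    find_bidirectional,
    pair_antisense_sense,
)
from tsratlas.orf import predict_orf_change

logger = logging.getLogger("tsratlas")

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    ctss: dict[str, str]  # tissue -> CTSS BED path
    gff3: str
    fasta: str
    outdir: str
    min_tpm: float = 1.0
    max_gap: int = 20
    iqr_narrow_max: int = 4  # informational; the shape rule is IQR <= 4
    promoter_up: int = 100
    promoter_down: int = 100
    proximal_len: int = 400
    bidirectional_span: int = 600
    presence_min_tpm: float = 1.0
    hierarchy: tuple[str, ...] = DEFAULT_HIERARCHY
    motif_upstream: int = 100
    motif_downstream: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.ctss)) != len(self.ctss):
            raise ValueError("tissue names must be unique")
        for name in (
            "min_tpm", "max_gap", "promoter_up", "promoter_down", "proximal_len",
            "bidirectional_span", "presence_min_tpm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "hierarchy" in raw:
        raw["hierarchy"] = tuple(raw["hierarchy"])
    return PipelineConfig(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns in-memory results plus the output manifest."""
    from tsratlas import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    t_start = time.time()

    def stage(name: str, rows: int):
        logger.info("stage %-12s rows=%d  %.2fs", name, rows, time.time() - t_start)
        stages.append({"stage": name, "rows": rows})

    # 1: quantify
    tracks = [read_ctss(path, tissue) for tissue, path in config.ctss.items()]
    tss = filter_tss(tracks, min_tpm=config.min_tpm)
    tss.df.to_csv(outdir / "tss.tsv", sep="\t", index=False)
    stage("quantify", len(tss))

    # 2: call TSRs
    tsrs = cluster_tsrs(tss, max_gap=config.max_gap)
    tissues = tss.tissues
    tsr_frame = tsrs_to_frame(tsrs, tissues)
    tsr_frame.to_csv(outdir / "tsrs.tsv", sep="\t", index=False)
    stage("call-tsr", len(tsrs))

    # 3: annotate
    model = build_genome_model(config.gff3)
    assignments = annotate_tsrs(tsrs, model, hierarchy=config.hierarchy)
    pd.DataFrame(
        [
            {
                "tsr_id": a.tsr_id,
                "category": a.category,
                "gene_id": a.gene_id or "",
                "transcript_id": a.transcript_id or "",
            }
            for a in assignments.values()
        ]
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    stage("annotate", len(assignments))

    presence = presence_matrix(tsrs, presence_min_tpm=config.presence_min_tpm)
    presence.to_csv(outdir / "presence.tsv", sep="\t")
    summarize_categories(assignments, presence).to_csv(
        outdir / "category_summary.tsv", sep="\t", index=False
    )

    # 4: pairs
    by_id = {t.id: t for t in tsrs}
    pairs = find_bidirectional(tsrs, max_span=config.bidirectional_span)
    for p in pairs:
        classify_bidirectional(p, model, assignments, by_id, max_span=config.bidirectional_span)
    anti_pairs, unpaired = pair_antisense_sense(tsrs, assignments)
    pd.DataFrame(
        [
            {
                "plus_tsr": p.plus_tsr_id,
                "minus_tsr": p.minus_tsr_id,
                "span": p.span,
                "category": p.category,
            }
            for p in pairs
        ]
    ).to_csv(outdir / "bidirectional.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sense_tsr": p.sense_tsr_id,
                "antisense_tsr": p.antisense_tsr_id,
                "gene_id": p.gene_id,
                "correlation": "" if p.correlation is None else p.correlation,
            }
            for p in anti_pairs
        ]
    ).to_csv(outdir / "antisense_pairs.tsv", sep="\t", index=False)
    stage("pairs", len(pairs))

    # 5: ORF consequences for CDS-category TSRs
    genome = Fasta(config.fasta)
    orf_records = {}
    for tid, a in sorted(assignments.items()):
        if a.category != "CDS" or a.transcript_id is None:
            continue
        tx = model.transcripts[a.transcript_id]
        if not tx.coding:
            continue
        orf_records[tid] = predict_orf_change(by_id[tid], tx, genome)
    pd.DataFrame(
        [
            {
                "tsr_id": r.tsr_id,
                "gene_id": r.gene_id,
                "outcome": r.outcome,
                "delta_aa": "" if r.delta_aa is None else r.delta_aa,
                "new_start": "" if r.new_start_genomic is None else r.new_start_genomic,
            }
            for r in orf_records.values()
        ]
    ).to_csv(outdir / "orf_consequences.tsv", sep="\t", index=False)
    stage("orf", len(orf_records))

    # 6: pairwise-tissue groups
    classes = classify_all_genes(tsrs, assignments, presence)
    for cls in classes:
        star_subset(cls, assignments, orf_records)
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "tissue_a": c.tissue_a,
                "tissue_b": c.tissue_b,
                "group": c.group,
                "star": c.star,
            }
            for c in classes
        ]
    ).to_csv(outdir / "gene_groups.tsv", sep="\t", index=False)
    group_summary(classes).to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
    stage("groups", len(classes))

    # 7: motif profiles around peaks
    peaks = [(t.chrom, t.peak, t.strand) for t in tsrs]
    windows, dropped = extract_windows(
        peaks, genome, config.motif_upstream, config.motif_downstream
    )
    tata = tata_profile(windows, config.motif_upstream)
    dinuc, pypu = pypu_profile(windows, config.motif_upstream)
    tata.to_frame().to_csv(outdir / "tata_profile.tsv", sep="\t", index=False)
    pypu.to_frame().to_csv(outdir / "pypu_profile.tsv", sep="\t", index=False)
    dinuc.rename("frequency").to_csv(outdir / "initiator_dinucleotides.tsv", sep="\t")
    stage("motifs", len(windows))

    manifest = {
        "version": __version__,
        "config": _jsonable_config(config),
        "inputs": {
            "gff3": _sha256(config.gff3),
            "fasta": _sha256(config.fasta),
            "ctss": {t: _sha256(p) for t, p in config.ctss.items()},
        },
        "stages": stages,
        "dropped_motif_windows": dropped,
    }
    with open(outdir / "pipeline_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return {
        "tss": tss,
        "tsrs": tsrs,
        "model": model,
        "assignments": assignments,
        "presence": presence,
        "presence_histogram": presence_histogram(presence),
        "pairs": pairs,
        "antisense_pairs": anti_pairs,
        "unpaired_antisense": unpaired,
        "orf_records": orf_records,
        "classes": classes,
        "group_summary": group_summary(classes),
        "tata_profile": tata,
        "pypu_profile": pypu,
        "initiator_dinucleotides": dinuc,
        "manifest": manifest,
    }


def _jsonable_config(config: PipelineConfig) -> dict:
    raw = asdict(config)
    raw["hierarchy"] = list(raw["hierarchy"])
    return raw
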