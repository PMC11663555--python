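"""Shared fixtures: synthetic datasets and small construction helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tsratlas.calling import Tsr
from tsratlas.ctss import CtssTrack, TssSet
from tsratlas.pipeline import PipelineConfig, run_pipeline
from tsratlas.simulate import SimConfig, generate_ctss, generate_genome


def make_tsr(tsr_id, chrom, strand, positions, pooled=None, tissue_tpm=None) -> Tsr:
    positions = np.asarray(positions, dtype=np.int64)
    if pooled is None:
        pooled = np.ones(len(positions))
    pooled = np.asarray(pooled, dtype=float)
    if tissue_tpm is None:
        tissue_tpm = {"t1": pooled}
    return Tsr(
        id=tsr_id,
        chrom=chrom,
        strand=strand,
        positions=positions,
        pooled=pooled,
        tissue_tpm={k: np.asarray(v, dtype=float) for k, v in tissue_tpm.items()},
    )


def make_track(tissue, rows) -> CtssTrack:
    """rows: iterable of (chrom, pos, strand, count)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    return CtssTrack(tissue=tissue, df=df)


def make_tss(positions, pooled=None, chrom="chr1", strand="+", tissues=("t1",)) -> TssSet:
    positions = list(positions)
    if pooled is None:
        pooled = [1.0] * len(positions)
    df = pd.DataFrame({"chrom": chrom, "pos": positions, "strand": strand})
    per = np.asarray(pooled, dtype=float) / len(tissues)
    for t in tissues:
        df[f"tpm_{t}"] = per
    df["pooled"] = np.asarray(pooled, dtype=float)
    return TssSet(df=df, tissues=list(tissues), min_tpm=1.0)


def run_sim_pipeline(cfg: SimConfig, root: Path):
    sg = generate_genome(cfg, outdir=root / "sim")
    generate_ctss(sg, outdir=root / "sim")
    pc = PipelineConfig(
        ctss={t: str(root / "sim" / f"{t}.ctss.bed") for t in cfg.tissue_names},
        gff3=str(root / "sim" / "annotation.gff3"),
        fasta=str(root / "sim" / "genome.fa"),
        outdir=str(root / "out"),
    )
    return sg, pc, run_pipeline(pc)


@pytest.fixture(scope="session")
def noiseless_sim(tmp_path_factory):
    """Mid-size noiseless simulation: truth recovery should be exact."""
    cfg = SimConfig(
        n_genes=140,
        genome_length=810_000,
        background_rate=0.0,
        seed=11,
    )
    root = tmp_path_factory.mktemp("noiseless")
    sg, pc, result = run_sim_pipeline(cfg, root)
    return {"cfg": cfg, "sg": sg, "pc": pc, "result": result, "root": root}


@pytest.fixture(scope="session")
def noisy_sim(tmp_path_factory):
    """Larger 4-tissue simulation at the documented default background."""
    cfg = SimConfig(
        n_genes=200,
        genome_length=1_200_000,
        seed=23,
    )
    root = tmp_path_factory.mktemp("noisy")
    sg, pc, result = run_sim_pipeline(cfg, root)
    return {"cfg": cfg, "sg": sg, "pc": pc, "result": result, "root": root}


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    cfg = SimConfig(seed=3)
    root = tmp_path_factory.mktemp("small")
    sg, pc, result = run_sim_pipeline(cfg, root)
    return {"cfg": cfg, "sg": sg, "pc": pc, "result": result, "root": root}
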