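"""Per-tissue 5'-end count tracks: loading, TPM normalization, detection filter.

A CTSS track stores, per strand, single-base genomic positions with the
number of capped 5' ends observed there.  Abundances are normalized to
tags per million (TPM = count / library_total * 1e6) before any
filtering, and a position is retained for downstream TSR calling when
its TPM exceeds ``min_tpm`` (strictly) in at least one tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CtssTrack",
    "TssSet",
    "read_ctss",
    "read_ctss_bedgraph",
    "filter_tss",
    "pool_tissues",
    "saturation_curve",
]


@dataclass
class CtssTrack:
    """Single-tissue, strand-specific map of 5'-end positions to counts.

    ``df`` has columns ``chrom, pos, strand, count, tpm`` with one row
    per nonzero base (0-based positions), sorted by (chrom, pos, strand).
    """

    tissue: str
    df: pd.DataFrame
    library_total: float = field(init=False)

    def __post_init__(self) -> None:
        df = self.df
        if (df["count"] <= 0).any():
            raise ValueError("CTSS counts must be positive")
        # merge duplicate positions before normalizing
        df = (
            df.groupby(["chrom", "pos", "strand"], as_index=False, sort=True)["count"]
            .sum()
        )
        self.library_total = float(df["count"].sum())
        df["tpm"] = df["count"] / self.library_total * 1e6
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class TssSet:
    """Retained TSS positions with per-tissue TPM vectors.

    ``df`` columns: ``chrom, pos, strand`` plus one ``tpm_<tissue>``
    column per tissue and a ``pooled`` column (sum of per-tissue TPM).
    Sub-threshold TPM values at retained positions are preserved.
    """

    df: pd.DataFrame
    tissues: list[str]
    min_tpm: float

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tpm_columns(self) -> list[str]:
        return [f"tpm_{t}" for t in self.tissues]


def read_ctss(path, tissue: str) -> CtssTrack:
    """Read a CTSS BED6 file (count in the score column) into a track.

    Every interval must be exactly one base wide; duplicate positions
    are summed.  Zero or negative counts are a format error.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 4, 5],
        names=["chrom", "start", "end", "count", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        comment="#",
    )
    if ((df["end"] - df["start"]) != 1).any():
        bad = df.index[(df["end"] - df["start"]) != 1][0]
        raise ValueError(f"CTSS row {bad} spans more than 1 bp")
    if (df["count"] <= 0).any():
        bad = df.index[df["count"] <= 0][0]
        raise ValueError(f"CTSS row {bad} has non-positive count")
    out = df.rename(columns={"start": "pos"})[["chrom", "pos", "strand", "count"]]
    return CtssTrack(tissue=tissue, df=out)


def read_ctss_bedgraph(plus_path, minus_path, tissue: str) -> CtssTrack:
    """Read a plus/minus bedGraph pair; multi-base intervals are expanded
    to per-base rows carrying the interval's value."""
    frames = []
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        bg = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "count"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
            comment="#",
        )
        bg = bg[bg["count"] != 0]
        if (bg["count"] < 0).any():
            raise ValueError("negative bedGraph value in CTSS input")
        widths = (bg["end"] - bg["start"]).to_numpy()
        chroms = np.repeat(bg["chrom"].to_numpy(), widths)
        starts = np.repeat(bg["start"].to_numpy(), widths) + _ragged_arange(widths)
        counts = np.repeat(bg["count"].to_numpy(), widths)
        frames.append(
            pd.DataFrame(
                {"chrom": chroms, "pos": starts, "strand": strand, "count": counts}
            )
        )
    return CtssTrack(tissue=tissue, df=pd.concat(frames, ignore_index=True))


def _ragged_arange(widths: np.ndarray) -> np.ndarray:
    # [3,2] -> [0,1,2,0,1]
    if len(widths) == 0:
        return np.array([], dtype=np.int64)
    ends = np.cumsum(widths)
    out = np.arange(ends[-1]) - np.repeat(ends - widths, widths)
    return out


def filter_tss(tracks: list[CtssTrack], min_tpm: float = 1.0) -> TssSet:
    """Retain positions whose TPM strictly exceeds ``min_tpm`` in >= 1 tissue."""
    if not tracks:
        raise ValueError("at least one CTSS track is required")
    tissues = [t.tissue for t in tracks]
    if len(set(tissues)) != len(tissues):
        raise ValueError("tissue names must be unique")
    chrom_sets = [frozenset(t.df["chrom"]) for t in tracks]
    if len(set(chrom_sets)) > 1:
        warnings.warn("chromosome sets differ across tracks; using the union")
    merged: pd.DataFrame | None = None
    for track in tracks:
        cols = track.df[["chrom", "pos", "strand", "tpm"]].rename(
            columns={"tpm": f"tpm_{track.tissue}"}
        )
        if merged is None:
            merged = cols
        else:
            merged = merged.merge(cols, on=["chrom", "pos", "strand"], how="outer")
    merged = merged.fillna(0.0)
    tpm_cols = [f"tpm_{t}" for t in tissues]
    keep = (merged[tpm_cols] > min_tpm).any(axis=1)
    out = merged[keep].sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)
    out["pooled"] = out[tpm_cols].sum(axis=1)
    return TssSet(df=out, tissues=tissues, min_tpm=min_tpm)


def pool_tissues(tss: TssSet) -> pd.Series:
    """Pooled abundance per position = sum of per-tissue TPM (order-invariant)."""
    return tss.df[tss.tpm_columns].sum(axis=1)


def saturation_curve(
    track: CtssTrack,
    depths: list[float],
    min_reads: list[int] = (3, 6, 9),
    seed: int = 0,
) -> pd.DataFrame:
    """Detected-position counts under binomial read subsampling.

    For each subsampling fraction the raw count at every position is
    thinned with an independent Binomial(count, fraction) draw; a
    position is "detected" at level ``m`` when its thinned count is at
    least ``m``.  Returns a tidy table (fraction, min_reads, detected).
    """
    rng = np.random.default_rng(seed)
    counts = track.df["count"].to_numpy(dtype=np.int64)
    rows = []
    for frac in depths:
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"subsampling fraction {frac} outside (0, 1]")
        thinned = counts if frac == 1.0 else rng.binomial(counts, frac)
        for m in min_reads:
            rows.append(
                {"fraction": frac, "min_reads": int(m), "detected": int((thinned >= m).sum())}
            )
    return pd.DataFrame(rows)
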