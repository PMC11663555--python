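"""Preprocess raw 5'-end reads and estimate sequencing saturation.

Read 1 of a cap-selective library starts with an 8-nt UMI followed by
the template-switch signature TATAGGG.  Preprocessing drops short or
signature-less reads, collapses byte-identical duplicates, and trims the
UMI + signature (recording the UMI in the read name).  Saturation is
estimated by binomially subsampling the CTSS counts and counting
positions that remain detected at >= 3/6/9 reads.
"""

import tempfile
from pathlib import Path

import numpy as np

from tsratlas.ctss import CtssTrack, saturation_curve
from tsratlas.preprocess import ReadFilterConfig, preprocess_reads

rng = np.random.default_rng(0)
PATTERN = "TATAGGG"

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    fin, fout = tmp / "raw.fastq", tmp / "clean.fastq"
    with open(fin, "w") as fh:
        for i in range(500):
            r = rng.random()
            if r < 0.1:  # degraded fragment
                seq = "".join(rng.choice(list("ACGT"), size=30))
            elif r < 0.25:  # no template-switch signature
                seq = "".join(rng.choice(list("AC"), size=80))
            else:  # UMI + signature + cDNA (a few duplicated molecules)
                umi = "AAAAAAAA" if r < 0.35 else "".join(rng.choice(list("ACGT"), 8))
                seq = umi + PATTERN + "GATTACA" * 10
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")

    report = preprocess_reads(fin, fout, ReadFilterConfig())
    print(f"input reads:          {report.input_reads}")
    print(f"removed (short):      {report.removed_short}")
    print(f"removed (no pattern): {report.removed_no_pattern}")
    print(f"collapsed duplicates: {report.collapsed_duplicates}")
    print(f"surviving reads:      {report.surviving_reads}")

import pandas as pd

counts = rng.integers(1, 60, size=2000)
track = CtssTrack(
    tissue="leaf",
    df=pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(2000) * 5, "strand": "+", "count": counts}
    ),
)
curve = saturation_curve(track, depths=[0.25, 0.5, 0.75, 1.0], seed=0)
print("\nsaturation (positions detected):")
print(curve.pivot(index="fraction", columns="min_reads", values="detected"))
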