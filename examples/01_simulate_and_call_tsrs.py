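"""Generate a synthetic multi-tissue 5'-end dataset and call TSRs.

The simulator plants transcription start regions (TSRs) of known
position, width and shape into a toy genome and emits per-tissue CTSS
(capped transcription start site) tracks.  We then run the first half of
the analysis: TPM normalization, the >1 TPM detection filter, and
single-linkage clustering into TSRs.
"""

import tempfile
from collections import Counter
from pathlib import Path

from tsratlas.calling import cluster_tsrs
from tsratlas.ctss import filter_tss, read_ctss
from tsratlas.simulate import SimConfig, generate_ctss, generate_genome

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    config = SimConfig(seed=1)  # 40 genes, 60 planted TSRs, 4 tissues
    sg = generate_genome(config, outdir=tmp)
    generate_ctss(sg, outdir=tmp)
    print(f"planted {len(sg.tsrs)} TSRs across {len(sg.genes)} genes")

    tracks = [read_ctss(tmp / f"{t}.ctss.bed", t) for t in config.tissue_names]
    for track in tracks[:2]:
        print(f"{track.tissue}: {len(track)} CTSS positions, "
              f"library total {track.library_total:.0f}")

    tss = filter_tss(tracks, min_tpm=1.0)
    print(f"{len(tss)} positions exceed 1 TPM in at least one tissue")

    tsrs = cluster_tsrs(tss, max_gap=20)
    shapes = Counter(t.shape for t in tsrs)
    print(f"called {len(tsrs)} TSRs; shapes: {dict(shapes)}")
    t = tsrs[0]
    print(f"example: {t.id} {t.chrom}:{t.start}-{t.end}({t.strand}) "
          f"peak={t.peak} iqr={t.iqr} shape={t.shape}")
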