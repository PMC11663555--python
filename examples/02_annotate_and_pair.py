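"""Annotate TSRs against a gene model and find bidirectional pairs.

Each called TSR is assigned one genomic feature category by its peak
position under the priority promoter > proximal > 5'UTR > CDS > intron >
3'UTR > antisense > intergenic.  Divergent opposite-strand TSR pairs
within 600 bp are then matched and classified as mRNA-mRNA, mRNA-PROMPT
or other-divergence.
"""

import tempfile
from collections import Counter
from pathlib import Path

from tsratlas.annotation import annotate_tsrs, build_genome_model
from tsratlas.calling import cluster_tsrs
from tsratlas.ctss import filter_tss, read_ctss
from tsratlas.directionality import classify_bidirectional, find_bidirectional
from tsratlas.simulate import SimConfig, generate_ctss, generate_genome

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    config = SimConfig(seed=1)
    sg = generate_genome(config, outdir=tmp)
    generate_ctss(sg, outdir=tmp)
    tracks = [read_ctss(tmp / f"{t}.ctss.bed", t) for t in config.tissue_names]
    tsrs = cluster_tsrs(filter_tss(tracks))

    model = build_genome_model(tmp / "annotation.gff3")
    assignments = annotate_tsrs(tsrs, model)
    print("category counts:",
          dict(Counter(a.category for a in assignments.values())))

    by_id = {t.id: t for t in tsrs}
    pairs = find_bidirectional(tsrs, max_span=600)
    for p in pairs:
        classify_bidirectional(p, model, assignments, by_id)
    print(f"{len(pairs)} bidirectional pairs:",
          dict(Counter(p.category for p in pairs)))
    if pairs:
        p = pairs[0]
        print(f"example pair: {p.plus_tsr_id}/{p.minus_tsr_id} "
              f"span={p.span} category={p.category}")
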