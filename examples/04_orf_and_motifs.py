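"""Predict protein consequences of coding-region TSRs and profile motifs.

A TSR inside an annotated CDS forces translation to start at the first
downstream AUG: in frame it truncates the protein, out of frame it
shifts the reading frame.  Around all TSR peaks we also profile the
TATA-box consensus (TATAWAWR) and the pyrimidine-purine initiator
dinucleotide that mark canonical plant core promoters.
"""

import tempfile
from collections import Counter
from pathlib import Path

from tsratlas.pipeline import PipelineConfig, run_pipeline
from tsratlas.simulate import SimConfig, generate_ctss, generate_genome

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    config = SimConfig(seed=1)
    sg = generate_genome(config, outdir=tmp)
    generate_ctss(sg, outdir=tmp)
    result = run_pipeline(
        PipelineConfig(
            ctss={t: str(tmp / f"{t}.ctss.bed") for t in config.tissue_names},
            gff3=str(tmp / "annotation.gff3"),
            fasta=str(tmp / "genome.fa"),
            outdir=str(tmp / "out"),
        )
    )

    outcomes = Counter(r.outcome for r in result["orf_records"].values())
    print("ORF consequences of CDS TSRs:", dict(outcomes))
    trunc = [r for r in result["orf_records"].values() if r.outcome == "truncation"]
    if trunc:
        r = trunc[0]
        print(f"example: {r.tsr_id} in {r.gene_id} removes {r.delta_aa} aa "
              f"(new start at {r.new_start_genomic})")

    tata = result["tata_profile"]
    print(f"\nTATA consensus argmax offset in [-50,-10]: "
          f"{tata.argmax_offset(-50, -10)}")
    dinuc = result["initiator_dinucleotides"]
    top = dinuc.sort_values(ascending=False).head(3)
    print("top initiator dinucleotides (-1,+1), all TSRs:",
          {k: round(v, 3) for k, v in top.items()})

    # the PyPu initiator stands out once restricted to canonical TSRs
    from tsratlas.context import extract_windows, pypu_profile

    canonical = [
        t for t in result["tsrs"]
        if result["assignments"][t.id].category in ("promoter", "5UTR")
    ]
    windows, _ = extract_windows(
        [(t.chrom, t.peak, t.strand) for t in canonical], sg.sequences, 100, 50
    )
    table, profile = pypu_profile(windows, upstream=100)
    idx = list(profile.offsets).index(-1)
    print(f"PyPu frequency at (-1,+1) over {len(windows)} canonical TSRs: "
          f"{profile.values[idx]:.2f}")
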