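# Methods

This document records the exact conventions, parameter defaults and
numerical choices used throughout `tsratlas`. All coordinates are
0-based, half-open, strand-specific unless stated otherwise.

## 1. CTSS quantification (`tsratlas.ctss`)

A CTSS track is a per-tissue map of single-base 5′-end positions to
counts, read from BED6 (count in the score column; every interval must
be exactly 1 bp) or from a plus/minus bedGraph pair (multi-base
intervals are expanded per base). Duplicate positions are summed; zero
or negative counts are format errors.

**Normalization.** TPM = count / library_total × 10⁶, where
library_total is the track's total count *before any filtering*, so TPM
values are comparable across tissues regardless of downstream
thresholds.

**Detection filter.** A position is retained when its TPM *strictly
exceeds* `min_tpm` (default 1) in at least one tissue. The merge across
tissues is an outer join: a position retained via one tissue keeps its
sub-threshold TPM values in the others, and the per-position pooled
abundance is the sum of per-tissue TPMs (order-invariant by
construction). Tracks with differing chromosome sets trigger a warning
and are merged over the union.

**Saturation.** For a subsampling fraction f ∈ (0, 1], each position's
count c is thinned with an independent Binomial(c, f) draw; a position
is detected at level m when the thinned count is ≥ m (defaults m = 3,
6, 9). f = 1 bypasses the random draw so full depth is exact. The
closed-form expectation Σᵢ P(Bin(cᵢ, f) ≥ m) is what the tests check
the sampler against.

## 2. TSR calling (`tsratlas.calling`)

Retained positions on one chromosome and strand are clustered by single
linkage: successive positions at distance ≤ `max_gap` (default 20 bp)
join the same TSR. Thus positions 100 and 120 merge while 100 and 121
do not. Chromosome or strand boundaries never merge.

**Peak.** The member position with maximal pooled TPM; ties break to
the 5′-most member (smallest coordinate on +, largest on −).

**IQR.** Quartiles use a left-continuous step-CDF on the pooled
positional mass: q25 (q75) is the *smallest member position* whose
cumulative pooled fraction reaches 0.25 (0.75); IQR = q75 − q25. On ten
uniform consecutive positions, q25 is the 3rd base and q75 the 8th, so
IQR = 5. This convention is exact on discrete mass; the only floating
point guard is a 10⁻¹² slack when comparing cumulative fractions to the
quartile targets, which protects against accumulated rounding in the
cumulative sum without changing any decision by more than one
representable value.

**Shape.** `S` when the TSR spans a single base; otherwise `N` (narrow)
when IQR ≤ 4 bp and `B` (broad) when IQR > 4 bp.

## 3. Feature annotation (`tsratlas.annotation`)

The gene model is parsed from GFF3 (gene → mRNA/transcript →
exon/CDS/UTR) with `gffutils`; orphan `Parent` references are an error.
Derived windows per transcript (strand-aware):

- annotated TSS: the transcript's 5′ end;
- promoter: 100 bp upstream through 100 bp downstream of the TSS
  (201 bp). A plus-strand transcript at [1000, 2000) has promoter
  [900, 1101); a minus-strand one has TSS 1999 and promoter [1899, 2100);
- promoter-proximal: the 400 bp immediately upstream of the promoter
  window (e.g. [500, 900) for the plus-strand example);
- introns: the transcript span minus its exons;
- 5′/3′ UTRs: taken from the annotation when present, otherwise derived
  as exonic sequence outside the CDS, split by side of the CDS.

Windows are clipped at chromosome bounds (taken from
`##sequence-region` pragmas when present); a window falling entirely
off-chromosome becomes empty.

A TSR is assigned exactly one category by testing its **peak** against
same-strand windows in priority order `promoter > proximal > 5UTR > CDS
> intron > 3UTR`, then against opposite-strand gene bodies
(`antisense`), else `intergenic`. When several transcripts match in the
winning category, the transcript whose annotated TSS is nearest the
peak wins (deterministic id tie-break after that). Annotation is
symmetric under strand reversal, which the tests check by mirroring a
fixture genome.

## 4. Bidirectional and antisense pairing (`tsratlas.directionality`)

Two opposite-strand TSRs form a divergent candidate when the
minus-strand TSR's peak is not 3′ of the plus-strand TSR's peak
(transcription points outward) and the span between their outermost
boundaries — plus TSR end minus minus TSR start — is ≤ `max_span`
(default 600 bp). Each TSR joins at most one pair: candidates are
matched greedily by increasing span, ties broken toward the larger
combined pooled abundance, then lexicographic ids.

Pair classes: `mRNA-mRNA` (both members promoter TSRs of two distinct
genes), `mRNA-PROMPT` (exactly one promoter member; the partner's 5′
boundary lies within `max_span` upstream of that gene's TSS),
`other-divergence` (both members intragenic for the same gene), else
`uncategorized`.

Antisense TSRs are paired with the host gene's most abundant
(pooled TPM) sense TSR; genes without a detected sense TSR leave the
antisense TSR listed as unpaired. Pearson correlation of per-tissue
abundances is reported only when ≥ 3 tissues are shared and neither
vector is constant; otherwise it is undefined (None), never 0.

## 5. Tissue atlas groups (`tsratlas.atlas`)

A TSR is *present* in a tissue when its per-tissue abundance is ≥
`presence_min_tpm` (default 1; inclusive, unlike the detection filter —
detection asks whether a position clears noise, presence asks whether
an already-called TSR is used in a tissue). The *dominant* TSR of a
gene in a tissue is its most abundant present TSR, ties toward the
5′-most peak.

For a gene and tissue pair with present TSR sets A and B (gene skipped
when both are empty):

| group | condition |
|---|---|
| 1 | \|A\| = \|B\| = 1 and A = B |
| 2 | \|A\| = \|B\| = 1 and A ≠ B |
| 3 | A = B, \|A\| > 1 |
| 4 | A ≠ B, both non-empty, dominant TSR shared |
| 5 | A ≠ B, both non-empty, dominant TSRs differ |
| 6 | exactly one of A, B empty |

Mixed cardinalities (e.g. one vs three TSRs) fall under groups 3–5 by
these conditions. Groups 2*/5* are the subsets of 2/5 with an unshared
CDS-category TSR whose predicted ORF consequence is a truncation or
frameshift; their percentages are reported relative to the group 2/5
counts, while group 1–6 percentages are over all classified genes of
the pair.

## 6. ORF consequences (`tsratlas.orf`)

For a TSR peak within a coding transcript, the spliced transcript
sequence is scanned 3′ of the peak for the first ATG. Intronic peaks
snap to the next exonic base in the direction of transcription; peaks
3′ of the last exon are an error; peaks at or 5′ of the annotated start
are `upstream_equivalent`. With the first downstream ATG at spliced
offset Δ from the annotated start codon: Δ ≡ 0 (mod 3) is a
`truncation` removing Δ/3 residues (flagged if the truncated ORF stops
before the annotated stop), otherwise a `frameshift`; an ATG-free
suffix is `no_start`. The scan looks for ATG only — intervening stop
codons do not end it.

## 7. Sequence context (`tsratlas.context`)

Windows around peaks are strand-aware (minus-strand windows reverse-
complemented) with the peak base at index `upstream`. Offsets follow
the promoter convention: peak = +1, first upstream base = −1, no 0.
Windows clipped by a chromosome edge are dropped and counted.

- **TATA profile**: per-offset frequency of IUPAC `TATAWAWR` matches
  *starting* at that offset, tested position by position so overlapping
  matches all count. The summary statistic is the argmax offset within
  [−50, −10].
- **Initiator**: the 16-entry table of the (−1, +1) dinucleotide and a
  per-offset pyrimidine→purine (PyPu) frequency; windows with ambiguous
  bases are excluded from the affected denominators rather than counted
  as misses.
- **Signal metaprofile**: mean bedGraph signal in fixed-size bins over
  ±`flank` around peaks, strand-flipped so upstream is left; bases
  without data count as 0.

## 8. Read preprocessing (`tsratlas.preprocess`)

Read 1 begins with a UMI (default 8 nt) followed by the literal
template-switch signature `TATAGGG`. Order of operations: (1) remove
reads shorter than 50 nt or lacking the signature within the first
`umi_length + 3` bases; (2) collapse byte-identical sequences keeping
the first occurrence (identical sequence implies identical UMI, so this
is molecule-level deduplication — collapsing *after* trimming would
wrongly merge distinct molecules); (3) trim through the signature,
appending the removed UMI to the read name after an underscore and
trimming qualities in lockstep. The read-fate identity surviving +
removed_short + removed_no_pattern + collapsed = input is asserted on
every run.

## 9. Synthetic data (`tsratlas.simulate`)

The generator builds a genome in which every downstream statistic has a
machine-readable truth (written to `manifest.json`/`manifest.tsv`).

**Gene architecture** (sense offsets from the TSS): 5′UTR [0, 250),
CDS-1 [250, 550), intron [550, 700), CDS-2 [700, 1000), 3′UTR
[1000, 1150); an ATG is written at the CDS start. Genes are placed
sparsely (head-to-head pairs for divergent gene promoters, wide gaps
otherwise) so planted TSRs never merge across genes.

**Defaults** (`SimConfig`): 2 × 250 kb chromosomes, 40 genes, 1.5 TSRs
per gene, four tissues. TSR widths are drawn single/narrow/broad at
0.648/0.163/0.189 — the shape regime of a plant 5′-end atlas dominated
by sharp initiation. Narrow profiles are 3–5 bp triangles (IQR ≤ 4);
broad profiles are 10–30 bp plateaus with a +2 center bump — a uniform
8–9 bp plateau would sit exactly at the IQR = 4 boundary, so broad
widths start at 10 to keep the planted class unambiguous. Categories
are drawn at promoter 0.30, 5′UTR 0.15, CDS 0.32, intron 0.05, 3′UTR
0.04, antisense 0.06, intergenic 0.08 (a promoter-heavy canonical
fraction with CDS-dominant intragenic initiation; `proximal` is not
planted — it arises only as a call). 25% of promoter abundance is
organized into divergent pairs (gene/gene head-to-head within the
600 bp span, PROMPT-like partners 220–480 bp upstream of single
genes); half of the antisense TSRs are placed to form intragenic
divergence with a CDS TSR. Tissue presence is 60% single-tissue
specific, otherwise independent Bernoulli(0.7) per tissue (at least one
guaranteed), with integer per-tissue scale factors 1–3. TATA boxes are
written at sense offset −30 from promoter peaks at rate 0.8; PyPu
initiator dinucleotides at (−1, +1) of promoter/5′UTR peaks at rate
0.9. CDS TSRs rewrite the bases between the peak and a planted
downstream ATG with pyrimidines, fixing the true truncation/frameshift
outcome. Background: Poisson(0.2 events/kb/tissue) single counts,
uniform over the genome, logged per tissue so emitted totals reconcile
exactly with planted totals.

**What it emulates**: sharp/narrow/broad initiation shapes, a canonical
and intragenic category mix, strong tissue specificity, divergent
transcription geometry, core-promoter motifs, uniform degradation
noise, and exact count bookkeeping.

**What it does not emulate**: realistic genome composition (background
sequence is i.i.d. uniform ACGT), alternative splicing or multiple
transcripts per gene, overlapping genes, expression-level distributions
(counts are small integers, not heavy-tailed), mapping artifacts,
sequencing error, UMI saturation, or correlated noise between tissues.

## 10. Pipeline and determinism

`run_pipeline` chains quantify → call → annotate → pair → ORF → groups
→ motifs with one config, writing TSVs plus a manifest containing the
package version, the full echoed config, SHA-256 checksums of all
inputs and per-stage row counts. All randomness anywhere in the package
flows from explicit integer seeds through `numpy.random.default_rng`;
the simulator uses the config seed for genome construction and the
derived seed `[seed, 1]` for CTSS emission, so the same config is
byte-reproducible file by file. The analysis pipeline itself is fully
deterministic (the config seed is recorded but nothing draws from it).

## Limitations

- Annotation considers only `gene`/`mRNA`-style models; *trans*-spliced
  or fusion transcripts are out of scope.
- The ORF scan predicts initiation consequences from sequence alone; it
  does not model Kozak context strength, leaky scanning or reinitiation.
- Bidirectional matching is greedy (nearest-span first), not a global
  optimum matching; with dense TSR clusters a different pairing could
  have smaller total span.
- Presence calls are threshold-based on TPM with no count-uncertainty
  model; lowly sequenced tissues are noisier near the threshold.
- The IQR step-CDF convention differs from interpolating quantile
  definitions; IQR values are only comparable within this convention.
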