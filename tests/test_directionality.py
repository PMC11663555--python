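"""Divergent pair detection, classification, and antisense/sense pairing."""

import numpy as np
import pytest

from tsratlas.annotation import FeatureAssignment, GenomeModel, Transcript
from tsratlas.directionality import (
    abundance_correlation,
    find_bidirectional,
    classify_bidirectional,
    pair_antisense_sense,
)

from conftest import make_tsr


def test_hand_case_span():
    minus = make_tsr("m", "chr1", "-", [1000, 1009])  # span [1000, 1010)
    plus = make_tsr("p", "chr1", "+", [1300, 1309])  # span [1300, 1310)
    pairs = find_bidirectional([minus, plus])
    assert len(pairs) == 1
    assert pairs[0].span == 1310 - 1000 == 310


def test_convergent_pairs_excluded():
    # plus TSR left of minus TSR: transcription points inward, not divergent
    plus = make_tsr("p", "chr1", "+", [1000])
    minus = make_tsr("m", "chr1", "-", [1200])
    assert find_bidirectional([plus, minus]) == []


def test_span_cutoff():
    minus = make_tsr("m", "chr1", "-", [1000])
    plus_in = make_tsr("p", "chr1", "+", [1599])  # span 600
    plus_out = make_tsr("q", "chr1", "+", [1600])  # span 601
    assert len(find_bidirectional([minus, plus_in])) == 1
    assert find_bidirectional([minus, plus_out]) == []


def test_each_tsr_in_at_most_one_pair_nearest_wins():
    minus = make_tsr("m", "chr1", "-", [1000])
    near = make_tsr("near", "chr1", "+", [1100])
    far = make_tsr("far", "chr1", "+", [1400])
    pairs = find_bidirectional([minus, near, far])
    assert len(pairs) == 1
    assert pairs[0].plus_tsr_id == "near"


def test_tie_breaks_toward_larger_abundance():
    m1 = make_tsr("m1", "chr1", "-", [1000], pooled=[1.0])
    m2 = make_tsr("m2", "chr1", "-", [2000], pooled=[50.0])
    # one plus TSR equidistant-by-span from both minus TSRs
    plus1 = make_tsr("p1", "chr1", "+", [1199], pooled=[5.0])
    plus2 = make_tsr("p2", "chr1", "+", [2199], pooled=[5.0])
    pairs = find_bidirectional([m1, m2, plus1, plus2])
    # both pairs have span 200 and can form without conflict
    assert len(pairs) == 2
    # true conflict: two plus TSRs at the same span from one minus TSR
    one_minus = make_tsr("m0", "chr1", "-", [3000], pooled=[1.0])
    weak = make_tsr("w", "chr1", "+", [3199], pooled=[2.0])
    strong = make_tsr("s", "chr1", "+", [3199], pooled=[9.0])
    pairs = find_bidirectional([one_minus, weak, strong])
    assert len(pairs) == 1
    assert pairs[0].plus_tsr_id == "s"


def oracle_pairs(tsrs, max_span=600):
    """Independent reimplementation: exhaustive candidates, greedy by
    (span, -combined abundance, ids)."""
    cands = []
    for a in tsrs:
        for b in tsrs:
            if a.strand != "-" or b.strand != "+" or a.chrom != b.chrom:
                continue
            if a.peak > b.peak:
                continue
            span = b.end - a.start
            if 0 < span <= max_span:
                cands.append((span, -(a.pooled_abundance + b.pooled_abundance),
                              a.id, b.id))
    cands.sort()
    used, out = set(), set()
    for span, _, mid, pid in cands:
        if mid in used or pid in used:
            continue
        used.update((mid, pid))
        out.add((pid, mid, span))
    return out


def test_matches_all_pairs_oracle():
    rng = np.random.default_rng(31)
    for trial in range(80):
        n = int(rng.integers(2, 25))
        tsrs = []
        for i in range(n):
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, 4000))
            width = int(rng.integers(1, 15))
            tsrs.append(
                make_tsr(
                    f"t{trial}_{i}", "chr1", strand,
                    list(range(start, start + width)),
                    pooled=rng.uniform(1, 20, size=width),
                )
            )
        got = {
            (p.plus_tsr_id, p.minus_tsr_id, p.span)
            for p in find_bidirectional(tsrs)
        }
        assert got == oracle_pairs(tsrs)


def _model_with_tx(tx_list):
    return GenomeModel(
        genes={},
        transcripts={t.id: t for t in tx_list},
        chrom_lengths={},
    )


def _tx(tid, gene_id, strand, tss, chrom="chr1"):
    start, end = (tss, tss + 1000) if strand == "+" else (tss - 999, tss + 1)
    return Transcript(
        id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
        start=start, end=end, exons=[(start, end)], cds=[], tss=tss,
    )


def test_classification_categories():
    model = _model_with_tx([_tx("tx1", "gA", "+", 1300), _tx("tx2", "gB", "-", 1010)])
    minus = make_tsr("m", "chr1", "-", [1000, 1009])
    plus = make_tsr("p", "chr1", "+", [1300, 1309])
    by_id = {"m": minus, "p": plus}
    pairs = find_bidirectional([minus, plus])

    # both promoters of distinct genes -> mRNA-mRNA
    asn = {
        "p": FeatureAssignment("p", "promoter", "gA", "tx1"),
        "m": FeatureAssignment("m", "promoter", "gB", "tx2"),
    }
    assert classify_bidirectional(pairs[0], model, asn, by_id) == "mRNA-mRNA"

    # promoter + upstream non-promoter partner -> mRNA-PROMPT
    asn = {
        "p": FeatureAssignment("p", "promoter", "gA", "tx1"),
        "m": FeatureAssignment("m", "intergenic", None, None),
    }
    # minus TSR 5' boundary (1009) lies 291 bp upstream of tx1 TSS (1300)
    assert classify_bidirectional(pairs[0], model, asn, by_id) == "mRNA-PROMPT"

    # both intragenic for the same gene -> other-divergence
    asn = {
        "p": FeatureAssignment("p", "CDS", "gA", "tx1"),
        "m": FeatureAssignment("m", "antisense", "gA", None),
    }
    assert classify_bidirectional(pairs[0], model, asn, by_id) == "other-divergence"

    # intragenic for different genes -> uncategorized
    asn = {
        "p": FeatureAssignment("p", "CDS", "gA", "tx1"),
        "m": FeatureAssignment("m", "antisense", "gB", None),
    }
    assert classify_bidirectional(pairs[0], model, asn, by_id) == "uncategorized"

    # two promoters of the same gene -> uncategorized, not mRNA-mRNA
    asn = {
        "p": FeatureAssignment("p", "promoter", "gA", "tx1"),
        "m": FeatureAssignment("m", "promoter", "gA", "tx1"),
    }
    assert classify_bidirectional(pairs[0], model, asn, by_id) == "uncategorized"


def test_prompt_requires_upstream_within_span():
    # partner 5' boundary downstream of the TSS is not a PROMPT
    model = _model_with_tx([_tx("tx1", "gA", "+", 1200)])
    minus = make_tsr("m", "chr1", "-", [1250])
    plus = make_tsr("p", "chr1", "+", [1300])
    pairs = find_bidirectional([minus, plus])
    asn = {
        "p": FeatureAssignment("p", "promoter", "gA", "tx1"),
        "m": FeatureAssignment("m", "5UTR", "gA", "tx1"),
    }
    assert classify_bidirectional(pairs[0], model, asn, {"m": minus, "p": plus}) == "uncategorized"


def test_antisense_pairs_most_abundant_sense_and_unpaired():
    sense_small = make_tsr("s1", "chr1", "+", [100], pooled=[2.0])
    sense_big = make_tsr("s2", "chr1", "+", [400], pooled=[9.0])
    anti = make_tsr("a1", "chr1", "-", [250], pooled=[3.0])
    orphan = make_tsr("a2", "chr2", "-", [250], pooled=[3.0])
    asn = {
        "s1": FeatureAssignment("s1", "promoter", "gA", "tx1"),
        "s2": FeatureAssignment("s2", "CDS", "gA", "tx1"),
        "a1": FeatureAssignment("a1", "antisense", "gA", None),
        "a2": FeatureAssignment("a2", "antisense", "gZ", None),
    }
    pairs, unpaired = pair_antisense_sense([sense_small, sense_big, anti, orphan], asn)
    assert len(pairs) == 1
    assert pairs[0].sense_tsr_id == "s2"
    assert pairs[0].gene_id == "gA"
    assert unpaired == ["a2"]


def test_correlation_perfect_and_inverse():
    a = {"t1": 1.0, "t2": 2.0, "t3": 3.0}
    assert abundance_correlation(a, {"t1": 2.0, "t2": 4.0, "t3": 6.0}) == pytest.approx(1.0)
    assert abundance_correlation(a, {"t1": 3.0, "t2": 2.0, "t3": 1.0}) == pytest.approx(-1.0)


def test_correlation_undefined_cases():
    assert abundance_correlation({"t1": 1.0, "t2": 2.0}, {"t1": 1.0, "t2": 2.0}) is None
    const = {"t1": 5.0, "t2": 5.0, "t3": 5.0}
    assert abundance_correlation(const, {"t1": 1.0, "t2": 2.0, "t3": 3.0}) is None


def test_correlation_matches_manual_formula():
    rng = np.random.default_rng(2)
    tissues = [f"t{i}" for i in range(6)]
    a = {t: float(rng.uniform(0, 10)) for t in tissues}
    b = {t: float(rng.uniform(0, 10)) for t in tissues}
    x = np.array([a[t] for t in tissues])
    y = np.array([b[t] for t in tissues])
    manual = ((x - x.mean()) * (y - y.mean())).sum() / (
        np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
    )
    assert abundance_correlation(a, b) == pytest.approx(manual)


def test_planted_pairs_recovered_noiseless(noiseless_sim):
    from tsratlas.evaluate import match_planted, planted_pairs

    sg = noiseless_sim["sg"]
    result = noiseless_sim["result"]
    matches = match_planted(sg.tsrs, result["tsrs"])
    called_pairs = {
        frozenset((p.plus_tsr_id, p.minus_tsr_id)): p.category
        for p in result["pairs"]
    }
    truth = planted_pairs(sg)
    assert truth, "simulation should plant divergent pairs"
    for id_a, id_b, category in truth:
        key = frozenset((matches[id_a].id, matches[id_b].id))
        assert key in called_pairs, (id_a, id_b)
        assert called_pairs[key] == category
    assert all(p.span <= 600 for p in result["pairs"])
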