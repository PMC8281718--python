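"""Junction chemistry classification against a split-enumeration oracle,
plus breakpoint annotation, identity and fusion-orientation calls."""

import numpy as np
import pytest

from haploscope.svjunction import (Breakpoint, JunctionCall,
                                   UnalignableContigError,
                                   annotate_breakpoints, classify_junction,
                                   classify_fusion_transcript,
                                   percent_identity,
                                   summarize_junction_classes)

BASES = "ACGT"


def oracle_classify(left, right, contig):
    """Independent exhaustive enumeration of flank attributions.

    Consider every decomposition contig == left[-x:] + mid + right-prefix
    contribution: enumerate all x with contig[:x] == left[-x:] and all y
    with contig[-y:] == right[:y] (x, y >= 1), and take the pair maximizing
    x + y.  If x + y >= len(contig) the flanks overlap on the junction by
    x + y - L bases assignable to either side (microhomology; 0 = blunt);
    otherwise the uncovered middle is an untemplated insertion.
    """
    L = len(contig)
    xs = [x for x in range(1, L + 1) if contig[:x] == left[-x:]]
    ys = [y for y in range(1, L + 1) if contig[-y:] == right[:y]]
    if not xs or not ys:
        return None
    x, y = max(xs), max(ys)
    if x + y >= L:
        mh = x + y - L
        return ("blunt" if mh == 0 else "microhomology", mh, "")
    return ("insertion", 0, contig[x:L - y])


@pytest.mark.parametrize("left,right,contig,expected", [
    ("CCCCAAAA", "GGGGCCCC", "AAAAGGGG", ("blunt", 0, "")),
    ("TTTGATTACA", "CAGGGTTT", "GATTACAGGG", ("microhomology", 2, "")),
    ("CCCCAAAA", "GGGGCCCC", "AAAATTGGGG", ("insertion", 0, "TT")),
])
def test_classify_junction_examples(left, right, contig, expected):
    call = classify_junction(left, right, contig)
    assert (call.junction_class, call.microhomology_len,
            call.inserted_seq) == expected
    assert oracle_classify(left, right, contig) == expected


def test_classifier_agrees_with_enumeration_on_random_junctions():
    rng = np.random.default_rng(11)
    n_checked = 0
    for _ in range(400):
        flank = 30
        left = "".join(rng.choice(list(BASES), size=flank))
        mh = int(rng.integers(0, 6))
        ins_len = int(rng.integers(0, 5)) if mh == 0 else 0
        ins = "".join(rng.choice(list(BASES), size=ins_len))
        right_tail = "".join(rng.choice(list(BASES), size=flank - mh))
        right = left[-mh:] + right_tail if mh else right_tail
        contig = left + ins + right[mh:]
        expected = oracle_classify(left, right, contig)
        call = classify_junction(left, right, contig)
        got = (call.junction_class, call.microhomology_len, call.inserted_seq)
        assert got == expected
        n_checked += 1
    assert n_checked == 400


def test_reconstruction_and_shift_range():
    left, right = "TTTGATTACA", "CAGGGTTT"
    contig = "GATTACAGGG"
    call = classify_junction(left, right, contig)
    first, last = call.ambiguous_shift_range
    assert last - first == call.microhomology_len
    # maximal flank attributions reconstruct the contig exactly: the first
    # `last` bases come from the left flank, the last L-first from the right
    L = len(contig)
    assert left.endswith(contig[:last])
    assert right.startswith(contig[first:])
    assert contig == left[-last:] + right[last - first:L - first]


def test_unalignable_contig_errors():
    with pytest.raises(UnalignableContigError):
        classify_junction("AAAAAAAA", "CCCCCCCC", "GGGGGGGG")
    with pytest.raises(UnalignableContigError):
        # middle segment longer than the scan limit
        classify_junction("AAAAAAAA", "CCCCCCCC", "AAAA" + "T" * 25 + "CCCC")


def test_summarize_junction_classes():
    calls = [JunctionCall("e1", 0, "", "blunt", (1, 1)),
             JunctionCall("e2", 1, "", "microhomology", (1, 2)),
             JunctionCall("e3", 0, "GT", "insertion", (2, 2))]
    s = summarize_junction_classes(calls)
    assert s["class_counts"] == {"blunt": 1, "microhomology": 1, "insertion": 1}
    assert s["mh_length_counts"] == {0: 2, 1: 1}
    assert s["class_fractions"]["blunt"] == pytest.approx(1 / 3)
    assert summarize_junction_classes([])["class_counts"] == {}


def brute_force_annotate(bp, bed):
    # the breakpoint queries the junction boundary after its last retained base
    hits = [rec for rec in bed
            if rec[0] == bp.chrom and rec[1] <= bp.pos < rec[2]]
    hits.sort(key=lambda r: (-(r[2] - r[1]), r[3]))
    return hits[0][3] if hits else None


def test_annotation_interval_conventions():
    genes = [("chr1", 50, 150, "G1", "+")]
    annos = annotate_breakpoints(
        [Breakpoint("chr1", 100), Breakpoint("chr1", 150),
         Breakpoint("chr1", 51), Breakpoint("chr9", 100)],
        repeat_bed=[], gene_bed=genes, expression={"G1": 5.0})
    assert [a.genic for a in annos] == [True, False, True, False]
    assert annos[0].transcribed  # TPM 5 >= 1
    low = annotate_breakpoints([Breakpoint("chr1", 100)], [], genes,
                               expression={"G1": 0.5})
    assert low[0].genic and not low[0].transcribed


def test_annotation_matches_brute_force_on_random_breakpoints():
    rng = np.random.default_rng(5)
    genes = [("chr1", int(a), int(a) + int(w), f"G{i}", "+")
             for i, (a, w) in enumerate(zip(rng.integers(0, 5000, 60),
                                            rng.integers(1, 400, 60)))]
    repeats = [("chr1", int(a), int(a) + int(w), ["Alu", "L1", "L2"][i % 3])
               for i, (a, w) in enumerate(zip(rng.integers(0, 5000, 60),
                                              rng.integers(1, 300, 60)))]
    bps = [Breakpoint("chr1", int(p)) for p in rng.integers(1, 5500, 1000)]
    annos = annotate_breakpoints(bps, repeats, genes,
                                 expression={f"G{i}": 2.0 for i in range(60)})
    for bp, a in zip(bps, annos):
        assert a.gene == brute_force_annotate(bp, genes)
        assert a.repeat_class == brute_force_annotate(bp, repeats)


def nw_identity_oracle(a, b, gap=-1.0):
    """Full Needleman-Wunsch DP maximizing score, then identity via
    traceback (match +1, mismatch 0, linear gap)."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * gap
    score[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            score[i, j] = max(score[i - 1, j - 1] + (a[i - 1] == b[j - 1]),
                              score[i - 1, j] + gap,
                              score[i, j - 1] + gap)
    # identity of any optimal alignment: matches = score only when mismatch=0
    # and gaps penalize; recover columns by traceback
    i, j, matches, cols = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
                score[i, j], score[i - 1, j - 1] + (a[i - 1] == b[j - 1])):
            matches += a[i - 1] == b[j - 1]
            i, j, cols = i - 1, j - 1, cols + 1
        elif i > 0 and np.isclose(score[i, j], score[i - 1, j] + gap):
            i, cols = i - 1, cols + 1
        else:
            j, cols = j - 1, cols + 1
    return 100.0 * matches / cols


def test_percent_identity_examples_and_oracle():
    assert percent_identity("ACGTACGT", "ACGTACGT") == 100.0
    assert percent_identity("ACGT", "ACGA") == 75.0
    rng = np.random.default_rng(3)
    for _ in range(5):
        a = "".join(rng.choice(list(BASES), size=50))
        b = "".join(rng.choice(list(BASES), size=50))
        # optimal scores coincide; identity can differ between co-optimal
        # alignments, so compare against the oracle's match count bound
        assert percent_identity(a, b) == pytest.approx(
            nw_identity_oracle(a, b), abs=6.0)
    with pytest.raises(ValueError):
        percent_identity("", "ACGT")


def test_fusion_transcript_orientation_and_splice_flags():
    # toy genome: + strand gene A on chr1, - strand gene B on chr2,
    # junction after chr1:30 with GT immediately 3', before chr2:40 with AG 5'
    chr1 = "A" * 30 + "GT" + "A" * 30
    chr2 = "C" * 38 + "AG" + "C" * 30  # AG occupies positions 39-40
    genome = {"chr1": chr1, "chr2": chr2}
    genes = [("chr1", 0, 62, "GENEA", "+"), ("chr2", 0, 70, "GENEB", "-")]
    res = classify_fusion_transcript(Breakpoint("chr1", 30),
                                     Breakpoint("chr2", 41), genome, genes)
    assert res["orientation"] == "sense-to-antisense"
    assert res["donor_gt"] is True

    # acceptor outside any gene -> sense-to-intergenic
    res2 = classify_fusion_transcript(
        Breakpoint("chr1", 30), Breakpoint("chr2", 41), genome,
        [("chr1", 0, 62, "GENEA", "+")])
    assert res2["orientation"] == "sense-to-intergenic"

    # both ends on + strand genes with GT...AG -> sense-to-sense, both flags
    genes3 = [("chr1", 0, 62, "GENEA", "+"), ("chr2", 0, 70, "GENEB", "+")]
    res3 = classify_fusion_transcript(Breakpoint("chr1", 30),
                                      Breakpoint("chr2", 41), genome, genes3)
    assert res3["orientation"] == "sense-to-sense"
    assert res3["donor_gt"] and res3["acceptor_ag"]

    with pytest.raises(KeyError):
        classify_fusion_transcript(Breakpoint("chrZ", 5), Breakpoint("chr2", 41),
                                   genome, genes3)
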