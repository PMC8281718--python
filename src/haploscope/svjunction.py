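"""Nucleotide-resolution classification and annotation of SV fusion junctions.

A structural-variant junction fuses the end of a "left" reference flank to
the start of a "right" reference flank.  Comparing the assembled fusion
contig with both flanks reveals the junction chemistry: blunt joins and
short microhomologies are the signature of classical non-homologous end
joining, while untemplated inserted bases point to polymerase-mediated end
joining.  Microhomology is defined by split ambiguity: the junction-adjacent
bases that can be attributed to either flank.  If a contig of length L
matches the left flank over its first A bases and the right flank over its
last B bases, every split position in [L-B, A] explains the contig, so the
microhomology length is A + B - L (the number of equivalent splits minus
one); when A + B < L the unexplained middle segment is an untemplated
insertion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "Breakpoint",
    "JunctionCall",
    "BreakpointAnnotation",
    "classify_junction",
    "summarize_junction_classes",
    "annotate_breakpoints",
    "percent_identity",
    "classify_fusion_transcript",
]


class UnalignableContigError(ValueError):
    """Fusion contig inconsistent with both flanks beyond the insertion model."""


@dataclass(frozen=True)
class Breakpoint:
    """1-based position of the last retained reference base on one side."""

    chrom: str
    pos: int
    orientation: str = "left"  # side of pos retained in the derivative

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("breakpoint pos must be >= 1")
        if self.orientation not in ("left", "right"):
            raise ValueError("orientation must be 'left' or 'right'")


@dataclass
class JunctionCall:
    event_id: str
    microhomology_len: int
    inserted_seq: str
    junction_class: str  # blunt | microhomology | insertion
    ambiguous_shift_range: tuple[int, int]  # [first, last] valid split position

    def __post_init__(self) -> None:
        ok = (
            (self.junction_class == "blunt"
             and self.microhomology_len == 0 and not self.inserted_seq)
            or (self.junction_class == "microhomology"
                and self.microhomology_len >= 1 and not self.inserted_seq)
            or (self.junction_class == "insertion"
                and self.microhomology_len == 0 and self.inserted_seq)
        )
        if not ok:
            raise ValueError("inconsistent junction call")


@dataclass
class BreakpointAnnotation:
    genic: bool
    gene: str | None
    transcribed: bool
    repeat_class: str | None
    homologous_pair_identity: float | None = None

    def __post_init__(self) -> None:
        if self.gene is None and self.genic:
            raise ValueError("genic annotation requires a gene name")


def _match_extents(contig: str, left_flank: str, right_flank: str) -> tuple[int, int]:
    """(A, B): longest contig prefix matching the left-flank suffix, and
    longest contig suffix matching the right-flank prefix."""
    limit_a = min(len(contig), len(left_flank))
    a = 0
    for x in range(1, limit_a + 1):
        if contig[:x] == left_flank[-x:]:
            a = x
    limit_b = min(len(contig), len(right_flank))
    b = 0
    for y in range(1, limit_b + 1):
        if contig[-y:] == right_flank[:y]:
            b = y
    return a, b


def classify_junction(
    left_flank: str,
    right_flank: str,
    fusion_contig: str,
    event_id: str = "",
    max_scan: int = 20,
) -> JunctionCall:
    """Classify one fusion junction from its contig and reference flanks.

    ``left_flank`` ends at (and includes) the left breakpoint base;
    ``right_flank`` starts at the right breakpoint base.  The canonical
    split is the leftmost equivalent placement; reporting is independent of
    that choice.  A contig whose unexplained middle segment exceeds
    ``max_scan`` bases, or that fails to match either flank at all, raises
    :class:`UnalignableContigError`.
    """
    contig = fusion_contig.upper()
    lf, rf = left_flank.upper(), right_flank.upper()
    L = len(contig)
    if L == 0:
        raise UnalignableContigError("empty fusion contig")
    a, b = _match_extents(contig, lf, rf)
    if a == 0 or b == 0:
        raise UnalignableContigError(
            f"contig matches left flank over {a} bp and right flank over {b} bp"
        )
    if a + b >= L:
        mh = a + b - L
        first, last = L - b, a  # all split positions in [first, last] are valid
        if mh > max_scan:
            raise UnalignableContigError(f"homology {mh} bp exceeds max_scan={max_scan}")
        return JunctionCall(
            event_id=event_id,
            microhomology_len=mh,
            inserted_seq="",
            junction_class="blunt" if mh == 0 else "microhomology",
            ambiguous_shift_range=(first, last),
        )
    ins = contig[a:L - b]
    if len(ins) > max_scan:
        raise UnalignableContigError(
            f"unexplained middle segment of {len(ins)} bp exceeds max_scan={max_scan}"
        )
    return JunctionCall(
        event_id=event_id,
        microhomology_len=0,
        inserted_seq=ins,
        junction_class="insertion",
        ambiguous_shift_range=(a, a),
    )


def summarize_junction_classes(calls: Sequence[JunctionCall]):
    """Histogram of junction classes and microhomology lengths.

    Returns a dict with per-class counts, per-microhomology-length counts,
    and fractions over the evaluable (classified) events.
    """
    n = len(calls)
    by_class = Counter(c.junction_class for c in calls)
    by_mh = Counter(c.microhomology_len for c in calls)
    return {
        "n_evaluable": n,
        "class_counts": dict(by_class),
        "mh_length_counts": dict(sorted(by_mh.items())),
        "class_fractions": {k: v / n for k, v in by_class.items()} if n else {},
    }


def _interval_trees(bed_records):
    """Per-chromosome interval trees from (chrom, start, end, name[, ...]) rows."""
    trees: dict[str, IntervalTree] = {}
    for rec in bed_records:
        chrom, start, end, name = rec[0], int(rec[1]), int(rec[2]), rec[3]
        if end <= start:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(start, end, tuple(rec[3:]) or (name,))
    return trees


def annotate_breakpoints(
    breakpoints: Sequence[Breakpoint],
    repeat_bed: Sequence[tuple],
    gene_bed: Sequence[tuple],
    expression: Mapping[str, float],
    min_tpm: float = 1.0,
) -> list[BreakpointAnnotation]:
    """Annotate breakpoints against repeat and gene tracks.

    BED records are 0-based half-open ``(chrom, start, end, name[, extra])``;
    a 1-based breakpoint position p occupies the half-open interval
    [p-1, p).  A breakpoint is genic when inside any gene interval and
    transcribed when that gene's expression is >= ``min_tpm``.  When several
    repeats overlap, the class with the largest overlap with the containing
    region wins (for a point query, ties go to the lexicographically first
    class).
    """
    gene_trees = _interval_trees(gene_bed)
    repeat_trees = _interval_trees(repeat_bed)
    out = []
    for bp in breakpoints:
        # the breakpoint is the junction boundary just after the last
        # retained base, i.e. 0-based coordinate == the 1-based base index
        point = bp.pos
        genes = sorted(
            (iv for iv in gene_trees.get(bp.chrom, IntervalTree()).at(point)),
            key=lambda iv: (-(iv.end - iv.begin), iv.data[0]),
        )
        repeats = sorted(
            (iv for iv in repeat_trees.get(bp.chrom, IntervalTree()).at(point)),
            key=lambda iv: (-(iv.end - iv.begin), iv.data[0]),
        )
        gene = genes[0].data[0] if genes else None
        tpm = float(expression.get(gene, 0.0)) if gene is not None else 0.0
        out.append(BreakpointAnnotation(
            genic=gene is not None,
            gene=gene,
            transcribed=gene is not None and tpm >= min_tpm,
            repeat_class=repeats[0].data[0] if repeats else None,
        ))
    return out


def percent_identity(seq_a: str, seq_b: str, gap_score: float = -1.0) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Scoring: match +1, mismatch 0, linear gap penalty ``gap_score``.
    Identity is matches / alignment columns x 100 over the highest-scoring
    alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = gap_score
    aligner.extend_gap_score = gap_score
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    matches = 0
    columns = 0
    sa, sb = str(aln[0]), str(aln[1])
    for x, y in zip(sa, sb):
        columns += 1
        if x == y and x != "-":
            matches += 1
    return 100.0 * matches / columns


def classify_fusion_transcript(
    donor: Breakpoint,
    acceptor: Breakpoint,
    genome: Mapping[str, str],
    gene_bed_with_strand: Sequence[tuple],
) -> dict:
    """Orientation class and splice-site flags of one fusion transcript.

    ``gene_bed_with_strand`` rows are (chrom, start, end, name, strand).
    The donor side is checked for the canonical 5'-splice dinucleotide GT
    immediately 3' of the junction on the transcribed strand, and the
    acceptor side for AG immediately 5' of the junction.  The orientation
    class is derived from the strands of the genes overlapping each end:
    sense-to-sense, sense-to-antisense, sense-to-intergenic, or
    antisense-origin when the donor end lies in no gene or only on the
    antisense strand of one.
    """
    for bp in (donor, acceptor):
        if bp.chrom not in genome:
            raise KeyError(f"junction chromosome {bp.chrom!r} not in genome")
        if bp.pos > len(genome[bp.chrom]):
            raise ValueError(f"junction at {bp.chrom}:{bp.pos} outside genome")
    trees = _interval_trees(gene_bed_with_strand)

    def gene_at(bp: Breakpoint):
        hits = trees.get(bp.chrom, IntervalTree()).at(bp.pos)
        if not hits:
            return None
        iv = sorted(hits, key=lambda iv: iv.data[0])[0]
        return iv.data[0], iv.data[1]  # name, strand

    def seq_of(chrom: str) -> str:
        s = genome.get(chrom)
        if s is None:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return s

    def after(chrom: str, pos1: int) -> str:
        """Two bases at 1-based positions pos1+1, pos1+2."""
        s = seq_of(chrom)[pos1: pos1 + 2]
        if len(s) < 2:
            raise ValueError(f"junction at {chrom}:{pos1} outside provided genome")
        return s.upper()

    def before(chrom: str, pos1: int) -> str:
        """Two bases at 1-based positions pos1-2, pos1-1."""
        if pos1 < 3:
            raise ValueError(f"junction at {chrom}:{pos1} outside provided genome")
        return seq_of(chrom)[pos1 - 3: pos1 - 1].upper()

    donor_gene = gene_at(donor)
    acceptor_gene = gene_at(acceptor)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def revcomp(s: str) -> str:
        return "".join(comp[b] for b in reversed(s))

    # donor: GT immediately 3' of the junction on the transcribed strand
    donor_gt = False
    if donor_gene is not None:
        if donor_gene[1] == "+":
            donor_gt = after(donor.chrom, donor.pos) == "GT"
        else:
            donor_gt = revcomp(before(donor.chrom, donor.pos)) == "GT"
    # acceptor: AG immediately 5' of the junction on the transcribed strand
    acceptor_strand = acceptor_gene[1] if acceptor_gene else "+"
    if acceptor_strand == "+":
        acceptor_ag = before(acceptor.chrom, acceptor.pos) == "AG"
    else:
        acceptor_ag = revcomp(after(acceptor.chrom, acceptor.pos)) == "AG"

    if donor_gene is None:
        orientation = "antisense-origin"
    elif acceptor_gene is None:
        orientation = "sense-to-intergenic"
    elif donor_gene[1] == acceptor_gene[1]:
        orientation = "sense-to-sense"
    else:
        orientation = "sense-to-antisense"

    return {
        "orientation": orientation,
        "donor_gene": donor_gene[0] if donor_gene else None,
        "acceptor_gene": acceptor_gene[0] if acceptor_gene else None,
        "donor_gt": donor_gt,
        "acceptor_ag": acceptor_ag,
    }
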