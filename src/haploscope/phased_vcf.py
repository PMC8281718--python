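"""Phased-VCF handling: phase-set haplotype blocks and haplotype vectors.

Linked-read phasing emits per-sample VCFs whose heterozygous genotypes are
phased ("0|1") and grouped into haplotype blocks by the FORMAT/PS phase-set
tag, with a per-call phase quality PQ.  This module reads and writes such
VCFs, assembles blocks from calls whose phase quality passes a threshold,
stitches blocks broken in one sample using the phasing of a matched sample
(e.g. a normal stitched with its tumor), and extracts labeled binary
haplotype vectors around a focal risk allele for downstream PCA and
fine-mapping.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VariantCall",
    "HaplotypeBlock",
    "HaplotypeVector",
    "VcfParseError",
    "read_phased_vcf",
    "write_phased_vcf",
    "build_haplotype_blocks",
    "stitch_blocks",
    "extract_haplotype_vectors",
    "site_concordance",
]

Site = tuple  # (chrom, pos, ref, alt)


class VcfParseError(ValueError):
    """Malformed VCF record; carries the offending 1-based line number."""


class FragmentedHaplotypeError(ValueError):
    """The focal window is not covered by a single phase-set block."""


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: tuple[int, int]
    phased: bool
    sample_id: str
    phase_set: int | None = None
    phase_quality: int | None = None
    info_freqs: dict | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if self.phase_set is not None and not self.phased:
            raise ValueError("phase_set present on an unphased call")

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]


@dataclass
class HaplotypeBlock:
    """Ordered alleles of both haplotypes over one phase set of one sample."""

    sample_id: str
    phase_set: int
    sites: list[Site]
    hap1_alleles: list[int]
    hap2_alleles: list[int]

    def __post_init__(self) -> None:
        if not (len(self.sites) == len(self.hap1_alleles) == len(self.hap2_alleles)):
            raise ValueError("sites and allele tracks must have equal length")
        positions = [s[1] for s in self.sites]
        if positions != sorted(positions):
            raise ValueError("block sites must be position-sorted")

    @property
    def start(self) -> int:
        return self.sites[0][1]

    @property
    def end(self) -> int:
        return self.sites[-1][1]


@dataclass
class HaplotypeVector:
    """Binary haplotype over an ordered site list, labeled by focal carriage."""

    site_index: list[Site]
    values: np.ndarray
    label: str  # "mutant" | "wild_type"
    origin: str = "cohort"  # "cohort" | "panel"
    population: str = "unknown"
    hap_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.site_index),):
            raise ValueError("values length must match site_index")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("haplotype values must be 0/1")
        if self.label not in ("mutant", "wild_type"):
            raise ValueError(f"bad label {self.label!r}")


# ---------------------------------------------------------------------------
# VCF I/O


def _prevalidate_vcf(path: str | Path) -> None:
    """Cheap structural scan so malformed records fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise VcfParseError(
                    f"line {lineno}: expected >= 10 tab-separated fields, got {len(fields)}"
                )
            try:
                int(fields[1])
            except ValueError:
                raise VcfParseError(f"line {lineno}: POS {fields[1]!r} is not an integer")


def read_phased_vcf(
    path: str | Path,
    sample_id: str | None = None,
    multiallelic: str = "split",
) -> list[VariantCall]:
    """Read one sample's calls from a VCF v4.2 file.

    Parameters
    ----------
    sample_id:
        Sample column to read; defaults to the only sample in the file.
    multiallelic:
        "split" decomposes multiallelic records into biallelic calls keeping
        the PS tag; "reject" raises on them.
    """
    from cyvcf2 import VCF

    _prevalidate_vcf(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_id is None:
        if len(samples) != 1:
            raise ValueError("sample_id required for a multi-sample VCF")
        sample_id = samples[0]
    if sample_id not in samples:
        raise KeyError(f"sample {sample_id!r} not in VCF ({samples})")
    si = samples.index(sample_id)

    calls: list[VariantCall] = []
    for rec in vcf:
        gt = rec.genotypes[si]  # [allele1, allele2, phased] for diploid
        if len(gt) != 3:
            continue  # haploid/missing ploidy records are skipped
        a1, a2, phased = int(gt[0]), int(gt[1]), bool(gt[2])
        if a1 < 0 or a2 < 0:
            continue  # missing genotype
        ps = _format_int(rec, "PS", si)
        pq = _format_int(rec, "PQ", si)
        alts = rec.ALT
        if len(alts) > 1 and multiallelic == "reject":
            raise VcfParseError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        for k, alt in enumerate(alts, start=1):
            g = (1 if a1 == k else 0, 1 if a2 == k else 0)
            if len(alts) > 1 and g == (0, 0):
                continue  # this decomposed allele is absent from the genotype
            calls.append(VariantCall(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                genotype=g, phased=phased, sample_id=sample_id,
                phase_set=ps if phased else None,
                phase_quality=pq,
            ))
    return calls


def _format_int(rec, tag: str, si: int) -> int | None:
    try:
        arr = rec.format(tag)
    except KeyError:
        return None
    if arr is None:
        return None
    val = arr[si]
    val = val[0] if np.ndim(val) else val
    if val is None or (isinstance(val, (int, float, np.integer, np.floating))
                       and (np.isnan(val) if isinstance(val, (float, np.floating)) else False)):
        return None
    v = int(val)
    return None if v < 0 else v


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
##FORMAT=<ID=PQ,Number=1,Type=Integer,Description="Phase quality">
"""


def write_phased_vcf(calls: Sequence[VariantCall], path: str | Path,
                     contigs: dict[str, int] | None = None) -> Path:
    """Write one sample's calls as an uncompressed VCF v4.2 file."""
    path = Path(path)
    if not calls:
        raise ValueError("no calls to write")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) != 1:
        raise ValueError(f"calls span multiple samples: {sorted(sample_ids)}")
    (sample_id,) = sample_ids
    lines = [_VCF_HEADER]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_id}\n")
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
        sep = "|" if c.phased else "/"
        gt = f"{c.genotype[0]}{sep}{c.genotype[1]}"
        fmt_keys, fmt_vals = ["GT"], [gt]
        if c.phase_set is not None:
            fmt_keys.append("PS")
            fmt_vals.append(str(c.phase_set))
        if c.phase_quality is not None:
            fmt_keys.append("PQ")
            fmt_vals.append(str(c.phase_quality))
        lines.append("\t".join([
            c.chrom, str(c.pos), ".", c.ref, c.alt, ".", "PASS", ".",
            ":".join(fmt_keys), ":".join(fmt_vals),
        ]) + "\n")
    path.write_text("".join(lines))
    return path


# ---------------------------------------------------------------------------
# Haplotype blocks


def build_haplotype_blocks(
    calls: Iterable[VariantCall],
    min_phase_quality: int = 23,
    with_excluded: bool = False,
):
    """Group qualifying phased het calls into per-phase-set blocks.

    A call enters a block iff it is heterozygous, phased with a phase set,
    and its phase quality is present and >= ``min_phase_quality`` (the
    threshold above which a call is considered reliably assigned to its
    haplotype).  Calls failing any condition are excluded; pass
    ``with_excluded=True`` to also get them back for audit.
    """
    calls = list(calls)
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"calls span multiple samples: {sorted(sample_ids)}")
    by_ps: dict[int, list[VariantCall]] = defaultdict(list)
    excluded: list[VariantCall] = []
    for c in calls:
        if (c.is_het and c.phased and c.phase_set is not None
                and c.phase_quality is not None
                and c.phase_quality >= min_phase_quality):
            by_ps[c.phase_set].append(c)
        else:
            excluded.append(c)
    blocks = []
    for ps, group in sorted(by_ps.items()):
        group.sort(key=lambda c: c.pos)
        blocks.append(HaplotypeBlock(
            sample_id=group[0].sample_id,
            phase_set=ps,
            sites=[c.site for c in group],
            hap1_alleles=[c.genotype[0] for c in group],
            hap2_alleles=[c.genotype[1] for c in group],
        ))
    blocks.sort(key=lambda b: b.start)
    if with_excluded:
        return blocks, excluded
    return blocks


def _orientation(bridge: HaplotypeBlock, target: HaplotypeBlock,
                 min_informative: int, min_consistency: float):
    """Relative phase of ``target`` vs ``bridge`` over shared het sites.

    Returns +1 (same), -1 (flipped) or None (too few shared sites or
    inconsistent evidence).
    """
    b_idx = {s: i for i, s in enumerate(bridge.sites)}
    shared = [(b_idx[s], j) for j, s in enumerate(target.sites) if s in b_idx]
    if len(shared) < min_informative:
        return None
    agree = sum(bridge.hap1_alleles[i] == target.hap1_alleles[j] for i, j in shared)
    frac = agree / len(shared)
    if frac >= min_consistency:
        return +1
    if (1 - frac) >= min_consistency:
        return -1
    return None


def stitch_blocks(
    target_blocks: Sequence[HaplotypeBlock],
    bridge_blocks: Sequence[HaplotypeBlock],
    min_informative: int = 3,
    min_consistency: float = 0.9,
) -> list[HaplotypeBlock]:
    """Merge adjacent target blocks using a bridging sample's phasing.

    Two position-adjacent target blocks are merged when a single bridge
    block overlaps both with at least ``min_informative`` shared het sites
    per side and the haplotype orientation on each side is supported by at
    least ``min_consistency`` allele agreement.  The second block's
    haplotypes are swapped when the two sides disagree in orientation
    relative to the bridge.  Allele values are never altered; non-stitchable
    input is returned unchanged.
    """
    blocks = sorted(target_blocks, key=lambda b: b.start)
    merged = True
    while merged and len(blocks) > 1:
        merged = False
        for i in range(len(blocks) - 1):
            a, b = blocks[i], blocks[i + 1]
            for bridge in bridge_blocks:
                ori_a = _orientation(bridge, a, min_informative, min_consistency)
                ori_b = _orientation(bridge, b, min_informative, min_consistency)
                if ori_a is None or ori_b is None:
                    continue
                flip_b = ori_a != ori_b
                h1b = b.hap2_alleles if flip_b else b.hap1_alleles
                h2b = b.hap1_alleles if flip_b else b.hap2_alleles
                blocks[i] = HaplotypeBlock(
                    sample_id=a.sample_id,
                    phase_set=a.phase_set,
                    sites=a.sites + b.sites,
                    hap1_alleles=a.hap1_alleles + list(h1b),
                    hap2_alleles=a.hap2_alleles + list(h2b),
                )
                del blocks[i + 1]
                merged = True
                break
            if merged:
                break
    return blocks


# ---------------------------------------------------------------------------
# Haplotype vectors


def extract_haplotype_vectors(
    blocks: Sequence[HaplotypeBlock],
    focal: tuple[str, int, str],
    panel_sites: Sequence[Site],
    halfwidth_bp: int = 100_000,
    hom_calls: Sequence[VariantCall] = (),
) -> tuple[HaplotypeVector, HaplotypeVector]:
    """Binary haplotype vectors over the focal window, labeled by carriage.

    The window is closed: ``[focal_pos - halfwidth, focal_pos + halfwidth]``.
    All phased het sites of the sample inside the window must belong to one
    (possibly stitched) block, else a fragmented-haplotype error names the
    gap.  Panel sites absent from the sample's calls are imputed as
    reference (0); homozygous-alt calls may be supplied via ``hom_calls``
    and set both haplotypes to 1 at their sites.  The haplotype carrying the
    focal alt allele is labeled mutant.
    """
    chrom, fpos, falt = focal
    lo, hi = fpos - halfwidth_bp, fpos + halfwidth_bp
    if not panel_sites:
        raise ValueError("panel_sites must be nonempty")

    in_window = [b for b in blocks
                 if any(s[0] == chrom and lo <= s[1] <= hi for s in b.sites)]
    if len(in_window) > 1:
        in_window.sort(key=lambda b: b.start)
        gaps = [(a.end, b.start) for a, b in zip(in_window, in_window[1:])]
        raise FragmentedHaplotypeError(
            f"window {chrom}:{lo}-{hi} spans {len(in_window)} blocks; "
            f"gap(s) at {gaps}"
        )
    block = in_window[0] if in_window else None

    window_sites = [s for s in panel_sites if s[0] == chrom and lo <= s[1] <= hi]
    allele_map: dict[Site, tuple[int, int]] = {}
    if block is not None:
        for s, a1, a2 in zip(block.sites, block.hap1_alleles, block.hap2_alleles):
            allele_map[s] = (a1, a2)
    for c in hom_calls:
        if c.genotype == (1, 1):
            allele_map[c.site] = (1, 1)

    v1 = np.array([allele_map.get(s, (0, 0))[0] for s in window_sites], dtype=np.int8)
    v2 = np.array([allele_map.get(s, (0, 0))[1] for s in window_sites], dtype=np.int8)

    focal_alleles = (0, 0)
    for s, pair in allele_map.items():
        if s[0] == chrom and s[1] == fpos and s[3] == falt:
            focal_alleles = pair
            break
    sample = block.sample_id if block is not None else (
        hom_calls[0].sample_id if hom_calls else "sample")
    out = []
    for hap_no, (v, fa) in enumerate(zip((v1, v2), focal_alleles), start=1):
        out.append(HaplotypeVector(
            site_index=window_sites, values=v,
            label="mutant" if fa == 1 else "wild_type",
            origin="cohort", hap_id=f"{sample}.h{hap_no}",
        ))
    return out[0], out[1]


def site_concordance(
    calls_a: Sequence[VariantCall],
    calls_b: Sequence[VariantCall],
):
    """Concordance between two call sets over the same samples.

    A site (keyed by sample, chrom, pos) is concordant when both sets call
    it with the same ref/alt and the same unordered genotype.  Returns the
    concordant fraction relative to the union of called sites and the list
    of concordant (chrom, pos, ref, alt) site keys for downstream
    restriction.
    """
    def keyed(calls):
        d = {}
        for c in calls:
            d[(c.sample_id, c.chrom, c.pos)] = (c.ref, c.alt, tuple(sorted(c.genotype)))
        return d

    da, db = keyed(calls_a), keyed(calls_b)
    union = set(da) | set(db)
    if not union:
        return 1.0, []
    concordant_keys = [k for k in union if k in da and k in db and da[k] == db[k]]
    concordant_sites = sorted({(k[1], k[2], da[k][0], da[k][1]) for k in concordant_keys})
    return len(concordant_keys) / len(union), concordant_sites
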