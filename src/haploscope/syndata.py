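"""Synthetic inputs for the haplotype-resolved pipeline, with truth records.

The generator emulates the study conditions end to end:

* a reference panel of phased haplotypes from three populations carrying a
  focal risk allele (the HbS analogue) on population-specific
  identity-by-descent cores inside a 200-kb window, plus ~14 diploid
  trait-carrier cohort cases (28 haplotypes) drawn from the same model;
* structural-variant truth sets whose fusion junctions have designed
  chemistry (blunt, k-bp microhomology, untemplated insertion);
* somatic SNV call sets with planted panel-of-normals artifacts and
  kataegis clusters.

Background population structure follows the Balding-Nichols model: each
site has an ancestral frequency p0, and each population's frequency is
drawn from Beta(p0(1-F)/F, (1-p0)(1-F)/F), so that across-population
variance of the site frequency is F*p0*(1-p0).  Identity-by-descent cores
are copied verbatim from one template haplotype per population; the tight
within-population clustering this produces is the object of the haplotype
PCA, and decay by mutation or recombination is deliberately not modelled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import svjunction
from .phased_vcf import VariantCall, write_phased_vcf

__all__ = [
    "PanelSimConfig",
    "SimulatedPanel",
    "SvTruthRecord",
    "CohortCase",
    "simulate_panel",
    "inject_ibd_core",
    "default_carrier_assignment",
    "simulate_cohort",
    "make_reference",
    "simulate_sv_truth",
    "flanks_for_event",
    "simulate_somatic_calls",
    "write_fixture_bundle",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PanelSimConfig:
    """Study-condition defaults for the reference-panel simulation.

    The window is 200 kb with the focal risk allele at its center; the
    panel holds three populations totalling ~137 carrier haplotypes
    (46+46+45) out of 92 haplotypes each, mirroring the carrier panel the
    haplotype PCA is compared against.
    """

    n_populations: int = 3
    haplotypes_per_population: int = 92
    window_bp: int = 200_000
    n_sites: int = 300
    ancestral_freq_dist: tuple = ("uniform", 0.05, 0.95)
    fst: float = 0.01
    focal_position: int = 100_000
    core_halfwidth_bp: int = 50_000
    chrom: str = "chr11"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if not (0 < self.focal_position <= self.window_bp):
            raise ValueError("focal_position must lie inside the window")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_populations < 1 or self.haplotypes_per_population < 1:
            raise ValueError("population counts must be >= 1")


@dataclass
class SimulatedPanel:
    chrom: str
    sites: list[tuple[int, str, str]]  # (position, ref, alt)
    haplotypes: np.ndarray  # (n_haplotypes, n_sites) in {0,1}
    population_label: list[str]
    carrier_flag: np.ndarray  # bool per haplotype
    pop_freqs: dict[str, np.ndarray]
    focal_position: int
    window_bp: int = 200_000
    truth: dict = field(default_factory=dict)  # population -> core boundaries
    seed: int = 0

    @property
    def focal_index(self) -> int:
        return [s[0] for s in self.sites].index(self.focal_position)

    @property
    def site_index(self) -> list[tuple]:
        """(chrom, pos, ref, alt) keys compatible with phased_vcf vectors."""
        return [(self.chrom, p, r, a) for p, r, a in self.sites]

    @property
    def populations(self) -> list[str]:
        return sorted(self.pop_freqs)


def _draw_p0(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=n)
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size=n)
    raise ValueError(f"unknown ancestral_freq_dist {dist!r}")


def simulate_panel(config: PanelSimConfig) -> SimulatedPanel:
    """Draw a phased haplotype panel under the Balding-Nichols model.

    The focal site is always included in the site list and starts with the
    alt allele absent everywhere; carriers acquire it via
    :func:`inject_ibd_core`.  Identical config and seed give bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n_other = config.n_sites - 1
    positions = rng.choice(np.arange(1, config.window_bp + 1), size=config.n_sites * 2,
                           replace=False)
    positions = [int(p) for p in positions if p != config.focal_position][:n_other]
    positions = sorted(positions + [config.focal_position])
    focal_idx = positions.index(config.focal_position)

    refs = _BASES[rng.integers(0, 4, size=config.n_sites)]
    alt_shift = rng.integers(1, 4, size=config.n_sites)
    alts = _BASES[(np.searchsorted(_BASES, refs) + alt_shift) % 4]
    sites = list(zip(positions, refs.tolist(), alts.tolist()))

    p0 = _draw_p0(rng, config.ancestral_freq_dist, config.n_sites)
    F = config.fst
    pops = [f"POP{i + 1}" for i in range(config.n_populations)]
    pop_freqs: dict[str, np.ndarray] = {}
    hap_rows, labels = [], []
    for pop in pops:
        if F > 0:
            alpha = p0 * (1 - F) / F
            beta = (1 - p0) * (1 - F) / F
            freqs = rng.beta(alpha, beta)
        else:
            freqs = p0.copy()
        freqs[focal_idx] = 0.0  # focal allele only enters via IBD cores
        pop_freqs[pop] = freqs
        draws = rng.random((config.haplotypes_per_population, config.n_sites)) < freqs
        hap_rows.append(draws.astype(np.int8))
        labels += [pop] * config.haplotypes_per_population

    haplotypes = np.vstack(hap_rows)
    haplotypes[:, focal_idx] = 0
    return SimulatedPanel(
        chrom=config.chrom,
        sites=sites,
        haplotypes=haplotypes,
        population_label=labels,
        carrier_flag=np.zeros(len(labels), dtype=bool),
        pop_freqs=pop_freqs,
        focal_position=config.focal_position,
        window_bp=config.window_bp,
        seed=config.seed,
    )


def default_carrier_assignment(config: PanelSimConfig) -> dict[str, int]:
    """~137 carriers split as evenly as possible across the populations."""
    total = min(137, config.n_populations * config.haplotypes_per_population // 2)
    base, extra = divmod(total, config.n_populations)
    return {f"POP{i + 1}": base + (1 if i < extra else 0)
            for i in range(config.n_populations)}


def inject_ibd_core(
    panel: SimulatedPanel,
    carrier_assignment: Mapping[str, int],
    core_halfwidth_bp: int,
    seed: int | None = None,
) -> SimulatedPanel:
    """Plant population-specific identity-by-descent cores around the focal site.

    Within each population one template haplotype's alleles inside
    [focal - halfwidth, focal + halfwidth] are copied verbatim onto every
    designated carrier, and the focal-site allele is set to 1 on carriers
    (and 0 on everyone else), so carrier_flag and the focal allele agree by
    construction.  Alleles outside the core are untouched.
    """
    if core_halfwidth_bp < 0:
        raise ValueError("negative core half-width")
    positions = np.array([s[0] for s in panel.sites])
    lo = panel.focal_position - core_halfwidth_bp
    hi = panel.focal_position + core_halfwidth_bp
    if lo < 1 or hi > panel.window_bp:
        raise ValueError(
            f"core [{lo}, {hi}] exceeds the simulated window [1, {panel.window_bp}]"
        )
    core_cols = np.flatnonzero((positions >= lo) & (positions <= hi))

    rng = np.random.default_rng(panel.seed + 104729 if seed is None else seed)
    haps = panel.haplotypes.copy()
    carrier = np.zeros(haps.shape[0], dtype=bool)
    labels = np.array(panel.population_label)
    truth = dict(panel.truth)
    for pop, count in carrier_assignment.items():
        members = np.flatnonzero(labels == pop)
        if count > len(members):
            raise ValueError(f"{count} carriers requested for {pop} with only "
                             f"{len(members)} haplotypes")
        if count == 0:
            continue
        chosen = rng.choice(members, size=count, replace=False)
        template = haps[chosen[0], core_cols].copy()
        for h in chosen:
            haps[h, core_cols] = template
        carrier[chosen] = True
        truth[pop] = {"core_lo": int(lo), "core_hi": int(hi),
                      "template_haplotype": int(chosen[0]),
                      "carriers": sorted(int(h) for h in chosen)}
    fi = panel.focal_index
    haps[:, fi] = 0
    haps[carrier, fi] = 1
    return replace(panel, haplotypes=haps, carrier_flag=carrier, truth=truth)


@dataclass
class CohortCase:
    """One diploid trait-carrier case: a mutant and a wild-type haplotype."""

    sample_id: str
    population: str
    hap_mutant: np.ndarray
    hap_wildtype: np.ndarray


def simulate_cohort(
    panel: SimulatedPanel,
    n_cases: int = 14,
    seed: int | None = None,
) -> list[CohortCase]:
    """Draw diploid trait-carrier cases from the injected panel model.

    Each case is assigned a population round-robin; its mutant haplotype
    copies that population's core template (focal allele 1) with
    population-model alleles outside the core, and its wild-type haplotype
    is drawn entirely from the population model with focal allele 0.
    Requires a panel that has been through :func:`inject_ibd_core`.
    """
    if not panel.truth:
        raise ValueError("panel has no injected cores; run inject_ibd_core first")
    rng = np.random.default_rng(panel.seed + 15485863 if seed is None else seed)
    positions = np.array([s[0] for s in panel.sites])
    fi = panel.focal_index
    pops = sorted(panel.truth)
    cases = []
    for i in range(n_cases):
        pop = pops[i % len(pops)]
        info = panel.truth[pop]
        core_cols = np.flatnonzero((positions >= info["core_lo"])
                                   & (positions <= info["core_hi"]))
        freqs = panel.pop_freqs[pop]
        hm = (rng.random(len(positions)) < freqs).astype(np.int8)
        hm[core_cols] = panel.haplotypes[info["template_haplotype"], core_cols]
        hm[fi] = 1
        hw = (rng.random(len(positions)) < freqs).astype(np.int8)
        hw[fi] = 0
        cases.append(CohortCase(sample_id=f"CASE{i + 1:02d}", population=pop,
                                hap_mutant=hm, hap_wildtype=hw))
    return cases


def cohort_calls(
    panel: SimulatedPanel,
    case: CohortCase,
    phase_quality: int = 40,
    phase_set: int = 1,
    break_at: int | None = None,
    swap_after_break: bool = False,
) -> list[VariantCall]:
    """Phased VCF-style calls for one diploid case.

    ``break_at`` splits the phasing into two phase sets at that position
    (emulating a phase-block break in one sample); ``swap_after_break``
    additionally swaps hap1/hap2 in the second phase set, which is exactly
    the ambiguity block stitching must resolve.  Homozygous-reference sites
    are not emitted, matching per-sample variant-caller output.
    """
    calls = []
    for j, (pos, ref, alt) in enumerate(panel.sites):
        g = (int(case.hap_mutant[j]), int(case.hap_wildtype[j]))
        if g == (0, 0):
            continue
        ps = phase_set
        if break_at is not None and pos >= break_at:
            ps = phase_set + 1
            if swap_after_break:
                g = (g[1], g[0])
        calls.append(VariantCall(
            chrom=panel.chrom, pos=pos, ref=ref, alt=alt, genotype=g,
            phased=True, sample_id=case.sample_id, phase_set=ps,
            phase_quality=phase_quality,
        ))
    return calls


# ---------------------------------------------------------------------------
# Structural-variant truth


@dataclass
class SvTruthRecord:
    event_id: str
    left_breakpoint: tuple[str, int, str]  # (contig, 1-based pos, orientation)
    right_breakpoint: tuple[str, int, str]
    designed_class: str  # blunt | microhomology | insertion
    designed_mh_len: int
    designed_ins_seq: str
    fusion_contig: str
    event_type: str  # deletion | translocation

    def __post_init__(self) -> None:
        if self.designed_class == "microhomology" and self.designed_mh_len < 1:
            raise ValueError("microhomology design requires k >= 1")
        if self.designed_class == "insertion" and not self.designed_ins_seq:
            raise ValueError("insertion design requires a nonempty sequence")


def make_reference(names: Sequence[str] = ("chrA", "chrB"), length: int = 10_000,
                   seed: int = 0) -> dict[str, str]:
    """Random uniform-composition reference sequences for SV simulation."""
    rng = np.random.default_rng(seed)
    return {n: "".join(_BASES[rng.integers(0, 4, size=length)]) for n in names}


def flanks_for_event(reference: Mapping[str, str], rec: SvTruthRecord,
                     flank_len: int = 60) -> tuple[str, str]:
    """Reference flanks around an event: left ends at, right starts at, the
    breakpoint base."""
    lc, lp, _ = rec.left_breakpoint
    rc, rp, _ = rec.right_breakpoint
    left = reference[lc][max(lp - flank_len, 0): lp]
    right = reference[rc][rp - 1: rp - 1 + flank_len]
    return left, right


def simulate_sv_truth(
    reference: Mapping[str, str],
    n_events: int,
    class_mix: Mapping[str, float],
    seed: int = 0,
    flank: int = 30,
    mh_range: tuple[int, int] = (1, 5),
    ins_range: tuple[int, int] = (1, 4),
    max_resample: int = 200,
) -> list[SvTruthRecord]:
    """Sample SV events with designed junction chemistry.

    ``class_mix`` gives probabilities over {"blunt", "microhomology",
    "insertion"}.  Microhomology events place the right breakpoint where
    the reference already repeats the k bases 5' of the junction; insertion
    events carry an untemplated segment engineered to extend neither flank.
    Every constructed contig is verified to round-trip through
    :func:`haploscope.svjunction.classify_junction` to its designed class,
    resampling on chance homology extensions, so designs are unambiguous.
    """
    if n_events == 0:
        return []
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix probabilities must sum to 1")
    names = sorted(reference)
    for n in names:
        if len(reference[n]) <= 2 * (flank + 25):
            raise ValueError(f"reference sequence {n!r} too short for flank={flank}")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_events):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        for attempt in range(max_resample):
            rec = _sample_event(reference, names, cls, rng, flank, mh_range,
                                ins_range, event_id=f"SV{i + 1:04d}")
            if rec is None:
                continue
            lf, rf = flanks_for_event(reference, rec, flank_len=2 * flank)
            try:
                call = svjunction.classify_junction(lf, rf, rec.fusion_contig)
            except svjunction.UnalignableContigError:
                continue
            if (call.junction_class == rec.designed_class
                    and call.microhomology_len == rec.designed_mh_len
                    and call.inserted_seq == rec.designed_ins_seq):
                records.append(rec)
                break
        else:
            raise RuntimeError(f"could not realize a {cls} junction in "
                               f"{max_resample} attempts")
    return records


def _sample_event(reference, names, cls, rng, flank, mh_range, ins_range,
                  event_id):
    lc = names[int(rng.integers(len(names)))]
    rc = names[int(rng.integers(len(names)))]
    seq_l, seq_r = reference[lc], reference[rc]
    margin = flank + 25
    lp = int(rng.integers(margin, len(seq_l) - margin))

    k, ins = 0, ""
    if cls == "microhomology":
        if mh_range[0] == mh_range[1]:
            k = mh_range[0]
        else:
            k = int(rng.integers(mh_range[0], mh_range[1] + 1))
        kmer = seq_l[lp - k: lp]
        # right breakpoint must start with the same k bases
        candidates = _kmer_starts(seq_r, kmer, margin, len(seq_r) - margin)
        if not candidates:
            return None
        rp = candidates[int(rng.integers(len(candidates)))] + 1  # 1-based
    else:
        rp = int(rng.integers(margin, len(seq_r) - margin))
        if cls == "insertion":
            if ins_range[0] == ins_range[1]:
                ln = ins_range[0]
            else:
                ln = int(rng.integers(ins_range[0], ins_range[1] + 1))
            ins = "".join(_BASES[rng.integers(0, 4, size=ln)])

    lf = seq_l[lp - flank: lp]
    rf = seq_r[rp - 1: rp - 1 + flank]
    contig = lf + ins + rf[k:]
    event_type = "deletion" if (lc == rc and rp > lp) else "translocation"
    return SvTruthRecord(
        event_id=event_id,
        left_breakpoint=(lc, lp, "left"),
        right_breakpoint=(rc, rp, "right"),
        designed_class=cls,
        designed_mh_len=k if cls == "microhomology" else 0,
        designed_ins_seq=ins,
        fusion_contig=contig,
        event_type=event_type,
    )


def _kmer_starts(seq: str, kmer: str, lo: int, hi: int) -> list[int]:
    out, start = [], lo
    while True:
        j = seq.find(kmer, start, hi + len(kmer))
        if j == -1:
            return out
        if lo <= j < hi:
            out.append(j)
        start = j + 1


# ---------------------------------------------------------------------------
# Somatic call sets


def simulate_somatic_calls(
    n_real: int,
    n_artifact: int,
    kataegis_clusters: int = 0,
    vaf_dist: tuple = ("uniform", 0.12, 0.45),
    seed: int = 0,
    depth: int = 80,
    n_normals: int = 12,
    n_germline_leak: int = 10,
    kataegis_size: int = 8,
):
    """Somatic SNV call set with planted artifact and kataegis structure.

    Returns ``(calls, normal_call_sets)``: a DataFrame of tumor calls with a
    ``truth`` column in {"real", "artifact", "kataegis", "germline_leak"},
    and per-normal site sets for panel-of-normals construction.  Artifacts
    are planted into >= 2 of the ``n_normals`` synthetic normals; kataegis
    clusters are runs of ``kataegis_size`` closely spaced SNVs (adjacent
    spacing <= 1 kb); real somatic sites draw VAF from ``vaf_dist`` with
    binomial alt counts at fixed ``depth`` (default 80, on the order of the
    tumor coverage the filter defaults were designed for); germline-leak
    sites carry a database population frequency above the removal cutoff.
    """
    if min(n_real, n_artifact, kataegis_clusters) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    normals: list[set] = [set() for _ in range(max(n_normals, 2))]

    def draw_vaf(n):
        kind = vaf_dist[0]
        if kind == "uniform":
            return rng.uniform(vaf_dist[1], vaf_dist[2], size=n)
        if kind == "beta":
            return rng.beta(vaf_dist[1], vaf_dist[2], size=n)
        raise ValueError(f"unknown vaf_dist {vaf_dist!r}")

    def add(chrom, pos, truth, vaf, pop_af):
        ref, alt = _random_snv(rng)
        alt_reads = int(rng.binomial(depth, vaf))
        rows.append({
            "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
            "alt_reads": alt_reads, "depth": depth,
            "vaf": alt_reads / depth, "population_af": float(pop_af),
            "truth": truth,
        })
        return (chrom, int(pos), ref, alt)

    # scattered real somatic calls, >= 2 kb apart so they never cluster
    grid = rng.choice(np.arange(1, 500_000), size=n_real, replace=False) if n_real else []
    for g in grid:
        add("chr1", 2000 * int(g), "real", float(draw_vaf(1)[0]), 0.0)

    # artifacts: present in the tumor and in >= 2 normals
    art_pos = rng.choice(np.arange(1, 400_000), size=n_artifact, replace=False) if n_artifact else []
    for g in art_pos:
        site = add("chr2", 2000 * int(g), "artifact", float(rng.uniform(0.1, 0.5)), 0.0)
        n_obs = int(rng.integers(2, max(n_normals, 2) + 1))
        for ni in rng.choice(len(normals), size=n_obs, replace=False):
            normals[int(ni)].add(site)

    # germline leakage: common database variants that slip into the calls
    leak_pos = rng.choice(np.arange(1, 400_000), size=n_germline_leak, replace=False) \
        if n_germline_leak else []
    for g in leak_pos:
        add("chr3", 2000 * int(g), "germline_leak", float(rng.uniform(0.3, 0.6)),
            float(rng.uniform(0.002, 0.3)))

    # kataegis: tight runs on the chromosome carrying the disrupted gene
    cursor = 1_000_000
    for _ in range(kataegis_clusters):
        pos = cursor
        for _ in range(kataegis_size):
            add("chr22", pos, "kataegis", float(draw_vaf(1)[0]), 0.0)
            pos += int(rng.integers(100, 901))
        cursor = pos + 50_000
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "alt_reads",
                                        "depth", "vaf", "population_af", "truth"])
    return calls, normals


def _random_snv(rng):
    ref = _BASES[int(rng.integers(0, 4))]
    alt = _BASES[(int(np.searchsorted(_BASES, ref)) + int(rng.integers(1, 4))) % 4]
    return str(ref), str(alt)


# ---------------------------------------------------------------------------
# Fixture bundle


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    panel: SimulatedPanel,
    sv_truth: Sequence[SvTruthRecord],
    somatic,
    out_dir: str | Path,
    cohort: Sequence[CohortCase] = (),
    reference: Mapping[str, str] | None = None,
    gene_bed: Sequence[tuple] = (),
    repeat_bed: Sequence[tuple] = (),
    expression: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Serialize a full fixture bundle and return its checksum manifest.

    Emits: panel haplotype TSV, per-case phased VCFs (GT "|", PS, PQ),
    reference FASTA, BEDPE-like breakpoint TSV with the assembled contig
    column, repeat/gene BED tracks, expression TSV, somatic-call TSVs, and
    ``manifest.tsv`` listing every file with its sha256.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # reference panel haplotypes
    site_cols = [f"{panel.chrom}:{p}:{r}:{a}" for p, r, a in panel.sites]
    hap_ids = [f"PANEL_H{i + 1:04d}" for i in range(panel.haplotypes.shape[0])]
    df = pd.DataFrame(panel.haplotypes, columns=site_cols)
    df.insert(0, "haplotype_id", hap_ids)
    df.insert(1, "population", panel.population_label)
    df.insert(2, "carrier", panel.carrier_flag.astype(int))
    p = out / "panel_haplotypes.tsv"
    df.to_csv(p, sep="\t", index=False)
    written.append(p)

    # cohort phased VCFs (first two cases get a phase break in the "normal"
    # file, bridged by an unbroken "tumor" file, to exercise stitching)
    contigs = {panel.chrom: max(s[0] for s in panel.sites) + 1000}
    for i, case in enumerate(cohort):
        broken = i < 2
        break_at = panel.focal_position + 20_000 if broken else None
        normal = cohort_calls(panel, case, break_at=break_at,
                              swap_after_break=broken)
        path_n = out / f"{case.sample_id}.normal.vcf"
        write_phased_vcf(normal, path_n, contigs=contigs)
        written.append(path_n)
        if broken:
            tumor = cohort_calls(panel, case)
            for c in tumor:
                c.sample_id = case.sample_id  # same individual, tumor aliquot
            path_t = out / f"{case.sample_id}.tumor.vcf"
            write_phased_vcf(tumor, path_t, contigs=contigs)
            written.append(path_t)

    if reference:
        p = out / "reference.fasta"
        with open(p, "w") as fh:
            for name in sorted(reference):
                fh.write(f">{name}\n")
                seq = reference[name]
                for j in range(0, len(seq), 60):
                    fh.write(seq[j: j + 60] + "\n")
        written.append(p)

    if sv_truth:
        rows = []
        for r in sv_truth:
            rows.append({
                "chrom1": r.left_breakpoint[0], "pos1": r.left_breakpoint[1],
                "strand1": "+", "chrom2": r.right_breakpoint[0],
                "pos2": r.right_breakpoint[1], "strand2": "+",
                "event_type": r.event_type, "contig_seq": r.fusion_contig,
                "event_id": r.event_id, "designed_class": r.designed_class,
                "designed_mh_len": r.designed_mh_len,
                "designed_ins_seq": r.designed_ins_seq,
            })
        p = out / "breakpoints.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)

    for name, bed in (("repeats.bed", repeat_bed), ("genes.bed", gene_bed)):
        if bed:
            p = out / name
            with open(p, "w") as fh:
                for rec in bed:
                    fh.write("\t".join(str(x) for x in rec) + "\n")
            written.append(p)

    if expression:
        p = out / "expression.tsv"
        pd.DataFrame(sorted(expression.items()), columns=["gene", "TPM"]) \
            .to_csv(p, sep="\t", index=False)
        written.append(p)

    if somatic is not None:
        calls, normals = somatic
        p = out / "somatic_calls.tsv"
        calls.to_csv(p, sep="\t", index=False)
        written.append(p)
        rows = []
        for ni, sites in enumerate(normals):
            for (chrom, pos, ref, alt) in sorted(sites):
                rows.append({"normal_id": f"NORM{ni + 1:02d}", "chrom": chrom,
                             "pos": pos, "ref": ref, "alt": alt})
        p = out / "normal_calls.tsv"
        pd.DataFrame(rows, columns=["normal_id", "chrom", "pos", "ref", "alt"]) \
            .to_csv(p, sep="\t", index=False)
        written.append(p)

    manifest = pd.DataFrame(
        [{"file": f.name, "bytes": f.stat().st_size, "sha256": _sha256(f)}
         for f in written]
    ).sort_values("file").reset_index(drop=True)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
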