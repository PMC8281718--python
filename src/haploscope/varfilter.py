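"""Germline/somatic filter cascades, risk-allele genotyping, kataegis
flagging, trait-enrichment statistics, and read-ratio sex inference.

The somatic cascade mirrors a standard tumor-normal pipeline: recurrent
technical artifacts are blacklisted with a panel of normals (sites seen in
at least two normals), then calls must clear a strict variant-allele-
fraction cutoff (> 10%), a minimum alt-read count (>= 6), and a population
database frequency ceiling (removed when > 0.1%).  The germline candidate
filter keeps disruptive consequences in a candidate gene list at population
frequency < 0.1%.  The strictness of each inequality follows the rules the
cascade was designed around and is asserted in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "PanelOfNormals",
    "RiskAlleleSpec",
    "SexCallResult",
    "build_pon",
    "filter_somatic",
    "filter_germline_candidates",
    "genotype_risk_alleles",
    "detect_kataegis",
    "trait_enrichment",
    "infer_sex",
]

Site = tuple  # (chrom, pos, ref, alt)


@dataclass
class PanelOfNormals:
    """Artifact blacklist: sites recurrently observed across normal samples."""

    observation_counts: dict[Site, int]
    min_samples: int

    @property
    def artifact_sites(self) -> set[Site]:
        return {s for s, n in self.observation_counts.items() if n >= self.min_samples}

    def __contains__(self, site: Site) -> bool:
        return site in self.artifact_sites


@dataclass(frozen=True)
class RiskAlleleSpec:
    """One component of a named risk genotype (e.g. APOL1 G1 has two)."""

    name: str
    group: str  # composite risk genotype this site belongs to, e.g. "G1"
    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SexCallResult:
    x_reads: int
    y_reads: int
    x_to_y_ratio: float
    call: str  # female | male | indeterminate


def build_pon(
    normal_call_sets: Sequence[set | Sequence[Site]],
    min_samples: int = 2,
) -> PanelOfNormals:
    """Panel of normals from per-normal site sets.

    A site enters the artifact list iff observed in >= ``min_samples``
    distinct normals.
    """
    counts: dict[Site, int] = {}
    for sites in normal_call_sets:
        for s in set(map(tuple, sites)):
            counts[s] = counts.get(s, 0) + 1
    return PanelOfNormals(observation_counts=counts, min_samples=min_samples)


def filter_somatic(
    calls: pd.DataFrame,
    pon: PanelOfNormals,
    min_vaf: float = 0.10,
    min_alt: int = 6,
    max_pop_af: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Somatic filter cascade with a per-call audit.

    Retains a call iff its site is not a PON artifact, VAF > ``min_vaf``
    (strict), alt reads >= ``min_alt``, and population AF <= ``max_pop_af``
    (calls are removed when the database frequency exceeds 0.1%).  Returns
    ``(retained, audit)`` where the audit assigns every input call either
    "retained" or the first rule that removed it ("pon", "vaf",
    "alt_reads", "population_af").
    """
    required = {"chrom", "pos", "ref", "alt", "alt_reads", "depth", "vaf",
                "population_af"}
    missing = required - set(calls.columns)
    if missing:
        raise KeyError(f"calls table lacks columns: {sorted(missing)}")
    reasons = []
    for row in calls.itertuples(index=False):
        site = (row.chrom, int(row.pos), row.ref, row.alt)
        if site in pon:
            reasons.append("pon")
        elif not (row.vaf > min_vaf):
            reasons.append("vaf")
        elif not (row.alt_reads >= min_alt):
            reasons.append("alt_reads")
        elif row.population_af > max_pop_af:
            reasons.append("population_af")
        else:
            reasons.append("retained")
    audit = calls.copy()
    audit["filter_reason"] = reasons
    retained = audit[audit["filter_reason"] == "retained"].drop(columns="filter_reason")
    return retained.reset_index(drop=True), audit


def filter_germline_candidates(
    calls: pd.DataFrame,
    candidate_genes: set[str],
    disruptive_classes: set[str] = frozenset(
        {"splice", "frameshift", "stopgain", "nonsense", "deletion"}),
    max_pop_af: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate deleterious germline variants.

    Retained iff annotated gene is in the candidate set, the consequence is
    disruptive, and population AF < ``max_pop_af`` (strict).  Unannotated
    calls are excluded with reason "unannotated".
    """
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence", "population_af"}
    missing = required - set(calls.columns)
    if missing:
        raise KeyError(f"calls table lacks columns: {sorted(missing)}")
    reasons = []
    for row in calls.itertuples(index=False):
        if pd.isna(row.gene) or pd.isna(row.consequence):
            reasons.append("unannotated")
        elif row.gene not in candidate_genes:
            reasons.append("gene")
        elif row.consequence not in disruptive_classes:
            reasons.append("consequence")
        elif not (row.population_af < max_pop_af):
            reasons.append("population_af")
        else:
            reasons.append("retained")
    audit = calls.copy()
    audit["filter_reason"] = reasons
    retained = audit[audit["filter_reason"] == "retained"].drop(columns="filter_reason")
    return retained.reset_index(drop=True), audit


def genotype_risk_alleles(
    calls: Mapping[str, Mapping[Site, tuple[int, int]]],
    specs: Sequence[RiskAlleleSpec],
) -> pd.DataFrame:
    """Per-sample carrier report for composite risk genotypes.

    ``calls`` maps sample -> {site: genotype}.  For every risk group (e.g.
    G1 comprising two component variants, or single-variant G2) the sample
    is "hom_risk" when every component is homozygous alt, "het" when every
    component carries at least one alt allele, else "non_carrier".  A site
    with no call is treated as homozygous reference and flagged.
    """
    groups: dict[str, list[RiskAlleleSpec]] = {}
    for spec in specs:
        groups.setdefault(spec.group, []).append(spec)
    rows = []
    for sample, geno in calls.items():
        for group, members in sorted(groups.items()):
            gts, imputed = [], False
            for spec in members:
                gt = geno.get(spec.site)
                if gt is None:
                    gt = (0, 0)
                    imputed = True
                gts.append(tuple(sorted(gt)))
            if all(gt == (1, 1) for gt in gts):
                status = "hom_risk"
            elif all(sum(gt) >= 1 for gt in gts):
                status = "het"
            else:
                status = "non_carrier"
            rows.append({"sample": sample, "risk_group": group, "status": status,
                         "absent_call_imputed_ref": imputed})
    return pd.DataFrame(rows)


def detect_kataegis(
    positions: Sequence[int],
    max_imd: int = 1000,
    min_run: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kataegis clusters on one chromosome.

    A cluster is a maximal run of >= ``min_run`` consecutive SNVs in which
    every adjacent inter-mutation distance is <= ``max_imd``.  Duplicate
    positions are collapsed before analysis.  Returns ``(clusters,
    rainfall)``: cluster table (start, end, n_snvs, span_bp) and the
    rainfall table (position, distance to previous SNV).
    """
    pos = sorted(set(int(p) for p in positions))
    rainfall = pd.DataFrame({
        "position": pos,
        "imd": [np.nan] + [b - a for a, b in zip(pos, pos[1:])],
    })
    clusters = []
    i = 0
    while i < len(pos):
        j = i
        while j + 1 < len(pos) and pos[j + 1] - pos[j] <= max_imd:
            j += 1
        run = j - i + 1
        if run >= min_run:
            clusters.append({
                "start": pos[i], "end": pos[j], "n_snvs": run,
                "span_bp": pos[j] - pos[i],
            })
        i = j + 1
    return pd.DataFrame(clusters, columns=["start", "end", "n_snvs", "span_bp"]), rainfall


def trait_enrichment(
    carriers: int,
    cohort_n: int,
    population_freq: float,
) -> tuple[float, float]:
    """Fold enrichment of trait carriers and one-sided binomial p-value.

    fold = (carriers / cohort_n) / population_freq;
    p = P(X >= carriers), X ~ Binomial(cohort_n, population_freq).
    """
    if not (0 < population_freq <= 1):
        raise ValueError("population_freq must be in (0, 1]")
    if not (0 <= carriers <= cohort_n):
        raise ValueError("carriers must be between 0 and cohort_n")
    fold = (carriers / cohort_n) / population_freq
    p = float(binom.sf(carriers - 1, cohort_n, population_freq))
    return fold, min(p, 1.0)


def infer_sex(
    read_counts: Mapping[str, int],
    boundary: float = math.sqrt(40 * 4),
    indeterminate_factor: float = 1.25,
) -> SexCallResult:
    """Sex from the chrX:chrY mapped-read ratio.

    Female when the ratio is >= the boundary (the geometric mean of the
    ~40:1 female and ~4:1 male anchor ratios, ~12.65), male when below;
    ratios within ``indeterminate_factor`` of the boundary are flagged
    indeterminate.  Zero chrY reads yield a female call with an infinite
    ratio.
    """
    try:
        x, y = int(read_counts["chrX"]), int(read_counts["chrY"])
    except KeyError as e:
        raise KeyError(f"read counts must include chrX and chrY: missing {e}")
    if y == 0:
        return SexCallResult(x_reads=x, y_reads=0, x_to_y_ratio=math.inf, call="female")
    ratio = x / y
    if boundary / indeterminate_factor <= ratio <= boundary * indeterminate_factor:
        call = "indeterminate"
    elif ratio >= boundary:
        call = "female"
    else:
        call = "male"
    return SexCallResult(x_reads=x, y_reads=y, x_to_y_ratio=ratio, call=call)
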