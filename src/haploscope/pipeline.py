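"""End-to-end orchestration of the haplotype-resolved analyses.

A run consumes either a simulated fixture bundle (the default) or
user-supplied files laid out the same way, and executes: simulate ->
hap-extract -> hap-pca -> fine-map -> sv-classify -> sv-annotate ->
filters.  Each stage reads its inputs from, and writes its outputs to, the
run directory, so stages are independently re-runnable; a JSON run manifest
records per-stage inputs, outputs, checksums and timings, and a completed
stage whose outputs still match their recorded checksums is skipped on
re-run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import finemap, popstruct, svjunction, syndata, varfilter
from .phased_vcf import (HaplotypeVector, build_haplotype_blocks,
                         extract_haplotype_vectors, read_phased_vcf,
                         stitch_blocks)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "haploscope_run"
    seed: int = 0
    simulate: bool = True

    # focal window
    halfwidth_bp: int = 100_000
    min_phase_quality: int = 23
    stitch_min_informative: int = 3
    stitch_min_consistency: float = 0.9

    # simulation sizes (study conditions)
    n_cases: int = 14
    n_sv_events: int = 24
    sv_class_mix: dict = field(default_factory=lambda: {
        "blunt": 0.50, "microhomology": 0.29, "insertion": 0.21})
    n_somatic_real: int = 40
    n_somatic_artifact: int = 12
    kataegis_clusters: int = 2

    # filter thresholds
    pon_min_samples: int = 2
    somatic_min_vaf: float = 0.10
    somatic_min_alt: int = 6
    somatic_max_pop_af: float = 0.001
    kataegis_max_imd: int = 1000
    kataegis_min_run: int = 6
    min_tpm: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class RunManifest:
    stages: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"stages": self.stages}, indent=2))

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(stages=data.get("stages", []))

    def stage(self, name: str) -> dict | None:
        for s in self.stages:
            if s["name"] == name:
                return s
        return None


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Runner:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest()
        mpath = self.out / "run_manifest.json"
        self.previous = RunManifest.from_json(mpath) if mpath.exists() else RunManifest()

    def _cached(self, name: str) -> dict | None:
        prev = self.previous.stage(name)
        if prev is None:
            return None
        for f, sha in prev["outputs"].items():
            p = self.out / f
            if not p.exists() or _sha(p) != sha:
                return None
        return prev

    def run_stage(self, name: str, func, inputs: list[str]) -> None:
        for f in inputs:
            if not (self.out / f).exists():
                raise FileNotFoundError(f"stage {name}: missing input {f}")
        cached = self._cached(name)
        if cached is not None:
            entry = dict(cached)
            entry["cached"] = True
            entry["seconds"] = 0.0
            self.manifest.stages.append(entry)
            return
        t0 = time.perf_counter()
        try:
            outputs = func()
        except Exception as e:
            raise RuntimeError(f"stage {name} failed: {e}") from e
        entry = {
            "name": name,
            "inputs": {f: _sha(self.out / f) for f in inputs},
            "outputs": {f: _sha(self.out / f) for f in outputs},
            "seconds": round(time.perf_counter() - t0, 4),
            "cached": False,
            "warnings": [],
        }
        self.manifest.stages.append(entry)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage on the configured run directory."""
    cfg = config
    r = _Runner(cfg)
    out = r.out

    if cfg.simulate:
        r.run_stage("simulate", lambda: _stage_simulate(cfg, out), inputs=[])

    r.run_stage("hap-extract", lambda: _stage_hap_extract(cfg, out),
                inputs=["panel_sites.tsv", "panel_haplotypes.tsv"])
    r.run_stage("hap-pca", lambda: _stage_hap_pca(cfg, out),
                inputs=["haplotype_vectors.tsv"])
    r.run_stage("fine-map", lambda: _stage_fine_map(cfg, out),
                inputs=["haplotype_vectors.tsv"])
    r.run_stage("sv-classify", lambda: _stage_sv_classify(cfg, out),
                inputs=["breakpoints.tsv", "reference.fasta"])
    r.run_stage("sv-annotate", lambda: _stage_sv_annotate(cfg, out),
                inputs=["breakpoints.tsv", "genes.bed", "repeats.bed",
                        "expression.tsv"])
    r.run_stage("filters", lambda: _stage_filters(cfg, out),
                inputs=["somatic_calls.tsv", "normal_calls.tsv"])

    r.manifest.to_json(out / "run_manifest.json")
    return r.manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, out: Path) -> list[str]:
    pconf = syndata.PanelSimConfig(seed=cfg.seed)
    panel = syndata.simulate_panel(pconf)
    panel = syndata.inject_ibd_core(panel, syndata.default_carrier_assignment(pconf),
                                    pconf.core_halfwidth_bp)
    cohort = syndata.simulate_cohort(panel, n_cases=cfg.n_cases)
    reference = syndata.make_reference(("chrA", "chrB"), length=12_000,
                                       seed=cfg.seed + 1)
    sv_truth = syndata.simulate_sv_truth(reference, cfg.n_sv_events,
                                         cfg.sv_class_mix, seed=cfg.seed + 2)
    somatic = syndata.simulate_somatic_calls(
        cfg.n_somatic_real, cfg.n_somatic_artifact,
        kataegis_clusters=cfg.kataegis_clusters, seed=cfg.seed + 3)
    gene_bed = [("chrA", 1000, 5000, "GENE1", "+"),
                ("chrA", 6000, 11000, "GENE2", "-"),
                ("chrB", 2000, 9000, "GENE3", "+")]
    repeat_bed = [("chrA", 1500, 2500, "L1"), ("chrA", 7000, 7800, "Alu"),
                  ("chrB", 4000, 5200, "L2")]
    expression = {"GENE1": 12.0, "GENE2": 0.2, "GENE3": 5.0}
    syndata.write_fixture_bundle(panel, sv_truth, somatic, out, cohort=cohort,
                                 reference=reference, gene_bed=gene_bed,
                                 repeat_bed=repeat_bed, expression=expression)
    focal_idx = panel.focal_index
    sites = pd.DataFrame(
        [{"chrom": panel.chrom, "pos": p, "ref": rf, "alt": al,
          "focal": int(i == focal_idx)}
         for i, (p, rf, al) in enumerate(panel.sites)]
    )
    sites.to_csv(out / "panel_sites.tsv", sep="\t", index=False)
    produced = [f.name for f in out.iterdir()
                if f.is_file() and f.name not in ("run_manifest.json",)]
    return sorted(produced)


def _read_panel_sites(out: Path):
    df = pd.read_csv(out / "panel_sites.tsv", sep="\t")
    sites = [(row.chrom, int(row.pos), row.ref, row.alt)
             for row in df.itertuples(index=False)]
    focal_row = df[df["focal"] == 1].iloc[0]
    focal = (focal_row["chrom"], int(focal_row["pos"]), focal_row["alt"])
    return sites, focal


def _stage_hap_extract(cfg: RunConfig, out: Path) -> list[str]:
    sites, focal = _read_panel_sites(out)
    vectors: list[HaplotypeVector] = []

    for vcf_path in sorted(out.glob("*.normal.vcf")):
        sample = vcf_path.name.split(".")[0]
        calls = read_phased_vcf(vcf_path, sample)
        blocks = build_haplotype_blocks(calls, cfg.min_phase_quality)
        tumor_path = out / f"{sample}.tumor.vcf"
        if tumor_path.exists() and len(blocks) > 1:
            bridge = build_haplotype_blocks(read_phased_vcf(tumor_path, sample),
                                            cfg.min_phase_quality)
            blocks = stitch_blocks(blocks, bridge,
                                   cfg.stitch_min_informative,
                                   cfg.stitch_min_consistency)
        hom = [c for c in calls if c.genotype == (1, 1)]
        v1, v2 = extract_haplotype_vectors(blocks, focal, sites,
                                           halfwidth_bp=cfg.halfwidth_bp,
                                           hom_calls=hom)
        vectors += [v1, v2]

    panel_df = pd.read_csv(out / "panel_haplotypes.tsv", sep="\t")
    site_cols = [c for c in panel_df.columns
                 if c not in ("haplotype_id", "population", "carrier")]
    panel_sites = []
    for c in site_cols:
        chrom, pos, ref, alt = c.split(":")
        panel_sites.append((chrom, int(pos), ref, alt))
    focal_chrom, focal_pos, _ = focal
    lo, hi = focal_pos - cfg.halfwidth_bp, focal_pos + cfg.halfwidth_bp
    keep = [j for j, s in enumerate(panel_sites)
            if s[0] == focal_chrom and lo <= s[1] <= hi]
    window_sites = [panel_sites[j] for j in keep]
    for row in panel_df.itertuples(index=False):
        values = np.array([row[3 + j] for j in keep], dtype=np.int8)
        vectors.append(HaplotypeVector(
            site_index=window_sites, values=values,
            label="mutant" if row.carrier else "wild_type",
            origin="panel", population=row.population,
            hap_id=row.haplotype_id,
        ))

    common = vectors[0].site_index
    rows = []
    for v in vectors:
        if v.site_index != common:
            raise ValueError("cohort and panel vectors disagree on the site index")
        rows.append({"haplotype_id": v.hap_id, "label": v.label,
                     "origin": v.origin, "population": v.population,
                     **{f"{s[0]}:{s[1]}:{s[2]}:{s[3]}": int(x)
                        for s, x in zip(common, v.values)}})
    pd.DataFrame(rows).to_csv(out / "haplotype_vectors.tsv", sep="\t", index=False)
    return ["haplotype_vectors.tsv"]


def load_haplotype_vectors(path) -> list[HaplotypeVector]:
    """Read a haplotype-vector TSV back into HaplotypeVector objects."""
    df = pd.read_csv(path, sep="\t")
    meta = ["haplotype_id", "label", "origin", "population"]
    site_cols = [c for c in df.columns if c not in meta]
    sites = []
    for c in site_cols:
        chrom, pos, ref, alt = c.split(":")
        sites.append((chrom, int(pos), ref, alt))
    out = []
    for row in df.itertuples(index=False):
        out.append(HaplotypeVector(
            site_index=sites,
            values=np.array(row[len(meta):], dtype=np.int8),
            label=row.label, origin=row.origin,
            population=str(row.population), hap_id=row.haplotype_id,
        ))
    return out


def _stage_hap_pca(cfg: RunConfig, out: Path) -> list[str]:
    vectors = load_haplotype_vectors(out / "haplotype_vectors.tsv")
    res, table = popstruct.haplotype_pca_report(vectors)
    table.to_csv(out / "haplotype_pca.tsv", sep="\t", index=False)
    pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(len(res.explained_variance_fraction))],
        "explained_variance_fraction": res.explained_variance_fraction,
    }).to_csv(out / "haplotype_pca_variance.tsv", sep="\t", index=False)
    return ["haplotype_pca.tsv", "haplotype_pca_variance.tsv"]


def _stage_fine_map(cfg: RunConfig, out: Path) -> list[str]:
    vectors = load_haplotype_vectors(out / "haplotype_vectors.tsv")
    mutant = [v for v in vectors if v.origin == "cohort" and v.label == "mutant"]
    wild = [v for v in vectors if v.origin == "cohort" and v.label == "wild_type"]
    results = finemap.fine_map_region(mutant, wild)
    finemap.results_to_frame(results).to_csv(out / "fine_mapping.tsv",
                                             sep="\t", index=False)
    return ["fine_mapping.tsv"]


def _read_reference_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def _stage_sv_classify(cfg: RunConfig, out: Path) -> list[str]:
    bp = pd.read_csv(out / "breakpoints.tsv", sep="\t")
    reference = _read_reference_fasta(out / "reference.fasta")
    rows = []
    for row in bp.itertuples(index=False):
        left = reference[row.chrom1][max(int(row.pos1) - 60, 0): int(row.pos1)]
        right = reference[row.chrom2][int(row.pos2) - 1: int(row.pos2) - 1 + 60]
        call = svjunction.classify_junction(left, right, row.contig_seq,
                                            event_id=row.event_id)
        rows.append({"event_id": call.event_id, "class": call.junction_class,
                     "mh_len": call.microhomology_len,
                     "ins_seq": call.inserted_seq or ".",
                     "shift_range": f"{call.ambiguous_shift_range[0]}-"
                                    f"{call.ambiguous_shift_range[1]}"})
    pd.DataFrame(rows).to_csv(out / "junction_calls.tsv", sep="\t", index=False)
    calls = [svjunction.JunctionCall(r["event_id"], r["mh_len"],
                                     "" if r["ins_seq"] == "." else r["ins_seq"],
                                     r["class"],
                                     tuple(map(int, r["shift_range"].split("-"))))
             for r in rows]
    summary = svjunction.summarize_junction_classes(calls)
    Path(out / "junction_summary.json").write_text(json.dumps(summary, indent=2))
    return ["junction_calls.tsv", "junction_summary.json"]


def _read_bed(path):
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                parts = line.rstrip("\n").split("\t")
                rows.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
    return rows


def _stage_sv_annotate(cfg: RunConfig, out: Path) -> list[str]:
    bp = pd.read_csv(out / "breakpoints.tsv", sep="\t")
    genes = _read_bed(out / "genes.bed")
    repeats = _read_bed(out / "repeats.bed")
    expr = pd.read_csv(out / "expression.tsv", sep="\t").set_index("gene")["TPM"].to_dict()
    points, meta = [], []
    for row in bp.itertuples(index=False):
        points.append(svjunction.Breakpoint(row.chrom1, int(row.pos1), "left"))
        meta.append((row.event_id, "left"))
        points.append(svjunction.Breakpoint(row.chrom2, int(row.pos2), "right"))
        meta.append((row.event_id, "right"))
    annos = svjunction.annotate_breakpoints(points, repeats, genes, expr,
                                            min_tpm=cfg.min_tpm)
    rows = []
    for (event_id, side), bpnt, a in zip(meta, points, annos):
        rows.append({"event_id": event_id, "side": side, "chrom": bpnt.chrom,
                     "pos": bpnt.pos, "genic": int(a.genic),
                     "gene": a.gene or ".", "transcribed": int(a.transcribed),
                     "repeat_class": a.repeat_class or "."})
    pd.DataFrame(rows).to_csv(out / "breakpoint_annotations.tsv", sep="\t",
                              index=False)
    return ["breakpoint_annotations.tsv"]


def _stage_filters(cfg: RunConfig, out: Path) -> list[str]:
    calls = pd.read_csv(out / "somatic_calls.tsv", sep="\t")
    normals_df = pd.read_csv(out / "normal_calls.tsv", sep="\t")
    normal_sets = [
        {(r.chrom, int(r.pos), r.ref, r.alt) for r in grp.itertuples(index=False)}
        for _, grp in normals_df.groupby("normal_id")
    ]
    pon = varfilter.build_pon(normal_sets, min_samples=cfg.pon_min_samples)
    retained, audit = varfilter.filter_somatic(
        calls, pon, min_vaf=cfg.somatic_min_vaf, min_alt=cfg.somatic_min_alt,
        max_pop_af=cfg.somatic_max_pop_af)
    retained.to_csv(out / "somatic_retained.tsv", sep="\t", index=False)
    audit.to_csv(out / "somatic_audit.tsv", sep="\t", index=False)

    chr22 = retained[retained["chrom"] == "chr22"]["pos"].tolist()
    clusters, rainfall = varfilter.detect_kataegis(
        chr22, max_imd=cfg.kataegis_max_imd, min_run=cfg.kataegis_min_run)
    clusters.to_csv(out / "kataegis_clusters.tsv", sep="\t", index=False)
    rainfall.to_csv(out / "kataegis_rainfall.tsv", sep="\t", index=False)
    return ["somatic_retained.tsv", "somatic_audit.tsv",
            "kataegis_clusters.tsv", "kataegis_rainfall.tsv"]
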