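"""Generator contracts: Balding-Nichols frequencies, IBD cores, junction
round-trips, somatic truth structure, and bundle determinism."""

import numpy as np
import pandas as pd
import pytest

from haploscope import syndata, svjunction, varfilter
from haploscope.phased_vcf import read_phased_vcf
from haploscope.syndata import (PanelSimConfig, inject_ibd_core,
                                make_reference, simulate_panel,
                                simulate_somatic_calls, simulate_sv_truth,
                                write_fixture_bundle)


def test_config_validation():
    with pytest.raises(ValueError):
        PanelSimConfig(fst=1.0)
    with pytest.raises(ValueError):
        PanelSimConfig(focal_position=300_000)
    with pytest.raises(ValueError):
        PanelSimConfig(n_sites=0)


def test_determinism_and_f0_limit():
    cfg = PanelSimConfig(seed=5, n_sites=60, haplotypes_per_population=10)
    p1, p2 = simulate_panel(cfg), simulate_panel(cfg)
    assert np.array_equal(p1.haplotypes, p2.haplotypes)
    assert p1.sites == p2.sites

    cfg0 = PanelSimConfig(seed=5, fst=0.0, n_sites=60,
                          haplotypes_per_population=10)
    p0 = simulate_panel(cfg0)
    freqs = np.vstack(list(p0.pop_freqs.values()))
    assert np.allclose(freqs, freqs[0])  # F -> 0: no divergence


def test_balding_nichols_moments():
    """Beta(p0(1-F)/F, (1-p0)(1-F)/F) has mean p0 and variance F p0 (1-p0)."""
    cfg = PanelSimConfig(seed=11, fst=0.5, n_sites=10_000,
                         ancestral_freq_dist=("uniform", 0.5, 0.5),
                         haplotypes_per_population=2, n_populations=3)
    p = simulate_panel(cfg)
    freqs = np.vstack(list(p.pop_freqs.values()))
    mask = np.ones(cfg.n_sites, dtype=bool)
    mask[p.focal_index] = False  # focal frequency is forced to zero
    f = freqs[:, mask]
    n = f.size
    se_mean = np.sqrt(0.5 * 0.5 * 0.5 / n)
    assert abs(f.mean() - 0.5) < 3 * se_mean
    var = f.var()
    expect_var = 0.5 * 0.5 * 0.5  # F p0 (1-p0)
    assert abs(var - expect_var) / expect_var < 0.05


def test_ibd_core_geometry(small_config):
    panel = simulate_panel(small_config)
    injected = inject_ibd_core(panel, {"POP1": 5, "POP2": 5, "POP3": 0},
                               core_halfwidth_bp=40_000)
    positions = np.array([s[0] for s in injected.sites])
    core = (positions >= small_config.focal_position - 40_000) & \
           (positions <= small_config.focal_position + 40_000)
    labels = np.array(injected.population_label)
    carriers1 = np.flatnonzero(injected.carrier_flag & (labels == "POP1"))
    # carriers of one population are identical inside the core
    for h in carriers1[1:]:
        assert np.array_equal(injected.haplotypes[h, core],
                              injected.haplotypes[carriers1[0], core])
    # carrier consistency invariant: carrier_flag <=> focal allele
    assert np.array_equal(injected.haplotypes[:, injected.focal_index] == 1,
                          injected.carrier_flag)
    # carriers in different populations generally differ inside the core
    carriers2 = np.flatnonzero(injected.carrier_flag & (labels == "POP2"))
    assert not np.array_equal(injected.haplotypes[carriers1[0], core],
                              injected.haplotypes[carriers2[0], core])


def test_ibd_core_degenerate_and_errors(small_config):
    panel = simulate_panel(small_config)
    zero = inject_ibd_core(panel, {"POP1": 4}, core_halfwidth_bp=0)
    diff = zero.haplotypes != panel.haplotypes
    changed_cols = np.flatnonzero(diff.any(axis=0))
    assert changed_cols.tolist() in ([], [panel.focal_index])

    with pytest.raises(ValueError):
        inject_ibd_core(panel, {"POP1": 4},
                        core_halfwidth_bp=small_config.window_bp)
    with pytest.raises(ValueError):
        inject_ibd_core(panel, {"POP1": 999}, core_halfwidth_bp=100)


def test_cohort_cases_carry_core_template(injected_panel, cohort):
    positions = np.array([s[0] for s in injected_panel.sites])
    fi = injected_panel.focal_index
    for case in cohort:
        assert case.hap_mutant[fi] == 1 and case.hap_wildtype[fi] == 0
        info = injected_panel.truth[case.population]
        core = (positions >= info["core_lo"]) & (positions <= info["core_hi"])
        template = injected_panel.haplotypes[info["template_haplotype"]]
        assert np.array_equal(case.hap_mutant[core], template[core])


def test_sv_truth_designed_classes_round_trip():
    ref = make_reference(("chrA", "chrB"), length=8000, seed=2)
    blunt = simulate_sv_truth(ref, 10, {"blunt": 1.0}, seed=3)
    for rec in blunt:
        lf, rf = syndata.flanks_for_event(ref, rec)
        call = svjunction.classify_junction(lf, rf, rec.fusion_contig)
        assert call.junction_class == "blunt"
        assert call.microhomology_len == 0 and call.inserted_seq == ""

    mh3 = simulate_sv_truth(ref, 10, {"microhomology": 1.0}, seed=4,
                            mh_range=(3, 3))
    for rec in mh3:
        lf, rf = syndata.flanks_for_event(ref, rec)
        call = svjunction.classify_junction(lf, rf, rec.fusion_contig)
        assert call.junction_class == "microhomology"
        assert call.microhomology_len == 3

    assert simulate_sv_truth(ref, 0, {"blunt": 1.0}) == []
    with pytest.raises(ValueError):
        simulate_sv_truth(ref, 2, {"blunt": 0.5})


def test_sv_truth_mixed_histogram_matches_design():
    ref = make_reference(("chrA",), length=20_000, seed=6)
    mix = {"blunt": 0.4, "microhomology": 0.35, "insertion": 0.25}
    recs = simulate_sv_truth(ref, 60, mix, seed=7)
    calls = []
    for rec in recs:
        lf, rf = syndata.flanks_for_event(ref, rec)
        calls.append(svjunction.classify_junction(lf, rf, rec.fusion_contig,
                                                  event_id=rec.event_id))
    summary = svjunction.summarize_junction_classes(calls)
    from collections import Counter
    designed = Counter(r.designed_class for r in recs)
    assert summary["class_counts"] == dict(designed)


def test_somatic_truth_structure():
    calls, normals = simulate_somatic_calls(20, 5, kataegis_clusters=1, seed=8)
    pon = varfilter.build_pon(normals, min_samples=2)
    artifacts = calls[calls["truth"] == "artifact"]
    assert len(artifacts) == 5
    for r in artifacts.itertuples(index=False):
        assert (r.chrom, r.pos, r.ref, r.alt) in pon

    kat = calls[calls["truth"] == "kataegis"].sort_values("pos")
    clusters, _ = varfilter.detect_kataegis(kat["pos"].tolist())
    assert len(clusters) == 1 and clusters.loc[0, "n_snvs"] == 8

    empty, _ = simulate_somatic_calls(0, 0, 0, seed=9, n_germline_leak=0)
    assert len(empty) == 0


def test_fixture_bundle_round_trip_and_determinism(tmp_path, injected_panel,
                                                   cohort):
    ref = make_reference(("chrA",), length=6000, seed=1)
    sv = simulate_sv_truth(ref, 4, {"blunt": 1.0}, seed=1)
    somatic = simulate_somatic_calls(5, 2, seed=1)

    def build(d):
        return write_fixture_bundle(injected_panel, sv, somatic, d,
                                    cohort=cohort, reference=ref,
                                    expression={"G1": 2.0})

    m1 = build(tmp_path / "a")
    m2 = build(tmp_path / "b")
    # byte-level determinism: same inputs -> identical checksums
    assert m1["sha256"].tolist() == m2["sha256"].tolist()
    # manifest lists every emitted file
    emitted = {f.name for f in (tmp_path / "a").iterdir()} - {"manifest.tsv"}
    assert set(m1["file"]) == emitted

    # VCF round trip through the reader reproduces the calls
    case = cohort[3]  # un-broken sample
    calls = syndata.cohort_calls(injected_panel, case)
    back = read_phased_vcf(tmp_path / "a" / f"{case.sample_id}.normal.vcf",
                           case.sample_id)
    assert back == sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt))
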