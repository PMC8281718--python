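import numpy as np
import pytest

from haploscope import syndata
from haploscope.phased_vcf import HaplotypeVector, VariantCall


@pytest.fixture(scope="session")
def small_config():
    return syndata.PanelSimConfig(seed=7, n_sites=120,
                                  haplotypes_per_population=20)


@pytest.fixture(scope="session")
def injected_panel(small_config):
    panel = syndata.simulate_panel(small_config)
    return syndata.inject_ibd_core(
        panel, {"POP1": 8, "POP2": 8, "POP3": 8},
        small_config.core_halfwidth_bp)


@pytest.fixture(scope="session")
def cohort(injected_panel):
    return syndata.simulate_cohort(injected_panel, n_cases=14)


def make_vectors(values, labels, site_index=None):
    """Helper: HaplotypeVectors from a list of 0/1 rows."""
    values = np.asarray(values)
    if site_index is None:
        site_index = [("chr1", 100 * (j + 1), "A", "T")
                      for j in range(values.shape[1])]
    return [HaplotypeVector(site_index=site_index, values=row, label=lab,
                            hap_id=f"h{i}")
            for i, (row, lab) in enumerate(zip(values, labels))]


def make_call(pos=100, gt=(0, 1), phased=True, ps=1, pq=30, sample="S1",
              chrom="chr1", ref="A", alt="T"):
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=gt,
                       phased=phased, sample_id=sample,
                       phase_set=ps if phased else None, phase_quality=pq)
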