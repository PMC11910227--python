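import numpy as np
import pandas as pd
import pytest

from epimmune.containers import BetaMatrix, PairedDesign
from epimmune.simulate import SimulationConfig, generate_cohort


def make_beta_matrix(values: np.ndarray, sample_ids=None, chrom="chr1", spacing=200,
                     region="Body", gene="", with_qc=False):
    """Build a minimal annotated BetaMatrix from a probe × sample array."""
    n_probes, n_samples = values.shape
    samples = list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n_samples)]
    probes = [f"cg{i:06d}" for i in range(n_probes)]
    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n_probes) * spacing + 1,
            "gene": gene,
            "region": region,
            "cytoband": "1q11",
            "snp_flag": False,
            "multimap_flag": False,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    if with_qc:
        for s in samples:
            ann[f"detection_p_{s}"] = 0.001
            ann[f"beads_ok_{s}"] = True
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples), ann)


def make_paired_design(n_pairs: int, sample_ids=None):
    samples = list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(2 * n_pairs)]
    return PairedDesign([(f"P{i}", samples[2 * i], samples[2 * i + 1]) for i in range(n_pairs)])


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort: full structure, reduced probe/gene counts."""
    return SimulationConfig(
        n_probes=1_800,
        n_genes=400,
        sting_size=10,
        m1_size=12,
        m2_size=12,
        apm_size=5,
        cta_size=20,
        tsg_size=30,
        n_planted_tsg_reversal=12,
        n_planted_cta=6,
        n_reference_probes=130,
        n_reference_overlap=110,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    return PairedDesign.from_sample_sheet(small_cohort.sample_sheet)


@pytest.fixture(scope="session")
def default_cohort():
    """Trial-scale cohort at the default configuration."""
    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_design(default_cohort):
    return PairedDesign.from_sample_sheet(default_cohort.sample_sheet)
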