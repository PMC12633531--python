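import numpy as np
import pytest

from kataegis_storm.datamodel import DetectionParams, GenomeRef
from kataegis_storm.detect import detect_cohort
from kataegis_storm.simulate import SimConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_cohort():
    """Small sequence-backed cohort for I/O and motif tests (3 x 4 Mb)."""
    cfg = SimConfig(n_samples=4, chrom_lengths=(4_000_000,) * 3,
                    kataegis_prevalence=1.0, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """The default-scale synthetic cohort used for recovery checks:
    20 samples, 3 x 50 Mb, 1 SNV/Mb background, planted events of >= 5 SNVs
    spanning <= 2.5 kb (gaps capped at 500 bp, 5-6 members)."""
    cfg = SimConfig(n_samples=20, chrom_lengths=(50_000_000,) * 3,
                    min_snvs_per_event=5, max_snvs_per_event=6,
                    gap_min=100, gap_max=500, seed=20260926)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_calls(study_cohort):
    params = DetectionParams()
    snvs = {s.sample_id: s.snvs for s in study_cohort.samples}
    return detect_cohort(snvs, params, study_cohort.genome)


@pytest.fixture
def lengths_only_genome():
    return GenomeRef(["chr1", "chr2", "chr3"], [50_000_000] * 3)
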