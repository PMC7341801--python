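import numpy as np
import pytest

from svclade.io import CladeMap, GenotypeMatrix, SVRecord
from svclade.simulate import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free cohort with injected cross-clade false positives."""
    return simulate_cohort(
        SimulationParams(m_variants=800, fp_cross_clade_rate=0.05, seed=11)
    )


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort with genotyping error and missing calls."""
    return simulate_cohort(
        SimulationParams(
            m_variants=800,
            fp_cross_clade_rate=0.05,
            genotyping_error_rate=0.02,
            missing_rate=0.02,
            seed=12,
        )
    )


@pytest.fixture
def small_clade_map():
    assignments = {}
    for i in range(4):
        assignments[f"A{i}"] = ("popA", "A")
    for i in range(6):
        assignments[f"B{i}"] = ("popB", "B")
    return CladeMap(assignments, {"A": 1, "B": 1})


@pytest.fixture
def tiny_records():
    return [
        SVRecord("chr1", 100, "v1", "DEL", 50, 149),
        SVRecord("chr1", 5000, "v2", "INS", 200, 5000),
        SVRecord("chr2", 300, "v3", "INV", 1000, 1299),
    ]


@pytest.fixture
def tiny_matrix(tiny_records):
    dosage = np.array(
        [[0, 1, 2, -1], [1, 1, 0, 0], [2, 0, -1, 1]], dtype=np.int8
    )
    return GenotypeMatrix([r.id for r in tiny_records], ["s1", "s2", "s3", "s4"], dosage)
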