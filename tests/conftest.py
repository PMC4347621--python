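import numpy as np
import pandas as pd
import pytest

from mirbiclust import preprocess, synthetic
from mirbiclust.types import Bicluster, BiclusterSet, CohortMetadata, CountMatrix


@pytest.fixture
def toy_counts() -> CountMatrix:
    """4 miRNAs x 3 samples with library totals 10, 5000, 4999."""
    frame = pd.DataFrame(
        [[2, 1000, 999], [3, 1500, 1500], [5, 1500, 1500], [0, 1000, 1000]],
        index=["hsa-miR-1", "hsa-miR-2", "hsa-miR-3", "hsa-miR-4"],
        columns=["S1", "S2", "S3"],
    )
    return CountMatrix(frame)


@pytest.fixture
def small_bicluster_set() -> BiclusterSet:
    return BiclusterSet(
        (
            Bicluster({"g1": 1.0, "g2": -0.25}, {"s1": -1.0, "s2": 0.5},
                      iterations=4, basin_count=7),
            Bicluster({"g3": 1.0}, {"s3": 1.0, "s4": 0.125}, iterations=2,
                      basin_count=1),
        ),
        params={"th_r": 3.5, "th_c": 1.0, "n_seeds": 300, "rng_seed": 42},
    )


@pytest.fixture(scope="session")
def planted_instance():
    """Benchmark instance (200x150, three 8x12 modules) plus its truth."""
    design = synthetic.benchmark_design(seed=0)
    cm, truth = synthetic.generate_counts(design)
    sp = preprocess.run_preprocessing(cm).standardized
    return design, cm, truth, sp


@pytest.fixture
def cohort() -> CohortMetadata:
    frame = pd.DataFrame(
        {
            "er_status": ["negative"] * 5 + ["positive"] * 5,
            "pr_status": ["negative"] * 5 + ["positive"] * 5,
            "her2_status": ["negative"] * 5 + ["positive", "negative"] * 2
            + ["positive"],
            "histology": ["IDC"] * 6 + ["DCIS", "Normal", "IDC", "Metaplastic"],
            "molecular_subtype": ["Basal"] * 5 + ["LuminalA"] * 3 + ["NA"] * 2,
        },
        index=[f"S{i}" for i in range(1, 11)],
    )
    return CohortMetadata(frame)


def make_rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
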