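import numpy as np
import pandas as pd
import pytest

import mitransfer as mt


@pytest.fixture(scope="session")
def small_cohort() -> mt.CohortBundle:
    """A compact null cohort exercised by several modules."""
    params = mt.SimulationParams(n_dyads=60, n_asvs=60, seed=7)
    return mt.simulate_cohort(params)


@pytest.fixture(scope="session")
def planted_cohort() -> mt.CohortBundle:
    """Cohort with strong transfer planted in Lactobacillales (VAG only)."""
    params = mt.SimulationParams(
        n_dyads=150,
        n_asvs=100,
        seed=11,
        compartments=("fecal",),
        transfer_log_or=mt.planted_transfer(2.3, modes=("VAG",), orders=("Lactobacillales",)),
    )
    return mt.simulate_cohort(params)


@pytest.fixture
def tiny_metadata() -> mt.SampleMetadata:
    rows = []
    for i in range(3):
        rows.append(dict(sample_id=f"M{i}-V36", subject_id=f"M{i}", dyad_id=f"D{i}",
                         role="mother", compartment="vaginal", timepoint_days=36,
                         delivery="VAG" if i < 2 else "CS-S"))
        rows.append(dict(sample_id=f"M{i}-V24", subject_id=f"M{i}", dyad_id=f"D{i}",
                         role="mother", compartment="vaginal", timepoint_days=24,
                         delivery="VAG" if i < 2 else "CS-S"))
    for i in range(2):  # dyad D2 has no child fecal sample at day 7
        rows.append(dict(sample_id=f"C{i}-F7", subject_id=f"C{i}", dyad_id=f"D{i}",
                         role="child", compartment="fecal", timepoint_days=7,
                         delivery="VAG"))
    return mt.SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def two_block_distance():
    """8 points in two tight blocks: within 0.05, between 0.9."""
    from skbio import DistanceMatrix

    n = 8
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    d = np.where(labels[:, None] == labels[None, :], 0.05, 0.9)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)]), labels
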