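import numpy as np
import pandas as pd
import pytest

import circadian_gate as cg


@pytest.fixture(scope="session")
def design():
    return cg.StudyDesign.standard()


@pytest.fixture(scope="session")
def small_dataset():
    """A light dataset for unit tests: 120 genes across all classes."""
    cfg = cg.SimulationConfig(
        seed=7,
        n_genes={
            "non_responsive": 40,
            "rhythmic_only": 20,
            "uniform_response": 10,
            "gated_induction": 24,
            "gated_reduction": 12,
            "stabilized": 14,
        },
        triad_fraction=0.5,
    )
    return cg.generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The full default simulation (2,000 genes) used for recovery checks."""
    return cg.generate_dataset(cg.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_results(default_dataset):
    ds = default_dataset
    return cg.run_analysis(ds.counts, ds.design, triads=ds.triads)


def make_cpm(design, control_profiles, cold_profiles, genes=None):
    """Build a CPM matrix whose replicate values equal the given per-ZT
    condition means (no replicate noise)."""
    control_profiles = np.atleast_2d(control_profiles)
    cold_profiles = np.atleast_2d(cold_profiles)
    n = control_profiles.shape[0]
    genes = genes or [f"g{i}" for i in range(n)]
    tps = design.timepoints
    data = {}
    for _, row in design.samples.iterrows():
        zt_idx = tps.index(row["timepoint_zt"])
        src = cold_profiles if row["condition"] == cg.COLD else control_profiles
        data[row.name] = src[:, zt_idx]
    return pd.DataFrame(data, index=genes, columns=design.samples.index)
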