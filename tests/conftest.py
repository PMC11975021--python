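import numpy as np
import pandas as pd
import pytest

from mmcc.simulate import SimConfig, simulate_cohort


def tiny_config(seed: int = 0, **kwargs) -> SimConfig:
    """A few-second cohort for structural tests."""
    defaults = dict(
        n_pairs=4, n_genes=60, n_peaks=80, cells_per_sample=40, n_snvs=4, seed=seed
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_bundle():
    bundle, truth = simulate_cohort(tiny_config(seed=11))
    return bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_pseudobulk_index(n_donors=4, lineages=("Monocyte", "B"), timepoints=("T1", "T2")):
    donors = [f"D{i}" for i in range(n_donors)]
    return pd.MultiIndex.from_product(
        [donors, timepoints, lineages], names=["donor_id", "timepoint", "lineage"]
    )
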