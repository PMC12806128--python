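import numpy as np
import pandas as pd
import pytest

from perturbdiff.data import PerturbationDataset
from perturbdiff.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def synthetic_default():
    """The default desk-scale synthetic dataset and its ground truth."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def synthetic_noiseless():
    return generate_dataset(SyntheticSpec(noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def tiny_synthetic():
    """A small dataset for fast pipeline tests: 10 genes, 4 drugs, 2 cells."""
    spec = SyntheticSpec(
        n_gene=10, n_drug=4, n_cell=2, n_dose_levels=2, samples_per_condition=3, seed=11
    )
    return generate_dataset(spec)


def make_dataset(control, perturbed, smiles, dose, cell, gene_names=None):
    """Hand-rolled dataset constructor for toy metric/DEG examples."""
    control = np.asarray(control, dtype=float)
    perturbed = np.asarray(perturbed, dtype=float)
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(control.shape[1])]
    obs = pd.DataFrame({"smiles": smiles, "dose_um": dose, "cell_line": cell})
    return PerturbationDataset(control, perturbed, obs, gene_names)
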