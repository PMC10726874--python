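import numpy as np
import pandas as pd
import pytest

from gerotarget.preprocess import ExpressionStudy
from gerotarget.synthio import SyntheticConfig, planted_truth


def make_study(matrix, ages=None, sexes=None, conditions=None, platform="rnaseq",
               tissue="tissue00"):
    """Wrap a raw gene x sample array into an ExpressionStudy."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[1]
    ages = np.asarray(ages if ages is not None else np.linspace(25, 75, n))
    sexes = np.asarray(sexes if sexes is not None else np.arange(n) % 2)
    conditions = conditions if conditions is not None else ["healthy"] * n
    genes = [f"G{i:05d}" for i in range(matrix.shape[0])]
    cols = [f"s{i:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "sample_id": cols,
            "age": ages,
            "sex": sexes,
            "tissue": tissue,
            "condition": conditions,
            "dataset_id": tissue,
        }
    )
    return ExpressionStudy(
        matrix=pd.DataFrame(matrix, index=genes, columns=cols),
        samples=meta,
        platform=platform,
    )


@pytest.fixture(scope="session")
def small_config():
    """A small but fully structured synthetic cohort."""
    return SyntheticConfig(
        n_tissues=2,
        samples_per_tissue=80,
        n_genes=400,
        n_cancers=2,
        datasets_per_cancer=2,
        cases_per_dataset=20,
        controls_per_dataset=20,
        n_pathways=30,
        genes_per_pathway=12,
        n_processes=10,
        worms_per_group=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return planted_truth(small_config)
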