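import numpy as np
import pandas as pd
import pytest

from wpcna.containers import AbundanceMatrix, SampleTraits
from wpcna.simulate import PlantedModule, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Module-scale cohort: 2 planted modules, 600 proteins, 8/group."""
    cfg = SimConfig(
        seed=7, n_per_group=8, n_proteins=600,
        modules=[
            PlantedModule("alpha", 60, "neuron", (0.0, 0.0, -0.6, -1.2), (0.25, 0.0, 0.1)),
            PlantedModule("inflammatory", 50, "astrocyte", (0.0, 0.3, 1.0, 1.6),
                          (0.2, 0.1, 0.0), c9_effect=0.6),
        ],
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def processed_small(small_cohort):
    """Imputed + regressed version of the small cohort."""
    from wpcna.preprocess import (filter_missingness, knn_impute, log2_transform,
                                  regress_covariates, remove_outliers)
    matrix, traits, truth = small_cohort
    imputed = knn_impute(log2_transform(filter_missingness(matrix)))
    cleaned, report = remove_outliers(imputed)
    traits_c = traits.aligned_to(cleaned.sample_ids)
    regressed = regress_covariates(cleaned, traits_c, seed=3)
    return regressed, traits_c, truth, report


def make_matrix(values, stage="regressed", scale="log2", prefix="P"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(values,
                      index=[f"{prefix}{i:03d}" for i in range(values.shape[0])],
                      columns=[f"S{j:02d}" for j in range(values.shape[1])])
    return AbundanceMatrix(values=df, stage=stage, scale=scale)


def make_traits(n_per_group=3, seed=0):
    rng = np.random.default_rng(seed)
    n = 4 * n_per_group
    return SampleTraits(pd.DataFrame({
        "group": np.repeat(np.arange(4), n_per_group),
        "age": rng.normal(65, 8, n).round(1),
        "sex": rng.integers(0, 2, n),
        "PMI": rng.uniform(4, 20, n).round(1),
        "pTDP_score": rng.integers(0, 4, n),
        "TDP_LFQ": rng.normal(25, 1, n),
        "C9_status": ["neg"] * n,
    }, index=[f"S{j:02d}" for j in range(n)]))
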