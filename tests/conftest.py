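import numpy as np
import pandas as pd
import pytest

from metlmm import (CohortConfig, CovariateInfo, MetabolomicsDataset,
                    generate_cohort)


@pytest.fixture
def toy_paired_dataset():
    """2 subjects x 2 tissues, 2 features, with one numeric covariate."""
    ab = pd.DataFrame(
        [[10.0, 20.0], [11.0, 21.0], [12.0, 22.0], [13.0, 23.0]],
        index=pd.Index(["s1_SAT", "s1_VAT", "s2_SAT", "s2_VAT"],
                       name="sample_id"),
        columns=["metA", "metB"])
    idx = ab.index
    return MetabolomicsDataset(
        abundances=ab,
        subject=pd.Series(["p1", "p1", "p2", "p2"], index=idx),
        class_label=pd.Series(["SAT", "VAT", "SAT", "VAT"], index=idx),
        class_levels=("SAT", "VAT"),
        covariates=pd.DataFrame({"age": [60.0, 60.0, 70.0, 70.0]}, index=idx),
        covariate_info={"age": CovariateInfo("age", "numeric")},
    )


@pytest.fixture
def small_cohort():
    """A modest synthetic paired cohort used across modules."""
    return generate_cohort(CohortConfig(n_subjects=25, n_features=20, seed=42))


def simulate_random_intercept(rng, n_subjects, n_per_subject, beta, X=None,
                              sigma_u=1.0, sigma_e=1.0):
    """Independent oracle-side generator for raw (y, X, groups) triples."""
    n = n_subjects * n_per_subject
    groups = np.repeat(np.arange(n_subjects), n_per_subject)
    if X is None:
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
    u = rng.normal(0.0, sigma_u, n_subjects)
    y = X @ np.asarray(beta) + u[groups] + rng.normal(0.0, sigma_e, n)
    return y, X, groups
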