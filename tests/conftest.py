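import numpy as np
import pandas as pd
import pytest

import sharplm as sl


@pytest.fixture(scope="session")
def small_cohort():
    """120-sample, 300-gene null cohort shared by fast tests."""
    spec = sl.CohortSpec(n_samples=120, n_genes=300, seed=11)
    return sl.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_expr(small_cohort):
    counts, samples, _ = small_cohort
    return sl.log_cpm(counts, sl.tmm_factors(counts)), samples


@pytest.fixture(scope="session")
def small_results(small_expr):
    expr, samples = small_expr
    schedule = sl.build_window_schedule(samples)
    return sl.run_sharplm(expr, samples, schedule), schedule


def make_counts(array, genes=None, samples=None):
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{j}" for j in range(array.shape[1])]
    return sl.CountMatrix(pd.DataFrame(array, index=genes, columns=samples))


def make_samples(ages, sexes=None, tissue="t1", **covariates):
    n = len(ages)
    sexes = sexes if sexes is not None else ["female", "male"] * (n // 2 + 1)
    df = pd.DataFrame(
        {
            "donor_id": [f"d{j}" for j in range(n)],
            "tissue": tissue,
            "age": ages,
            "sex": list(sexes)[:n],
            **covariates,
        },
        index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"),
    )
    return sl.SampleTable(df)
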