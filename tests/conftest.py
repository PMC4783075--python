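import numpy as np
import pandas as pd
import pytest

from phlabayes import CohortTable, PriorSpec, worked_example_cohort


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_cohort()


@pytest.fixture
def single_allele_cohort():
    """20 single-copy carriers of one allele, 7 positive: the conjugate toy
    whose exact posterior is Beta(8, 14)."""
    n, k = 20, 7
    return CohortTable(
        subject_ids=[f"s{i}" for i in range(n)],
        allele_names=["A"],
        copy_matrix=np.ones((n, 1), dtype=int),
        responses=pd.DataFrame({"pep_1": [True] * k + [False] * (n - k)}, dtype="boolean"),
    )


@pytest.fixture
def toy_two_allele_cohort():
    """Six subjects, two alleles, mixed carriage including a homozygote."""
    rows = np.array([[1, 0], [1, 0], [1, 1], [0, 1], [0, 1], [2, 1]])
    resp = pd.DataFrame({"pep_1": [True, False, True, True, False, True]}, dtype="boolean")
    return CohortTable([f"s{i}" for i in range(6)], ["A", "B"], rows, resp)


@pytest.fixture
def empty_cohort():
    return CohortTable(
        subject_ids=[],
        allele_names=["A", "B"],
        copy_matrix=np.zeros((0, 2), dtype=int),
        responses=pd.DataFrame({"pep_1": pd.array([], dtype="boolean")}),
    )


@pytest.fixture
def uniform_prior_two():
    return PriorSpec.uniform(["A", "B"])
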