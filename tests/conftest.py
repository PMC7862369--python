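import numpy as np
import pandas as pd
import pytest

from imsig import (ClinicalTable, Cohort, ExpressionMatrix, SignatureScores,
                   SyntheticConfig, generate_cohorts)


@pytest.fixture(scope="session")
def default_cohorts():
    """Three default-config synthetic cohorts with their planted truth."""
    return generate_cohorts(SyntheticConfig(seed=0))


@pytest.fixture()
def toy_matrix():
    """4 genes x 4 samples log2 matrix with easy hand-checkable values."""
    values = pd.DataFrame(
        [[4.0, 6.0, 2.0, 8.0],
         [6.0, 2.0, 4.0, 0.0],
         [2.0, 2.0, 2.0, 2.0],
         [4.0, 4.0, 4.0, 4.0]],
        index=["GA", "GB", "HK1", "HK2"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, scale_tag="log2")


def make_scores(values, sample_ids=None, name="score"):
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(len(values))]
    return SignatureScores(name, pd.Series(values, index=sample_ids, dtype=float))


def make_clinical(responses, sample_ids=None, os_time=None, os_event=None):
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(len(responses))]
    data = {"sample_id": sample_ids, "response": responses}
    if os_time is not None:
        data["os_time"] = os_time
        data["os_event"] = os_event
    return ClinicalTable(pd.DataFrame(data))


def make_cohort(name, gene_values, responses, scale_tag="log2_hknorm_ifngadj"):
    """Cohort from a dict gene -> per-sample values plus RECIST labels."""
    df = pd.DataFrame(gene_values)
    df.index = [f"s{i + 1}" for i in range(len(df))]
    expr = ExpressionMatrix(df.T, scale_tag=scale_tag)
    clinical = make_clinical(responses, sample_ids=list(df.index))
    return Cohort(name, expr, clinical)
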