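import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from popnoise.io import Cohort, ExpressionMatrix, SampleSheet, bind_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def cohort_from_arrays(
    values, genes, samples, patients, tissues, purity=None, stages=None
) -> Cohort:
    """Assemble a Cohort from plain arrays (test helper)."""
    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index(genes, name="gene_id"),
            columns=samples,
        )
    )
    data = {"sample_id": samples, "patient_id": patients, "tissue": tissues}
    if purity is not None:
        data["purity"] = purity
    if stages is not None:
        data["stage"] = stages
    return bind_cohort(matrix, SampleSheet(pd.DataFrame(data)))


@pytest.fixture
def toy_cohort() -> Cohort:
    """Two informative genes plus one all-zero-in-normal gene, 3 paired patients.

    gene g1: normal [1,2,3] (noise 0.5), tumor [2,4,9] (noise sqrt(13)/5).
    """
    values = [
        [1.0, 2.0, 3.0, 2.0, 4.0, 9.0],  # g1
        [5.0, 5.0, 6.0, 4.0, 7.0, 8.0],  # g2
        [0.0, 0.0, 0.0, 1.0, 2.0, 3.0],  # g3: zero mean in normal -> excluded
    ]
    return cohort_from_arrays(
        values,
        genes=["g1", "g2", "g3"],
        samples=["N1", "N2", "N3", "T1", "T2", "T3"],
        patients=["p1", "p2", "p3", "p1", "p2", "p3"],
        tissues=["normal"] * 3 + ["tumor"] * 3,
    )


@pytest.fixture
def normal_group():
    return ["N1", "N2", "N3"]


@pytest.fixture
def tumor_group():
    return ["T1", "T2", "T3"]
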