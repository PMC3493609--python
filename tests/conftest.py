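import numpy as np
import pandas as pd
import pytest

from lipidcohort.core import CohortTable, MetaboliteAnnotation, MetabolitePanel
from lipidcohort.synth import default_paper_spec, generate_cohort


@pytest.fixture(scope="session")
def paper_cohort():
    """One packaged-recipe cohort (12 + 43 subjects), shared across tests."""
    return generate_cohort(default_paper_spec(seed=0))


@pytest.fixture(scope="session")
def paper_spec():
    return default_paper_spec(seed=0)


def make_table(conc: dict, group: list, clinical: dict | None = None,
               classes: dict | None = None, edges=None) -> CohortTable:
    """Small hand-built cohort table for unit tests."""
    df = pd.DataFrame(conc)
    df.index = [f"s{i}" for i in range(len(df))]
    classes = classes or {}
    panel = MetabolitePanel(
        annotations={
            m: MetaboliteAnnotation(m, classes.get(m, "SFA"), 16, 0, "uM")
            for m in df.columns
        },
        pathway_edges=edges or [],
    )
    return CohortTable(
        concentrations=df,
        group=pd.Series(group, index=df.index),
        clinical=pd.DataFrame(index=df.index),
        panel=panel,
    )


@pytest.fixture
def tiny_table():
    rng = np.random.default_rng(42)
    return make_table(
        {
            "A": np.exp(rng.normal(0, 0.3, 10)),
            "B": np.exp(rng.normal(1, 0.3, 10)),
        },
        ["g0"] * 4 + ["g1"] * 6,
    )
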