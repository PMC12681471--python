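import numpy as np
import pandas as pd
import pytest

from hopit.designs import RespondentTable, TableSchema
from hopit.model import fit
from hopit.simulate import SyntheticConfig, generate


@pytest.fixture(scope="session")
def compact_synth():
    """A small generated survey with the reduced design (5 conditions,
    group + deprivation reporting covariates) and known truth."""
    return generate(SyntheticConfig(n=4000, seed=7).compact())


@pytest.fixture(scope="session")
def compact_fit(compact_synth):
    s = compact_synth
    return fit(
        s.latent,
        s.threshold,
        s.table.outcome("Mobility"),
        s.table.weights,
        dimension="Mobility",
    )


def make_toy_table(n: int = 12, seed: int = 3) -> RespondentTable:
    """A tiny hand-checkable respondent table: three conditions, one
    two-level group family, unit-ish weights."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "rating": rng.integers(1, 6, size=n),
            "cond_a": rng.integers(0, 2, size=n),
            "cond_b": rng.integers(0, 2, size=n),
            "cond_c": rng.integers(0, 2, size=n),
            "limitation": rng.choice(["no", "a_little", "a_lot"], size=n),
            "grp_base": 0,
            "grp_focal": 0,
            "weight": rng.uniform(0.5, 2.0, size=n),
        }
    )
    focal = rng.integers(0, 2, size=n)
    frame["grp_focal"] = focal
    frame["grp_base"] = 1 - focal
    schema = TableSchema(
        outcomes={"Rating": "rating"},
        conditions=("cond_a", "cond_b", "cond_c"),
        limitation="limitation",
        families={"grp": ("grp_base", "grp_focal")},
        baselines={"grp": "grp_base"},
        weight="weight",
    )
    return RespondentTable.from_frame(frame, schema)


@pytest.fixture
def toy_table():
    return make_toy_table()
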