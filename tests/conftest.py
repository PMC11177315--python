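import numpy as np
import pytest

from upbo import benchmark as bench
from upbo import synthetic as syn
from upbo.space import BOOLEAN, NUMERIC, SOLVENT, SearchSpace, VariableSpec


def make_tiny_space(n_solvents: int = 4, seed: int = 0) -> SearchSpace:
    """Small but structurally complete space (cardinality 1152)."""
    records = syn.solvent_records(syn.generate_solvent_table(n_solvents, seed))
    variables = (
        VariableSpec("acid_base_equiv", NUMERIC, (-5.0, 0.0, 5.0), unit="equiv"),
        VariableSpec("menhnh2_equiv", NUMERIC, (1.0, 5.0), unit="equiv"),
        VariableSpec("dsi2", BOOLEAN, (0, 1)),
        VariableSpec("ptc", BOOLEAN, (0, 1)),
        VariableSpec("ms", BOOLEAN, (0, 1)),
        VariableSpec("temp_c", NUMERIC, (0.0, 25.0, 50.0), unit="degC"),
        VariableSpec("vol_ml_per_g", NUMERIC, (10.0, 30.0), unit="mL/g"),
        VariableSpec("solvent", SOLVENT, tuple(records)),
    )
    return SearchSpace(variables, records)


@pytest.fixture(scope="session")
def tiny_space() -> SearchSpace:
    return make_tiny_space()


@pytest.fixture(scope="session")
def campaign_fixture() -> syn.SyntheticDataset:
    """The canonical 248-row synthetic campaign dataset."""
    return syn.knorr_like_fixture(seed=7)


@pytest.fixture(scope="session")
def lookup_oracle(campaign_fixture) -> bench.LookupOracle:
    return bench.make_lookup_oracle(
        campaign_fixture.table, dict(campaign_fixture.space.solvent_table)
    )


def brute_force_front(points: np.ndarray) -> np.ndarray:
    """Independent O(n^2) nondominated filter (maximize both columns)."""
    n = len(points)
    keep = []
    for i in range(n):
        dominated = False
        for j in range(n):
            if j == i:
                continue
            if (
                points[j, 0] >= points[i, 0]
                and points[j, 1] >= points[i, 1]
                and (points[j, 0] > points[i, 0] or points[j, 1] > points[i, 1])
            ):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return np.array(keep, dtype=int)
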