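import numpy as np
import pytest

from mimfa import MultiOmicsSet, OmicsTable
from mimfa.synthetic import insert_missingness, liver_preset, liver_row_scenarios


def make_table(name, values, ids, observed=None, prefix=None):
    values = np.asarray(values, dtype=float)
    observed = (
        np.ones(values.shape[0], dtype=bool) if observed is None else np.asarray(observed, bool)
    )
    values = values.copy()
    values[~observed] = np.nan
    return OmicsTable(
        name=name,
        values=values,
        individual_ids=ids,
        variable_ids=[f"{prefix or name}_v{k}" for k in range(values.shape[1])],
        observed_mask=observed,
    )


def small_two_table_set(seed=0, I=10, p=(3, 4), n_strata=2, missing=()):
    """Random complete two-table set; ``missing`` lists (table_idx, row_idx)
    pairs to flag as missing rows."""
    rng = np.random.default_rng(seed)
    ids = [f"r{i+1}" for i in range(I)]
    strata = {ids[i]: f"s{(i * n_strata) // I + 1}" for i in range(I)}
    tables = []
    for j, pj in enumerate(p):
        observed = np.ones(I, dtype=bool)
        for tj, ri in missing:
            if tj == j:
                observed[ri] = False
        tables.append(
            make_table(f"t{j+1}", rng.standard_normal((I, pj)), ids, observed)
        )
    return MultiOmicsSet(tables=tables, strata=strata)


@pytest.fixture
def two_tables():
    return small_two_table_set(seed=1)


@pytest.fixture(scope="session")
def liver():
    """Complete liver-shaped synthetic base (8 strata of 8; 300+10 variables)."""
    return liver_preset(seed=11)


@pytest.fixture(scope="session")
def liver_low_incomplete(liver):
    ds, _ = insert_missingness(liver, liver_row_scenarios()["low"], seed=12)
    return ds
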