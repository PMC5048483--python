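import itertools
from math import comb

import numpy as np
import pytest

from mimfa import (
    count_incomplete_cases,
    generate_multitable,
    insert_missingness,
    mfa,
)
from mimfa.synthetic import (
    MissingnessScenario,
    liver_preset,
    liver_row_scenarios,
    liver_table1_scenarios,
    nci60_preset,
    nci60_table2_scenario,
    nci60_uncertainty_scenarios,
    scenario_from_yaml,
)


TABLE1 = [((1, 1), 56), ((2, 1), 168), ((1, 2), 168), ((3, 1), 280),
          ((2, 2), 420), ((3, 2), 560), ((4, 1), 280)]


@pytest.mark.parametrize("removals,expected", TABLE1)
def test_disjoint_case_counts_for_stratum_of_eight(removals, expected):
    assert count_incomplete_cases(8, removals, disjoint=True) == expected


def test_case_count_edge_cases_and_independent_mode():
    assert count_incomplete_cases(8, (0, 0)) == 1
    assert count_incomplete_cases(8, (1, 1), disjoint=False) == 64
    with pytest.raises(ValueError):
        count_incomplete_cases(4, (3, 2), disjoint=True)
    with pytest.raises(ValueError):
        count_incomplete_cases(4, (5,), disjoint=False)


@pytest.mark.parametrize("n", [3, 4, 5, 6])
@pytest.mark.parametrize("removals", [(1, 1), (2, 1), (1, 2), (2, 2)])
@pytest.mark.parametrize("disjoint", [True, False])
def test_case_counts_match_exhaustive_enumeration(n, removals, disjoint):
    """Brute-force oracle: enumerate every (set-for-table-1, set-for-table-2)
    removal pattern and count the admissible ones."""
    if disjoint and sum(removals) > n:
        return
    members = range(n)
    count = 0
    for s1 in itertools.combinations(members, removals[0]):
        for s2 in itertools.combinations(members, removals[1]):
            if disjoint and set(s1) & set(s2):
                continue
            count += 1
    assert count_incomplete_cases(n, removals, disjoint=disjoint) == count


def test_generator_shapes_and_validity():
    ds = liver_preset(seed=0)
    assert ds.n_individuals == 64 and ds.n_tables == 2
    assert [t.n_variables for t in ds.tables] == [300, 10]
    assert len(ds.stratum_labels) == 8
    assert all(len(ds.stratum_members(s)) == 8 for s in ds.stratum_labels)
    nci = nci60_preset(seed=0)
    assert nci.n_individuals == 60 and len(nci.stratum_labels) == 9
    sizes = sorted(len(nci.stratum_members(s)) for s in nci.stratum_labels)
    assert sizes == [2, 6, 6, 6, 7, 8, 8, 8, 9]
    with pytest.raises(ValueError):
        generate_multitable(S=1, n_per_stratum=4, p=(3,))
    with pytest.raises(ValueError):
        generate_multitable(S=2, n_per_stratum=1, p=(3,))


def test_zero_effect_spectrum_is_noise_like():
    """With effect_size=0 the first-eigenvalue share of the MFA matches the
    Monte-Carlo null band of pure i.i.d. noise of the same shape."""
    S, n, p = 4, 5, (20, 6)
    ds = generate_multitable(S, n, p, effect_size=0.0, noise_sd=1.0, seed=42)
    cfg = mfa(ds, d=2)
    I = ds.n_individuals
    # direct spectrum share for the generated data
    share = cfg.eigenvalues[0]
    null_shares = []
    rng = np.random.default_rng(777)
    from mimfa.data_model import MultiOmicsSet, OmicsTable

    for _ in range(40):
        tables = [
            OmicsTable(
                name=f"t{j}",
                values=rng.standard_normal((I, pj)),
                individual_ids=ds.individual_ids,
                variable_ids=[f"t{j}v{k}" for k in range(pj)],
                observed_mask=np.ones(I, bool),
            )
            for j, pj in enumerate(p)
        ]
        null = MultiOmicsSet(tables=tables, strata=dict(ds.strata))
        null_shares.append(mfa(null, d=2).eigenvalues[0])
    lo, hi = np.min(null_shares), np.max(null_shares)
    assert lo - 0.05 <= share <= hi + 0.05


def test_large_effect_clusters_by_stratum():
    from sklearn.metrics import silhouette_score

    ds = generate_multitable(S=6, n_per_stratum=8, p=(60, 10),
                             effect_size=4.0, noise_sd=1.0, seed=3)
    cfg = mfa(ds, d=2)
    labels = [ds.strata[i] for i in ds.individual_ids]
    assert silhouette_score(cfg.scores, labels) > 0.5


def test_insert_missingness_counts_and_determinism():
    ds = liver_preset(seed=1)
    for name, total in [("low", 8), ("medium", 16), ("high", 24)]:
        out, ledger = insert_missingness(ds, liver_row_scenarios()[name], seed=9)
        assert len(ledger) == total
        assert out.n_missing_rows() == total
        assert all(t == "transcriptome" for t, _ in ledger)
    a = insert_missingness(ds, liver_row_scenarios()["high"], seed=5)[1]
    b = insert_missingness(ds, liver_row_scenarios()["high"], seed=5)[1]
    assert a == b
    # all-zero scenario leaves the dataset unchanged
    out, ledger = insert_missingness(ds, MissingnessScenario((0, 0)), seed=0)
    assert ledger == [] and out.is_complete()


def test_disjoint_constraint_holds_within_stratum():
    ds = liver_preset(seed=2)
    scen = MissingnessScenario((1, 1), disjoint=True)
    _, ledger = insert_missingness(ds, scen, seed=3)
    assert len(ledger) == 16
    removed_ids = [i for _, i in ledger]
    assert len(set(removed_ids)) == len(removed_ids)  # nobody removed twice


def test_nci60_scenarios_bookkeeping():
    ds = nci60_preset(seed=4)
    out, ledger = insert_missingness(ds, nci60_table2_scenario(), seed=5)
    # per-stratum totals from the scenario definition
    assert len(ledger) == sum([1, 2, 2, 4, 2, 4, 2, 0, 3])
    unc = nci60_uncertainty_scenarios()
    _, led10 = insert_missingness(ds, unc["10pct"], seed=6)
    assert len(led10) == 6 and len(led10) / ds.n_individuals == pytest.approx(0.10)
    _, led30 = insert_missingness(ds, unc["30pct"], seed=6)
    assert len(led30) == 18 and len(led30) / ds.n_individuals == pytest.approx(0.30)
    assert all(t == "transcriptome" for t, _ in led10 + led30)


def test_infeasible_scenario_names_stratum():
    ds = nci60_preset(seed=0)
    with pytest.raises(ValueError, match="prostate"):
        insert_missingness(ds, MissingnessScenario({"prostate": (2, 1)}), seed=0)


def test_scenario_yaml_roundtrip(tmp_path):
    p = tmp_path / "scen.yaml"
    p.write_text("name: high\ndisjoint: true\nrows_removed: [3, 0]\n")
    s = scenario_from_yaml(p)
    assert s.name == "high" and s.per_table_rows_removed == (3, 0) and s.disjoint
    p2 = tmp_path / "scen2.yaml"
    p2.write_text("name: unc\nrows_removed:\n  melanoma: [4, 0]\n  leukemia: [2, 0]\n")
    s2 = scenario_from_yaml(p2)
    assert s2.per_table_rows_removed == {"melanoma": (4, 0), "leukemia": (2, 0)}
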