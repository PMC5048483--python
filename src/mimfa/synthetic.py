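"""Synthetic stratified multi-table datasets and missing-row patterns.

The generator emulates the shape of the two benchmark designs used to
study missing-row imputation in multi-omics integration:

* a liver-toxicity-like design — 64 individuals in 8 strata of 8 (treatment
  x time groups), one wide expression-like table and one narrow
  clinical-like table;
* an NCI-60-like design — 60 individuals in 9 unequal strata (cancer cell
  line types), a transcriptome-like and a proteome-like table.

The signal model is one shared latent factor per stratum: each stratum gets
a latent position in a low-dimensional space, each table loads it through a
sparse loading matrix scaled by ``effect_size``, and i.i.d. Gaussian noise
of scale ``noise_sd`` is added. Strata are therefore recoverable by MFA
whenever effect_size is large relative to noise_sd.

Missing-row scenarios remove a stated number of rows per stratum from each
table, by default *disjointly* (an individual loses its row in at most one
table); the count of distinct incomplete cases per stratum is the
sequential product of binomial coefficients C(n,t1)*C(n-t1,t2)*...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import yaml

from .data_model import MultiOmicsSet, OmicsTable

__all__ = [
    "MissingnessScenario",
    "generate_multitable",
    "insert_missingness",
    "count_incomplete_cases",
    "liver_preset",
    "nci60_preset",
    "liver_row_scenarios",
    "liver_table1_scenarios",
    "nci60_table2_scenario",
    "scenario_from_yaml",
]

# latent dimensionality of the stratum factor
_LATENT_DIM = 2
# fraction of each table's variables carrying the stratum signal
_SUPPORT_FRACTION = 0.5


@dataclass
class MissingnessScenario:
    """Rows to remove per stratum from each table.

    ``per_table_rows_removed`` is either one tuple of per-table counts
    applied to every targeted stratum, or a mapping stratum -> tuple for
    stratum-specific patterns. With ``disjoint=True`` (default) an
    individual is removed from at most one table within a stratum.
    """

    per_table_rows_removed: tuple[int, ...] | dict[str, tuple[int, ...]]
    strata_targeted: list[str] | None = None  # None = all strata
    disjoint: bool = True
    name: str = ""

    def counts_for(self, stratum: str, n_tables: int) -> tuple[int, ...]:
        if isinstance(self.per_table_rows_removed, dict):
            counts = tuple(self.per_table_rows_removed.get(stratum, (0,) * n_tables))
        else:
            counts = tuple(self.per_table_rows_removed)
        if len(counts) != n_tables:
            raise ValueError(
                f"scenario lists {len(counts)} tables but dataset has {n_tables}"
            )
        return counts

    def validate_for(self, dataset: MultiOmicsSet) -> None:
        J = dataset.n_tables
        targeted = self.strata_targeted or dataset.stratum_labels
        for s in targeted:
            n = len(dataset.stratum_members(s))
            counts = self.counts_for(s, J)
            if any(c < 0 for c in counts):
                raise ValueError(f"stratum {s!r}: negative removal count")
            if self.disjoint:
                if sum(counts) > n:
                    raise ValueError(
                        f"stratum {s!r}: disjoint removals {counts} exceed size {n}"
                    )
            elif max(counts, default=0) > n:
                raise ValueError(f"stratum {s!r}: removals {counts} exceed size {n}")


def count_incomplete_cases(
    stratum_size: int, removals: tuple[int, ...], disjoint: bool = True
) -> int:
    """Number of distinct incomplete cases for one stratum.

    Disjoint removal draws the tables' removed sets sequentially without
    overlap: C(n,t1)*C(n-t1,t2)*...; independent (non-disjoint) removal is
    the plain product of binomials.
    """
    n = stratum_size
    if any(t < 0 for t in removals):
        raise ValueError("negative removal count")
    if disjoint:
        if sum(removals) > n:
            raise ValueError(f"removals {removals} infeasible for stratum size {n}")
        total, remaining = 1, n
        for t in removals:
            total *= comb(remaining, t)
            remaining -= t
        return total
    if max(removals, default=0) > n:
        raise ValueError(f"removals {removals} infeasible for stratum size {n}")
    total = 1
    for t in removals:
        total *= comb(n, t)
    return total


def generate_multitable(
    S: int,
    n_per_stratum: int | list[int],
    p: tuple[int, ...] | list[int],
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    table_names: list[str] | None = None,
    stratum_labels: list[str] | None = None,
) -> MultiOmicsSet:
    """Generate a complete stratified multi-table dataset.

    Each table j is ``effect_size * A_j g_{s(i)} + noise_sd * eps`` with
    g_s a 2-dimensional latent stratum position and A_j a sparse loading
    matrix (half the variables load the factor, the rest are pure noise).
    """
    if S < 2:
        raise ValueError("need at least 2 strata")
    sizes = [n_per_stratum] * S if isinstance(n_per_stratum, int) else list(n_per_stratum)
    if len(sizes) != S or any(n < 2 for n in sizes):
        raise ValueError("every stratum needs at least 2 individuals")
    if any(q < 1 for q in p):
        raise ValueError("every table needs at least one variable")
    rng = np.random.default_rng(seed)
    I = sum(sizes)
    labels = stratum_labels or [f"s{k+1}" for k in range(S)]
    ids: list[str] = []
    strata: dict[str, str] = {}
    for s, (lab, n) in enumerate(zip(labels, sizes)):
        for i in range(n):
            ind = f"ind{len(ids)+1:03d}"
            ids.append(ind)
            strata[ind] = lab
    g = rng.standard_normal((S, _LATENT_DIM))  # latent stratum positions
    member_stratum = np.array([labels.index(strata[i]) for i in ids])

    tables: list[OmicsTable] = []
    for j, pj in enumerate(p):
        A = rng.standard_normal((pj, _LATENT_DIM))
        support = rng.random(pj) < _SUPPORT_FRACTION
        if not support.any():
            support[rng.integers(pj)] = True
        A[~support] = 0.0
        signal = effect_size * g[member_stratum] @ A.T
        X = signal + noise_sd * rng.standard_normal((I, pj))
        name = table_names[j] if table_names else f"table{j+1}"
        tables.append(
            OmicsTable(
                name=name,
                values=X,
                individual_ids=list(ids),
                variable_ids=[f"{name}_v{k+1}" for k in range(pj)],
                observed_mask=np.ones(I, dtype=bool),
            )
        )
    return MultiOmicsSet(tables=tables, strata=strata)


def liver_preset(seed: int = 0, effect_size: float = 1.0, noise_sd: float = 1.0) -> MultiOmicsSet:
    """Liver-toxicity-shaped design: 8 strata of 8 individuals, a wide
    expression-like table (300 variables, scaled down from thousands) and a
    narrow clinical table (10 variables)."""
    return generate_multitable(
        S=8,
        n_per_stratum=8,
        p=(300, 10),
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
        table_names=["transcriptome", "clinical"],
        stratum_labels=[f"trt{k+1}" for k in range(8)],
    )


NCI60_STRATA: dict[str, int] = {
    "breast": 8, "cns": 6, "colon": 7, "lung": 9, "leukemia": 6,
    "melanoma": 8, "ovarian": 6, "prostate": 2, "renal": 8,
}


def nci60_preset(seed: int = 0, effect_size: float = 1.0, noise_sd: float = 1.0) -> MultiOmicsSet:
    """NCI-60-shaped design: 60 individuals in 9 unequal cancer-type strata,
    a transcriptome-like table (150 variables) and a proteome-like table
    (30 variables)."""
    return generate_multitable(
        S=len(NCI60_STRATA),
        n_per_stratum=list(NCI60_STRATA.values()),
        p=(150, 30),
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
        table_names=["transcriptome", "proteome"],
        stratum_labels=list(NCI60_STRATA),
    )


def liver_row_scenarios() -> dict[str, MissingnessScenario]:
    """Low/medium/high missingness for the liver-shaped design: 1, 2 or 3
    rows removed per stratum from the wide table only (totals 8/16/24)."""
    return {
        name: MissingnessScenario(per_table_rows_removed=(t, 0), name=name)
        for name, t in [("low", 1), ("medium", 2), ("high", 3)]
    }


def liver_table1_scenarios() -> list[MissingnessScenario]:
    """The seven two-table removal scenarios of the liver design
    (transcriptome, clinical rows removed per stratum of 8; disjoint)."""
    grid = [(1, 1), (2, 1), (1, 2), (3, 1), (2, 2), (3, 2), (4, 1)]
    return [
        MissingnessScenario(per_table_rows_removed=tc, name=f"scenario{k+1}")
        for k, tc in enumerate(grid)
    ]


def nci60_table2_scenario() -> MissingnessScenario:
    """The NCI-60 two-table removal pattern (per cancer type; disjoint)."""
    return MissingnessScenario(
        per_table_rows_removed={
            "breast": (1, 0), "cns": (1, 1), "colon": (2, 0), "lung": (2, 2),
            "leukemia": (1, 1), "melanoma": (2, 2), "ovarian": (1, 1),
            "prostate": (0, 0), "renal": (2, 1),
        },
        name="nci60_table2",
    )


def nci60_uncertainty_scenarios() -> dict[str, MissingnessScenario]:
    """Transcriptome-only patterns for the uncertainty study: 6 rows
    (10% of 60: 4 melanoma + 2 leukemia) and 18 rows (30%)."""
    ten = MissingnessScenario(
        per_table_rows_removed={"melanoma": (4, 0), "leukemia": (2, 0)},
        name="10pct",
    )
    thirty = MissingnessScenario(
        per_table_rows_removed={
            "breast": (2, 0), "cns": (2, 0), "colon": (2, 0), "lung": (3, 0),
            "leukemia": (2, 0), "melanoma": (4, 0), "ovarian": (2, 0),
            "renal": (1, 0),
        },
        name="30pct",
    )
    return {"10pct": ten, "30pct": thirty}


def insert_missingness(
    dataset: MultiOmicsSet,
    scenario: MissingnessScenario,
    seed: int = 0,
) -> tuple[MultiOmicsSet, list[tuple[str, str]]]:
    """Randomly flag rows missing per the scenario; returns the modified
    copy and a ledger of removed (table, individual) pairs.

    Removals are drawn among currently observed rows; the disjoint
    constraint is honoured within each stratum; a draw that would leave an
    individual missing from every table is redrawn.
    """
    scenario.validate_for(dataset)
    rng = np.random.default_rng(seed)
    J = dataset.n_tables
    targeted = scenario.strata_targeted or dataset.stratum_labels
    out = dataset.copy()
    ledger: list[tuple[str, str]] = []
    table_index = {t.name: t for t in out.tables}
    for s in targeted:
        members = dataset.stratum_members(s)
        counts = scenario.counts_for(s, J)
        for _attempt in range(1000):
            picks: list[list[str]] = []
            if scenario.disjoint:
                perm = [members[k] for k in rng.permutation(len(members))]
                pos = 0
                for t in counts:
                    picks.append(perm[pos : pos + t])
                    pos += t
            else:
                for t in counts:
                    idx = rng.choice(len(members), size=t, replace=False)
                    picks.append([members[k] for k in sorted(idx)])
            # reject a draw leaving someone with no observed row anywhere
            ok = True
            for i in members:
                lost = {j for j, pk in enumerate(picks) if i in pk}
                observed_elsewhere = any(
                    out.tables[j].observed_mask[out.individual_ids.index(i)]
                    for j in range(J)
                    if j not in lost
                )
                if lost and not observed_elsewhere:
                    ok = False
                    break
            if ok:
                break
        else:  # pragma: no cover - only for pathological scenarios
            raise ValueError(f"stratum {s!r}: could not draw a feasible removal pattern")
        for j, (tname, pk) in enumerate(zip([t.name for t in dataset.tables], picks)):
            table = table_index[tname]
            for i in pk:
                row = table.individual_ids.index(i)
                if not table.observed_mask[row]:
                    raise ValueError(f"stratum {s!r}: row {i!r} already missing in {tname!r}")
                table.values[row] = np.nan
                table.observed_mask[row] = False
                ledger.append((tname, i))
    for t in out.tables:
        t.validate()
    out.validate()
    return out, ledger


def scenario_from_yaml(path: str | Path) -> MissingnessScenario:
    """Load a scenario from YAML.

    Schema::

        name: high
        disjoint: true
        strata_targeted: [trt1, trt2]   # optional, default all
        rows_removed: [3, 0]            # one count per table, or:
        rows_removed:
          melanoma: [4, 0]
          leukemia: [2, 0]
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    removed = raw["rows_removed"]
    if isinstance(removed, dict):
        removed = {str(k): tuple(int(x) for x in v) for k, v in removed.items()}
    else:
        removed = tuple(int(x) for x in removed)
    return MissingnessScenario(
        per_table_rows_removed=removed,
        strata_targeted=raw.get("strata_targeted"),
        disjoint=bool(raw.get("disjoint", True)),
        name=str(raw.get("name", "")),
    )
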