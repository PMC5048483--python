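"""Stratified multiple hot-deck imputation of missing rows.

A recipient is an individual whose row is missing from a table; its donor
pool is the set of individuals of the same stratum observed in the same
table. Each completion draws, independently per recipient and with
replacement across recipients, one donor per recipient and copies the
donor's row verbatim. M completions with pairwise-distinct assignment maps
form an :class:`ImputationSet`.

The number of distinct assignment maps is ``M_total = prod over recipients
of |pool|``; drawing is prefix-stable under a fixed seed, so the first
``M'`` completions of an M-completion run equal the completions of an
``M'``-completion run with the same seed (this gives the nested collections
used by the stability procedure for free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import MultiOmicsSet

__all__ = [
    "DonorPool",
    "ImputationSet",
    "build_donor_pools",
    "count_total_imputations",
    "impute_once",
    "multiple_imputation",
]

# assignment map: (table name, recipient id) -> donor id
Assignment = dict[tuple[str, str], str]

_RETRY_FACTOR = 100


class EmptyDonorPoolError(ValueError):
    pass


@dataclass(frozen=True)
class DonorPool:
    """Donors available to the recipients of one (table, stratum)."""

    table: str
    stratum: str
    donor_ids: tuple[str, ...]
    recipient_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.donor_ids) & set(self.recipient_ids):
            raise ValueError(
                f"({self.table}, {self.stratum}): donors and recipients overlap"
            )


@dataclass
class ImputationSet:
    """M hot-deck completions of one incomplete dataset.

    Completions agree exactly on all originally observed entries and carry
    pairwise-distinct assignment maps.
    """

    completions: list[MultiOmicsSet]
    assignments: list[Assignment]
    seed: int
    M: int

    def assignments_json(self) -> list[dict]:
        """Audit-friendly encoding: one record per (completion, recipient)."""
        return [
            {"completion": m, "table": t, "recipient": r, "donor": d}
            for m, a in enumerate(self.assignments)
            for (t, r), d in sorted(a.items())
        ]


def build_donor_pools(dataset: MultiOmicsSet) -> list[DonorPool]:
    """One pool per (table, stratum) that has at least one recipient.

    Raises :class:`EmptyDonorPoolError` if some (table, stratum) has a
    recipient but no observed member to act as donor.
    """
    pools: list[DonorPool] = []
    for t in dataset.tables:
        observed = {i for i, ok in zip(t.individual_ids, t.observed_mask) if ok}
        for s in dataset.stratum_labels:
            members = dataset.stratum_members(s)
            recipients = tuple(i for i in members if i not in observed)
            if not recipients:
                continue
            donors = tuple(i for i in members if i in observed)
            if not donors:
                raise EmptyDonorPoolError(
                    f"empty donor pool: table {t.name!r}, stratum {s!r} "
                    "has recipients but no observed individuals"
                )
            pools.append(
                DonorPool(table=t.name, stratum=s, donor_ids=donors, recipient_ids=recipients)
            )
    return pools


def count_total_imputations(dataset: MultiOmicsSet) -> int:
    """M_total: the number of distinct assignment maps, i.e. the product of
    donor-pool sizes over all recipients (1 for a complete dataset)."""
    total = 1
    for pool in build_donor_pools(dataset):
        total *= len(pool.donor_ids) ** len(pool.recipient_ids)
    return total


def _draw_assignment(pools: list[DonorPool], rng: np.random.Generator) -> Assignment:
    a: Assignment = {}
    for pool in pools:
        for r in pool.recipient_ids:
            a[(pool.table, r)] = pool.donor_ids[rng.integers(len(pool.donor_ids))]
    return a


def _apply(dataset: MultiOmicsSet, assignment: Assignment) -> MultiOmicsSet:
    out = dataset.copy()
    for t in out.tables:
        index = {i: k for k, i in enumerate(t.individual_ids)}
        for (tab, r), donor in assignment.items():
            if tab != t.name:
                continue
            t.values[index[r]] = t.values[index[donor]]
            t.observed_mask[index[r]] = True
    for t in out.tables:
        t.validate()
    return out


def impute_once(
    dataset: MultiOmicsSet,
    pools: list[DonorPool] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[MultiOmicsSet, Assignment]:
    """One hot-deck completion: every missing row replaced by a verbatim copy
    of a randomly drawn same-(table, stratum) donor row. A complete dataset
    is returned unchanged with an empty assignment."""
    if pools is None:
        pools = build_donor_pools(dataset)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    recipients = {
        (t.name, i) for t in dataset.tables
        for i, ok in zip(t.individual_ids, t.observed_mask) if not ok
    }
    covered = {(p.table, r) for p in pools for r in p.recipient_ids}
    uncovered = recipients - covered
    if uncovered:
        raise EmptyDonorPoolError(f"recipients without a donor pool: {sorted(uncovered)}")
    assignment = _draw_assignment(pools, rng)
    return _apply(dataset, assignment), assignment


def multiple_imputation(dataset: MultiOmicsSet, M: int, seed: int) -> ImputationSet:
    """Draw M completions with pairwise-distinct assignment maps.

    Duplicates are redrawn (rejection sampling, cap 100*M attempts); the
    draw is sequential from a single seeded stream, so for a fixed seed the
    first M' completions of any longer run are identical to a run asking
    for M' directly.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    pools = build_donor_pools(dataset)
    m_total = count_total_imputations(dataset)
    if M > m_total:
        raise ValueError(
            f"M={M} exceeds M_total={m_total}, the number of distinct hot-deck completions"
        )
    rng = np.random.default_rng(seed)
    assignments: list[Assignment] = []
    seen: set[tuple] = set()
    attempts = 0
    while len(assignments) < M:
        attempts += 1
        if attempts > _RETRY_FACTOR * M:
            raise RuntimeError(
                f"could not find {M} distinct assignments in {attempts} draws; "
                f"M_total={m_total} — use a smaller M"
            )
        a = _draw_assignment(pools, rng)
        key = tuple(sorted(a.items()))
        if key in seen:
            continue
        seen.add(key)
        assignments.append(a)
    completions = [_apply(dataset, a) for a in assignments]
    return ImputationSet(completions=completions, assignments=assignments, seed=seed, M=M)
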