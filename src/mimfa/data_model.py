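"""Domain types and delimited-file I/O for stratified multi-table datasets.

A dataset is a list of quantitative tables (individuals x variables) sharing
one ordered individual index, plus a stratum label per individual. An
individual may be missing as a whole row from some tables ("missing rows");
cell-level missingness is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsTable",
    "MultiOmicsSet",
    "Configuration",
    "read_multiomics",
    "write_configuration",
    "read_configuration",
    "write_manifest",
]


class StructuralError(ValueError):
    """Raised when a dataset violates the multi-table missing-row structure."""


@dataclass
class OmicsTable:
    """One table of quantitative variables over identified individuals.

    Parameters
    ----------
    name
        Table label (e.g. ``"transcriptome"``).
    values
        Float matrix of shape (I, p). Rows flagged missing hold NaN.
    individual_ids
        Ordered, duplicate-free row labels of length I.
    variable_ids
        Ordered column labels of length p.
    observed_mask
        Boolean vector of length I; ``True`` where the row is present.
    """

    name: str
    values: np.ndarray
    individual_ids: list[str]
    variable_ids: list[str]
    observed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        I, p = self.values.shape
        if len(self.individual_ids) != I:
            raise StructuralError(
                f"table {self.name!r}: {I} rows but {len(self.individual_ids)} individual ids"
            )
        if len(self.variable_ids) != p:
            raise StructuralError(
                f"table {self.name!r}: {p} columns but {len(self.variable_ids)} variable ids"
            )
        if len(set(self.individual_ids)) != I:
            dupes = sorted({i for i in self.individual_ids if self.individual_ids.count(i) > 1})
            raise StructuralError(f"table {self.name!r}: duplicate individual ids {dupes}")
        if self.observed_mask.shape != (I,):
            raise StructuralError(f"table {self.name!r}: observed_mask shape mismatch")
        # a missing row carries no numeric content; an observed row is complete
        for i in range(I):
            row_nan = np.isnan(self.values[i])
            if self.observed_mask[i] and row_nan.any():
                raise StructuralError(
                    f"table {self.name!r}: observed row {self.individual_ids[i]!r} contains NaN"
                )
            if not self.observed_mask[i] and not row_nan.all():
                raise StructuralError(
                    f"table {self.name!r}: missing row {self.individual_ids[i]!r} "
                    "carries numeric content"
                )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def observed_values(self) -> np.ndarray:
        """The submatrix of observed rows."""
        return self.values[self.observed_mask]

    def copy(self) -> "OmicsTable":
        return OmicsTable(
            name=self.name,
            values=self.values.copy(),
            individual_ids=list(self.individual_ids),
            variable_ids=list(self.variable_ids),
            observed_mask=self.observed_mask.copy(),
        )


@dataclass
class MultiOmicsSet:
    """A collection of J tables sharing one individual index and strata.

    Invariants: all tables carry the identical ordered ``individual_ids``;
    every individual has exactly one stratum label; every individual is
    observed in at least one table.
    """

    tables: list[OmicsTable]
    strata: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.tables:
            raise StructuralError("dataset must contain at least one table")
        ids = self.tables[0].individual_ids
        for t in self.tables[1:]:
            if t.individual_ids != ids:
                raise StructuralError(
                    f"table {t.name!r} individual ids differ from table "
                    f"{self.tables[0].name!r}"
                )
        missing_strata = [i for i in ids if i not in self.strata]
        if missing_strata:
            raise StructuralError(f"individuals without stratum label: {missing_strata}")
        extra = [i for i in self.strata if i not in set(ids)]
        if extra:
            raise StructuralError(f"strata file lists unknown individuals: {sorted(extra)}")
        observed_any = np.zeros(len(ids), dtype=bool)
        for t in self.tables:
            observed_any |= t.observed_mask
        orphans = [ids[i] for i in np.nonzero(~observed_any)[0]]
        if orphans:
            raise StructuralError(
                f"individuals missing from every table (cannot be imputed): {orphans}"
            )

    @property
    def individual_ids(self) -> list[str]:
        return self.tables[0].individual_ids

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_tables(self) -> int:
        return len(self.tables)

    @property
    def stratum_labels(self) -> list[str]:
        """Distinct stratum labels in order of first appearance."""
        seen: dict[str, None] = {}
        for i in self.individual_ids:
            seen.setdefault(self.strata[i], None)
        return list(seen)

    def stratum_members(self, stratum: str) -> list[str]:
        return [i for i in self.individual_ids if self.strata[i] == stratum]

    def is_complete(self) -> bool:
        return all(t.observed_mask.all() for t in self.tables)

    def n_missing_rows(self) -> int:
        return int(sum((~t.observed_mask).sum() for t in self.tables))

    def copy(self) -> "MultiOmicsSet":
        return MultiOmicsSet(tables=[t.copy() for t in self.tables], strata=dict(self.strata))


@dataclass
class Configuration:
    """Individual coordinates (scores) on the leading components of an
    MFA/PCA, with eigenvalues and the per-table weights that produced them.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    individual_ids: list[str]
    table_weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.validate()

    def validate(self, tol: float = 1e-8) -> None:
        I, d = self.scores.shape
        if len(self.individual_ids) != I:
            raise StructuralError("configuration: id/row count mismatch")
        ev = self.eigenvalues
        if np.any(np.diff(ev) > tol * max(1.0, abs(ev[0]) if ev.size else 1.0)):
            raise StructuralError("configuration: eigenvalues not nonincreasing")
        if ev.size and ev[-1] < -tol * max(1.0, abs(ev[0])):
            raise StructuralError("configuration: negative eigenvalue")
        # score columns mutually orthogonal (scores are principal coordinates)
        if d > 1:
            g = self.scores.T @ self.scores
            off = g - np.diag(np.diag(g))
            scale = max(np.abs(np.diag(g)).max(), 1.0)
            if np.abs(off).max() > 1e-6 * scale:
                raise StructuralError("configuration: score columns not orthogonal")

    @property
    def d(self) -> int:
        return self.scores.shape[1]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _read_matrix(path: Path, missing_marker: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=[missing_marker],
        keep_default_na=False,
        encoding="utf-8",
        float_precision="round_trip",
    )
    df.index = df.index.astype(str)
    return df


def read_multiomics(
    table_paths: Sequence[str | Path],
    strata_path: str | Path,
    missing_marker: str = "NA",
    table_names: Sequence[str] | None = None,
) -> MultiOmicsSet:
    """Load a stratified multi-table dataset from delimited files.

    Each table file is a delimited matrix (.csv comma, .tsv/.tab/.txt tab)
    with a header of variable ids and a first column of individual ids. The
    strata file has columns ``individual_id,stratum`` and fixes the canonical
    individual order enforced on every table. A row is treated as missing if
    it is absent from a table file or if every entry equals ``missing_marker``.

    Raises
    ------
    StructuralError
        If a table contains individuals unknown to the strata file, an
        individual has no stratum, ids are duplicated, or an individual is
        missing from all tables.
    """
    strata_path = Path(strata_path)
    strata_df = pd.read_csv(strata_path, sep=_sep_for(strata_path), encoding="utf-8")
    if strata_df.shape[1] < 2:
        raise StructuralError(f"strata file {strata_path} needs columns individual_id,stratum")
    ids = [str(x) for x in strata_df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        raise StructuralError("strata file contains duplicate individual ids")
    strata = {str(i): str(s) for i, s in zip(ids, strata_df.iloc[:, 1])}

    tables: list[OmicsTable] = []
    for j, tp in enumerate(table_paths):
        tp = Path(tp)
        name = table_names[j] if table_names else tp.stem
        df = _read_matrix(tp, missing_marker)
        unknown = [i for i in df.index if i not in strata]
        if unknown:
            raise StructuralError(
                f"table {name!r}: individuals absent from strata file: {unknown}"
            )
        if df.index.has_duplicates:
            raise StructuralError(f"table {name!r}: duplicate individual ids")
        I, p = len(ids), df.shape[1]
        values = np.full((I, p), np.nan)
        observed = np.zeros(I, dtype=bool)
        present = {idx: k for k, idx in enumerate(df.index)}
        raw = df.to_numpy(dtype=float)
        for i, ind in enumerate(ids):
            if ind in present:
                row = raw[present[ind]]
                if np.isnan(row).all():
                    continue  # marker-encoded missing row
                if np.isnan(row).any():
                    raise StructuralError(
                        f"table {name!r}: row {ind!r} is partially missing; "
                        "only whole-row missingness is supported"
                    )
                values[i] = row
                observed[i] = True
        tables.append(
            OmicsTable(
                name=name,
                values=values,
                individual_ids=list(ids),
                variable_ids=[str(c) for c in df.columns],
                observed_mask=observed,
            )
        )
    return MultiOmicsSet(tables=tables, strata=strata)


def write_configuration(config: Configuration, path: str | Path) -> None:
    """Write a configuration as a delimited file, one row per individual,
    columns ``dim1..dimd``, at full round-trip precision."""
    if config.d == 0:
        raise ValueError("configuration has zero dimensions; nothing to write")
    path = Path(path)
    df = pd.DataFrame(
        config.scores,
        index=pd.Index(config.individual_ids, name="individual_id"),
        columns=[f"dim{k+1}" for k in range(config.d)],
    )
    # default float repr is shortest-round-trip: read-back is bit-exact
    df.to_csv(path, sep=_sep_for(path), encoding="utf-8")


def read_configuration(path: str | Path) -> Configuration:
    """Read back a configuration written by :func:`write_configuration`.

    Eigenvalues are not stored in the delimited file; the returned object
    carries the column variances of the scores (which equal the eigenvalues
    for principal coordinates under uniform 1/I row weights).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, encoding="utf-8",
                     float_precision="round_trip")
    scores = df.to_numpy(dtype=float)
    ev = (scores**2).mean(axis=0)
    order = np.argsort(-ev, kind="stable")
    return Configuration(
        scores=scores[:, order],
        eigenvalues=ev[order],
        individual_ids=[str(i) for i in df.index],
    )


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (paths, parameters, seed)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=2, default=str)
        fh.write("\n")
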