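"""Shared data model for honeybee pedigrees, matings and colony records.

A honeybee pedigree is unusual in that it contains three kinds of entries:

* queens — diploid individuals with a dam and a sire entry;
* mate entries — the "sire" side of a mating.  Because a queen mates once,
  with drones from one drone-producing queen (DPQ) or from a group of
  sister-DPQs, the male side of every mating is represented by a single
  pedigree entry.  It may be an identified DPQ, a dummy DPQ, a pseudo-sire
  group of S sister-DPQs, or a large group of unknown queens standing in for
  an open-mating drone population;
* worker groups — the workers of one colony, modelled as a single entity
  whose genetic value is the average breeding value of the workers.

Files are plain TSV with a header; unknown parents are encoded as "0" and
identifiers are positive integers assigned in creation order, so emitted
files are diff-able across runs.  Sparse matrices are exchanged in
MatrixMarket coordinate format (1-based, lower triangle for symmetric
matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

UNKNOWN = 0

# entity kinds
QUEEN = "QUEEN"
MATE = "MATE"
WORKER_GROUP = "WORKER_GROUP"

# mate-entry styles
IDENTIFIED_DPQ = "IDENTIFIED_DPQ"
DUMMY_DPQ = "DUMMY_DPQ"
PS_GROUP = "PS_GROUP"
OPEN_GROUP = "OPEN_GROUP"

# open-group labels for colony records
CONTROLLED = "CONTROLLED"
BASE_OPEN = "BASE_OPEN"
SUBPOP_A = "SUBPOP_A"
SUBPOP_B = "SUBPOP_B"

_PED_COLUMNS = [
    "id", "kind", "dam", "sire_entry", "style", "member",
    "dpq_dam", "dpq_dam_mate", "S", "D", "birth_year",
]
_PERF_COLUMNS = [
    "colony_id", "queen_id", "worker_group_id", "mate_entry_id",
    "year", "open_group_label", "phenotype",
]


@dataclass
class PedigreeEntity:
    """A queen or a worker group.

    For queens, ``dam_id``/``sire_entry_id`` are the dam and the dam's mate
    entry (the queen's father side).  For worker groups, ``dam_id`` is the
    colony queen and ``sire_entry_id`` the queen's own mate entry.
    """

    id: int
    kind: str
    dam_id: int = UNKNOWN
    sire_entry_id: int = UNKNOWN
    birth_year: int = 0


@dataclass
class MateEntry:
    """The male side of one or more matings.

    ``S`` is the number of DPQs the entry comprises and ``D`` the number of
    drones it contributes to each mating.  For an identified DPQ the entry
    points at the member queen; dummy DPQs and pseudo-sire groups carry the
    DPQ dam and her mate entry as parents.
    """

    id: int
    style: str
    member_queen_id: int = UNKNOWN
    dpq_dam_id: int = UNKNOWN
    dpq_dam_mate_id: int = UNKNOWN
    S: int = 1
    D: int = 8
    birth_year: int = 0


@dataclass
class ColonyRecord:
    """One phenotyped (or dead, phenotype None) colony."""

    colony_id: int
    queen_id: int
    worker_group_id: int
    mate_entry_id: int
    year: int
    open_group_label: str
    phenotype: float | None


Row = Union[PedigreeEntity, MateEntry]


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """An ordered collection of pedigree rows (parents precede children)."""

    rows: list[Row] = field(default_factory=list)
    _by_id: dict[int, Row] = field(default_factory=dict, repr=False)

    def add(self, row: Row) -> Row:
        if row.id in self._by_id:
            raise PedigreeError(f"duplicate id {row.id}")
        if row.id <= 0:
            raise PedigreeError(f"non-positive id {row.id}")
        self.rows.append(row)
        self._by_id[row.id] = row
        return row

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, eid: int) -> bool:
        return eid in self._by_id

    def get(self, eid: int) -> Row:
        return self._by_id[eid]

    @property
    def queens(self) -> list[PedigreeEntity]:
        return [r for r in self.rows if isinstance(r, PedigreeEntity) and r.kind == QUEEN]

    @property
    def worker_groups(self) -> list[PedigreeEntity]:
        return [r for r in self.rows if isinstance(r, PedigreeEntity) and r.kind == WORKER_GROUP]

    @property
    def mates(self) -> list[MateEntry]:
        return [r for r in self.rows if isinstance(r, MateEntry)]

    # -- validation ----------------------------------------------------

    def _parent_ids(self, row: Row) -> list[int]:
        if isinstance(row, PedigreeEntity):
            return [p for p in (row.dam_id, row.sire_entry_id) if p != UNKNOWN]
        if row.style == IDENTIFIED_DPQ:
            return [row.member_queen_id]
        return [p for p in (row.dpq_dam_id, row.dpq_dam_mate_id) if p != UNKNOWN]

    def validate(self) -> None:
        """Check referential integrity and parent-before-child ordering.

        The row order is the topological order; because ids are assigned in
        creation order, a cycle would require a parent id larger than the
        child's, which is reported as an ordering error.
        """
        seen: set[int] = set()
        for row in self.rows:
            for pid in self._parent_ids(row):
                if pid not in self._by_id:
                    raise PedigreeError(
                        f"row {row.id}: reference to missing id {pid}")
                if pid not in seen:
                    raise PedigreeError(
                        f"row {row.id}: parent {pid} does not precede it "
                        "(ordering violation or cycle)")
            if isinstance(row, PedigreeEntity):
                if row.kind == QUEEN:
                    if row.dam_id != UNKNOWN and not self._is_queen(row.dam_id):
                        raise PedigreeError(f"queen {row.id}: dam {row.dam_id} is not a queen")
                    if row.sire_entry_id != UNKNOWN and not isinstance(self.get(row.sire_entry_id), MateEntry):
                        raise PedigreeError(f"queen {row.id}: sire entry {row.sire_entry_id} is not a mate entry")
                elif row.kind == WORKER_GROUP:
                    if not self._is_queen(row.dam_id):
                        raise PedigreeError(f"worker group {row.id}: queen {row.dam_id} missing or not a queen")
                    if not isinstance(self.get(row.sire_entry_id), MateEntry):
                        raise PedigreeError(f"worker group {row.id}: mate {row.sire_entry_id} missing or not a mate entry")
                else:
                    raise PedigreeError(f"row {row.id}: unknown kind {row.kind}")
            else:
                if row.S < 1 or row.D < 1:
                    raise PedigreeError(f"mate {row.id}: S and D must be >= 1")
                if row.style in (IDENTIFIED_DPQ, DUMMY_DPQ) and row.S != 1:
                    raise PedigreeError(f"mate {row.id}: style {row.style} requires S = 1")
                if row.style == PS_GROUP and row.S < 2:
                    raise PedigreeError(f"mate {row.id}: PS_GROUP requires S >= 2")
                if row.style == IDENTIFIED_DPQ and not self._is_queen(row.member_queen_id):
                    raise PedigreeError(f"mate {row.id}: member {row.member_queen_id} missing or not a queen")
            seen.add(row.id)

    def _is_queen(self, eid: int) -> bool:
        r = self._by_id.get(eid)
        return isinstance(r, PedigreeEntity) and r.kind == QUEEN

    # -- dataframe conversion -------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            if isinstance(row, PedigreeEntity):
                recs.append((row.id, row.kind, row.dam_id, row.sire_entry_id,
                             "", UNKNOWN, UNKNOWN, UNKNOWN, 0, 0, row.birth_year))
            else:
                recs.append((row.id, MATE, UNKNOWN, UNKNOWN, row.style,
                             row.member_queen_id, row.dpq_dam_id,
                             row.dpq_dam_mate_id, row.S, row.D, row.birth_year))
        return pd.DataFrame.from_records(recs, columns=_PED_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        ped = cls()
        for rec in df.itertuples(index=False):
            if rec.kind == MATE:
                ped.add(MateEntry(
                    id=int(rec.id), style=str(rec.style),
                    member_queen_id=int(rec.member), dpq_dam_id=int(rec.dpq_dam),
                    dpq_dam_mate_id=int(rec.dpq_dam_mate), S=int(rec.S),
                    D=int(rec.D), birth_year=int(rec.birth_year)))
            else:
                ped.add(PedigreeEntity(
                    id=int(rec.id), kind=str(rec.kind), dam_id=int(rec.dam),
                    sire_entry_id=int(rec.sire_entry),
                    birth_year=int(rec.birth_year)))
        ped.validate()
        return ped


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree TSV; rows must be topologically ordered."""
    df = pd.read_csv(path, sep="\t", dtype={"kind": str, "style": str},
                     keep_default_na=False)
    missing = [c for c in _PED_COLUMNS if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree file {path} lacks columns {missing}")
    return Pedigree.from_frame(df[_PED_COLUMNS])


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def records_to_frame(records: Iterable[ColonyRecord]) -> pd.DataFrame:
    recs = [(r.colony_id, r.queen_id, r.worker_group_id, r.mate_entry_id,
             r.year, r.open_group_label, r.phenotype) for r in records]
    return pd.DataFrame.from_records(recs, columns=_PERF_COLUMNS)


def write_performance(records: Iterable[ColonyRecord] | pd.DataFrame,
                      path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def read_performance(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PERF_COLUMNS if c not in df.columns]
    if missing:
        raise PedigreeError(f"performance file {path} lacks columns {missing}")
    return df


def export_sparse(matrix: sp.spmatrix, path: str | Path,
                  symmetric: bool = True) -> None:
    """Write a sparse matrix in MatrixMarket coordinate format.

    Symmetric matrices are stored as their lower triangle; a non-symmetric
    matrix passed with ``symmetric=True`` is rejected.
    """
    m = sp.csr_matrix(matrix)
    if symmetric:
        if abs(m - m.T).max() > 1e-10 * max(1.0, abs(m).max()):
            raise PedigreeError("matrix is not symmetric")
        scipy.io.mmwrite(str(path), sp.tril(m), symmetry="symmetric")
    else:
        scipy.io.mmwrite(str(path), m)


def read_sparse(path: str | Path) -> sp.csr_matrix:
    return sp.csr_matrix(scipy.io.mmread(str(path)))
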