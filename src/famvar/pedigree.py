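"""Pedigree structures and 6-column PED I/O.

A :class:`Pedigree` is a thin wrapper over a pandas DataFrame in standard
PED layout (family, individual, father, mother, sex, phenotype) plus a
``role`` convenience column. Phenotype coding: 1 = unaffected, 2 = affected.
Sex coding: 1 = male, 2 = female.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

PED_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]
MISSING = "0"


@dataclass(frozen=True)
class Individual:
    fid: str
    iid: str
    father: str  # "0" when unknown
    mother: str
    sex: int  # 1 male, 2 female
    affected: bool

    @property
    def is_male(self) -> bool:
        return self.sex == 1

    @property
    def is_founder(self) -> bool:
        return self.father == MISSING and self.mother == MISSING


@dataclass
class Family:
    fid: str
    members: list[Individual] = field(default_factory=list)

    @property
    def children(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    @property
    def parents(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def affected_children(self) -> list[Individual]:
        return [c for c in self.children if c.affected]

    @property
    def unaffected_children(self) -> list[Individual]:
        return [c for c in self.children if not c.affected]

    @property
    def family_type(self) -> str:
        """SPX (one affected child) or MPX (two or more)."""
        return "MPX" if len(self.affected_children) >= 2 else "SPX"


class Pedigree:
    """Cohort of nuclear families."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in PED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"PED table missing columns: {missing}")
        self.table = table.reset_index(drop=True).copy()
        self._individuals: dict[str, Individual] = {}
        self._families: dict[str, Family] = {}
        for row in self.table.itertuples(index=False):
            ind = Individual(
                fid=str(row.fid),
                iid=str(row.iid),
                father=str(row.father),
                mother=str(row.mother),
                sex=int(row.sex),
                affected=int(row.phenotype) == 2,
            )
            if ind.iid in self._individuals:
                raise ValueError(f"duplicate individual id {ind.iid}")
            self._individuals[ind.iid] = ind
            self._families.setdefault(ind.fid, Family(fid=ind.fid)).members.append(ind)

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._individuals

    def individual(self, iid: str) -> Individual:
        return self._individuals[iid]

    @property
    def individuals(self) -> list[Individual]:
        return list(self._individuals.values())

    @property
    def families(self) -> list[Family]:
        return list(self._families.values())

    def family(self, fid: str) -> Family:
        return self._families[fid]

    def iter_trios(self) -> Iterator[tuple[Individual, Individual | None, Individual | None]]:
        """Yield (child, father, mother); a missing parent is None."""
        for child in self._individuals.values():
            if child.is_founder:
                continue
            father = self._individuals.get(child.father)
            mother = self._individuals.get(child.mother)
            yield child, father, mother

    def parents_of(self, iid: str) -> tuple[Individual | None, Individual | None]:
        child = self._individuals[iid]
        return self._individuals.get(child.father), self._individuals.get(child.mother)

    def unaffected_brothers(self, iid: str) -> list[Individual]:
        child = self._individuals[iid]
        fam = self._families[child.fid]
        return [
            s
            for s in fam.children
            if s.iid != iid
            and s.is_male
            and not s.affected
            and s.father == child.father
            and s.mother == child.mother
        ]

    @property
    def affected_children(self) -> list[Individual]:
        return [c for f in self.families for c in f.affected_children]

    @property
    def unaffected_children(self) -> list[Individual]:
        return [c for f in self.families for c in f.unaffected_children]

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self._individuals.values() if i.is_founder]

    # -- I/O --------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        self.table[PED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "Pedigree":
        table = pd.read_csv(path, sep="\t", header=None, names=PED_COLUMNS, dtype=str)
        table["sex"] = table["sex"].astype(int)
        table["phenotype"] = table["phenotype"].astype(int)
        return cls(table)
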