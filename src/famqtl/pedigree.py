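"""Pedigree data model, validation, kinship, and PLINK PED/FAM I/O.

A :class:`Pedigree` is the unit of analysis throughout the package: every
family-specific operation (gene dropping, segregation analysis, variance
components) receives one or more validated pedigrees.  Founders — members
with no parents in the pedigree — are the only route by which a new allele
can enter a family in the absence of mutation, which is why founder
identification is treated as a first-class operation here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "read_ped",
    "write_ped",
]

MISSING_PARENT = "0"  # PLINK convention


class PedigreeError(ValueError):
    """Structural or validation error in a pedigree."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id`` and ``mother_id`` are either both set or both ``None``;
    both-``None`` marks a founder.  Sex follows PLINK coding on disk
    (1=male, 2=female) and is stored symbolically here.
    """

    id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female"
    family_id: str

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.id!r}: exactly one parent recorded; "
                "parents must be both present or both absent"
            )
        if self.sex not in ("male", "female"):
            raise PedigreeError(f"individual {self.id!r}: invalid sex {self.sex!r}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """A validated single-family pedigree.

    Validation enforces: referenced parents exist, father is male and
    mother female, the parent graph is acyclic.  Members are kept in input
    order; :attr:`topological_order` lists member indices parents-first
    (ties broken by input order, so output is deterministic).
    """

    def __init__(self, family_id: str, members: Sequence[Individual]):
        self.family_id = family_id
        self.members: tuple[Individual, ...] = tuple(members)
        if not self.members:
            raise PedigreeError(f"family {family_id!r}: empty pedigree")
        self._index = {m.id: i for i, m in enumerate(self.members)}
        if len(self._index) != len(self.members):
            raise PedigreeError(f"family {family_id!r}: duplicate individual ids")
        self._validate()
        self.father_idx = np.array(
            [self._index[m.father_id] if m.father_id is not None else -1 for m in self.members],
            dtype=np.int64,
        )
        self.mother_idx = np.array(
            [self._index[m.mother_id] if m.mother_id is not None else -1 for m in self.members],
            dtype=np.int64,
        )
        self.topological_order = self._toposort()

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self.family_id == other.family_id and self.members == other.members

    def __repr__(self) -> str:
        return (
            f"Pedigree(family_id={self.family_id!r}, n={len(self)}, "
            f"founders={len(self.founder_ids)})"
        )

    def index_of(self, individual_id: str) -> int:
        return self._index[individual_id]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def founder_ids(self) -> set[str]:
        return {m.id for m in self.members if m.is_founder}

    def founders(self) -> set[str]:
        """Ids of members with no parents in the pedigree."""
        return self.founder_ids

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        for m in self.members:
            if m.family_id != self.family_id:
                raise PedigreeError(
                    f"individual {m.id!r} has family {m.family_id!r}, "
                    f"expected {self.family_id!r}"
                )
            for role, pid, want in (("father", m.father_id, "male"), ("mother", m.mother_id, "female")):
                if pid is None:
                    continue
                if pid not in self._index:
                    raise PedigreeError(
                        f"individual {m.id!r}: {role} {pid!r} not in pedigree"
                    )
                if self.members[self._index[pid]].sex != want:
                    raise PedigreeError(
                        f"individual {m.id!r}: {role} {pid!r} is not {want}"
                    )

    def _toposort(self) -> np.ndarray:
        """Parents-first order; raises on cycles naming an involved individual."""
        n = len(self.members)
        indeg = np.zeros(n, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for p in (self.father_idx[i], self.mother_idx[i]):
                if p >= 0:
                    indeg[i] += 1
                    children[p].append(i)
        # stable Kahn: ready queue kept sorted by input index
        import heapq

        ready = [i for i in range(n) if indeg[i] == 0]
        heapq.heapify(ready)
        order = []
        while ready:
            i = heapq.heappop(ready)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(ready, c)
        if len(order) != n:
            stuck = next(self.members[i].id for i in range(n) if indeg[i] > 0)
            raise PedigreeError(
                f"family {self.family_id!r}: cycle in parent links involving "
                f"individual {stuck!r}"
            )
        return np.asarray(order, dtype=np.int64)

    # -- kinship -----------------------------------------------------------
    def kinship_matrix(self) -> np.ndarray:
        """Kinship coefficients phi by the recursive (tabular) method.

        phi(i,i) = (1 + f_i)/2 with f_i the inbreeding coefficient
        (kinship of the parents); phi(i,j) for a non-ancestor j is the mean
        of the parental kinships with j.  Processing in ancestral order
        makes the recursion well defined; looped (consanguineous)
        pedigrees are handled correctly.  Rows/columns follow member
        input order.
        """
        n = len(self.members)
        phi = np.zeros((n, n))
        for i in self.topological_order:
            f, m = self.father_idx[i], self.mother_idx[i]
            if f < 0:
                phi[i, i] = 0.5
            else:
                phi[i, i] = 0.5 * (1.0 + phi[f, m])
            for j in range(n):
                if j == i:
                    continue
                if phi[j, j] == 0.0:
                    continue  # j not yet processed; handled when j's turn comes
                if f < 0:
                    # founder: unrelated to everyone already processed unless
                    # j descends from i, resolved when j is processed
                    continue
                val = 0.5 * (phi[f, j] + phi[m, j])
                phi[i, j] = val
                phi[j, i] = val
        return phi


def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Module-level alias for :meth:`Pedigree.kinship_matrix`."""
    return ped.kinship_matrix()


def founders(ped: Pedigree) -> set[str]:
    """Module-level alias for :meth:`Pedigree.founders`."""
    return ped.founders()


# -- PED I/O ----------------------------------------------------------------

_SEX_FROM_CODE = {"1": "male", "2": "female"}
_CODE_FROM_SEX = {"male": "1", "female": "2"}


def read_ped(path: str | Path) -> list[Pedigree]:
    """Read a PLINK-style PED/FAM file into one Pedigree per family.

    Expects whitespace-delimited columns: family, id, father, mother, sex
    (1=male, 2=female), optionally followed by phenotype columns (ignored).
    Missing parents are coded "0"; a single "0" parent is rejected.
    Families are returned in order of first appearance.
    """
    fams: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or line.lstrip().startswith("#"):
                continue
            if len(fields) < 5:
                raise PedigreeError(f"{path}:{lineno}: expected >= 5 columns")
            fam, iid, fid, mid, sex = fields[:5]
            if sex not in _SEX_FROM_CODE:
                raise PedigreeError(
                    f"{path}:{lineno}: sex code {sex!r} not in {{1,2}}"
                )
            fams.setdefault(fam, []).append(
                Individual(
                    id=iid,
                    father_id=None if fid == MISSING_PARENT else fid,
                    mother_id=None if mid == MISSING_PARENT else mid,
                    sex=_SEX_FROM_CODE[sex],
                    family_id=fam,
                )
            )
    return [Pedigree(fam, members) for fam, members in fams.items()]


def write_ped(peds: Iterable[Pedigree], path: str | Path) -> None:
    """Write pedigrees in PLINK FAM layout (phenotype column fixed at -9)."""
    with open(path, "w") as fh:
        for ped in peds:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.id,
                            m.father_id or MISSING_PARENT,
                            m.mother_id or MISSING_PARENT,
                            _CODE_FROM_SEX[m.sex],
                            "-9",
                        ]
                    )
                    + "\n"
                )
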