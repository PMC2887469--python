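"""Pedigree structure, validation and PED-style I/O.

The family graph is the unit of both linkage and segregation analysis.  The
on-disk dialect is the widely used whitespace-separated PED layout: family,
individual, father, mother, sex (1=male, 2=female), affection (1=unaffected,
2=affected, 0=unknown), plus one extra column flagging whether the individual
was genotyped (1/0).  ``0`` in a parent column means founder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional


class PedigreeError(ValueError):
    """Structural problem in a family graph (cycles, missing parents...)."""


class PedigreeParseError(PedigreeError):
    """Malformed PED text."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Affection(str, Enum):
    UNAFFECTED = "unaffected"
    AFFECTED = "affected"
    UNKNOWN = "unknown"


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFF_CODES = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED, "0": Affection.UNKNOWN}


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Sex
    affection: Affection = Affection.UNKNOWN
    genotyped: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A validated single-family graph."""

    individuals: list[Individual]
    family_id: str = "FAM1"

    def __post_init__(self) -> None:
        self._by_id = {ind.id: ind for ind in self.individuals}
        if len(self._by_id) != len(self.individuals):
            raise PedigreeError("duplicate individual ids in pedigree")
        self._validate()

    def _validate(self) -> None:
        for ind in self.individuals:
            has_f, has_m = ind.father_id is not None, ind.mother_id is not None
            if has_f != has_m:
                raise PedigreeError(
                    f"{ind.id}: must have both parents or neither (founder)"
                )
            for pid, want in ((ind.father_id, Sex.MALE), (ind.mother_id, Sex.FEMALE)):
                if pid is None:
                    continue
                if pid == ind.id:
                    raise PedigreeError(f"{ind.id} lists itself as a parent")
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeError(f"{ind.id}: parent {pid} not in pedigree")
                if parent.sex is not want:
                    raise PedigreeError(
                        f"{ind.id}: parent {pid} has unexpected sex for its role"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(
                    f"cyclic parentage involving {iid} (an individual is its own ancestor)"
                )
            state[iid] = 0
            ind = self._by_id[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1

        for ind in self.individuals:
            visit(ind.id, [])

    # -- accessors -----------------------------------------------------
    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [i for i in self.individuals if not i.is_founder]

    @property
    def affected(self) -> list[Individual]:
        return [i for i in self.individuals if i.affection is Affection.AFFECTED]

    @property
    def unaffected(self) -> list[Individual]:
        return [i for i in self.individuals if i.affection is Affection.UNAFFECTED]

    @property
    def genotyped(self) -> list[Individual]:
        return [i for i in self.individuals if i.genotyped]

    def children_of(self, iid: str) -> list[Individual]:
        return [
            i for i in self.individuals if iid in (i.father_id, i.mother_id)
        ]

    def topological_order(self) -> list[Individual]:
        """Founders first, every parent before its children."""
        out: list[Individual] = []
        done: set[str] = set()
        pending = list(self.individuals)
        while pending:
            progressed = False
            rest = []
            for ind in pending:
                parents_ok = all(
                    pid is None or pid in done
                    for pid in (ind.father_id, ind.mother_id)
                )
                if parents_ok:
                    out.append(ind)
                    done.add(ind.id)
                    progressed = True
                else:
                    rest.append(ind)
            pending = rest
            if not progressed:  # pragma: no cover - caught by _check_acyclic
                raise PedigreeError("cannot topologically order pedigree")
        return out

    def generation_count(self) -> int:
        """Number of generations (longest founder-to-leaf chain)."""
        depth: dict[str, int] = {}
        for ind in self.topological_order():
            if ind.is_founder:
                depth[ind.id] = 1
            else:
                depth[ind.id] = 1 + max(depth[ind.father_id], depth[ind.mother_id])
        return max(depth.values()) if depth else 0

    def with_affection(self, labels: dict[str, Affection]) -> "Pedigree":
        """A copy with affection statuses replaced from ``labels``."""
        new = [
            replace(ind, affection=labels.get(ind.id, ind.affection))
            for ind in self.individuals
        ]
        return Pedigree(new, self.family_id)


# ---------------------------------------------------------------------------
# PED I/O
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 7-column PED-style file (6 standard columns + genotyped flag)."""
    rows: list[Individual] = []
    family: Optional[str] = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 7:
            raise PedigreeParseError(
                f"line {lineno}: expected >= 7 columns, got {len(fields)}"
            )
        fam, iid, fid, mid, sex, aff, gt = fields[:7]
        if family is None:
            family = fam
        elif fam != family:
            raise PedigreeParseError(
                f"line {lineno}: multiple family ids ({family!r} and {fam!r})"
            )
        if sex not in _SEX_CODES:
            raise PedigreeParseError(f"line {lineno}: unknown sex code {sex!r}")
        if aff not in _AFF_CODES:
            raise PedigreeParseError(f"line {lineno}: unknown affection code {aff!r}")
        if gt not in ("0", "1"):
            raise PedigreeParseError(f"line {lineno}: genotyped flag must be 0/1")
        rows.append(
            Individual(
                id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_SEX_CODES[sex],
                affection=_AFF_CODES[aff],
                genotyped=gt == "1",
            )
        )
    if not rows:
        raise PedigreeParseError(f"{path}: no pedigree records")
    return Pedigree(rows, family_id=family or "FAM1")


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2"}
    aff_out = {
        Affection.UNAFFECTED: "1",
        Affection.AFFECTED: "2",
        Affection.UNKNOWN: "0",
    }
    lines = []
    for ind in pedigree.individuals:
        lines.append(
            "\t".join(
                [
                    pedigree.family_id,
                    ind.id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    sex_out[ind.sex],
                    aff_out[ind.affection],
                    "1" if ind.genotyped else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
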