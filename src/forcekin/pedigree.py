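"""Pedigree data model, PED-style I/O, and pairwise relationship templates.

A :class:`Pedigree` is a directed acyclic parent->child structure with sexed
individuals.  Relationship hypotheses used throughout the kinship machinery
are expressed as small template pedigrees connecting two typed individuals
(``A`` and ``B``) through untyped intermediates; the standard unlinked IBD
coefficients (kappa0, kappa1, kappa2) for each template are carried alongside
for closed-form single-marker checks and fast unlinked-mode computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "Individual",
    "Pedigree",
    "RelationshipHypothesis",
    "RELATIONSHIPS",
    "relationship_template",
    "read_ped",
    "write_ped",
]

MALE = "M"
FEMALE = "F"


@dataclass(frozen=True)
class Individual:
    iid: str
    sex: str  # "M" or "F"
    father: str | None = None
    mother: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """A validated pedigree: topologically ordered, sex-consistent parents."""

    def __init__(self, individuals: Iterable[Individual]):
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.members:
                raise ValueError(f"duplicate individual id {ind.iid!r}")
            if (ind.father is None) != (ind.mother is None):
                raise ValueError(
                    f"{ind.iid!r}: both parents must be given or both absent"
                )
            self.members[ind.iid] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self.members.values():
            if ind.sex not in (MALE, FEMALE):
                raise ValueError(f"{ind.iid!r}: sex must be M or F")
            for pid, want in ((ind.father, MALE), (ind.mother, FEMALE)):
                if pid is None:
                    continue
                if pid not in self.members:
                    raise ValueError(f"{ind.iid!r}: unknown parent {pid!r}")
                if self.members[pid].sex != want:
                    raise ValueError(
                        f"{ind.iid!r}: parent {pid!r} has inconsistent sex"
                    )
        self.topo_order()  # raises on cycles

    def topo_order(self) -> list[str]:
        """Individual ids with every parent preceding its children."""
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            st = state.get(iid, 0)
            if st == 1:
                raise ValueError(f"pedigree cycle involving {iid!r}")
            if st == 2:
                return
            state[iid] = 1
            ind = self.members[iid]
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    visit(pid)
            state[iid] = 2
            order.append(iid)

        for iid in self.members:
            visit(iid)
        return order

    @property
    def founders(self) -> list[str]:
        return [i for i, m in self.members.items() if m.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [i for i in self.topo_order() if not self.members[i].is_founder]

    def sex(self, iid: str) -> str:
        return self.members[iid].sex

    def with_individual(self, ind: Individual) -> "Pedigree":
        """A new pedigree with one individual added (or replaced)."""
        members = dict(self.members)
        members[ind.iid] = ind
        return Pedigree(members.values())

    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RelationshipHypothesis:
    """A pairwise relationship hypothesis between two typed individuals.

    ``degree`` follows the usual genealogical convention (parent/offspring and
    full siblings are first degree, ..., second cousins once removed are
    sixth degree); ``kappa`` are the unlinked IBD-sharing coefficients.
    """

    name: str
    degree: int | None
    kappa: tuple[float, float, float]

    def __post_init__(self):
        if abs(sum(self.kappa) - 1.0) > 1e-12:
            raise ValueError("kappa coefficients must sum to 1")


RELATIONSHIPS: dict[str, RelationshipHypothesis] = {
    h.name: h
    for h in [
        RelationshipHypothesis("parent_offspring", 1, (0.0, 1.0, 0.0)),
        RelationshipHypothesis("full_siblings", 1, (0.25, 0.5, 0.25)),
        RelationshipHypothesis("half_siblings", 2, (0.5, 0.5, 0.0)),
        RelationshipHypothesis("first_cousins", 3, (0.75, 0.25, 0.0)),
        RelationshipHypothesis(
            "first_cousins_once_removed", 4, (7 / 8, 1 / 8, 0.0)
        ),
        RelationshipHypothesis("second_cousins", 5, (15 / 16, 1 / 16, 0.0)),
        RelationshipHypothesis(
            "second_cousins_once_removed", 6, (31 / 32, 1 / 32, 0.0)
        ),
        RelationshipHypothesis("unrelated", None, (1.0, 0.0, 0.0)),
    ]
}


def _chain(top_child: str, n_down: int, sexes: str, prefix: str) -> list[Individual]:
    """Descend ``n_down`` generations from ``top_child`` via untyped spouses."""
    out: list[Individual] = []
    cur = top_child
    for g in range(n_down):
        spouse = f"{prefix}sp{g}"
        child = f"{prefix}c{g}"
        out.append(Individual(spouse, FEMALE))
        out.append(Individual(child, sexes[min(g, len(sexes) - 1)], cur, spouse))
        cur = child
    return out


def relationship_template(
    name: str, sex_a: str = MALE, sex_b: str = FEMALE
) -> tuple[Pedigree, str, str]:
    """Build the template pedigree for a named relationship.

    Returns ``(pedigree, id_a, id_b)`` where ``A`` and ``B`` are the two
    typed individuals.  Lineage individuals are male and spouses female
    except for ``A``/``B`` themselves, whose sexes are configurable (this
    matters only in X-chromosomal mode).
    """
    if name not in RELATIONSHIPS:
        raise KeyError(f"unknown relationship {name!r}")
    A, B = "A", "B"
    inds: list[Individual]
    if name == "unrelated":
        inds = [Individual(A, sex_a), Individual(B, sex_b)]
    elif name == "parent_offspring":
        inds = [
            Individual(A, sex_a),
            Individual("sp", FEMALE if sex_a == MALE else MALE),
            Individual(
                B,
                sex_b,
                A if sex_a == MALE else "sp",
                "sp" if sex_a == MALE else A,
            ),
        ]
    elif name == "full_siblings":
        inds = [
            Individual("f", MALE),
            Individual("m", FEMALE),
            Individual(A, sex_a, "f", "m"),
            Individual(B, sex_b, "f", "m"),
        ]
    elif name == "half_siblings":
        # maternal half siblings: shared untyped mother
        inds = [
            Individual("m", FEMALE),
            Individual("f1", MALE),
            Individual("f2", MALE),
            Individual(A, sex_a, "f1", "m"),
            Individual(B, sex_b, "f2", "m"),
        ]
    else:
        # cousin-type: shared grandparental couple, two untyped sib parents,
        # then a descent chain of (possibly unequal) length on each side.
        down_a, down_b = {
            "first_cousins": (1, 1),
            "first_cousins_once_removed": (1, 2),
            "second_cousins": (2, 2),
            "second_cousins_once_removed": (2, 3),
        }[name]
        inds = [
            Individual("g1", MALE),
            Individual("g2", FEMALE),
            Individual("p1", MALE, "g1", "g2"),
            Individual("p2", MALE, "g1", "g2"),
        ]
        for side, top, n_down, sex_typed, typed in (
            ("a", "p1", down_a, sex_a, A),
            ("b", "p2", down_b, sex_b, B),
        ):
            chain = _chain(top, n_down - 1, MALE, side)
            inds.extend(chain)
            parent = chain[-1].iid if chain else top
            spouse = f"{side}sp_last"
            inds.append(Individual(spouse, FEMALE))
            inds.append(Individual(typed, sex_typed, parent, spouse))
    return Pedigree(inds), A, B


_SEX_CODE = {"1": MALE, "2": FEMALE, "M": MALE, "F": FEMALE}


def read_ped(path: str | Path) -> dict[str, Pedigree]:
    """Read PED-style TSV (family, id, father, mother, sex); 0 = no parent.

    Returns one :class:`Pedigree` per family id.
    """
    fams: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}: line {ln}: expected 5+ columns")
            fam, iid, father, mother, sex = parts[:5]
            if sex not in _SEX_CODE:
                raise ValueError(f"{path}: line {ln}: bad sex code {sex!r}")
            fams.setdefault(fam, []).append(
                Individual(
                    iid,
                    _SEX_CODE[sex],
                    None if father == "0" else father,
                    None if mother == "0" else mother,
                )
            )
    return {fam: Pedigree(inds) for fam, inds in fams.items()}


def write_ped(pedigrees: dict[str, Pedigree], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# family\tid\tfather\tmother\tsex\n")
        for fam, ped in pedigrees.items():
            for iid in ped.topo_order():
                ind = ped.members[iid]
                fh.write(
                    "\t".join(
                        [
                            fam,
                            iid,
                            ind.father or "0",
                            ind.mother or "0",
                            "1" if ind.sex == MALE else "2",
                        ]
                    )
                    + "\n"
                )
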