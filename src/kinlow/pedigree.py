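"""Pedigrees, true kinship coefficients, and degree classification.

The kinship coefficient phi(a, b) is the probability that one allele drawn
at random from each of two individuals at an autosomal locus is identical
by descent.  For outbred pedigrees phi takes the canonical values 0.5
(identical genomes / monozygotic twins), 0.25 (parent-offspring, full
siblings), 0.125 (second degree: grandparent, avuncular, half-sibling),
0.0625 (third degree: great-grandparent, first cousin) and 0 (unrelated).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache

from .errors import InputError

__all__ = [
    "Degree",
    "Pedigree",
    "TrueRelationship",
    "true_kinship",
    "degree_from_phi",
    "fixture_pedigree",
    "related_pairs",
    "FIXTURE_NAMES",
]


class Degree(str, enum.Enum):
    IDENTICAL = "identical"
    FIRST = "first"
    SECOND = "second"
    THIRD = "third"
    UNRELATED = "unrelated"


# Midpoints between adjacent theoretical phi expectations
# (0.5, 0.25, 0.125, 0.0625, 0), on a log-2 ladder.
_PHI_BOUNDS = (
    (0.75 * 0.5, Degree.IDENTICAL),   # > 0.375
    (0.75 * 0.25, Degree.FIRST),      # > 0.1875
    (0.75 * 0.125, Degree.SECOND),    # > 0.09375
    (0.75 * 0.0625, Degree.THIRD),    # > 0.046875
)


def degree_from_phi(phi: float) -> Degree:
    """Classify a kinship coefficient into a relationship degree.

    Boundaries are midpoints between adjacent theoretical expectations.
    """
    for bound, degree in _PHI_BOUNDS:
        if phi > bound:
            return degree
    return Degree.UNRELATED


@dataclass(frozen=True)
class TrueRelationship:
    """Pedigree-derived ground truth for one unordered pair."""

    pair: tuple[str, str]
    phi: float
    degree: Degree


@dataclass
class Pedigree:
    """A set of individuals with parent links and optional genome duplicates.

    Parameters
    ----------
    parents
        Maps each individual id to ``(mother, father)`` or ``None`` for
        founders.  Every non-founder must have both parents present.
    duplicates
        Maps an id to the id whose genome it copies exactly (monozygotic
        twin / same-individual resampling).  Duplicate ids are full members
        but carry no parent entry of their own.
    """

    parents: dict[str, tuple[str, str] | None]
    duplicates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for ind, par in self.parents.items():
            if par is None:
                continue
            if len(par) != 2 or any(p is None for p in par):
                raise InputError(
                    f"individual {ind!r} has exactly one recorded parent; "
                    "each non-founder needs both"
                )
            for p in par:
                if p not in self.parents:
                    raise InputError(f"parent {p!r} of {ind!r} not in pedigree")
        for dup, src in self.duplicates.items():
            if src not in self.parents:
                raise InputError(f"duplicate source {src!r} not in pedigree")
            if dup in self.parents:
                raise InputError(f"duplicate id {dup!r} collides with a pedigree member")
        self._depths()  # raises on cycles

    @property
    def members(self) -> list[str]:
        """All ids, duplicates included, in deterministic order."""
        return list(self.parents) + list(self.duplicates)

    def genome_source(self, ind: str) -> str:
        """The id whose genome ``ind`` carries (itself unless a duplicate)."""
        return self.duplicates.get(ind, ind)

    def _depths(self) -> dict[str, int]:
        depths: dict[str, int] = {}

        def depth(ind: str, stack: frozenset) -> int:
            if ind in depths:
                return depths[ind]
            if ind in stack:
                raise InputError(f"pedigree parent graph has a cycle through {ind!r}")
            par = self.parents[ind]
            d = 0 if par is None else 1 + max(depth(p, stack | {ind}) for p in par)
            depths[ind] = d
            return d

        for ind in self.parents:
            depth(ind, frozenset())
        return depths

    def topological_order(self) -> list[str]:
        """Members ordered parents-before-children (duplicates last)."""
        depths = self._depths()
        ordered = sorted(self.parents, key=lambda i: (depths[i], i))
        return ordered + list(self.duplicates)

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient between two members (recursive, outbred)."""
        a, b = self.genome_source(a), self.genome_source(b)
        depths = self._depths()

        @lru_cache(maxsize=None)
        def phi(x: str, y: str) -> float:
            if x == y:
                return 0.5
            # Recurse on the individual deeper in the pedigree: it cannot
            # be an ancestor of the other, which the recursion requires.
            if depths[x] < depths[y] or (depths[x] == depths[y] and self.parents[x] is None):
                x, y = y, x
            par = self.parents[x]
            if par is None:
                return 0.0
            return 0.5 * (phi(par[0], y) + phi(par[1], y))

        return phi(*sorted((a, b)))

    def check_outbred(self) -> None:
        """Raise if any individual's parents are themselves related."""
        for ind, par in self.parents.items():
            if par is not None and self.kinship(*par) > 0:
                raise InputError(
                    f"pedigree is inbred: parents of {ind!r} are related; "
                    "only outbred pedigrees are supported"
                )


def true_kinship(pedigree: Pedigree, pair: tuple[str, str]) -> TrueRelationship:
    """Ground-truth kinship coefficient and degree for an unordered pair."""
    a, b = pair
    for ind in (a, b):
        if ind not in pedigree.parents and ind not in pedigree.duplicates:
            raise InputError(f"individual {ind!r} not in pedigree")
    pedigree.check_outbred()
    phi = pedigree.kinship(a, b)
    return TrueRelationship(pair=tuple(sorted((a, b))), phi=phi, degree=degree_from_phi(phi))


def related_pairs(pedigree: Pedigree, max_degree: Degree = Degree.SECOND) -> set[tuple[str, str]]:
    """All unordered pairs related at or closer than ``max_degree``."""
    rank = {
        Degree.IDENTICAL: 0,
        Degree.FIRST: 1,
        Degree.SECOND: 2,
        Degree.THIRD: 3,
        Degree.UNRELATED: 4,
    }
    members = pedigree.members
    out = set()
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            rel = true_kinship(pedigree, (a, b))
            if rank[rel.degree] <= rank[max_degree]:
                out.add(rel.pair)
    return out


def _trios() -> Pedigree:
    """Five independent father-mother-offspring trios (15 ids)."""
    parents: dict[str, tuple[str, str] | None] = {}
    for k in range(1, 6):
        f, m, c = f"T{k}_father", f"T{k}_mother", f"T{k}_child"
        parents[f] = None
        parents[m] = None
        parents[c] = (m, f)
    return Pedigree(parents)


def _family() -> Pedigree:
    """A 15-id extended family containing identical, 1st, 2nd, 3rd degree
    and unrelated pairs.

    Three generations descend from founders A x B; S2_twin duplicates S2's
    genome, G1 x D yields a great-grandchild of A, and S2 x U3 yields K1,
    first cousin to G1/G2.
    """
    parents: dict[str, tuple[str, str] | None] = {
        "A": None, "B": None, "C": None, "D": None,
        "U1": None, "U2": None, "U3": None, "U4": None,
        "S1": ("A", "B"),
        "S2": ("A", "B"),
        "G1": ("S1", "C"),
        "G2": ("S1", "C"),
        "H1": ("G1", "D"),
        "K1": ("S2", "U3"),
    }
    return Pedigree(parents, duplicates={"S2_twin": "S2"})


def _unrelated5() -> Pedigree:
    """Five mutually unrelated individuals (all founders)."""
    return Pedigree({f"U{k}": None for k in range(1, 6)})


def _village() -> Pedigree:
    """28 ids: mostly unrelated founders plus one small nuclear cluster
    (two brothers and a nephew)."""
    parents: dict[str, tuple[str, str] | None] = {
        "P1": None, "P2": None, "Q1": None,
        "B1": ("P1", "P2"),
        "B2": ("P1", "P2"),
        "N1": ("Q1", "B1"),
    }
    for k in range(1, 23):
        parents[f"V{k:02d}"] = None
    return Pedigree(parents)


_FIXTURES = {
    "trios": _trios,
    "family": _family,
    "unrelated5": _unrelated5,
    "village": _village,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def fixture_pedigree(name: str) -> Pedigree:
    """Return one of the shipped benchmark pedigrees by name.

    ``trios``      five independent father-mother-offspring trios (15 ids);
    ``family``     15-id three-generation family with a duplicated genome;
    ``unrelated5`` five mutually unrelated individuals;
    ``village``    28 ids with a handful of relatives among founders.
    """
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise InputError(
            f"unknown pedigree fixture {name!r}; available: {', '.join(_FIXTURES)}"
        ) from None
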