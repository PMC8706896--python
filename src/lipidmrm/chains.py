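"""Fatty-acyl chain space and per-class lipid species enumeration.

Targeted lipidomics MRM methods for plant matrices are built over a
combinatorial space of fatty-acyl chains: even carbon numbers 14-22 with
0-6 double bonds give 35 chains; two-chain classes (diacyl glycerolipids
and glycerophospholipids) are multisets of two chains (C(36,2) = 630),
triacylglycerols are multisets of three (C(37,3) = 7770).  Sphingolipid
classes carry a fixed sphingoid base (d18:1 or d18:0) plus one variable
N-acyl chain, so they enumerate like single-chain classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterator

__all__ = [
    "FattyAcylChain",
    "ChainSpace",
    "LipidSpecies",
    "DEFAULT_SPACE",
    "LIPID_CLASSES",
    "ACYL_POSITIONS",
    "SPHINGOID_BASES",
    "enumerate_chains",
    "enumerate_species",
]


@dataclass(frozen=True, order=True)
class FattyAcylChain:
    """A fatty-acyl chain identified by (carbons, double bonds).

    ``carbons`` counts all acyl carbons including the carboxyl carbon.
    Equality and ordering are componentwise on (carbons, double_bonds).
    """

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"chain needs at least one carbon, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"negative double-bond count: {self.double_bonds}")
        # H count of the free fatty acid is 2C - 2DB; it must stay positive
        if 2 * self.carbons - 2 * self.double_bonds <= 0:
            raise ValueError(
                f"chemically impossible chain {self.carbons}:{self.double_bonds} "
                "(hydrogen count 2C-2DB would be non-positive)"
            )

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    @classmethod
    def parse(cls, text: str) -> "FattyAcylChain":
        """Parse shorthand like ``"18:1"``."""
        c, _, d = text.partition(":")
        return cls(int(c), int(d))


@dataclass(frozen=True)
class ChainSpace:
    """An enumerable rectangle of (carbon, double-bond) combinations.

    Defaults reproduce the even-chain plant-lipid space: C14-C22 in steps
    of 2, double bonds 0-6, i.e. 5 x 7 = 35 chains.
    """

    carbon_min: int = 14
    carbon_max: int = 22
    carbon_step: int = 2
    db_min: int = 0
    db_max: int = 6

    def __post_init__(self) -> None:
        if self.carbon_min > self.carbon_max:
            raise ValueError(
                f"empty carbon range: carbon_min={self.carbon_min} exceeds "
                f"carbon_max={self.carbon_max}"
            )
        if self.db_min > self.db_max:
            raise ValueError(
                f"empty double-bond range: db_min={self.db_min} exceeds "
                f"db_max={self.db_max}"
            )
        if self.carbon_step < 1:
            raise ValueError(f"carbon_step must be positive, got {self.carbon_step}")

    @property
    def n_carbons(self) -> int:
        return (self.carbon_max - self.carbon_min) // self.carbon_step + 1

    @property
    def n_double_bonds(self) -> int:
        return self.db_max - self.db_min + 1

    def __len__(self) -> int:
        return self.n_carbons * self.n_double_bonds

    def __iter__(self) -> Iterator[FattyAcylChain]:
        for c in range(self.carbon_min, self.carbon_max + 1, self.carbon_step):
            for d in range(self.db_min, self.db_max + 1):
                yield FattyAcylChain(c, d)


DEFAULT_SPACE = ChainSpace()

# Acylation count per class: number of variable fatty-acyl chains.
# Sphingolipid classes have one variable N-acyl chain on a fixed base.
ACYL_POSITIONS: dict[str, int] = {
    # single chain
    "FA": 1, "CAR": 1, "MG": 1,
    "LPA": 1, "LPC": 1, "LPE": 1, "LPG": 1, "LPI": 1, "LPS": 1,
    "SM": 1, "CER": 1, "dhCER": 1, "glcCER": 1, "glc-dhCER": 1,
    "lacCER": 1, "lac-dhCER": 1,
    # two chains
    "DG": 2, "MGDG": 2, "DGDG": 2,
    "PA": 2, "PC": 2, "PE": 2, "PG": 2, "PI": 2, "PS": 2,
    # three chains
    "TG": 3,
}

# Fixed sphingoid base per sphingolipid class; d18:1 = sphingosine,
# d18:0 = sphinganine (the dihydro- classes).
SPHINGOID_BASES: dict[str, str] = {
    "SM": "d18:1",
    "CER": "d18:1", "glcCER": "d18:1", "lacCER": "d18:1",
    "dhCER": "d18:0", "glc-dhCER": "d18:0", "lac-dhCER": "d18:0",
}

LIPID_CLASSES: tuple[str, ...] = tuple(sorted(ACYL_POSITIONS))

CERAMIDE_FAMILY: tuple[str, ...] = (
    "CER", "dhCER", "glcCER", "glc-dhCER", "lacCER", "lac-dhCER",
)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species: class scaffold plus an unordered multiset of chains.

    ``chains`` is stored sorted, so species identity is invariant under
    chain reordering (sn positions are deliberately unresolved; the
    positional question only arises when choosing fragment leaving groups).
    """

    lipid_class: str
    chains: tuple[FattyAcylChain, ...]
    fixed_base: str | None = None

    def __post_init__(self) -> None:
        if self.lipid_class not in ACYL_POSITIONS:
            raise KeyError(
                f"unknown lipid class {self.lipid_class!r}; registered classes: "
                f"{', '.join(LIPID_CLASSES)}"
            )
        want = ACYL_POSITIONS[self.lipid_class]
        if len(self.chains) != want:
            raise ValueError(
                f"{self.lipid_class} carries {want} acyl chain(s), got {len(self.chains)}"
            )
        object.__setattr__(self, "chains", tuple(sorted(self.chains)))
        expected_base = SPHINGOID_BASES.get(self.lipid_class)
        if expected_base is not None and self.fixed_base is None:
            object.__setattr__(self, "fixed_base", expected_base)

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(c.double_bonds for c in self.chains)

    @property
    def name(self) -> str:
        body = "_".join(str(c) for c in self.chains)
        if self.fixed_base is not None:
            body = f"{self.fixed_base}/{body}"
        return f"{self.lipid_class} {body}"

    def __str__(self) -> str:
        return self.name


def parse_species_name(name: str) -> LipidSpecies:
    """Inverse of :attr:`LipidSpecies.name`, e.g. ``"PE 16:0_18:2"``."""
    cls, _, body = name.partition(" ")
    base = None
    if "/" in body:
        base, _, body = body.partition("/")
    chains = tuple(FattyAcylChain.parse(tok) for tok in body.split("_"))
    return LipidSpecies(cls, chains, base)


def enumerate_chains(space: ChainSpace = DEFAULT_SPACE) -> list[FattyAcylChain]:
    """All chains of ``space`` sorted by (carbons, double_bonds)."""
    return sorted(space)


def enumerate_species(
    lipid_class: str, space: ChainSpace = DEFAULT_SPACE
) -> list[LipidSpecies]:
    """All species of a class over a chain space, in deterministic order.

    For k acylation positions over n chains this is every multiset of size
    k, hence C(n+k-1, k) species.  Sphingolipid classes return n species
    (fixed base x variable N-acyl chain).  Order: (total C, total DB,
    lexicographic chain tuple).
    """
    if lipid_class not in ACYL_POSITIONS:
        raise KeyError(
            f"unknown lipid class {lipid_class!r}; registered classes: "
            f"{', '.join(LIPID_CLASSES)}"
        )
    chains = enumerate_chains(space)
    k = ACYL_POSITIONS[lipid_class]
    species = [
        LipidSpecies(lipid_class, combo)
        for combo in combinations_with_replacement(chains, k)
    ]
    species.sort(key=lambda s: (s.total_carbons, s.total_double_bonds, s.chains))
    return species
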