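"""Monoisotopic mass arithmetic: compositions, adducts, fragments.

Every lipid species mass is assembled as

    neutral M = scaffold + sum(free fatty acids) - n_linkages * H2O

where the scaffold is the fully hydroxylated backbone-plus-head-group of
the class (e.g. glycerophosphocholine for PC/LPC, sphingosine for CER)
and each ester/amide linkage condenses out one water.  Precursor m/z adds
the adduct delta (proton, sodium, formate, or protonation-with-water-loss)
including the electron-mass correction; product m/z follows the per-class
fragmentation rule (head-group constant, sn-chain carboxylate, neutral
loss of a fatty acid, or glycerol loss to the acylium).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .chains import FattyAcylChain, LipidSpecies, SPHINGOID_BASES

__all__ = [
    "Composition",
    "AdductRule",
    "FragmentKind",
    "FragmentRule",
    "ADDUCTS",
    "SCAFFOLDS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "CH2_MASS",
    "chain_composition",
    "species_composition",
    "species_mass",
    "precursor_mz",
    "product_mz",
]

# Monoisotopic atomic masses, CODATA/AME2020 values as tabulated by IUPAC
# (Da).  "D" is deuterium, used only for labelled internal standards.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "D": 2.01410177812,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS  # 1.00727645...
H2O_MASS = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]
CH2_MASS = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["H"]  # 14.01565

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Composition:
    """An elemental composition with an optional integer charge.

    Stored as a sorted tuple of (element, count) pairs so instances are
    hashable; addition/subtraction is element-wise and subtraction that
    would drive a count negative raises.
    """

    elements: tuple[tuple[str, int], ...] = ()
    charge: int = 0

    @classmethod
    def from_dict(cls, counts: dict[str, int], charge: int = 0) -> "Composition":
        for el, n in counts.items():
            if el not in ATOMIC_MASS:
                raise KeyError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        items = tuple(sorted((el, n) for el, n in counts.items() if n > 0))
        return cls(items, charge)

    @classmethod
    def from_formula(cls, formula: str, charge: int = 0) -> "Composition":
        """Parse a Hill-style formula such as ``"C42H82NO8P"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            el, num = match.group(1), match.group(2)
            if not el:
                break
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = match.end()
            if pos == len(formula):
                break
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls.from_dict(counts, charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.elements)

    def __add__(self, other: "Composition") -> "Composition":
        counts = self.as_dict()
        for el, n in other.elements:
            counts[el] = counts.get(el, 0) + n
        return Composition.from_dict(counts, self.charge + other.charge)

    def __sub__(self, other: "Composition") -> "Composition":
        counts = self.as_dict()
        for el, n in other.elements:
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count "
                    f"({counts.get(el, 0)} - {n})"
                )
            counts[el] = new
        return Composition.from_dict(counts, self.charge - other.charge)

    @property
    def mass(self) -> float:
        """Monoisotopic mass (m/z for singly charged ions)."""
        m = sum(ATOMIC_MASS[el] * n for el, n in self.elements)
        return m - self.charge * ELECTRON_MASS

    def formula(self) -> str:
        order = {"C": 0, "H": 1, "D": 2}
        items = sorted(self.elements, key=lambda t: (order.get(t[0], 3), t[0]))
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in items)


WATER = Composition.from_formula("H2O")
GLYCEROL = Composition.from_formula("C3H8O3")

# Fully hydroxylated class scaffolds (backbone + head group) and the
# number of ester/amide linkages condensing the acyl chains onto them.
# Sphingolipid scaffolds depend on the base and are resolved per species.
_SCAFFOLD_FORMULAS: dict[str, tuple[str, int]] = {
    "FA": ("", 0),                # the chain *is* the species
    "CAR": ("C7H15NO3", 1),       # carnitine
    "MG": ("C3H8O3", 1),          # glycerol
    "DG": ("C3H8O3", 2),
    "TG": ("C3H8O3", 3),
    "LPA": ("C3H9O6P", 1),        # glycerophosphate
    "PA": ("C3H9O6P", 2),
    "LPC": ("C8H20NO6P", 1),      # glycerophosphocholine
    "PC": ("C8H20NO6P", 2),
    "LPE": ("C5H14NO6P", 1),      # glycerophosphoethanolamine
    "PE": ("C5H14NO6P", 2),
    "LPG": ("C6H15O8P", 1),       # glycerophosphoglycerol
    "PG": ("C6H15O8P", 2),
    "LPI": ("C9H19O11P", 1),      # glycerophosphoinositol
    "PI": ("C9H19O11P", 2),
    "LPS": ("C6H14NO8P", 1),      # glycerophosphoserine
    "PS": ("C6H14NO8P", 2),
    "MGDG": ("C9H18O8", 2),       # galactosylglycerol
    "DGDG": ("C15H28O13", 2),     # digalactosylglycerol
}

_BASE_FORMULAS: dict[str, str] = {
    "d18:1": "C18H37NO2",  # sphingosine
    "d18:0": "C18H39NO2",  # sphinganine
}

# Head/sugar extensions on the sphingoid base, one amide linkage each.
_SPHINGO_EXTENSION: dict[str, str] = {
    "CER": "", "dhCER": "",
    "glcCER": "C6H10O5", "glc-dhCER": "C6H10O5",
    "lacCER": "C12H20O10", "lac-dhCER": "C12H20O10",
    "SM": "C5H12NO3P",  # phosphorylcholine, net of the linking water
}


def _scaffold(species: LipidSpecies) -> tuple[Composition, int]:
    cls = species.lipid_class
    if cls in SPHINGOID_BASES:
        base = _BASE_FORMULAS[species.fixed_base or SPHINGOID_BASES[cls]]
        comp = Composition.from_formula(base)
        ext = _SPHINGO_EXTENSION[cls]
        if ext:
            comp = comp + Composition.from_formula(ext)
        return comp, 1
    if cls not in _SCAFFOLD_FORMULAS:
        raise KeyError(f"no scaffold registered for class {cls!r}")
    formula, linkages = _SCAFFOLD_FORMULAS[cls]
    comp = Composition.from_formula(formula) if formula else Composition()
    return comp, linkages


SCAFFOLDS = dict(_SCAFFOLD_FORMULAS)  # read-only view for introspection


def chain_composition(chain: FattyAcylChain) -> Composition:
    """Composition of the free fatty acid: CnH(2n-2d)O2."""
    h = 2 * chain.carbons - 2 * chain.double_bonds
    return Composition.from_dict({"C": chain.carbons, "H": h, "O": 2})


def species_composition(species: LipidSpecies) -> Composition:
    scaffold, linkages = _scaffold(species)
    comp = scaffold
    for chain in species.chains:
        comp = comp + chain_composition(chain)
    for _ in range(linkages):
        comp = comp - WATER
    return comp


def species_mass(species: LipidSpecies) -> float:
    """Neutral monoisotopic mass of a species (Da)."""
    return species_composition(species).mass


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class AdductRule:
    """A named ionization adduct with its exact m/z delta from neutral M."""

    name: str
    delta: float
    polarity: Polarity


ADDUCTS: dict[str, AdductRule] = {
    "[M+H]+": AdductRule("[M+H]+", PROTON_MASS, Polarity.POSITIVE),
    "[M-H]-": AdductRule("[M-H]-", -PROTON_MASS, Polarity.NEGATIVE),
    "[M+Na]+": AdductRule(
        "[M+Na]+", ATOMIC_MASS["Na"] - ELECTRON_MASS, Polarity.POSITIVE
    ),
    "[M+HCOO]-": AdductRule(
        "[M+HCOO]-",
        Composition.from_formula("CHO2").mass + ELECTRON_MASS,
        Polarity.NEGATIVE,
    ),
    # protonation accompanied by water loss (dehydration, 18.0106 Da)
    "[M+H-18]+": AdductRule("[M+H-18]+", PROTON_MASS - H2O_MASS, Polarity.POSITIVE),
}


def precursor_mz(species: LipidSpecies, adduct: AdductRule | str) -> float:
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    return species_mass(species) + adduct.delta


class FragmentKind(str, Enum):
    FIXED_MZ = "fixed_mz"
    SN_CHAIN_CARBOXYLATE = "sn_chain_carboxylate"
    NEUTRAL_LOSS_OF_CHAIN = "neutral_loss_of_chain"
    NEUTRAL_LOSS_OF_FA_REARRANGEMENT = "neutral_loss_of_fatty_acid_with_rearrangement"
    LOSS_OF_GLYCEROL = "loss_of_glycerol"
    INTACT_DEPROTONATED = "intact_deprotonated"


@dataclass(frozen=True)
class FragmentRule:
    kind: FragmentKind
    fixed_mz: float | None = None  # printed constant, used verbatim on export

    def __post_init__(self) -> None:
        if self.kind is FragmentKind.FIXED_MZ and self.fixed_mz is None:
            raise ValueError("fixed_mz fragments need a value")


# Exactly computable counterparts of the printed head-group constants,
# exposed through recompute_fixed=True.
PHOSPHOCHOLINE_CATION = Composition.from_formula("C5H15NO4P", charge=1)  # 184.0733
_SPHINGOID_FRAGMENT = {  # base - 2 H2O + H+, the long-chain-base ion
    "d18:1": Composition.from_formula("C18H37NO2").mass - 2 * H2O_MASS + PROTON_MASS,
    "d18:0": Composition.from_formula("C18H39NO2").mass - 2 * H2O_MASS + PROTON_MASS,
}
_CARNITINE_FRAGMENT = Composition.from_formula("C4H5O2", charge=1).mass  # 85.0284

_CHAIN_DEPENDENT = {
    FragmentKind.SN_CHAIN_CARBOXYLATE,
    FragmentKind.NEUTRAL_LOSS_OF_CHAIN,
    FragmentKind.NEUTRAL_LOSS_OF_FA_REARRANGEMENT,
}


def _recomputed_fixed(species: LipidSpecies, printed: float) -> float:
    if printed == 184.1:
        return PHOSPHOCHOLINE_CATION.mass
    if printed in (264.1, 266.1):
        return _SPHINGOID_FRAGMENT[species.fixed_base or "d18:1"]
    if printed == 85.1:
        return _CARNITINE_FRAGMENT
    return printed


def product_mz(
    species: LipidSpecies,
    fragment: FragmentRule,
    adduct: AdductRule | str,
    leaving_chain: FattyAcylChain | None = None,
    *,
    recompute_fixed: bool = False,
    glycerol_loss_as_radical: bool = False,
) -> float:
    """Product-ion m/z for a species under a class fragmentation rule.

    ``leaving_chain`` is required for chain-dependent rules and must be a
    member of the species' chain multiset.  ``recompute_fixed`` replaces
    printed head-group constants with their exactly computed m/z.
    ``glycerol_loss_as_radical`` switches the monoacylglycerol fragment
    from neutral-glycerol loss (acylium, default) to the printed C3H7O3
    radical loss.
    """
    kind = fragment.kind
    if kind in _CHAIN_DEPENDENT:
        if leaving_chain is None:
            raise ValueError(f"{kind.value} fragment requires a leaving chain")
        if leaving_chain not in species.chains:
            raise ValueError(
                f"leaving chain {leaving_chain} is not part of {species.name}"
            )
    if kind is FragmentKind.FIXED_MZ:
        assert fragment.fixed_mz is not None
        if recompute_fixed:
            return _recomputed_fixed(species, fragment.fixed_mz)
        return fragment.fixed_mz
    if kind is FragmentKind.SN_CHAIN_CARBOXYLATE:
        return chain_composition(leaving_chain).mass - PROTON_MASS
    if kind in (
        FragmentKind.NEUTRAL_LOSS_OF_CHAIN,
        FragmentKind.NEUTRAL_LOSS_OF_FA_REARRANGEMENT,
    ):
        return precursor_mz(species, adduct) - chain_composition(leaving_chain).mass
    if kind is FragmentKind.LOSS_OF_GLYCEROL:
        if glycerol_loss_as_radical:
            # printed notation: [M - C3H7O3]+ as a radical-formula loss
            return (
                species_mass(species)
                - Composition.from_formula("C3H7O3").mass
                - ELECTRON_MASS
            )
        return precursor_mz(species, adduct) - GLYCEROL.mass
    if kind is FragmentKind.INTACT_DEPROTONATED:
        return precursor_mz(species, adduct)
    raise ValueError(f"unhandled fragment kind {kind!r}")
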