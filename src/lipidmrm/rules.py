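"""Per-class MRM acquisition rules and the internal-standard registry.

One :class:`LipidClassRule` per lipid class: ionization polarity, adduct,
product-ion rule, the four triple-quadrupole voltages (declustering
potential DP, entrance potential EP, collision energy CE, collision-cell
exit potential CXP; negative-mode voltages are signed negative) and the
assigned internal standard.  The 21 internal standards are deuterated or
odd-chain surrogates, one per class, with the six ceramide-family classes
sharing a single labelled ceramide.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .chains import (
    ACYL_POSITIONS,
    ChainSpace,
    FattyAcylChain,
    LipidSpecies,
)
from .masses import ADDUCTS, AdductRule, FragmentKind, FragmentRule, Polarity

__all__ = [
    "LipidClassRule",
    "InternalStandard",
    "default_rules",
    "default_internal_standards",
    "load_config",
]


@dataclass(frozen=True)
class LipidClassRule:
    class_id: str
    adduct: AdductRule
    fragment: FragmentRule
    dp: float
    ep: float
    ce: float
    cxp: float
    internal_standard: str

    def __post_init__(self) -> None:
        if self.class_id not in ACYL_POSITIONS:
            raise KeyError(f"unknown lipid class {self.class_id!r}")
        neg = self.adduct.polarity is Polarity.NEGATIVE
        for name in ("dp", "ep", "ce", "cxp"):
            v = getattr(self, name)
            if neg and v > 0 or (not neg and v < 0):
                raise ValueError(
                    f"{self.class_id}: voltage {name.upper()}={v} has the wrong "
                    f"sign for {self.adduct.polarity.value} mode"
                )

    @property
    def polarity(self) -> Polarity:
        return self.adduct.polarity


def _frag(kind: FragmentKind, fixed: float | None = None) -> FragmentRule:
    return FragmentRule(kind, fixed)


_F = FragmentKind

# (adduct, fragment, DP, EP, CE, CXP, internal standard)
_RULE_TABLE: dict[str, tuple[str, FragmentRule, float, float, float, float, str]] = {
    "CAR": ("[M+H]+", _frag(_F.FIXED_MZ, 85.1), 93, 10, 31, 16, "24:0 (d4) Carnitine"),
    "CER": ("[M+H-18]+", _frag(_F.FIXED_MZ, 264.1), 130, 10, 55, 10, "C15 Ceramide-d7"),
    "DG": ("[M+Na]+", _frag(_F.NEUTRAL_LOSS_OF_CHAIN), 93, 9, 42, 25, "15:0-18:1(d7) DG-Na"),
    "DGDG": ("[M+Na]+", _frag(_F.NEUTRAL_LOSS_OF_FA_REARRANGEMENT), 80, 10, 65, 20, "Hydrog DGDG (18:0-18:0)"),
    "dhCER": ("[M+H-18]+", _frag(_F.FIXED_MZ, 266.1), 130, 10, 55, 10, "C15 Ceramide-d7"),
    "FA": ("[M-H]-", _frag(_F.INTACT_DEPROTONATED), -80, -10, -17, -20, "Stearic acid-d3"),
    "glc-dhCER": ("[M+H-18]+", _frag(_F.FIXED_MZ, 266.1), 130, 8, 45, 27, "C15 Ceramide-d7"),
    "glcCER": ("[M+H-18]+", _frag(_F.FIXED_MZ, 264.1), 130, 8, 45, 27, "C15 Ceramide-d7"),
    "lac-dhCER": ("[M+H-18]+", _frag(_F.FIXED_MZ, 266.1), 126, 10, 56, 15, "C15 Ceramide-d7"),
    "lacCER": ("[M+H-18]+", _frag(_F.FIXED_MZ, 264.1), 126, 10, 56, 15, "C15 Ceramide-d7"),
    "LPA": ("[M-H]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -80, -6, -45, -20, "17:0 Lyso PA"),
    "LPC": ("[M+H]+", _frag(_F.FIXED_MZ, 184.1), 90, 6, 35, 20, "18:1(d7) Lyso PC"),
    "LPE": ("[M-H]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -88, -12, -42, -20, "18:1(d7) Lyso PE"),
    "LPG": ("[M-H]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -75, -10, -38, -24, "17:1 Lyso PG"),
    "LPI": ("[M-H]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -90, -6, -40, -24, "17:1 Lyso PI"),
    "LPS": ("[M-H]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -72, -10, -53, -24, "17:1 Lyso PS"),
    "MG": ("[M+H]+", _frag(_F.LOSS_OF_GLYCEROL), 140, 10, 16, 10, "18:1(d7) MG"),
    "MGDG": ("[M+Na]+", _frag(_F.NEUTRAL_LOSS_OF_FA_REARRANGEMENT), 100, 10, 50, 30, "Hydrog MGDG (18:0-16:0)"),
    "PA": ("[M-H]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -80, -6, -45, -20, "15:0-18:1-D7-PA"),
    "PC": ("[M+HCOO]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -90, -10, -50, -20, "15:0-18:1(d7) PC"),
    "PE": ("[M-H]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -88, -12, -42, -20, "15:0-18:1(d7) PE"),
    "PG": ("[M-H]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -75, -10, -38, -24, "15:0-18:1(d7) PG"),
    "PI": ("[M-H]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -50, -10, -55, -10, "15:0-18:1(d7) PI"),
    "PS": ("[M-H]-", _frag(_F.SN_CHAIN_CARBOXYLATE), -72, -10, -53, -24, "15:0-18:1(d7) PS"),
    "SM": ("[M+H]+", _frag(_F.FIXED_MZ, 184.1), 124, 10, 32.5, 23, "d18:1-18:1(d9) SM"),
    "TG": ("[M+Na]+", _frag(_F.NEUTRAL_LOSS_OF_CHAIN), 90, 10, 40, 10, "15:0-18:1(d7)-15:0 TG-Na"),
}


def default_rules() -> dict[str, LipidClassRule]:
    """The shipped 26-class rule set."""
    rules = {}
    for cls, (adduct, fragment, dp, ep, ce, cxp, is_name) in _RULE_TABLE.items():
        rules[cls] = LipidClassRule(
            cls, ADDUCTS[adduct], fragment, dp, ep, ce, cxp, is_name
        )
    return rules


@dataclass(frozen=True)
class InternalStandard:
    """A labelled (or odd-chain) surrogate compound spiked per class.

    ``n_deuterium`` deuteriums sit on ``labelled_chain`` (0-based index
    into ``chains``) when that chain exists, otherwise on the backbone;
    the precursor m/z shifts by n_d x (D - H) either way, and fragments
    involving the labelled chain carry the shift with them.
    ``amount_ug`` is the amount spiked per sample under the default
    extraction protocol (15 uL of a 10 mg/mL mix = 150 ug).
    """

    name: str
    class_id: str
    chains: tuple[FattyAcylChain, ...]
    n_deuterium: int = 0
    labelled_chain: int | None = None
    covers: tuple[str, ...] = ()
    amount_ug: float = 150.0

    @property
    def species(self) -> LipidSpecies:
        return LipidSpecies(self.class_id, self.chains)


def _ch(*specs: str) -> tuple[FattyAcylChain, ...]:
    return tuple(FattyAcylChain.parse(s) for s in specs)


def default_internal_standards() -> list[InternalStandard]:
    """The 21 internal standards, keyed to the classes they quantify."""
    return [
        InternalStandard("24:0 (d4) Carnitine", "CAR", _ch("24:0"), 4, 0),
        InternalStandard(
            "C15 Ceramide-d7", "CER", _ch("15:0"), 7, None,
            covers=("CER", "dhCER", "glcCER", "glc-dhCER", "lacCER", "lac-dhCER"),
        ),
        InternalStandard("15:0-18:1(d7) DG-Na", "DG", _ch("15:0", "18:1"), 7, 1),
        InternalStandard("Hydrog DGDG (18:0-18:0)", "DGDG", _ch("18:0", "18:0")),
        InternalStandard("Stearic acid-d3", "FA", _ch("18:0"), 3, 0),
        InternalStandard("17:0 Lyso PA", "LPA", _ch("17:0")),
        InternalStandard("18:1(d7) Lyso PC", "LPC", _ch("18:1"), 7, 0),
        InternalStandard("18:1(d7) Lyso PE", "LPE", _ch("18:1"), 7, 0),
        InternalStandard("17:1 Lyso PG", "LPG", _ch("17:1")),
        InternalStandard("17:1 Lyso PI", "LPI", _ch("17:1")),
        InternalStandard("17:1 Lyso PS", "LPS", _ch("17:1")),
        InternalStandard("18:1(d7) MG", "MG", _ch("18:1"), 7, 0),
        InternalStandard("Hydrog MGDG (18:0-16:0)", "MGDG", _ch("18:0", "16:0")),
        InternalStandard("15:0-18:1-D7-PA", "PA", _ch("15:0", "18:1"), 7, 1),
        InternalStandard("15:0-18:1(d7) PC", "PC", _ch("15:0", "18:1"), 7, 1),
        InternalStandard("15:0-18:1(d7) PE", "PE", _ch("15:0", "18:1"), 7, 1),
        InternalStandard("15:0-18:1(d7) PG", "PG", _ch("15:0", "18:1"), 7, 1),
        InternalStandard("15:0-18:1(d7) PI", "PI", _ch("15:0", "18:1"), 7, 1),
        InternalStandard("15:0-18:1(d7) PS", "PS", _ch("15:0", "18:1"), 7, 1),
        InternalStandard("d18:1-18:1(d9) SM", "SM", _ch("18:1"), 9, 0),
        InternalStandard(
            "15:0-18:1(d7)-15:0 TG-Na", "TG", _ch("15:0", "18:1", "15:0"), 7, None
        ),
    ]


def is_class_map(
    standards: list[InternalStandard] | None = None,
) -> dict[str, InternalStandard]:
    """Map every lipid class to its assigned internal standard."""
    standards = standards if standards is not None else default_internal_standards()
    mapping: dict[str, InternalStandard] = {}
    for std in standards:
        for cls in std.covers or (std.class_id,):
            mapping[cls] = std
    return mapping


def default_is_map(
    standards: list[InternalStandard] | None = None,
) -> dict[str, tuple[str, float]]:
    """class -> (IS transition id, spiked amount in ug), for semi_quantify."""
    return {
        cls: (f"IS {std.name}", std.amount_ug)
        for cls, std in is_class_map(standards).items()
    }


def load_config(path: str) -> dict:
    """Read a YAML config: global/per-class chain spaces and option flags.

    Schema::

        chain_space: {carbon_min: 14, carbon_max: 22, carbon_step: 2,
                      db_min: 0, db_max: 6}
        class_spaces:
          CAR: {carbon_min: 2, carbon_max: 26, ...}
        dedup_decimals: 1

    Returns a dict with keys ``chain_space`` (ChainSpace),
    ``class_spaces`` (dict class -> ChainSpace) and any scalar options.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = dict(raw)
    out["chain_space"] = ChainSpace(**raw.get("chain_space", {}))
    out["class_spaces"] = {
        cls: ChainSpace(**kw) for cls, kw in (raw.get("class_spaces") or {}).items()
    }
    return out
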