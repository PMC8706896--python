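"""Assemble, deduplicate and export MRM transition lists.

A *transition* is a (Q1, Q2) precursor/product m/z pair with its
acquisition parameters.  For chain-dependent product ions (carboxylate or
neutral loss of an acyl chain) the sn position of a chain multiset is
unresolved; by default one transition per species monitors a designated
chain, or every distinct chain can be emitted as a candidate leaving
group (``leaving_policy="all"``).  The full default method splits into
independent positive- and negative-mode lists with the 21 internal
standards flagged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .chains import (
    CERAMIDE_FAMILY,
    ChainSpace,
    DEFAULT_SPACE,
    FattyAcylChain,
    enumerate_species,
)
from .masses import (
    ATOMIC_MASS,
    FragmentKind,
    PROTON_MASS,
    chain_composition,
    precursor_mz,
    product_mz,
    species_mass,
)
from .rules import (
    InternalStandard,
    LipidClassRule,
    default_internal_standards,
    default_rules,
)

__all__ = [
    "MRMTransition",
    "MRMMethod",
    "build_class_transitions",
    "build_internal_standard_transition",
    "dedup_transitions",
    "build_method",
    "export_transition_list",
    "read_transition_list",
]

_DEUTERIUM_SHIFT = ATOMIC_MASS["D"] - ATOMIC_MASS["H"]

_CHAIN_DEPENDENT = {
    FragmentKind.SN_CHAIN_CARBOXYLATE,
    FragmentKind.NEUTRAL_LOSS_OF_CHAIN,
    FragmentKind.NEUTRAL_LOSS_OF_FA_REARRANGEMENT,
}


@dataclass(frozen=True)
class MRMTransition:
    transition_id: str
    lipid_class: str
    q1: float
    q2: float
    polarity: str  # "positive" | "negative"
    dp: float
    ep: float
    ce: float
    cxp: float
    species_ids: tuple[str, ...]
    leaving_chain: str | None = None
    is_internal_standard: bool = False

    def __post_init__(self) -> None:
        if self.q1 <= 0 or self.q2 <= 0:
            raise ValueError(f"{self.transition_id}: non-positive Q1/Q2")


def build_class_transitions(
    rule: LipidClassRule,
    space: ChainSpace = DEFAULT_SPACE,
    *,
    leaving_policy: str = "designated",
    recompute_fixed: bool = False,
) -> list[MRMTransition]:
    """Build the transition list of one class over a chain space.

    For chain-dependent fragments the sn position of a chain multiset is
    unknown; ``leaving_policy`` decides how the leaving group is chosen:

    - ``"designated"`` (default): one transition per species, monitoring
      the highest-sorted chain (most carbons, then most double bonds) as
      the nominal sn2/sn3 chain — the one-MRM-per-compound convention a
      published method ships.
    - ``"all"``: one transition per (species, distinct chain), auditing
      every candidate leaving group; duplicates within a species (equal
      chains) are merged.
    """
    if leaving_policy not in ("designated", "all"):
        raise ValueError(f"unknown leaving_policy {leaving_policy!r}")
    out: list[MRMTransition] = []
    chain_dependent = rule.fragment.kind in _CHAIN_DEPENDENT
    for species in enumerate_species(rule.class_id, space):
        if chain_dependent:
            candidates = sorted(set(species.chains))
            if leaving_policy == "designated":
                candidates = candidates[-1:]
            leavers: Iterable[FattyAcylChain | None] = candidates
        else:
            leavers = [None]
        q1 = precursor_mz(species, rule.adduct)
        multi = len(species.chains) > 1
        for leaver in leavers:
            q2 = product_mz(
                species,
                rule.fragment,
                rule.adduct,
                leaver,
                recompute_fixed=recompute_fixed,
            )
            tid = species.name
            if chain_dependent and multi:
                tid = f"{species.name} [{leaver}]"
            out.append(
                MRMTransition(
                    transition_id=tid,
                    lipid_class=rule.class_id,
                    q1=q1,
                    q2=q2,
                    polarity=rule.polarity.value,
                    dp=rule.dp,
                    ep=rule.ep,
                    ce=rule.ce,
                    cxp=rule.cxp,
                    species_ids=(species.name,),
                    leaving_chain=str(leaver) if leaver is not None else None,
                )
            )
    return out


def build_internal_standard_transition(
    std: InternalStandard, rule: LipidClassRule
) -> MRMTransition:
    """Q1/Q2 of a labelled internal standard under its class rule.

    The deuterium label shifts the precursor by n_d x (D - H).  For
    carboxylate fragments the label rides on the monitored chain; for
    neutral-loss fragments an unlabelled chain leaves so the label stays
    on the product.  Printed fixed product constants are kept verbatim.
    """
    species = std.species
    shift = std.n_deuterium * _DEUTERIUM_SHIFT
    q1 = species_mass(species) + shift + rule.adduct.delta
    kind = rule.fragment.kind
    leaver: FattyAcylChain | None = None
    if kind is FragmentKind.SN_CHAIN_CARBOXYLATE:
        idx = std.labelled_chain if std.labelled_chain is not None else 0
        leaver = std.chains[idx]
        q2 = chain_composition(leaver).mass + (shift if std.n_deuterium else 0) - PROTON_MASS
    elif kind in (
        FragmentKind.NEUTRAL_LOSS_OF_CHAIN,
        FragmentKind.NEUTRAL_LOSS_OF_FA_REARRANGEMENT,
    ):
        unlabelled = [
            i for i in range(len(std.chains)) if i != std.labelled_chain
        ] or [0]
        leaver = std.chains[unlabelled[0]]
        q2 = q1 - chain_composition(leaver).mass
    elif kind is FragmentKind.LOSS_OF_GLYCEROL:
        q2 = product_mz(species, rule.fragment, rule.adduct) + shift
    elif kind is FragmentKind.INTACT_DEPROTONATED:
        q2 = q1
    else:  # fixed product constant, printed value
        q2 = rule.fragment.fixed_mz  # type: ignore[assignment]
    return MRMTransition(
        transition_id=f"IS {std.name}",
        lipid_class=rule.class_id,
        q1=q1,
        q2=float(q2),
        polarity=rule.polarity.value,
        dp=rule.dp,
        ep=rule.ep,
        ce=rule.ce,
        cxp=rule.cxp,
        species_ids=(f"IS {std.name}",),
        leaving_chain=str(leaver) if leaver is not None else None,
        is_internal_standard=True,
    )


def _sort_key(t: MRMTransition) -> tuple:
    return (t.polarity, t.q1, t.q2, t.transition_id)


def dedup_transitions(
    transitions: Sequence[MRMTransition], q_precision: int = 1
) -> list[MRMTransition]:
    """Merge transitions whose (Q1, Q2) collide after rounding.

    The merged record keeps the acquisition parameters of the first
    contributor (in sorted order) and carries all contributing species
    ids.  Idempotent at a fixed precision.
    """
    if q_precision < 0:
        raise ValueError("q_precision must be >= 0")
    groups: dict[tuple, list[MRMTransition]] = {}
    for t in sorted(transitions, key=_sort_key):
        key = (t.polarity, round(t.q1, q_precision), round(t.q2, q_precision))
        groups.setdefault(key, []).append(t)
    out = []
    for members in groups.values():
        head = members[0]
        ids = tuple(dict.fromkeys(sid for m in members for sid in m.species_ids))
        out.append(replace(head, species_ids=ids))
    out.sort(key=_sort_key)
    return out


@dataclass(frozen=True)
class MRMMethod:
    """Two polarity-split transition lists plus the flagged standards."""

    positive: tuple[MRMTransition, ...]
    negative: tuple[MRMTransition, ...]

    @property
    def transitions(self) -> tuple[MRMTransition, ...]:
        return self.positive + self.negative

    @property
    def internal_standards(self) -> tuple[MRMTransition, ...]:
        return tuple(t for t in self.transitions if t.is_internal_standard)

    def class_compound_counts(self) -> dict[str, int]:
        """Distinct analyte species per class ("compounds in method")."""
        counts: dict[str, set] = {}
        for t in self.transitions:
            if t.is_internal_standard:
                continue
            counts.setdefault(t.lipid_class, set()).update(t.species_ids)
        return {cls: len(ids) for cls, ids in sorted(counts.items())}

    def summary_rows(self) -> list[tuple[str, int]]:
        """Per-class compound counts with the ceramide family merged."""
        counts = self.class_compound_counts()
        merged: dict[str, int] = {}
        for cls, n in counts.items():
            row = "CER" if cls in CERAMIDE_FAMILY else cls
            merged[row] = merged.get(row, 0) + n
        return sorted(merged.items())


def build_method(
    rules: dict[str, LipidClassRule] | None = None,
    spaces: dict[str, ChainSpace] | None = None,
    standards: Sequence[InternalStandard] | None = None,
    *,
    default_space: ChainSpace = DEFAULT_SPACE,
    leaving_policy: str = "designated",
    recompute_fixed: bool = False,
) -> MRMMethod:
    """Build the full method: all classes, polarity split, IS flagged."""
    rules = rules if rules is not None else default_rules()
    spaces = spaces or {}
    standards = (
        standards if standards is not None else default_internal_standards()
    )
    pos: list[MRMTransition] = []
    neg: list[MRMTransition] = []
    for cls in sorted(rules):
        rule = rules[cls]
        space = spaces.get(cls, default_space)
        ts = build_class_transitions(
            rule, space, leaving_policy=leaving_policy,
            recompute_fixed=recompute_fixed,
        )
        (pos if rule.polarity.value == "positive" else neg).extend(ts)
    for std in standards:
        if std.class_id not in rules:
            raise KeyError(
                f"internal standard {std.name!r} references unknown class "
                f"{std.class_id!r}"
            )
        t = build_internal_standard_transition(std, rules[std.class_id])
        (pos if t.polarity == "positive" else neg).append(t)
    pos.sort(key=_sort_key)
    neg.sort(key=_sort_key)
    return MRMMethod(tuple(pos), tuple(neg))


_COLUMNS = [
    "transition_id",
    "lipid_class",
    "species_ids",
    "q1",
    "q2",
    "polarity",
    "dp",
    "ep",
    "ce",
    "cxp",
    "leaving_chain",
    "is_internal_standard",
]


def export_transition_list(
    transitions: Sequence[MRMTransition], path: str, dialect: str = "1dp"
) -> None:
    """Write a vendor-neutral delimited transition list.

    ``dialect`` controls Q1/Q2 rounding: ``"1dp"`` (one decimal, the
    instrument-facing convention) or ``"exact"`` (four decimals).
    Output is byte-stable for identical inputs.
    """
    if dialect not in ("1dp", "exact"):
        raise ValueError(f"unknown dialect {dialect!r}")
    decimals = 1 if dialect == "1dp" else 4
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for t in sorted(transitions, key=_sort_key):
            writer.writerow(
                [
                    t.transition_id,
                    t.lipid_class,
                    ";".join(t.species_ids),
                    f"{t.q1:.{decimals}f}",
                    f"{t.q2:.{decimals}f}",
                    t.polarity,
                    t.dp,
                    t.ep,
                    t.ce,
                    t.cxp,
                    t.leaving_chain or "",
                    int(t.is_internal_standard),
                ]
            )


def read_transition_list(path: str) -> list[MRMTransition]:
    """Re-import a transition list written by :func:`export_transition_list`."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(
                MRMTransition(
                    transition_id=row["transition_id"],
                    lipid_class=row["lipid_class"],
                    q1=float(row["q1"]),
                    q2=float(row["q2"]),
                    polarity=row["polarity"],
                    dp=float(row["dp"]),
                    ep=float(row["ep"]),
                    ce=float(row["ce"]),
                    cxp=float(row["cxp"]),
                    species_ids=tuple(row["species_ids"].split(";")),
                    leaving_chain=row["leaving_chain"] or None,
                    is_internal_standard=bool(int(row["is_internal_standard"])),
                )
            )
    return out
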