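"""Mass arithmetic against an independent whole-formula oracle (pyteomics)."""

import numpy as np
import pytest
from pyteomics.mass import calculate_mass

from lipidmrm.chains import FattyAcylChain, LipidSpecies, enumerate_chains
from lipidmrm.masses import (
    ADDUCTS,
    CH2_MASS,
    Composition,
    PHOSPHOCHOLINE_CATION,
    chain_composition,
    precursor_mz,
    product_mz,
    species_composition,
    species_mass,
)
from lipidmrm.rules import default_rules

# one species per class with its molecular formula written out by hand
# from the class structure (backbone + head + chains), summed by pyteomics
REFERENCE_PANEL = {
    ("CAR", ("16:0",)): "C23H45NO4",
    ("CER", ("16:0",)): "C34H67NO3",
    ("dhCER", ("16:0",)): "C34H69NO3",
    ("glcCER", ("16:0",)): "C40H77NO8",
    ("glc-dhCER", ("16:0",)): "C40H79NO8",
    ("lacCER", ("16:0",)): "C46H87NO13",
    ("lac-dhCER", ("16:0",)): "C46H89NO13",
    ("SM", ("16:0",)): "C39H79N2O6P",
    ("MG", ("16:0",)): "C19H38O4",
    ("DG", ("16:0", "18:1")): "C37H70O5",
    ("TG", ("16:0", "16:0", "16:0")): "C51H98O6",
    ("MGDG", ("16:0", "18:1")): "C43H80O10",
    ("DGDG", ("16:0", "18:1")): "C49H90O15",
    ("FA", ("16:0",)): "C16H32O2",
    ("PA", ("16:0", "18:1")): "C37H71O8P",
    ("PC", ("16:0", "18:1")): "C42H82NO8P",
    ("PE", ("16:0", "18:1")): "C39H76NO8P",
    ("PG", ("16:0", "18:1")): "C40H77O10P",
    ("PI", ("16:0", "18:1")): "C43H81O13P",
    ("PS", ("16:0", "18:1")): "C40H76NO10P",
    ("LPA", ("16:0",)): "C19H39O7P",
    ("LPC", ("16:0",)): "C24H50NO7P",
    ("LPE", ("18:1",)): "C23H46NO7P",
    ("LPG", ("17:1",)): "C23H45O9P",
    ("LPI", ("17:1",)): "C26H49O12P",
    ("LPS", ("17:1",)): "C23H44NO9P",
}


def _species(cls, chains):
    return LipidSpecies(cls, tuple(FattyAcylChain.parse(c) for c in chains))


class TestChainComposition:
    def test_palmitic_acid(self):
        comp = chain_composition(FattyAcylChain(16, 0))
        assert comp.formula() == "C16H32O2"
        assert comp.mass == pytest.approx(256.2402, abs=1e-4)

    def test_hydrogen_rule(self):
        assert chain_composition(FattyAcylChain(18, 1)).as_dict()["H"] == 34
        assert chain_composition(FattyAcylChain(14, 6)).as_dict()["H"] == 16


class TestSpeciesMass:
    @pytest.mark.parametrize("key, formula", sorted(REFERENCE_PANEL.items()))
    def test_scaffold_route_matches_whole_formula(self, key, formula):
        """Release gate: scaffold+chains-water vs independent formula sum."""
        cls, chains = key
        sp = _species(cls, chains)
        assert species_composition(sp).formula() == formula
        assert species_mass(sp) == pytest.approx(
            calculate_mass(formula=formula), abs=1e-3
        )

    def test_fa_species_is_just_its_chain(self):
        sp = _species("FA", ("16:0",))
        assert species_mass(sp) == chain_composition(FattyAcylChain(16, 0)).mass

    def test_two_chain_additivity_identity(self):
        """mass({a,b}) - mass({a,a}) = mass(b) - mass(a), random pairs."""
        rng = np.random.default_rng(7)
        chains = enumerate_chains()
        for _ in range(100):
            a, b = rng.choice(len(chains), 2)
            a, b = chains[a], chains[b]
            lhs = species_mass(LipidSpecies("PC", (a, b))) - species_mass(
                LipidSpecies("PC", (a, a))
            )
            rhs = chain_composition(b).mass - chain_composition(a).mass
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_homolog_shifts(self):
        """+2 C shifts every precursor by +28.0313; +1 DB by -2.0157."""
        for cls, chains in [("PE", ("16:0", "18:1")), ("TG", ("16:0", "18:1", "18:2"))]:
            adduct = default_rules()[cls].adduct
            sp = _species(cls, chains)
            up_c = LipidSpecies(
                cls, (FattyAcylChain(sp.chains[0].carbons + 2, sp.chains[0].double_bonds),)
                + sp.chains[1:],
            )
            up_d = LipidSpecies(
                cls, (FattyAcylChain(sp.chains[0].carbons, sp.chains[0].double_bonds + 1),)
                + sp.chains[1:],
            )
            base = precursor_mz(sp, adduct)
            assert precursor_mz(up_c, adduct) - base == pytest.approx(
                2 * CH2_MASS, abs=1e-4
            )
            assert precursor_mz(up_d, adduct) - base == pytest.approx(
                -2.01565, abs=1e-4
            )


class TestPrecursors:
    def test_deprotonated_palmitate(self):
        assert precursor_mz(_species("FA", ("16:0",)), "[M-H]-") == pytest.approx(
            255.2330, abs=1e-4
        )

    def test_sodiation_vs_protonation_constant_offset(self):
        sp = _species("DG", ("16:0", "18:1"))
        delta = precursor_mz(sp, "[M+Na]+") - precursor_mz(sp, "[M+H]+")
        assert delta == pytest.approx(21.98194, abs=1e-4)

    def test_electron_mass_bookkeeping(self):
        """[M+H]+ and [M-H]- bracket 2M exactly (proton symmetry)."""
        for key in REFERENCE_PANEL:
            sp = _species(*key)
            total = precursor_mz(sp, "[M+H]+") + precursor_mz(sp, "[M-H]-")
            assert abs(total - 2 * species_mass(sp)) < 1.2e-3

    def test_water_loss_adduct(self):
        sp = _species("CER", ("16:0",))
        assert precursor_mz(sp, "[M+H-18]+") == pytest.approx(
            species_mass(sp) + 1.00728 - 18.01056, abs=1e-4
        )


class TestProducts:
    def test_phosphocholine_head_rounds_to_printed_constant(self):
        assert PHOSPHOCHOLINE_CATION.mass == pytest.approx(184.0733, abs=1e-4)
        assert round(PHOSPHOCHOLINE_CATION.mass, 1) == 184.1

    def test_lpc_product_is_printed_head_constant(self):
        rule = default_rules()["LPC"]
        sp = _species("LPC", ("16:0",))
        assert product_mz(sp, rule.fragment, rule.adduct) == 184.1
        assert product_mz(
            sp, rule.fragment, rule.adduct, recompute_fixed=True
        ) == pytest.approx(184.0733, abs=1e-4)

    def test_fa_product_equals_precursor(self):
        rule = default_rules()["FA"]
        sp = _species("FA", ("16:0",))
        assert product_mz(sp, rule.fragment, rule.adduct) == precursor_mz(
            sp, rule.adduct
        )

    def test_carboxylate_fragment(self):
        rule = default_rules()["PE"]
        sp = _species("PE", ("16:0", "18:1"))
        q2 = product_mz(sp, rule.fragment, rule.adduct, FattyAcylChain(18, 1))
        assert q2 == pytest.approx(281.2486, abs=1e-3)  # oleate anion

    def test_mg_glycerol_loss_gives_acylium(self):
        rule = default_rules()["MG"]
        sp = _species("MG", ("16:0",))
        q2 = product_mz(sp, rule.fragment, rule.adduct)
        assert q2 == pytest.approx(239.2369, abs=1e-3)  # palmitoyl acylium
        radical = product_mz(
            sp, rule.fragment, rule.adduct, glycerol_loss_as_radical=True
        )
        assert radical == pytest.approx(239.2375, abs=1e-3)

    def test_neutral_loss_requires_member_chain(self):
        rule = default_rules()["DG"]
        sp = _species("DG", ("16:0", "18:1"))
        with pytest.raises(ValueError, match="not part of"):
            product_mz(sp, rule.fragment, rule.adduct, FattyAcylChain(20, 4))
        with pytest.raises(ValueError, match="leaving chain"):
            product_mz(sp, rule.fragment, rule.adduct)


class TestComposition:
    def test_formula_roundtrip(self):
        comp = Composition.from_formula("C42H82NO8P")
        assert comp.formula() == "C42H82NO8P"
        assert comp.mass == pytest.approx(calculate_mass(formula="C42H82NO8P"), abs=1e-6)

    def test_subtraction_never_goes_negative(self):
        with pytest.raises(ValueError, match="negative"):
            Composition.from_formula("CH4") - Composition.from_formula("C2")
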