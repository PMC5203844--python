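"""Mass model: residues, glycoforms, assembled species, m/z arithmetic."""

import pytest
from hypothesis import given, settings, strategies as st

from murosearch import chem

GM = "GlcN-MurNAc"


class TestResidues:
    def test_mdap_equals_met_plus_offset(self):
        # the mDAP residue mass must reproduce 131.0405 + 41.0443
        assert chem.residue_mass("m") == pytest.approx(131.0405 + 41.0443, abs=1e-4)

    @pytest.mark.parametrize(
        "code, expected",
        [("A", 71.0371), ("G", 57.0215), ("E", 129.0426), ("I", 113.0841)],
    )
    def test_standard_residues(self, code, expected):
        assert chem.residue_mass(code) == pytest.approx(expected, abs=1e-4)

    def test_unknown_code_names_the_letter(self):
        with pytest.raises(KeyError, match="'B'"):
            chem.residue_mass("B")

    def test_all_residue_masses_match_formula_sum(self):
        for code, spec in chem.RESIDUES.items():
            from pyteomics.mass import calculate_mass

            assert spec.monoisotopic_mass == pytest.approx(
                calculate_mass(composition=spec.composition), abs=1e-9
            ), code


class TestGlycoforms:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("MurNAc", 277.116),
            ("GlcN-MurN", 396.174),
            ("GlcN-anhMurNAc", 420.174),
            ("GlcN-MurNAc", 438.185),
            ("GlcNAc-MurNAc", 480.196),
        ],
    )
    def test_five_glycoform_masses(self, name, expected):
        assert chem.glycan_mass(chem.glycoform(name)) == pytest.approx(
            expected, abs=1e-3
        )

    def test_empty_glycoform_is_massless(self):
        assert chem.glycan_mass(chem.glycoform("none")) == 0.0
        assert chem.glycan_mass(chem.glycoform(None)) == 0.0

    def test_reduction_adds_h2(self):
        red = chem.Glycoform(("GlcN", "MurNAc"), reduced=True)
        unred = chem.Glycoform(("GlcN", "MurNAc"), reduced=False)
        assert red.modification_mass - unred.modification_mass == pytest.approx(
            2 * chem.H_ATOM, abs=1e-9
        )

    def test_anhydro_excludes_reduction(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            chem.Glycoform(("GlcN", "anhydro-MurNAc"), reduced=True)

    def test_unsupported_monosaccharide_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            chem.Glycoform(("Xylose",))


class TestStemModifications:
    def test_amidation_delta(self):
        assert chem.AMIDATION_DELTA == pytest.approx(-0.984, abs=1e-3)

    def test_amidation_only_on_e_or_mdap(self):
        chem.Muropeptide(chem.glycoform(GM), "AEm", (chem.amidation(2),))
        chem.Muropeptide(chem.glycoform(GM), "AEm", (chem.amidation(3),))
        with pytest.raises(ValueError, match="only on E or mDAP"):
            chem.Muropeptide(chem.glycoform(GM), "AEm", (chem.amidation(1),))

    def test_wildcard_range_enforced(self):
        chem.wildcard(-130.0, 4)
        chem.wildcard(210.0, 4)
        with pytest.raises(ValueError, match="wildcard"):
            chem.wildcard(211.0, 4)


# Table rows recomputed from composition (printed values frozen as expected):
TRIMER_ROWS = [
    (["AEm", "AEm", "AEmA"], [GM, GM, GM], 2520.096),
    (["AEm", "AEmA", "AEmA"], [GM, GM, GM], 2591.133),
    (["AEm", "AEm", "AEm"], [GM, GM, GM], 2449.059),
    (["AEmA", "AEmA", "AEmA"], [GM, GM, GM], 2662.170),
    (["AEm", "AEm", "AEmG"], [GM, GM, GM], 2506.080),
    (["AEm", "AEm", "AEmA"], [GM, "MurNAc", GM], 2359.027),
    (["AEm", "AEm", "AEmA"], [GM, GM, "none"], 2081.911),
    (["AEm", "AEm", "AEmA"], [GM, "none", "none"], 1643.726),
    (["AEm", "AEmA", "AEmG"], [GM, GM, GM], 2577.117),
]


class TestSpecies:
    @pytest.mark.parametrize("stems, glycos, expected", TRIMER_ROWS)
    def test_trimer_neutral_masses(self, stems, glycos, expected):
        species = chem.chain_species(stems, glycos)
        assert chem.species_neutral_mass(species) == pytest.approx(
            expected, abs=2e-3
        )

    def test_dimer_mass_additivity(self):
        d = chem.chain_species(["AEm", "AEmA"], [GM, GM])
        assert d.neutral_mass == pytest.approx(1709.747, abs=2e-3)
        # sum of unit masses minus one condensation water
        assert d.neutral_mass == pytest.approx(
            chem.monomer("AEm").neutral_mass
            + chem.monomer("AEmA").neutral_mass
            - chem.WATER,
            abs=1e-9,
        )

    def test_monomer_is_identity(self):
        m = chem.monomer("AEmA")
        assert m.neutral_mass == m.units[0].neutral_mass

    def test_formula_and_modification_mass_paths_agree(self):
        from pyteomics.mass import calculate_mass

        for stems, glycos, _ in TRIMER_ROWS:
            species = chem.chain_species(stems, glycos)
            formula_route = calculate_mass(composition=species.composition)
            assert species.neutral_mass == pytest.approx(formula_route, abs=2e-3)
            # as-configured (rounded search-engine masses) stays within 2e-3 too
            configured = chem.chain_species(stems, glycos, as_configured=True)
            assert configured.neutral_mass == pytest.approx(formula_route, abs=2e-3)

    def test_exactly_isobaric_dimer_pair(self):
        four_three = chem.chain_species(["AEmA", "AEmA"], [GM, GM])
        three_three = chem.chain_species(["AEm", "AEmAA"], [GM, GM])
        assert four_three.composition == three_three.composition
        assert four_three.neutral_mass == pytest.approx(
            three_three.neutral_mass, abs=1e-12
        )

    def test_link_topology_validation(self):
        # a 3-3 donor must be a tripeptide; a 4-3 donor needs position 4
        with pytest.raises(ValueError, match="3-3 donor"):
            chem.CrosslinkedSpecies(
                (
                    chem.Muropeptide(chem.glycoform(GM), "AEmA"),
                    chem.Muropeptide(chem.glycoform(GM), "AEmA"),
                ),
                (chem.CrossLink(0, 3, 1),),
            )
        with pytest.raises(ValueError, match="4-3 donor"):
            chem.CrosslinkedSpecies(
                (
                    chem.Muropeptide(chem.glycoform(GM), "AEm"),
                    chem.Muropeptide(chem.glycoform(GM), "AEmA"),
                ),
                (chem.CrossLink(0, 4, 1),),
            )
        with pytest.raises(ValueError, match="units need"):
            chem.CrosslinkedSpecies(
                (chem.Muropeptide(chem.glycoform(GM), "AEm"),),
                (chem.CrossLink(0, 3, 0),),
            )


class TestMzArithmetic:
    def test_singly_charged_is_mass_plus_proton(self):
        assert chem.mz_from_neutral(1000.0, 1) == pytest.approx(
            1000.0 + 1.00728, abs=1e-5
        )

    def test_trimer_at_three_plus(self):
        assert chem.mz_from_neutral(2520.096, 3) == pytest.approx(841.039, abs=1e-3)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            chem.mz_from_neutral(1000.0, 0)

    @settings(deadline=None, max_examples=50)
    @given(
        m1=st.floats(min_value=100.0, max_value=5000.0),
        m2=st.floats(min_value=100.0, max_value=5000.0),
    )
    def test_ppm_diff_symmetric_nonnegative(self, m1, m2):
        assert chem.ppm_diff(m1, m2) == chem.ppm_diff(m2, m1)
        assert chem.ppm_diff(m1, m2) >= 0
        assert chem.ppm_diff(m1, m1) == 0

    @settings(deadline=None, max_examples=50)
    @given(
        m=st.floats(min_value=100.0, max_value=5000.0),
        z=st.integers(min_value=1, max_value=4),
    )
    def test_mz_round_trip(self, m, z):
        assert chem.neutral_from_mz(chem.mz_from_neutral(m, z), z) == pytest.approx(
            m, abs=1e-9
        )

    def test_constants(self):
        assert chem.CONSTANTS.water_mass == pytest.approx(18.0106, abs=5e-4)
        assert chem.CONSTANTS.proton_mass == pytest.approx(1.00728, abs=1e-5)
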