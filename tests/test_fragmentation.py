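"""Fragment prediction: ion arithmetic, complementarity, topology awareness."""

import pytest

from murosearch import chem, fragmentation as fr

GM = "GlcN-MurNAc"


def _series(frags, *names, charge=None):
    out = [f for f in frags if f.series in names]
    if charge is not None:
        out = [f for f in out if f.charge == charge]
    return out


class TestLinearPrediction:
    def test_hcd_b2_of_bare_stem(self):
        unit = chem.Muropeptide(chem.glycoform("none"), "AEm")
        frags = fr.predict_linear_fragments(unit, "HCD", (1,))
        b2 = [f for f in frags if f.series == "b" and f.cleavage_site == "u1:2"]
        assert b2[0].mz == pytest.approx(201.087, abs=1e-3)

    def test_glycan_retained_on_n_terminal_fragments(self):
        unit = chem.Muropeptide(chem.glycoform(GM), "AEmA")
        frags = fr.predict_linear_fragments(unit, "HCD", (1,))
        b1 = [f for f in frags if f.series == "b" and f.cleavage_site == "u1:1"][0]
        assert b1.neutral_mass == pytest.approx(
            chem.glycan_mass(chem.glycoform(GM)) + chem.residue_mass("A"), abs=1e-9
        )

    def test_etd_emits_both_z_variants(self):
        unit = chem.Muropeptide(chem.glycoform(GM), "AEmA")
        frags = fr.predict_linear_fragments(unit, "ETD", (1,))
        z = _series(frags, "z", charge=1)
        zh = _series(frags, "z+H", charge=1)
        assert len(z) == len(zh) == 3
        for a, b in zip(
            sorted(z, key=lambda f: f.cleavage_site),
            sorted(zh, key=lambda f: f.cleavage_site),
        ):
            assert b.mz - a.mz == pytest.approx(chem.H_ATOM, abs=1e-9)

    def test_glycosidic_cleavages_present(self):
        unit = chem.Muropeptide(chem.glycoform(GM), "AEm")
        for activation in ("HCD", "ETD"):
            frags = fr.predict_linear_fragments(unit, activation, (1,))
            sites = {f.cleavage_site for f in _series(frags, "Y")}
            assert {
                "u1:glycan:GlcN|MurNAc",
                "u1:glycan:MurNAc|lactyl",
                "u1:glycan:lactyl|Ala1",
            } <= sites
        # losing the full glycan leaves the bare peptide + water
        bare = [f for f in frags if f.cleavage_site == "u1:glycan:lactyl|Ala1"
                and f.series == "Y" and f.charge == 1][0]
        assert bare.neutral_mass == pytest.approx(
            sum(chem.residue_mass(c) for c in "AEm") + chem.WATER, abs=1e-9
        )

    @pytest.mark.parametrize(
        "stem, glyco",
        [("AEm", GM), ("AEmA", GM), ("AEmG", "GlcNAc-MurNAc"), ("AEmAA", "none")],
    )
    @pytest.mark.parametrize("activation", ["HCD", "ETD"])
    def test_complementarity_identities(self, stem, glyco, activation):
        """b+y = M + 2 protons; c+z = M + H + 2 protons, for every bond."""
        unit = chem.Muropeptide(chem.glycoform(glyco), stem)
        M = chem.monomer(stem, glyco).neutral_mass
        frags = fr.predict_linear_fragments(unit, activation, (1,))
        sites = {f.cleavage_site for f in frags if f.series in ("b", "c")}
        for site in sites:
            if activation == "HCD":
                b = [f for f in frags if f.series == "b" and f.cleavage_site == site][0]
                y = [f for f in frags if f.series == "y" and f.cleavage_site == site][0]
                assert b.mz + y.mz == pytest.approx(M + 2 * chem.PROTON, abs=1e-3)
            else:
                c = [f for f in frags if f.series == "c" and f.cleavage_site == site][0]
                z = [f for f in frags if f.series == "z" and f.cleavage_site == site][0]
                assert c.mz + z.mz == pytest.approx(
                    M + chem.H_ATOM + 2 * chem.PROTON, abs=1e-3
                )

    def test_internal_fragments_capped(self):
        unit = chem.Muropeptide(chem.glycoform("none"), "AEmAAAG")
        frags = fr.predict_linear_fragments(unit, "HCD", (1,))
        internals = _series(frags, "internal")
        assert internals  # present
        for f in internals:
            start, end = f.cleavage_site.split(":")[1].split("-")
            assert int(end) - int(start) + 1 <= fr.MAX_INTERNAL_LENGTH

    def test_activation_validated(self):
        unit = chem.Muropeptide(chem.glycoform(GM), "AEm")
        with pytest.raises(ValueError, match="activation"):
            fr.predict_linear_fragments(unit, "CID", (1,))


class TestCrosslinkedPrediction:
    def test_fig5_donor_splitting_c_ion(self, fig5_pair):
        """Cleaving the 3-3 cross-link yields the c-ion covering the intact
        disaccharide-tripeptide donor at 828.38 and the complementary z at
        884.39 (the values annotated on the published ETD spectrum)."""
        sp33, _ = fig5_pair
        split = fr.crosslink_splitting_ions(sp33, "ETD", (1,))
        c = [f for f in split if f.series == "c"][0]
        z = [f for f in split if f.series == "z"][0]
        assert round(c.mz, 2) == 828.38
        assert round(z.mz, 2) == 884.39

    def test_fig4_splitting_pair(self, fig4_pair):
        """For the 4-3 dimer of two disaccharide-tetrapeptides the splitting
        c/z ions land near the strong observed peaks 899.45 / 884.42."""
        sp43, _ = fig4_pair
        split = fr.crosslink_splitting_ions(sp43, "ETD", (1,))
        c = [f for f in split if f.series == "c"][0]
        z = [f for f in split if f.series == "z"][0]
        assert c.mz == pytest.approx(899.420, abs=1e-3)
        assert z.mz == pytest.approx(884.386, abs=1e-3)
        assert abs(c.mz - 899.45) < 0.5 and abs(z.mz - 884.42) < 0.5

    def test_monomer_degenerates_to_linear(self):
        m = chem.monomer("AEmA")
        a = fr.predict_crosslinked_fragments(m, "ETD", (1, 2))
        b = fr.predict_linear_fragments(m.units[0], "ETD", (1, 2))
        assert sorted(round(f.mz, 6) for f in a) == sorted(round(f.mz, 6) for f in b)

    def test_fragment_masses_invariant_under_donor_relabeling(self):
        units = (
            chem.Muropeptide(chem.glycoform(GM), "AEm"),
            chem.Muropeptide(chem.glycoform(GM), "AEm"),
            chem.Muropeptide(chem.glycoform(GM), "AEmA"),
        )
        a = chem.CrosslinkedSpecies(
            units, (chem.CrossLink(0, 3, 1), chem.CrossLink(1, 3, 2))
        )
        # relabel the two identical donor units (and permute the link list)
        b = chem.CrosslinkedSpecies(
            units, (chem.CrossLink(1, 3, 2), chem.CrossLink(0, 3, 1))
        )
        fa = sorted(round(f.mz, 5) for f in fr.predict_crosslinked_fragments(a, "ETD"))
        fb = sorted(round(f.mz, 5) for f in fr.predict_crosslinked_fragments(b, "ETD"))
        assert fa == fb

    def test_disconnected_graph_rejected(self):
        with pytest.raises(ValueError, match="connect"):
            chem.CrosslinkedSpecies(
                (
                    chem.Muropeptide(chem.glycoform(GM), "AEm"),
                    chem.Muropeptide(chem.glycoform(GM), "AEmA"),
                    chem.Muropeptide(chem.glycoform(GM), "AEmA"),
                ),
                (chem.CrossLink(0, 3, 1), chem.CrossLink(0, 3, 1)),
            )

    def test_b_y_complementarity_holds_for_dimers(self, fig4_pair):
        sp43, _ = fig4_pair
        M = sp43.neutral_mass
        frags = fr.predict_crosslinked_fragments(sp43, "HCD", (1,))
        bs = {f.cleavage_site: f for f in frags if f.series == "b" and f.charge == 1}
        ys = {f.cleavage_site: f for f in frags if f.series == "y" and f.charge == 1}
        assert set(bs) == set(ys)
        for site in bs:
            assert bs[site].mz + ys[site].mz == pytest.approx(
                M + 2 * chem.PROTON, abs=1e-3
            )


class TestDiagnostics:
    def test_two_mdap_internal_is_three_three_only(self, fig4_pair):
        sp43, sp33 = fig4_pair
        diag = fr.diagnostic_internal_fragments(sp33, sp43)
        two_mdap = 2 * chem.residue_mass("m")
        hits = [f for f in diag if abs(f.neutral_mass - two_mdap) < 1e-6]
        assert hits and all(f.diagnostic_for == "3-3" for f in hits)
        assert two_mdap == pytest.approx(344.170, abs=1e-3)

    def test_ala_two_mdap_excluded_as_ambiguous(self, fig4_pair):
        sp43, sp33 = fig4_pair
        diag = fr.diagnostic_internal_fragments(sp33, sp43)
        shared = chem.residue_mass("A") + 2 * chem.residue_mass("m")
        assert all(abs(f.neutral_mass - shared) > 1e-3 for f in diag)

    def test_non_isobaric_pair_rejected(self, fig5_pair):
        sp33, _ = fig5_pair
        other = chem.chain_species(["AEm", "AEm"], [GM, GM])
        with pytest.raises(ValueError, match="isobaric"):
            fr.diagnostic_internal_fragments(sp33, other)

    def test_flagged_fragments_differ_beyond_tolerance(self, fig4_pair):
        sp43, sp33 = fig4_pair
        tol = 0.5
        f43 = fr.predict_crosslinked_fragments(sp43, "ETD", (1,))
        f33 = fr.predict_crosslinked_fragments(sp33, "ETD", (1,))
        flagged43, flagged33 = fr.flag_topology_diagnostics(
            f43, "4-3", f33, "3-3", tol
        )
        diag43 = [f for f in flagged43 if f.diagnostic_for == "4-3"]
        assert diag43
        for f in diag43:
            assert all(abs(f.mz - g.mz) > tol for g in f33)

    def test_fragment_table_export(self, fig5_pair):
        frame = fr.fragments_to_frame(
            fr.predict_crosslinked_fragments(fig5_pair[0], "ETD", (1,))
        )
        assert {"series", "mz", "cleavage_site", "diagnostic_for"} <= set(
            frame.columns
        )
        assert (frame["mz"] > 0).all()
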