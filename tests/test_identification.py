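"""Precursor/fragment matching, scoring, ranking and isobaric grouping."""

import numpy as np
import pytest

from murosearch import chem, fragmentation as fr, identification as idn
from murosearch import search_space as ss
from murosearch.identification import SpectrumRecord

from conftest import simulated_ms2

GM = "GlcN-MurNAc"


def _spectrum(mzs, intensities=None, activation="ETD", charge=2, precursor=1000.0):
    mzs = np.asarray(mzs, dtype=float)
    if intensities is None:
        intensities = np.full(mzs.size, 100.0)
    return SpectrumRecord(
        "t", 5.0, 2, mzs, np.asarray(intensities, float),
        precursor_mz=precursor, precursor_charge=charge, activation=activation,
    )


class TestSpectrumRecord:
    def test_peaks_sorted_on_construction(self):
        s = _spectrum([300.0, 100.0, 200.0], [3, 1, 2])
        assert list(s.mz) == [100.0, 200.0, 300.0]
        assert list(s.intensity) == [1.0, 2.0, 3.0]

    def test_ms2_requires_precursor(self):
        with pytest.raises(ValueError, match="precursor"):
            SpectrumRecord("x", 1.0, 2, np.array([100.0]), np.array([1.0]))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _spectrum([100.0], [-1.0])


class TestPrecursorMatching:
    def test_identity_match_near_zero_ppm(self):
        db = ss.build_monomer_db(ss.SearchConfig())
        target = chem.monomer("AEmA")
        mz = chem.mz_from_neutral(target.neutral_mass, 2)
        hits = idn.match_precursor(mz, 2, db, tol_ppm=5)
        assert hits
        idx, ppm = hits[0]
        assert db.entries[idx].label() == target.label()
        assert abs(ppm) < 1e-6

    def test_38ppm_pair_resolved_at_5ppm(self):
        """GlcNAc-MurNAc-AEmA vs GlcN-MurNAc-AEm(I/L): ~38 ppm apart, far
        beyond the 5 ppm precursor window, so only the true one returns."""
        a = chem.monomer("AEmA", "GlcNAc-MurNAc")
        b = chem.monomer("AEmI", GM)
        db = ss.CandidateDB([a, b])
        mz = chem.mz_from_neutral(a.neutral_mass, 1)
        hits = idn.match_precursor(mz, 1, db, tol_ppm=5)
        assert [db.entries[i].label() for i, _ in hits] == [a.label()]
        assert chem.ppm_diff(a.neutral_mass, b.neutral_mass) > 5 * 7

    def test_exactly_isobaric_pair_both_returned(self, fig4_pair):
        sp43, sp33 = fig4_pair
        db = ss.CandidateDB([sp43, sp33])
        mz = chem.mz_from_neutral(sp43.neutral_mass, 2)
        hits = idn.match_precursor(mz, 2, db, tol_ppm=5)
        assert len(hits) == 2
        assert hits[0][1] == pytest.approx(hits[1][1], abs=1e-9)

    def test_widening_tolerance_never_drops_candidates(self):
        db = ss.build_monomer_db(ss.SearchConfig(amidation=True))
        mz = chem.mz_from_neutral(chem.monomer("AEm").neutral_mass, 2) + 0.001
        narrow = {i for i, _ in idn.match_precursor(mz, 2, db, tol_ppm=3)}
        wide = {i for i, _ in idn.match_precursor(mz, 2, db, tol_ppm=30)}
        assert narrow <= wide


class TestFragmentMatching:
    def test_etd_tolerance_accepts_04da_hcd_does_not(self):
        frag = fr.TheoreticalFragment("c", "u1:1", 1, 800.0, 799.0, frozenset({0}))
        etd = _spectrum([800.4])
        hcd = _spectrum([800.4], activation="HCD")
        assert idn.match_fragments(etd, [frag])  # 0.4 Da within 0.5 Da
        assert not idn.match_fragments(hcd, [frag])  # 20 ppm of 800 = 0.016 Da

    def test_empty_spectrum_empty_matches(self):
        frag = fr.TheoreticalFragment("c", "u1:1", 1, 800.0, 799.0, frozenset({0}))
        empty = _spectrum([])
        assert idn.match_fragments(empty, [frag]) == []

    def test_each_peak_used_once(self):
        frags = [
            fr.TheoreticalFragment("c", f"u1:{i}", 1, 500.0, 499.0, frozenset({0}))
            for i in (1, 2)
        ]
        s = _spectrum([500.0])
        matches = idn.match_fragments(s, frags)
        assert len(matches) == 1


class TestScoring:
    def test_own_noise_free_spectrum_scores_two(self, fig5_pair):
        sp33, _ = fig5_pair
        spec = simulated_ms2(sp33, "ETD", charge=2)
        score, _ = idn.score_identification(spec, sp33)
        assert score == pytest.approx(2.0, abs=1e-9)

    def test_unrelated_candidate_scores_zero(self):
        spec = _spectrum([111.111, 222.222, 333.333], activation="HCD")
        score, _ = idn.score_identification(spec, chem.monomer("AEmG"))
        assert score == 0.0

    def test_half_coverage_eighty_percent_intensity(self):
        """Half the predicted primary fragments present, carrying 80% of the
        observed intensity, scores 0.5 + 0.8 = 1.3."""
        cand = chem.monomer("AEmA", "none")
        spec_template = simulated_ms2(cand, "HCD", charge=2)
        frags = idn.predict_for_spectrum(cand, spec_template)
        primary = [f for f in frags if f.series in ("b", "y")]
        half = primary[: len(primary) // 2]
        # spectrum: half the primary ions plus one unexplained peak at 20%
        mzs = [f.mz for f in half]
        matched_total = 80.0
        per_peak = matched_total / len(half)
        spec = _spectrum(
            mzs + [1234.5678],
            [per_peak] * len(half) + [20.0],
            activation="HCD",
            charge=2,
        )
        score, _ = idn.score_identification(spec, cand)
        assert score == pytest.approx(1.3, abs=1e-9)

    def test_score_monotone_in_matched_set(self, fig5_pair):
        sp33, _ = fig5_pair
        full = simulated_ms2(sp33, "ETD", charge=2)
        # drop half the peaks: the score can only decrease
        keep = slice(0, full.n_peaks // 2)
        partial = SpectrumRecord(
            "p", 5.0, 2, full.mz[keep], full.intensity[keep],
            precursor_mz=full.precursor_mz, precursor_charge=2, activation="ETD",
        )
        s_full, _ = idn.score_identification(full, sp33)
        s_partial, _ = idn.score_identification(partial, sp33)
        assert s_full >= s_partial

    def test_rank_prefers_generating_candidate(self, fig5_pair):
        sp33, sp43 = fig5_pair
        db = ss.CandidateDB([sp43, sp33])
        spec = simulated_ms2(sp33, "ETD", charge=2)
        hits = idn.match_precursor(spec.precursor_mz, 2, db, 5)
        ranked = idn.score_and_rank(spec, hits, db)
        assert ranked[0].candidate.label() == sp33.label()
        assert ranked[0].score > ranked[1].score


class TestIsobaricGroups:
    def test_isobaric_dimer_pair_one_group(self, fig4_pair):
        db = ss.CandidateDB(list(fig4_pair))
        groups = idn.isobaric_groups(db, tol_ppm=5)
        assert [len(g) for g in groups] == [2]
        assert idn.group_annotation(db, groups[0]).startswith("[")

    def test_38ppm_pair_separate_groups(self):
        db = ss.CandidateDB(
            [chem.monomer("AEmA", "GlcNAc-MurNAc"), chem.monomer("AEmI", GM)]
        )
        groups = idn.isobaric_groups(db, tol_ppm=5)
        assert sorted(len(g) for g in groups) == [1, 1]

    def test_singleton_db(self):
        db = ss.CandidateDB([chem.monomer("AEm")])
        assert idn.isobaric_groups(db) == [[0]]


class TestRecovery:
    def test_noise_free_recovery_rate(self, headline_truth, headline_report):
        """On a noise-free synthetic run, the top-ranked identification must
        recover the generating composition for >= 99% of MS2 spectra."""
        truth_by_mass = {
            e.species.neutral_mass: e.species.label()
            for e in headline_truth.entries
        }
        idents = headline_report.identifications
        ok = sum(
            1
            for ident in idents
            if ident.candidate.label()
            == truth_by_mass[
                min(
                    truth_by_mass,
                    key=lambda m: abs(
                        chem.neutral_from_mz(
                            ident.spectrum.precursor_mz,
                            ident.spectrum.precursor_charge,
                        )
                        - m
                    ),
                )
            ]
        )
        assert ok / len(idents) >= 0.99

    def test_noisy_recovery_rate(self, headline_truth, noisy_report):
        """With 20% spurious peaks and 10% dropout, recovery stays >= 95%."""
        truth_by_mass = {
            e.species.neutral_mass: e.species.label()
            for e in headline_truth.entries
        }
        idents = noisy_report.identifications
        ok = sum(
            1
            for ident in idents
            if ident.candidate.label()
            == truth_by_mass[
                min(
                    truth_by_mass,
                    key=lambda m: abs(
                        chem.neutral_from_mz(
                            ident.spectrum.precursor_mz,
                            ident.spectrum.precursor_charge,
                        )
                        - m
                    ),
                )
            ]
        )
        assert ok / len(idents) >= 0.95
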