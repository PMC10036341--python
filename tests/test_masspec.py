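"""Monoisotopic masses, modification variants, and MS matching."""

import random

import pytest
from pyteomics import mass as pt_mass

from npforge.annotate import MaturePeptide
from npforge.masspec import (DEFAULT_MODSET, RESIDUE_MASSES, MatchResult,
                             ModificationState, ObservedPeptide,
                             coverage_summary, enumerate_variants,
                             match_observed, monoisotopic_mass)

AMINO = "ACDEFGHIKLMNPQRSTVWY"


def _pep(seq, amidated=False, pid="p1", start=1, copy_index=1):
    return MaturePeptide(pid, start, start + len(seq) - 1, seq, amidated,
                         copy_index=copy_index)


class TestMass:
    def test_glycine_constant(self):
        assert monoisotopic_mass("G") == pytest.approx(75.032029, abs=1e-5)

    def test_amidation_delta(self):
        rng = random.Random(2)
        for _ in range(30):
            seq = "".join(rng.choice(AMINO) for _ in range(rng.randint(2, 30)))
            delta = (monoisotopic_mass(seq, ModificationState(amidated=True))
                     - monoisotopic_mass(seq))
            assert delta == pytest.approx(-0.984016, abs=1e-6)

    def test_residue_table_matches_pyteomics(self):
        # independent oracle: pyteomics' monoisotopic amino-acid masses
        for aa, m in RESIDUE_MASSES.items():
            assert m == pytest.approx(pt_mass.std_aa_mass[aa], abs=2e-5), aa

    def test_amidated_motif_matches_summation_oracle(self):
        expected = (pt_mass.calculate_mass(sequence="WRPQGRF")
                    + DEFAULT_MODSET.amidation_delta)
        got = monoisotopic_mass("WRPQGRF", ModificationState(amidated=True))
        assert got == pytest.approx(expected, abs=1e-4)

    def test_concatenation_additivity(self):
        rng = random.Random(3)
        for _ in range(30):
            a = "".join(rng.choice(AMINO) for _ in range(rng.randint(1, 15)))
            b = "".join(rng.choice(AMINO) for _ in range(rng.randint(1, 15)))
            assert monoisotopic_mass(a + b) == pytest.approx(
                monoisotopic_mass(a) + monoisotopic_mass(b)
                - DEFAULT_MODSET.water, abs=1e-6)

    @pytest.mark.parametrize("seq,state,rule", [
        ("AAAF", ModificationState(pyroglu=True), "pyroGlu"),
        ("AMAF", ModificationState(n_met_oxidized=2), "oxidation"),
        ("ACAF", ModificationState(n_disulfides=1), "disulfide"),
    ])
    def test_inconsistent_state_names_rule(self, seq, state, rule):
        with pytest.raises(ValueError, match=rule.split("G")[0]):
            monoisotopic_mass(seq, state)


class TestVariants:
    @pytest.mark.parametrize("seq,expected", [
        ("QAAF", 2),        # pyroGlu on/off
        ("ACMCA", 4),       # 2 Met-ox states x 2 disulfide states
        ("AAAF", 1),        # nothing modifiable
        ("EMMCC", 2 * 3 * 2),
    ])
    def test_variant_counts(self, seq, expected):
        assert len(enumerate_variants(seq)) == expected

    def test_variant_masses_are_delta_sums(self):
        base = monoisotopic_mass("QMCMC")
        for state, m in enumerate_variants("QMCMC"):
            expected = base
            if state.pyroglu:
                expected += DEFAULT_MODSET.pyroglu_from_q
            expected += state.n_met_oxidized * DEFAULT_MODSET.met_oxidation
            expected += state.n_disulfides * DEFAULT_MODSET.disulfide_per_bond
            assert m == pytest.approx(expected, abs=1e-9)

    def test_amidation_never_enumerated(self):
        states = [s for s, _ in enumerate_variants("QMA", amidated=True)]
        assert all(s.amidated for s in states)
        states = [s for s, _ in enumerate_variants("QMA", amidated=False)]
        assert not any(s.amidated for s in states)


class TestMatching:
    CATALOG = [_pep("FMRF", amidated=True, pid="pA"),
               _pep("APGW", amidated=True, pid="pA", start=10),
               _pep("WRPQGRF", amidated=True, pid="pB"),
               _pep("SEALING", pid="pB", start=20)]

    def test_exact_full_match(self):
        [m] = match_observed([ObservedPeptide("FMRF")], self.CATALOG)
        assert m.match_type == "full" and m.il_substitutions == 0
        assert m.precursor_id == "pA"

    def test_il_equivalence_flag(self):
        obs = [ObservedPeptide("SEALLNG")]  # I -> L at position 5
        [m] = match_observed(obs, self.CATALOG, il_equiv=True)
        assert m.match_type == "full" and m.il_substitutions == 1
        assert match_observed(obs, self.CATALOG, il_equiv=False) == []

    def test_fragment_match(self):
        [m] = match_observed([ObservedPeptide("QGRF")], self.CATALOG)
        assert m.match_type == "fragment"
        assert m.peptide.sequence == "WRPQGRF"

    def test_full_preempts_fragment(self):
        catalog = self.CATALOG + [_pep("ALING", pid="pC")]
        [m] = match_observed([ObservedPeptide("ALING")], catalog)
        assert m.match_type == "full" and m.precursor_id == "pC"

    def test_mass_filter_rejects_wrong_mass(self):
        right = monoisotopic_mass("FMRF", ModificationState(amidated=True))
        assert match_observed([ObservedPeptide("FMRF", observed_mass=right)],
                              self.CATALOG)
        assert match_observed(
            [ObservedPeptide("FMRF", observed_mass=right + 1.0)],
            self.CATALOG) == []

    def test_mass_filter_accepts_modified_variant(self):
        ox = monoisotopic_mass("FMRF", ModificationState(amidated=True,
                                                         n_met_oxidized=1))
        [m] = match_observed([ObservedPeptide("FMRF", observed_mass=ox)],
                             self.CATALOG)
        assert m.modification_state.n_met_oxidized == 1
        assert abs(m.mass_error_ppm) < 1e-6

    def test_ties_all_reported(self):
        catalog = [_pep("FMRF", pid="p1"), _pep("FMRF", pid="p2")]
        ms = match_observed([ObservedPeptide("FMRF")], catalog)
        assert {m.precursor_id for m in ms} == {"p1", "p2"}

    def test_matching_invariant_under_il_relabeling(self):
        obs = [ObservedPeptide("SEALING"), ObservedPeptide("WRPQGRF")]
        relabeled = [ObservedPeptide(o.sequence.replace("I", "L"))
                     for o in obs]
        a = match_observed(obs, self.CATALOG)
        b = match_observed(relabeled, self.CATALOG)
        assert [(m.precursor_id, m.peptide.sequence, m.match_type)
                for m in a] == \
               [(m.precursor_id, m.peptide.sequence, m.match_type)
                for m in b]


class TestCoverage:
    def test_empty_matches(self):
        summ = coverage_summary([], TestMatching.CATALOG)
        assert summ["percent_matched"] == 0.0
        assert summ["n_catalog"] == 4

    def test_all_matched(self):
        catalog = TestMatching.CATALOG
        obs = [ObservedPeptide(p.sequence) for p in catalog]
        summ = coverage_summary(match_observed(obs, catalog), catalog)
        assert summ["percent_matched"] == 100.0
        assert summ["n_precursors_with_match"] == 2

    def test_tandem_copies_count_once(self):
        catalog = [_pep("FMRF", pid="p1"), _pep("FMRF", pid="p1", start=8,
                                                copy_index=2),
                   _pep("SEALING", pid="p1", start=20)]
        summ = coverage_summary(
            match_observed([ObservedPeptide("FMRF")], catalog), catalog)
        assert summ["n_catalog"] == 2
        assert summ["n_matched"] == 1
        assert summ["percent_matched"] == 50.0
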