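"""Peptide chemistry: masses, ions, transitions, scrambled controls.

pyteomics (an independent mass-spec library) serves as the external
oracle for unmodified masses; the capped modifications are checked via
their exact cancellation identity (pyroGlu + amide = -water).
"""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass

from cappedpep.chemistry import (
    CAPPED_MODS,
    ModificationSet,
    build_transition_list,
    fragment_ions,
    ion_mz,
    peptide_mass,
    precursor_ion,
    scramble_control,
)
from cappedpep.constants import PROTON_MASS, WATER_MASS

PEPTIDE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NO_MODS = ModificationSet(pyroglu_from_gln=False, c_amide=False)
peptides = st.text(alphabet=PEPTIDE_ALPHABET, min_size=2, max_size=30)


class TestPeptideMass:
    def test_glycine_free_acid(self):
        assert peptide_mass("G", NO_MODS) == pytest.approx(75.03203, abs=1e-4)

    def test_capped_cancellation_identity(self):
        """pyroGlu + amide deltas cancel the water term exactly."""
        bare_residue_sum = peptide_mass("QFFGLM", NO_MODS) - WATER_MASS
        assert peptide_mass("QFFGLM", CAPPED_MODS) == pytest.approx(
            bare_residue_sum, abs=1e-6
        )

    def test_cap_tac1_neutral_mass(self):
        assert peptide_mass("QFFGLM", CAPPED_MODS) == pytest.approx(723.3414, abs=5e-4)

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            peptide_mass("GGJGG", NO_MODS)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(peptides)
    def test_unmodified_mass_matches_pyteomics(self, seq):
        assert peptide_mass(seq, NO_MODS) == pytest.approx(
            pmass.fast_mass(seq), abs=1e-3
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(peptides)
    def test_capped_mass_equals_residue_sum(self, seq):
        assert peptide_mass(seq, CAPPED_MODS) == pytest.approx(
            peptide_mass(seq, NO_MODS) - WATER_MASS, abs=1e-6
        )

    def test_carbamidomethyl_applied_per_cysteine(self):
        delta = peptide_mass(
            "ACCA", ModificationSet(False, False, carbamidomethyl_cys=True)
        ) - peptide_mass("ACCA", NO_MODS)
        assert delta == pytest.approx(2 * 57.0214637, abs=1e-6)


class TestIonMz:
    def test_cap_tac1_parent_ion(self):
        mz = ion_mz(peptide_mass("QFFGLM", CAPPED_MODS), 1)
        assert mz == pytest.approx(724.3487, abs=5e-4)
        # agrees with the observed extracted-ion value at 20 ppm
        assert abs(mz - 724.341) / 724.341 * 1e6 < 20

    def test_charge_state_algebra(self):
        m = 723.3414
        mz1, mz2 = ion_mz(m, 1), ion_mz(m, 2)
        assert 2 * mz2 - 2 * PROTON_MASS == pytest.approx(mz1 - PROTON_MASS, abs=1e-9)

    @pytest.mark.parametrize("mass,charge", [(723.0, 0), (723.0, -1), (0.0, 1), (-5.0, 1)])
    def test_invalid_inputs_rejected(self, mass, charge):
        with pytest.raises(ValueError):
            ion_mz(mass, charge)


class TestFragmentIons:
    def test_cap_tac1_b4(self):
        frags = {f.annotation: f.mz for f in fragment_ions("QFFGLM", CAPPED_MODS)}
        assert round(frags["b4+"], 1) == 463.2
        assert frags["b4+"] == pytest.approx(463.198, abs=5e-4)

    def test_cap_tac1_y2_with_amide(self):
        frags = {f.annotation: f.mz for f in fragment_ions("QFFGLM", CAPPED_MODS)}
        # L + M + NH3 + proton
        assert frags["y2+"] == pytest.approx(262.158, abs=5e-4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(peptides)
    def test_by_complementarity(self, seq):
        """b_i + y_(n-i) - 2 protons = neutral mass, for every index i."""
        neutral = peptide_mass(seq, CAPPED_MODS)
        frags = {f.annotation: f.mz for f in fragment_ions(seq, CAPPED_MODS)}
        n = len(seq)
        for i in range(1, n):
            total = frags[f"b{i}+"] + frags[f"y{n-i}+"] - 2 * PROTON_MASS
            assert total == pytest.approx(neutral, abs=1e-4)

    def test_doubly_charged_fragments(self):
        frags = {f.annotation: f.mz for f in fragment_ions("QFFGLM", CAPPED_MODS, max_charge=2)}
        assert frags["b4++"] == pytest.approx(
            (frags["b4+"] - PROTON_MASS + 2 * PROTON_MASS) / 2, abs=1e-9
        )

    def test_series_validation(self):
        with pytest.raises(ValueError):
            fragment_ions("QFFGLM", CAPPED_MODS, series=("a",))
        with pytest.raises(ValueError):
            fragment_ions("Q", CAPPED_MODS)


class TestBuildTransitionList:
    def test_reference_spectrum_selects_tallest_matching_fragment(self):
        frags = {f.annotation: f.mz for f in fragment_ions("QFFGLM", CAPPED_MODS)}
        spectrum = [(frags["b4+"], 999.0), (frags["y5+"], 100.0)]
        trans, flagged = build_transition_list(
            ["QFFGLM"], msms_reference={"pGlu-FFGLM-NH2": spectrum}
        )
        assert not flagged
        (t,) = trans
        assert t.product_annotation == "b4+"
        assert round(t.precursor_mz, 1) == 724.3
        assert round(t.product_mz, 1) == 463.2

    def test_dipeptide_below_floor_is_flagged(self):
        trans, flagged = build_transition_list(["QG"])
        assert trans == []
        assert flagged == ["pGlu-G-NH2"]

    def test_round_trip_annotations(self, rng):
        cores = [
            "Q" + "".join(rng.choices(PEPTIDE_ALPHABET, k=rng.randint(4, 19)))
            for _ in range(100)
        ]
        trans, flagged = build_transition_list(cores)
        assert len(trans) + len(flagged) == 100
        by_compound = {f"pGlu-{c[1:]}-NH2": c for c in cores}
        for t in trans:
            core = by_compound[t.compound]
            frags = {f.annotation: f.mz for f in fragment_ions(core, CAPPED_MODS)}
            assert t.product_mz == pytest.approx(frags[t.product_annotation], abs=1e-9)
            assert t.product_mz >= 200.0


class TestScrambleControl:
    def test_preserves_composition_and_leading_q(self):
        core = "QLELRLRVAAGR"
        out = scramble_control(core, seed=7)
        assert out[0] == "Q"
        assert sorted(out) == sorted(core)
        assert out != core

    def test_known_scramble_is_reachable_composition(self):
        # the published scrambled control of the same core
        assert sorted("QGLEALRARLRV") == sorted("QLELRLRVAAGR")

    def test_homogeneous_body_returned_unchanged(self):
        assert scramble_control("QAA", seed=1) == "QAA"

    def test_deterministic_per_seed(self):
        assert scramble_control("QACDEFG", 3) == scramble_control("QACDEFG", 3)

    def test_too_short_or_uncapped_rejected(self):
        with pytest.raises(ValueError):
            scramble_control("QA", 1)
        with pytest.raises(ValueError):
            scramble_control("AQA", 1)
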