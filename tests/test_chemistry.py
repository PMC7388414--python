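"""Mass and m/z arithmetic, disulfide correction, modification catalog."""

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pyteomics_mass

from venomics.chemistry import (
    DISULFIDE_DELTA,
    HYDROGEN_MASS,
    MODIFICATION_CATALOG,
    MONOISOTOPIC,
    PROTON_MASS,
    WATER_MONO,
    ToxinRecord,
    apply_record_modifications,
    mass_from_mz,
    monoisotopic_mass,
    mz_from_mass,
)

RESIDUES = sorted(MONOISOTOPIC)
sequences = st.text(alphabet=RESIDUES, min_size=1, max_size=40)


class TestResidueTable:
    def test_all_twenty_residues_present_and_positive(self):
        assert len(MONOISOTOPIC) == 20
        assert all(m > 0 for m in MONOISOTOPIC.values())
        assert MONOISOTOPIC["G"] < MONOISOTOPIC["A"] < MONOISOTOPIC["W"]

    def test_agrees_with_independent_reference_masses(self):
        # pyteomics carries the same standard residue masses
        for residue, value in MONOISOTOPIC.items():
            assert value == pytest.approx(
                pyteomics_mass.std_aa_mass[residue], abs=1e-5
            )

    def test_modification_catalog_is_the_study_set(self):
        assert set(MODIFICATION_CATALOG) == {
            "carbamidomethyl",
            "oxidation",
            "deamidation",
            "acetylation",
            "amidation",
        }
        assert MODIFICATION_CATALOG["carbamidomethyl"].delta == pytest.approx(57.021464)
        assert MODIFICATION_CATALOG["oxidation"].delta == pytest.approx(15.994915)
        assert MODIFICATION_CATALOG["amidation"].delta == pytest.approx(-0.984016)
        assert MODIFICATION_CATALOG["carbamidomethyl"].mode == "fixed"


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "sequence, ss, expected, tol",
        [
            ("ACGSFMWKCSERLPCCQEYVCSPQWKWCQNP", 3, 3690.49, 0.01),
            ("VPPILKY", 0, 828.51, 0.01),
            ("G", 0, 75.032, 0.001),
        ],
    )
    def test_known_peptide_masses(self, sequence, ss, expected, tol):
        assert monoisotopic_mass(sequence, ss) == pytest.approx(expected, abs=tol)

    def test_peptide_bond_loses_one_water(self):
        assert monoisotopic_mass("GG") == pytest.approx(
            2 * monoisotopic_mass("G") - WATER_MONO, abs=1e-9
        )

    def test_matches_pyteomics_oracle_on_plain_peptides(self):
        for seq in ("PEPTIDE", "ACDEFGHIKLMNPQRSTVWY", "KKKKR"):
            assert monoisotopic_mass(seq) == pytest.approx(
                pyteomics_mass.calculate_mass(sequence=seq), abs=1e-4
            )

    def test_unknown_residue_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            monoisotopic_mass("GGXG")

    def test_excess_disulfides_rejected(self):
        with pytest.raises(ValueError, match="Cys"):
            monoisotopic_mass("ACCA", ss_bonds=2)

    @given(a=sequences, b=sequences)
    @settings(max_examples=50, deadline=None)
    def test_additivity_under_concatenation(self, a, b):
        total = monoisotopic_mass(a) + monoisotopic_mass(b) - WATER_MONO
        assert monoisotopic_mass(a + b) == pytest.approx(total, abs=1e-8)

    def test_each_disulfide_removes_two_hydrogens(self):
        seq = "CCCCCCAA"
        masses = [monoisotopic_mass(seq, ss) for ss in range(4)]
        for lighter, heavier in zip(masses[1:], masses):
            assert heavier - lighter == pytest.approx(2 * HYDROGEN_MASS, abs=1e-9)
        assert DISULFIDE_DELTA == pytest.approx(2.015650, abs=1e-6)


class TestMzConversions:
    def test_singly_charged_adds_one_proton(self):
        assert mz_from_mass(3690.489, 1) == pytest.approx(3691.496, abs=0.001)

    def test_quadruply_charged(self):
        assert mz_from_mass(3690.489, 4) == pytest.approx(923.630, abs=0.001)

    def test_decharge_example(self):
        assert mass_from_mz(924.0, 1) == pytest.approx(922.993, abs=0.001)

    @given(
        m=st.floats(min_value=100.0, max_value=20000.0),
        z=st.integers(min_value=1, max_value=9),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, m, z):
        assert mass_from_mz(mz_from_mass(m, z), z) == pytest.approx(m, rel=1e-9)

    @pytest.mark.parametrize("charge", [0, -1])
    def test_nonpositive_charge_rejected(self, charge):
        with pytest.raises(ValueError):
            mz_from_mass(1000.0, charge)
        with pytest.raises(ValueError):
            mass_from_mz(500.0, charge)

    def test_subproton_mz_rejected(self):
        with pytest.raises(ValueError):
            mass_from_mz(0.5, 1)
        assert mz_from_mass(1000.0, 2) > PROTON_MASS


class TestToxinRecord:
    def test_validates_sequence_and_disulfide_capacity(self):
        with pytest.raises(ValueError):
            ToxinRecord("x", "ACA", ss_bonds=1)
        with pytest.raises(ValueError):
            ToxinRecord("x", "AC1A")

    def test_amidation_consumes_glycine_donor(self):
        # alpha-amidation of a Gly-extended precursor: the terminal Gly
        # is lost and the preceding residue gains the amide
        rec = ToxinRecord("x", "AKSG", modifications=["amidation"])
        assert rec.mass_form_sequence == "AKS"
        expected = monoisotopic_mass("AKS") - 0.984016
        assert rec.theoretical_mass() == pytest.approx(expected, abs=1e-8)

    def test_amidation_without_gly_applies_delta_only(self):
        assert apply_record_modifications("AKS", 0, ["amidation"]) == pytest.approx(
            monoisotopic_mass("AKS") - 0.984016, abs=1e-8
        )

    def test_acetylation_adds_fixed_delta(self):
        rec = ToxinRecord("x", "AKS", modifications=["acetylation"])
        assert rec.theoretical_mass() == pytest.approx(
            monoisotopic_mass("AKS") + 42.010565, abs=1e-8
        )


class TestReferenceTableMasses:
    """The 18 validated mature toxins against their printed masses."""

    EXACT = {"U1-TRTX-Agm3a", "VPPILKY", "FETPNNPDGKVTKQE", "YPPPPPPPH"}
    TIGHT = {"PLPVFV", "VVVPFVV", "VENLAEP"}
    # printed 812.40 vs sequence-derived 812.52: a known discrepancy in
    # the printed value, reported but not forced
    DISCREPANT = {"VLPPLKF"}

    def test_all_reference_masses_within_60_ppm_except_flagged(
        self, reference_toxins, reference_toxin_table
    ):
        printed = dict(
            zip(reference_toxin_table.toxin_id, reference_toxin_table.printed_mass)
        )
        for toxin in reference_toxins:
            ppm = abs(toxin.theoretical_mass() - printed[toxin.id]) / printed[toxin.id] * 1e6
            if toxin.id in self.DISCREPANT:
                assert ppm > 60  # stays an open discrepancy, not forced
            else:
                assert ppm <= 60, f"{toxin.id}: {ppm:.1f} ppm"

    def test_exact_subset_within_hundredth_dalton(
        self, reference_toxins, reference_toxin_table
    ):
        printed = dict(
            zip(reference_toxin_table.toxin_id, reference_toxin_table.printed_mass)
        )
        for toxin in reference_toxins:
            if toxin.id in self.EXACT:
                assert toxin.theoretical_mass() == pytest.approx(
                    printed[toxin.id], abs=0.01
                )
            elif toxin.id in self.TIGHT:
                assert toxin.theoretical_mass() == pytest.approx(
                    printed[toxin.id], abs=0.02
                )
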