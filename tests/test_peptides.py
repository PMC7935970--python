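"""Sequence-model tests: registers, motif grafting, wheels, moments, masses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccswitch import library
from ccswitch.peptides import (COILED_COIL_DEGREES, EISENBERG, HEPTAD,
                               ExtinctionTable, RegisteredPeptide,
                               assign_register, epsilon280, helical_wheel,
                               hydrophobic_moment, insert_kinase_motif,
                               molecular_mass, substitute_at_register)

CANON = "ACDEFGHIKLMNPQRSTVWY"

# independent residue average-mass table: hand-summed from the residue
# elemental formulas with IUPAC 2021 atomic weights (C 12.011, H 1.008,
# N 14.007, O 15.999, S 32.06)
RESIDUE_AVG = {
    "G": 57.052, "A": 71.079, "S": 87.078, "P": 97.117, "V": 99.133,
    "T": 101.105, "C": 103.139, "L": 113.160, "I": 113.160, "N": 114.104,
    "D": 115.088, "Q": 128.131, "K": 128.175, "E": 129.115, "M": 131.193,
    "H": 137.142, "F": 147.177, "R": 156.189, "Y": 163.176, "W": 186.214,
}


class TestRegister:
    def test_single_heptad_starting_at_a(self):
        assert "".join(assign_register("EIAALEQ", 0)) == "abcdefg"

    def test_periodicity(self):
        assert "".join(assign_register("EIAALEQEIAALEQ", 0)) == "abcdefg" * 2

    def test_switch_serine_lands_at_a_of_second_heptad(self):
        """The phospho-acceptor Ser of the grafted motif sits at register a
        of heptad 2 of the interaction module."""
        p = library.CC_DI_B_RRS
        idx = p.index_of("a", 2)
        assert p.sequence[idx - 1] == "S"
        assert p.registers[idx - 1] == "a"

    def test_rejects_noncanonical_with_index(self):
        with pytest.raises(ValueError, match="position 3"):
            assign_register("AAXAA", 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(offset=st.integers(0, 6), i=st.integers(1, 60), k=st.integers(1, 8))
    def test_register_pure_function_and_periodic(self, offset, i, k):
        seq = "A" * (i + 7 * k)
        regs = assign_register(seq, offset)
        assert regs[i - 1] == HEPTAD[(offset + i - 1) % 7]
        assert regs[i - 1] == regs[i - 1 + 7 * (k - 1)]


class TestMotifGrafting:
    def test_reproduces_switch_peptide(self):
        made = insert_kinase_motif(library.CC_DI_B_N4, "RRxS", "a", 2)
        assert made.sequence == library.CC_DI_B_RRS.sequence

    def test_arg_pair_occupies_e_and_f_of_previous_heptad(self):
        p = library.CC_DI_B_RRS
        assert p.residue_at("e", 1) == "R"
        assert p.residue_at("f", 1) == "R"

    def test_x_keeps_parent_residue(self):
        parent = library.CC_DI_B_N4
        made = insert_kinase_motif(parent, "RRxS", "a", 2)
        g1 = parent.index_of("g", 1)
        assert made.sequence[g1 - 1] == parent.sequence[g1 - 1]

    def test_all_x_motif_is_identity(self):
        parent = library.CC_DI_B_N4
        assert insert_kinase_motif(parent, "xxxx", "a", 2).sequence == parent.sequence

    def test_overrun_raises_with_positions(self):
        toy = RegisteredPeptide(name="t", sequence="AAASAAA", register_offset=0)
        with pytest.raises(ValueError, match="overruns"):
            insert_kinase_motif(toy, "RRxS", "a", 1)

    @pytest.mark.parametrize("heptad_index", [2, 3, 4])
    def test_requested_placement_for_all_valid_anchors(self, heptad_index):
        parent = library.CC_DI_B_N4
        made = insert_kinase_motif(parent, "RRxS", "a", heptad_index)
        assert made.residue_at("a", heptad_index) == "S"
        assert made.residue_at("e", heptad_index - 1) == "R"
        assert made.residue_at("f", heptad_index - 1) == "R"


class TestSubstitution:
    def test_reproduces_ser_partner(self):
        made = substitute_at_register(library.CC_DI_A_N4, "a", 2, "S")
        assert made.sequence == library.CC_DI_A_S.sequence

    def test_identity_when_residue_already_present(self, toy_heptad):
        assert substitute_at_register(toy_heptad, "a", 1, "I").sequence == \
            toy_heptad.sequence

    def test_involution(self):
        parent = library.CC_DI_A_N4
        orig = parent.residue_at("a", 2)
        fwd = substitute_at_register(parent, "a", 2, "S")
        back = substitute_at_register(fwd, "a", 2, orig)
        assert back.sequence == parent.sequence

    def test_out_of_range(self, toy_heptad):
        with pytest.raises(ValueError):
            substitute_at_register(toy_heptad, "a", 2, "S")


class TestWheel:
    def test_seven_distinct_angles_one_turn(self, toy_heptad):
        layout = helical_wheel(toy_heptad)
        angles = [a for *_, a in layout.residues]
        assert len({round(a, 6) for a in angles}) == 7
        steps = np.diff(sorted(angles))
        assert np.allclose(steps, 360.0 / 7.0)

    def test_residues_seven_apart_share_angle(self):
        p = RegisteredPeptide(name="t", sequence="IAALEQE" * 2, register_offset=0)
        layout = helical_wheel(p)
        angles = [a for *_, a in layout.residues]
        for i in range(7):
            assert math.isclose(angles[i], angles[i + 7], abs_tol=1e-9)

    def test_a_d_adjacent_sectors(self, toy_heptad):
        by_reg = helical_wheel(toy_heptad).angles_by_register()
        delta = abs(by_reg["a"] - by_reg["d"])
        delta = min(delta, 360 - delta)
        assert delta <= 360.0 / 7.0 + 1e-9

    def test_too_short(self):
        with pytest.raises(ValueError):
            helical_wheel(RegisteredPeptide(name="t", sequence="AAA"))

    def test_mts_hydrophobics_cluster_on_one_face(self):
        """The membrane-targeting 13-mer presents its hydrophobic residues
        within a half-wheel face."""
        layout = helical_wheel(library.HYB_SNF7_1_13)
        hydro = [a for _, _, res, a in layout.residues
                 if EISENBERG[res] > 0.5]
        assert len(hydro) >= 5
        # all hydrophobic angles within a 180-degree arc
        rad = np.radians(hydro)
        mean_dir = np.angle(np.exp(1j * rad).sum())
        spread = np.abs(np.angle(np.exp(1j * (rad - mean_dir))))
        assert np.max(np.degrees(spread)) <= 90.0


class TestHydrophobicMoment:
    def test_homopolymer_vanishes_over_whole_heptads(self):
        p = RegisteredPeptide(name="t", sequence="L" * 14)
        mag, _ = hydrophobic_moment(p)
        assert mag == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_vector_sum(self):
        p = RegisteredPeptide(name="t", sequence="LKLKLKLKLKLKLK")
        mag, direction = hydrophobic_moment(p)
        step = math.radians(COILED_COIL_DEGREES)
        vx = sum(EISENBERG[r] * math.cos(step * n) for n, r in enumerate(p.sequence))
        vy = sum(EISENBERG[r] * math.sin(step * n) for n, r in enumerate(p.sequence))
        assert mag == pytest.approx(math.hypot(vx, vy), rel=1e-12)
        assert direction == pytest.approx(math.degrees(math.atan2(vy, vx)) % 360,
                                          abs=1e-9)

    def test_mts_more_amphipathic_than_scrambles(self, rng):
        """Permutation oracle: the designed MTS moment exceeds the mean
        moment of 1000 composition-preserving shuffles."""
        seq = library.HYB_SNF7_1_13.sequence
        mag, _ = hydrophobic_moment(library.HYB_SNF7_1_13)
        shuffled = []
        for _ in range(1000):
            s = "".join(rng.permutation(list(seq)))
            m, _ = hydrophobic_moment(RegisteredPeptide(name="s", sequence=s))
            shuffled.append(m)
        assert mag > np.mean(shuffled)

    def test_scale_sign_flip_preserves_magnitude(self):
        p = RegisteredPeptide(name="t", sequence="MWSKLFSLWKNLA")
        neg = {k: -v for k, v in EISENBERG.items()}
        m1, d1 = hydrophobic_moment(p)
        m2, d2 = hydrophobic_moment(p, scale=neg)
        assert m1 == pytest.approx(m2, rel=1e-12)
        assert abs(((d1 - d2) % 360) - 180) < 1e-6

    def test_missing_residue_in_scale(self):
        p = RegisteredPeptide(name="t", sequence="AAAAAAW")
        with pytest.raises(ValueError, match="W"):
            hydrophobic_moment(p, scale={"A": 0.62})


class TestMass:
    def test_glycine_free_peptide(self):
        assert molecular_mass("G") == pytest.approx(75.07, abs=0.01)

    def test_phospho_delta(self):
        delta = molecular_mass(library.CC_DI_B_RRPS) - molecular_mass(
            library.CC_DI_B_RRS)
        assert delta == pytest.approx(79.98, abs=0.01)

    def test_acetyl_amide_deltas(self, toy_heptad):
        from dataclasses import replace
        capped = replace(toy_heptad, n_term_mod="acetyl", c_term_mod="amide")
        delta = molecular_mass(capped) - molecular_mass(toy_heptad)
        assert delta == pytest.approx(42.0367 - 0.9847, abs=0.01)

    def test_monotone_in_length(self):
        assert molecular_mass("AAAA") > molecular_mass("AAA")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet=CANON, min_size=1, max_size=30))
    def test_matches_independent_residue_table(self, seq):
        """Hand-summed residue-mass-table oracle, water included."""
        expected = sum(RESIDUE_AVG[r] for r in seq) + 18.015
        assert molecular_mass(seq) == pytest.approx(expected, abs=0.01)

    def test_matches_biopython_cross_check(self, rng):
        # gross-error guard only: Biopython's residue table differs from
        # IUPAC 2021 atomic weights at the ~0.002 Da/residue level
        from Bio.SeqUtils.ProtParam import ProteinAnalysis
        for _ in range(20):
            seq = "".join(rng.choice(list(CANON), size=25))
            ours = molecular_mass(seq)
            theirs = ProteinAnalysis(seq).molecular_weight()
            assert ours == pytest.approx(theirs, abs=0.1)

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            molecular_mass("AA", convention="nominal")


class TestEpsilon280:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAA", 0.0),
        ("WWYYY", 15220.0),
        ("W", 5690.0),
    ])
    def test_values(self, seq, expected):
        assert epsilon280(seq) == expected

    def test_additive_over_concatenation(self):
        assert epsilon280("WWY" + "YAW") == epsilon280("WWY") + epsilon280("YAW")

    def test_table_validation(self):
        with pytest.raises(ValueError):
            ExtinctionTable(eps280_trp=-1.0)


class TestFastaRoundTrip:
    def test_modifications_survive(self, tmp_path):
        from ccswitch import io
        path = tmp_path / "peps.fasta"
        io.write_fasta([library.CC_DI_B_RRPS, library.HYB_SNF7_1_13], path)
        back = io.read_fasta(path)
        assert back[0] == library.CC_DI_B_RRPS
        assert back[1] == library.HYB_SNF7_1_13
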