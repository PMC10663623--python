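"""Folding-shape alphabet and fragment-classification geometry."""

import collections

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pfvmkit import (
    ALPHABET,
    CELL_TO_SYMBOL,
    CATrace,
    DegenerateGeometryError,
    classify_descriptors,
    classify_fragment,
    code_class,
    cube_neighbors,
    encode_structure,
    make_ideal_helix,
    make_ideal_strand,
    make_random_coil,
    representative_fragment,
    virtual_descriptors,
)
from pfvmkit.geometry import FragmentDescriptors


def reference_torsion(p0, p1, p2, p3):
    """Independent signed-torsion oracle (atan2 formulation)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    # Sign convention: a right-handed helix has a positive Cα torsion.
    return np.degrees(
        np.arctan2(np.dot(np.cross(n2, n1), b2 / np.linalg.norm(b2)), np.dot(n1, n2))
    )


def reference_superpose_rmsd(x, y):
    """Independent Kabsch-superposition RMSD oracle (SVD form)."""
    xc, yc = x - x.mean(0), y - y.mean(0)
    u, s, vt = np.linalg.svd(yc.T @ xc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    return np.sqrt(np.mean(np.sum((xc - yc @ rot.T) ** 2, axis=1)))


class TestAlphabet:
    def test_alphabet_size_and_composition(self):
        assert len(ALPHABET) == 27
        symbols = set(ALPHABET)
        assert "$" in symbols
        assert sum(s.isalpha() for s in symbols) == 26

    def test_class_partition(self):
        by_class = collections.Counter(c.ss_class for c in ALPHABET.values())
        assert by_class == {
            "helix": 1,
            "partial_helix": 4,
            "strand": 1,
            "partial_strand": 4,
            "mixed": 2,
            "irregular": 15,
        }
        assert code_class("A") == "helix"
        assert code_class("B") == "strand"
        assert {s for s, c in ALPHABET.items() if c.ss_class == "partial_helix"} == set("YPDH")
        assert {s for s, c in ALPHABET.items() if c.ss_class == "partial_strand"} == set("EGSM")
        assert {s for s, c in ALPHABET.items() if c.ss_class == "mixed"} == set("VJ")
        assert code_class("$") == "irregular"

    def test_cell_symbol_bijection(self):
        assert len(CELL_TO_SYMBOL) == 27
        assert len(set(CELL_TO_SYMBOL.values())) == 27
        for symbol, code in ALPHABET.items():
            assert CELL_TO_SYMBOL[code.cell] == symbol

    def test_cube_neighbors_counts_and_symmetry(self):
        for symbol in ALPHABET:
            nbs = cube_neighbors(symbol)
            assert 3 <= len(nbs) <= 6
            assert symbol not in nbs
            for other in nbs:
                assert symbol in cube_neighbors(other)
        # The two pure-secondary-structure codes sit at opposite corners.
        assert len(cube_neighbors("A")) == 3
        assert len(cube_neighbors("B")) == 3

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            code_class("?")
        with pytest.raises(ValueError):
            cube_neighbors("a")


class TestDescriptors:
    def test_ideal_helix_descriptors_match_analytic_torsion(self):
        helix = make_ideal_helix(6)
        d = virtual_descriptors(helix.coords[:5])
        expected = reference_torsion(*helix.coords[:4])
        assert d.delta1 == pytest.approx(expected, abs=1e-9)
        assert d.delta1 == pytest.approx(50.04, abs=0.05)
        assert d.delta2 == pytest.approx(d.delta1, abs=1e-9)
        assert d.kappa == pytest.approx(6.203, abs=0.005)

    def test_collinear_points_are_degenerate(self):
        frag = np.column_stack([np.arange(5) * 3.8, np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            virtual_descriptors(frag)

    def test_rigid_motion_invariance(self):
        frag = make_random_coil(5, seed=11).coords
        ref = virtual_descriptors(frag)
        for rot in Rotation.random(25, rng=np.random.default_rng(3)):
            moved = rot.apply(frag) + np.array([5.0, -2.0, 13.0])
            got = virtual_descriptors(moved)
            assert got.delta1 == pytest.approx(ref.delta1, abs=1e-6)
            assert got.delta2 == pytest.approx(ref.delta2, abs=1e-6)
            assert got.kappa == pytest.approx(ref.kappa, abs=1e-6)

    def test_window_overlap_shares_torsion(self):
        # delta2 of window i and delta1 of window i+1 use the same 4 atoms.
        coil = make_random_coil(20, seed=7)
        for i in range(len(coil) - 5):
            d_i = virtual_descriptors(coil.window(i))
            d_next = virtual_descriptors(coil.window(i + 1))
            assert d_i.delta2 == pytest.approx(d_next.delta1, abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            virtual_descriptors(np.zeros((4, 3)))
        frag = make_random_coil(5, seed=1).coords.copy()
        frag[2] = frag[1]
        with pytest.raises(ValueError):
            virtual_descriptors(frag)


class TestClassification:
    def test_pure_cells_map_to_typical_codes(self):
        alpha = classify_descriptors(FragmentDescriptors(50.0, 50.0, 6.2))
        beta = classify_descriptors(FragmentDescriptors(180.0, 180.0, 13.0))
        assert alpha.symbol == "A"
        assert beta.symbol == "B"

    def test_strand_bin_wraps_branch_cut(self):
        for d in (150.0, 179.9, 180.0, -179.9, -150.1):
            code = classify_descriptors(FragmentDescriptors(d, d, 13.0))
            assert code.symbol == "B", d

    def test_boundary_values_deterministic_half_open(self):
        # Dihedral bins are [20, 80) for alpha; kappa [0, 8) compact.
        at_lo = classify_descriptors(FragmentDescriptors(20.0, 20.0, 6.2))
        at_hi = classify_descriptors(FragmentDescriptors(80.0, 80.0, 6.2))
        assert at_lo.symbol == "A"
        assert at_lo.cell == ("alpha", "alpha", "alpha")
        assert at_hi.cell == ("other", "other", "alpha")
        at_kappa = classify_descriptors(FragmentDescriptors(50.0, 50.0, 8.0))
        assert at_kappa.cell == ("alpha", "alpha", "other")

    def test_classification_total_over_descriptor_space(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            d = FragmentDescriptors(
                rng.uniform(-180, 180), rng.uniform(-180, 180), rng.uniform(0, 16)
            )
            assert classify_descriptors(d).symbol in ALPHABET

    def test_ideal_fragments(self):
        assert classify_fragment(make_ideal_helix(5).coords).symbol == "A"
        assert classify_fragment(make_ideal_strand(5).coords).symbol == "B"


class TestRepresentatives:
    @pytest.mark.parametrize("symbol", sorted(ALPHABET))
    def test_round_trip_every_code(self, symbol):
        frag = representative_fragment(symbol)
        assert classify_fragment(frag).symbol == symbol

    def test_representative_bond_lengths(self):
        for symbol in ALPHABET:
            bonds = np.linalg.norm(np.diff(representative_fragment(symbol), axis=0), axis=1)
            assert np.allclose(bonds, 3.8, atol=1e-6)

    def test_helix_representative_close_to_ideal_helix(self):
        rmsd = reference_superpose_rmsd(
            representative_fragment("A"), make_ideal_helix(5).coords
        )
        assert rmsd < 1.0


class TestEncodeStructure:
    def test_ideal_helix_encodes_all_A(self):
        assert encode_structure(make_ideal_helix(12)) == "A" * 8

    def test_ideal_strand_encodes_all_B(self):
        assert encode_structure(make_ideal_strand(9)) == "B" * 5

    def test_minimal_trace_single_window(self):
        assert len(encode_structure(make_ideal_helix(5))) == 1

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            encode_structure(CATrace("AAAA", np.zeros((4, 3)) + np.arange(4)[:, None]))

    def test_chain_break_marks_covering_windows(self):
        helix = make_ideal_helix(12)
        coords = helix.coords.copy()
        coords[6:] += 30.0  # break between residues 6 and 7 (0-based 5|6)
        broken = CATrace(helix.residues, coords)
        encoded = encode_structure(broken)
        assert len(encoded) == 8
        # Windows 2..5 (0-based) straddle the broken bond 5-6.
        assert encoded == "AA????AA"

    def test_noncanonical_residue_marks_covering_windows(self):
        helix = make_ideal_helix(12, sequence="AAAAAXAAAAAA")
        encoded = encode_structure(helix)
        # Windows 1..5 (0-based) cover the X at residue index 5.
        assert encoded == "A?????AA"

    def test_rigid_motion_invariance_of_encoding(self):
        coil = make_random_coil(25, seed=13)
        ref = encode_structure(coil)
        for rot in Rotation.random(10, rng=np.random.default_rng(5)):
            moved = CATrace(coil.residues, rot.apply(coil.coords) - 7.5)
            assert encode_structure(moved) == ref
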