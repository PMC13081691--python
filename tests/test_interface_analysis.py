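import numpy as np
import pytest

from foldscreen.config import ScoringConfig
from foldscreen.confidence_scores import ipsae
from foldscreen.interface_analysis import (
    DomainAnnotation,
    InterfaceSet,
    MembraneFrame,
    find_interface,
    membrane_proximal_residues,
    pymol_selection,
    read_domain_annotations,
    shared_interface_fraction,
    trim_to_domain,
)
from foldscreen.model import Atom, Chain, ComplexModel, Residue
from foldscreen.synthetic_data import SyntheticSpec, make_dimer, _transform_chain

from conftest import make_pae_pair
from _oracles import contacts_bruteforce


def two_residue_model(separation):
    """Two single-residue chains whose closest atoms sit `separation` apart."""
    a = Chain("A", [Residue(1, "ALA", [Atom("CA", 0, 0, 0),
                                       Atom("CB", 1.0, 0, 0)], 90.0)])
    b = Chain("B", [Residue(1, "ALA", [Atom("CA", 1.0 + separation + 1.5, 0, 0),
                                       Atom("CB", 1.0 + separation, 0, 0)], 90.0)])
    return ComplexModel("tiny", [a, b])


class TestFindInterface:
    def test_distant_chains_give_empty_set(self):
        model = two_residue_model(50.0)
        iface = find_interface(model, "A", "B")
        assert iface.contacts == []
        assert not iface.residues_a and not iface.residues_b

    @pytest.mark.parametrize("sep,expected", [(4.9, 1), (5.1, 0)])
    def test_cutoff_boundary(self, sep, expected):
        model = two_residue_model(sep)
        assert len(find_interface(model, "A", "B").contacts) == expected

    def test_matches_bruteforce_on_docked_dimer(self, docked_dimer):
        model, _ = docked_dimer
        iface = find_interface(model, "A", "B")
        atoms_a = [[(a.x, a.y, a.z) for a in r.atoms]
                   for r in model.chain("A").residues]
        atoms_b = [[(a.x, a.y, a.z) for a in r.atoms]
                   for r in model.chain("B").residues]
        want = contacts_bruteforce(atoms_a, atoms_b, 5.0)
        got = [(a, b, d) for a, b, d in iface.contacts]
        assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in want]
        np.testing.assert_allclose([d for *_, d in got],
                                   [d for *_, d in want], atol=1e-9)
        assert len(got) > 0

    def test_symmetry(self, docked_dimer):
        model, _ = docked_dimer
        ab = find_interface(model, "A", "B")
        ba = find_interface(model, "B", "A")
        assert {(a, b) for a, b, _ in ab.contacts} == \
               {(b, a) for a, b, _ in ba.contacts}


class TestTrimToDomain:
    def test_counting(self, rng):
        pair = make_pae_pair(10, 10, rng)
        trimmed = trim_to_domain(pair, [DomainAnnotation("A", "dom", 3, 7)])
        assert len(trimmed.model.chain("A")) == 5
        assert len(trimmed.model.chain("B")) == 10
        assert trimmed.pae.shape == (15, 15)

    def test_full_range_is_identity(self, docked_pair):
        trimmed = trim_to_domain(
            docked_pair, [DomainAnnotation("A", "full", 1, 30)])
        np.testing.assert_array_equal(trimmed.pae, docked_pair.pae)
        s0 = ipsae(docked_pair, "A", "B")
        s1 = ipsae(trimmed, "A", "B")
        assert s0 == s1

    def test_pae_slice_preserves_entries(self, rng):
        pair = make_pae_pair(6, 4, rng)
        trimmed = trim_to_domain(pair, [DomainAnnotation("A", "d", 2, 4)])
        # global survivors: A2,A3,A4 (old rows 1..3), B1..4 (old rows 6..9)
        old = pair.pae
        np.testing.assert_array_equal(
            trimmed.pae, old[np.ix_([1, 2, 3, 6, 7, 8, 9],
                                    [1, 2, 3, 6, 7, 8, 9])])

    def test_trim_tail_matches_d0chn_with_reduced_length(self, rng):
        # removing a non-interface tail changes d0chn only through L_A
        la, lb, keep = 12, 8, 7
        pae = rng.uniform(0, 30, size=(la + lb, la + lb))
        pae[keep:la, :] = 34.0  # the tail never scores
        pae[:, keep:la] = 34.0
        np.fill_diagonal(pae, 0.0)
        pair = make_pae_pair(la, lb, rng, pae=pae)
        trimmed = trim_to_domain(pair, [DomainAnnotation("A", "d", 1, keep)])
        got = ipsae(trimmed, "A", "B")["d0chn"]
        small = make_pae_pair(keep, lb, rng,
                              pae=pair.pae[np.ix_(
                                  list(range(keep)) + list(range(la, la + lb)),
                                  list(range(keep)) + list(range(la, la + lb)))])
        want = ipsae(small, "A", "B")["d0chn"]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_idempotent(self, rng):
        pair = make_pae_pair(10, 10, rng)
        ann = [DomainAnnotation("A", "d", 3, 7)]
        once = trim_to_domain(pair, ann)
        twice = trim_to_domain(once, [DomainAnnotation("A", "d", 1, 5)])
        np.testing.assert_array_equal(once.pae, twice.pae)

    def test_range_beyond_chain_raises(self, rng):
        pair = make_pae_pair(10, 10, rng)
        with pytest.raises(ValueError, match="exceeds"):
            trim_to_domain(pair, [DomainAnnotation("A", "d", 5, 20)])


class TestSharedInterfaceFraction:
    def _iface(self, res_a, res_b=frozenset({1})):
        return InterfaceSet("A", "B", frozenset(res_a), frozenset(res_b), [])

    def test_identical_sets(self):
        i1 = self._iface({1, 2, 3})
        jac, direc = shared_interface_fraction(i1, i1)
        assert jac == 1.0 and direc == 1.0

    def test_disjoint_sets(self):
        jac, direc = shared_interface_fraction(
            self._iface({1, 2}, {1}), self._iface({5, 6}, {9}))
        assert jac == 0.0 and direc == 0.0

    def test_hand_enumerated_overlap(self):
        # A-side sets {1..10} vs {6..15}, same single B residue
        i1 = InterfaceSet("A", "B", frozenset(range(1, 11)), frozenset(), [])
        i2 = InterfaceSet("A", "B", frozenset(range(6, 16)), frozenset(), [])
        jac, direc = shared_interface_fraction(i1, i2)
        assert jac == pytest.approx(5 / 15)
        assert direc == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        empty = InterfaceSet("A", "B", frozenset(), frozenset(), [])
        assert shared_interface_fraction(empty, empty) == (1.0, 1.0)

    def test_jaccard_symmetric(self):
        i1 = self._iface({1, 2, 3, 4}, {7})
        i2 = self._iface({3, 4, 5}, {7, 8})
        assert shared_interface_fraction(i1, i2)[0] == \
               shared_interface_fraction(i2, i1)[0]


class TestMembraneProximity:
    @pytest.mark.parametrize("dz,flagged", [(3.4, True), (3.6, False)])
    def test_boundary(self, dz, flagged):
        model = ComplexModel("m", [Chain("A", [
            Residue(1, "ALA", [Atom("CA", 0, 0, 20.0 + dz)], 90.0)])])
        frame = MembraneFrame(z_upper=20.0, z_lower=-20.0)
        got = membrane_proximal_residues(model, frame)
        assert (("A", 1) in got) == flagged

    def test_xy_translation_invariance(self, docked_dimer):
        model, _ = docked_dimer
        frame = MembraneFrame(z_upper=10.0, z_lower=-30.0)
        before = membrane_proximal_residues(model, frame)
        moved = ComplexModel(model.model_id, [
            _transform_chain(c, np.eye(3), np.array([100.0, 0, 0]))
            for c in model.chains])
        assert membrane_proximal_residues(moved, frame) == before

    def test_both_leaflets_flag(self):
        model = ComplexModel("m", [Chain("A", [
            Residue(1, "ALA", [Atom("CA", 0, 0, -20.0)], 90.0)])])
        frame = MembraneFrame(z_upper=20.0, z_lower=-20.0)
        assert membrane_proximal_residues(model, frame) == set()
        assert membrane_proximal_residues(
            model, frame, both_leaflets=True) == {("A", 1)}


class TestAnnotationsIO:
    def test_domain_tsv_round_trip(self, tmp_path):
        path = tmp_path / "domains.tsv"
        path.write_text("protein_id\tdomain\tstart\tend\nA\tORD\t3\t7\n")
        anns = read_domain_annotations(path)
        assert anns == [DomainAnnotation("A", "ORD", 3, 7)]

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            DomainAnnotation("A", "d", 5, 2)

    def test_pymol_selection_format(self):
        sel = pymol_selection("memb", {("A", 3), ("A", 1), ("B", 2)})
        assert sel == "select memb, (chain A and resi 1+3) or (chain B and resi 2)"
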