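"""Geometry, H-bonds, LW/Saenger classification, annotation, multiplets."""

import math
import random

import numpy as np
import pytest
from scipy.optimize import minimize

from extpair.basepair_annotation import (
    ALL_FAMILIES,
    DEFAULT_PARAMS,
    Edge,
    Orientation,
    annotate,
    classify_pair,
    edge_of_atom,
    edges_of_atom,
    find_hbonds,
    fit_base_plane,
    glycosidic_orientation,
)
from extpair.errors import IncompleteBaseError
from extpair.structure_io import Atom, Residue
from extpair.synthetic_fixtures import (
    base_frame,
    extended_strand,
    get_template,
    hairpin,
    ideal_duplex,
    plant_pair,
)


def _residue(base, atoms, chain="A", number=1):
    return Residue(chain_id=chain, number=number, insertion_code="",
                   base_type=base, is_modified=False,
                   atoms=[Atom(name=n, element=n[0], position=p)
                          for n, p in atoms.items()])


def _hexagon(radius=1.4, dz=None):
    coords = {}
    for k, name in enumerate(["N1", "C2", "N3", "C4", "C5", "C6"]):
        a = math.radians(60 * k)
        z = (0.1 if k % 2 == 0 else -0.1) if dz else 0.0
        coords[name] = np.array([radius * math.cos(a), radius * math.sin(a), z])
    return coords


class TestBasePlane:
    def test_flat_ring_normal_and_zero_rms(self):
        normal, centroid, rms = fit_base_plane(_residue("U", _hexagon()))
        assert rms == pytest.approx(0.0, abs=1e-12)
        assert abs(normal[2]) == pytest.approx(1.0)
        np.testing.assert_allclose(centroid[:2], [0, 0], atol=1e-12)

    def test_alternating_displacement_rms_matches_oracle(self):
        """rms equals a brute-force least-squares plane fit of the ring."""
        res = _residue("U", _hexagon(dz=True))
        coords = np.array([a.position for a in res.atoms])

        def sum_sq(x):  # plane: unit normal from angles, offset d
            th, ph, d = x
            n = np.array([math.sin(th) * math.cos(ph),
                          math.sin(th) * math.sin(ph), math.cos(th)])
            return float(((coords @ n - d) ** 2).sum())

        best = min(
            minimize(sum_sq, x0, method="Nelder-Mead").fun
            for x0 in [(0.1, 0.1, 0.0), (1.0, 2.0, 0.5), (2.0, 4.0, -0.5)]
        )
        oracle_rms = math.sqrt(best / len(coords))
        _, _, rms = fit_base_plane(res)
        assert rms == pytest.approx(oracle_rms, abs=1e-6)
        assert rms == pytest.approx(0.1, abs=1e-6)

    def test_too_few_ring_atoms(self):
        atoms = dict(list(_hexagon().items())[:3])
        with pytest.raises(IncompleteBaseError):
            fit_base_plane(_residue("U", atoms))


class TestHBonds:
    def test_canonical_gc_has_three_bonds(self, templates):
        model = templates["cis-WC-WC-GC"].render()
        bonds = find_hbonds(*model.residues)
        atoms = {(hb.atoms_for(model.residues[0]), hb.atoms_for(model.residues[1]))
                 for hb in bonds}
        assert atoms == {("N1", "N3"), ("N2", "O2"), ("O6", "N4")}

    def test_beyond_cutoff_is_empty(self):
        a = _residue("G", {"N1": np.zeros(3)})
        b = _residue("C", {"N3": np.array([4.0, 0, 0])}, chain="B")
        assert find_hbonds(a, b) == []

    def test_cutoff_boundary_is_closed(self):
        a = _residue("G", {"N1": np.zeros(3)})
        b = _residue("C", {"N3": np.array([3.4, 0, 0])}, chain="B")
        bonds = find_hbonds(a, b)
        assert len(bonds) == 1 and bonds[0].distance == pytest.approx(3.4)

    def test_donor_donor_contact_is_not_a_bond(self):
        a = _residue("G", {"N1": np.zeros(3)})          # donor
        b = _residue("U", {"N3": np.array([2.9, 0, 0])}, chain="B")  # donor
        assert find_hbonds(a, b) == []

    def test_non_edge_atoms_do_not_participate(self):
        a = _residue("G", {"N9": np.zeros(3)})
        b = _residue("C", {"N3": np.array([2.9, 0, 0])}, chain="B")
        assert find_hbonds(a, b) == []


class TestEdges:
    @pytest.mark.parametrize("base,atom,expected", [
        ("A", "N1", Edge.WATSON_CRICK),
        ("A", "N7", Edge.HOOGSTEEN),
        ("G", "O2'", Edge.SUGAR),
        ("U", "O4", Edge.WATSON_CRICK),
        ("C", "C5", Edge.HOOGSTEEN),
        ("G", "P", None),
    ])
    def test_primary_edge_lookup(self, base, atom, expected):
        assert edge_of_atom(base, atom) is expected

    def test_unknown_base_raises(self):
        with pytest.raises(ValueError):
            edge_of_atom("X", "N1")

    def test_primary_edges_partition(self):
        """No atom maps to two primary edges within one base type."""
        from extpair.basepair_annotation import _EDGE_TABLE

        for base in "ACGU":
            atoms = [a for b, a in _EDGE_TABLE if b == base]
            assert len(atoms) == len(set(atoms))
            for atom in atoms:
                assert edge_of_atom(base, atom) in Edge

    def test_twelve_families_with_unique_strings(self):
        keys = {f.unordered_key() for f in ALL_FAMILIES}
        strings = {str(f) for f in ALL_FAMILIES}
        assert len(keys) == 12
        assert len(strings) == len(ALL_FAMILIES)


class TestOrientation:
    def _pair_with_dihedral(self, deg):
        a = _residue("A", {
            "N9": np.array([0.0, 0.0, 0.0]),
            "C1'": np.array([-1.0, 1.0, 0.0]),
        })
        rad = math.radians(deg)
        b = _residue("A", {
            "N9": np.array([5.0, 0.0, 0.0]),
            "C1'": np.array([6.0, math.cos(rad), math.sin(rad)]),
        }, chain="B")
        return a, b

    @pytest.mark.parametrize("deg,expected", [
        (0, Orientation.CIS),
        (180, Orientation.TRANS),
        (90, Orientation.CIS),     # boundary closed on CIS
        (91, Orientation.TRANS),
    ])
    def test_dihedral_thresholds(self, deg, expected):
        assert glycosidic_orientation(*self._pair_with_dihedral(deg)) is expected

    def test_missing_nucleoside_atoms(self):
        a = _residue("A", {"N9": np.zeros(3)})
        b = _residue("A", {"N9": np.ones(3), "C1'": np.zeros(3)}, chain="B")
        with pytest.raises(IncompleteBaseError):
            glycosidic_orientation(a, b)


class TestClassifyPair:
    def test_canonical_gc(self, templates):
        model = templates["cis-WC-WC-GC"].render()
        pair = classify_pair(*model.residues)
        assert pair.canonical and str(pair.lw) == "cis W-C/W-C"
        assert pair.n_hbonds == 3 and pair.saenger == "XIX"

    def test_reverse_hoogsteen_ua(self, templates):
        model = templates["trans-WC-Hoogsteen-UA"].render()
        pair = classify_pair(*model.residues)
        assert not pair.canonical
        assert str(pair.lw) == "trans W-C/Hoogsteen"
        assert pair.saenger == "XXIV"

    def test_stacked_bases_rejected_by_stagger(self):
        """Parallel bases 3.0 A apart H-bond vertically but do not pair."""
        u = dict(base_frame("U"))
        a_coords = {n: p + np.array([0, 0, 3.0]) for n, p in base_frame("A").items()}
        res_u = _residue("U", u)
        res_a = _residue("A", a_coords, chain="B")
        assert find_hbonds(res_u, res_a)  # a contact exists...
        assert classify_pair(res_u, res_a) is None  # ...but stagger rejects

    def test_symmetry_under_argument_swap(self, templates):
        model = templates["cis-WC-Sugar-AG"].render()
        fwd = classify_pair(model.residues[0], model.residues[1])
        rev = classify_pair(model.residues[1], model.residues[0])
        assert fwd.lw == rev.lw.swapped()
        assert {hb.distance for hb in fwd.hbonds} == {hb.distance for hb in rev.hbonds}
        assert fwd.saenger == rev.saenger


class TestAnnotate:
    def test_ideal_duplex_counts_and_classes(self):
        rng = random.Random(11)
        for n in (2, 5, 9):
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            result = annotate(ideal_duplex(seq))
            assert len(result.pairs) == n
            assert all(p.canonical and str(p.lw) == "cis W-C/W-C"
                       for p in result.pairs)
            assert result.multiplets == []

    def test_wobble_steps_annotated_xxviii(self):
        model = ideal_duplex("GGCG", partner_seq="UGCC")
        classes = {(p.res_i.base_type, p.res_j.base_type): p.saenger
                   for p in annotate(model).pairs}
        assert classes[("G", "U")] == "XXVIII"

    def test_extended_strand_has_no_pairs(self):
        model = extended_strand("A" * 10)
        # geometry oracle: no inter-residue polar contact within H-bond range
        min_d = min(
            np.linalg.norm(a.position - b.position)
            for ra in model.residues for rb in model.residues if ra is not rb
            for a in ra.atoms for b in rb.atoms
        )
        assert min_d > DEFAULT_PARAMS.hbond_max
        assert annotate(model).pairs == []

    def test_planted_third_base_forms_multiplet(self, templates):
        # stem pair (1,10) is canonical G-C; residue 11 binds G1's free
        # sugar edge -> base triple, reported as one multiplet of 2 pairs
        model = hairpin("GCG", "GAGA", tail_seq="A")
        model = plant_pair(model, 1, 11, templates["cis-Sugar-Hoogsteen-GA"])
        result = annotate(model)
        assert len(result.pairs) == 4
        assert len(result.multiplets) == 1
        member_pairs = {(result.pairs[k].idx_i, result.pairs[k].idx_j)
                        for k in result.multiplets[0]}
        assert member_pairs == {(1, 10), (1, 11)}
        non_members = [p for p in result.pairs if p.multiplet_id is None]
        assert len(non_members) == 2
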