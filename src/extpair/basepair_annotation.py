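"""Geometric base-pair detection and classification.

Pairs are found from heavy-atom hydrogen-bond distances between base-edge
atoms, filtered by coplanarity (inter-plane angle and vertical stagger),
and classified into the 12 Leontis-Westhof geometric families (cis/trans x
Watson-Crick/Hoogsteen/sugar edges).  Saenger classes are assigned from a
packaged taxonomy table keyed by base combination, LW family and H-bond
atom set.  Higher-order associations (triplets and beyond) are reported as
multiplets: connected groups of pairs that share a residue.

No hydrogen positions are used: crystallographic and predicted models
usually lack them, so an H-bond is a donor/acceptor heavy-atom contact
within a distance window (2.4-3.4 A by default).
"""

from __future__ import annotations

import csv
import enum
import itertools
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .errors import IncompleteBaseError
from .structure_io import Residue, StructureModel

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: Glycosidic nitrogen: N9 for purines, N1 for pyrimidines.
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

CANONICAL_COMBOS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


class Edge(enum.Enum):
    WATSON_CRICK = "W-C"
    HOOGSTEEN = "Hoogsteen"
    SUGAR = "Sugar"


class Orientation(enum.Enum):
    CIS = "cis"
    TRANS = "trans"


UNASSIGNED = "UNASSIGNED"

ROMAN_CLASSES = (
    "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI XVII XVIII XIX XX "
    "XXI XXII XXIII XXIV XXV XXVI XXVII XXVIII"
).split()


@dataclass(frozen=True, slots=True)
class LWFamily:
    """A Leontis-Westhof geometric family, ordered 5'->3' by partner."""

    orientation: Orientation
    edge_5p: Edge
    edge_3p: Edge

    def __str__(self) -> str:
        return f"{self.orientation.value} {self.edge_5p.value}/{self.edge_3p.value}"

    def swapped(self) -> "LWFamily":
        return LWFamily(self.orientation, self.edge_3p, self.edge_5p)

    def unordered_key(self) -> tuple[str, frozenset]:
        """Key identifying one of the 12 families irrespective of order."""
        return (self.orientation.value, frozenset({self.edge_5p.value, self.edge_3p.value}))


#: All 12 distinct families (2 orientations x 6 unordered edge combinations).
ALL_FAMILIES: tuple[LWFamily, ...] = tuple(
    LWFamily(o, e1, e2)
    for o in Orientation
    for e1, e2 in itertools.combinations_with_replacement(Edge, 2)
)


@dataclass(frozen=True, slots=True)
class HBond:
    """Heavy-atom donor/acceptor contact between two residues."""

    donor_res: Residue
    donor_atom: str
    acceptor_res: Residue
    acceptor_atom: str
    distance: float

    def atoms_for(self, residue: Residue) -> str:
        if residue is self.donor_res:
            return self.donor_atom
        if residue is self.acceptor_res:
            return self.acceptor_atom
        raise ValueError("residue not part of this H-bond")


@dataclass(slots=True)
class BasePair:
    """An annotated base-base interaction (res_i before res_j globally)."""

    res_i: Residue
    res_j: Residue
    hbonds: list[HBond]
    lw: LWFamily | None
    saenger: str
    canonical: bool
    multiplet_id: int | None = None
    idx_i: int = 0   # 1-based global sequence indices, set by annotate()
    idx_j: int = 0

    @property
    def n_hbonds(self) -> int:
        return len(self.hbonds)

    def bond_atoms(self) -> list[tuple[str, str]]:
        """H-bonded atom names as (atom on res_i, atom on res_j)."""
        return [(hb.atoms_for(self.res_i), hb.atoms_for(self.res_j)) for hb in self.hbonds]


@dataclass(slots=True)
class AnnotationResult:
    pairs: list[BasePair]
    multiplets: list[list[int]] = field(default_factory=list)


@dataclass(slots=True)
class AnnotationParams:
    """Geometric cutoffs; all distances in Angstroms, angles in degrees.

    Annotators in this field disagree in strictness, so every threshold is
    tunable.  Defaults: H-bond window 2.4-3.4 A, inter-plane angle <= 65
    deg, stagger <= 2.5 A, candidate search within 15 A between glycosidic
    nitrogens.
    """

    hbond_min: float = 2.4
    hbond_max: float = 3.4
    max_plane_angle: float = 65.0
    max_stagger: float = 2.5
    neighbor_cutoff: float = 15.0

    def __post_init__(self):
        for name in ("hbond_min", "hbond_max", "max_plane_angle",
                     "max_stagger", "neighbor_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_PARAMS = AnnotationParams()


# ---------------------------------------------------------------------------
# Packaged tables

def _load_edge_table() -> tuple[dict, dict]:
    edges: dict[tuple[str, str], tuple[Edge, ...]] = {}
    roles: dict[tuple[str, str], str] = {}
    text = resources.files("extpair.data").joinpath("edge_atoms.csv").read_text()
    for row in csv.DictReader(text.splitlines()):
        key = (row["base"], row["atom"])
        edges[key] = tuple(Edge(e) for e in row["edges"].split("|"))
        roles[key] = row["role"]
    return edges, roles


_EDGE_TABLE, _ROLE_TABLE = _load_edge_table()


def _load_saenger_table() -> list[dict]:
    text = resources.files("extpair.data").joinpath("saenger.csv").read_text()
    rows = []
    for row in csv.DictReader(text.splitlines()):
        rows.append({
            "class": row["class"],
            "base_i": row["base_i"],
            "base_j": row["base_j"],
            "orientation": Orientation(row["orientation"]),
            "edge_i": Edge(row["edge_i"]),
            "edge_j": Edge(row["edge_j"]),
            "bonds": frozenset(tuple(b.split("-")) for b in row["bonds"].split(";")),
        })
    return rows


_SAENGER_TABLE = _load_saenger_table()


def edges_of_atom(base_type: str, atom_name: str) -> tuple[Edge, ...]:
    """All edges an atom can belong to (shared atoms list two)."""
    if base_type not in RING_ATOMS:
        raise ValueError(f"unknown base type {base_type!r}")
    return _EDGE_TABLE.get((base_type, atom_name), ())

def edge_of_atom(base_type: str, atom_name: str) -> Edge | None:
    """Primary edge of an atom (None for non-edge atoms).

    Atoms shared between two edges report their primary (Watson-Crick
    wherever applicable); classification resolves sharing by partner
    context, see :func:`classify_pair`.
    """
    edges = edges_of_atom(base_type, atom_name)
    return edges[0] if edges else None


# ---------------------------------------------------------------------------
# Geometry

def fit_base_plane(residue: Residue) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through the base ring atoms.

    Returns (unit normal, centroid, rms distance of ring atoms from the
    plane).  Requires at least 4 ring atoms.
    """
    coords = np.array([
        a.position for name in RING_ATOMS[residue.base_type]
        if (a := residue.atom(name)) is not None
    ])
    if len(coords) < 4:
        raise IncompleteBaseError(
            f"residue {residue.label}: {len(coords)} ring atoms (need >= 4)"
        )
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    rms = float(np.sqrt(np.mean(((coords - centroid) @ normal) ** 2)))
    return normal, centroid, rms


def find_hbonds(res_a: Residue, res_b: Residue,
                params: AnnotationParams = DEFAULT_PARAMS) -> list[HBond]:
    """Donor/acceptor heavy-atom contacts between base-edge atoms.

    Only atoms in the edge table participate (the 2'-hydroxyl counts as a
    sugar-edge atom; phosphate and other sugar atoms never pair).  The
    distance window is closed on both ends.
    """
    bonds: list[HBond] = []
    for atom_a in res_a.atoms:
        key_a = (res_a.base_type, atom_a.name)
        role_a = _ROLE_TABLE.get(key_a, "none")
        if role_a == "none" or key_a not in _EDGE_TABLE:
            continue
        for atom_b in res_b.atoms:
            key_b = (res_b.base_type, atom_b.name)
            role_b = _ROLE_TABLE.get(key_b, "none")
            if role_b == "none" or key_b not in _EDGE_TABLE:
                continue
            a_donates = role_a in ("donor", "both") and role_b in ("acceptor", "both")
            b_donates = role_b in ("donor", "both") and role_a in ("acceptor", "both")
            if not (a_donates or b_donates):
                continue
            d = float(np.linalg.norm(atom_a.position - atom_b.position))
            if params.hbond_min <= d <= params.hbond_max:
                if a_donates:
                    bonds.append(HBond(res_a, atom_a.name, res_b, atom_b.name, d))
                else:
                    bonds.append(HBond(res_b, atom_b.name, res_a, atom_a.name, d))
    bonds.sort(key=lambda hb: hb.distance)
    return bonds


def glycosidic_orientation(res_a: Residue, res_b: Residue) -> Orientation:
    """cis/trans from the C1'(a)-N(a)-N(b)-C1'(b) pseudo-dihedral.

    CIS iff the absolute dihedral is <= 90 degrees (closed boundary).
    """
    points = []
    for res, reverse in ((res_a, False), (res_b, True)):
        n_name = GLYCOSIDIC_N[res.base_type]
        c1 = res.atom("C1'")
        gn = res.atom(n_name)
        if c1 is None or gn is None:
            raise IncompleteBaseError(
                f"residue {res.label}: missing C1' or {n_name} (incomplete nucleoside)"
            )
        points.append((gn.position, c1.position) if reverse else (c1.position, gn.position))
    p0, p1 = points[0]
    p2, p3 = points[1]
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n0 = np.cross(b0, b1)
    n1 = np.cross(b1, b2)
    m = np.cross(n0, b1 / (np.linalg.norm(b1) or 1.0))
    angle = math.degrees(math.atan2(float(m @ n1), float(n0 @ n1)))
    return Orientation.CIS if abs(angle) <= 90.0 else Orientation.TRANS


# ---------------------------------------------------------------------------
# Classification

def _resolve_edge(res: Residue, atom_name: str, partner_res: Residue,
                  partner_atoms: list[str]) -> Edge | None:
    """Edge of one participating atom, disambiguating shared atoms.

    An atom listed under both the Watson-Crick and another edge counts as
    Watson-Crick when its H-bond partner can itself be Watson-Crick, and
    as the other edge otherwise.
    """
    edges = edges_of_atom(res.base_type, atom_name)
    if not edges:
        return None
    if len(edges) == 1:
        return edges[0]
    partner_possibly_wc = any(
        Edge.WATSON_CRICK in edges_of_atom(partner_res.base_type, pa)
        for pa in partner_atoms
    )
    if Edge.WATSON_CRICK in edges:
        other = next(e for e in edges if e is not Edge.WATSON_CRICK)
        return Edge.WATSON_CRICK if partner_possibly_wc else other
    return edges[0]


def _majority_edge(res: Residue, partner: Residue, hbonds: list[HBond]) -> Edge:
    """Majority edge over a residue's participating atoms.

    Ties are broken toward the edge of the residue's atom in the shortest
    H-bond (hbonds arrive sorted by distance).
    """
    atom_partners: dict[str, list[str]] = {}
    for hb in hbonds:
        mine, theirs = hb.atoms_for(res), hb.atoms_for(partner)
        atom_partners.setdefault(mine, []).append(theirs)
    votes: dict[Edge, int] = {}
    atom_edges: dict[str, Edge] = {}
    for atom_name, partners in atom_partners.items():
        edge = _resolve_edge(res, atom_name, partner, partners)
        if edge is None:
            continue
        atom_edges[atom_name] = edge
        votes[edge] = votes.get(edge, 0) + 1
    if not votes:
        return Edge.WATSON_CRICK
    best = max(votes.values())
    leaders = [e for e, v in votes.items() if v == best]
    if len(leaders) == 1:
        return leaders[0]
    for hb in hbonds:  # sorted by distance: first resolvable leader wins
        edge = atom_edges.get(hb.atoms_for(res))
        if edge in leaders:
            return edge
    return leaders[0]


def saenger_of(base_i: str, base_j: str, lw: LWFamily,
               bond_atoms: list[tuple[str, str]]) -> str:
    """Saenger class from the packaged taxonomy, or UNASSIGNED.

    A row matches when base combination, orientation and edges agree and
    every H-bond the row requires is present (extra observed bonds are
    allowed).  The most specific matching row (most required bonds) wins.
    """
    observed_fwd = set(bond_atoms)
    observed_rev = {(b, a) for a, b in bond_atoms}
    best: tuple[int, str] | None = None
    for row in _SAENGER_TABLE:
        for bi, bj, ei, ej, observed in (
            (base_i, base_j, lw.edge_5p, lw.edge_3p, observed_fwd),
            (base_j, base_i, lw.edge_3p, lw.edge_5p, observed_rev),
        ):
            if (row["base_i"], row["base_j"]) != (bi, bj):
                continue
            if row["orientation"] is not lw.orientation:
                continue
            if (row["edge_i"], row["edge_j"]) != (ei, ej):
                continue
            if row["bonds"] <= observed:
                cand = (len(row["bonds"]), row["class"])
                if best is None or cand[0] > best[0]:
                    best = cand
    return best[1] if best else UNASSIGNED


def _is_canonical(base_i: str, base_j: str, lw: LWFamily) -> bool:
    return (
        lw.orientation is Orientation.CIS
        and lw.edge_5p is Edge.WATSON_CRICK
        and lw.edge_3p is Edge.WATSON_CRICK
        and (base_i, base_j) in CANONICAL_COMBOS
    )


def classify_pair(res_a: Residue, res_b: Residue,
                  params: AnnotationParams = DEFAULT_PARAMS) -> BasePair | None:
    """Classify one candidate residue pair, or return None.

    A pair requires (a) at least one base-base H-bond, (b) inter-plane
    angle within ``max_plane_angle``, (c) centroid separation along the
    mean normal within ``max_stagger`` (rejects stacked bases).
    """
    if res_a is res_b:
        raise ValueError("cannot pair a residue with itself")
    hbonds = find_hbonds(res_a, res_b, params)
    if not hbonds:
        return None
    try:
        n_a, c_a, _ = fit_base_plane(res_a)
        n_b, c_b, _ = fit_base_plane(res_b)
        orientation = glycosidic_orientation(res_a, res_b)
    except IncompleteBaseError:
        return None
    cosang = abs(float(n_a @ n_b))
    angle = math.degrees(math.acos(min(1.0, cosang)))
    if angle > params.max_plane_angle:
        return None
    n_b_aligned = n_b if float(n_a @ n_b) >= 0 else -n_b
    n_mean = n_a + n_b_aligned
    n_mean = n_mean / np.linalg.norm(n_mean)
    if abs(float((c_b - c_a) @ n_mean)) > params.max_stagger:
        return None

    edge_a = _majority_edge(res_a, res_b, hbonds)
    edge_b = _majority_edge(res_b, res_a, hbonds)
    lw = LWFamily(orientation, edge_a, edge_b)
    pair = BasePair(
        res_i=res_a, res_j=res_b, hbonds=hbonds, lw=lw,
        saenger="", canonical=_is_canonical(res_a.base_type, res_b.base_type, lw),
    )
    pair.saenger = saenger_of(res_a.base_type, res_b.base_type, lw, pair.bond_atoms())
    return pair


def _swap_pair(pair: BasePair) -> BasePair:
    return replace(
        pair,
        res_i=pair.res_j, res_j=pair.res_i,
        lw=pair.lw.swapped() if pair.lw else None,
        idx_i=pair.idx_j, idx_j=pair.idx_i,
    )


def annotate(model: StructureModel,
             params: AnnotationParams = DEFAULT_PARAMS) -> AnnotationResult:
    """Detect and classify all base pairs and multiplets in a model.

    Candidate pairs are residue pairs whose glycosidic nitrogens lie
    within ``neighbor_cutoff``.  Pairs are reported with res_i before
    res_j in global (concatenated-chain) order and carry 1-based global
    sequence indices.
    """
    residues = model.residues
    glyco = []
    for r in residues:
        gn = r.atom(GLYCOSIDIC_N[r.base_type])
        glyco.append(gn.position if gn is not None else None)

    pairs: list[BasePair] = []
    for p in range(len(residues)):
        if glyco[p] is None:
            continue
        for q in range(p + 1, len(residues)):
            if glyco[q] is None:
                continue
            if float(np.linalg.norm(glyco[p] - glyco[q])) > params.neighbor_cutoff:
                continue
            pair = classify_pair(residues[p], residues[q], params)
            if pair is not None:
                pair.idx_i, pair.idx_j = p + 1, q + 1
                pairs.append(pair)

    # multiplets: connected components (>= 2 pairs) of the shares-a-residue graph
    parent = list(range(len(pairs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_residue: dict[int, int] = {}
    for k, pair in enumerate(pairs):
        for idx in (pair.idx_i, pair.idx_j):
            if idx in by_residue:
                ra, rb = find(by_residue[idx]), find(k)
                if ra != rb:
                    parent[rb] = ra
            else:
                by_residue[idx] = k

    groups: dict[int, list[int]] = {}
    for k in range(len(pairs)):
        groups.setdefault(find(k), []).append(k)
    multiplets = sorted(
        (sorted(g) for g in groups.values() if len(g) >= 2),
        key=lambda g: g[0],
    )
    for mid, group in enumerate(multiplets, start=1):
        for k in group:
            pairs[k].multiplet_id = mid
    return AnnotationResult(pairs=pairs, multiplets=multiplets)
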