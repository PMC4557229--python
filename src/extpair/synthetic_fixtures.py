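"""Synthetic PDB-style test structures with known ground truth.

Generates ideal A-form duplexes and hairpins (twist 32.7 deg/bp, rise
2.81 A/bp) from standard planar base geometries, plants non-canonical
pair templates with declared LW families and H-bond atom sets, and adds
seeded Gaussian coordinate noise.  Only the atoms the annotation pipeline
uses are modeled: base ring and exocyclic atoms, C1' and the 2'-hydroxyl;
there is no full backbone, sugar pucker, or refinement.

Every :class:`PairTemplate` is self-consistent by construction: the
partner base is placed by a deterministic in-plane rigid-body fit to the
declared H-bond distances (with clash and spurious-contact penalties) and
the placement is verified by running the annotator on the rendered pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import differential_evolution

from .basepair_annotation import (
    DEFAULT_PARAMS,
    Edge,
    LWFamily,
    Orientation,
    classify_pair,
    find_hbonds,
    glycosidic_orientation,
)
from .structure_io import Atom, Residue, StructureModel

TWIST_DEG = 32.7
RISE = 2.81

#: Planar base geometries (A): standard reference frame, base in z=0.
_FRAMES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.0), "C8": (0.024, 4.897, 0.0),
        "N7": (0.877, 3.902, 0.0), "C5": (0.071, 2.771, 0.0),
        "C6": (0.369, 1.398, 0.0), "N6": (1.611, 0.909, 0.0),
        "N1": (-0.668, 0.532, 0.0), "C2": (-1.912, 1.023, 0.0),
        "N3": (-2.320, 2.290, 0.0), "C4": (-1.267, 3.124, 0.0),
        "C1'": (-2.479, 5.346, 0.0),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.0), "C8": (0.023, 4.962, 0.0),
        "N7": (0.870, 3.969, 0.0), "C5": (0.071, 2.833, 0.0),
        "C6": (0.424, 1.460, 0.0), "O6": (1.554, 0.955, 0.0),
        "N1": (-0.700, 0.641, 0.0), "C2": (-1.999, 1.087, 0.0),
        "N2": (-2.949, 0.139, 0.0), "N3": (-2.342, 2.364, 0.0),
        "C4": (-1.265, 3.177, 0.0),
        "C1'": (-2.477, 5.399, 0.0),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.0), "C2": (-1.472, 3.158, 0.0),
        "O2": (-2.628, 2.709, 0.0), "N3": (-0.391, 2.344, 0.0),
        "C4": (0.837, 2.868, 0.0), "N4": (1.875, 2.027, 0.0),
        "C5": (1.056, 4.275, 0.0), "C6": (-0.023, 5.068, 0.0),
        "C1'": (-2.477, 5.402, 0.0),
    },
    "U": {
        "N1": (-1.284, 4.500, 0.0), "C2": (-1.462, 3.131, 0.0),
        "O2": (-2.563, 2.608, 0.0), "N3": (-0.302, 2.397, 0.0),
        "C4": (0.989, 2.884, 0.0), "O4": (1.935, 2.094, 0.0),
        "C5": (1.089, 4.311, 0.0), "C6": (-0.024, 5.053, 0.0),
        "C1'": (-2.481, 5.354, 0.0),
    },
}

#: 2'-hydroxyl offset from C1' (no explicit ribose is modeled).
_O2P_OFFSET = np.array([-1.0, -0.6, -1.3])

_ELEMENT = {"N": "N", "C": "C", "O": "O"}

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

#: Two-motif K-turn + GNRA-loop construct sequence (31 nt).
_CONSTRUCT = "CGCCUUGGAUUGCGCGAGAGCGCGUCAGGCG"

#: Polar (donor/acceptor-capable) atoms per base used by the template
#: optimizer's spurious-contact penalty; mirrors the packaged edge table.
_POLAR = {
    "A": {"N1": "acceptor", "N6": "donor", "N7": "acceptor", "N3": "acceptor",
          "O2'": "both"},
    "G": {"N1": "donor", "N2": "donor", "O6": "acceptor", "N7": "acceptor",
          "N3": "acceptor", "O2'": "both"},
    "C": {"N3": "acceptor", "O2": "acceptor", "N4": "donor", "O2'": "both"},
    "U": {"N3": "donor", "O2": "acceptor", "O4": "acceptor", "O2'": "both"},
}


def base_frame(base: str) -> dict[str, np.ndarray]:
    """Idealized coordinates of one base (plus C1' and O2')."""
    coords = {name: np.array(xyz) for name, xyz in _FRAMES[base].items()}
    coords["O2'"] = coords["C1'"] + _O2P_OFFSET
    return coords


def _flip(p: np.ndarray) -> np.ndarray:
    return np.array([p[0], -p[1], -p[2]])


def _rot_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _make_residue(base: str, chain: str, number: int,
                  coords: dict[str, np.ndarray]) -> Residue:
    atoms = [
        Atom(name=name, element=_ELEMENT[name[0]], position=pos)
        for name, pos in coords.items()
    ]
    return Residue(chain_id=chain, number=number, insertion_code="",
                   base_type=base, is_modified=False, atoms=atoms)


def _transform(coords: dict[str, np.ndarray], rot: np.ndarray,
               shift: np.ndarray) -> dict[str, np.ndarray]:
    return {name: rot @ p + shift for name, p in coords.items()}


# ---------------------------------------------------------------------------
# Pair templates

@dataclass(frozen=True)
class PairTemplate:
    """An idealized two-base geometry realizing one LW family.

    ``coords_i`` sits in the standard frame; ``coords_j`` is the placed
    partner.  ``expected_hbonds`` lists the designated donor/acceptor atom
    names (atom on base_i, atom on base_j); ``expected_saenger`` is the
    taxonomy class the rendered geometry maps to (possibly UNASSIGNED).
    """

    name: str
    base_i: str
    base_j: str
    lw: LWFamily
    expected_hbonds: tuple[tuple[str, str], ...]
    coords_i: dict[str, np.ndarray]
    coords_j: dict[str, np.ndarray]
    expected_saenger: str = ""

    def render(self, source_id: str = "") -> StructureModel:
        """Two chains of one residue each, in template geometry."""
        res_i = _make_residue(self.base_i, "A", 1, self.coords_i)
        res_j = _make_residue(self.base_j, "B", 1, self.coords_j)
        return StructureModel(chains=["A", "B"], residues=[res_i, res_j],
                              source_id=source_id or self.name)


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n0, n1 = np.cross(b0, b1), np.cross(b1, b2)
    m = np.cross(n0, b1 / (np.linalg.norm(b1) or 1.0))
    return math.degrees(math.atan2(float(m @ n1), float(n0 @ n1)))


def _place_partner(base_i: str, base_j: str, bonds, targets, mirror: bool,
                   orientation: Orientation):
    """Fit the in-plane rigid placement of base_j against bond targets."""
    from .basepair_annotation import GLYCOSIDIC_N

    ci = base_frame(base_i)
    cj0 = base_frame(base_j)
    if mirror:
        cj0 = {n: _flip(p) for n, p in cj0.items()}
    names_j = list(cj0.keys())
    stack_j = np.array([cj0[n] for n in names_j])

    polar_i = [(n, ci[n], _POLAR[base_i][n]) for n in _POLAR[base_i] if n in ci]
    polar_j_idx = [(k, _POLAR[base_j][names_j[k]]) for k in range(len(names_j))
                   if names_j[k] in _POLAR[base_j]]
    designated = set(bonds)
    heavy_i = np.array(list(ci.values()))
    gn_i = ci[GLYCOSIDIC_N[base_i]]
    c1_i = ci["C1'"]
    gn_j_idx = names_j.index(GLYCOSIDIC_N[base_j])
    c1_j_idx = names_j.index("C1'")

    def cost(x):
        rot = _rot_z(math.degrees(x[0]))
        placed = stack_j @ rot.T + np.array([x[1], x[2], 0.0])
        total = 0.0
        for (ai, aj), target in zip(bonds, targets):
            d = np.linalg.norm(ci[ai] - placed[names_j.index(aj)])
            excess = max(0.0, abs(d - target) - 0.25)  # flat-bottom well
            total += 50.0 * excess ** 2
        # glycosidic orientation must come out on the declared side of 90 deg
        dihedral = abs(_dihedral(c1_i, gn_i, placed[gn_j_idx], placed[c1_j_idx]))
        if (dihedral <= 90.0) != (orientation is Orientation.CIS):
            total += 50.0
        # keep the dihedral well-conditioned: neither glycosidic bond may be
        # near-collinear with the N-N axis, or noise flips cis/trans
        axis = placed[gn_j_idx] - gn_i
        axis = axis / np.linalg.norm(axis)
        for bond_vec in (c1_i - gn_i, placed[c1_j_idx] - placed[gn_j_idx]):
            u = bond_vec / np.linalg.norm(bond_vec)
            s = float(np.linalg.norm(np.cross(u, axis)))
            if s < 0.35:
                total += 2000.0 * (0.35 - s) ** 2
        # spurious donor/acceptor contacts below 3.7 A are penalized
        for ni, pi, ri in polar_i:
            for k, rj in polar_j_idx:
                if (ni, names_j[k]) in designated:
                    continue
                compat = (ri in ("donor", "both") and rj in ("acceptor", "both")) or \
                         (rj in ("donor", "both") and ri in ("acceptor", "both"))
                if not compat:
                    continue
                d = np.linalg.norm(pi - placed[k])
                if d < 3.7:
                    total += 10.0 * (3.7 - d) ** 2
        # steric: any heavy-atom pair below 3.0 A
        dmat = np.linalg.norm(heavy_i[:, None, :] - placed[None, :, :], axis=2)
        mask = dmat < 3.0
        for (ai, aj) in bonds:
            mask[list(ci.keys()).index(ai), names_j.index(aj)] = False
        total += 20.0 * float(((3.0 - dmat[mask]) ** 2).sum())
        return total

    res = differential_evolution(
        cost, bounds=[(-math.pi, math.pi), (-9.0, 9.0), (-9.0, 9.0)],
        seed=0, tol=1e-10, maxiter=400, polish=True,
    )
    rot = _rot_z(math.degrees(res.x[0]))
    shift = np.array([res.x[1], res.x[2], 0.0])
    return {n: rot @ p + shift for n, p in cj0.items()}


def _verify_template(t: PairTemplate) -> str:
    """Render, annotate, and require the declared family and bond set."""
    model = t.render()
    res_i, res_j = model.residues
    hbonds = find_hbonds(res_i, res_j, DEFAULT_PARAMS)
    observed = {(hb.atoms_for(res_i), hb.atoms_for(res_j)) for hb in hbonds}
    if observed != set(t.expected_hbonds):
        raise RuntimeError(
            f"template {t.name}: H-bond set {observed} != declared "
            f"{set(t.expected_hbonds)}"
        )
    orientation = glycosidic_orientation(res_i, res_j)
    if orientation is not t.lw.orientation:
        raise RuntimeError(f"template {t.name}: orientation {orientation} wrong")
    pair = classify_pair(res_i, res_j, DEFAULT_PARAMS)
    if pair is None or pair.lw != t.lw:
        raise RuntimeError(
            f"template {t.name}: classified {pair.lw if pair else None}, "
            f"declared {t.lw}"
        )
    return pair.saenger


_WC_SHIFT = {  # fixed placements: flip for cis W-C geometries
    "GC": np.zeros(3), "CG": np.zeros(3), "AU": np.zeros(3), "UA": np.zeros(3),
    "GU": np.array([1.856, 0.10, 0.0]), "UG": np.array([1.856, 0.10, 0.0]),
}

_TEMPLATE_SPECS: tuple[tuple, ...] = (
    # name, base_i, base_j, orientation, edge_i, edge_j, bonds, targets, fixed
    ("cis-WC-WC-GC", "G", "C", "cis", "W-C", "W-C",
     (("N1", "N3"), ("N2", "O2"), ("O6", "N4")), None, True),
    ("cis-WC-WC-AU", "A", "U", "cis", "W-C", "W-C",
     (("N1", "N3"), ("N6", "O4")), None, True),
    ("cis-WC-WC-GU", "G", "U", "cis", "W-C", "W-C",
     (("O6", "N3"), ("N1", "O2")), None, True),
    # reverse Hoogsteen: with coplanar bases the O4-mediated bond set is
    # geometrically cis, so the trans member of this family bonds via O2
    ("trans-WC-Hoogsteen-UA", "U", "A", "trans", "W-C", "Hoogsteen",
     (("N3", "N7"), ("O2", "N6")), (2.7, 3.2), False),
    # the classic sheared G.A (N2-N7, N3-N6) leaves the adenine glycosidic
    # bond collinear with the N9-N9 axis, where the dihedral-based cis/trans
    # measure is degenerate; these two Sugar/Hoogsteen realizations keep the
    # dihedral well-conditioned instead
    ("trans-Sugar-Hoogsteen-GG", "G", "G", "trans", "Sugar", "Hoogsteen",
     (("N2", "N7"), ("O2'", "O6")), (3.0, 3.0), False),
    ("cis-Sugar-Hoogsteen-GA", "G", "A", "cis", "Sugar", "Hoogsteen",
     (("O2'", "N7"), ("N3", "N6")), (2.8, 3.0), False),
    ("trans-WC-WC-GC", "G", "C", "trans", "W-C", "W-C",
     (("N1", "O2"), ("N2", "N3")), (2.9, 2.9), False),
    ("cis-WC-Sugar-AG", "A", "G", "cis", "W-C", "Sugar",
     (("N1", "O2'"), ("N6", "N3")), (2.75, 3.2), False),
)

_TEMPLATES: dict[str, PairTemplate] | None = None


def _build_templates() -> dict[str, PairTemplate]:
    out: dict[str, PairTemplate] = {}
    for name, bi, bj, orient, ei, ej, bonds, targets, fixed in _TEMPLATE_SPECS:
        lw = LWFamily(Orientation(orient), Edge(ei), Edge(ej))
        coords_i = base_frame(bi)
        if fixed:
            shift = _WC_SHIFT[bi + bj]
            coords_j = {n: _flip(p) + shift for n, p in base_frame(bj).items()}
            candidates = [coords_j]
        else:
            candidates = [
                _place_partner(bi, bj, bonds, targets, mirror, lw.orientation)
                for mirror in (False, True)
            ]
        last_error: Exception | None = None
        for coords_j in candidates:
            t = PairTemplate(name=name, base_i=bi, base_j=bj, lw=lw,
                             expected_hbonds=bonds, coords_i=coords_i,
                             coords_j=coords_j)
            try:
                saenger = _verify_template(t)
            except RuntimeError as exc:
                last_error = exc
                continue
            out[name] = PairTemplate(
                name=name, base_i=bi, base_j=bj, lw=lw, expected_hbonds=bonds,
                coords_i=coords_i, coords_j=coords_j, expected_saenger=saenger,
            )
            break
        else:
            raise RuntimeError(f"could not realize template {name}: {last_error}")
    return out


def all_templates() -> dict[str, PairTemplate]:
    """The shipped pair templates (built and self-verified on first use)."""
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = _build_templates()
    return _TEMPLATES


def get_template(name: str) -> PairTemplate:
    templates = all_templates()
    if name not in templates:
        raise KeyError(f"unknown template {name!r}; have {sorted(templates)}")
    return templates[name]


# ---------------------------------------------------------------------------
# Structure generators

def _pair_level_coords(base_a: str, base_b: str, level: int):
    """Coordinates of the two bases of pair ``level`` in an ideal helix.

    Watson-Crick partners share the flipped standard frame; wobble G.U
    steps shear the partner so the O6..N3 / N1..O2 bonds form.
    """
    rot = _rot_z(TWIST_DEG * level)
    shift = np.array([0.0, 0.0, RISE * level])
    if (base_a, base_b) == ("G", "U"):
        wobble = _WC_SHIFT["GU"]
    elif (base_a, base_b) == ("U", "G"):
        wobble = _flip(_WC_SHIFT["GU"]) * -1.0
    else:
        wobble = np.zeros(3)
    ca = _transform(base_frame(base_a), rot, shift)
    cb = _transform({n: _flip(p) + wobble for n, p in base_frame(base_b).items()},
                    rot, shift)
    return ca, cb


def ideal_duplex(seq: str, partner_seq: str | None = None,
                 source_id: str = "duplex") -> StructureModel:
    """Ideal A-form duplex; chain A = ``seq``, chain B its complement.

    ``partner_seq`` (5'->3') overrides the Watson-Crick reverse complement,
    e.g. to introduce GU wobbles; every opposing base combination must be
    pairable (AU, GC or GU).
    """
    seq = seq.upper()
    if not seq or any(b not in COMPLEMENT for b in seq):
        raise ValueError(f"unpairable sequence {seq!r}")
    if partner_seq is None:
        partner = [COMPLEMENT[b] for b in seq]          # partner of seq[k]
    else:
        partner_seq = partner_seq.upper()
        if len(partner_seq) != len(seq):
            raise ValueError("partner_seq length mismatch")
        partner = list(reversed(partner_seq))
        for a, b in zip(seq, partner):
            if (a, b) not in _PAIRABLE:
                raise ValueError(f"unpairable combination {a}-{b}")

    n = len(seq)
    residues: list[Residue] = []
    b_coords: list[dict[str, np.ndarray]] = []
    for k, base in enumerate(seq):
        ca, cb = _pair_level_coords(base, partner[k], k)
        residues.append(_make_residue(base, "A", k + 1, ca))
        b_coords.append(cb)
    for m in range(n):  # chain B runs antiparallel: level n-1 first
        level = n - 1 - m
        residues.append(_make_residue(partner[level], "B", m + 1, b_coords[level]))
    return StructureModel(chains=["A", "B"], residues=residues, source_id=source_id)


def hairpin(stem_seq: str, loop_seq: str, tail_seq: str = "",
            source_id: str = "hairpin") -> StructureModel:
    """Single-chain hairpin: ideal stem, unpaired loop stacked above.

    Residue numbering runs 5'->3': stem 5' arm, loop, stem 3' arm, then an
    optional unpaired 3' tail placed well away from the helix.
    """
    stem_seq, loop_seq = stem_seq.upper(), loop_seq.upper()
    if not loop_seq:
        raise ValueError("loop must contain at least one residue")
    if not stem_seq or any(b not in COMPLEMENT for b in stem_seq):
        raise ValueError(f"unpairable stem {stem_seq!r}")
    s = len(stem_seq)
    residues: list[Residue] = []
    number = 0
    b_coords: list[tuple[str, dict[str, np.ndarray]]] = []
    for k, base in enumerate(stem_seq):
        ca, cb = _pair_level_coords(base, COMPLEMENT[base], k)
        number += 1
        residues.append(_make_residue(base, "A", number, ca))
        b_coords.append((COMPLEMENT[base], cb))
    for m, base in enumerate(loop_seq.upper()):
        level = s + m
        rot = _rot_z(TWIST_DEG * level)
        shift = np.array([0.0, 0.0, RISE * s + 4.0 + RISE * m])
        number += 1
        residues.append(_make_residue(base, "A", number,
                                      _transform(base_frame(base), rot, shift)))
    for level in range(s - 1, -1, -1):
        base, coords = b_coords[level]
        number += 1
        residues.append(_make_residue(base, "A", number, coords))
    for m, base in enumerate(tail_seq.upper()):
        shift = np.array([40.0 + 10.0 * m, 0.0, -10.0])
        number += 1
        residues.append(_make_residue(base, "A", number,
                                      _transform(base_frame(base), np.eye(3), shift)))
    return StructureModel(chains=["A"], residues=residues, source_id=source_id)


def extended_strand(seq: str, source_id: str = "strand") -> StructureModel:
    """Helix-free single strand: bases 10 A apart along x, no contacts."""
    seq = seq.upper()
    if not seq or any(b not in COMPLEMENT for b in seq):
        raise ValueError(f"invalid sequence {seq!r}")
    residues = [
        _make_residue(base, "A", k + 1,
                      _transform(base_frame(base), np.eye(3),
                                 np.array([10.0 * k, 0.0, 0.0])))
        for k, base in enumerate(seq)
    ]
    return StructureModel(chains=["A"], residues=residues, source_id=source_id)


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (rot, shift) minimizing |rot@moving + shift - fixed|."""
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, fc - rot @ mc


def plant_pair(model: StructureModel, i: int, j: int,
               template: PairTemplate) -> StructureModel:
    """Reposition residue ``j`` to pair with residue ``i`` per template.

    ``i`` and ``j`` are 1-based global indices.  Residue ``i`` keeps its
    coordinates (the template frame is mapped onto it); residue ``j`` is
    rebuilt from the template partner; everything else is untouched.
    """
    n = len(model.residues)
    if not (1 <= i <= n and 1 <= j <= n) or i == j:
        raise ValueError(f"indices ({i}, {j}) out of range for {n} residues")
    res_i, res_j = model.residues[i - 1], model.residues[j - 1]
    if res_i.base_type != template.base_i or res_j.base_type != template.base_j:
        raise ValueError(
            f"template {template.name} needs {template.base_i}-{template.base_j}, "
            f"got {res_i.base_type}-{res_j.base_type}"
        )
    common = [n_ for n_ in template.coords_i if res_i.atom(n_) is not None]
    moving = np.array([template.coords_i[n_] for n_ in common])
    fixed = np.array([res_i.atom(n_).position for n_ in common])
    rot, shift = _kabsch(moving, fixed)

    new_residues = []
    for k, res in enumerate(model.residues):
        if k == j - 1:
            atoms = [
                Atom(name=name, element=_ELEMENT[name[0]],
                     position=rot @ pos + shift)
                for name, pos in template.coords_j.items()
            ]
            new_residues.append(Residue(
                chain_id=res.chain_id, number=res.number,
                insertion_code=res.insertion_code, base_type=res.base_type,
                is_modified=res.is_modified, atoms=atoms,
            ))
        else:
            new_residues.append(res)
    return StructureModel(chains=list(model.chains), residues=new_residues,
                          source_id=model.source_id)


def perturb(model: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Isotropic Gaussian coordinate noise of scale sigma, seeded."""
    rng = np.random.default_rng(seed)
    residues = []
    for res in model.residues:
        atoms = [
            Atom(name=a.name, element=a.element,
                 position=a.position + rng.normal(0.0, sigma, 3),
                 occupancy=a.occupancy, alt_loc=a.alt_loc)
            for a in res.atoms
        ]
        residues.append(Residue(
            chain_id=res.chain_id, number=res.number,
            insertion_code=res.insertion_code, base_type=res.base_type,
            is_modified=res.is_modified, atoms=atoms,
        ))
    return StructureModel(chains=list(model.chains), residues=residues,
                          source_id=model.source_id)


def kturn_gnra_construct_sequence() -> str:
    """The 31-nt K-turn-GNRA construct sequence (5'->3')."""
    return _CONSTRUCT
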