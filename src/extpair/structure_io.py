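"""Read and write nucleotide structures in PDB format.

The in-memory model is deliberately small: ordered chains of nucleotide
residues, each residue holding named atoms with coordinates.  Parsing is
delegated to Biopython's ``Bio.PDB`` machinery; this module adds the
nucleotide filtering, modified-residue mapping, alternate-location and
model selection conventions, and a fixed-column writer so that models can
be round-tripped through text.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from .errors import EmptyStructureError, StructureParseError

logger = logging.getLogger(__name__)

#: Standard residue names accepted as unmodified ribonucleotides.
STANDARD_NAMES = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U",
}

#: Modified-residue name -> parent base.  Extensible via
#: :func:`register_modified_residue`; unmapped HETATM residues are dropped
#: with a logged warning.
MODIFIED_PARENT = {
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "UR3": "U", "DHU": "U",
    "1MA": "A", "6MA": "A", "A2M": "A", "MIA": "A", "MA6": "A",
    "5MC": "C", "OMC": "C", "4OC": "C",
    "OMG": "G", "1MG": "G", "2MG": "G", "M2G": "G", "7MG": "G", "YG": "G",
    "I": "G",
}

#: Residue names silently skipped (solvent, common ions).
_SKIP_NAMES = {"HOH", "WAT", "NA", "K", "MG", "CL", "ZN", "MN", "CA", "SO4", "PO4"}


def register_modified_residue(name: str, parent: str) -> None:
    """Extend the modified-residue mapping (``parent`` in A/C/G/U)."""
    if parent not in "ACGU" or len(parent) != 1:
        raise ValueError(f"parent base must be one of A,C,G,U, got {parent!r}")
    MODIFIED_PARENT[name.strip().upper()] = parent


@dataclass(slots=True)
class Atom:
    """A named heavy atom with a position in Angstroms."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass(slots=True)
class Residue:
    """One nucleotide: author numbering plus its atoms.

    ``base_type`` is the parent base (A/C/G/U); ``is_modified`` marks
    residues read from a modified-residue record (e.g. PSU).
    """

    chain_id: str
    number: int
    insertion_code: str
    base_type: str
    is_modified: bool
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        """Human-readable residue tag, e.g. ``A.17``."""
        return f"{self.chain_id}.{self.number}{self.insertion_code}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, *names: str) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)


@dataclass(slots=True)
class StructureModel:
    """Ordered nucleotide chains; residues grouped by chain, file order."""

    chains: list[str]
    residues: list[Residue]
    source_id: str = ""

    def __post_init__(self):
        if not self.residues:
            raise EmptyStructureError("structure contains no nucleotide residues")
        seen: dict[str, tuple[int, str]] = {}
        for r in self.residues:
            if r.chain_id in seen and (r.number, r.insertion_code) <= seen[r.chain_id]:
                raise ValueError(
                    f"residue order not strictly increasing in chain {r.chain_id!r} "
                    f"at {r.number}{r.insertion_code}"
                )
            seen[r.chain_id] = (r.number, r.insertion_code)

    def by_chain(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {c: [] for c in self.chains}
        for r in self.residues:
            out[r.chain_id].append(r)
        return out


def _normalize_atom_name(name: str) -> str:
    # PDB v2 primed names use '*' where v3 uses "'"
    return name.strip().replace("*", "'")


_COORD_FIELDS = ((30, 38, "x"), (38, 46, "y"), (46, 54, "z"))


def _prescan(text: str) -> None:
    """Validate coordinate columns so errors can name the offending line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureParseError("truncated coordinate record", lineno)
        for lo, hi, label in _COORD_FIELDS:
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise StructureParseError(
                    f"malformed {label} coordinate field {fieldtxt!r}", lineno
                ) from None


def _pick_conformer(bp_atom):
    """Highest-occupancy alternate location; ties prefer altloc 'A' / first."""
    if not bp_atom.is_disordered():
        return bp_atom
    children = bp_atom.disordered_get_list()
    return sorted(
        children,
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc() or "~"),
    )[0]


def read_structure(text: str, model_index: int = 1, source_id: str = "") -> StructureModel:
    """Parse PDB text into a nucleotide-only :class:`StructureModel`.

    Only model ``model_index`` (1-based, file order) is read.  Standard
    A/C/G/U residues are kept as-is; HETATM residues with a known parent
    base are kept with ``is_modified=True``; everything else (waters,
    ions, protein, unmapped ligands) is skipped.
    """
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise StructureParseError("no ATOM/HETATM records in input")
    _prescan(text)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            structure = parser.get_structure(source_id or "model", io.StringIO(text))
        except StructureParseError:
            raise
        except Exception as exc:  # Bio.PDB raises assorted exception types
            raise StructureParseError(f"PDB parse failed: {exc}") from exc

    models = list(structure.get_models())
    if model_index < 1 or model_index > len(models):
        raise StructureParseError(
            f"model_index {model_index} out of range (file has {len(models)} model(s))"
        )
    model = models[model_index - 1]

    chains: list[str] = []
    residues: list[Residue] = []
    for chain in model:
        chain_res: list[Residue] = []
        for res in chain:
            resname = res.get_resname().strip().upper()
            hetflag, number, icode = res.get_id()
            icode = icode.strip()
            if resname in _SKIP_NAMES:
                continue
            if resname in STANDARD_NAMES:
                base, modified = STANDARD_NAMES[resname], False
            elif resname in MODIFIED_PARENT:
                base, modified = MODIFIED_PARENT[resname], True
            else:
                if hetflag.strip():
                    logger.warning("dropping unmapped HETATM residue %s %s%s",
                                   resname, number, icode)
                continue
            atoms: list[Atom] = []
            names_seen: set[str] = set()
            for bp_atom in res.get_list():
                a = _pick_conformer(bp_atom)
                name = _normalize_atom_name(a.get_name())
                if name in names_seen:
                    continue
                names_seen.add(name)
                atoms.append(Atom(
                    name=name,
                    element=(a.element or "").strip(),
                    position=np.array(a.get_coord(), dtype=float),
                    occupancy=float(a.get_occupancy() or 1.0),
                    alt_loc=(a.get_altloc() or "").strip(),
                ))
            if atoms:
                chain_res.append(Residue(
                    chain_id=chain.id.strip() or "A",
                    number=int(number),
                    insertion_code=icode,
                    base_type=base,
                    is_modified=modified,
                    atoms=atoms,
                ))
        if chain_res:
            chain_res.sort(key=lambda r: (r.number, r.insertion_code))
            chains.append(chain_res[0].chain_id)
            residues.extend(chain_res)

    if not residues:
        raise EmptyStructureError("structure contains no nucleotide residues")
    return StructureModel(chains=chains, residues=residues, source_id=source_id)


def sequence_of(model: StructureModel) -> list[tuple[str, str]]:
    """One (chain_id, sequence) per chain; modified residues lowercase."""
    out = []
    for chain, residues in model.by_chain().items():
        seq = "".join(
            r.base_type.lower() if r.is_modified else r.base_type for r in residues
        )
        out.append((chain, seq))
    return out


def write_structure(model: StructureModel) -> str:
    """Serialize a model back to fixed-column PDB text (single model)."""
    lines: list[str] = []
    serial = 0
    for chain, residues in model.by_chain().items():
        for r in residues:
            record = "HETATM" if r.is_modified else "ATOM"
            resname = r.base_type
            for a in r.atoms:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name}"
                lines.append(
                    f"{record:<6}{serial:>5} {name:<4}{'':1}{resname:>3} "
                    f"{chain:1}{r.number:>4}{r.insertion_code or ' ':1}   "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2}"
                )
        serial += 1
        lines.append(f"{'TER':<6}{serial:>5}")
    lines.append("END")
    return "\n".join(lines) + "\n"
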