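"""Structure parsing and the binding-pocket rule.

Proteins are read from PDB files (Bio.PDB), ligands from SDF or MOL2 files
(RDKit).  Both are merged into a single flat atom table (:class:`Complex`)
with a ligand/receptor flag per atom, which is what the graph featurizer
consumes.  The binding pocket is the set of protein atoms whose minimum
distance to any ligand atom is at most a cutoff radius (default 6 Angstrom);
the rest of the protein is discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import EmptyInputError, EmptyPocketError, FormatError

__all__ = [
    "AtomRecord",
    "Complex",
    "read_complex",
    "extract_pocket",
    "assign_hbond_role",
    "write_atom_table",
    "read_atom_table",
    "DEFAULT_POCKET_RADIUS",
]

DEFAULT_POCKET_RADIUS = 6.0

#: Hydrogen-bond roles of protein atoms, keyed by (residue, atom name).
#: Backbone amide N donates; backbone carbonyl O accepts.  Side chains follow
#: standard residue templates.  Anything not listed gets role "none".
_BACKBONE_ROLES = {"N": "donor", "O": "acceptor", "OXT": "acceptor"}
_SIDECHAIN_ROLES = {
    ("SER", "OG"): "both",
    ("THR", "OG1"): "both",
    ("TYR", "OH"): "both",
    ("CYS", "SG"): "none",
    ("ASN", "OD1"): "acceptor",
    ("ASN", "ND2"): "donor",
    ("GLN", "OE1"): "acceptor",
    ("GLN", "NE2"): "donor",
    ("ASP", "OD1"): "acceptor",
    ("ASP", "OD2"): "acceptor",
    ("GLU", "OE1"): "acceptor",
    ("GLU", "OE2"): "acceptor",
    ("LYS", "NZ"): "donor",
    ("ARG", "NE"): "donor",
    ("ARG", "NH1"): "donor",
    ("ARG", "NH2"): "donor",
    ("HIS", "ND1"): "both",
    ("HIS", "NE2"): "both",
    ("TRP", "NE1"): "donor",
    ("MET", "SD"): "none",
}

#: Element-based roles for ligand atoms: without protonation information,
#: nitrogens and oxygens are treated as ambivalent polar atoms.
_LIGAND_ELEMENT_ROLES = {"N": "both", "O": "both"}

_WATER_RESNAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a protein-ligand complex."""

    atom_id: int
    element: str
    position: tuple
    is_ligand: bool
    residue_name: str = ""
    residue_index: int = -1
    chain: str = ""
    atom_name: str = ""
    hbond_role: str = "none"

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: non-finite position")
        if self.hbond_role not in ("donor", "acceptor", "both", "none"):
            raise ValueError(f"atom {self.atom_id}: bad hbond_role "
                             f"{self.hbond_role!r}")

    @property
    def key(self):
        """Cross-structure protein-atom identity (chain, residue, atom name)."""
        return (self.chain, self.residue_index, self.atom_name)


@dataclass
class Complex:
    """An ordered atom table for one bound structure."""

    complex_id: str
    atoms: list = field(default_factory=list)
    pocket_applied: bool = False

    def __post_init__(self):
        ids = [a.atom_id for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate atom_ids in complex")
        if not any(a.is_ligand for a in self.atoms):
            raise EmptyInputError(
                f"complex {self.complex_id!r} has no ligand atoms")

    def __len__(self):
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def is_ligand(self) -> np.ndarray:
        return np.array([a.is_ligand for a in self.atoms], dtype=bool)

    @property
    def ligand_atoms(self):
        return [a for a in self.atoms if a.is_ligand]

    @property
    def protein_atoms(self):
        return [a for a in self.atoms if not a.is_ligand]

    def atom_by_id(self, atom_id: int) -> AtomRecord:
        for atom in self.atoms:
            if atom.atom_id == atom_id:
                return atom
        raise KeyError(atom_id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "Complex":
        """Return a copy with all positions rigidly moved."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        atoms = [
            replace(a, position=tuple(rotation @ np.asarray(a.position)
                                      + translation))
            for a in self.atoms
        ]
        return Complex(self.complex_id, atoms, self.pocket_applied)


def _normalize_element(symbol: str) -> str:
    symbol = symbol.strip()
    if not symbol:
        return ""
    return symbol[0].upper() + symbol[1:].lower()


def assign_hbond_role(element: str, atom_name: str, residue_name: str,
                      is_ligand: bool) -> str:
    """Donor/acceptor assignment from the fixed rule table.

    Protein atoms are looked up by backbone atom name and then by
    (residue, atom name); ligand atoms by element.  Defaults to ``none``.
    """
    if is_ligand:
        return _LIGAND_ELEMENT_ROLES.get(element, "none")
    if atom_name in _BACKBONE_ROLES:
        return _BACKBONE_ROLES[atom_name]
    return _SIDECHAIN_ROLES.get((residue_name, atom_name), "none")


def _read_protein_pdb(path, keep_hydrogens: bool, keep_waters: bool) -> list:
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("protein", str(path))
    except (PDBConstructionException, ValueError, KeyError) as exc:
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc

    records = []
    model = next(structure.get_models(), None)
    if model is None:
        raise FormatError(f"PDB file {path} contains no model")
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            if resname in _WATER_RESNAMES and not keep_waters:
                continue
            for atom in residue:
                # Disordered atoms: Bio.PDB exposes the highest-occupancy
                # conformer as the selected child; iterate only that one.
                element = _normalize_element(atom.element or atom.get_name()[0])
                if element == "H" and not keep_hydrogens:
                    continue
                records.append(dict(
                    element=element,
                    position=tuple(float(v) for v in atom.get_coord()),
                    residue_name=resname,
                    residue_index=int(residue.get_id()[1]),
                    chain=str(chain.get_id()),
                    atom_name=atom.get_name().strip(),
                ))
    return records


def _read_ligand(path, keep_hydrogens: bool) -> list:
    from rdkit import Chem

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False,
                                      removeHs=False)
        mol = next(iter(supplier), None)
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    else:
        raise FormatError(f"unsupported ligand format {suffix!r} for {path}")
    if mol is None:
        raise FormatError(f"could not parse ligand file {path}")
    if mol.GetNumConformers() == 0 or mol.GetNumAtoms() == 0:
        raise EmptyInputError(f"ligand file {path} contains no atoms")

    conformer = mol.GetConformer()
    records = []
    for atom in mol.GetAtoms():
        element = _normalize_element(atom.GetSymbol())
        if element == "H" and not keep_hydrogens:
            continue
        pos = conformer.GetAtomPosition(atom.GetIdx())
        records.append(dict(
            element=element,
            position=(float(pos.x), float(pos.y), float(pos.z)),
            atom_name=f"{element}{atom.GetIdx() + 1}",
        ))
    if not records:
        raise EmptyInputError(f"ligand file {path} has no heavy atoms")
    return records


def read_complex(protein_path, ligand_path, keep_hydrogens: bool = False,
                 keep_waters: bool = False, complex_id: str | None = None
                 ) -> Complex:
    """Merge a protein PDB file and a ligand SDF/MOL2 file into one Complex.

    Ligand atoms come first in the atom order.  Element symbols are
    normalized to standard capitalization and hydrogen-bond roles assigned
    from the rule table.  Raises :class:`FormatError` for unparseable files
    and :class:`EmptyInputError` when either side has no atoms left.
    """
    ligand_records = _read_ligand(ligand_path, keep_hydrogens)
    protein_records = _read_protein_pdb(protein_path, keep_hydrogens,
                                        keep_waters)
    if not protein_records:
        raise EmptyInputError(
            f"protein file {protein_path} has no atoms after filtering")

    atoms = []
    for i, rec in enumerate(ligand_records):
        atoms.append(AtomRecord(
            atom_id=i, element=rec["element"], position=rec["position"],
            is_ligand=True, atom_name=rec["atom_name"],
            hbond_role=assign_hbond_role(rec["element"], rec["atom_name"],
                                         "", True)))
    offset = len(atoms)
    for i, rec in enumerate(protein_records):
        atoms.append(AtomRecord(
            atom_id=offset + i, element=rec["element"],
            position=rec["position"], is_ligand=False,
            residue_name=rec["residue_name"],
            residue_index=rec["residue_index"], chain=rec["chain"],
            atom_name=rec["atom_name"],
            hbond_role=assign_hbond_role(rec["element"], rec["atom_name"],
                                         rec["residue_name"], False)))

    if complex_id is None:
        complex_id = Path(protein_path).stem
    return Complex(complex_id, atoms)


def extract_pocket(complex_: Complex, radius: float = DEFAULT_POCKET_RADIUS
                   ) -> Complex:
    """Keep all ligand atoms and protein atoms within ``radius`` of any
    ligand atom (closed boundary).

    Atom order is preserved.  Raises :class:`EmptyPocketError` when no
    protein atom is within reach, reporting the closest observed distance.
    """
    if radius <= 0:
        raise ValueError(f"pocket radius must be positive, got {radius}")
    ligand_pos = np.array([a.position for a in complex_.ligand_atoms])
    if ligand_pos.size == 0:
        raise EmptyInputError("complex has no ligand atoms")

    kept = []
    min_seen = np.inf
    for atom in complex_.atoms:
        if atom.is_ligand:
            kept.append(atom)
            continue
        dist = float(np.min(np.linalg.norm(
            ligand_pos - np.asarray(atom.position), axis=1)))
        min_seen = min(min_seen, dist)
        if dist <= radius:
            kept.append(atom)

    if all(a.is_ligand for a in kept):
        raise EmptyPocketError(
            f"no protein atom within {radius} A of the ligand "
            f"(closest at {min_seen:.2f} A)")
    return Complex(complex_.complex_id, kept, pocket_applied=True)


# -- inspection IO -------------------------------------------------------

def write_atom_table(complex_: Complex, path) -> None:
    """Write the Complex as a JSON-lines atom table."""
    with open(path, "w") as handle:
        header = {"complex_id": complex_.complex_id,
                  "pocket_applied": complex_.pocket_applied}
        handle.write(json.dumps(header) + "\n")
        for atom in complex_.atoms:
            handle.write(json.dumps({
                "atom_id": atom.atom_id, "element": atom.element,
                "position": list(atom.position),
                "is_ligand": atom.is_ligand,
                "residue_name": atom.residue_name,
                "residue_index": atom.residue_index, "chain": atom.chain,
                "atom_name": atom.atom_name, "hbond_role": atom.hbond_role,
            }) + "\n")


def read_atom_table(path) -> Complex:
    with open(path) as handle:
        header = json.loads(handle.readline())
        atoms = []
        for line in handle:
            rec = json.loads(line)
            rec["position"] = tuple(rec["position"])
            atoms.append(AtomRecord(**rec))
    return Complex(header["complex_id"], atoms, header["pocket_applied"])


def write_pdb(complex_: Complex, path, protein_only: bool = True) -> None:
    """Write protein atoms in PDB format (fixed-width ATOM records).

    Used to round-trip synthetic complexes through the standard parsers;
    ligand atoms are written separately as SDF.
    """
    with open(path, "w") as handle:
        serial = 1
        for atom in complex_.atoms:
            if atom.is_ligand and protein_only:
                continue
            x, y, z = atom.position
            name = atom.atom_name[:4]
            resname = (atom.residue_name or "UNK")[:3]
            chain = (atom.chain or "A")[:1]
            handle.write(
                f"ATOM  {serial:>5d} {name:<4s} {resname:<3s} {chain}"
                f"{atom.residue_index:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}\n")
            serial += 1
        handle.write("END\n")


def write_ligand_sdf(complex_: Complex, path) -> None:
    """Write ligand atoms as a bond-less SDF molecule via RDKit."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    conf_positions = []
    for atom in complex_.ligand_atoms:
        rd_atom = Chem.Atom(atom.element)
        rd_atom.SetNoImplicit(True)
        mol.AddAtom(rd_atom)
        conf_positions.append(atom.position)
    conformer = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(conf_positions):
        conformer.SetAtomPosition(i, Point3D(x, y, z))
    mol.AddConformer(conformer)
    with Chem.SDWriter(str(path)) as writer:
        writer.write(mol.GetMol())
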