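"""Structure input/output and normalisation.

Reads protein structures from PDB files and ligand molecules from SYBYL
Mol2 or SDF files, assigns van der Waals radii, infers covalent bonds
and defines the ligand binding pocket. All coordinates are in Angstrom.

Mol2 is the preferred ligand format because it carries SYBYL atom types
verbatim; these type strings are part of the interaction-unit type keys
and must not be re-perceived. For SDF input, SYBYL types are assigned
from element and hybridisation by a small perception table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "ProteinStructure",
    "LigandMolecule",
    "ComplexRecord",
    "PDBParseError",
    "EmptyStructureError",
    "read_protein_pdb",
    "read_ligand",
    "write_ligand_mol2",
    "assign_vdw_radii",
    "define_pocket",
    "read_library_index",
    "load_complex",
    "BONDI_RADII",
    "DEFAULT_VDW_RADIUS",
    "STANDARD_RESIDUES",
    "RESIDUE_BOND_TEMPLATES",
]


# Bondi (1964) van der Waals radii, Angstrom.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "B": 1.92, "SI": 2.10,
}
DEFAULT_VDW_RADIUS = 1.70

# Single-bond covalent radii for the distance-fallback bond perception.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
}
_BOND_TOLERANCE = 0.45  # Angstrom added to covalent-radius sum

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

# Heavy-atom side-chain connectivity of the 20 standard amino acids.
RESIDUE_BOND_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CA", "CB")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
}

# SYBYL atom types accepted verbatim; anything else is downgraded to "Any".
_SYBYL_TYPES = {
    "C.3", "C.2", "C.1", "C.ar", "C.cat",
    "N.3", "N.2", "N.1", "N.ar", "N.am", "N.pl3", "N.4",
    "O.3", "O.2", "O.co2", "O.spc", "O.t3p",
    "S.3", "S.2", "S.O", "S.o", "S.O2", "S.o2",
    "P.3", "H", "H.spc", "H.t3p",
    "F", "Cl", "Br", "I", "Li", "Na", "K", "Mg", "Ca", "Al", "Si",
    "Zn", "Fe", "Mn", "Cu", "Se", "B", "Du", "LP", "Any",
}


class PDBParseError(ValueError):
    """A PDB record could not be parsed."""


class EmptyStructureError(ValueError):
    """A structure file yielded no usable atoms."""


@dataclass
class Atom:
    """One heavy atom or hydrogen of a protein or ligand.

    ``residue_name``/``residue_id`` are set for protein atoms only;
    ``sybyl_type`` for ligand atoms only.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    sybyl_type: Optional[str] = None
    vdw_radius: Optional[float] = None
    residue_name: Optional[str] = None
    residue_id: Optional[tuple[str, int, str]] = None
    is_hydrogen: bool = False
    nonstandard: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")


@dataclass
class ProteinStructure:
    atoms: list[Atom] = field(default_factory=list)
    bonds: set[frozenset[int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._by_serial = {a.serial: a for a in self.atoms}

    @property
    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out

    def atom(self, serial: int) -> Atom:
        return self._by_serial[serial]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def calpha(self, residue_id: tuple[str, int, str]) -> Optional[Atom]:
        for a in self.residues.get(residue_id, []):
            if a.name == "CA" and not a.is_hydrogen:
                return a
        return None

    def residue_bond_graph(
        self, residue_id: tuple[str, int, str]
    ) -> dict[int, set[int]]:
        """Adjacency (by serial) restricted to heavy atoms of one residue."""
        serials = {a.serial for a in self.residues[residue_id]
                   if not a.is_hydrogen}
        adj: dict[int, set[int]] = {s: set() for s in serials}
        for bond in self.bonds:
            s1, s2 = tuple(bond)
            if s1 in serials and s2 in serials:
                adj[s1].add(s2)
                adj[s2].add(s1)
        return adj


@dataclass
class LigandMolecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    name: str = "LIG"

    def __post_init__(self) -> None:
        if self.atoms and not any(not a.is_hydrogen for a in self.atoms):
            raise EmptyStructureError("ligand has no heavy atoms")
        for a in self.atoms:
            if a.sybyl_type is None:
                raise ValueError(f"ligand atom {a.serial} lacks a SYBYL type")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class ComplexRecord:
    """A protein-ligand complex, optionally with its experimental affinity
    as a binding constant in logarithmic units (-logKd / -logKi / -logIC50,
    treated interchangeably)."""

    complex_id: str
    protein: ProteinStructure
    ligand: LigandMolecule
    affinity: Optional[float] = None


# ---------------------------------------------------------------------------
# PDB reading


def _scan_pdb_lines(path: Path) -> None:
    """Cheap pre-validation so malformed records fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError):
                    raise PDBParseError(
                        f"{path}: malformed coordinate record at line {lineno}"
                    ) from None


def read_protein_pdb(path: str | Path) -> ProteinStructure:
    """Read a protein from a PDB file.

    Only polymer (ATOM) residues are kept; waters and hetero groups are
    ignored. For alternate locations the highest-occupancy conformer is
    retained (ties: first encountered). Hydrogens are kept but flagged.
    Covalent bonds are inferred from residue templates for the 20
    standard amino acids, with a covalent-distance fallback for anything
    the templates do not cover, plus peptide and disulfide links.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _scan_pdb_lines(path)

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("protein", str(path))
    except Exception as exc:  # pragma: no cover - biopython internals
        raise PDBParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    model = next(structure.get_models(), None)
    if model is not None:
        for chain in model:
            for residue in chain:
                hetflag, resseq, icode = residue.id
                if hetflag.strip():
                    continue  # waters / hetero groups are not the protein
                resname = residue.get_resname().strip()
                rid = (chain.id, resseq, icode.strip())
                for batom in residue:
                    # Bio.PDB's disordered atoms already select the
                    # highest-occupancy altLoc (first on ties).
                    element = (batom.element or "").strip().upper()
                    if not element:
                        element = batom.get_name().strip()[:1].upper()
                    atoms.append(
                        Atom(
                            serial=batom.get_serial_number(),
                            name=batom.get_name().strip(),
                            element=element,
                            coords=np.array(batom.get_coord(), dtype=float),
                            residue_name=resname,
                            residue_id=rid,
                            is_hydrogen=element in ("H", "D"),
                            nonstandard=resname not in STANDARD_RESIDUES,
                        )
                    )
    if not atoms:
        raise EmptyStructureError(f"{path}: no polymer atoms found")

    protein = ProteinStructure(atoms=atoms)
    protein.bonds = _infer_protein_bonds(protein)
    return protein


def _infer_protein_bonds(protein: ProteinStructure) -> set[frozenset[int]]:
    bonds: set[frozenset[int]] = set()
    residues = protein.residues

    for rid, ratoms in residues.items():
        heavy = {a.name: a for a in ratoms if not a.is_hydrogen}
        resname = ratoms[0].residue_name
        template = None
        if resname in STANDARD_RESIDUES:
            template = _BACKBONE_BONDS + RESIDUE_BOND_TEMPLATES[resname]
        if template is not None:
            covered = set()
            for n1, n2 in template:
                if n1 in heavy and n2 in heavy:
                    bonds.add(frozenset((heavy[n1].serial, heavy[n2].serial)))
                    covered.update((n1, n2))
            leftovers = [a for n, a in heavy.items() if n not in covered]
        else:
            leftovers = list(heavy.values())
        # Distance fallback for atoms the template did not connect.
        if leftovers:
            others = [a for a in ratoms if not a.is_hydrogen]
            for a in leftovers:
                for b in others:
                    if a.serial >= b.serial:
                        continue
                    if _covalent_cutoff(a, b) > _dist(a, b):
                        bonds.add(frozenset((a.serial, b.serial)))

    # Peptide bonds C(i)-N(i+1) and disulfides, by distance.
    carbons = [a for a in protein.atoms if a.name == "C" and not a.is_hydrogen]
    nitros = {a.residue_id: a for a in protein.atoms if a.name == "N"}
    for c in carbons:
        for rid, n in nitros.items():
            if rid == c.residue_id:
                continue
            if _dist(c, n) < 1.9:
                bonds.add(frozenset((c.serial, n.serial)))
    sulfurs = [a for a in protein.atoms if a.name == "SG"]
    for i, s1 in enumerate(sulfurs):
        for s2 in sulfurs[i + 1:]:
            if _dist(s1, s2) < 2.5:
                bonds.add(frozenset((s1.serial, s2.serial)))
    return bonds


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.coords - b.coords))


def _covalent_cutoff(a: Atom, b: Atom) -> float:
    ra = _COVALENT_RADII.get(a.element.upper(), 0.76)
    rb = _COVALENT_RADII.get(b.element.upper(), 0.76)
    return ra + rb + _BOND_TOLERANCE


# ---------------------------------------------------------------------------
# Ligand reading / writing


def read_ligand(path: str | Path, format: Optional[str] = None) -> LigandMolecule:
    """Read a ligand from a Mol2 or SDF file.

    SYBYL atom types are taken verbatim from Mol2; unknown type strings
    are recorded as ``"Any"`` with a warning. For SDF, types are
    perceived from element + hybridisation (see :func:`perceive_sybyl_type`).
    """
    path = Path(path)
    if format is None:
        format = "sdf" if path.suffix.lower() in (".sdf", ".sd", ".mol") else "mol2"
    if format == "mol2":
        return _read_mol2(path)
    if format == "sdf":
        return _read_sdf(path)
    raise ValueError(f"unknown ligand format: {format!r}")


def _read_mol2(path: Path) -> LigandMolecule:
    atoms: list[Atom] = []
    bonds: list[tuple[int, int, str]] = []
    name = path.stem
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("@<TRIPOS>"):
                section = line[9:].strip().upper()
                mol_line = 0
                continue
            if not line.strip() or line.startswith("#"):
                continue
            if section == "MOLECULE":
                mol_line += 1
                if mol_line == 1:
                    name = line.strip() or name
            elif section == "ATOM":
                parts = line.split()
                if len(parts) < 6:
                    raise ValueError(
                        f"{path}: malformed Mol2 ATOM record at line {lineno}")
                serial = int(parts[0])
                aname = parts[1]
                x, y, z = (float(parts[2]), float(parts[3]), float(parts[4]))
                styp = parts[5]
                if styp not in _SYBYL_TYPES:
                    warnings.warn(
                        f"{path}: unknown SYBYL atom type {styp!r} for atom "
                        f"{serial}; recorded as 'Any'")
                    styp = "Any"
                element = styp.split(".")[0].upper()
                atoms.append(Atom(
                    serial=serial, name=aname, element=element,
                    coords=(x, y, z), sybyl_type=styp,
                    is_hydrogen=element == "H"))
            elif section == "BOND":
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(
                        f"{path}: malformed Mol2 BOND record at line {lineno}")
                bonds.append((int(parts[1]), int(parts[2]), parts[3]))
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms in Mol2 file")
    return LigandMolecule(atoms=atoms, bonds=bonds, name=name)


def _read_sdf(path: Path) -> LigandMolecule:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise EmptyStructureError(f"{path}: no parseable molecule in SDF")
    if mol.GetNumAtoms() == 0:
        raise EmptyStructureError(f"{path}: zero-atom molecule")
    conf = mol.GetConformer()
    atoms: list[Atom] = []
    for rd_atom in mol.GetAtoms():
        idx = rd_atom.GetIdx()
        pos = conf.GetAtomPosition(idx)
        element = rd_atom.GetSymbol()
        styp = perceive_sybyl_type(rd_atom)
        atoms.append(Atom(
            serial=idx + 1,
            name=f"{element}{idx + 1}",
            element=element.upper(),
            coords=(pos.x, pos.y, pos.z),
            sybyl_type=styp,
            is_hydrogen=element.upper() == "H"))
    bonds = [(b.GetBeginAtomIdx() + 1, b.GetEndAtomIdx() + 1,
              _rd_bond_code(b)) for b in mol.GetBonds()]
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem
    return LigandMolecule(atoms=atoms, bonds=bonds, name=name or path.stem)


def _rd_bond_code(bond) -> str:
    from rdkit import Chem

    if bond.GetIsAromatic():
        return "ar"
    order = bond.GetBondType()
    return {Chem.BondType.SINGLE: "1", Chem.BondType.DOUBLE: "2",
            Chem.BondType.TRIPLE: "3"}.get(order, "1")


def perceive_sybyl_type(rd_atom) -> str:
    """Assign a SYBYL atom type from element and hybridisation.

    Perception table (RDKit hybridisation): C sp3/sp2/sp/aromatic ->
    C.3/C.2/C.1/C.ar; N aromatic -> N.ar, amide N -> N.am, quaternary ->
    N.4, otherwise by hybridisation; O with a double bond -> O.2,
    carboxylate O -> O.co2, otherwise O.3; S with two bonded O -> S.o2,
    one -> S.o, double bond -> S.2, else S.3; P -> P.3; halogens and
    metals by element symbol; anything unrecognised -> "Any".
    """
    from rdkit import Chem

    sym = rd_atom.GetSymbol()
    hyb = rd_atom.GetHybridization()
    H = Chem.HybridizationType
    if sym == "H":
        return "H"
    if sym == "C":
        if rd_atom.GetIsAromatic():
            return "C.ar"
        return {H.SP3: "C.3", H.SP2: "C.2", H.SP: "C.1"}.get(hyb, "C.3")
    if sym == "N":
        if rd_atom.GetIsAromatic():
            return "N.ar"
        if rd_atom.GetTotalDegree() == 4:
            return "N.4"
        for nbr in rd_atom.GetNeighbors():
            if nbr.GetSymbol() == "C":
                for b in nbr.GetBonds():
                    other = b.GetOtherAtom(nbr)
                    if (other.GetSymbol() == "O"
                            and b.GetBondType() == Chem.BondType.DOUBLE):
                        return "N.am"
        return {H.SP3: "N.3", H.SP2: "N.2", H.SP: "N.1"}.get(hyb, "N.3")
    if sym == "O":
        double = any(b.GetBondType() == Chem.BondType.DOUBLE
                     for b in rd_atom.GetBonds())
        if double or rd_atom.GetIsAromatic():
            # carboxylate oxygens share type O.co2
            for nbr in rd_atom.GetNeighbors():
                if nbr.GetSymbol() == "C":
                    n_o = sum(1 for b in nbr.GetBonds()
                              if b.GetOtherAtom(nbr).GetSymbol() == "O"
                              and b.GetOtherAtom(nbr).GetTotalDegree() == 1)
                    if n_o == 2:
                        return "O.co2"
            return "O.2"
        return "O.3"
    if sym == "S":
        n_oxo = sum(1 for nbr in rd_atom.GetNeighbors()
                    if nbr.GetSymbol() == "O" and nbr.GetTotalDegree() == 1)
        if n_oxo >= 2:
            return "S.o2"
        if n_oxo == 1:
            return "S.o"
        double = any(b.GetBondType() == Chem.BondType.DOUBLE
                     for b in rd_atom.GetBonds())
        return "S.2" if double else "S.3"
    if sym == "P":
        return "P.3"
    if sym in ("F", "Cl", "Br", "I", "Li", "Na", "K", "Mg", "Ca", "Al",
               "Si", "Zn", "Fe", "Mn", "Cu", "Se", "B"):
        return sym
    warnings.warn(f"no SYBYL type perception for element {sym!r}; using 'Any'")
    return "Any"


def write_ligand_mol2(ligand: LigandMolecule, path: str | Path) -> None:
    """Write a ligand as a SYBYL Mol2 file (coordinates to 4 decimals)."""
    path = Path(path)
    lines = ["@<TRIPOS>MOLECULE", ligand.name,
             f"{len(ligand.atoms)} {len(ligand.bonds)} 0 0 0",
             "SMALL", "NO_CHARGES", "", "@<TRIPOS>ATOM"]
    for a in ligand.atoms:
        x, y, z = a.coords
        lines.append(
            f"{a.serial:>7d} {a.name:<8s} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
            f"{a.sybyl_type:<8s} 1 LIG 0.0000")
    lines.append("@<TRIPOS>BOND")
    for i, (s1, s2, order) in enumerate(ligand.bonds, start=1):
        lines.append(f"{i:>6d} {s1:>5d} {s2:>5d} {order:>4s}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Radii and pocket


def assign_vdw_radii(structure: ProteinStructure | LigandMolecule):
    """Assign Bondi van der Waals radii by element, in place.

    Unknown elements fall back to 1.70 A with a warning. Returns the
    structure for chaining.
    """
    for atom in structure.atoms:
        element = atom.element.upper()
        if element in BONDI_RADII:
            atom.vdw_radius = BONDI_RADII[element]
        else:
            warnings.warn(
                f"no van der Waals radius for element {atom.element!r}; "
                f"using default {DEFAULT_VDW_RADIUS} A")
            atom.vdw_radius = DEFAULT_VDW_RADIUS
    return structure


def define_pocket(
    complex: ComplexRecord, cutoff: float = 4.5
) -> set[tuple[str, int, str]]:
    """Residues with any heavy atom within ``cutoff`` of any ligand heavy atom.

    Distances are measured centre-to-centre between heavy atoms. An empty
    pocket is returned with a warning.
    """
    lig = np.array([a.coords for a in complex.ligand.heavy_atoms()])
    pocket: set[tuple[str, int, str]] = set()
    if lig.size:
        for rid, ratoms in complex.protein.residues.items():
            coords = np.array([a.coords for a in ratoms if not a.is_hydrogen])
            if not coords.size:
                continue
            d2 = np.sum(
                (coords[:, None, :] - lig[None, :, :]) ** 2, axis=-1)
            if np.any(d2 <= cutoff ** 2):
                pocket.add(rid)
    if not pocket:
        warnings.warn(f"empty binding pocket at cutoff {cutoff} A")
    return pocket


# ---------------------------------------------------------------------------
# Library index


def read_library_index(path: str | Path) -> pd.DataFrame:
    """Read a reference-library index (TSV).

    Columns: ``complex_id``, ``protein_path``, ``ligand_path``,
    ``affinity_logKa``. Paths are resolved relative to the index file.
    This mirrors the PDBbind INDEX layout so real PDBbind directories can
    be ingested unmodified.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"complex_id": str})
    required = {"complex_id", "protein_path", "ligand_path", "affinity_logKa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: index missing columns {sorted(missing)}")
    if df["complex_id"].duplicated().any():
        dup = df.loc[df["complex_id"].duplicated(), "complex_id"].iloc[0]
        raise ValueError(f"{path}: duplicate complex_id {dup!r}")
    base = path.parent
    for col in ("protein_path", "ligand_path"):
        df[col] = df[col].map(lambda p: str((base / p).resolve()))
    return df


def load_complex(
    complex_id: str,
    protein_path: str | Path,
    ligand_path: str | Path,
    affinity: Optional[float] = None,
) -> ComplexRecord:
    """Load and normalise one complex: parse, assign radii."""
    protein = assign_vdw_radii(read_protein_pdb(protein_path))
    ligand = assign_vdw_radii(read_ligand(ligand_path))
    return ComplexRecord(complex_id=complex_id, protein=protein,
                         ligand=ligand, affinity=affinity)


def iter_library(index: pd.DataFrame) -> Iterator[ComplexRecord]:
    """Yield complexes for an index frame, skipping unreadable entries."""
    for row in index.itertuples(index=False):
        try:
            yield load_complex(row.complex_id, row.protein_path,
                               row.ligand_path, row.affinity_logKa)
        except Exception as exc:
            warnings.warn(f"skipping complex {row.complex_id}: {exc}")
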