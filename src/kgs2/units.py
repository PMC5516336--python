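"""Interaction units: four-atom protein-ligand contact elements.

An interaction unit couples a *protein fragment* — three covalently
bonded heavy atoms forming a simple path within one residue — with one
ligand heavy atom in direct contact. The ligand atom's position is
expressed in a local Cartesian frame defined by the fragment: origin at
the middle atom, xy plane through the three atoms, z axis pointing
toward the ligand side. This makes unit geometry invariant under rigid
motion of the complex and comparable across structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from kgs2.structures import Atom, ComplexRecord, LigandMolecule, ProteinStructure
from kgs2.structures import define_pocket

__all__ = [
    "UnitTypeKey",
    "InteractionUnit",
    "CollinearFragmentError",
    "find_contacts",
    "enumerate_fragments",
    "local_frame",
    "extract_units",
    "COLLINEAR_ANGLE_DEG",
]

logger = logging.getLogger(__name__)

COLLINEAR_ANGLE_DEG = 1.0
CONTACT_MARGIN = 1.0  # Angstrom beyond the vdW-radius sum


class CollinearFragmentError(ValueError):
    """Fragment atoms are (nearly) collinear; no plane can be defined."""


@dataclass(frozen=True)
class UnitTypeKey:
    """Identity of an interaction-unit type.

    String form ``"ASP:O-C-CA|O.2"``: residue name, the three fragment
    atom names in canonical orientation, and the ligand SYBYL type.
    """

    residue_name: str
    fragment_atom_names: tuple[str, str, str]
    ligand_atom_type: str

    def __str__(self) -> str:
        frag = "-".join(self.fragment_atom_names)
        return f"{self.residue_name}:{frag}|{self.ligand_atom_type}"

    @classmethod
    def from_string(cls, s: str) -> "UnitTypeKey":
        head, _, ltype = s.partition("|")
        resname, _, frag = head.partition(":")
        names = tuple(frag.split("-"))
        if not (resname and ltype and len(names) == 3):
            raise ValueError(f"unparseable unit type key: {s!r}")
        return cls(resname, names, ltype)


@dataclass
class InteractionUnit:
    type_key: UnitTypeKey
    local_coords: np.ndarray
    source: tuple[str, tuple[str, int, str], int]  # complex, residue, serial
    frame: tuple[np.ndarray, np.ndarray]  # (3x3 rotation rows, origin)

    def __post_init__(self) -> None:
        self.local_coords = np.asarray(self.local_coords, dtype=float)


def find_contacts(
    protein: ProteinStructure,
    ligand: LigandMolecule,
    margin: float = CONTACT_MARGIN,
    protein_atoms: Optional[list[Atom]] = None,
) -> list[tuple[Atom, Atom]]:
    """Heavy-atom pairs closer than the sum of vdW radii plus ``margin``.

    The comparison is strict (<). ``protein_atoms`` restricts the search
    to a subset (e.g. pocket residues).
    """
    p_atoms = [a for a in (protein_atoms if protein_atoms is not None
                           else protein.atoms)
               if not a.is_hydrogen and not a.nonstandard]
    l_atoms = ligand.heavy_atoms()
    if not p_atoms or not l_atoms:
        return []
    p_xyz = np.array([a.coords for a in p_atoms])
    l_xyz = np.array([a.coords for a in l_atoms])
    p_rad = np.array([a.vdw_radius for a in p_atoms])
    l_rad = np.array([a.vdw_radius for a in l_atoms])
    d = np.linalg.norm(p_xyz[:, None, :] - l_xyz[None, :, :], axis=-1)
    cut = p_rad[:, None] + l_rad[None, :] + margin
    out = []
    for i, j in zip(*np.nonzero(d < cut)):
        out.append((p_atoms[i], l_atoms[j]))
    return out


def _canonical_path(a: Atom, b: Atom, c: Atom) -> tuple[Atom, Atom, Atom]:
    """Orient a path a-b-c deterministically: end atoms ordered so the
    first end's name is lexicographically <= the last's; identical names
    are broken by serial."""
    if (a.name, a.serial) <= (c.name, c.serial):
        return (a, b, c)
    return (c, b, a)


def enumerate_fragments(
    protein: ProteinStructure,
    residue_id: tuple[str, int, str],
    anchor_atom: Atom,
) -> list[tuple[Atom, Atom, Atom]]:
    """All canonical three-heavy-atom simple paths within one residue
    that contain ``anchor_atom`` at any position."""
    adj = protein.residue_bond_graph(residue_id)
    if anchor_atom.serial not in adj:
        return []
    triples: dict[tuple[int, int, int], tuple[Atom, Atom, Atom]] = {}
    for mid_serial, nbrs in adj.items():
        nbr = sorted(nbrs)
        for i in range(len(nbr)):
            for j in range(i + 1, len(nbr)):
                serials = {nbr[i], mid_serial, nbr[j]}
                if anchor_atom.serial not in serials:
                    continue
                a = protein.atom(nbr[i])
                b = protein.atom(mid_serial)
                c = protein.atom(nbr[j])
                path = _canonical_path(a, b, c)
                key = (path[0].serial, path[1].serial, path[2].serial)
                triples[key] = path
    return [triples[k] for k in sorted(triples)]


def local_frame(
    a_xyz: np.ndarray,
    b_xyz: np.ndarray,
    c_xyz: np.ndarray,
    ligand_xyz: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Local frame of a fragment a-b-c (rows of the returned matrix are
    the x, y, z axes; origin is the middle atom b).

    x = unit(a-b); z is normal to the fragment plane, sign chosen so the
    ligand atom has a non-negative z component (exactly in-plane atoms
    default to +z); y completes a right-handed frame.
    """
    a_xyz = np.asarray(a_xyz, float)
    b_xyz = np.asarray(b_xyz, float)
    c_xyz = np.asarray(c_xyz, float)
    ligand_xyz = np.asarray(ligand_xyz, float)

    u = a_xyz - b_xyz
    v = c_xyz - b_xyz
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise CollinearFragmentError("degenerate fragment (coincident atoms)")
    u /= nu
    v /= nv
    cross = np.cross(u, v)
    sin_angle = np.linalg.norm(cross)
    if sin_angle < np.sin(np.deg2rad(COLLINEAR_ANGLE_DEG)):
        raise CollinearFragmentError(
            "fragment atoms are collinear within tolerance")
    z = cross / sin_angle
    if np.dot(z, ligand_xyz - b_xyz) < 0:
        z = -z
    x = u
    y = np.cross(z, x)
    rot = np.vstack([x, y, z])
    return rot, b_xyz


def _to_local(frame: tuple[np.ndarray, np.ndarray],
              world_xyz: np.ndarray) -> np.ndarray:
    rot, origin = frame
    return rot @ (np.asarray(world_xyz, float) - origin)


def extract_units(
    complex: ComplexRecord,
    pocket_only: bool = False,
    margin: float = CONTACT_MARGIN,
    pocket_cutoff: float = 4.5,
) -> list[InteractionUnit]:
    """Enumerate all interaction units of a complex.

    For every contacting (protein atom, ligand atom) pair, every
    fragment path through the protein atom is paired with the ligand
    atom. A unit is retained iff the nearest of its three fragment atoms
    to the ligand atom passes the vdW-sum + margin contact test.
    Duplicate (fragment, ligand atom) combinations arising from several
    contacting atoms of the same fragment collapse to one unit.
    Nonstandard residues and hydrogens never participate. Collinear
    fragments are skipped (counted in a debug log).
    """
    protein, ligand = complex.protein, complex.ligand
    if pocket_only:
        pocket = define_pocket(complex, cutoff=pocket_cutoff)
        subset = [a for a in protein.atoms if a.residue_id in pocket]
        contacts = find_contacts(protein, ligand, margin, protein_atoms=subset)
    else:
        contacts = find_contacts(protein, ligand, margin)

    seen: set[tuple[tuple[int, int, int], int]] = set()
    units: list[InteractionUnit] = []
    n_collinear = 0
    for p_atom, l_atom in contacts:
        for path in enumerate_fragments(protein, p_atom.residue_id, p_atom):
            key = (tuple(at.serial for at in path), l_atom.serial)
            if key in seen:
                continue
            seen.add(key)
            # contact criterion on the nearest fragment atom
            dists = [np.linalg.norm(at.coords - l_atom.coords) for at in path]
            nearest = path[int(np.argmin(dists))]
            if min(dists) >= nearest.vdw_radius + l_atom.vdw_radius + margin:
                continue
            try:
                frame = local_frame(path[0].coords, path[1].coords,
                                    path[2].coords, l_atom.coords)
            except CollinearFragmentError:
                n_collinear += 1
                continue
            units.append(InteractionUnit(
                type_key=UnitTypeKey(
                    residue_name=path[0].residue_name,
                    fragment_atom_names=tuple(at.name for at in path),
                    ligand_atom_type=l_atom.sybyl_type,
                ),
                local_coords=_to_local(frame, l_atom.coords),
                source=(complex.complex_id, p_atom.residue_id, l_atom.serial),
                frame=frame,
            ))
    if n_collinear:
        logger.debug("%s: skipped %d collinear fragments",
                     complex.complex_id, n_collinear)
    return units
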