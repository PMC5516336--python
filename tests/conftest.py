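"""Shared fixtures: synthetic libraries, inline structure files, helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from kgs2.structures import (
    Atom,
    ComplexRecord,
    LigandMolecule,
    ProteinStructure,
    assign_vdw_radii,
    iter_library,
    read_library_index,
)
from kgs2.patterns import mine_pattern_library
from kgs2.fingerprints import build_fingerprint
from kgs2.synthetic import FixtureSpec, make_library

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


# A three-residue peptide with hand-placed coordinates. The GLY-1
# geometry is axis-aligned so local-frame arithmetic is checkable by
# hand; ASP-3 carries a full side chain for fragment enumeration.
THREE_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1      -1.500   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       0.000   1.500   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.000   2.200   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2      18.542  20.000  20.000  1.00  0.00           N
ATOM      6  CA  ALA A   2      20.000  20.000  20.000  1.00  0.00           C
ATOM      7  C   ALA A   2      20.525  21.437  20.000  1.00  0.00           C
ATOM      8  O   ALA A   2      21.746  21.631  20.000  1.00  0.00           O
ATOM      9  CB  ALA A   2      19.464  19.223  21.208  1.00  0.00           C
ATOM     10  N   ASP A   3      38.542  40.000  40.000  1.00  0.00           N
ATOM     11  CA  ASP A   3      40.000  40.000  40.000  1.00  0.00           C
ATOM     12  C   ASP A   3      40.525  41.437  40.000  1.00  0.00           C
ATOM     13  O   ASP A   3      41.746  41.631  40.000  1.00  0.00           O
ATOM     14  CB  ASP A   3      39.464  39.223  41.208  1.00  0.00           C
ATOM     15  CG  ASP A   3      39.901  37.762  41.169  1.00  0.00           C
ATOM     16  OD1 ASP A   3      41.050  37.450  41.430  1.00  0.00           O
ATOM     17  OD2 ASP A   3      39.049  36.900  40.920  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   GLY A   1      -1.500   0.000   0.000  1.00  0.00           N
ATOM      2  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA BGLY A   1       0.100   0.000   0.000  0.60  0.00           C
ATOM      4  C   GLY A   1       0.000   1.500   0.000  1.00  0.00           C
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""

FIVE_ATOM_MOL2 = """\
@<TRIPOS>MOLECULE
toy
5 4 0 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
      1 C1        0.0000    0.0000    0.0000 C.3      1 LIG 0.0000
      2 C2        1.5200    0.0000    0.0000 C.3      1 LIG 0.0000
      3 O1        2.1300    1.0800    0.0000 O.2      1 LIG 0.0000
      4 N1        2.2000   -1.2000    0.0000 N.am     1 LIG 0.0000
      5 C3        3.6500   -1.3000    0.0000 C.3      1 LIG 0.0000
@<TRIPOS>BOND
     1     1     2 1
     2     2     3 2
     3     2     4 am
     4     4     5 1
"""

ACETONE_SDF = """\
acetone
  synthetic fixture

  4  3  0  0  0  0  0  0  0  0999 V2000
   -1.2800    0.4000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -0.3800    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2800    0.4000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.6000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  2  0
M  END
$$$$
"""


@pytest.fixture()
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture()
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture()
def water_pdb(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(WATER_ONLY_PDB)
    return path


@pytest.fixture()
def toy_mol2(tmp_path):
    path = tmp_path / "toy.mol2"
    path.write_text(FIVE_ATOM_MOL2)
    return path


@pytest.fixture()
def acetone_sdf(tmp_path):
    path = tmp_path / "acetone.sdf"
    path.write_text(ACETONE_SDF)
    return path


def make_ligand(coords, sybyl_types):
    """In-memory ligand with radii assigned."""
    atoms = [
        Atom(serial=i + 1, name=f"L{i + 1}",
             element=t.split(".")[0].upper(), coords=c, sybyl_type=t,
             is_hydrogen=t == "H")
        for i, (c, t) in enumerate(zip(coords, sybyl_types))
    ]
    return assign_vdw_radii(LigandMolecule(atoms=atoms))


def transform_record(record: ComplexRecord, rotation: np.ndarray,
                     translation: np.ndarray,
                     complex_id: str | None = None) -> ComplexRecord:
    """Copy of a complex under a global rigid motion."""
    def move(atom: Atom) -> Atom:
        return Atom(
            serial=atom.serial, name=atom.name, element=atom.element,
            coords=rotation @ atom.coords + translation,
            sybyl_type=atom.sybyl_type, vdw_radius=atom.vdw_radius,
            residue_name=atom.residue_name, residue_id=atom.residue_id,
            is_hydrogen=atom.is_hydrogen, nonstandard=atom.nonstandard)

    protein = ProteinStructure(atoms=[move(a) for a in record.protein.atoms])
    protein.bonds = set(record.protein.bonds)
    ligand = LigandMolecule(
        atoms=[move(a) for a in record.ligand.atoms],
        bonds=list(record.ligand.bonds), name=record.ligand.name)
    return ComplexRecord(
        complex_id=complex_id or record.complex_id,
        protein=protein, ligand=ligand, affinity=record.affinity)


class LibraryFixture:
    def __init__(self, root, spec, manifest, records, pattern_library, fps):
        self.root = root
        self.spec = spec
        self.manifest = manifest
        self.records = records
        self.pattern_library = pattern_library
        self.fingerprints = fps
        self.by_id = {r.complex_id: r for r in records}
        self.fp_by_id = {fp.complex_id: fp for fp in fps}

    def twin_of(self, complex_id):
        for cman in self.manifest["complexes"]:
            if cman["complex_id"] == complex_id:
                return cman["twin_id"]
        raise KeyError(complex_id)


@pytest.fixture(scope="session")
def small_library(tmp_path_factory):
    """10 complexes, 8 sites; mining thresholds lowered so the small
    library clears the occurrence filters (thresholds themselves are
    exercised elsewhere with replicated unit clouds)."""
    root = tmp_path_factory.mktemp("smalllib")
    spec = FixtureSpec(n_complexes=10, sites_per_complex=8, seed=7)
    manifest = make_library(root, spec)
    records = list(iter_library(read_library_index(root / "INDEX.tsv")))
    lib = mine_pattern_library(records, min_type_occurrence=10,
                               min_component_occurrence=10, seed=0)
    fps = [build_fingerprint(r, lib) for r in records]
    return LibraryFixture(root, spec, manifest, records, lib, fps)


@pytest.fixture(scope="session")
def full_library(tmp_path_factory):
    """The study-scale fixture: 30 complexes (15 twin pairs), 12 sites,
    every planted unit type above the default occurrence-100 filters."""
    root = tmp_path_factory.mktemp("fulllib")
    spec = FixtureSpec(seed=1)
    manifest = make_library(root, spec)
    records = list(iter_library(read_library_index(root / "INDEX.tsv")))
    lib = mine_pattern_library(records, seed=0)
    fps = [build_fingerprint(r, lib) for r in records]
    return LibraryFixture(root, spec, manifest, records, lib, fps)
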