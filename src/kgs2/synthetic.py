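"""Synthetic toy complexes with planted interaction geometry.

Every stage of the pipeline is testable without downloads: this module
fabricates small protein-ligand complexes in which each residue hosts
exactly one (or, for the aspartate variant, two) interaction units of a
known type at a known local-frame position, writes them as PDB/Mol2
files, and records the planted ground truth in a manifest.

The generator keeps its own copy of the combinatorics it plants —
residue fragment tables, contact arithmetic, frame construction — so
manifests are derived from the construction, not from the code under
test.

Residue variants are deliberately minimal (truncated glycine, alanine
and aspartate) so that fragment enumeration stays hand-checkable:

* ``GLY`` — atoms N, CA, C: the single fragment C-CA-N.
* ``ALA`` — atoms N, CA, CB: the single fragment CB-CA-N.
* ``ASP`` — atoms CA, CB, CG, OD1: fragments CA-CB-CG and CB-CG-OD1,
  so one planted contact yields two units (both recorded as expected).

Libraries are built as *twin pairs*: two complexes per pair share the
same site arrangement up to a small geometric jitter and a global rigid
motion, so each complex's planted nearest neighbour is its twin. The
score model plants a linear relation between raw score and true
affinity with a systematic error shared within a twin pair (the
premise that makes reference anchoring useful) plus small independent
noise; library affinities carry independent measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from kgs2.structures import BONDI_RADII, Atom, LigandMolecule, write_ligand_mol2

__all__ = [
    "FixtureSpec",
    "Planting",
    "Arrangement",
    "make_complex",
    "make_library",
    "simulate_scoring",
    "VARIANTS",
    "DEFAULT_VOCAB",
]

# Idealised heavy-atom coordinates shared by all residue variants.
_TEMPLATE_XYZ = {
    "N": np.array([-1.458, 0.000, 0.000]),
    "CA": np.array([0.000, 0.000, 0.000]),
    "C": np.array([0.525, 1.437, 0.000]),
    "CB": np.array([-0.536, -0.777, 1.208]),
    "CG": np.array([-0.099, -2.238, 1.169]),
    "OD1": np.array([1.050, -2.550, 1.430]),
}

# variant -> (atom names, fragment triples in canonical order,
#             designated planting fragment)
VARIANTS: dict[str, dict] = {
    "GLY": {
        "atoms": ("N", "CA", "C"),
        "triples": (("C", "CA", "N"),),
        "plant_fragment": ("C", "CA", "N"),
    },
    "ALA": {
        "atoms": ("N", "CA", "CB"),
        "triples": (("CB", "CA", "N"),),
        "plant_fragment": ("CB", "CA", "N"),
    },
    "ASP": {
        "atoms": ("CA", "CB", "CG", "OD1"),
        "triples": (("CA", "CB", "CG"), ("CB", "CG", "OD1")),
        "plant_fragment": ("CB", "CG", "OD1"),
    },
}

# (variant, ligand SYBYL type, planted local-frame mean). Means sit well
# inside the contact shell of the planting fragment with z clearly
# positive, so jitter can neither break the contact nor flip the frame.
DEFAULT_VOCAB: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
    ("GLY", "C.3", (1.2, 1.6, 2.2)),
    ("ALA", "O.2", (1.3, 1.5, 2.3)),
    ("ASP", "N.3", (0.8, 1.3, 2.4)),
)

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "CB": "C", "CG": "C", "OD1": "O"}
_CONTACT_MARGIN = 1.0


@dataclass
class Planting:
    """One site: a residue variant hosting one ligand atom."""

    variant: str
    ligand_type: str
    local_coords: tuple[float, float, float]
    position: tuple[float, float, float]
    rotation: Sequence[Sequence[float]]  # 3x3


@dataclass
class Arrangement:
    plantings: list[Planting]


@dataclass
class FixtureSpec:
    """Study conditions for a synthetic library.

    30 complexes (15 twin pairs) of 12 sites each put every planted unit
    type above the occurrence-100 mining filter; geometric jitter of
    0.12 A keeps twins within the 1 A overlap threshold after
    superposition. The score model is linear with unit slope, a 1.5
    logKa systematic error shared within a pair, 0.1 logKa independent
    noise, and 0.3 logKa measurement noise on library affinities.
    """

    n_complexes: int = 30
    sites_per_complex: int = 12
    seed: int = 0
    sigma_geom: float = 0.12  # A, jitter on planted local coords
    box_size: float = 30.0  # A, site placement volume
    min_site_separation: float = 10.0  # A
    affinity_range: tuple[float, float] = (2.0, 11.0)  # logKa
    sigma_affinity_twin: float = 0.25  # logKa, within-pair spread
    score_slope: float = 1.0  # logKa per score unit
    score_intercept: float = 0.0  # logKa
    sigma_sf: float = 1.5  # systematic score error, score units
    sigma_noise: float = 0.1  # independent score noise, score units
    sigma_ref: float = 0.3  # logKa, library affinity measurement noise
    vocab: tuple = DEFAULT_VOCAB


class UnrealizableSpecError(ValueError):
    """Planted geometry violates its own contact or separation rules."""


# ---------------------------------------------------------------------------
# Generator-side geometry (independent of kgs2.units)


def _plant_frame(names: Sequence[str], coords: dict[str, np.ndarray]):
    """Frame of a fragment a-b-c with the +z side chosen a priori
    (planted ligand z is always positive)."""
    a, b, c = (coords[n] for n in names)
    x = a - b
    x = x / np.linalg.norm(x)
    v = c - b
    v = v / np.linalg.norm(v)
    z = np.cross(x, v)
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    return np.vstack([x, y, z]), b


def _expected_units_for_site(
    variant: str,
    ligand_type: str,
    residue_xyz: dict[str, np.ndarray],
    ligand_xyz: np.ndarray,
) -> list[str]:
    """Unit type keys the extractor must produce for one site, from the
    generator's own contact arithmetic and fragment tables."""
    spec = VARIANTS[variant]
    r_lig = BONDI_RADII[ligand_type.split(".")[0].upper()]
    dists = {n: float(np.linalg.norm(residue_xyz[n] - ligand_xyz))
             for n in spec["atoms"]}
    contacting = {
        n for n, d in dists.items()
        if d < BONDI_RADII[_ELEMENT[n]] + r_lig + _CONTACT_MARGIN
    }
    expected = []
    for triple in spec["triples"]:
        if not contacting.intersection(triple):
            continue
        nearest = min(triple, key=lambda n: dists[n])
        if nearest in contacting:
            expected.append(f"{variant}:{'-'.join(triple)}|{ligand_type}")
    return expected


# ---------------------------------------------------------------------------
# Complex construction


def make_complex(
    complex_id: str,
    plantings: Sequence[Planting],
    out_dir: str | Path,
    affinity: Optional[float] = None,
    rigid_motion: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> dict:
    """Write one synthetic complex (PDB + Mol2) and return its manifest.

    Each planting becomes one residue plus one ligand atom placed at the
    planted local-frame coordinates of the designated fragment.
    ``rigid_motion`` (rotation, translation) moves the whole complex.
    Raises :class:`UnrealizableSpecError` if a planted ligand atom is
    out of contact with its own residue or in contact with another site.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    residues = []  # (variant, {name: xyz})
    ligand_atoms = []  # (sybyl_type, xyz)
    site_records = []
    for planting in plantings:
        spec = VARIANTS[planting.variant]
        rot = np.asarray(planting.rotation, float)
        pos = np.asarray(planting.position, float)
        xyz = {n: rot @ _TEMPLATE_XYZ[n] + pos for n in spec["atoms"]}
        frame_rot, origin = _plant_frame(spec["plant_fragment"], xyz)
        local = np.asarray(planting.local_coords, float)
        if local[2] <= 0:
            raise UnrealizableSpecError(
                f"{complex_id}: planted z must be positive, got {local[2]}")
        lig_xyz = origin + frame_rot.T @ local
        expected = _expected_units_for_site(
            planting.variant, planting.ligand_type, xyz, lig_xyz)
        if not expected:
            raise UnrealizableSpecError(
                f"{complex_id}: planted ligand atom is out of contact "
                f"range of its {planting.variant} site")
        residues.append((planting.variant, xyz))
        ligand_atoms.append((planting.ligand_type, lig_xyz))
        site_records.append({
            "variant": planting.variant,
            "ligand_type": planting.ligand_type,
            "local_coords": [round(float(v), 6) for v in local],
            "expected_units": expected,
        })

    # cross-site clash check: a ligand atom may touch only its own site
    for i, (ltype, lxyz) in enumerate(ligand_atoms):
        r_lig = BONDI_RADII[ltype.split(".")[0].upper()]
        for j, (_, xyz) in enumerate(residues):
            if i == j:
                continue
            for n, axyz in xyz.items():
                cut = BONDI_RADII[_ELEMENT[n]] + r_lig + _CONTACT_MARGIN
                if np.linalg.norm(axyz - lxyz) < cut:
                    raise UnrealizableSpecError(
                        f"{complex_id}: ligand atom {i} clashes with site {j}")

    if rigid_motion is not None:
        rot, trans = rigid_motion
        residues = [(v, {n: rot @ p + trans for n, p in xyz.items()})
                    for v, xyz in residues]
        ligand_atoms = [(t, rot @ p + trans) for t, p in ligand_atoms]

    pdb_path = out_dir / f"{complex_id}_protein.pdb"
    mol2_path = out_dir / f"{complex_id}_ligand.mol2"
    _write_pdb(pdb_path, residues)
    ligand = LigandMolecule(
        atoms=[
            Atom(serial=i + 1, name=f"L{i + 1}",
                 element=t.split(".")[0].upper(), coords=xyz, sybyl_type=t,
                 is_hydrogen=False)
            for i, (t, xyz) in enumerate(ligand_atoms)
        ],
        bonds=[(i, i + 1, "1") for i in range(1, len(ligand_atoms))],
        name=complex_id,
    )
    write_ligand_mol2(ligand, mol2_path)

    expected_all = sorted(
        key for site in site_records for key in site["expected_units"])
    manifest = {
        "complex_id": complex_id,
        "affinity": affinity,
        "protein_path": pdb_path.name,
        "ligand_path": mol2_path.name,
        "sites": site_records,
        "expected_units": expected_all,
        "expected_nodes": {
            "protein": len(residues),
            "ligand": len(ligand_atoms),
        },
    }
    return manifest


def _write_pdb(path: Path, residues) -> None:
    lines = []
    serial = 1
    for resseq, (variant, xyz) in enumerate(residues, start=1):
        for name in VARIANTS[variant]["atoms"]:
            x, y, z = xyz[name]
            lines.append(
                f"ATOM  {serial:>5d} {(' ' + name).ljust(4)} {variant:>3s} "
                f"A{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {_ELEMENT[name]:>2s}")
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Library construction


def _place_sites(n: int, rng: np.random.Generator, box: float,
                 min_sep: float) -> np.ndarray:
    """Rejection-sample site centres with a minimum pairwise distance."""
    positions: list[np.ndarray] = []
    for _ in range(20000):
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in positions):
            positions.append(cand)
            if len(positions) == n:
                return np.array(positions)
    raise UnrealizableSpecError(
        f"could not place {n} sites at {min_sep} A separation in a "
        f"{box} A box")


def make_library(out_dir: str | Path, spec: Optional[FixtureSpec] = None) -> dict:
    """Generate a synthetic reference library on disk.

    Writes per-complex subdirectories with ``<id>_protein.pdb`` and
    ``<id>_ligand.mol2``, an ``INDEX.tsv``, a ``scores.tsv`` with the
    planted raw scores, and a ``manifest.json`` with the full ground
    truth (twin assignment, true affinities, planted sites).
    Byte-identical output for a given spec (seed included).
    """
    spec = spec or FixtureSpec()
    if spec.n_complexes % 2:
        raise ValueError("n_complexes must be even (twin pairs)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    n_pairs = spec.n_complexes // 2
    manifests = []
    index_rows = []
    score_rows = []
    for pair in range(n_pairs):
        positions = _place_sites(spec.sites_per_complex, rng, spec.box_size,
                                 spec.min_site_separation)
        rotations = Rotation.random(spec.sites_per_complex, random_state=rng)
        vocab_idx = [i % len(spec.vocab)
                     for i in range(spec.sites_per_complex)]
        pair_affinity = rng.uniform(*spec.affinity_range)
        u_pair = rng.normal(0.0, spec.sigma_sf)

        for twin in range(2):
            cid = f"C{2 * pair + twin:04d}"
            plantings = []
            for s in range(spec.sites_per_complex):
                variant, ltype, mean = spec.vocab[vocab_idx[s]]
                local = np.asarray(mean) + rng.normal(
                    0.0, spec.sigma_geom, size=3)
                plantings.append(Planting(
                    variant=variant, ligand_type=ltype,
                    local_coords=tuple(local),
                    position=tuple(positions[s]),
                    rotation=rotations[s].as_matrix().tolist()))
            motion = None
            if twin == 1:
                rot = Rotation.random(random_state=rng).as_matrix()
                trans = rng.uniform(-20.0, 20.0, size=3)
                motion = (rot, trans)

            true_aff = pair_affinity + rng.normal(
                0.0, spec.sigma_affinity_twin)
            stored_aff = true_aff + rng.normal(0.0, spec.sigma_ref)
            raw = ((true_aff - spec.score_intercept) / spec.score_slope
                   + u_pair + rng.normal(0.0, spec.sigma_noise))

            cdir = out_dir / cid
            manifest = make_complex(cid, plantings, cdir,
                                    affinity=round(stored_aff, 6),
                                    rigid_motion=motion)
            manifest.update({
                "pair": pair,
                "twin_id": f"C{2 * pair + (1 - twin):04d}",
                "true_affinity": round(float(true_aff), 6),
                "stored_affinity": round(float(stored_aff), 6),
                "raw_score": round(float(raw), 6),
            })
            manifests.append(manifest)
            index_rows.append({
                "complex_id": cid,
                "protein_path": f"{cid}/{cid}_protein.pdb",
                "ligand_path": f"{cid}/{cid}_ligand.mol2",
                "affinity_logKa": round(float(stored_aff), 6),
            })
            score_rows.append({
                "complex_id": cid,
                "raw_score": round(float(raw), 6),
                "experimental": round(float(stored_aff), 6),
            })

    pd.DataFrame(index_rows).to_csv(out_dir / "INDEX.tsv", sep="\t",
                                    index=False)
    pd.DataFrame(score_rows).to_csv(out_dir / "scores.tsv", sep="\t",
                                    index=False)
    library_manifest = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "complexes": manifests,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(library_manifest, indent=1, sort_keys=True))
    return library_manifest


# ---------------------------------------------------------------------------
# Structure-free Monte Carlo of the score model


def simulate_scoring(
    n_queries: int,
    spec: Optional[FixtureSpec] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate (query, reference) score pairs under the planted model.

    For each query: a true affinity, a raw score with pair-systematic
    and independent noise, a similar reference sharing the systematic
    error, and the reference's noisy library affinity. Columns:
    ``true_q``, ``raw_q``, ``raw_r``, ``ref_exp``.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for _ in range(n_queries):
        true_q = rng.uniform(*spec.affinity_range)
        true_r = true_q + rng.normal(0.0, spec.sigma_affinity_twin)
        u = rng.normal(0.0, spec.sigma_sf)
        raw_q = ((true_q - spec.score_intercept) / spec.score_slope + u
                 + rng.normal(0.0, spec.sigma_noise))
        raw_r = ((true_r - spec.score_intercept) / spec.score_slope + u
                 + rng.normal(0.0, spec.sigma_noise))
        ref_exp = true_r + rng.normal(0.0, spec.sigma_ref)
        rows.append({"true_q": true_q, "raw_q": raw_q,
                     "raw_r": raw_r, "ref_exp": ref_exp})
    return pd.DataFrame(rows)
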