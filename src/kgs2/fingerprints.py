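"""3D interaction fingerprints.

A complex's pocket interaction units are matched against the pattern
library by Mahalanobis distance (match iff D < 2.5; a unit may match
several components of its type). Every matched pattern is then degraded
into a pair of typed nodes: one on the backbone C-alpha of the residue
carrying the fragment (labelled by residue type, e.g. "ARG") and one on
the ligand atom (labelled by SYBYL type, e.g. "O.2"). The deduplicated
node set is the fingerprint used for structural comparison; pocket
residues contributing no pattern are absent from it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from kgs2.structures import ComplexRecord
from kgs2.patterns import InteractionPattern, PatternLibrary
from kgs2.units import InteractionUnit, extract_units

__all__ = [
    "FingerprintNode",
    "Fingerprint",
    "mahalanobis",
    "match_unit",
    "build_fingerprint",
    "save_fingerprints",
    "load_fingerprints",
    "MATCH_THRESHOLD",
]

MATCH_THRESHOLD = 2.5


@dataclass(frozen=True)
class FingerprintNode:
    """A typed, positioned node: residue C-alpha or ligand atom."""

    kind: str  # "protein" | "ligand"
    label: str  # residue 3-letter code, or SYBYL atom type
    coords: tuple[float, float, float]
    anchor: tuple  # residue_id for protein nodes, (serial,) for ligand nodes

    @property
    def xyz(self) -> np.ndarray:
        return np.array(self.coords, float)

    def identity(self) -> tuple:
        return (self.kind, self.anchor, self.label)


@dataclass
class Fingerprint:
    complex_id: str
    nodes: list[FingerprintNode] = field(default_factory=list)
    affinity: Optional[float] = None
    mode: str = "full"
    # pattern multiplicity per node-pair; informational, unused by the
    # similarity index
    multiplicity: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def nodes_for_mode(self, mode: Optional[str] = None) -> list[FingerprintNode]:
        mode = mode or self.mode
        if mode == "protein_only":
            return [n for n in self.nodes if n.kind == "protein"]
        return list(self.nodes)


def mahalanobis(x: np.ndarray, pattern: InteractionPattern) -> float:
    """Mahalanobis distance of a point to a pattern's Gaussian component,
    D = sqrt((x - mu)^T Sigma^-1 (x - mu))."""
    delta = np.asarray(x, float) - pattern.mean
    sol = cho_solve(cho_factor(pattern.covariance, lower=True), delta)
    return float(np.sqrt(delta @ sol))


def match_unit(
    unit: InteractionUnit,
    library: PatternLibrary,
    threshold: float = MATCH_THRESHOLD,
) -> list[InteractionPattern]:
    """Patterns of the unit's type within Mahalanobis distance
    ``threshold`` (strict); possibly several, possibly none."""
    return [p for p in library.get(unit.type_key)
            if mahalanobis(unit.local_coords, p) < threshold]


def build_fingerprint(
    complex: ComplexRecord,
    library: PatternLibrary,
    mode: str = "full",
    threshold: float = MATCH_THRESHOLD,
    margin: float = 1.0,
    pocket_cutoff: float = 4.5,
) -> Fingerprint:
    """Fingerprint a complex against a pattern library.

    ``mode`` is recorded on the fingerprint and selects the node subset
    used at comparison time ("protein_only" ignores ligand nodes, the
    variation in which only pocket-residue nodes are compared); the
    fingerprint itself always stores both node kinds.
    """
    if mode not in ("full", "protein_only"):
        raise ValueError(f"unknown fingerprint mode {mode!r}")
    units = extract_units(complex, pocket_only=True, margin=margin,
                          pocket_cutoff=pocket_cutoff)
    ligand_atoms = {a.serial: a for a in complex.ligand.atoms}
    nodes: dict[tuple, FingerprintNode] = {}
    multiplicity: dict[tuple, int] = {}
    for unit in units:
        matches = match_unit(unit, library, threshold=threshold)
        if not matches:
            continue
        _, residue_id, ligand_serial = unit.source
        ca = complex.protein.calpha(residue_id)
        if ca is None:
            warnings.warn(
                f"{complex.complex_id}: residue {residue_id} has no C-alpha; "
                "its matched patterns are dropped")
            continue
        l_atom = ligand_atoms[ligand_serial]
        p_node = FingerprintNode(
            kind="protein",
            label=unit.type_key.residue_name,
            coords=tuple(float(v) for v in ca.coords),
            anchor=residue_id,
        )
        l_node = FingerprintNode(
            kind="ligand",
            label=l_atom.sybyl_type,
            coords=tuple(float(v) for v in l_atom.coords),
            anchor=(ligand_serial,),
        )
        pair_key = (p_node.identity(), l_node.identity())
        multiplicity[pair_key] = multiplicity.get(pair_key, 0) + len(matches)
        nodes[p_node.identity()] = p_node
        nodes[l_node.identity()] = l_node
    return Fingerprint(
        complex_id=complex.complex_id,
        nodes=[nodes[k] for k in sorted(nodes)],
        affinity=complex.affinity,
        mode=mode,
        multiplicity=multiplicity,
    )


# ---------------------------------------------------------------------------
# Persistence


def save_fingerprints(fps: list[Fingerprint], path: str | Path) -> None:
    payload = {
        "schema_version": 1,
        "fingerprints": [
            {
                "complex_id": fp.complex_id,
                "affinity": fp.affinity,
                "mode": fp.mode,
                "nodes": [
                    {"kind": n.kind, "label": n.label,
                     "coords": list(n.coords), "anchor": list(n.anchor)}
                    for n in fp.nodes
                ],
            }
            for fp in fps
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fingerprints(path: str | Path) -> list[Fingerprint]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != 1:
        raise ValueError(f"{path}: unsupported fingerprint schema version")
    fps = []
    for entry in payload["fingerprints"]:
        nodes = [
            FingerprintNode(
                kind=n["kind"], label=n["label"],
                coords=tuple(n["coords"]),
                anchor=tuple(n["anchor"]))
            for n in entry["nodes"]
        ]
        fps.append(Fingerprint(
            complex_id=entry["complex_id"], nodes=nodes,
            affinity=entry["affinity"], mode=entry.get("mode", "full")))
    return fps
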