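"""Mining statistically preferred interaction geometries.

Interaction units of the same type, pooled over a structure library,
form a cloud of 3D points (ligand-atom positions in the fragment frame).
The cloud is modelled as a Gaussian mixture p(x) = sum_k pi_k N(x | mu_k,
Sigma_k) fitted by variational Bayes, which drives the weights of
unnecessary components to zero. Each surviving component with enough
support becomes an *interaction pattern*: a preferred geometry of that
unit type.

Filtering defaults: a unit type with occurrence below 100 is ignored; a
component is kept only with occurrence over 100 and weight >= 0.01.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from sklearn.mixture import BayesianGaussianMixture

from kgs2.structures import ComplexRecord
from kgs2.units import InteractionUnit, UnitTypeKey, extract_units

__all__ = [
    "UnitTypeStats",
    "InteractionPattern",
    "PatternLibrary",
    "aggregate_units",
    "fit_gmm",
    "extract_patterns",
    "mine_pattern_library",
    "save_pattern_library",
    "load_pattern_library",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

# Mixture components whose converged weight falls below this are treated
# as "adjusted to zero" by the variational fit and pruned outright.
PRUNE_WEIGHT = 1e-3
COVARIANCE_FLOOR = 1e-4  # Angstrom^2, diagonal regularisation


@dataclass
class UnitTypeStats:
    """All observed local-frame points of one interaction-unit type."""

    type_key: UnitTypeKey
    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 3)

    @property
    def occurrence(self) -> int:
        return self.points.shape[0]


@dataclass
class InteractionPattern:
    """One retained Gaussian component of a unit-type mixture."""

    type_key: UnitTypeKey
    mean: np.ndarray
    covariance: np.ndarray
    weight: float
    occurrence: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float).reshape(3)
        self.covariance = np.asarray(self.covariance, float).reshape(3, 3)


@dataclass
class PatternLibrary:
    """Interaction patterns indexed by unit type key."""

    patterns: dict[UnitTypeKey, list[InteractionPattern]] = field(
        default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def get(self, type_key: UnitTypeKey) -> list[InteractionPattern]:
        return self.patterns.get(type_key, [])

    def add(self, pattern: InteractionPattern) -> None:
        self.patterns.setdefault(pattern.type_key, []).append(pattern)

    @property
    def n_patterns(self) -> int:
        return sum(len(v) for v in self.patterns.values())

    @property
    def n_types(self) -> int:
        return len(self.patterns)


def aggregate_units(
    library: Iterable[ComplexRecord], **extract_kwargs
) -> dict[UnitTypeKey, UnitTypeStats]:
    """Extract and pool interaction units over a structure library.

    Units are taken over the whole binding interface (``pocket_only``
    defaults to False for mining). Complexes that fail to process are
    skipped with a warning; the sweep never aborts.
    """
    extract_kwargs.setdefault("pocket_only", False)
    buckets: dict[UnitTypeKey, list[np.ndarray]] = {}
    for record in library:
        try:
            units = extract_units(record, **extract_kwargs)
        except Exception as exc:
            warnings.warn(
                f"skipping complex {getattr(record, 'complex_id', '?')}: {exc}")
            continue
        for u in units:
            buckets.setdefault(u.type_key, []).append(u.local_coords)
    return {
        key: UnitTypeStats(type_key=key, points=np.array(pts))
        for key, pts in buckets.items()
    }


def fit_gmm(
    points: np.ndarray, k_max: int = 15, seed: int = 0
) -> BayesianGaussianMixture:
    """Fit a variational-Bayes Gaussian mixture to local-frame points.

    At most ``k_max`` components (the default 15 matches the mining
    protocol); a small weight-concentration prior encourages the fit to
    shut down unnecessary components. Covariances carry a 1e-4 A^2
    diagonal floor so that repeated or near-degenerate points cannot
    produce a singular component. Deterministic for a given seed.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    n = points.shape[0]
    if n < 2:
        raise ValueError("cannot fit a mixture to fewer than 2 points")
    k = min(k_max, n)
    gmm = BayesianGaussianMixture(
        n_components=k,
        covariance_type="full",
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=0.01,
        reg_covar=COVARIANCE_FLOOR,
        max_iter=500,
        n_init=3,  # restarts guard against split local optima on tight clouds
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny clouds
        gmm.fit(points)
    return gmm


def _floor_covariance(cov: np.ndarray,
                      floor: float = COVARIANCE_FLOOR) -> np.ndarray:
    """Clip covariance eigenvalues at the regularisation floor so stored
    patterns are always safely invertible."""
    vals, vecs = np.linalg.eigh(np.asarray(cov, float))
    if vals.min() >= floor:
        return np.asarray(cov, float)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def extract_patterns(
    stats: UnitTypeStats,
    mixture: BayesianGaussianMixture,
    min_type_occurrence: int = 100,
    min_component_occurrence: int = 100,
    min_weight: float = 0.01,
    soft_counts: bool = False,
) -> list[InteractionPattern]:
    """Apply the significance filters to a fitted mixture.

    A type with occurrence below ``min_type_occurrence`` yields nothing.
    A component becomes a pattern iff its occurrence exceeds
    ``min_component_occurrence`` (strictly) and its weight is at least
    ``min_weight``. Occurrence is the hard-assignment count (argmax
    responsibility); ``soft_counts`` switches to summed responsibilities.
    """
    if stats.occurrence < min_type_occurrence:
        return []
    resp = mixture.predict_proba(stats.points)
    if soft_counts:
        counts = resp.sum(axis=0)
    else:
        counts = np.bincount(resp.argmax(axis=1), minlength=mixture.n_components)
    out: list[InteractionPattern] = []
    for k in range(mixture.n_components):
        weight = float(mixture.weights_[k])
        if weight < PRUNE_WEIGHT:
            continue  # adjusted to zero by the variational fit
        occ = float(counts[k])
        if occ <= min_component_occurrence or weight < min_weight:
            continue
        out.append(InteractionPattern(
            type_key=stats.type_key,
            mean=mixture.means_[k],
            covariance=_floor_covariance(mixture.covariances_[k]),
            weight=weight,
            occurrence=int(round(occ)),
        ))
    return out


def mine_pattern_library(
    library: Iterable[ComplexRecord],
    k_max: int = 15,
    min_type_occurrence: int = 100,
    min_component_occurrence: int = 100,
    min_weight: float = 0.01,
    seed: int = 0,
    source: str = "",
) -> PatternLibrary:
    """Full mining sweep: aggregate units, fit mixtures, filter patterns."""
    stats = aggregate_units(library)
    lib = PatternLibrary(provenance={
        "source": source,
        "seed": seed,
        "k_max": k_max,
        "min_type_occurrence": min_type_occurrence,
        "min_component_occurrence": min_component_occurrence,
        "min_weight": min_weight,
        "n_unit_types_observed": len(stats),
        "n_units_observed": int(sum(s.occurrence for s in stats.values())),
        "created": datetime.date.today().isoformat(),
    })
    for key in sorted(stats, key=str):
        st = stats[key]
        if st.occurrence < max(min_type_occurrence, 2):
            continue
        mixture = fit_gmm(st.points, k_max=k_max, seed=seed)
        for pattern in extract_patterns(
                st, mixture,
                min_type_occurrence=min_type_occurrence,
                min_component_occurrence=min_component_occurrence,
                min_weight=min_weight):
            lib.add(pattern)
    return lib


# ---------------------------------------------------------------------------
# Persistence (versioned JSON)


def save_pattern_library(lib: PatternLibrary, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "provenance": lib.provenance,
        "patterns": [
            {
                "type_key": str(p.type_key),
                "mean": p.mean.tolist(),
                "covariance": p.covariance.tolist(),
                "weight": p.weight,
                "occurrence": p.occurrence,
            }
            for patterns in lib.patterns.values()
            for p in patterns
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_pattern_library(path: str | Path) -> PatternLibrary:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid pattern library file: {exc}")
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: pattern library schema version {version!r} "
            f"(expected {SCHEMA_VERSION})")
    lib = PatternLibrary(provenance=payload.get("provenance", {}))
    for entry in payload["patterns"]:
        lib.add(InteractionPattern(
            type_key=UnitTypeKey.from_string(entry["type_key"]),
            mean=np.array(entry["mean"]),
            covariance=np.array(entry["covariance"]),
            weight=float(entry["weight"]),
            occurrence=int(entry["occurrence"]),
        ))
    return lib
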