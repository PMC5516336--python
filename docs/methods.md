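# Methods

## The model

`kgs2` treats binding-affinity prediction as a *relative* problem.
A scoring function SF is first calibrated against experiment by
ordinary least squares, `affinity = b + k·score`, over a training set of
complexes with known binding constants; the slope `k` (logKa per score
unit) is the only parameter carried forward. For a query complex the
package searches a reference library for the complex most similar in
its 3D protein–ligand interaction geometry and predicts

    Q̂ = R_exp + k · (Q_score − R_score).

The premise is that a scoring function's error decomposes into a
component systematic across similar binding chemotypes and a smaller
idiosyncratic component; anchoring to a similar reference cancels the
systematic part, leaving the idiosyncratic score noise and the
measurement error of the reference's experimental affinity. The method
therefore helps exactly when reference measurement error is smaller
than the systematic score error, and it degrades to the calibration
line (with an explicit fallback flag) when no qualified reference
exists. All affinities are handled in logKa units; −logKd, −logKi and
−logIC50 are treated interchangeably, as reference collections such as
PDBbind do.

## Interaction units and local frames

An interaction unit couples a protein *fragment* — three covalently
bonded heavy atoms forming a simple path within a single residue — with
one ligand heavy atom in direct contact (centre distance below the
Bondi van der Waals radius sum plus a 1.0 Å margin, strict). Fragments
are intra-residue because the unit type key carries a single residue
name; the backbone oxygen of the preceding residue is not bridged.
Hydrogens and nonstandard residues never participate: protonation
states vary across deposited structures, and nonstandard residue names
could not accumulate enough occurrences to pass the significance
filters anyway.

Unit geometry is the ligand atom's position in the fragment's local
frame: origin at the middle atom, x along (first − middle), z normal to
the fragment plane and oriented toward the ligand (an exactly in-plane
ligand atom defaults to +z), y completing a right-handed frame. The
canonical orientation of a path a–b–c fixes the middle atom and orders
the ends lexicographically by PDB atom name (serial number on ties), so
type keys such as `ASP:CB-CG-OD1|N.3` are deterministic. Fragments with
an internal angle under 1° at the middle atom define no usable plane
and are skipped (counted in a debug log). By construction the local z
coordinate is non-negative and the local norm equals the world-frame
distance to the middle atom; both are exercised as test invariants.

The contact requirement on a unit is evaluated on the *nearest* of the
three fragment atoms to the ligand atom — the plain reading of the
contact rule — and duplicate (fragment, ligand-atom) combinations
arising from several contacting atoms of one fragment collapse to one
unit.

## Pattern mining

Local-frame points of one unit type, pooled over a library, are fitted
with a Gaussian mixture by variational Bayes
(`sklearn.mixture.BayesianGaussianMixture`), at most K = 15 components,
with a small weight-concentration prior (0.01, Dirichlet-process form)
so that unnecessary components are driven to negligible weight;
components below weight 1e-3 are treated as switched off. Three
restarts (`n_init=3`) guard against split local optima on tight
unimodal clouds, which a single k-means initialisation occasionally
produces. Covariances carry a 1e-4 Å² diagonal regularisation during
fitting, and stored pattern covariances are eigenvalue-floored at the
same value, so Mahalanobis distances are always defined. Fits are
deterministic given the seed, which is recorded in the pattern
library's provenance.

Significance filters: a unit type with fewer than 100 occurrences is
ignored; a surviving component becomes a pattern only with occurrence
strictly over 100 and weight at least 0.01. Component occurrence is the
hard-assignment count (argmax responsibility) for auditability — each
observed unit counts exactly once — with summed responsibilities
available behind a `soft_counts` flag. A type that passes the
occurrence filter but whose components all fail simply yields no
patterns. Thresholds are configurable so that small test libraries can
exercise the machinery; the defaults are the method's standard values.

## Fingerprints and similarity

Pocket units (residues with any heavy atom within 4.5 Å of any ligand
heavy atom, centre-to-centre) are matched against the pattern library
by Mahalanobis distance with the strict threshold D < 2.5; a unit may
match several components of its type. Each matched pattern degrades
into a node pair: the residue's Cα (labelled by residue type) and the
ligand atom (labelled by SYBYL type). Node sets are deduplicated on
(kind, anchor, label) — several patterns between the same residue and
ligand atom produce one node pair, with a multiplicity count kept as
metadata but unused by the similarity index, since nodes are positional
entities. Residues without a Cα cannot host a protein node; their
patterns are dropped with a warning. A `protein_only` comparison mode
(a documented variation of the method) restricts both node sets to
protein nodes at comparison time; fingerprints always store both kinds.

Two fingerprints are compared through a correspondence graph: a vertex
per same-kind, same-label node pair, an edge where the implied intra-set
distances agree within ratio k = 1.1 (equal distances, including zero,
are compatible by convention). *All* maximum-cardinality cliques are
enumerated (networkx `find_cliques`, Bron–Kerbosch with pivoting) and
each seeds a rigid Kabsch superposition; enumerating every maximum
clique rather than an arbitrary one keeps results independent of
enumeration order, and the solution with the most overlapped pairs
(post-transform distance < 1.0 Å, strict) wins. Overlap counting runs
over all matched vertices, not only clique members, with one-to-one
greedy nearest-first assignment; cliques smaller than 3 give an
under-determined rotation and fall back to translation-only centroid
alignment. Comparison runs in a canonical direction (the
lexicographically smaller complex id is the superposition target), so
SI(P, Q) = SI(Q, P) exactly. Graphs over 2000 vertices abort with an
explicit too-large-comparison error instead of risking a runaway
enumeration.

The similarity index is the Tanimoto coefficient
SI = Npq / (Np + Nq − Npq), zero for two empty sets. A candidate
qualifies as a reference only with Npq ≥ 5; reference search returns
the qualified candidate with the highest SI at or above the cutoff
(default 0.10, the permissive setting used for pose re-ranking), always
excluding the query's own id, with ties broken by larger Npq and then
by smaller complex id for reproducibility.

## Scoring, evaluation, re-ranking

`calibrate` reports slope, intercept, Pearson r and the residual
standard deviation of the fit (n − 2 denominator) — the "standard
deviation in regression" conventionally reported for scoring-function
benchmarks — and `evaluate_set` applies the same definition to a
prediction set (fitting experimental on predicted), so SD here is not
the raw RMSE. Pose re-ranking fingerprints each docking pose
independently, adjusts its score, sorts by adjusted affinity and
reports the top pose's value as the ligand's prediction; when every
pose falls back to the calibration line the ranking equals the raw
ranking, since the line is a monotone transform.

## Structure input

PDB files are parsed with Bio.PDB: polymer residues only, highest-
occupancy alternate locations (first on ties), hydrogens kept but
flagged. Covalent bonds come from per-residue heavy-atom templates for
the 20 standard amino acids with a covalent-radius distance fallback,
plus peptide and disulfide links. Van der Waals radii are the Bondi
(1964) values, 1.70 Å with a warning for unknown elements. Mol2 is
parsed directly so SYBYL atom types survive verbatim — they are part of
unit type keys, and re-perception would silently change the type
vocabulary; unknown type strings are downgraded to `Any` with a
warning. SDF input is read with RDKit and typed by a documented
element + hybridisation perception table (carbonyl O → `O.2`,
carboxylate O → `O.co2`, amide N → `N.am`, etc.). Waters, metal ions
and other hetero groups are not interaction partners — a stated
limitation of the unit definition, relevant e.g. for metalloenzyme
pockets.

## The synthetic generator

`kgs2.synthetic` fabricates complexes in which every planted site is a
minimal residue variant hosting one ligand atom at a known local-frame
position: truncated glycine (N, CA, C → single fragment C-CA-N),
alanine (N, CA, CB) and aspartate (CA, CB, CG, OD1 → two fragments, so
one site plants two unit types). Minimal variants make the expected
unit set computable by hand; the generator derives each manifest from
its own fragment tables and contact arithmetic, not from the code under
test. Sites are rejection-sampled at ≥ 10 Å separation so no ligand
atom touches a foreign residue, and planted local positions keep z
clearly positive and sit well inside the contact shell, so jitter can
neither flip a frame nor break a contact.

Default study conditions: 30 complexes as 15 twin pairs, 12 sites each,
three (residue, ligand-type) vocabulary entries assigned round-robin —
every planted unit type then occurs ~120 times and clears the
occurrence-100 filters. Twins share an arrangement up to 0.12 Å local
jitter and a global rigid motion, so each complex's planted nearest
neighbour is its twin. Affinities are uniform on 2–11 logKa per pair
(±0.25 within a pair). The score model is linear (slope 1, intercept 0)
with a 1.5-unit systematic error shared within a twin pair, 0.1-unit
independent noise, and 0.3-logKa measurement noise on stored library
affinities. The shared systematic term realises the cancellation
premise stated above; with fully independent per-complex score errors
anchoring would necessarily *add* noise and the method's central
property would be false by construction. `simulate_scoring` runs the
same score model structure-free for Monte-Carlo checks.

What the generator does not emulate: real protein connectivity and
side-chain diversity, chemically sensible ligands (planted ligand atoms
form an arbitrary chain), crystallographic noise, pocket crowding, or
competing near-matches in reference search. Passing tests demonstrate
the algorithmic contracts — extraction, mining, matching, clique
similarity, anchoring arithmetic — not predictive performance on real
complexes, which depends on library coverage and scoring-function
behaviour.

## Numerical and design notes

* Contact, Mahalanobis-match and overlap comparisons are strict
  inequalities, as specified for each rule.
* Pocket membership is measured centre-to-centre between heavy atoms,
  not radius-adjusted.
* Unit extraction, fingerprints and SI are invariant under global rigid
  motion (tested to 1e-7 over random transforms); node coordinates
  transform covariantly.
* Library mining skips unreadable complexes with a warning rather than
  aborting a long sweep.
* Problem sizes in the test suite (30-complex closure library, n = 1000
  mixture recovery, 200-graph clique oracle, 100 random transforms)
  keep the full suite under about a minute while leaving every planted
  effect far from threshold.
* Reference search accepts candidates with SI ≥ the cutoff (inclusive),
  which keeps a cutoff of 1.0 meaningful for exact-duplicate detection.

## Known limitations

* No protonation, charge assignment or structure repair; input files
  are taken as deposited.
* Structural waters and metal ions are ignored as interaction partners.
* Every pattern contributes equally to the similarity index; a hydrogen
  bond and a hydrophobic contact carry the same weight.
* The method is designed for affinity prediction and pose re-ranking on
  well-characterised targets; it is not applicable when the reference
  library contains nothing similar to the query, and it is not a
  virtual-screening tool.
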