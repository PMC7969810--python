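# Methods

## Scope and design

pharmscreen reimplements, as an open and testable pipeline, a ligand-based
virtual-screening workflow for kinase-inhibitor discovery: quantitative
(activity-trained) and qualitative (common-feature) 3D pharmacophore
models, their validation statistics, and the downstream filter cascade.
The commercial modeling environment this style of workflow is usually run
in (feature dictionaries, the HypoGen cost function, proprietary ADMET
descriptor models, the docking engine) is closed; every place where this
package had to substitute an open construction is listed below, together
with what the substitution preserves.

## Feature perception

Features are perceived per conformer from an editable SMARTS rule file
(`data/feature_rules.yaml`), following the published Catalyst-style
conventions:

- **HBA** — N/O with an available lone pair, no positive charge; amide,
  sulfonamide and anilinic nitrogens excluded. Placed on the heavy atom,
  direction along the mean-bond axis.
- **HBD** — N–H/O–H matched on the heavy atom (implicit hydrogens count).
- **HY** — contiguous components of nonpolar carbons (non-aromatic, not
  bonded to heteroatoms) of ≥ 3 atoms, collapsed to one centroid each.
  The minimum size is a rule-file field.
- **AR** — aromatic rings as centroid plus ring-plane normal (smallest
  principal axis).

Directions are perception metadata only; the fit never scores them. The
projected-point (two-sphere) representation of vectorized features is not
implemented. Feature lists are sorted (kind, then source atom indices) so
perception is deterministic, and rigid motion of the conformer moves every
feature center rigidly (tested to 1e-6 Å).

## Fit scoring

A model is a list of sphere constraints (kind, center, tolerance radius,
weight) with an omission budget. Fit uses the quadratic fall-off
`Σ w·max(0, 1 − (d/t)²)` over mapped constraints, the convention published
for Catalyst-type fit values; tolerances default to 1.6 Å and weights to
1.0, with learned-scale weights (≈ 2.4) carried as model data, never
hard-coded (a five-feature model with such weights has a fit ceiling near
11.9, the scale on which the training tables print fit values).

Correspondences are enumerated by backtracking (injective, kind-matched,
≤ `max_omitted` omissions) with pairwise-distance pruning
(|d_features − d_constraints| ≤ t_i + t_j). Each correspondence is scored
after least-squares rigid superposition (Kabsch, SVD with reflection
guard) of the mapped feature centers onto the constraint centers, plus one
weight-refined pass; a correspondence is admissible only if every mapped
feature lands inside its tolerance sphere. The maximum over admissible
correspondences is the fit; ties go to the lexicographically lowest
mapping, and conformer ties to the lowest index. On instances up to 4
constraints and 6 features this equals a brute-force oracle (exhaustive
correspondences, dense multi-start rotation search with Nelder-Mead
polish) to 1e-3.

Two scoring entry points exist deliberately. `fit_value` optimizes the
rigid transform and is invariant to any rigid motion of the molecule;
`score_pose` evaluates the same formula in the molecule's current pose
(no alignment), which is the closed-form primitive (a single feature
displaced 0.8 Å from a tolerance-1.6 sphere scores 0.75). With one mapped
constraint, alignment is always exact, so the two differ there by design.

## Quantitative layer

The fit→activity mapping is log-linear, `log10 IC50 = C − fit`, with a
single constant per model, `C = mean(fit + log10 IC50)` (least squares).
This one-constant form reproduces every row of the 21-compound training
table and the 38-compound test table shipped in `data/` to better than
0.1% relative error, which is what forces the functional form. On the
log10 scale the training table gives Pearson r = 0.9865 (r² = 0.9732) and
the test table r = 0.9202 (r² = 0.8469); the workflow's reported
"correlation coefficients" of 0.99/0.973 (training) and 0.847 (test) are
therefore r and r² respectively — both conventions are exposed on
`AssessmentReport`. The training table's compound 4 carries a printed
activity-scale label inconsistent with the stated class boundaries
(0.0157 μM labeled ++); it is treated as a typographical anomaly and
excluded from label-reproduction checks.

Error factors are signed folds: +pred/exp when over-predicting IC50,
−exp/pred otherwise, magnitude always ≥ 1. Activity classes: +++ for
IC50 ≤ 0.1 μM, + for ≥ 3 μM, ++ between (both boundaries as quoted).

**Model construction.** The cost-guided simulated annealing of commercial
HypoGen is proprietary; model search is replaced by an explicit, loggable
procedure: candidate constraint sets are all feature subsets (size 4–6 by
default) of the two most active training compounds, realized as tolerance
spheres at the feature centers; each candidate is scored by the Pearson
correlation of its fits with −log10 IC50 over the whole training set; the
best candidate wins and C is calibrated on it. Preconditions: ≥ 8
annotated compounds and ≥ 1 log unit of activity span (≥ 3 is the design
regime). On synthetic data this recovers the planted constraint kinds
exactly and pairwise distances within 0.5 Å.

## Common-feature layer

Arrangements shared by all actives are found by correspondence-graph
cliques: reference = the most feature-rich active (ties by id, for
determinism); per other molecule, a product graph over kind-matched
feature pairs with edges requiring pairwise-distance agreement within a
bin (default 1.0 Å, commensurate with the 1.6 Å sphere tolerance);
maximal cliques (networkx) give per-molecule realizable subsets, and
iterated intersection keeps the maximal subsets realizable in every
molecule. Candidates are realized with the reference geometry
(`max_omitted` = 1 by default: qualitative models tolerate partial
mapping) and ranked by support then size, with an optional second ranking
by mean-fit discrimination between actives and inactives. On instances
with ≤ 8 features per molecule the candidate sets equal a brute-force
subset-enumeration oracle, and the output is invariant to active input
order.

## Validation statistics

Decoy metrics follow the Güner-Henry formulas (see README). Internal
precision is kept full; two-decimal (GF: four-decimal) rounding happens
only in reports. Count validity additionally requires Ht − Ha ≤ D − A
(inactive hits cannot exceed inactives); under that constraint GF lies in
[0, 1] over exhaustive enumeration of all count tuples with D ≤ 60. One
printed inconsistency is documented rather than emulated: the
common-feature validation table prints GF 0.91, but the footnote formula
on its own printed counts (241, 21, 22, 21) evaluates to 0.9615.

Fischer randomization shuffles activity labels n = 100/(100−CL)−1 times
(19 at 95%), rebuilds the model per shuffle, and requires the true
training score to strictly exceed all permuted scores (rank 1; ties count
against significance). The scoring statistic is the fit/activity
log-correlation of the rebuilt model — the commercial workflow uses its
internal cost function here, which is not printable; the correlation
preserves the test's logic (a real structure–activity link must beat
chance relabelings). Under a fixed model the null scores are exchangeable,
so the type-I error equals 1/(n+1) = 5% at the 95% design, which the
simulation test confirms over 200 seeded replicates.

Selectivity index: IC50(reference cells)/IC50(target cells), reported to
two decimals.

## Screening cascade

Per arm: map → fit threshold (strict >, as the workflow quotes) →
Lipinski → ADMET → optional docking-score filter (inclusive ≥; docking is
never executed, scores are ingested from an external id/score TSV, last
duplicate wins, unscored hits drop with a warning). With two arms the
final hit list is the intersection of arm survivors. Stage outputs never
exceed inputs and each stage's input ids are the previous stage's
survivors.

Lipinski is the strict rule (no one-violation allowance): MW ≤ 500 Da,
rotatable ≤ 10, HBA ≤ 10, HBD ≤ 5, all inclusive. Rotatable bonds are
non-ring single bonds between non-terminal heavy atoms with amide C–N
excluded (RDKit's strict definition).

ADMET levels come from surrogate descriptor models with the same
level/cutoff semantics as the original protocol (favorable levels 3, 0, 3
for solubility, absorption, blood-brain-barrier; pass = equality with the
favorable level, override-able in config since the original cutoff
ordering is not stated): an ESOL-style logS estimate binned at
(−8, −6, −4, −2, 0); a (TPSA, logP) absorption box with level 0 inside
TPSA ≤ 131.6 Å², logP ≤ 5; BBB binned on TPSA at (40, 60, 90). The bin
edges are documented constants chosen from the standard absorption/BBB
rules of thumb, not fitted values; the levels are *not* claims of
equivalence to any proprietary descriptor model.

Similarity search is Tanimoto on RDKit hashed topological fingerprints
with an inclusive threshold (default 0.40) and an optional required
substructure anchor, reflecting the dual scaffold-plus-similarity usage.

## Synthetic data

The generator plants a pharmacophore geometry and emits real, parsable
multi-fragment molecules: dimethyl ether for HBA (feature on O), formamide
for HBD (donor on N; its carbonyl O adds one nearby acceptor, so planted
models used for exact-kind recovery avoid HBD — as does the default
planted model, one HBA plus four hydrophobes), isobutane for HY (feature
at the heavy-atom centroid), benzene for AR. Fragments are randomly
rotated and placed so the perceived feature sits at the planted center
plus jitter (0.05 Å default). The i-th active's features are displaced
radially by a fraction ramping to 0.8 of the tolerance, with seeded
rejection-resampling so every active genuinely maps the model; decoys get
every center perturbed by a separation parameter (3 Å default) and both
carry unshared random extra features. Activities follow
IC50 = 10^(C − fit + ε), ε ~ N(0, 0.3²) in log10 units, C = 8.33 — under
the default model this spans roughly 1e-4 to a few μM over 21 actives,
the regime of the training table. The default decoy database is 25
actives + 300 decoys. Everything is deterministic per seed
(byte-identical SDF).

What the generator does **not** emulate: real chemical connectivity
between feature-bearing groups (fragments are disconnected), conformer
flexibility, realistic decoy property matching (no DUD-E-style matching),
and the chemistry distribution of any real compound database. Passing
tests therefore demonstrate correctness of the algorithms under known
ground truth, not screening performance on real libraries.

## Problem sizes and numerics

Test and driver simulations use 8–21 actives, decoy databases of ≤ 325,
cascade databases of ~100, and oracle instances of ≤ 4 constraints / ≤ 6
features — sizes at which the brute-force oracles are exhaustive and the
whole suite runs in well under a minute. Degenerate inputs are defined
rather than left to float behavior: empty hit lists report yield/EF as
not-applicable; a molecule with no admissible correspondence fits 0 with
an empty mapping; collinear point sets superpose via SVD with a
determinant guard (no reflections); all report rounding is formatting
only. The spec-level interfaces are plain functions plus the numbered
analysis drivers; no console-script CLI is installed.

## Known limitations

- Fit values are comparable across models only when weights are; the
  calibration constant C is meaningful only on its own model's fit scale.
- The clique-intersection common-feature search returns arrangements in
  the reference molecule's geometry; it does not average geometries
  across actives.
- ADMET surrogates rank-order molecules plausibly but their absolute
  levels should not be compared against any commercial descriptor output.
- The fixed-pose/optimized-pose distinction (see Fit scoring) means
  single-constraint fits are always 1·w under optimization.
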