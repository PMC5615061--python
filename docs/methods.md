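# Methods

This note records the models implemented in `ogtscreen`, every tunable
parameter with its default and rationale, what the synthetic generators do
and do not emulate, and the numerical choices that affect results.

## 1. Physicochemical filter cascade (`mol_props`)

Molecules are parsed from SMILES or SDF with RDKit and converted to an
explicit `MolecularGraph` (atoms with element, formal charge, implicit-H
count; bonds with order/aromaticity). Descriptors:

- **Molecular weight** — sum of average atomic masses (RDKit periodic
  table) including implicit hydrogens.
- **Ring systems** — ring bonds are the non-bridge edges of the molecular
  graph (networkx `bridges`); a ring system is a connected component of the
  subgraph they induce. Fused and spiro rings therefore count once, which is
  the intended "ring system" notion (naphthalene = 1, biphenyl = 2).
- **HBD / HBA** — Lipinski convention: donors are N/O bearing at least one
  hydrogen, acceptors are all N and O. An option excludes pyrrole-type N
  from acceptors; it is off by default to keep the plain Lipinski count.
- **Ionization** — formal charges exactly as drawn in the input; a
  zwitterion has both a positive and a negative atom regardless of net
  charge. No pKa model is applied: protonation-state assignment is a
  separate preparation step outside this package's scope.

A compound passes the cascade iff all four rules hold
(`FilterRules` defaults): MW in [250, 600] Da; net charge 0 and not
zwitterionic; 2–4 ring systems; HBA ≥ 1 and HBD ≥ 2. The bounds encode a
lead-like window for a large polar nucleotide-sugar pocket: heavy enough to
span sub-pockets, light enough to leave optimization headroom, enough polar
handles to engage the pocket's hydrogen-bonding residues.

## 2. Ensemble consensus ranking (`ensemble_screen`)

Docking outputs are parsed from PDBQT text via the
`REMARK VINA RESULT: <affinity> ...` line of each MODEL; a model without the
remark is an error, never a silent skip. The default receptor ensemble has
16 members (crystal-structure conformations of the OGT UDP-GlcNAc pocket);
the default search box is a 22 Å cube centred on a reference side-chain
centroid (backbone N/CA/C/O/OXT excluded so the box tracks the pocket-lining
sidechain, Pro559 in the original setup).

Consensus score: per (ligand, receptor), take the best = most negative pose
affinity; average those over receptors; rank ascending with ties broken by
ligand id so ranking is total and deterministic. `strict` mode requires every
ligand to have scores for every ensemble member; `available` mode averages
over present receptors. Top-K default K = 200. Enrichment factor at K is
(actives in top K / K) / (actives overall / N).

## 3. Superposition and pose clustering (`structure_align`)

PDB files are parsed with Biopython (first model; for alternate locations
the first-encountered atom of a given name in a residue is kept).
Superposition is the Kabsch algorithm: centre both point sets, SVD of the
covariance H = Pᶜᵀ Qᶜ, rotation R = Vᵀᵀ · diag(1, 1, det) · Uᵀ so that
det R = +1 (proper rotation, no reflection). Fewer than 3 points or a
rank-deficient covariance with ambiguous sign raises an error rather than
returning an arbitrary frame. Structure-level superposition matches residues
by (chain, number, insertion code) and fits on common CA atoms.

Pose RMSD is computed in the common receptor frame **without** re-fitting —
after ensemble alignment, translational/rotational differences between poses
are signal, not noise. Atom correspondence is by input order; symmetry
equivalence (e.g. a flipped phenyl) is not corrected, which can inflate RMSD
for symmetric ligands (a known limitation).

Clustering is single linkage at threshold 2.0 Å — the conventional
"same binding mode" radius — implemented as connected components of the
thresholded RMSD graph (scipy `csgraph`). Clusters are relabelled
deterministically by (size desc, best affinity, lowest pose id); the biggest
cluster's best-affinity member is the ligand's representative pose.

## 4. Interaction fingerprints, triage, energies (`interaction_profile`)

**Hydrogen bond**: donor heavy atom D (N/O with attached H), acceptor A
(N/O), with |D−A| ≤ 3.5 Å and angle D–H–A ≥ 120°. Hydrogens are assigned to
the nearest heavy atom within 1.3 Å. If a pose carries no hydrogens at all,
detection falls back to the distance criterion only and the bonds are
flagged `distance_only` — never silently mixed with angle-validated bonds.
Both directions (ligand donor → receptor acceptor and vice versa) are
scanned; duplicates by (donor, acceptor) pair are merged. A residue is a
polar contact if any ligand N/O is within 4.0 Å of a residue N/O (a
hydrogen bond implies a polar contact).

**Triage**: the key-residue set defaults to {Gln839, Lys842, Thr921} and the
rule passes if the fingerprint contacts *any* of them (`mode="all"`
available). The source literature states Thr921 in one place and Thr922 in
another; the set is a plain parameter so either convention can be used. A
required residue missing from the receptor model raises an error instead of
vacuously failing the pose.

**Energy decomposition**: for ligand atom i and receptor atom j,

```
E_ij = 332.0636 q_i q_j / (eps * r_ij)                       (Coulomb)
     + sqrt(e_i e_j) * [ (rmin_ij / r)^12 - 2 (rmin_ij / r)^6 ]   (12-6 LJ)
```

with rmin_ij = rmin_i + rmin_j (Lorentz–Berthelot for rmin/2 parameters),
dielectric eps = 1.0 (vacuum; a surrogate score, not a solvated free
energy), pair cutoff 10 Å, and a small built-in element table for LJ
parameters. At r = rmin with q = 0 the pair energy is exactly −ε, which the
tests pin. Per-residue sums and the grand total satisfy exact conservation:
the total equals the sum over residues equals the brute-force double loop.
This is a transparent pairwise surrogate — no polarization, no solvation
(MM-PBSA/GBSA is out of scope).

## 5. Assay models (`assay_models`)

**4PL**: response(d) = bottom + (top − bottom) / (1 + (d / IC50)^hill).
Fitting uses `scipy.optimize.curve_fit` (trf) with bounds bottom ∈
[−0.1, 0.5], top ∈ [0.5, 1.5], IC50 ∈ [d_min/10, d_max·10], hill ∈ [0.1, 10]
and tight tolerances; the start point is taken from the extreme-dose
responses with the IC50 seeded at the half-max bracketing dose. If the
observed response span is below 0.2 the curve is declared right-censored and
IC50 is reported as ≥ d_max rather than a meaningless extrapolation.

**Inhibition modes** (Michaelis–Menten with substrate S, parameters Ki, Km,
Vmax, mixed-mode α; default S = 40 µM):

| mode | rate law denominator | Cheng–Prusoff IC50 |
|---|---|---|
| competitive | Km(1 + I/Ki) + S | Ki (1 + S/Km) |
| uncompetitive | Km + S(1 + I/Ki) | Ki (1 + Km/S) |
| noncompetitive | (Km + S)(1 + I/Ki) | Ki |
| mixed | Km(1 + I/Ki) + S(1 + I/(αKi)) | Ki (S + Km) / (Km + S/α) |

Each closed form was verified algebraically against its rate law (the dose
at which fractional activity = 1/2). Default grids match the study design:
doses (0.25, 1, 3, 10, 30, 100, 250, 500) µM and substrate
(2, 10, 25, 50, 100, 200, 400) µM; `ic50_vs_substrate` re-centres its dose
grid on the predicted IC50 at each S so the fit is well-conditioned across
the whole substrate range.

**Noise**: multiplicative mean-one lognormal. For coefficient of variation
CV, σ² = ln(1 + CV²) and the factor is exp(N(−σ²/2, σ²)), so the expected
response is unbiased. Default CV 5 %, 3 replicates — typical plate-assay
precision.

## 6. Synthetic generators (`synthetic_data`)

All generators draw from `numpy.random.default_rng(seed * 16 + stream)` so
each generator has an independent stream per user seed and results are
reproducible across platforms.

- **Library** (`gen_library`): compositional molecule building (benzene /
  naphthalene units linked by single bonds, with hydroxyl, methoxy,
  ammonium, carboxylate and alkyl substituents at unsubstituted ring
  positions). Each rule's pass/fail is planted independently with
  configurable fractions, and the true descriptors (MW, charge,
  zwitterionicity, ring systems, HBD/HBA) are recorded as ground truth. MW
  control is exact: the molecule is built, weighed, then alkyl-padded to
  land inside or outside [250, 600] as planted. It emulates descriptor
  diversity of a screening library, **not** real chemotype diversity — no
  heteroaromatics, stereochemistry or sp³ scaffolds.
- **Score matrix** (`gen_score_matrix`): actives draw a latent affinity from
  N(−9.0, 0.5) and decoys from N(−6.0, 1.0) kcal/mol; per-receptor jitter
  sd 0.3 models conformation-dependent docking variability; non-best poses
  add positive exponential offsets (mean 0.5). Defaults (4,234 decoys + 10
  actives × 16 receptors, 5 poses) are the study-scale conditions. The
  separation is generous relative to real screens — the generator tests
  ranking machinery, not docking accuracy.
- **Toy complex** (`gen_toy_complex`): eight UDP-pocket residues (Asn557,
  Gln839, Lys842, Ala897, Lys898, His920, Thr921, Phe868) on a ring of
  radius 8 Å with polar side-chain atoms placed inward; planted hydrogen
  bonds position a ligand acceptor by law-of-cosines so that the D–A
  distance and D–H–A angle are met exactly. Geometry only — no real rotamer
  or backbone structure.
- **Pose clouds** (`gen_pose_cloud`): k jittered copies of a pose within a
  cluster radius plus one stray pose 10 Å away, the minimal structure that
  exercises clustering and representative selection.
- **Assays** (`gen_assay_data`): dose–response tables from the models in
  §5 with the lognormal noise above.

Generator defaults are the study conditions and are set from the modelled
experiment, not adjusted against any test outcome.

## 7. Pipeline (`pipeline`)

`run_screen` chains filter → synthetic or supplied scores → consensus
ranking → top-K → toy-complex clustering and triage, writing
`filter_report.tsv`, `consensus.tsv`, `top_k.tsv`, `clusters.tsv`,
`triage.tsv` and `report.json`. Stage counts are non-increasing by
construction. Reports contain no timestamps — wall-clock text lives only in
`run.log` — so a rerun with the same configuration is byte-identical. The
configuration hash covers scientific parameters only (output directory and
log level excluded). Unknown configuration keys are an error, not a warning.

## 8. Numerical and determinism choices

- Ranking, clustering and relabelling always carry explicit deterministic
  tie-breaks (ligand id, pose id), so no result depends on sort stability
  of intermediate containers.
- Kabsch is validated in-tree against an independent quaternion (Horn)
  RMSD oracle; consensus ranking against a brute-force loop; energies
  against a brute-force double loop; hydrogen-bond detection against an
  exhaustive O(n²) scan.
- Seeds derived internally stay below 2³¹ − 1 for portability.
- Floating-point table output uses fixed formats; JSON reports use sorted
  keys.

## 9. Limitations

- No conformer generation or docking is performed; scores are parsed or
  simulated. The package models the decision layer of the screen.
- RMSD is not symmetry-corrected.
- The energy decomposition is a vacuum pairwise surrogate (no solvation,
  polarization or entropy), suitable for ranking contacts, not for
  absolute affinities.
- Protonation states are taken as drawn; no pKa engine.
- The Thr921/Thr922 key-residue ambiguity is left as a parameter.
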