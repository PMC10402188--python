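# Methods

This note documents the model, the numerical choices, and what the synthetic
validation does and does not establish.

## Scoring function

The pose score is a linear expansion of all ligand–ligand (i ≠ j) and
ligand–pocket atom distances in a Gaussian radial basis:

D̂_i = Σ_j Σ_k C_ijk exp(−(d_ij − d̃_k)²/σ²) + β,  score = (1/L) Σ_i D̂_i.

* Basis: K = 24 reference distances d̃_k = k·(32/24) Å, k = 0…23, width
  σ = 32/24 Å. "Evenly spaced from 0 to 32 Å" is ambiguous for 24 points;
  we set the spacing equal to σ, so the last center sits at 23·32/24 ≈
  30.67 Å. Gaussians of this width cover the 0–32 Å range either way and the
  choice keeps spacing = σ exactly.
* Self pairs (i = j) are excluded; ligand–ligand pairs are counted once per
  scored atom i (ordered pairs), since the sum is per atom.
* D̂ is not clamped; negative predictions are allowed. An optional 40 Å
  distance cutoff exists for speed but is off by default — beyond ~32 Å + 4σ
  a unit coefficient contributes < 1e−6, so the cutoff is numerically
  irrelevant.

## Pose parameterization

A pose is (translation ∈ R³ in Å, rotation ∈ R³ as an axis-angle vector,
one dihedral update per rotatable bond, radians). Application order is fixed:
torsions first (each rotates only its moving-side atoms about the current
bond axis), then the rigid rotation about the centroid of the input
conformation, then the translation. The fixed order makes inversion closed
form; torsion rotations about distinct bonds commute (moving-side sets are
nested or disjoint), so negated torsions invert the torsional part and the
rigid part is inverted analytically. Rotations go through a
Rodrigues form R v = v + a(θ²)(r×v) + b(θ²)(r×(r×v)) whose coefficients
switch to series below θ² = 1e−6, keeping value *and derivative* smooth at
θ = 0 — the L-BFGS start point.

Rotatable bonds are non-ring single bonds whose endpoints both have ≥ 2
heavy neighbours, excluding amide C–N bonds (standard docking convention;
deterministic and testable). The moving side is the smaller fragment, ties
broken toward the side containing the bond's higher-indexed endpoint.

RMSD is computed without realignment (poses share the pocket frame).
Symmetry correction minimizes over feature-preserving graph automorphisms
(networkx VF2), capped at 10,000 mappings with the identity always included;
it is on by default in evaluation because aromatic and terminal symmetries
otherwise inflate RMSD.

## Pocket representation

Residue selection: every standard amino-acid residue with any heavy atom
within the cutoff (default 5 Å, read inclusively) of any heavy atom of any
reference ligand pose; atom–atom distances, not residue centers. Residues
without an α-carbon record are unusable and dropped. Curation filters reject
pockets with fewer than 5 residues or an axis-aligned bounding box over 42 Å
on any side. Residue graph edges connect α-carbons within 10 Å (closed
comparison); the pocket centroid is the unweighted mean of its heavy-atom
coordinates. Waters and hetero groups are ignored; inputs are assumed
prepared (no protonation or tautomer handling).

## Noising (training-pair generation)

Severity levels t = 1…16 with σ(t) = σ_max·(t/T)², the simplest quadratic
reaching σ_max at T; maxima are 4 Å (translation), 1.5 rad (each
rotation-vector component), 2.5 rad (each torsion). Noise is drawn directly
at level t from the crystal pose rather than accumulated through a Markov
chain: the regression target is the per-atom distance to the crystal
position, which depends only on the endpoint. Torsion draws are returned
unwrapped — an angle and its 2π shift give the identical pose, and the raw
draws keep the configured σ empirically checkable (a `wrap_angle` helper
normalizes for display). The target level t is sampled uniformly per
example.

## Encoder

The Twister maintains seven tracks (ligand atoms, dense ligand bonds with a
learned "no bond" embedding, residues, residue-edge hiddens seeded from a
16-RBF encoding of CA distances spanning 0–10 Å, pocket atoms, and the
ligand–ligand / ligand–residue / ligand–pocket-atom interaction tracks,
the interactions initialized to zeros). Each block runs: an edge-featured
attention convolution on the ligand and residue graphs (node and edge states
updated), residue ↔ pocket-atom cross-attention, interaction entries
refreshed from their endpoint nodes, each node attending over the
interaction entries that involve it, and a dense + layer-norm finalizer per
track; LeakyReLU (slope 0.1) follows each operation, and after every other
block each track adds its state from two blocks earlier. Attention is
standard scaled dot product (4 heads by default). Pocket atom *coordinates*
never enter the encoder — geometry enters only through CA-distance
encodings — so the coefficients are invariant to rigid motion of the pocket
by construction, and all operations are permutation-equivariant in the
ligand atoms.

Heads: linear maps from the ligand–ligand and ligand–pocket-atom interaction
tracks emit the 24 coefficients per pair; β comes from a single scalar head
over mean-pooled final tracks (pose-independent, since no track sees pose
coordinates). Routing every track into that head also guarantees the
dead-path detector's property that each parameter receives gradient.

Reference depth is 32 blocks; the default configuration here is 4 blocks
with widths 64/32/… scaled to 32 node / 16 interaction channels so the full
architecture is exercised end to end on one CPU. Layer widths, head counts,
the attention variant and the optimizer are open choices; we use Adam
(default lr 1e−4; the toy overfitting runs below use 2e−3, which converges
in a few hundred steps at this scale). Input vocabularies are closed
(elements, charges −2…+2, sp/sp2/sp3/other, 0–4 hydrogens, four bond orders,
20 amino acids); anything outside raises an explicit unknown-feature error.

Training pre-generates a fixed pool of noised examples per complex (default
32) and draws minibatches (default 8 per complex per step) from it. Because
an example's coordinates are fixed, its RBF features Φ are precomputed once
and the per-example loss is linear in C; only the encoder forward/backward
is paid per step and per complex. A non-finite loss aborts with a
diagnostic. Everything is float64 NumPy, so fixed seeds give bitwise
identical traces.

## Inference

Conformers come from RDKit distance-geometry embedding (ETKDGv3, seeded,
hydrogens added) followed by UFF relaxation; embedding retries with shifted
seeds a bounded number of times. Initialization: torsions uniform on
(−π, π], rotation uniform over SO(3) via a random unit quaternion, ligand
centroid placed at the pocket centroid plus N(0, σ²) translation noise with
σ = 4 Å, matching the training maximum. L-BFGS (scipy L-BFGS-B: history 10,
max 200 iterations, ftol = gtol = 1e−6) minimizes the score over the pose
parameters starting from zero relative to the initialization, with the
exact gradient obtained by backpropagating through the pose transform.
Restarts whose scores go non-finite are excluded and counted; 16 restarts by
default, lowest final score wins. The encoder runs exactly once per docking
job.

## Evaluation

A record is a (pocket, ligand, best-pose RMSD) triple. Success is strict
RMSD < threshold (2 Å and 5 Å by default). Normalized accuracy is the
unweighted mean of per-pocket success fractions; unnormalized is the pooled
fraction. The benchmark harness extracts the pocket from the union of
reference ligand poses, applies the curation filters (failing rows are
skipped with a reason, not counted as failures), docks, and reports both the
best-scored pose's RMSD and, diagnostically, the best RMSD over all restarts.

## Synthetic fixtures and the oracle

Toy complexes place a small embedded ligand (butane, pentane, a 3-torsion
diether, benzene, …) at the origin and surround it with n residues whose
heavy atoms (α-carbon plus three satellites each) sit on a shell of radius
r ± 0.5 Å with random amino-acid classes and protein-like elements. They are
geometric scaffolds: they have realistic distance scales and pass the
curation filters, but no chemistry — no sterics, no interaction
preferences, no receptor conformational change. Benchmarks on them therefore
validate the *machinery* (featurization, scoring, gradients, minimization,
bookkeeping), not chemical pose-prediction accuracy on real proteins. The
default benchmark fixtures use r = 6 Å with a 7.5 Å extraction cutoff so
every shell residue qualifies.

Oracle coefficients are fitted per ligand atom by kernel ridge regression of
the true distance-to-crystal over 200 perturbed poses (half at graded noise
levels, half fully randomized like a docking restart). The bias β is fixed
to the mean target distance and C regresses the deviation from it: a pose
drifting outside the sampled cloud then scores the unattractive baseline
instead of zero, which would otherwise hand the minimizer a spurious
far-field minimum. The ridge is 1e−2 × the mean kernel diagonal — strong
enough to keep the interpolant smooth between samples, which matters more
for minimization than the last digit of fit residual (RMS residual ≈
0.02 Å; prediction error ≈ 0.2 Å at the crystal, ≈ 0.1 Å at held-out 2 Å
displacements). Degenerate (zero-variance) perturbation sets trigger a
warning and fall back to the regularized constant solution.

## Numerical / degenerate-input notes

* The analytic oracle objective adds 1e−12 inside its square root so the
  gradient stays finite at the exact optimum.
* Self-pair distances are masked before the square root in the
  differentiable scorer for the same reason.
* Atoms with no graph neighbours receive zero messages in the graph
  convolutions (masked softmax would otherwise be uniform over garbage).
* scipy's L-BFGS-B line search guarantees a non-increasing accepted-score
  trace; as a belt-and-braces measure a final score above the initial one
  returns the start pose.

## Problem sizes used in the shipped validation

Recovery and docking experiments use 5 (resp. 3) complexes of 3–6 heavy
atoms with up to 3 torsions, 8 residues / 32 pocket atoms, and 16 restarts;
training uses 3 complexes, a 4-block encoder, a 96-example pool and 300 Adam
steps; noise statistics use 10,000 draws; gradient checks use 20 seeded
instances. These sizes were chosen so the whole validation runs in minutes
on a single CPU while still exercising every code path at full depth.

## Known limitations

* No trained weights are shipped; reproducing published cross-docking
  accuracy requires the external training corpus and GPU-scale training,
  which are out of scope here. The learned-score path is validated at toy
  scale (overfitting synthetic complexes) and by contracts (equivariance,
  invariance, gradient flow).
* Rigid receptor; no ring flexibility; no bond-length/angle relaxation of
  the ligand during minimization.
* No structure preparation (protonation, tautomers, altloc logic beyond
  first-model reading); cross-structure pockets must arrive pre-aligned.
* The torsion-commutation argument behind closed-form pose inversion relies
  on moving sides forming a laminar family, which holds for the
  smaller-fragment convention used here; it is additionally pinned by
  property tests.
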