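# Methods

This note documents the models, numerical choices and known limits of
conformap's analyses, and what its synthetic benchmarks do and do not
demonstrate about real structures.

## Coordinate handling

Files are parsed with gemmi; only the first model is kept (the package
targets crystal structures, which have one).  Alternate locations are
collapsed before any geometry: per atom name within a residue the
highest-occupancy altloc wins, ties going to the alphabetically first
label.  Residues are identified by author numbering plus insertion
code throughout, because that is how structure papers name residues
(His274, Glu91, ...).  Waters (HOH/WAT) and heteroatoms are retained;
monatomic ions are recognised as single-atom HETATM residues whose
element is a common cation/anion.  PDB output refuses residue numbers
above 9999 rather than silently truncating fixed-column records.

## Superposition and residue correspondence

The rigid superposition is the closed-form least-squares fit (SVD of
the 3x3 covariance) with the determinant-sign correction that excludes
reflections.  Degenerate inputs — point sets of rank < 2, where one
rotational degree of freedom is undetermined — are still solved
optimally but flagged.  RMSD values are unweighted, single-pass, over
all shared atoms of the chosen selection: no outlier rejection or
iterative trimming, which matches how "global RMSD over n CA atoms" is
conventionally reported alongside near-complete atom counts.

Cross-homolog correspondence uses global Needleman-Wunsch with affine
gaps (Gotoh recurrences; a gap of length L costs open + (L−1)·extend),
BLOSUM62, defaults −11/−1.  The traceback tie-break is fixed —
diagonal, then vertical (gap in B), then horizontal — so the mapping
is deterministic.  Unknown residues score as 'X'.  The implementation
is dynamic-programming from first principles because the deterministic
tie-break is part of the contract; its scores are cross-checked against
Biopython's PairwiseAligner in the test suite.

## Interlobe rotation

Domain motion is quantified by the standard two-stage decomposition:
align on one selection, then fit the rotation of the other; the angle
comes from the trace, the axis from the antisymmetric part (with an
eigenvector fallback near 180 deg).  Domains are user-specified
residue ranges, not automatically decomposed, and the screw-axis
translation component is not reported.  The angle is symmetric in the
two structures and invariant to any rigid transform applied to either.

Noise sensitivity: with isotropic coordinate noise of sd sigma on both
structures, the fitted angle of a selection with n atoms and
per-axis inertia I (sum of squared distances from the centroid,
perpendicular to the axis) has spread ~ sigma·sqrt(2/I).  For the
default synthetic benchmark (60-atom alignment lobe, 0.3 A noise) this
is ~0.3-0.4 deg (1 sigma), so the benchmark's 1-degree recovery bound
is a ~3-sigma check.  Near zero true angle the reported angle (a norm)
is biased upward by error components about the other axes; this is a
property of the angle-of-rotation estimator, not of the fit.

## Ensemble PCA

The ensemble core is the set of reference residues whose chosen atom is
resolved in every member (mapped by numbering or by alignment), ordered
by the reference.  Members are aligned by iterating superposition onto
the mean and mean recomputation until the mean shifts < 1e-4 A RMSD
(max 10 iterations; non-convergence proceeds with a warning).  The
alignment frame for ensemble PCA is not standardised in the literature;
aligning to the evolving mean is the common choice and is seeded by a
named reference for determinism.

Coordinates are unweighted (no masses), so projections are in Angstrom.
Variances are sample (n−1) eigenvalues; the mode signs are fixed by (a)
the member with the largest interlobe opening projecting positively on
PC1 when opening values are supplied, (b) otherwise the first non-zero
component of each mode being positive.

**Counting modes above the noise floor.**  A mode is reported
significant when its variance is at least 5% of the leading variance
(scree criterion) *and* more than twice the median non-zero variance
(so a pure-noise spectrum, where all eigenvalues share one scale,
reports zero).  Both constants are ordinary scree-plot practice.

**Curvature caveat.**  A family of rigid rotations traces a curved arc
in coordinate space, so a one-parameter hinge ensemble is not exactly
rank-1: PCA places a small "quadratic" mode (variance ~ var(theta^2)/4
relative to the leading mode) after the genuine degrees of freedom.
At a 15-degree opening spread this mode carries ~1-4% of the leading
variance and falls below the significance floor; at a 45-degree spread
(the noise-free opening-grid demonstration) it reaches ~0.6% of total
variance, which is why that demonstration asserts a leading-variance
fraction of >= 0.95 with a large spectral gap rather than exactly 1.

## Ion-site classification

The classifier reproduces the distance/coordination-number reasoning
used to assign monovalent cations in electron density: K+ prefers ~6
O/N ligands near 2.8 A, Na+ sits near 2.4 A, and a water cannot accept
donation from four or more carbonyl/water oxygens at once.  Shell
membership uses a 3.5 A cutoff (bounds the first shell of K+);
the K+/Na+ boundary is 2.6 A, splitting the two canonical bond
lengths; all thresholds are configurable.  This is deliberately a
simplification of full metal-site validation: no bond-valence sums, no
electron-density or B-factor evidence (which requires maps and
refinement output), and no divalent-ion geometry.  The rationale string
attached to every call states that the evidence is geometric only.

## Synthetic generator

The generator emulates the features the analyses rely on and nothing
else: two rigid lobes joined at a hinge, an exactly known opening
(rotation about y through the hinge) and twist (subsequent rotation
about the interlobe x axis) applied to the large lobe, isotropic
Gaussian coordinate noise (per component), ideal helices, and
octahedral ion shells with seeded radial distortion.  All randomness is
`numpy.random.default_rng` under explicit seeds; ensemble member seeds
derive as base + index so ensembles extend without collisions.

Lobes are crossed helical bundles (helices alternating along y and z,
stepping outward in x).  Two design constraints set this shape: each
lobe needs spread in all three dimensions, because a lobe that is thin
in any plane fits its rigid-body orientation poorly under coordinate
noise and that error dominates recovered interlobe angles; and the two
lobes' inertias about the hinge are kept similar so ensemble alignment
splits an interlobe rotation near-symmetrically, minimising the
curvature mode described above.  Within those constraints the exact
offsets are aesthetic.

The benchmark ensemble (`make_benchmark_ensemble`) draws opening and
twist as stratified normal quantiles, shuffled by the seed,
standardised so the sample sd equals the nominal value exactly, and
orthogonalised in-sample.  This is a variance-reduction design: the
benchmark's stated conditions (spreads, independence) then hold for
every seed rather than only in expectation, so parameter-recovery
results measure the method, not sampling luck.  Member coordinate
noise remains fully stochastic.

What passing these benchmarks does *not* show about real data: real
domains are not rigid (hinge-bending mixes with internal strain), real
ensembles are tiny and unevenly sampled, crystal contacts bias
conformations, and real coordinate error is neither isotropic nor
homogeneous.  Absolute PC coordinates depend on the ensemble
membership and selection ranges, so landscape positions are
comparable only within one fitted model.

## Pipeline determinism and problem sizes

`run_pipeline` writes byte-identical CSV outputs for identical configs
and inputs (timestamps appear only in the report's provenance block);
per-task failures are recorded in the report without aborting other
tasks.  The test suite and the acceptance script run entirely on
generated structures of 180 residues (ensembles of 30 members) and
100 ion sites — sizes chosen so the full ground-truth sweep, including
the direct-minimization superposition oracle, completes in seconds
while leaving the estimators' noise properties clearly measurable.
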