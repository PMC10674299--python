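# Methods

This note documents the models, conventions and numerical choices behind
`dualqsar`, in the order the pipeline runs them.

## Molecule records and atomic properties

A `MoleculeRecord` carries one 3D conformer and four per-atom properties:
partial charge q_i (elementary charges), an approximate accessible van der
Waals surface contribution v_i (Å²), and the Wildman–Crippen logP and molar
refractivity contributions L_i and R_i.  When built from a structure
(`from_smiles` / `from_rdkit` / `from_sdf`):

* the conformer comes from a **seeded ETKDG distance-geometry embed** followed
  by MMFF94 minimization (the seed is recorded in the record metadata, so
  descriptor tables are reproducible);
* charges are **Gasteiger PEOE** — an iterative partial-equalization of
  orbital electronegativities.  The original models were fitted with
  semi-empirical AM1 charges from a proprietary suite; PEOE is a documented,
  open replacement, and single-compound descriptor values printed alongside
  the original models are therefore treated as loose references only
  (`published.MOE_REFERENCE_VALUES`), never as targets;
* v_i are Labute's connection-table approximation to the accessible VDW
  surface; L_i, R_i are Crippen atomic contributions.

The van der Waals radii table (Bondi values, versioned
`bondi-1964/v1`) is shipped in `molecule.py`.

## Descriptors

**Partial-charge VSA.**  Q_VSA_FHYD = Σ{v_i : |q_i| ≤ 0.2}/Σv_i and
Q_VSA_PNEG = Σ{v_i : q_i < 0}/Σv_i are fractions in [0, 1].  Q_VSA_POL is
implemented as the *unnormalized* surface sum over atoms with non-negative
charge: the printed description of that descriptor is the conventional
"total positive surface area" definition, and we follow the printed text
rather than the name.  Q_RPC− is the most negative q_i divided by the sum of
negative q_i, defined as 0 for molecules with no negative atom.

**SlogP-binned VSA.**  SlogP_VSA3 sums v_i with L_i ∈ (0, 0.1];
SlogP_VSA4 with L_i ∈ (0.1, 0.15].  Bins are lower-exclusive /
upper-inclusive; a complete bin series partitions the total surface.

**Topological.**  Balaban J is computed on the unweighted heavy-atom graph:
J = q/(μ+1) · Σ_edges (s_i s_j)^(−1/2) with q edges, μ the cyclomatic
number and s_i distance-matrix row sums.  The GCUT_SMR descriptors are
ordered eigenvalues of a Burden-style matrix: diagonal R_i, off-diagonal
0.1·(bond order) for bonded pairs and 0.001 otherwise.  GCUT_SMR_0 is the
smallest eigenvalue; GCUT_SMR_1 the eigenvalue at position ⌈n/3⌉ of the
ascending spectrum (clamped for tiny molecules, so a single heavy atom
returns R₁ for both).

**Dipole components and DCASA.**  The frame in which the original dipole
components were reported is not recoverable, so components are made
reproducible by re-orienting every molecule into a **canonical inertial
frame**: principal axes of the heavy-atom unit-mass inertia tensor, ordered
by descending moment, each axis sign-fixed so the atom with the largest
absolute projection has a positive coordinate.  DipoleY/Z = 4.803·Σq_i·r_i
(Debye).  DCASA = |ASA⁺·max(q_i>0) − ASA⁻·|min(q_i<0)|| where ASA± are
water-accessible surface areas (probe 1.4 Å) of positively/negatively
charged atoms; a missing charge sign contributes 0.  SASA is a
Shrake–Rupley numerical surface (256 golden-spiral samples per atom,
≈2% accurate for isolated spheres), evaluated in the canonical frame so the
result is invariant under rigid motion of the input up to the hard
in/out sampling mask (~0.1% relative).

**Energies.**  E is the total MMFF94 energy of the stored conformer; E_tor
the torsion plus out-of-plane subtotal (term-enable flags).  Force-field
energies are convention-dependent, so only ordering and invariance
properties are asserted (e.g. eclipsed > staggered ethane torsion energy).

**Grid-field (VolSurf-style) descriptors.**  A regular grid (spacing 0.5 Å,
margin 4 Å) encloses the molecule.  The polar probe combines a unit-charge
Coulomb term (332.06·q_i/r kcal/mol) with a Lennard-Jones term (well depth
0.15 kcal/mol at r_i + 1.4 Å); the hydrophobic probe is LJ-only with
shallow per-atom wells (0.25 kcal/mol for C/S/Cl/Br/I, 0.02 for polar
atoms) at r_i + 1.7 Å.  The integy moment at level k is the distance from
the heavy-atom centroid to the barycenter of grid points with field energy
at or below the k-th threshold (hydrophilic schedule −0.2, −0.5, −1 … −6;
hydrophobic −0.2 … −1.6 in 0.2 steps); an empty sub-level set gives 0, and
vsurf_EDmin1 is the deepest hydrophobic field value (0 when nothing is
attractive).  These conventions reproduce the qualitative behaviour of the
VolSurf family and are explicitly **not** value-compatible with proprietary
engines.

**Pharmacophore-feature surface.**  Every heavy atom receives exactly one
type (aromatic; O/N donors, acceptors, or polar for O–H; hydrophobic
aliphatic carbons and Cl/Br/I; everything else "other"), so the per-type
surface sums partition the heavy-atom surface; vsa_other is the "other"
sum.

## Dataset design

Constancy checking removes every column constant overall **or within any**
cancellation group ("any" is the stricter reading and the one implemented;
it is configurable).  Cancellation groups are venetian blinds over the
stored row order (row i → group i mod 5).  Autoscaling uses the sample
(n−1) standard deviation.  PCA is the SVD of the autoscaled matrix; the
split runs classic Kennard–Stone (initialize with the most distant pair,
then repeatedly add the point maximizing its minimum distance to the
selected set, ties to the lowest row index) on [8 PC scores ∥ autoscaled
response].  A duplex variant (alternating train/test picks along the
selection order) is available behind a flag; classic selection is the
default because the published description matches it.

## PLS, cross-validation and ISE

NIPALS PLS1 runs on internally autoscaled data and reports collapsed
coefficients on the original scale; latent-space and collapsed predictions
agree to 1e−8 by construction and by test.  Zero latent variables predict
the training mean.  Cross-validation leaves out each venetian-blind group in
turn; Q² = 1 − PRESS_cv/TSS.  The latent-variable count is not prescribed by
the published description, so each fit selects it by maximizing Q² over
1..min(10, rank) — logged per cycle.

The printed importance formula has no absolute values, which would make
"minimum importance" depend on coefficient sign; the standard ISE form
z_v = |b_v|·s_v / Σ|b_v|·s_v is used instead.  Each elimination cycle drops
the single minimum-importance descriptor (ties: first column) and records
Q²; the selected cycle maximizes Q², with ties resolved toward fewer
descriptors.  A run starting from p descriptors records p cycle states
(p − 1 eliminations).

External validation: PRESS = Σ(y_test − ŷ)², SD = Σ(y_test − ȳ_train)²,
r²_pred = (SD − PRESS)/SD, RMSE = √(PRESS/n_test) on the evaluation set
(the refit entry point reports it on the training fit, matching how the
published statistic is quoted), and r²_ncv the squared fitted/observed
correlation on training.

## Frozen published models

`model_A.json` / `model_B.json` carry the published coefficients verbatim
(model A intercept 5.88651, 10 descriptors; model B 7.00986, 11
descriptors) plus the published relative-importance indices and the sign of
association.  The package never refits them.  **Limitation:** the
coefficients are calibrated to the descriptor conventions of the engine
they were fitted with.  This package's engine differs (PEOE vs AM1 charges,
Labute vs proprietary surfaces, its own field probes), so applying the
frozen equations to descriptors computed here yields shifted absolute pKi
values; they are served for use with descriptor tables on the original
conventions, and for interpretation (signs, importance ranking).
`reproduce_published_fit` refits PLS on a per-compound descriptor table
restricted to a frozen model's descriptors; the original per-compound
supplementary tables are not redistributable here, so the corresponding
acceptance check fails by construction and the computational path is
exercised on synthetic stand-ins.

The selectivity classifier labels a compound TAAR1-selective when
ΔpKi = pKi(TAAR1) − pKi(α₂-ADR) ≥ 1 log unit (ten-fold), ADR-selective
below −1, dual otherwise; the threshold is configurable because the source
work never quantifies "selective".

## Pharmacophore models

PM_A and PM_B ship as constraint graphs — typed slots and pairwise
distances — not rigid templates, because the published distance graphs are
incomplete (PM_A's flexible hydrophobic spacer F2 carries no distance and is
a class-only slot).  Matching enumerates class-compatible injective slot
assignments (AroǀHyd slots accept aromatic or hydrophobic features),
minimizes the RMS constraint deviation, and declares a match when every
deviation is within the tolerance (default ±0.5 Å; the source work prints
no tolerances).  Feature perception places aromatic features at ring
centroids, hydrophobic features at centroids of connected groups of two or
more hydrophobic heavy atoms (a lone methyl carbon is not a hydrophobe
core), and donors/acceptors on the N/O atoms themselves, including aromatic
NH donors and pyridine-type acceptors.

## Synthetic data

`gen_pls_dataset` draws X = T·Pᵀ + E (standard-normal scores, sparse
loadings, Gaussian noise, default sd 0.1) and
y = c + s·(Tq)/σ₀ + f, with c and s fixed so the noiseless signal is
centred at the midpoint of the pKi window 5.4–8.7 (derived from the printed
Ki extremes 2–4250 nM) with ±2 sd spanning it, and f Gaussian with sd
0.3 pKi by default.  The true coefficient vector β = P(PᵀP)⁻¹q·s/σ₀ and its
support are returned.  Two loading structures are available: `random`
(dense Gaussian loadings on the support — realistic collinear descriptor
blocks) and `identity` (one factor per support descriptor — the
uncorrelated, identifiable setting equivalent to a direct sparse regression
y = Xβ + ε, used to measure variable-selection recovery, since under
rank-deficient collinearity full-support recovery is not statistically
identifiable).  What the generator does **not** emulate: real descriptor
distributions are skewed, bounded and block-correlated by construction
(surface sums, eigenvalues), and real affinity noise is not homoscedastic
Gaussian — passing recovery tests therefore demonstrates correctness of the
selection machinery, not expected performance on laboratory data.

`gen_pharm_points` embeds a constraint graph by seeded least-squares stress
minimization (restart until the worst residual is below 1e−6 Å, typically
the first attempt) and adds Gaussian positional jitter.

`fixture_sar_table` stores only Ki pairs that are individually reported;
two values pinned uniquely by a two-compound range statement and its other
member are marked "derived by elimination" in the provenance column, and
one compound has a deliberately missing cell.

## Problem sizes and determinism

Everything stochastic is driven by explicit integer seeds
(`numpy.random.default_rng`).  The test suite runs the variable-selection
recovery study at 45×30 over 25 replicates and keeps grid-field molecules
small (≤ 3 heavy atoms for field symmetry checks, ethanol/benzene
elsewhere); these sizes were chosen to keep the full suite under a minute
while leaving every statistical conclusion comfortably powered.
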