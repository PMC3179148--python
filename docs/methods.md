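# Methods

This note documents the models, conventions and numerical choices behind
`fieldqsar`, and what the synthetic-data experiments do and do not show.

## Ligand preparation

Input conformers are authoritative: the package performs no geometry
optimization, conformer generation or tautomer enumeration.  Structures are
read from SDF (V2000) or MOL2; records without genuine 3D coordinates
(including all-z-zero "flat" records) are rejected by id.  Explicit
hydrogens are required for charges and fields; when a structure arrives with
implicit hydrogens they are added with coordinates inferred from the heavy-
atom geometry.

Partial charges are Gasteiger (PEOE) charges as implemented in RDKit.  The
classic field-QSAR literature mostly used the Gasteiger–Hückel variant of a
commercial package; plain Gasteiger is a documented source of numerical
divergence from such results, but is self-consistent within this package.

Atomic field properties (the ω_ik of the similarity indices) come from a
versioned scheme file (`schemes/default.yaml`):

| property | convention | default |
|---|---|---|
| steric | (r_vdW/r_vdW(C))³, carbon ≡ 1.0 | Bondi radii |
| electrostatic | Gasteiger partial charge (e) | — |
| hydrophobic | Wildman–Crippen atomic logP contribution | RDKit table |
| donor / acceptor | SMARTS rules, flag on the heavy atom | scheme file |
| Lennard-Jones | generic ε (kcal/mol), R* (Å) per element | scheme file |

Protonation: the scheme protonates aliphatic (sp³, non-amide, non-aryl)
amines, the usual pH 7.4 convention for amine-bearing CNS ligand series;
this is configurable per scheme because the appropriate states are a
modeling decision, not a property of the file format.

Kᵢ (nM) → pKᵢ conversion is pKᵢ = −log₁₀(Kᵢ·10⁻⁹); it is exact, strictly
decreasing, and shifts by −1 per tenfold affinity loss.

## Alignment

The series is aligned on its common core: a connected, ring-bond-constrained
maximum common substructure over heavy atoms (RDKit rdFMCS), or a
user-supplied SMARTS for the common case where the chemist knows the core.
Each molecule is rigidly superposed onto the chosen template (by default the
most potent compound) with the Kabsch SVD algorithm; reflections are never
returned, and collinear cores raise an error because the rotation is then
underdetermined.  When a symmetric core admits several atom correspondences,
the one minimizing the post-superposition RMSD is used, with a lexicographic
tie-break for determinism.  Substituent torsions are never adjusted.

## Lattice and fields

The grid spans the union bounding box of all aligned heavy atoms plus a
margin (default 4.0 Å) at 2.0 Å spacing, with the origin snapped down to a
multiple of the spacing so that rigidly translated inputs produce rigidly
translated (not re-rastered) grids.  This snapping is this package's
reproducibility convention; commercial tools place the box opaquely.

CoMFA: steric energy is a 6–12 Lennard-Jones sum over atoms with
R_ij = R_i + R_probe and ε_ij = √(ε_i ε_probe) for an sp³-carbon probe;
electrostatic is 332.0636·q_probe·q_i/(ε(r)·r) with ε(r) = r.  Both are
truncated to ±30 kcal/mol.  A probe exactly on an atom is a steric
exclusion, not a numerical fault.  At excluded points the electrostatic
value is meaningless and is replaced by the **training-set** column mean
(computed over non-excluded training entries, frozen for test-set mapping).

CoMSIA: A_k(q) = −Σᵢ ω_probe,k·ω_ik·exp(−α·r²) with α = 0.3 and all probe
properties +1; no cutoff.  The implementation is a single vectorized
Gauss-kernel/property product; tests pin it to a naive per-point loop at
1e-10 and to rotational invariance at 1e-9.

Block assembly (the CoMFA-STD analogue): columns with training standard
deviation below a minimum σ are dropped (defaults: 2.0 kcal/mol for CoMFA
blocks, 0 for CoMSIA); each retained field block is rescaled to unit total
variance so no block dominates by units alone; appended whole-molecule
descriptors are autoscaled to unit variance as one-column blocks of their
own, making their contributions commensurable with the field blocks.  All
filter masks, substitution means and scale factors are learned on the
training set only and frozen for test-set transformation.

## Topological descriptors

CIC2 uses two rounds of neighborhood refinement (element + incident bond
orders) to partition atoms into radius-2 equivalence classes — the standard
iterative construction of the information-content indices — with hydrogens
included; IC2 is the Shannon information of the partition and
CIC2 = log₂(n) − IC2 exactly.  BEHv2 is the second-largest eigenvalue of
the Burden matrix over heavy atoms: diagonal = vdW volume scaled to carbon,
bonded off-diagonals 0.1×bond order (aromatic 1.5), 0.001 otherwise.  These
pinned conventions are internally consistent but absolute values may differ
from proprietary descriptor suites; models are always fit on these values.
The selection stage that historically picked this pair from a ~700-strong
2D pool is exposed as forward-stepwise MLR ranking by partial F with
lexicographic tie-breaks (the direction of stepping — forward — is this
package's choice; best-subset at that pool size is impractical).

## PLS and validation

PLS is scikit-learn's NIPALS with centering and no per-column autoscaling
(block scaling has already happened).  Beyond the effective rank NIPALS
degenerates; the fit silently caps the component count at the largest that
yields finite, non-degenerate score vectors.

- **q²** = 1 − PRESS_cv/Σ(yᵢ−ȳ)², LOO with a full refit (centering
  included) in every fold — no shortcut formulas, so a brute-force loop of n
  refits reproduces it bit-for-bit.  The denominator uses the full-training
  mean (the convention of the classic SAMPLS-style implementations);
  per-fold means are a configuration away but change little at n ≳ 50.
- **OPN** = argmax q² over 1..max_components (default 10), ties to fewer
  components, then lower SEE.
- **SEE** = √(RSS/(n−OPN−1)); **F** = (r²/OPN)/((1−r²)/(n−OPN−1)).  The
  degrees of freedom charge one per latent component plus the intercept;
  whether historic reports used exactly this convention is not always
  stated, so the formula is pinned here.
- **r²_ncv** is the squared correlation of fitted vs. observed.
- **r²_pred** = 1 − PRESS_test/SD with SD the squared deviation of the test
  activities about the **training** mean; it is invariant to shifting all
  activities, equals 1 for perfect predictions and 0 for predicting the
  training mean.
- **Block contributions** are Σ_j |coef_j|·sd_j per block, normalized; with
  the unit-variance block scaling this matches how field-QSAR packages
  report relative field importance.

A y-randomization diagnostic (LOO q² under seeded permutations of the
response) is available; at the reference size the null q² is negative
essentially always, so q² ≤ 0.1 in ≥95/100 permutations is the expected
behavior of an unbiased validation loop.

## Contour maps

The map value at a lattice point is (training column sd)×(PLS coefficient);
dropped columns are 0.  The block scale factor cancels in this product, so
the map is identical on raw or scaled columns, and the sum of |map| equals
the block's contribution mass (tested).  Contour levels use a
percentile-of-cumulative-|contribution| convention: the favored level at
80% is the smallest positive value such that points above it carry the top
20% of positive contribution mass; the disfavored level mirrors this on the
negative side.  Commercial "contribution level %" algorithms are
proprietary; this convention is pinned, written into the cube metadata, and
comparisons with published figures are qualitative only.  Maps export as
Gaussian cube files (Bohr units, C-order) and round-trip at 1e-6.

## Synthetic series: what it emulates

The generator builds n = 120 ligands (defaults) on a rigid
2-methylbenzenesulfonamide scaffold — the ortho methyl breaks the ring
mirror symmetry so the core match is unique — with substituents drawn from
{H, methyl, F, Cl, Br, hydroxyl, amino, methoxy, methylsulfonyl, phenyl,
extended aryl} at the two meta and the para positions.  The para vocabulary
spans the full bulk range and drives the planted signal.  Activity is

    pKᵢ = 6.3 + scale · Σ_regions c_r · mean(field over region) + N(0, σ)

with one planted steric region centered at (−4, 0, 0) (on the para axis,
on the even-2 Å lattice the analysis grid snaps to, so the planted response
is exactly linear in retained field columns and the noiseless limit fits to
machine precision).  `scale` is set so the noiseless activities span exactly
3.0 pKᵢ units — the typical span of a congeneric binding series (roughly
6.3–9.6).  Defaults: noise σ = 0.15 pKᵢ, core jitter 0.05 Å, 90/30
activity-stratified split, seed 7.  Every molecule except the template also
receives a random rigid motion so alignment has real work to do.

Because the response is built from the package's own field definitions, the
recovery experiment tests the *pipeline* (alignment → fields → scaling →
PLS → contours) as an inverse problem, not the physical realism of the
fields — that is pinned separately by the analytic and oracle tests.  The
generator does not emulate conformational flexibility, measurement-protocol
heterogeneity, activity cliffs from discrete binding-mode switches, or
series with multiple scaffolds; passing recovery tests therefore does not
certify performance on real data with those features.

The split policy stratifies by activity quintile with largest-remainder
rounding and forces the global extremes into the training set, so the test
range always lies inside the training range (extrapolation is never scored
as external predictivity).

## Problem sizes and determinism

The reference experiments use n = 120 molecules, ~3.8k retained descriptor
columns, LOO over 90 training molecules and up to 10 components, and 100
response permutations — sizes chosen so the full suite and the acceptance
script each run in about a minute on a single core while leaving the
statistics stable.  All randomness flows from explicit seeds (one global
seed fanned out by fixed offsets per stage), and a repeated run with the
same configuration is byte-identical.

## Known limitations

- Gasteiger charges and the generic LJ table differ numerically from the
  proprietary force fields used in the classic studies; published absolute
  statistics are not reproducible from drawn structures and are not a
  target here.
- Rigid-body alignment only; flexible series need external conformer
  preparation.
- CIC2/BEHv2 follow pinned public conventions, not any proprietary
  descriptor engine's exact atom typing.
- The contour-level convention is this package's own (documented in every
  exported map); favored/disfavored regions are comparable across runs of
  this package, qualitatively comparable with published maps.
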