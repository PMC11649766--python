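# Methods

This note documents the models, parameter choices and numerical conventions
behind `wristqct`, and what the synthetic-phantom tests do and do not show
about real scans.

## Calibration model

A CBCT voxel is modelled as water plus an added mineral (hydroxyapatite,
HA) mass density ρ [g/cm³], with additive linear attenuation:

    mu(rho) = (mu/rho)_water · 1.0 + (mu/rho)_HA · rho.

With HU = 1000·(mu − mu_water)/mu_water this gives a linear HU↔density
relation through the origin, `rho = HU · mu_w / (1000 · mu_HA)`, so water
(HU 0) maps to density 0 and the relation is strictly increasing. Mass
attenuation coefficients are log-log interpolated at the 48 keV effective
energy of an 85 kV spectrum from the NIST XCOM compilation (total, with
coherent scattering): water 0.2683/0.2269/0.2059 cm²/g at 40/50/60 keV, and
H, O, P, Ca likewise, combined to HA Ca₁₀(PO₄)₆(OH)₂ by mass fraction
(Ca 39.9 %, P 18.5 %, O 41.4 %, H 0.2 %). At 48 keV this yields
≈ 0.235 cm²/g for water and ≈ 0.49 cm²/g for HA, i.e. ≈ 4.8·10⁻⁴ g/cm³
per HU. Density can alternatively be expressed as calcium mass density
(`units="ca"`), scaling by the Ca mass fraction of HA; the unit system is
recorded in volume metadata.

The grey→HU calibration is an ordinary least-squares line through three
phantom points. Air (−1000 HU by definition of the scale) supplies the third
reference alongside POM (300 HU) and PTFE (950 HU): a two-parameter line
needs three points for a residual, and air is always in the field of view.
Least squares rather than exact interpolation is used because real ROI means
are never perfectly collinear; the per-material residuals are reported so
calibration uncertainty can be propagated. Negative densities are clamped to
zero (physical non-negativity). ROIs are accepted as explicit voxel-index
sets, boolean masks, or axis-aligned cylinders.

## Geometry conventions

+z is distal. The VOI covers `round(length/h)` slices whose distal-most
slice lies `round(offset/h)` slices proximal to the user-supplied reference
slice (defaults 10 mm and 9.5 mm; rounding half away from zero). Endplate
localisation is deliberately not automated — it is a manual step in
practice, and synthetic ground truth supplies it for tests. Alignment maps
the dominant eigenvector of the bone mask's second-moment tensor to +z,
resampling trilinearly (nearest-neighbour for label images); a mask without
a dominant axis (eigenvalue ratio < 1.05) returns the identity with a
warning.

## Segmentation

**Bone/background.** A two-list front evolution of the piecewise-constant
two-phase energy: per cycle the inside/outside means are refreshed and every
6-connected front voxel moves in the direction that lowers
`(I − c_own)² − (I − c_other)²`, converging when no front voxel flips in a
full cycle. On a noise-free two-constant image this reproduces the
generating mask exactly. Because a wrist field of view holds *three*
populations (air, soft tissue/marrow, bone), multiple instances run in
sequence: the bright class is split again whenever the new class-mean
separation exceeds 0.5× the previous split's separation. The 0.5 gate is
the key numerical choice: two-means applied to pure Gaussian noise separates
means by ≈ 1.6 SD, far below any genuine tissue contrast, so a homogeneous
noisy bone class is never subdivided. The largest 26-connected component is
returned.

**Compartments.** The endosteal interior is the morphological closing of
the marrow space (filled periosteal region minus bone) with a ball of
0.5 mm radius — large enough to bridge the trabecular lattice, small enough
not to erase the cortex; at a flat endosteal wall the closing lands on the
wall itself, and on a shell-over-marrow phantom the recovered cortex is
voxel-exact. The transitional zone is a fixed-width band (2 voxels) just
inside the cortex — the literature gives no intensity-based definition, so a
geometric one is an explicit assumption. Solid bone (no marrow) falls back
to a depth rule: cortical down to a configurable 3 mm, trabecular beyond.
Periosteal filling is per-slice (the medullary canal is open at the VOI
ends).

**ARG.** Seeds are the voxels beyond the 1st/99th percentiles of the
region's intensities. Iteration k grows both classes with acceptance rule
`|I − running class mean| ≤ τ_k`, τ_k = k·Δ, Δ = 1 % of the intensity range,
up to 100 iterations; growth carries over between iterations, so grown
regions are monotone in τ. Each iteration is scored by the
voxel-count-weighted sum of class variances after provisionally assigning
unreached voxels to the nearer class mean; the arg-min iteration wins.
Seed percentiles, Δ and the iteration cap are declared defaults, not
reconstructions of any particular legacy implementation. Connectivity: 26
for growing and labelling, 6 for level-set fronts.

**Porosity.** Cortical voxels with density strictly below 0.600 g/cm³ HA
are pores (tie convention: exactly 0.600 is not a pore) and are removed from
the FE solid.

## Morphometry

Thickness uses the model-independent sphere-fitting definition: Euclidean
distance transform, then spheres painted in decreasing radius order; the
thickness at a voxel is the diameter of the largest sphere containing it.
The image border counts as background, and the sphere diameter is `2·EDT`
(distance to the nearest background voxel centre): exact on plates an even
number of voxels thick, at most one voxel off otherwise, and about one voxel
generous on cylinders — the expected voxel-scale overestimation of Tb.Th at
clinical resolutions. Tb.Sc is measured on the marrow space restricted to
the trabecular compartment (cortical space must not inflate spacing). Tb.Nd
counts 26-connected clusters of skeleton voxels with ≥ 3 skeleton
neighbours, per mm³ of VOI; the clustering rule is documented because raw
junction-voxel counts are skeletonizer-dependent. TV counts every voxel
inside the periosteal surface, TBV the segmented bone voxels, mean area the
per-slice in-surface count; whole-volume BV/TV is TBV/TV. BMC integrates
density over a compartment, BMD divides by compartment volume; compartment
BMCs add to the whole to machine precision by construction.

## Micro-FE

One 8-node trilinear hexahedron per bone voxel, full 2×2×2 Gauss
quadrature, isotropic linear elasticity (E = 15 000 N/mm², ν = 0.3 —
standard values for this application; configurable). Fragments not
26-connected to a component spanning both z faces are removed before
meshing. Load case: proximal-face nodes fully constrained, distal-face
axial DOF prescribed to −0.1 mm (≈ 1 % strain on a 10 mm specimen) with
lateral DOFs free; a `frictionless` variant (both faces axially constrained
only, rigid-body modes pinned) exists for verification against the
homogeneous uniaxial solution. The solver is matrix-free
Jacobi-preconditioned conjugate gradients over the regular grid with one
precomputed 24×24 element matrix (default relative residual 10⁻⁸); a dense
direct assembly of the same element matrix serves as the small-model
verification oracle, and the element formulation itself is verified against
E·A/L bar closed forms.

Effective strain is `sqrt(2U/E)` with U the strain-energy density at the
element centroid. The failure load scales the linear solution to the
Pistoia criterion: Q is the 98th-percentile effective strain taken as the
order statistic at index ⌈0.98·N⌉ (1-based, no interpolation — ties and
interpolation would change the scale factor), and F_max = (0.007/Q)·F.
Element-count and volume weighting coincide for uniform voxels. All derived
quantities are invariant to the applied displacement magnitude (linearity).
Strength divides F_max by the TV-based mean cross-sectional area (a
bone-area variant is a one-line change in the caller).

## Synthetic phantoms

A phantom is a hollow elliptic-cylinder cortical shell (default semi-axes
0.33/0.27 of the cross-section, 1.25 mm cortex at 1.53 g/cm³ — typical
elderly distal-radius values) filled with an analytic trabecular lattice
(parallel plates, orthogonal rod grid, or gyroid; default BV/TV target
0.44) and marrow, plus three peripheral insert cylinders at the reference
HU values. The density map passes through the *same* HU relation as the
calibration module (single source of truth), then `grey = slope·HU +
intercept`, an optional multiplicative radial parabola peaking at the
volume centre (the "capping" grey-value inflation that biases peripheral
phantom calibration), and Gaussian noise. Everything is seeded and
bit-reproducible. The default 96³ grid at 0.125 mm (a 12 mm cube) keeps FE
models desk-sized; the standard 9.5 mm + 10 mm VOI protocol does not fit in
such a cube, so synthetic pipelines use a scaled VOI (documented per test).

Cohorts draw per-subject BV/TV, cortical thickness and densities from
normal distributions (defaults 0.44 ± 0.04, 1.25 ± 0.08 mm,
1.53 ± 0.09 g/cm³). The reference table carries DXA-like BMC/BMD and a
stiffness surrogate constructed as `r·z(BMC) + sqrt(1−r²)·ε` with the
population moments of the analytic true BMC estimated once from a 20 000
draw fixed-seed sample — so the *population* correlations (defaults 0.8 to
the reference, 0.9 to the stiffness surrogate) are exact by construction,
which is what Fisher-CI coverage studies require.

What the phantoms do **not** emulate: projection/reconstruction physics
(no Feldkamp, scatter or beam hardening beyond the parametric capping
field), realistic carpal anatomy, motion artifacts, and the connectivity
statistics of real trabecular bone (parallel plates have zero skeleton
junctions by construction — Tb.Nd tests use rod lattices). Passing tests
therefore demonstrate correctness of the computational chain under known
ground truth, not clinical accuracy on scanner data.

## Statistics

Pearson CIs use the Fisher z-transform (`z ± z_{1−α/2}/√(n−3)`), p-values
the exact t reference with n−2 df; two-sided throughout (sidedness is fixed
by convention, not data). Mann-Whitney U is exact by full enumeration when
min(n, m) ≤ 8 without ties, otherwise the tie-corrected,
continuity-corrected normal approximation (the switch is documented and
tested against an independent implementation). Shapiro-Wilk follows
Royston's 1995 polynomial approximation; it matches an independent
reference implementation to < 10⁻⁴ in both W and p. Bland-Altman limits are
the classical mean ± 1.96·SD (not t-based small-sample limits). Descriptive
summaries are gated by Shapiro-Wilk at α = 0.05: mean ± SD when normality
is not rejected, else median [Q1 ; Q3], reported per sex group and total.
No multiple-testing correction is applied by default. Degenerate inputs
(zero variance, n < 3) raise or surface as NA cells, never as numbers.

## Problem sizes

Test and acceptance runs use 48³–96³ phantom grids (6–12 mm cubes), FE
models up to ≈ 3·10⁵ elements for the single full-pipeline subject and
≤ 200 elements for dense-oracle comparisons, and 1000 repeated cohorts of
n = 21 at the reference-table level for coverage studies — chosen as the
smallest sizes at which every oracle is meaningful (several lattice periods
per VOI, CLT-scale ROI counts, Monte-Carlo error well below the coverage
band being tested).
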