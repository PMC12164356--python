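# Methods

This note documents the models implemented in `pistack`, the provenance of
every shipped parameter, the conventions chosen where the design was open,
and what the test fixtures do and do not establish about real systems.

## Geometry model

Monomers are rigid, idealized planar rings.  Ring atoms are placed on a
common circumscribed circle whose radius is solved (by 1-D root finding) so
that every bond length is exact and the six-ring closes: r(C–C) = 1.39 Å,
r(C–N)<sub>ring</sub> = 1.34 Å, r(C–H) = 1.08 Å.  Substituents attach at C1
along the +x axis with standard idealized bond lengths and angles (e.g.
C–C≡N 1.43/1.16 Å linear; C–NO₂ 1.47 Å with 124° O–N–O; tetrahedral methyl).
Templates are therefore validated by symmetry and bond-length checks, not
against any external structure; real monomer geometries differ from these
idealizations at the ~0.01 Å level, which shifts absolute energies slightly
but not the surface topography.

Body frame: ring-atom centroid at the origin, ring plane = xy, normal = +z,
unique atom (heteroatom or substituted carbon) on the +x side.  A dimer is
monomer B displaced to (x, 0, z); since A stays at the origin with its
unique atom at +x *and* B's displacement is +x, positive x moves B's
substituent/heteroatom *away* from the partner ring.  Orientation flags:
`antialigned`/`substituent_opposite` rotate B 180° about its normal before
displacement (used for heteroaromatic homodimers and mixed substituted
sandwiches with anti substituents).  T-shaped mode tips B edge-on so that
its C1–H bond points straight down at A's centroid; z is the
centroid–centroid separation.  All placements are proper rigid motions, so
every potential is exactly invariant under overall rotation/translation
(tested to 1e-9 kcal/mol).

## σ/π charge model

σ charges sit at nuclei; each π-system atom carries a pair of charges at
±δ along the *current* ring normal (placement is equivariant under rigid
motion).  δ = 0.47 Å is taken as a fixed calibration constant.  Charge sets
are data, not computed: the package ships

* **benzene** — per-site q_π = −0.50, forced exactly by the −6 total
  π-charge and six-fold symmetry.  The C/H σ split is not published; the
  shipped split is calibrated so the point-charge model reproduces the
  experimental benzene quadrupole (Θ_zz ≈ −8.7 D·Å): with the template
  geometry and the fixed δ this pins σ(C) = +0.96, σ(H) = +0.04.  The file
  format accepts any other split.
* **pyridine** — q_π(N) = −0.52, q_π(C4) = −0.48; the ortho/meta carbons
  take −0.50, forced by the −6 sum rule given those two values and
  ortho/meta equivalence.  σ values are placeholders consistent with the
  benzene H value and neutrality.
* ***s*-triazine** — q_π(N) = −0.53, q_π(C) = −0.47 (sums to exactly −6);
  σ placeholders as above.
* **hexafluorobenzene** — a validator exercise (no template geometry):
  ring C per-site q_π = −0.54 with fluorine lone-pair π sites closing an
  18-electron π sum.

The validator reports the π-sum and neutrality residuals and never repairs
a set.  Substituent atoms may carry π sites; membership is declared per
charge set, never inferred from connectivity.

**Synthetic substituted-benzene sets.**  The charge sets for C6H5X
(X = F, CH₃, NH₂, OH, OCH₃, CN, NO₂, CCH) are *synthetic*: they start from
the benzene set and move a substituent-specific amount w of π charge
between the ring (weighted onto ipso/ortho/para, the resonance positions)
and a π pair on the substituent attachment atom, with heuristic dipolar σ
charges on the substituent and exact enforcement of both sum rules.  The w
values have chemically sensible signs (withdrawing groups deplete the ring
π cloud) but are not derived from any electronic-structure calculation.
They exist so the substituent pipeline can run end to end; conclusions
about specific real substituents require user-supplied charge sets, for
which the validator is the gatekeeper.

## σ/π potential parameters

The Coulomb constant is fixed at 332.0637 kcal·Å/(mol·e²) (overridable).
The exp-6 parameters are a single global (C, α, A) plus per-element scale
factors k, read from a plain-text file.  The historical parameter values
behind this model are not published with it, so the shipped set is a
calibration chosen once against the qualitative shapes this potential is
known to produce and then frozen:

* C–C pair well depth 0.09 kcal/mol at R\* = 3.8 Å, α = 3.2 Å⁻¹
  (⇒ C = 16743, A = 534.93); k_C = 1.0, k_H = 0.45, k_N = k_O = 0.95,
  k_F = 0.9.

With the quadrupole-calibrated benzene charges this yields: a double-well
z = 3.5 Å slice for the parallel benzene dimer with exaggerated lateral
minima (±2.5 Å), 2-D minima at (±2.8, 3.4) with the sandwich saddle at
(0, 3.7), an everywhere-repulsive electrostatic layer for |x| < 3 Å, and a
C2v T-shaped minimum near z = 5.45 Å that is slightly shallow — the
qualitative signature (including the known errors) of this class of model.
The exp-6 form diverges to −∞ at small R; distances below a guard radius
(default 1.0 Å) raise an error rather than returning garbage, and scans
record such nodes as undefined rather than aborting.

## Gaussian-Pauli + damped-dispersion parameters

Pauli: A_ij e^(−α_ij R²) with A_ij constant (an 1/R prefactor form is also
supported behind the same interface).  Dispersion: Tang–Toennies-damped
C₆/R⁶ + C₈/R⁸, with f_n evaluated through the regularized incomplete gamma
function Q(n+1, x), which equals the truncated exponential sum exactly and
is numerically safe at large x.  The damping function is isolated behind
one interface so an alternative form can be swapped without touching the
energy assembly.

Parameter values for this model are likewise unpublished; the shipped
per-pair table is a calibration validated against the model's two signature
behaviors for the parallel benzene dimer and then frozen: the z = 3.5 Å
slice is a double well (minima ±2.0 Å, barrier 1.44 kcal/mol), while the
full 2-D surface has a *single* minimum at (0, 3.85) on the default lattice
— the repulsive ridge at x = 0 decays away just above z ≈ 3.8 Å.  Strong
damping (β_CC = 1.30 Å⁻¹) flattens the dispersion's vertical slope so a
modest Pauli term can pin the vertical minimum near 3.9 Å without
re-corrugating the surface laterally.  The model is treated as qualitative
only; it has no electrostatic term by construction, and fixed-z slices
below its z = 3.5 Å floor evaluate at the floor and are flagged.

## Surfaces, MEPs, stationary points

Scans evaluate a potential on an (x, z) lattice; the default lattice is
x ∈ [−4, 4] Å step 0.1 and z ∈ [3, 6] Å step 0.05 (T-shaped: z ∈ [4, 7]),
chosen to bracket all features of the shipped systems at a cost of a few
seconds per scan.  The MEP relaxes z at each x: grid argmin refined by the
parabola through the bracketing triple (refinement is skipped, and the
point flagged, when the minimum falls on the z boundary — the signal that
the grid is too small).  Stationary points are classified against the 8
surrounding nodes with strict comparisons; equal-valued plateaus are
reported once at the node nearest their centroid, smaller x first.  All
topography statements are therefore grid-resolution statements.  The
starred composition is exact nodewise arithmetic on identical lattices —
no interpolation, and a lattice mismatch is an error rather than a silent
resample.

## Substituent statistics

Substituent effects are interaction energies relative to the benzene dimer
under the same potential and geometry convention.  Each sandwich dimer
(x = 0, substituents anti) is evaluated at its own vertically relaxed
separation (z ∈ [3.2, 5.2] step 0.05, quadratically refined).  r² is the
squared Pearson correlation of the two ΔE lists — the standard reading of a
scatter-plot r², documented so regression-through-origin variants can be
compared — and RMSE is the root-mean-square difference without recentering,
so a constant offset leaves r² = 1 but appears fully in the RMSE.  The
additivity analysis compares ΔE(X·Y) with ΔE(X) + ΔE(Y) from the same
model.  Because the potential is strictly pairwise and anti-oriented
substituents share no local environment, near-perfect additivity is a
genuine model property, not a fitted one: with the synthetic sets the 45
mixed dimers give r² ≈ 0.99, RMSE ≈ 0.12 kcal/mol, with the largest
residuals for the pairs whose σ dipoles interact most strongly across the
stack.  Mixed-pair labels are unordered; relabeling (X, Y) → (Y, X) leaves
the statistics unchanged because the anti sandwich construction is
orientation-symmetric.

## Surrogate reference surface

Tests and the starred-composition checks need a reference surface with
*known* topography; external high-level reference grids are inputs the
package cannot assume.  The surrogate is an analytic double well,

    E(x, z) = wall·e^(−2z) − D·[g(x−x₀) + g(x+x₀)]·e^(−k_z (z−z_w)²/(2D)),

with g a unit-height Gaussian of width w.  Defaults (x₀ = 1.7 Å, D = 1.6,
w = 0.9 Å, z_w = 3.5 Å, k_z = 8, wall = 500) give two minima at ±1.70 Å and
a saddle 1.0 kcal/mol above them — the canonical stacked-dimer topography.
Its ground truth comes from an independent dense-lattice brute force (the
two half-plane minima and the highest point of the z-relaxed path between
them), so the grid classifier is tested against an oracle that shares none
of its code path.  The surrogate emulates topography only: it has no
component decomposition and no short-range divergence, so tests that pass
on it establish the correctness of the surface machinery, not the physical
accuracy of any potential.

## Known limitations

* Absolute energies under the shipped calibrations are qualitative; only
  surface *shapes* are validated.  Users with quantitative charge/parameter
  sets can drop them in via the data-file formats.
* No charge penetration, polarization, or many-body terms — for the σ/π
  model this omission is the point, and the repulsive central electrostatic
  layer it causes is asserted, not corrected.
* Planar rings only; no tilted (Cs) T-shapes; no intramolecular energetics.
* The benzene–pyridine bias statistic (positive-x minimum minus negative-x
  minimum along the MEP) is reported with the sign convention that a
  negative value means displacement of the heteroatom *away* from the
  partner ring is favored; the shipped model favors that direction by
  ~0.14 kcal/mol, a qualitative-direction result only.
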