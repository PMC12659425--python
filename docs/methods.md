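# Methods

## Model and assumptions

The solvent is a scaled perfect conductor.  On the cavity surface the
total electrostatic potential vanishes, giving the linear system
`0 = Φ + Aq` for the apparent surface (screening) charges q.  The solute
is classical: point nuclei (charges Z, positions in Å) and spherical
Gaussian electron clouds `ρ(r) = n (α/π)^{3/2} e^{−αr²}` (total charge n,
exponent α in Bohr⁻²).  A cloud's potential is `n·erf(√α r)/r` with the
finite limit `2n√(α/π)` at the center, and its charge inside a centered
sphere of radius R is `n·[erf(√αR) − 2√(α/π)·R·e^{−αR²}]` — both closed
forms, which is why Gaussians (rather than exponential densities) were
chosen as the stand-in for quantum-mechanical electron density.  All
internal electrostatics uses Hartree atomic units with
1 Bohr = 0.52917721092 Å fixed in `constants.py`; all geometry I/O is in Å.

## Cavity construction

Each sphere is tessellated with a pentakisdodecahedron: the regular
dodecahedron apexed at its radially projected face centers (32 vertices,
90 edges, 60 spherical triangles; the faces are found by grouping coplanar
convex-hull triangles rather than assuming a dual-icosahedron orientation).
Refinement is by midpoint 4-split with radial projection: 60 → 240 → 960
faces for the coarse/fine/xfine levels.  Tessera centers are radially
projected centroids; areas are exact spherical-triangle areas (l'Huilier),
so the tesserae of a full sphere partition 4πR² to round-off.

For the van der Waals cavity, tesserae whose three vertices and center lie
strictly inside another sphere are dropped; tesserae straddling a boundary
are split once more and the exposed children kept as independent segments
(no regrouping into parents).  Strict inequality in the inside test keeps
points lying exactly on another sphere's surface, stabilizing tangent
configurations.  Area is Σsᵢ and volume `(1/3)Σ sᵢ(cᵢ·nᵢ)` by the
divergence theorem.

The approximate solvent-excluding surface augments the atomic spheres with
auxiliary spheres.  For a pair with radii R₁ ≥ R₂ at distance d, no filler
is added when the probe passes (`d ≥ R₁+R₂+2r_solv`) or when the spheres
are deeply fused (overlap `(R₁+R₂−d)/(2R₂) ≥ ofac`, default 0.8).
Otherwise the probe simultaneously tangent to both spheres has its center
at axial offset `x = (d²+(R₁+r_s)²−(R₂+r_s)²)/2d` and height
`h = √((R₁+r_s)²−x²)`; the new sphere sits on the axis at x with radius
`h − r_s`, i.e. tangent to the rolling probe, and is discarded below
`rmin` (default 0.5 Å) or when engulfed by an existing sphere.  The scan
repeats over new spheres until it converges (the tangency construction
regenerates existing spheres, which the engulfment test rejects, so the
iteration is self-terminating).  The probe radius only controls
accessibility; it adds no thickness.  Note that filler spheres do not
always *reduce* area: for two separated spheres bridged by a thin neck the
exposed filler band can exceed the caps it buries, exactly as the true
reentrant surface of that geometry exceeds the vdW area.  For overlapping
chains (the alkane-like regime) the SES area is smaller, as expected.

### Segment merging

Segment centers from adjacent spheres can fall arbitrarily close near
clipping boundaries, which makes the point-charge Coulomb matrix nearly
singular.  Any pair closer than d_min is merged — transitive closure via
union-find, merged center at the area-weighted centroid, areas summed,
normal the renormalized area-weighted mean — and the pass repeats until
all pairwise distances are ≥ d_min (centroids of distinct groups can
otherwise land close together).  d_min is `mfactor × 0.5 × ℓ`, where ℓ is
the mean edge length of a *secondary* (once-subdivided) tessera on a
probe-sized sphere at the current level.  The secondary tesserae are the
smallest legitimate segments clipping can produce, so half their spacing
cleanly separates boundary artifacts from regular neighbors; using the
primary edge length instead would merge large numbers of ordinary
segments, visibly degrading the surface quadrature (the nuclear scaling
factor f_N moves from ~0.9998 to ~0.96 on a three-sphere test case).
mfactor is linear (0 disables merging) and defaults to 1.0.

## Conductor solve and dielectric scaling

The KS matrix uses `A_ij = 1/r_ij` and `A_ii = 1.07·√(4π/sᵢ)` (the
diagonal constant is configurable).  The YK matrix replaces point charges
by spherical Gaussians: `A_ij = erf(ζ_ij r_ij)/r_ij` with
`ζ_ij = ζᵢζⱼ/√(ζᵢ²+ζⱼ²)` and `A_ii = ζᵢ√(2/π)`, finite for any geometry.
Exponents follow `ζᵢ = ζ̄/√sᵢ` (equal-area segments get equal exponents,
the uniform-density condition); ζ̄ is found per tessellation level by
Brent root-finding so that the discretized Born energy of a unit sphere is
exact, and the rule is scale-invariant in R by construction
(ζ̄ ≈ 4.748/4.740/4.739 for coarse/fine/xfine).

The linear system is solved densely (Cholesky with up to two steps of
iterative refinement) or by Jacobi-preconditioned conjugate gradient
(rtol 1e-13, at most 10·m iterations); `auto` selects dense up to 7500
segments and iterative above.  The residual contract is
`‖Aq+Φ‖∞ < 1e-10‖Φ‖∞` plus a round-off floor `100·ε_mach·‖A‖∞·‖q‖∞`
(with ‖q‖ taken over the split components), needed because neutral
solutes have nearly self-cancelling potentials whose relative residual
cannot beat machine precision.  Nuclear and electronic potentials are
solved with the same factorization; q = q_N + q_e by linearity.

Finite dielectrics scale the charges, `q_ε = f_ε q`, with
`f_ε = (ε−1)/(ε+0.5)` (KS), `(ε−1)/ε` (ST), or 1 (ideal).  Scaling is
applied after the outlying-charge correction, and the energy uses the
boundary-consistent solute-side potential with the scaled charges,
`E = ½Φ′ᵀ(f_ε q′)` — linear in f_ε, reducing to the conventional `½f_εΦᵀq`
when no correction is active.  All correction benchmarks in this package
are run at ideal screening, where the ordering is immaterial.

## Outlying-charge correction

The scale path enforces the charge rule componentwise with
`f_N = −Q_N/(1ᵀq_N)` and `f_e = −Q_e/(1ᵀq_e)`.  With this sign convention
the corrected sums satisfy `−Q = 1ᵀq′` exactly and both factors sit near
+1 (f_N ≈ 1 up to quadrature error, since nuclei are always enclosed).  A
component that is identically absent (no clouds) passes through with
factor 1; a zero-sum component with nonzero charge is an error.  The
Lagrangian path minimizes `½qᵀAq + Φᵀq` under the single total-charge
constraint `1ᵀq = −(Q_N+Q_e)`, closed form
`q′ = −A⁻¹(Φ + λ1)`, `λ = (Q − 1ᵀA⁻¹Φ)/(1ᵀA⁻¹1)`.

After either correction the potential is updated, `Φ′ = −Aq′`, and
`Φ_e′ = Φ′ − Φ_N`.  The dielectric energy is `E = ½Φ′ᵀq′`; the legacy
path (flag `potcorr`) instead pairs the *uncorrected* Φ with corrected
charges, affecting only the energy expression, never the charges.  With
correction off, Φ′ is set to Φ identically (they agree through the solved
system), so the legacy and corrected energies coincide exactly.

## The fixture generator

The catalogue stands in for a benchmark set of real molecules:

* `born_ion` — +1 point charge centered in a 2 Å sphere; the analytic
  oracle `E = −q²/2R`.
* `born_anion` — Z = 8 nucleus with a −9 e cloud whose exponent is solved
  (Brent) so exactly 99% of the cloud lies inside the 2 Å sphere,
  emulating the ~1% outlying density typical of anions in scaled-vdW
  cavities.
* `diatomic` — homonuclear two-center model at an N₂-like bond length.
* `water_like` — bent three-center model with a polar charge split
  (O −0.4 e, H +0.2 e net) on experimental water geometry and
  Rowland–Taylor × 1.18 radii.
* `chain9` — nine colinear spheres at 1.53 Å spacing, the alkane-backbone
  shape used for vdW-vs-SES area comparisons.

Fixtures are deterministic; the seed only feeds Monte-Carlo estimates
downstream.  What the generator does **not** emulate: true quantum
densities (no shell structure, no density response to the reaction field,
no SCF coupling), conformational flexibility, and chemically diverse
charge anisotropy — so passing tests demonstrate the correctness of the
cavity/solver/correction machinery, not chemical accuracy of predicted
solvation energies.  Energies for the neutral classical models are
correspondingly mild (≈ −1.6 kcal/mol for `water_like`).

## Numerical choices

* Strict `<` in inside tests; tangent spheres remain exposed.
* Merging tolerance comparisons use exact d_min (no fuzz); the repeat-
  until-separated loop terminates because each pass strictly reduces the
  segment count.
* The YK calibration brackets ζ̄ in [0.5, 50] and reports the bracket on
  failure.
* Monte-Carlo outlying charge samples each cloud's Gaussian directly
  (σ = 1/√(2α) per axis; 200 000 samples by default) and reports a 1σ
  binomial error.
* Problem sizes: all shipped tests and the acceptance script run at the
  fine level (240 tesserae per sphere; the largest fixture cavity is
  ~2900 segments across the catalogue), which keeps the full suite at
  about ten seconds while leaving every oracle comfortably inside its
  tolerance.

## Known limitations

* The SES is the GEPOL-style approximation (filler spheres), not an exact
  Connolly surface; partially clipped tesserae are resolved only one
  subdivision level deep, so cavity areas carry O(h) boundary noise
  (the two-sphere cap-area test sits at ~0.05% at the fine level).
* The Lagrangian path constrains only the total charge; no attempt is
  made to preserve dipole or higher multipoles of the surface-charge
  distribution (both correction schemes perturb them).
* The iterative path stores the dense matrix; there is no matrix-free or
  fast-multipole operator, so very large cavities are memory-bound.
* Merged segments sit at centroids slightly off the sphere surface; their
  normals are area-weighted means, which is a documented convention, not
  a geometric necessity.
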