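# cosmosol

A desk-scale engine for the **conductor-like screening model (COSMO)** of
continuum solvation: GEPOL-style cavity construction (van der Waals and
approximate solvent-excluding surfaces), conductor surface charges in the
point-charge (KS) and Gaussian-smeared (YK) discretizations, dielectric
scaling, outlying-charge corrections with corrected surface potentials,
Turbomole-style COSMO output files, and σ-profiles for COSMO-SAC-type
activity-coefficient models.

Instead of coupling to a quantum-chemistry code, solutes are **classical
charge models** — point nuclei plus spherical Gaussian electron clouds —
which reproduce the one feature of real electron densities that drives the
correction machinery (charge leaking outside the cavity) while keeping
every quantity checkable against closed forms.  The package is aimed at
people developing or teaching continuum solvation and COSMO-RS/SAC
workflows who need a transparent, fully testable reference implementation.

## The model

The solvent is approximated by a scaled perfect conductor.  The cavity
surface is discretized into *m* segments with areas *s·ᵢ*; the conductor
boundary condition (vanishing total potential on the surface) gives

```
0 = Φ + A q
```

where Φ is the solute potential at the segment centers, q the screening
charges, and A the symmetric segment–segment Coulomb matrix, with
self-interaction diagonals `A_ii = 1.07·√(4π/sᵢ)` (KS point charges) or
`A_ii = ζᵢ·√(2/π)` with `A_ij = erf(ζᵢⱼ rᵢⱼ)/rᵢⱼ` (YK Gaussians, exponents
`ζᵢ = ζ̄/√sᵢ` calibrated per tessellation level to reproduce the exact
Born-ion energy `−q²/2R`).  For a finite dielectric the charges are scaled
by `f_ε = (ε−1)/(ε+0.5)` (KS), `(ε−1)/ε` (ST) or 1 (ideal conductor).

Gauss's law requires `−Q = 1ᵀq` (the *charge rule*).  Discretization error
and solute charge outside the cavity leave a *charge defect* `1ᵀq + Q`,
removed either by componentwise scaling factors
`f_N = −Q_N/(1ᵀq_N)`, `f_e = −Q_e/(1ᵀq_e)` or by minimizing
`½qᵀAq + Φᵀq` subject to `1ᵀq = −Q` (Lagrange multiplier).  The surface
potential is then updated to stay consistent with the corrected charges,
`Φ′ = −Aq′`, and the dielectric energy is

```
E_diel = ½ Φ′ᵀ q′
```

Cavities are unions of atom-centered spheres (tabulated radii × 1.18),
each tessellated by a pentakisdodecahedron refined to 60/240/960 spherical
triangles; buried tesserae are clipped, boundary tesserae refined once
more, and segments closer than a distance d_min (scaled by `mfactor`) are
merged to protect the point-charge matrix from near-singularities.  The
approximate solvent-excluding surface adds auxiliary spheres wherever a
probe of radius 1.3 Å cannot pass between two spheres.

## Worked example

```sh
python examples/outlying_charge.py
```

```
cloud charge outside cavity : -0.0924 ± 0.0020 e (1.03% of Q_e)
       off: defect -6.81e-03 -> -6.81e-03 e, E_diel   -81.8892 kcal/mol
     scale: defect -6.81e-03 -> -1.11e-15 e, E_diel   -83.0159 kcal/mol  (f_N=1.00000, f_e=1.00076)
lagrangian: defect -6.81e-03 -> +0.00e+00 e, E_diel   -83.0159 kcal/mol
legacy potential path       : E_diel   -82.4506 kcal/mol (uncorrected potential with corrected charges)
```

The anion model leaves ~1% of its electron cloud outside the cavity.  The
conductor solution alone already shrinks the resulting Gauss-law violation
to −0.0068 e; both correction schemes eliminate it to numerical precision
and agree on the energy, which matches the analytic Born value
(−83.016 kcal/mol for net charge −1 in a 2 Å cavity).  Correcting only the
charges but not the potential (the legacy path) misses ~0.6 kcal/mol.

Other examples: `born_ion_energy.py` (discretization vs the analytic Born
energy), `ses_cavity_area.py` (vdW vs SES area for an alkane-like chain),
`sigma_profile_water.py` (σ-profile and COSMO file output).  The same
pipeline is scriptable from the shell:

```sh
cosmosol --fixture water_like --charge-correction scale --cosmo-file water.cosmo
cosmosol --xyz water.xyz --radii rt18.par --method ks --cavity ses
```

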