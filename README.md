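# pistack

Empirical interaction potentials for stacked aromatic dimers: build benzene,
pyridine, *s*-triazine and monosubstituted-benzene monomers, assemble
sandwich, parallel-displaced and T-shaped dimers, scan two-dimensional
interaction-energy surfaces, extract minimum-energy paths and stationary
points, and analyse heteroatom and substituent effects on π-stacking.

## Who this is for

Computational and physical-organic chemists who want a fast, transparent
model of π–π interactions — for exploring surface topography, teaching, or
benchmarking qualitative claims — without running quantum chemistry.  All
energies are in kcal/mol, all distances in Å.

## The models

**σ/π point-charge potential.**  Each planar aromatic monomer is reduced to
a positively charged σ-framework (point charges *q*<sub>σ</sub> at the
nuclei) sandwiched between two negative π-clouds: a pair of charges
*q*<sub>π</sub> at ±δ along the ring normal above and below every π-system
atom, with δ = 0.47 Å calibrated so the benzene charge model reproduces the
experimental molecular quadrupole moment.  The dimer interaction energy is

```
E_int = Σ_i∈A Σ_j∈B q_i q_j / R_ij  +  Σ_i∈A Σ_j∈B k_i k_j (C e^(−αR_ij) − A R_ij⁻⁶)
```

a Coulomb sum over all σ/π sites plus a Buckingham exp-6 van der Waals term
over atoms, scaled by per-element factors *k*<sub>i</sub>.  Two sum rules
constrain every charge set: 2·Σ*q*<sub>π</sub> = −(number of π electrons)
and total charge = net molecular charge; `pistack validate-charges` checks
both.  The model has a famous defect — it neglects charge penetration, so
its electrostatic term is repulsive wherever π clouds overlap — which the
package reproduces faithfully rather than patches.

**Gaussian-Pauli + damped-dispersion potential.**  The vdW-only alternative

```
E_int = Σ A_ij e^(−α_ij R_ij²) − Σ [ f6(β_ij R_ij) C_ij R_ij⁻⁶ + f8(β_ij R_ij) D_ij R_ij⁻⁸ ]
```

models steric repulsion as overlap of spherical Gaussians and damps the
R⁻⁶/R⁻⁸ dispersion with Tang–Toennies functions
f<sub>n</sub>(x) = 1 − e^(−x) Σ<sub>m≤n</sub> x^m/m!.  It has no
electrostatic term and is conventionally undefined below z = 3.5 Å
(fixed-z slices clamp to that floor).

**Reference-anchored relative surfaces.**  To isolate a model's heteroatom
or substituent effect from its benzene-dimer defects, the starred
composition adds the model's *differential* energy to an externally supplied
benzene-dimer reference grid:

```
E*(X···C6H6) = E_ref(C6H6···C6H6) + [ E_model(X···C6H6) − E_model(C6H6···C6H6) ]
```

nodewise on identical (x, z) lattices.  Reference grids are CSV inputs; the
package never computes them.

## Worked example

```python
import numpy as np
from pistack import HSPotential, scan, stationary_points, slice_at_z
from pistack.fixtures import load_fixture
from pistack.geometry import dimer_family

bz = load_fixture("benzene")             # monomer + charges + parameters
pot = HSPotential(bz.chargeset, bz.chargeset, bz.vdw_params)
fam = dimer_family(bz.monomer, bz.monomer, "parallel")
grid = scan(fam, pot, np.arange(-4, 4.01, 0.1), np.arange(3.0, 6.01, 0.05))
for p in stationary_points(grid):
    if p.kind != "maximum":
        print(f"{p.kind:8s} x={p.x:+.1f}  z={p.z:.2f}  E={p.energy:.2f} kcal/mol")
```

prints (with the shipped calibration parameters):

```
minimum  x=-2.8  z=3.40  E=-2.97 kcal/mol
saddle   x=+0.0  z=3.70  E=-2.16 kcal/mol
minimum  x=+2.8  z=3.40  E=-2.97 kcal/mol
```

two equivalent parallel-displaced minima separated by the sandwich saddle —
the signature double-well topography of the stacked benzene dimer, with the
lateral displacement exaggerated and the vertical separation compressed in
the way this point-charge model is known for.  The same scan under
`CFHPotential` instead yields a single minimum at (0, 3.85), even though its
z = 3.5 Å slice is a double well:

```python
from pistack import CFHPotential
grid2 = scan(fam, CFHPotential(bz.cfh_params), grid.x_values, grid.z_values)
print(grid2.min_node())   # (0.0, 3.85, -3.32)
```

The same operations are available from the shell:

```
pistack stationary --system benzene --potential hs --out run/
pistack mep --system C6H5CN --charges my_benzonitrile.charges --out run2/
pistack validate-charges src/pistack/data/pyridine.charges
pistack substituents --out subst/
```

Every run directory contains the CSV artifacts plus a `manifest.json` with
all numeric constants and parameter values; identical configurations give
byte-identical outputs.

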