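# sphpatch

Electrostatics of charged **spherical-triangle surface patches** — curved
boundary elements for the surface charge method (SCM).

## The problem

Boundary-integral electrostatics for molecules (implicit- or
explicit-solvent) discretizes the dielectric interface into panels carrying
an induced surface charge density. Flat triangular panels make the electric
field diverge at panel vertices, where the approximate surface has no
normal. Richards–Connolly molecular surfaces, however, are built entirely
from pieces of spheres (and tori), so the natural panel is the *spherical
triangle*: a patch bounded by three great arcs on a sphere. This package
provides the machinery to use such curved panels exactly:

* canonical parametrization of a spherical triangle — one vertex at the
  pole, the opposite side the geodesic `cot θ = a cos(φ − φ₀)`;
* coordinate-free interpolation of the three vertex charge densities over
  the patch by central projection from the inscribed flat triangle,
  `σ(θ, φ) = σ₁ + t(θ)[(1 − λ(φ))σ₂ + λ(φ)σ₃ − σ₁]`;
* the electric field immediately above/below a patch vertex: a continuous
  (principal-value) part, evaluated either exactly or as a series in the
  small parameter β = arc length × curvature with strict order control
  (O(β), O(β³), O(β⁵), O(β⁷)), plus the Gaussian-units jump ±2πσ;
* exact patch area, direction averages, and charge moments through second
  order — the coefficients of the on-sphere and exterior moment
  expansions, with a convergence gate and adaptive-quadrature fallback;
* a brute-force adaptive quadrature oracle (the package's source of
  truth), and a demonstration SCM solve for a dielectric sphere validated
  against the classical Legendre-series solution.

Internally everything is computed on the unit sphere in Gaussian units:
fields scale as σ and potentials as σR when units are restored.

## Worked example

The area of the symmetric patch with one vertex at the pole, the others at
polar angle β = 0.15 and azimuths 0 and π/3, via the exact closed form and
via the series `F(0,0,2)/2 − 3F(0,0,4)/8 + 5F(0,0,6)/16`:

```python
>>> import math
>>> from sphpatch import SphericalTriangle, canonicalize, geodesic_params
>>> from sphpatch import area, area_series
>>> b = 0.15
>>> tri = SphericalTriangle((0, 0, 1), (math.sin(b), 0, math.cos(b)),
...     (math.sin(b) * 0.5, math.sin(b) * math.sqrt(3) / 2, math.cos(b)))
>>> frame = canonicalize(tri, pole_index=1)
>>> g = geodesic_params(frame)
>>> print(f"{area(frame, g):.8f}")
0.00975183
>>> print(f"{area_series(frame, g, n_terms=2):.8f}")
0.00974961
>>> print(f"{area_series(frame, g, n_terms=3):.8f}")
0.00975187
```

The exact area is 0.00975183 steradians; the two-term series is already
accurate to 2×10⁻⁶ and the three-term series to 4×10⁻⁸ — the series error
falls as β² per added term, which is the accuracy-control handle the
curved-panel formalism provides.

The demonstration boundary solve (point charge at 0.5R inside a sphere
with ε_in = 1, ε_out = 80, icosphere level 3):

```bash
$ sphpatch demo-sphere --level 3 --eps-in 1 --eps-out 80 \
      --charge 1 --charge-pos 0,0,0.5 --out report.json
```

reports `l2_rel_error_vs_analytic ≈ 0.00098` (0.1 % against the 50-term
Legendre-series surface density) and `total_induced_charge ≈ -0.98760`
versus the exact sum rule q(1/ε_out − 1) = −0.9875.

## Command line

`sphpatch` exposes thin subcommands over the library: `frame`, `area`,
`moments`, `field-vertex`, `field-sphere`, `field-exterior`, `validate`,
`demo-sphere`, `fixtures`. Patch files are versioned JSON (see
`sphpatch fixtures --help` to generate examples).

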