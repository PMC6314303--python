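# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Geometry and canonical frame

A spherical triangle is fixed by its three vertex directions on a sphere
(unit radius internally; every quantity scales by an explicit power of R).
`canonicalize` rotates a chosen vertex to the pole and the remaining two to
azimuths 0 and α, forcing 0 < α < π by relabeling the non-pole vertices when
the raw winding gives the reflex angle; the relabeling permutes the vertex
densities consistently. The side opposite the pole is the geodesic
cot θ = a cos(φ − φ₀) with

    a cos φ₀ = cot β₃,   a sin φ₀ = (cot β₂ − cos α cot β₃)/sin α,

solved with `atan2`/`hypot` so the octant limit (β = π/2 sides, a = 0) is
exact; for a = 0 the azimuth φ₀ is unidentifiable and set to 0 (β(φ) = π/2
regardless). The opposite arc length uses the closed form
β₁ = atan[tan(α−φ₀)/√(1+a²)] + atan[tan φ₀/√(1+a²)], cross-checked in the
tests against adaptive quadrature of the line element and against the
spherical law of cosines. The identity √(1+a²) sin α sin β₂ sin β₃ = sin β₁
is verified as a property test; the interpretation of its grouping was
fixed by the law-of-cosines oracle.

Angle comparisons use absolute tolerance 1e−12 radians; identities that
involve cancellation are checked at 1e−10.

## Density interpolation

Vertex densities are interpolated linearly on the flat triangle through the
vertices and carried to the sphere by central projection. In canonical
coordinates this is σ(θ,φ) = σ₁ + t(θ)[(1−λ)σ₂ + λσ₃ − σ₁] with the chord
fraction λ(φ) (evaluated in its sin form, regular at φ = π/2) and the
radial fraction t(θ) = sin θ/(C sin θ + D cos θ), where
C = (1−cos β) + (δ/R)cos β = O(β²) and D = (1−δ/R)sin β = O(β) at azimuthal
chord depth δ/R = 1 − √(1 − 2λ(1−λ)ζ₂₃), ζ₂₃ = 1 − r̂₂·r̂₃.

Two structural facts matter downstream:

* **Edge intrinsic-ness.** On any great-arc side the interpolant depends
  only on the two endpoint densities (the chord fraction is intrinsic to
  the chord), so neighboring patches sharing an edge interpolate
  identically along it — verified to 1e−12.
* **Subdivision is not exact.** Splitting a patch at edge midpoints and
  re-interpolating the corner densities does *not* reproduce the parent
  interpolant exactly: the sub-chords span different planes, and the
  mismatch in integrated quantities scales as (arc)⁴. The additivity test
  asserts the measured fourth-order falloff and a 1e−9 absolute bound at
  the small-fixture scale (arcs ≤ 0.035), where it genuinely holds.

The order-1 combination h̃ = ζ₂₃ λ(1−λ) a² cos²(φ−φ₀) is stored via the
product ζ₂₃λ(1−λ), which remains defined at a = 0; series mode refuses
patches with a < 1 (they are outside the small-arc regime anyway).

## The F/G integral family and order counting

All series reduce to F_{nc,ns}(ℓ,d,p) = ∫₀^α h̃^ℓ λ^d cosⁿᶜφ sinⁿˢφ
/(a^p cos^p(φ−φ₀)) dφ. Substituting x = tan(φ/2) and expanding the
near-equal quantities tan φ₀ and (sin β₃/sin β₂ − cos α)/sin α (their
difference is O(β²)) yields terms G(ℓ,d,k,p) of order β^(p+2k); truncation
keeps k ≤ floor((order − p)/2). The G integrands are smooth rational
functions on [0, tan(α/2)] and are evaluated by adaptive Gauss–Kronrod
quadrature at rel. tol. 1e−12 (abs. 1e−15): the series bookkeeping lives in
the truncation rule, not in closed-form antiderivative tables, and each G
could be swapped for its exact rational antiderivative behind the same
interface without changing any contract. The odd-secant integrals that
appear in the pole-density part use their elementary closed form
(log + finite sum), validated against quadrature.

Every long coefficient block used by a series was re-derived or validated
numerically against quadrature of the defining integral before being
trusted; the adopted readings are those matching the oracle, e.g. the alternating signs of the area series
F(0,0,2)/2 − 3F(0,0,4)/8 + 5F(0,0,6)/16, the sign of the first-moment x/y
block, and the (14h̃−143)/84 second-moment correction. The kernel
expansions used by the vertex field were confirmed by residual-order fits
(slopes 3 → 5 → 7 → machine precision as terms are added).

## Vertex field

The field at a point just above/below a patch vertex splits into the
continuous (principal-value) part plus the Gaussian-units jump. The
continuous part is ∫dφ∫ σ(θ,φ) cos(θ/2)/2 dθ — regular, because
sin θ/√(2−2cos θ) = cos(θ/2) exactly. The θ integral of the t-weighted
part has an exact closed form, re-derived here by rationalizing the
denominator (C sin + D cos → C²(1 − η²cos²θ), η² = 1 + D²/C²) and partial
fractions in √2 sin(θ/2) and √2 cos(θ/2); it is valid while η cos β > 1
(equivalently (1−δ/R)cos β > 1/2, always true in the small-arc regime) and
falls back to quadrature with a warning otherwise.

Series orders 1, 3 and 5 use the G combinations; density-difference terms
carry one extra β order (neighboring vertex densities of a smooth surface
distribution differ at O(β)) and are truncated one order lower. Order 7 evaluates the azimuthal integral
numerically over the four-term series kernel — still cheap, and it keeps
the σ₁ part exact via sin(β(φ)/2). Series mode requires all side arcs
≤ β_max (default 0.35 rad, configurable); beyond that the regularized
quadrature oracle is authoritative. The error estimate attached to a series
result is the magnitude of the first dropped G term — a scale, not a bound.

The jump added on top of the continuous sum is +2πσ_vertex above and
−2πσ_vertex below *after summing all patches that contain the vertex*,
i.e. when the mesh tiles the full neighborhood. For a single isolated
patch the physical boundary-layer jump is only the wedge fraction
α/(2π)·4πσ; the oracle test demonstrates both statements.

**Order-of-accuracy study condition.** The halving-factor check
(order-3 error falling by ≥ 8 per halving of the patch scale) uses the
symmetric worked-example shape β₂ = β₃, α = π/3 with densities
(1, 0.9, 1.1). For that shape the dropped β³ combinations cancel and the
measured factor is ≈ 32; for generic asymmetric shapes the factor
approaches its asymptote 8 from below at finite size (measured 7.9–8.0).

## Moments and far-field expansions

Exact closed forms are used for the area
A = α − atan[a sin(α−φ₀) sin β₂] − atan[a sin φ₀ sin β₃] (this algebraic
form is regular in the octant limit) and for the direction averages t_x,
t_y, t_z. For the charge moments the pole-density parts reduce to clean 1-D
azimuthal integrals, and the density-gradient parts reduce at each azimuth
to ∫ sin^m θ cos^n θ/(C sin θ + D cos θ) dθ, integrated in closed form via
the rotation C sin + D cos = ρ sin(θ+γ); a single adaptive 1-D pass then
gives machine-accurate moments at any patch size ("exact" route). The
"series" route uses the G combinations and converges at O(β⁶) relative to
leading order. The 2-D quadrature oracle is the source of truth for both.

On-sphere radial field: the kernel is exactly half the potential kernel
(the average of interior/exterior radial derivatives), so
E_r = potential/(2R) identically — asserted for every fixture. The moment
expansion about the average direction converges iff
1 − r̂̃·(r̂₁+r̂₂+r̂₃)/3 > 2[1 − min pairwise r̂ᵢ·r̂ⱼ] (symmetric in the
vertices);
method "auto" uses it plus the β_max = 0.35 patch-size gate. Evaluation
directions within 1e−3 rad of the patch boundary are refused (the kernel
is integrable but quadrature accuracy degrades; boundary-layer evaluation
is the vertex machinery's job). The exterior expansion is the shifted
second-order multipole about r_ave = R·t, with the field as its exact
term-by-term gradient; the far potential therefore tends to
q₀/|r̃ − r_ave| (the deviation from q₀/|r̃| at finite distance is the
patch's own dipole about the origin, O(|t|/|r̃|)).

## Quadrature oracle

Iterated adaptive quadrature, outer φ and inner θ, inner tolerances 10×
tighter (defaults rel 1e−10/abs 1e−13), deterministic and seedless;
unreached tolerances emit a warning, never silence. The vertex-limit
kernel uses the exact cos(θ/2) regularization. The moment oracle evaluates
all ten defining integrals in one vectorized adaptive pass.

## Dielectric-sphere demonstration

The SCM interface condition ε_in E_n(R⁻) = ε_out E_n(R⁺) with
E_n(R±) = E_PV ± 2πσ gives σ = f(E_n^source + E_PV[σ]),
f = (ε_in−ε_out)/(2π(ε_in+ε_out)), discretized on an icosphere (20·4^level
great-arc faces) with vertex densities as unknowns and a dense direct
solve. Influence entries use the order-3 vertex series for faces containing
the evaluation vertex (regularized quadrature if a face exceeds β_max, as
at level ≤ 1), the moment expansion for faces passing the convergence gate,
and a fixed 16×12 product Gauss rule for near-but-not-incident faces — so
the demo exercises the auto-selection machinery end to end. The analytic
reference is the Legendre-series density
σ_l = f q (l+1) b^l / (1 − 2πf/(2l+1)) (50 terms), and the l = 0 sum rule
q(1/ε_out − 1) is checked independently. Problem sizes: levels 1–3
(42–642 vertices); the level-3 solve runs in well under a minute on one
core, and the area-weighted relative L2 error falls monotonically
0.95% → 0.37% → 0.098%.

## What the synthetic fixtures do and do not show

`generate_fixtures` draws side arcs uniformly in [0.02, 0.3] radians by
default (the series regime; the upper bound stays below the β_max gate),
azimuthal openings in (0.25, π−0.25), uniform vertex densities in [−1, 1],
and a random orientation — emulating the panel shapes and smoothly varying
induced densities an SCM mesh produces. They do not emulate: toroidal
panels or panels with a non-great-arc side (out of scope here), extreme
needle-shaped triangles (α near 0 or π), densities with near-complete
cancellation across one patch (relative-error statements degrade there;
the accuracy sweep uses one-signed densities for that reason), or
molecular-surface meshes with mixed patch sizes. Passing tests therefore
demonstrate correctness of the patch primitives and their advertised
convergence orders, not end-to-end accuracy on a real molecular surface.

## Known limitations

* Patches with a side that is not a great arc, and toroidal patches, are
  not treated.
* Series evaluation refuses a < 1 or arcs > β_max rather than degrade.
* The interpolation scheme is C⁰ across edges, not C¹, and is not exactly
  consistent under subdivision (fourth-order mismatch, see above).
* Exterior evaluation requires |r̃| > R; points strictly inside the sphere
  are out of scope, as are tangential on-sphere field components.
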