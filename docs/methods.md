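# Methods

This document records the mathematical model, the numerical methods and
the known limitations behind `atflap`'s results.  Units are mm, MPa and
degrees throughout.

## 1. Flap geometry

The excised region is an isosceles triangle with apex angle *2θ*
circumscribing the circular defect of radius *r* (the incircle of the
triangle touches the base).  With *θ* the half-apex angle:

* length-width ratio  `h/d = 1 / (2 tan θ)`
* maximum suture distance (base width)  `d = 2 r (1 + sin θ) / cos θ`
* suture area  `S = r² (1 + sin θ)² / (sin θ cos θ)`

`S = d·h/2` holds identically (triangle area), which the tests use as a
cross-check.  Setting `d(log S)/dθ = 2 cos θ/(1 + sin θ) − cot θ + tan θ`
to zero gives the unique interior minimum at `θ = 30°` (apex `2θ = 60°`);
`optimal_apex` performs a grid search so that a clinical length-width
bound `h/d ≤ c` (an active lower bound on θ) can be imposed.  For
`r = 10 mm` at 60°: `h = 30 mm`, `d = 34.64 mm`, `S = 519.6 mm²`.

The lateral base-extension incisions extend from the base corners
`B = (−d/2, 0)`, `C = (d/2, 0)` outward to `±L` with `L = max(d/2, 3r)`
(30 mm in the reference design).

## 2. Skin material

Skin is modelled as an incompressible two-term Ogden solid,

`W = Σₙ μₙ/αₙ (λ₁^αₙ + λ₂^αₙ + λ₃^αₙ − 3)`,  `λ₁λ₂λ₃ = 1`,

with the facial-skin parameters `μ = (7.5809·10⁻⁷, 0.1683) MPa`,
`α = (2.1065, 12.006)` used as the package default.  The closed-form
uniaxial Cauchy stress is `σ = Σₙ μₙ (λ^αₙ − λ^(−αₙ/2))`; an
independent oracle (numerical minimisation of *W* over the lateral
stretch followed by differencing) agrees with it to 10⁻⁶ relative, which
pins the sign and normalisation conventions.

The membrane is in plane stress: the thickness stretch
`λ₃ = 1/det F₂ₓ₂` eliminates the pressure via `σ₃₃ = 0`, giving the
principal in-plane stresses `σᵢ = Σₙ μₙ (λᵢ^αₙ − λ₃^αₙ)` which are
reassembled spectrally from `b = FFᵀ` (with a guard for nearly equal
eigenvalues).  `fit_ogden` recovers parameters from uniaxial
stress-stretch curves by multi-start bounded least squares.

Note the strong strain-stiffening: `α₂ ≈ 12` means the stress grows
roughly as `λ¹²`, so a principal stretch of 1.27 already produces
~3 MPa and a stretch of 1.75 produces ~150 MPa.  This single fact
dominates the interpretation of the simulation maxima below.

## 3. Meshing

The analysis domain is a `width × height` rectangle (default 90 × 100)
with the future T-joint at the origin.  The mesher is deterministic and
block-structured: a regular grid below the incision line and graded
columns above the excision profile (the triangle waists are exact
element boundaries), with nodes duplicated across the extension cuts.
Reference Jacobians are positive by construction at every admissible
element size (0.5–10 mm); at 3 mm the reference setup yields 1060
elements / 1144 nodes.  Quality metrics per element: inverted
(non-positive Gauss Jacobian), distorted (minimum corner scaled Jacobian
< 0.5), bad aspect (edge-length ratio > 1.5).

## 4. Closure kinematics

The closed wound is idealised as a "T" polyline: two straight lateral
limbs from the incision tips `(±L, 0)` to a joint at `(0, y_J)` and a
vertical limb from the joint to the settled apex.  Every wound-margin
node is assigned a target on this polyline by arc length, so that

* each lateral limb joins the incision-side margin (tip → base centre,
  arc length `L`) to the flap-side margin (extension cut + lower waist,
  also exactly arc `L`) — the seam pairing is stitch-for-stitch length
  preserving (residual tangential stretch 1.054 at the defaults);
* the upper waist halves (arc `L_w − d/2` each, where `L_w` is the
  waist length) zip mirror-to-mirror onto the vertical limb at natural
  length.

The joint height minimises the largest prescribed displacement; the two
extreme movers (base centre rising to the joint, waist split point
swinging onto it) travel equally when

`y_J = [ (d/2)² (1 − (d/2)/L_w)² + (h d / (2 L_w))² ] / (h d / L_w)`,

which evaluates to 10 mm for the reference design, making the largest
prescribed suture displacement exactly 10 mm.  Alternative target
strategies that drag the base corners all the way to the joint were
analysed and rejected: they impose an intrinsic tangential stretch of
`L/(L − d/2) ≈ 2.37` on the flap edge, which with `α₂ ≈ 12` produces
seam stresses of order 10³ MPa and endangers Newton convergence, without
changing the qualitative picture.

Stitches are modelled as node-to-node gluing, not contact: a tie binds
the *current positions* of a margin pair,
`u_slave = u_master + (X_master − X_slave)` (stitched pairs are
generally not coincident in the reference configuration).

## 5. Finite-element solver

Total-Lagrangian 4-node quadrilaterals with 2 × 2 Gauss quadrature and
unit thickness; the first Piola-Kirchhoff stress is `P = σ F^{−T}`
(plane-stress incompressibility makes the in-plane Jacobian carry the
volume change).  Element tangents are central finite differences of the
analytic internal force (h = 10⁻⁶), symmetrised; assembly is sparse CSR
and the linearised systems are solved by sparse LU.

Constraints are handled by a master-slave transform `u = T q + u_tie +
u_pres(τ)`: prescribed dofs are ramped with the load factor τ over the
load steps, ties are condensed exactly.  Each step runs Newton with an
optional backtracking line search; a diverging step is bisected (up to
4 times by default).  Convergence demands a residual below `10⁻⁸`
relative to the internal-force scale.

* **Suture stage** — all margin targets ramped from the reference
  configuration; the four domain corners are fixed.
* **Release stage** — starting from the suture state, the prescriptions
  are removed and replaced by the stitch ties; the locked-in margin
  reactions `g₀ = Tᵀ f_int(u_suture)` are unloaded by force
  continuation, `f_ext = (1 − τ) g₀`, so the wound settles into the
  tied equilibrium.

Stress postprocessing extrapolates Gauss values to element corners and
averages per node; the reported von Mises stress is that of the averaged
tensor, `√(σ₁₁² − σ₁₁σ₂₂ + σ₂₂² + 3σ₁₂²)`.

## 6. Verification

* Uniaxial closed form vs the energy-minimisation oracle: 10⁻⁶ relative
  over λ ∈ [0.85, 1.6].
* Single-element and 2 × 2 patch tests reproduce the homogeneous
  uniaxial plane-stress state to 10⁻⁸ relative; rigid translations and
  rotations are force- and stress-free to 10⁻⁹.
* Assembled tangent matches directional finite differences of the
  internal force to 10⁻⁵ relative; the unconstrained tangent has
  exactly three zero-energy modes.
* Ogden fitting round-trips synthetic curves to RMS < 10⁻⁴ MPa.
* Meshes at 4/3/2/1 mm contain zero inverted elements; displacement
  fields are mirror-symmetric to machine precision; tied pairs remain
  closed (< 10⁻⁶ mm gap) after release.

## 7. Results and interpretation

Reference simulation (r = 10 mm, 60°, 90 × 100 mm, 3 mm, default skin):

| stage | max von Mises [MPa] | at | max displacement [mm] | at |
| --- | --- | --- | --- | --- |
| suture | 562.3 | waist split point (maps to T-joint) | 10.00 | base centre |
| release | 168.9 | defect apex | 11.63 | base centre |

Element-size sensitivity (release stage):

| size [mm] | elements | nodes | max vM [MPa] | max u [mm] | inverted |
| --- | --- | --- | --- | --- | --- |
| 4 | 596 | 659 | 163.0 | 11.78 | 0 |
| 3 | 1060 | 1144 | 168.9 | 11.63 | 0 |
| 2 | 2436 | 2563 | 181.8 | 11.50 | 0 |
| 1 | 9560 | 9814 | 200.0 | 11.34 | 0 |

The displacement field is mesh-converged (1.4% change from 2 mm to
1 mm).  The stress maxima are *not*: they sit at re-entrant material
points of the closed T (the seam corner at the joint, the apex of the
closed notch) where the continuum solution is singular, so the reported
maximum grows slowly under refinement.  Away from these corners the
seam stresses are of order 1–3 MPa, consistent with the ~5% residual
tangential seam stretch and the `λ¹²` stiffening law.  Peak *nodal*
stress values should therefore be read as mesh-indexed concentration
indicators, not as pointwise material stresses; comparisons between
designs should be made at fixed element size (as in the sensitivity
table) or on field quantiles.

Releasing the prescriptions relaxes the peak stress by ~3× while the
maximum displacement *rises* slightly (10.0 → 11.6 mm): the prescribed
closure is the minimum-travel one, and the tied equilibrium lets the
seam settle a little past it.

## 8. Limitations

* 2-D plane stress: no out-of-plane buckling, bending or true "dog-ear"
  formation; cat-ear/dog-ear tendencies only appear as in-plane
  compression near the incision tips.
* No contact mechanics or friction: stitches are ideal node-to-node
  bonds; margins cannot slide or separate.
* Homogeneous, isotropic skin; no Langer-line anisotropy, no
  viscoelasticity, no growth or remodelling; no prestretch (in vivo skin
  tension is not modelled).
* Corner stress maxima are mesh-unconverged by nature (see above).
* Load stepping with bisection cannot traverse genuine limit points; on
  some small, finely meshed domains the release stage encounters an
  in-plane snap-through of the tangentially compressed seam band and
  stops with a `SolverError` (arc-length continuation would be needed).
* The closure targets are a kinematic idealisation; real suturing
  sequences and tension distribution vary between surgeons.
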