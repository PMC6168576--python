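# Methods

## The physical picture

The outermost stratum corneum of papillated skin is modelled as a thin,
brittle, intrinsically curved sheet — a *shell*: its stress-free shape is
the papillated dermal surface it formed on, and, being built of dead
keratinised cells, that rest shape is permanent.  Two loading hypotheses
are implemented on identical substrates:

* **Growth.**  New keratinous sheets are added from below, pushing the
  outer sheet outward.  Numerically, every node is tethered to its original
  substrate *foot point* displaced by an offset `h` along the substrate
  normal frozen at initialisation.  Because normals converge inside a
  trough, the offset target surface pinches, and the compliant (bending-soft)
  sheet must curve ever more sharply in the valleys; the resulting
  outer-fibre bending strain is what breaks bonds there.
* **Shrinkage (desiccation).**  The in-plane rest metric contracts
  uniformly (`l0 -> l0 (1 - s)`, rest areas by `(1 - s)^2`, rest dihedral
  angles unchanged) at fixed offset.  Tension builds everywhere; the sheet
  partially relieves the across-trough component by lifting off the valley
  floors, while the solid dermis prevents relief over the papilla caps —
  so desiccation cracks run across the troughs and over the papillae, the
  classic mud-crack morphology, incompatible with trough-confined cracking.

## Discrete energies

On a triangle mesh with vertices `x_i`, unique edges and interior hinges:

| term | form | notes |
| --- | --- | --- |
| stretch | `Σ (k_s/2) l0 ε²`, `ε = (l-l0)/l0` | per unbroken edge; `l0` weight makes `k_s` a per-length material constant |
| bending | `Σ k_b (θ - θ0)²` | signed dihedral angle per hinge, `θ0` frozen at initialisation; hinge inactive when its edge breaks |
| area | `Σ (k_v/2) A0 (A/A0 - 1)²` | per face with no broken edge; the in-plane "volumetric" response of the sheet |
| substrate tether | `Σ (k_sub/2) |x_i - (p_i + h n_i)|²` | foot points `p_i` and normals `n_i` frozen at initialisation; `h` is the growth offset |
| dermis penetration | `Σ (k_pen/2) max(0, S(x,y) - z)²` | one-sided: the dermis is solid from below but does not hold the sheet down, so troughs can lift off |
| self-contact | `(k_c/2)(d_c - d)²` per node-face pair with `d < d_c` | pairs exclude the node's own faces and 1-ring; forces distributed by barycentric weights of the closest point |

All forces are exact negative gradients of these energies; the test suite
verifies each term against central finite differences at 1e-4 relative
accuracy on randomized cracked configurations.  The one-sided penetration
term was added after simulations showed the symmetric tether alone lets a
contracting sheet sink ~0.1 mm into papilla caps, which suppresses the cap
tension that desiccation cracking depends on.

## Fracture criterion

An edge's curvature is `κ = 2θ/(h1+h2)` with `h1, h2` the heights of its
two triangles over the edge; `κ` is negative in a valley for an
upward-oriented mesh.  The default fracture measure is the tensile strain
of the **substrate-facing (inner) fibre** of a sheet of thickness `t_s`:

    ε_eff = ε_membrane − (t_s/2)(κ − κ0)

Deepening a valley (growth) or flattening a papilla cap stretches this
fibre; flattening a valley (desiccation lift-off) compresses it.  This sign
structure is what discriminates the two protocols: a sign-blind
`ε_membrane + (t_s/2)|κ − κ0|` variant (available as
`strain_criterion="outer-fibre"`, along with a pure `"membrane"` option)
breaks valley bonds under *both* protocols, because valley flattening and
valley pinching produce the same `|Δκ|`.  Boundary edges carry the membrane
term only.  An edge breaks, irreversibly, when `ε_eff > ε_c`.

## Quasi-static loading and relaxation

Loading alternates increments with full relaxation: grow `h` by `h_max/8`
(or shrink by `Δs = 0.02`), relax, then break the single highest-strain
edge (ties to the lowest edge id), re-relax, and repeat until no edge
exceeds `ε_c`; stop at a broken-edge fraction of 3% (the presentation point
for all statistics) or at the load ceiling.  One-bond-at-a-time breaking
with interleaved relaxation yields crack *propagation* rather than
simultaneous shattering, and makes event logs exactly reproducible.

Relaxation is damped Newtonian dynamics, `m a = F − γ v`, integrated with
semi-implicit Euler at a time step capped by half the stability bound of
the stiffest term; the bending coefficient in that bound carries a large
safety factor because strongly folded crack-flap hinges stiffen far beyond
any flat-state estimate.  Convergence requires the largest nodal force and
speed to fall below tolerance.  The default force tolerance is 0.02 —
about 7% of the tension in an edge at the critical strain — because cracked
shells sit in badly conditioned energy valleys (very stiff transverse
modes against nearly flat crack-flap modes) where micro-Newton residuals
cost enormous step counts and do not change which edge breaks next.
Uncracked configurations converge orders of magnitude below the tolerance;
tests that need micro-strain accuracy pass tighter tolerances explicitly.
Damping is set heavily overcritical (`γ = 6`) for the same reason: lightly
damped cracked shells wander chaotically among near-degenerate flap
micro-states.

## Parameters

Units: millimetres; energies in units of `k_s·mm`.

| parameter | default | meaning / why |
| --- | --- | --- |
| `k_s` | 1 | stretch scale (sets the unit) |
| `k_b` | 0.005 | soft enough that a tethered sheet complies with trough curvature instead of bridging; with `t_s`, makes the bending contribution to `ε_eff` at trough-scale curvature comparable to membrane strain |
| `k_v` | 0.5 | weak area preservation |
| `k_sub` | 0.5 | soft enough for desiccation lift-off relief in troughs, stiff enough to drive growth compliance |
| `k_pen` | 30 | dermis ≫ tether: solid tissue is effectively rigid against the sheet |
| `k_c`, `d_c` | 2, 0.08 | self-contact; required for convergence once crack flaps open |
| `t_s` | 0.2 (= spacing/10) | mechanical sheet thickness in the fibre strain |
| `ε_c` | 0.3 | critical strain; standard operating point |
| `h_max` | spacing/6 | growth ceiling; standard operating point |
| stop | 3% broken edges | presentation point for all crack statistics |

## Synthetic substrate

Papilla centers on a hexagonal lattice (spacing 2 mm) with isotropic
Gaussian jitter (sd 0.25 mm), one margin ring beyond the domain; each
center carries a compact smooth bump `A·exp(1 − 1/(1 − (r/R)²))`
(A = 0.7 mm, R = 0.9 mm), combined by a p-norm smooth maximum (p = 8) so
trough floors are genuinely flat and the field stays smooth where bumps
overlap.  A flatter-topped `dome` kernel (squared argument) is available.
The default mesh samples the field on a near-equilateral triangular grid at
12 edges per papilla spacing over an 8 × 7 mm domain (~2 400 vertices,
~7 000 edges, ~15-20 papillae in-domain) — chosen as the standard fixture
size for all headline statistics.  What the generator does *not* emulate:
papilla height and spacing variability beyond positional jitter, anisotropic
or clumped papilla arrangements, and measured elephant-skin geometry
statistics; conclusions from these fixtures are about the mechanism, not
about quantitative agreement with any animal.

Trough labelling: a point is "in the trough" when its substrate height is
below `τ·A` with `τ = 0.4` (on the steep flank of the default kernel; the
trough mask covers ~64% of the default substrate's area).  The local trough
direction is the eigenvector of the height-field Hessian with the smallest
absolute eigenvalue (valley line), undefined at umbilic points (relative
eigenvalue gap < 0.15), which are excluded from orientation averages.

## Crack-network statistics

Simulated cracks are projected to 2D as a graph with one node per broken
edge (midpoint of its rest position) and segments between broken edges
sharing a mesh face; degree-2 chains form the crack polylines.
Tri-junctions are graph nodes of degree 3 after chain contraction; branch
bearings are taken at an arc length `r` along each incident chain
(`r` = 2 mesh edge lengths for cracks, 0.2 spacing for trough lines), and
the three sorted circular gaps `(θ1, θ2, θ3)` sum to 360°.  Junctions
within 0.5 mm of the domain border are dropped (clipped branches bias the
angles); degree ≥ 4 nodes are excluded and counted.

At the 3% presentation stop, growth-crack lines are mostly isolated and
carry only a handful of tri-junctions, and branch bearings measured two
mesh edges from a junction are quantised to lattice directions.  Junction
statistics therefore use a *matured* network
(`analysis.mature_crack_network`): the growth run is continued beyond the
display point (offset up to 0.55 mm, break target 5.5%) before junctions
are extracted — crack junctions only form once cracks meet, so the network
must be allowed to develop.  Localisation and orientation metrics are still
reported at the 3% stop.

The angular spreading is `σθ = sqrt(A/π)` where `A` is the area of the
ellipse containing 68% of the probability mass of a 2D Gaussian fitted to
the `(θ1, θ2)` scatter: `A = π c sqrt(det Σ)`, `c = −2 ln 0.32 ≈ 2.28`.
"One standard deviation" and "68%" conflict in 2D (a Mahalanobis-1 ellipse
holds ~39%); the 68% reading is the default and the Mahalanobis variant is
available through the `mass` argument.  Junctions are classified by nearest
archetype among (120, 120), (90, 135), (90, 90) — the Voronoi partition of
the admissible region — with exact ties resolved in that fixed order.
Angle densities use a reflected Gaussian KDE (Silverman bandwidth) with a
seeded bootstrap 95% band.  The trough-line comparator network is the
Voronoi tessellation of the papilla centers clipped to the domain.

## Numerical choices and degenerate inputs

* Hinge angles use the `atan2` form, exact for any fold short of ±180°;
  degenerate (zero-area) faces raise rather than silently continue.
* Mesh regularisation: tangential umbrella smoothing (step 0.6) with
  re-projection onto the original surface (closest point on the input mesh,
  or the analytic surface when one backs the substrate); boundary vertices
  smooth only along the boundary polyline, and boundary *feature* vertices
  (polyline turns > 30°) are pinned.  Connectivity is never changed, so
  the Euler characteristic and boundary vertex count are invariants.
* Voronoi trough junctions of a perfect hexagonal lattice are exactly
  (120, 120, 120); the degenerate zero-covariance scatter is reported as
  `σθ = 0` with a flag.
* Shrinkage rescales rest lengths, areas and hinge heights but not rest
  angles: isotropic in-plane desiccation of an intrinsically curved sheet.
  Scaling `θ0` would model a different hypothesis (through-thickness
  gradients) and is deliberately not done.

## Known limitations

* The relaxation tolerance trades exact equilibrium for tractability in
  cracked states; residual forces up to 0.02 can, in principle, reorder
  nearly tied fracture events.  Event logs are still bit-reproducible for
  a fixed configuration.
* At the standard 3% stop, desiccation statistics mix an early trough-edge
  population (lift-off hinge lines, cross-trough orientation) with a later
  papilla-cap population; the growth-vs-shrinkage *orientation* contrast is
  large (~15° vs ~70°), while the trough-*localisation* difference measures
  ≈ 0.29 on the standard fixture — the two protocols differ cleanly in
  mechanism but not by an arbitrarily wide localisation margin at this
  stop fraction.
* Abrasion, viscoelasticity, moisture gradients through the thickness and
  remeshing at crack tips are out of scope; crack width is one mesh spacing
  by construction.
* True dynamic fracture (stress waves) is excluded by design: the
  quasi-static loop re-equilibrates after every single bond break.
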