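# Methods

This note documents the models implemented in `patellofem`, the defaults
and why they were chosen, the numerical machinery, and what the synthetic
geometry does and does not represent.

## Scope and frame

The package studies retropatellar cartilage load in a healthy and a
severely trochleodysplastic knee, before and after a virtual
sulcus-deepening trochleoplasty, under identical quasi-static loading at
30–75° of knee flexion. All computations use one frame — origin at the
deepest mid-trochlear sulcus point, +x lateral along the posterior
condylar baseline (BL), +y anterior, +z proximal — and one unit system
(mm, N, MPa). Models are generated as right knees; left knees are exact
mirrors.

## Synthetic knee geometry

Both knees are parametric lofts of axial profiles, not segmented images.
Each femoral station carries an anterior arc through the medial condyle
(MC), the sulcus (S) and the lateral condyle (LC), built as a monotone
piecewise-cubic through those control points, closed posteriorly by a
condylar half-ellipse; stations are stacked into a watertight shell with
per-vertex cartilage labels and a smooth thickness map (1.4–2.6 mm,
thickest over the groove). Groove depth varies axially; distally the
groove dives into the intercondylar notch (a quadratic posterior drop
past z = −10 mm), which is what terminates the distal correction plane.

Two presets define the study conditions:

* **healthy** — sulcus depth 5 mm tapering to 3.5 mm proximally, sulcus
  angle 138°, no spur. The patellar articular facets are carved to
  conform to the trochlea's mid-station arc, so the unloaded joint is
  congruent.
* **dysplastic_D** — shallow distal groove (1.5 mm) becoming flat to
  convex proximally (−1.5 mm), widened sulcus angle (162°), medial facet
  hypoplasia (scale 0.75), and a supratrochlear spur (2 mm high, 8 mm
  wide) over the proximal groove. The patellar ridge is flattened
  (2.5 mm, a Wiberg II/III-like shape) — congruent enough with the flat
  trochlea that the large post-surgical incongruence is produced by the
  deepened groove, which is the effect under study.

The presets are calibrated to the clinical indices of the two study
conditions — TT-TG 17 mm, patellar tilt 18°, bisect offset 76 % for the
dysplastic knee; TT-TG 9 mm, tilt 12°, bisect offset 48.5 % for the
healthy control — by construction: the tibial tuberosity reference point
and the patellar start pose are placed to meet them exactly. TT-TG and
bisect offset are read at the most proximal fully cartilage-covered
station, the clinical convention for locating the trochlear groove. All
remaining shape parameters (widths, condylar heights, spur shape,
thickness field) are the generator's own design choices at adult-female
scale; they are *not* patient-derived, and the default sizes are
calibrated so that the healthy knee's contact area is of order 600 mm²
across flexion. Two geometric choices were made after inspecting solved
contact states and are deliberate parts of the study conditions: LC sits
15 mm lateral of the groove (narrower trochleae leave an unphysically
sharp LC–S1 wall after lateralizing the sulcus by 6.1 mm), and the
trochlear cartilage extends past the loaded zone (z from −24 to +18 mm)
so that load-bearing contact never rides the cartilage margin.

Vertex jitter is available (seeded, default 0) for robustness testing
only.

What the generator does **not** emulate: real subchondral bone
morphology, patient-specific cartilage thickness distributions, menisci
and the tibiofemoral compartment, osteophytes, and the full Dejour
spectrum. Passing tests therefore demonstrate correct mechanics and the
qualitative surgical effects on a controlled geometry family — not
validated absolute stresses for any patient.

## Virtual trochleoplasty

The operator relocates S to S1 = S + f·(L·BL_lat − D·n_post) with mean
lateralization L = 6.1 mm and mean deepening D = 4.0 mm, scaled by the
correction factor f (nominally 0.5, 1.0, 1.5). L is fixed by the
operator's own linearity: the TT-TG reduction is f·L, i.e. 3.05 mm at
f = 0.5 and 9.15 mm at f = 1.5. D has no comparable anchor in the
reference literature; 4 mm is a configurable default of this package.

The two correction planes are located automatically: proximally the most
proximal station whose full MC–LC arc is cartilage-covered, distally the
last station before the sulcus polyline's tangent to the axis exceeds
45° (the groove turning into the notch). Between the planes the full
correction applies; outside, a cosine taper of width `blend` (default
3 mm) takes it smoothly to zero — the simplest reading of anchoring the
correction at two planes, avoiding slope discontinuities. At each
station the anterior arc between MC and LC is replaced by a monotone
piecewise-cubic through MC, S1, LC (a straight two-segment mode exists
for strict literalism). The cartilage flap is treated as re-draped onto
the new bed: the per-vertex thickness map is carried over unchanged, and
the 2 mm bony shingle of the surgical technique is not modeled separately
(consistent with rigid bone and a bonded interface). The resected wedge
volume is the integral of the anterior material removed.

## Cartilage FE model

Cartilage is homogeneous, isotropic, linear elastic — E = 5.0 MPa,
ν = 0.47, cartilage–cartilage friction μ = 0.02 — and bones are rigid:
the femoral osteochondral interface is fixed, the patellar one rides the
patellar rigid body. The layer is meshed by extruding the labeled
articular patch along inward vertex normals through the thickness map,
splitting each prism into three conforming 4-node tetrahedra
(smallest-global-index diagonal rule). Three layers through the
thickness at default surface resolution give ≈ 22k deformable elements
per knee, the same order as the reference models (≈ 35–40k); the bundled
study uses two layers on a coarser surface (≈ 6k elements per knee) to
keep twenty solves affordable on one CPU. Constant-strain tetrahedra
with near-incompressible ν are stiff in bending but behave well in the
predominantly confined compression of thin bonded layers; the confined
modulus E(1−ν)/((1+ν)(1−2ν)) = 30.045 MPa is reproduced to machine
precision (the element is exact for uniform strain), and mesh-refinement
drift of the knee peak pressure is held below 5 % by a regression test.

## Loading protocol

Per flexion angle θ ∈ {30, 45, 60, 75}°:

* quadriceps force 276 N split 111 : 67 : 98 (RF/VI : VM : VL) exactly;
  per-θ unit direction vectors from an editable table (default posterior
  inclination growing 6°→15° from 30°→75°, VM 32° medial, VL 22° lateral
  in the coronal plane — stand-ins for the cited experimental directions,
  which are not printed anywhere reusable);
* a three-spring patellar tendon fan, total stiffness 4334 N/mm split
  equally, tension-only, with its origin at the tibial tuberosity rotated
  about the posterior condylar axis by 0.55·θ (the tendon-to-shaft angle
  grows slower than the joint angle because of femoral rollback; 0.55 is
  a design choice that produces a physiological rise of joint compression
  from ≈ 0.45·Q at 30° to ≈ 1.1·Q at 75°);
* MPFL (6.45 N/mm) and LPFL (5.42 N/mm) as tension-only springs with 2 %
  prestrain (prestrain magnitude unspecified in the source literature;
  2 % is the package default), attached at the adductor tubercle /
  medial patellar edge midpoint and lateral epicondyle / most lateral
  patellar point;
* patellar rotations fixed at the configured start orientation; the
  three translations are free. The start pose engages the patella
  distally with flexion (z from +4 mm at 30° to −9 mm at 75°); for
  postoperative models the search starts with the ridge near the
  relocated groove (a deepening trochleoplasty medializes tracking).

Tibiofemoral kinematics appear only through this tendon-origin map —
the single role they play for patellofemoral statics with a fixed femur.

## Contact solver

Node-to-surface contact: patellar articular nodes against the deformed
femoral articular surface. Detection is a deterministic k-d-tree
proximity query with closest-point projection; the gap is measured along
barycentric-interpolated vertex normals (a C1-ish gap on faceted
masters), pairs whose projection falls on the free boundary of the
master patch are released, and a node wedged into a concave corner keeps
one pair per wall (all interior projections), which stabilizes contact
in the deepened groove. The penalty formulation (default
100 MPa/mm tributary-area-weighted springs) is insensitive at the 1–2 %
level to doubling the stiffness, and an augmented-Lagrange outer loop is
available when penetrations must be driven below a set tolerance.
Friction uses a regularized Coulomb law about the first-contact anchor
(μ = 0.02); the default study path is frictionless, the difference being
far below the study's effect sizes.

The coupled unknowns (nodal displacements + rigid patellar translation)
are solved by damped Newton with load ramping (4 steps), line search, a
step cap, and sparse direct factorizations — bitwise-reproducible across
runs. When pairing chatter on flat faceted terrain prevents full
convergence, a staggered phase freezes the pairing, converges the smooth
subproblem, releases, and re-verifies, keeping the best verified state.
Convergence is declared when ‖R‖ ≤ `newton_tol` × applied load. The
default tolerance is 1e-6; the bundled study runs at 1e-2 (1 % force
imbalance) because the C0 contact pairing on the flat dysplastic facets
bounds the reachable residual — at that level the stress metrics move by
well under a percent. Solves that do not reach their tolerance are
returned flagged (`max_iterations`, or `dislocated` when the patella
leaves the trochlea), and the metrics layer refuses to report stresses
for them; the study driver retries such cells from laterally nudged
start poses before recording a failure.

## Output measures

* Contact pressure per patellar face (penalty/augmented multiplier
  recovery). Peak = max over contacting faces; mean = area-weighted mean
  over faces above τ = 0.271 MPa (the literature inclusion rule —
  including all faces would dilute the mean with near-zero values).
* Contact area = summed undeformed areas of faces with any positive
  pressure (numeric floor 1e-6 MPa); τ is *not* applied to area by
  default, since the inclusion rule exists to make the *mean* meaningful
  — a thresholded area is available explicitly.
* Von Mises equivalent stress √(3 J₂) per element; statistics
  (volume-weighted, same τ rule) over elements adjacent to either the
  articular (chondro-chondral) or the osteochondral interface — the
  literature is ambiguous about which interface is reported, so both are
  first-class outputs; the sensitivity driver uses the articular side.
* Alignment: patellar tilt (axial-plane angle of the transverse patellar
  axis against BL), bisect offset (percent of patellar width lateral to
  the sagittal plane through the groove reference point), TT-TG
  (lateral offset of the tibial tuberosity from that point along BL).

Statistics: pooled mean and sample SD (n−1) rounded half-away-from-zero
to two decimals (1.965 → 1.97); percent changes to integer percent;
two-sided Student (pooled variance) and Welch (Satterthwaite) t-tests,
with a summary-statistic variant for literature comparisons and p = 1 by
convention when both groups are constant and equal. The postoperative
"all angles" summary pools all 12 values (4 angles × 3 correction
factors) — verified to reproduce the printed reference rows exactly. No
multiple-testing correction is applied (none is applied in the reference
tables).

## Verification

* Patch test: linear displacement fields reproduce uniform stress to
  1e-10 relative; rigid-body modes carry zero force.
* Confined compression: FE modulus = 30.045 MPa to < 0.1 %.
* Rigid-sphere indentation of a bonded 3 mm slab (R = 10 mm, F = 10 N)
  lands at ≈ 0.7 of the Winkler elastic-foundation peak: at these
  parameters the contact radius (≈ 1.9 mm) is smaller than the layer is
  thick, so the local-column assumption behind the Winkler oracle does
  not hold and the continuum spreads load laterally; the computed value
  lies between the Hertz (half-space) and Winkler limits, as it must.
  The flat-punch limit of the same slab reproduces p = F/A and the
  global force balance to 1e-15.
* Hertz benchmark (ν = 0.3, thick slab): the FE peak converges toward
  the half-space value from above; at the finest mesh exercised in the
  tests the raw nodal peak is within ~10–15 % — the residual excess is
  the bonded finite-depth correction plus the slow convergence of
  constant-strain tetrahedra at a contact-pressure maximum.
* Global force balance at convergence: < 1e-6 of the applied load on the
  smooth benchmarks and the healthy knee fixture.

## Bundled study and problem sizes

The default study (`run_study()`) solves 4 angles × 5 configurations at
the reduced study resolution (≈ 8.5k deformable elements per solve,
2 tet layers, penalty 100 MPa/mm, tolerance 1 %), which keeps the
twenty solves plus retries within a few minutes on one CPU. Reported
regressions on these fixtures (dysplastic mean pressure ≥ healthy,
postoperative contact area < preoperative, lateral pressure
concentration) are properties of the shipped fixture pair under the
shipped loading protocol — not claims about all knees. Absolute stress
values of the two reference patients are out of scope by design: they
require the original MRI geometries.

## Known limitations

Linear-elastic monophasic cartilage (no biphasic/poroelastic time
dependence), rigid bone, no menisci or tibiofemoral contact, fixed
patellar rotations, straight-axis trochlea (no helical groove), springs
rather than wrapped muscle paths, and a single synthetic knee per
condition. The contact landscape on coarse faceted surfaces limits the
reachable force-balance residual on flat dysplastic terrain (see the
solver section); refining the master surface reduces this floor at
roughly quadratic cost.
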