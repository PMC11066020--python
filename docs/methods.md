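# Methods

This note records the models implemented by `bulbflow`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations. Units are CGS throughout (cm, s, g;
viscosity in Poise, stress in dyn/cm², pressure converted from mmHg at the
API boundary with 1 mmHg = 1333.22 dyn/cm²).

## Boundary conditions (`bulbflow.windkessel`)

Subject-specific outlet conditions follow the standard clinical recipe for
carotid simulations. Mean arterial pressure is the diastolic-weighted mean
MAP = DBP + (SBP − DBP)/3; because MAP is linear in the two pressures, a
group's mean MAP equals the MAP of the group-mean pressures, which is what
makes cohort-level MAP arithmetic well defined. Total peripheral
resistance is R = MAP/Q̄ with Q̄ the time-averaged inlet flow, and total
compliance is C = SV/PP (stroke volume over pulse pressure). Outlets share
the totals by Murray's law with exponent 2.1 on the outlet diameter: flow
fractions fᵢ = dᵢ²·¹/Σdⱼ²·¹, per-outlet resistances Rᵢ = R_total/fᵢ (so
the parallel combination recovers the total exactly) and capacitances
Cᵢ = fᵢ C_total. The exponent acts on diameters; since the fraction is
scale-invariant the diameter-vs-radius choice is cosmetic, but it is fixed
and documented here.

Each three-element (Rp–C–Rd) outlet is split with a proximal fraction
Rp/(Rp+Rd) = 0.09, a conventional carotid value; the split and the venous
reference pressure (default 0 mmHg) are configurable because neither is
uniquely determined by the estimation recipe. A 0D validator integrates
C dP_d/dt = Q(t) − (P_d − P_ref)/Rd with classical RK4 (default
dt = T/400, at most T/100) from the steady initial guess
P_d(0) = P_ref + Rd Q̄ for five cycles; the constant-flow steady state
P_in = P_ref + Q(Rp + Rd) is exact to integrator tolerance and the last
two cycles agree to <0.5%, which is the convergence contract used in
testing.

## Geometry (`bulbflow.geometry`)

The centerline is extracted by marching cross-section centroids: a cutting
plane advances along the running tangent in steps of 0.25 × local radius;
the plane/tetrahedron intersection polygons are computed exactly and
grouped into connected components (shared mesh vertices, plus a geometric
merge of components whose centroids fall within 0.25 × local radius —
this heals the non-conformal joints of the synthetic bifurcation's
union-of-tubes junction). The followed component contributes the next
station: its area centroid, and an equivalent radius √(A/π), which is the
package's single definition of "lumen radius". The first station at which
the section splits into two substantial components (area ≥ 25% of the
followed one, confirmed at the next station) marks the bifurcation; the
recorded branch point is the last single-section station, and the march
then follows the component nearest the ICA outlet. This
cross-section-marching scheme replaces a Voronoi/medial-axis centerline;
it is simpler and adequate for near-tubular lumens, and on a straight tube
recovers the axis to ~1e-16 and the radius to the polygon-inscription
deficit (<1%).

Percent narrowing follows the ECST idea — 100 (1 − d_min/d_ref) — with an
operational reference: d_ref is interpolated linearly between the median
diameters of a proximal and a distal window (window width = 2 × local
radius, separated from the lesion by one window). Medians make the
reference robust to single bad stations and to the junction region of a
bifurcation.

The bulb ROI runs from the lesion (the narrowest station; the bifurcation
station, or a caller-provided anchor, for unnarrowed vessels) to
1.5 × CCA diameter downstream along the trunk→ICA path, where the CCA
diameter is twice the median radius over the first 0.5 cm of centerline.
Faces and cells join the ROI by nearest-centerline-point arclength
projection, gated at 2.2 local radii of path distance so the ECA side of
a bifurcation is excluded; membership is therefore monotone in the span.
An ROI that runs off the meshed domain is truncated with a recorded
warning, not an error.

## Wall indices (`bulbflow.wall`)

WSS is estimated per wall face by probing the interpolated velocity along
the inward normal at δ = 0.1 × local radius and δ/2 and applying the
one-sided second-order difference τ = μ(4 v_t(δ/2) − v_t(δ))/δ to the
tangential component. This formula is exact for a parabolic profile, so
the remaining error is barycentric-interpolation error and vanishes under
mesh refinement (measured: 2.0% worst-case on the default tube, 0.4%
after one refinement step). A single-probe first-order variant
(`scheme="linear"`) is retained for reference; it carries an irreducible
−δ/(2R) bias on curved profiles. Faces whose probe points fall outside
the mesh are flagged and excluded from area statistics. Probing accuracy
is also why generated tubes default to a boundary-layer-like radial
grading (`wall_grading = 1.6`): with uniform rings, linear interpolation
pins the recovered gradient to the mid-cell radius and the error to
~1/(2 n_radial).

TAWSS is the periodic trapezoid time-average of |τ|;
OSI = ½(1 − ‖∫τ dt‖/∫‖τ‖ dt) with the 0/0 case defined as 0, clipped to
[0, 0.5], and values below 1e-12 floored to exactly zero so unidirectional
flow does not yield round-off OSI; RRT = 1/((1 − 2 OSI) TAWSS) with an inf
sentinel (excluded from statistics) where the denominator vanishes. Area
fractions use strict inequalities (γ < threshold, OSI > threshold) and
face-area weighting — the boundary set has measure zero for continuous
fields and the convention is stated for discrete ones.

## Volumetric indices (`bulbflow.volumetric`)

A tetrahedron is low-velocity at a frame when its centroid speed — the
mean of its four vertex speed magnitudes — is strictly below the
threshold; the low-velocity volume percentage is the volume of those cells
over the ROI volume, and on a steady parabolic tube it converges to the
analytic annulus fraction v_t/(2 v̄). Stasis is the percentage of frames
whose low-velocity volume exceeds a presence floor of 0.1% of the ROI
volume; a literal "> 0" rule is available (`presence_floor=0`) but is
sensitive to single-cell mesh noise, which is why a small floor is the
default. The time-averaged volume metric is defined as the arithmetic
mean of the per-frame curve (frames are uniform), so curve and scalar are
identical by construction.

## Cohort statistics (`bulbflow.stats`)

Pooled thresholds concatenate face values across subjects, unweighted by
area (an area-weighted variant exists but is not the default), and take
the tail percentile with linear interpolation between order statistics —
the convention matters for tail percentiles and is fixed here. ROC AUC is
the Mann–Whitney probability with ties counted ½, which equals the
trapezoid area under the empirical curve to 1e-12; Gini = 2 AUC − 1. The
threshold sweep recomputes the low-velocity score at each candidate and
returns the AUC-maximizing candidate, ties to the smallest.

Group comparison uses tie-corrected Kruskal–Wallis H with the chi-square
omnibus approximation and Dunn's pairwise z on pooled ranks with
Bonferroni adjustment (the adjustment is configurable and recorded). At
the tiny group sizes this package targets, the chi-square approximation
is poor — for three groups of three it can differ from the exact
permutation p by an order of magnitude — so a Monte-Carlo permutation
omnibus p (`p_method="permutation"`) is provided and is the variant
checked against exhaustive enumeration in the tests.

## The synthetic-flow generator (`bulbflow.synthetic`)

The generator exists to give every downstream stage an exact oracle, not
to solve the flow equations.

**Waveform.** Baseline plus two Gaussian bumps (systolic peak at 0.16 T,
dicrotic bump at 0.45 T); baseline and amplitude are solved so the
discrete periodic mean and the maximum match the requested values exactly.
Negative-flow waveforms are permitted (needed to exercise OSI reversal)
even though physiological carotid waveforms are positive.

**Meshes.** Structured disk × axial extrusion, prisms split into
tetrahedra with index-based diagonals (conforming across neighbors);
boundary faces are extracted by face counting and labeled inlet / wall /
outlet; normals are oriented outward using the adjacent tetrahedron. The
default tube resolution keeps the volume within 2% of πR²L (error ∝
1/n²). A radius-profile hook produces focal Gaussian narrowings (webs,
plaques); a bend map produces curved tubes for centerline validation; the
Y-bifurcation is a geometric (non-conformal) union of three tubes with
the branches extended back into the trunk so the junction is filled —
sufficient for the marching centerline and membership metrics, not for
conforming FEM.

**Fields.** Per-branch parabolic profiles
v = 2 Q_b(t)/(πR²)(1 − (r/R)²) along the local axis with exact no-slip at
wall vertices; branch flows split by Murray fractions. Surface-integrated
inlet flux matches Q(t) to <2% at default resolution.

**Pocket.** Inside one or two spheres the velocity is replaced by a
swirl-plus-axial-bleed pattern whose maximum speed follows a schedule:
below the cap for exactly round(dwell_fraction × frames) frames (ties
toward more frames; the dwell frames are the lowest-ambient-speed, i.e.
diastolic, frames) and far above it otherwise. The sphere radius is
calibrated discretely — the smallest radius whose fully-contained cells
reach the target volume — so the programmed volume fraction is what the
cell-level metric measures; targets beyond what one wall-clear sphere can
hold are realized as two axially offset spheres (a recirculation zone is
elongated along the vessel). The pocket keeps one cell layer clear of the
wall so that no cell mixes swirl vertices with zero-speed wall vertices.

**Cohorts.** Thirteen web, seven atherosclerosis and six normal subjects
by default. Geometry: webs narrow the lumen by 30 ± 11%, plaques by
42 ± 17%, normals are straight; all on straight tubes standing in for the
trunk→ICA path, with radius 0.27 ± 0.01 cm (inlet area ≈ 0.23 cm²).
Vitals are drawn from the group-level clinical distributions (e.g. web
SBP 126.9 ± 11.8 mmHg) and the cardiac period is 0.9 ± 0.07 s. Flow is
drawn as cross-section mean velocity (19 ± 1 cm/s, peak/mean 2.0 ± 0.1),
which keeps every subject's Reynolds number ρv̄D/μ within the
physiological 100–350 band while the diastolic near-wall cells stay above
3 cm/s (see below). Group effects are carried entirely by the pockets:
dwell fractions 1.00/0.55/0.78 (± 0.035/0.08/0.05) and pocket volume
fractions 0.115/0.075/0.05 (± 0.015/0.018/0.012) for web / athero /
normal, truncated at ±1.5 SD. These defaults preserve the clinical
ordering of the biomarkers (web ≫ normal > athero for stasis; web ≫ both
for volume) with spreads tight enough that the web-vs-other
Dunn–Bonferroni contrasts are detectable at these group sizes in ≥90% of
seeds — at clinical-table spreads that power is unattainable (even
perfect rank separation of 13 vs 6 gives adjusted p ≈ 0.036), so the
generator trades spread realism for a testable contrast.

Two deliberate discretization choices make the pocket the *sole* source
of low-velocity volume at the 3 cm/s operating threshold: cohort tubes
use a mildly coarsened wall layer (`wall_grading = 0.7`, n_radial = 4),
so the thin sub-3 cm/s annulus of the parabolic profile is unresolved,
while near-wall cells in diastole do fall below 5 cm/s and act as
realistic nuisance volume for the larger candidate thresholds; and pocket
dwell speeds are confined to (2.1, 2.8) cm/s with flush speeds above
27 cm/s, so candidates ≤ 2 cm/s see nothing and 3 cm/s detects every
dwell frame fully. Together these make the ROC sweep peak at 3 cm/s by
construction and make stasis recover the programmed dwell fraction to one
frame quantum.

**What the generator does not emulate.** There is no Navier–Stokes
solve: no secondary flows, no Womersley profile, no turbulence, no
moving walls, no real web-shaped separation zones — the pocket is
kinematic fiction with controllable statistics. Passing tests therefore
demonstrate that the *measurement pipeline* is correct on fields with
known answers, and that the statistical machinery has the claimed
operating characteristics; they say nothing about the fidelity of any
particular patient simulation. Wall-metric group *contrasts* are likewise
not programmed: on cohort fields the low-shear area is ~0 for every group
(parabolic wall shear is far above 10 s⁻¹) and elevated OSI appears only
incidentally near pockets, so the cohort-level comparisons of those two
biomarkers are exercised structurally, not calibrated.

## Pipeline (`bulbflow.pipeline`, `bulbflow.cli`)

Per subject: centerline → CCA diameter → lesion location (narrowest
station if narrowing ≥ 5%, else bifurcation, else anchor) → ROI → wall
metrics → per-candidate volume curves. Cohort level: pooled top-1% OSI
threshold, ROC sweep, final metrics at the chosen threshold, group table
with the full-cycle-stasis count. Failures are isolated per subject and
recorded in the manifest; reports use fixed float formatting so reruns
are byte-identical. The 50-seed directionality study skips wall metrics
(the contrast under test is volumetric), which keeps it within a few
minutes on one CPU; problem sizes throughout (cohort meshes ~5k cells,
20 frames/cycle, oracle meshes up to ~300k cells) were chosen as the
smallest at which the analytic checks sit comfortably in their asymptotic
regimes.

## Known limitations

- The centerline marcher assumes near-tubular, simply-connected lumens;
  it has no medial-axis fallback for plate-like or multi-branch geometry
  beyond one bifurcation.
- The WSS probe needs the probe points inside the mesh; at extreme
  coarseness faces are dropped (flagged) rather than extrapolated.
- The bifurcation mesh is a non-conformal union; it is not suitable as an
  FEM domain and its junction wall faces are approximate.
- The chi-square Kruskal–Wallis p is anti-conservative at n ≤ 4 per
  group; use the permutation method there.
- Clinical-scale values for the wall biomarkers (low-shear and high-OSI
  area percentages) require patient-specific separated flow, which the
  generator does not produce.
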