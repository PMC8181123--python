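# Methods

This note documents the modeling assumptions, parameter defaults, numerical
choices, and limitations of the package. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Volumetric body model

The body is 17 rigid segments in a tree rooted at the pelvis: head
(ellipsoid), neck (circular cylinder), thorax / abdomen / pelvis
(elliptical cylinders), and per side upper arm, forearm, thigh, shank and
foot (conical frustums; a frustum with zero distal radius is a cone and is
legal) and hand (sphere). Segment dimensions come from a 36-key
anthropometric profile: girths map to radii as c/2π, breadths and depths to
semi-axes as b/2. The published studies this design follows do not
enumerate their exact measurement list or solid assignments, so the
packaged schema is a documented stand-in: 30 shape measures, 3 attachment
measures (shoulder and hip breadths, ankle height), and three informational
entries (`hand_length`, `stature`, `body_mass`). Density is uniform and set
to 1, so the density constant cancels in the CoM weights and body mass is
metadata only. Closed-form volumes and axial centroids are used throughout;
the tests verify every closed form against 1-D numerical integration of the
cross-sectional area to 1e-8 relative.

Left/right limb segments share measures, so the default model is exactly
mirror-symmetric. Scaling all linear dimensions by k scales volumes by k³,
centroids by k, and leaves mass weights invariant.

## Kinematics

The generalized-coordinate vector has 50 entries: 3 rotations orienting the
pelvis relative to the lab axes, then the internal joint angles in segment
order — fifteen 3-DOF joints plus a 2-DOF neck (3 + 15·3 + 2 = 50). Each
joint uses an intrinsic Z-X-Y Euler sequence (the neck uses Z-X); the
convention is internal and self-consistent — any fixed convention yields the
same analysis on synthetic data. Angles are radians internally; degree
conversion happens at file I/O when declared.

`PV_lab` is taken as the pelvis-anchored CoM expressed in lab-oriented
axes, i.e. a function of the 50 angles only. The alternative reading — a
lab-fixed origin including pelvis translation — is representable by adding
the pelvis anchor explicitly, but the pelvis-anchored form is the default
because its magnitude (a few centimeters) matches the reported decimeter-
scale regime of lab-referenced CoM offsets, whereas a lab-origin distance
would be dominated by the arbitrary origin choice. `PV_foot` adds the
lab-frame pelvis position and subtracts the right-foot (malleolus-midpoint)
position; consequently `PV_foot − PV_lab = r_Pelvis − r_RFoot` holds
identically, which the tests assert exactly.

Batched forward evaluation is the computational core (the permutation stage
evaluates millions of configurations). A numba-compiled kernel handles
batches of ≥ 64 rows; a vectorized NumPy path handles everything else and
doubles as the fallback when numba is absent. Both paths are checked
against an independent rotation-object chain evaluation to 1e-10 m.

## Gait events and normalization

Right-foot stance is detected from the heel and toe markers' vertical
kinematics. Signals are low-pass filtered with a zero-lag 4th-order
Butterworth response (2nd-order filter, forward and backward pass) at a
15 Hz cutoff before differentiation. At foot strike the heel's vertical
velocity steps from its descent value to ≈ 0; at toe off the toe's vertical
velocity steps from ≈ 0 to its ascent value. Each event is located at the
half-height crossing of the filtered velocity step: a zero-lag filter
smears a step symmetrically, so the half-height crossing is an unbiased
frame estimate. Magnitude guards (30 % of the global velocity scale)
prevent filter ripple in truncated cycles from being read as events;
incomplete cycles at either end of a record are dropped. The original
event-detection literature gives only a citation, so this operationalization
is validated against the synthetic generator's ground truth: every event
within ±1 frame at 200 Hz for marker noise up to 2 mm and cadences
80–100 strides/min.

The foot-strike angle is the signed angle between the heel→toe axis and
the ground plane at the strike frame, positive for a heel-first strike.

Stance windows are resampled to 100 points with a natural cubic spline
(endpoints exact); points 1–50 form the absorption phase and 51–100 the
propulsion phase, and phase summaries are arithmetic means of their 50
points. Normalization is idempotent on already-normalized cycles.

## Variability

CV = 100 · SD / mean across cycles, per normalized time point, using the
sample SD (n−1); the denominator choice is configurable. Per-axis CVs use
absolute component values by default, because reported per-axis lengths are
positive magnitudes; a signed-component mode exists but is not the default
(a signed medio-lateral component can have a near-zero mean, which makes
the CV ill-defined).

## T/N/C decomposition

Five datasets per time point: D1 (state 1), D2 (D1 with every EV column
independently permuted across cycles — covariation destroyed, marginals
preserved exactly), D3 (D2 shifted by the column-mean difference to D5's
position), D4 (D5 permuted likewise), D5 (state 2). V(·) is the CV of the
PV through the forward model; for permutation ensembles it is the mean CV
over replicates (the standard choice; pooling across replicates would mix
between-arrangement variance into the estimate). Components:

- T = V(D3) − V(D2): position in EV space (sensitivity / error tolerance);
- N = V(D4) − V(D3): marginal dispersion;
- C = [V(D2) − V(D1)] + [V(D5) − V(D4)]: covariation, with the sign fixed
  by the additivity identity T + N + C = V(D5) − V(D1), which telescopes
  algebraically and holds to 1e-12 in floating point.

Positive values mean variability increased from state 1 to state 2 due to
that component.

The EV set is the 50 angles for `PV_lab`; for `PV_foot` the 6 lab-frame
anchor coordinates are appended as permutable EVs (mixed units are
unproblematic because the analysis lives in the result space); an
angles-only `PV_foot` mode is available. D2 and D4 share permutation index
sets by default ("paired"), which makes the D1 = D5 null evaluate to
exactly zero components and lowers estimator variance; independent index
sets are available, under which null component magnitudes shrink as the
permutation count grows. Permutations sample row orders with replacement
across replicates; at the default 19 cycles collisions are negligible, and
an exhaustive mode enumerates all (n!)^k arrangements for tiny matrices
(used by the oracle tests). The default permutation count is 1,000;
tests and the acceptance script run at 100–200, which the convergence
checks show is ample for phase-mean components.

The decomposition runs independently at each of the 100 normalized time
points from a single seeded random stream; absorption/propulsion means are
taken afterwards.

## Group statistics

Lengths and CVs: dependent t-tests between states. T/N/C: one-sample
t-tests against zero (they are already change scores). Cohen's
d = |t|/√n — equivalently mean difference over the SD of differences — is
the convention that reproduces every published (p, d) anchor pair at n = 13
to the printed precision, which pooled-SD d does not; the tests verify all
seven anchors. Effect bands: small < 0.5, medium 0.5–0.8, large > 0.8.
α = 0.05, two-sided, no multiplicity correction by default (a Holm option
exists). Identical PRE/POST samples yield the defined null result
(t = 0, p = 1, d = 0); a zero-variance sample that is not identically null
raises a degenerate-test error. Subjects with missing values are excluded
per variable with a warning.

## Synthetic cohort generator

The generator defines the study conditions for all tests: 13 subjects × 2
states × 19 cycles × 100 time points × 50 DOF. Waveforms are sums of three
stance harmonics (1, cos πτ, sin πτ) encoding a mid-stance running posture:
forward-leaning trunk with a lateral lean over the stance leg, antiphase
arm swing, stance hip sweeping flexion→extension with knee yield, flexed
swing leg. The trunk coefficients are chosen so the pelvis-anchored CoM
offsets sit in the observed regime (|x| ≈ 0.033 m, |y| ≈ 0.022 m,
|z| ≈ 0.019 m, 3D ≈ 0.045 m), and the anchor trajectories (pelvis ≈ 0.94 m
dropping 0.05 m across stance; foot strike 0.20 m ahead, 0.62 m of
backward travel, malleolus at 0.07 m) put `PV_foot` phase means in the
0.80–0.95 m regime.

Stride-to-stride noise is Gaussian on the harmonic *coefficients*
(per-harmonic SD = σ/√2 so the time-averaged angle SD equals the configured
σ), not on samples, so every cycle is smooth — splines, filters, and event
logic see realistic signals. Defaults: cycle noise 0.009 rad (≈ 0.5°) per
DOF, between-subject offsets 0.02 rad, anchor noise 3 mm. These place the
default CVs near 4 % (`PV_lab`) and 0.5 % (`PV_foot`), the reported order
of magnitude.

POST-state manipulations (one per cohort, magnitude ≥ 0):

- **tolerance** (default 0.07 rad): the mean configuration shifts along the
  negative unit gradient of the PV_lab norm (estimated per subject by
  central differences at the mean mid-stance posture). Same dispersion at a
  smaller mean PV ⇒ larger CV ⇒ T expected positive. The default magnitude
  (≈ 4° distributed over 50 DOF) was fixed at design time as the smallest
  shift whose T clearly dominates the sampling noise of the other
  components at 19 cycles.
- **noise** (default 1.0): all cycle-noise SDs scale by (1 + magnitude);
  N expected positive.
- **covariation** (default 0.8): POST coefficient deviations are projected
  partially out of the PV-sensitive direction, ε′ = ε − m(ε·ĝ)ĝ —
  compensatory coupling that lowers measured PV variability below what the
  marginals imply; C expected negative. The projection is a direction
  change, not a rescaling: with 50 EVs the per-EV marginal SDs change by
  only a few percent, which the tests bound at 5 % averaged over replicate
  cohorts.

`expected_component` maps each manipulation to the component that must
dominate, for parameter-recovery tests.

Marker tracks are generated analytically per stride: the heel lands with a
finite descent velocity and stays down until heel-off (30 % of the
stride); the toe starts at the configured strike angle above the heel
(default 3.5°, the reported rear-foot regime), flattens by 10 %, and leaves
the ground at the stance fraction (35 %) with a finite ascent velocity.
Ground-truth event frames are recorded at generation.

What the generator does **not** emulate: soft-tissue artifact, timing
(phase) variability that time normalization would mask, non-Gaussian or
autocorrelated stride noise, physiological fatigue dynamics (leg stiffness,
lactate), and left-foot events. Passing tests therefore demonstrate that
the pipeline recovers the statistical structure it assumes — not that real
fatigued runners exhibit that structure.

## Problem sizes and determinism

Every random stage takes an explicit seed; fixed seeds give bit-identical
cohorts, permutation ensembles, and output files. The test suite and the
acceptance script run the decomposition at 100–200 permutations and the
parameter-recovery checks on 2–3 replicate cohorts per manipulation
(26–39 subject-level analyses each); the convergence and null tests
document that component estimates at these sizes are well inside the
tolerances asserted. Reported group statistics use the full default cohort
(13 subjects, 19 cycles, 100 points).

## Known limitations

- The 36-measure schema and solid assignments are a reconstruction, not
  the original instrument; absolute volumes (≈ 65 L total) are plausible
  but not validated against cadaver or scan data.
- No inertia tensors or segment-specific densities; the model supports CoM
  analysis only.
- Inverse kinematics is out of scope: joint angles are inputs.
- The TNC analysis is coordinate-dependent by construction; results are
  specific to the chosen EV set and axes.
- `PV_lab`'s per-axis CV uses magnitudes; axes whose true mean projection
  is near zero have large, noisy CVs (visible in the medio-lateral channel).
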