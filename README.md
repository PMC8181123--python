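# comvar

Stride-to-stride variability analysis of the running center of mass (CoM):
a subject-specific volumetric body model, forward kinematics from joint
angles to the whole-body CoM, coefficient-of-variation tracking across
stance cycles, and a permutation-based decomposition of variability change
into **Tolerance**, **Noise**, and **Covariation** components.

## Who this is for

Biomechanics and motor-control researchers who ask whether runners (or any
cyclic movers) keep a task-level variable — here the CoM trajectory —
constant from repetition to repetition, and *why* its variability changes
between two conditions (e.g. rested vs. fatigued): because the mean posture
moved to a more/less error-tolerant region of the forward map (T), because
the joint angles scatter more (N), or because compensatory coupling among
the joints changed (C).

## The model

**Body model.** Seventeen geometric solids (ellipsoid head, cylindrical
neck, elliptical-cylinder trunk segments, conical-frustum limbs, spherical
hands) in a kinematic tree rooted at the pelvis, sized from a 36-entry
anthropometric profile. Under uniform density the solid volumes *V<sub>i</sub>*
double as mass weights, so the whole-body CoM is

```
r_CoM = ( Σᵢ rᵢ Vᵢ ) / ( Σᵢ Vᵢ )
```

with *r<sub>i</sub>* the segment centroids relative to the pelvis. The model
carries 50 generalized coordinates: 3 rotations orienting the pelvis in the
lab frame plus 47 joint angles (fifteen 3-DOF joints, one 2-DOF neck).

**Performance variables.** Two views of the CoM are tracked over the
time-normalized stance phase (100 points; absorption = points 1–50,
propulsion = 51–100):

- `PV_lab` — the pelvis-anchored CoM in lab-oriented axes
  (x anterior-posterior, y medio-lateral, z vertical): `r_PV_lab = r_CoM`;
- `PV_foot` — the CoM relative to the right foot (malleolus midpoint):
  `r_PV_foot = r_CoM + r_Pelvis − r_RFoot`.

Variability is the coefficient of variation (CV = 100 · SD / mean) of the
vector length across cycles, per normalized time point, in 3D and per axis.

**T/N/C decomposition.** For two states, five datasets are compared: the
measured execution variables D1 (state 1) and D5 (state 2); D2 and D4,
column-wise permutations of D1 and D5 that destroy all covariation while
preserving marginals exactly; and D3, D2 relocated to D5's mean position.
With V(·) the CV of the PV evaluated through the forward model (mean over
1,000 permutations by default):

```
T = V(D3) − V(D2)      N = V(D4) − V(D3)
C = [V(D2) − V(D1)] + [V(D5) − V(D4)]
T + N + C = V(D5) − V(D1)   (exactly)
```

Group inference mirrors the repeated-measures design: dependent t-tests on
lengths and CVs, one-sample t-tests against zero on T/N/C, Cohen's
d = |t|/√n with small < 0.5 ≤ medium ≤ 0.8 < large.

Because the underlying motion-capture data are not publicly deposited, the
package ships a first-class synthetic-cohort generator (13 subjects × 2
states × 19 cycles × 100 points × 50 DOF by default) with controllable
mean-shift, dispersion, and covariation structure, plus heel/toe marker
tracks with ground-truth events for the stance-detection stage.

## Worked example

Generate a cohort whose POST state doubles the stride-to-stride noise, and
decompose the change:

```python
from comvar.synth import SyntheticConfig, generate_cohort
from comvar.pipeline import analyze_arrays

cohort = generate_cohort(SyntheticConfig(manipulation="noise", seed=1))
res = analyze_arrays(cohort.angles, cohort.pelvis, cohort.rfoot, cohort.model,
                     pv_kinds=("lab",), n_perm=200, seed=1)
table = res["lab"].table
print(table[table.channel == "3D"].round(3).to_string(index=False))
```

```
    pv channel quantity      phase  mean_pre  sd_pre  mean_post  sd_post      t     p     d effect
PV_lab      3D   Length absorption     0.043   0.003      0.043    0.003 -0.870 0.402 0.241  small
PV_lab      3D   Length propulsion     0.045   0.004      0.045    0.004 -0.937 0.367 0.260  small
PV_lab      3D       CV absorption     4.127   0.552      7.958    0.914 12.754 0.000 3.537  large
PV_lab      3D       CV propulsion     3.906   0.617      7.669    0.705 13.453 0.000 3.731  large
PV_lab      3D        T absorption     0.030   0.071        NaN      NaN  1.525 0.153 0.423  small
PV_lab      3D        T propulsion     0.031   0.068        NaN      NaN  1.650 0.125 0.458  small
PV_lab      3D        N absorption     4.368   0.644        NaN      NaN 24.472 0.000 6.787  large
PV_lab      3D        N propulsion     4.016   0.858        NaN      NaN 16.884 0.000 4.683  large
PV_lab      3D        C absorption    -0.567   1.169        NaN      NaN -1.748 0.106 0.485  small
PV_lab      3D        C propulsion    -0.284   0.838        NaN      NaN -1.221 0.246 0.339  small
```

Reading the output: the mean CoM offset (Length, ~0.043 m from the pelvis)
is unchanged between states, but the stride-to-stride CV roughly doubles
(4.1 % → 8.0 % in absorption), and the decomposition attributes that
increase to the Noise component (N ≈ +4.4 percentage points, p < 0.001,
d = 6.8) while Tolerance and Covariation stay near zero — exactly the
structure that was injected.

The same pipeline is available from the shell:

```bash
comvar simulate --seed 4 --out sim/                   # delimited cohort files
comvar events --markers sim/markers.csv --out events.csv
comvar analyze --simulate --pv both --n-perm 1000 --seed 4 --out run/
comvar report --per-subject run/per_subject_pv_lab.csv --out table.csv
```

`analyze` writes per-subject phase means, group mean±SD time courses of
length and CV, rounded and full-precision group tables, and a manifest with
seeds, permutation counts, and input hashes.

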