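# Methods

`stenosim` is a desk-scale simulator of left-ventricular (LV) mechanics
coupled to a closed-loop circulation, built to study how graded aortic
stenosis (AS) raises LV myofiber stress. This note documents the model,
its assumptions, the calibration procedure, the numerical choices, and —
importantly — what the reduced-order construction can and cannot
reproduce of a full 3-D finite-element (FE) heart.

## Chamber model

### Geometry and fibre field

The unloaded, zero-stress LV is a truncated thick-walled prolate
ellipsoid. Defaults: endocardial semi-axes 24 mm (short) x 60 mm
(long), lateral wall 13 mm, apical wall 10 mm, basal truncation plane
18 mm above the equator. This gives an unloaded cavity of ~104 ml and a
wall volume of ~172 ml (LV mass ~180 g). The wall is thicker than an
average heart on purpose: with the unloaded sarcomere lengths
(1.78 um endocardium to 1.91 um epicardium, linear in depth) and a
zero-active-tension length l0 = 1.58 um, a thinner wall would leave too
little muscle above l0 at end-systolic volumes near 55 ml under the
volume-only kinematics described below, and an ejection fraction of 60%
would be unreachable.

Fibres follow the rule-based helix field, +60 deg at the endocardium to
-60 deg at the epicardium, measured from the circumferential direction;
the sheet axis is taken in-surface (the wall normal completes the
right-handed frame). Each material point carries a reference position,
transmural depth, volume weight (layer volumes are analytic, so the
weights sum to the exact wall volume), fibre frame, unloaded sarcomere
length, and an AHA-17 segment label (basal/mid/apical thirds by
long-axis height with 6/6/4 sectors plus apical cap).

### Kinematics

Deformation is axisymmetric and exactly incompressible: every
transmural shell conserves its wall volume, the in-surface stretch is
isotropic,

    lambda(d) = [ (V + Vw(d)) / (V0 + Vw(d)) ]^(1/3),

with Vw(d) the cumulative wall volume inside depth d, and the
transmural stretch is lambda^-2, so det F = 1 at every point. Fibres
lie in-surface, so the fibre stretch equals lambda and the fibre Green
strain is Eff = (lambda^2 - 1)/2. There is no torsion, no long-axis
motion and no residual stress. Consequences worth stating up front:

- the chamber is **stiffer than a 3-D FE model** of the same material,
  because the constrained family excludes the softer deformation modes
  (long-axis lengthening, torsion, shear);
- fibre shortening at the endocardium is **exaggerated** at low volume
  (all shortening must come out of the in-surface stretch), so
  length-dependent deactivation of the inner wall at end-systole is
  stronger than in a 3-D model;
- reported fibre strains are smaller in magnitude at peak systole
  (about -4 to -8% here vs. -22% for the FE heart) because peak LV
  pressure occurs earlier in ejection, at larger volume.

### Material laws

Passive stress is the Holzapfel–Ogden law (a = 3.354 kPa, b = 7.08,
a_f = 2.501 kPa, b_f = 5.34, other anisotropic terms zero) with
tension-only fibre/sheet terms and volumetric penalty
Psi_vol = (1/D)((J^2-1)/2 - ln J), D = 2/K, K = 1000 kPa, so K is the
exact bulk modulus at J = 1. The analytic Cauchy stress (exact
isochoric projection) is verified against a central finite-difference
of the total energy to better than 1e-4 relative error on random
deformations.

Active tension is the time-varying elastance law

    sigma_af = Tmax/2 * Ca0^2/(Ca0^2 + ECa50(l)^2) * (1 - cos w(t, l)),

with ECa50 = Ca0max / sqrt(exp(B(l - l0)) - 1), l = lr sqrt(2 Eff + 1),
a linear rise of the phase to pi at t0 and a half-cosine relaxation of
duration tr(l) = m l + b. Constants: Tmax = 135.7 kPa,
Ca0 = Ca0max = 4.35 umol/l, B = 4.75 um^-1, l0 = 1.58 um,
m = 1.0489 s/um, b = -1.429 s. For l <= l0 the tension is clamped to
zero (the continuous limit of ECa50 -> infinity). t0 (time to peak
tension) is not a printed constant and is calibrated (default 0.15 s,
calibrated value ~0.36 s in a 0.7 s cycle). A fraction n = 0.4 of the
fibre tension also acts along the sheet direction.

**Relaxation latch.** The phase w is defined with the instantaneous
sarcomere length. During refilling l grows, tr(l) grows, and the
relaxation phase would rewind below 2*pi and re-develop several kPa of
tension in mid-diastole — an artifact that in early testing blocked
filling entirely. The coupled chamber therefore latches a layer's
tension to zero for the remainder of the cycle once its relaxation
window closes (t > t0 + tr(l)), and latches the whole wall as soon as
refilling begins after peak tension. The material-law functions
themselves are unmodified.

### Wall force balance and reported stress

Cavity pressure follows from radial equilibrium of the shell stack (the
layer-wise generalization of the one-fibre relation
P = (sigma/3) ln(1 + Vw/V)):

    P = sum_i g_i/3 * ln((V + v_{i+1})/(V + v_i)),
    g  = 3 (sigma_p,ff + sigma_p,ss) + (1 + n) sigma_af,

where v_i are cumulative wall volumes at the shell boundaries and g is
the in-plane generating stress (passive in-plane components enter with
the factor 3 because the traceless passive tensor contributes
(sigma_tt + sigma_pp - 2 sigma_rr) to the equilibrium integrand). The
same integration gives the transmural radial-stress profile, sigma_rr
from -P at the endocardium to 0 at the epicardium. The **reported
myofiber stress** is the fibre-direction Cauchy component including
that equilibrium hydrostatic part:

    sigma_ff = sigma_p,ff + sigma_af + (sigma_rr - sigma_p,nn).

At peak systole this produces the qualitative transmural pattern of the
FE reference: strongly loaded mid/epicardial wall and low-to-negative
endocardial values (short, deactivated sarcomeres plus sigma_rr ~ -P).

End-diastolic stress is reported at the end-diastolic volume in the
zero-tension state: physiological end-diastole precedes contraction
onset, whereas in the lumped timing convention activation starts
exactly at the cycle origin, a few milliseconds before the mitral
valve finishes closing.

### Passive stiffness anchor

Because the constrained kinematics is systematically stiffer than the
3-D reference, a single **diastolic-anchor scale** multiplies the four
stress-like passive moduli: it is fixed (per geometry) so that the
passively loaded chamber sits at the target end-diastolic volume
(137 ml) at the ~4 mmHg diastolic LV pressure of the initialization
targets, and is then polished within [0.75, 1.3]x by the calibration.
The anchored value is ~0.46; the law's constants themselves are never
changed. Without this scale the unloaded-to-137-ml pressure is
7.4 mmHg, end-diastolic fibre stress is ~1.9 kPa (vs. the sub-kPa
reference level), and EF 60% is unreachable at any contractility.

## Circulation

A closed loop of diode-resistor valves, linear compliances (systemic
arterial, venous, pulmonary) and time-varying elastance stand-ins for
the left/right atria and right ventricle, at a cycle length of 0.7 s:

    LA -R_mitral-> LV -R_aorta-> ART -R_system-> VEN -R_venous->
    RA -R_tricuspid-> RV -R_pulmonary-> PUL -R_pulmonary_system-> LA

The three aortic valve resistances are taken verbatim from the study
conditions: 1.0e-9 (baseline), 5.0e-9 (moderate AS), 1.0e-8 (severe AS)
MPa.s/mm^3. The remaining printed circuit constants are dimensionally
inconsistent with physiologic flows (e.g. a systemic resistance of
1.4e+02 MPa.s/mm^3 would imply ~1e5 mmHg gradients at a normal cardiac
output) and are treated as exponent typos: physiologic defaults are
used instead and the key ones are calibrated. Right-heart and atrial
parameters are chosen so the initialization targets approximate the
limit cycle, which is what makes the three-cycle steady-state protocol
satisfiable.

Initialization ramps every compartment pressure linearly from zero to
the physiologic targets (RA 2, RV 2, PA 8, LA 4, LV 4, aorta/arterial
80, venous 2 mmHg), reaching them at 70% of the diastolic duration
(cycle length minus the minimum mechanical systole t0 + tr(l0)); a
calibrated blood-volume offset is then added to the venous pool.

### Time integration

Fixed-step (default dt = 0.5 ms), deterministic. Flows between linear
compartments use the unconditionally stable semi-implicit form
Q = dP / (R + dt (1/C_up + 1/C_down)); every flow is applied
antisymmetrically, so total blood volume is conserved to round-off
(<1e-9 relative per cycle, vs. the 1e-6 requirement). The two LV valve
flows are refined each step by a scalar Newton solve on the end-of-step
pressures, so that dP = R Q holds across an open valve essentially
exactly (asserted at 1e-6 relative in the tests). Valve opening is
decided implicitly with a small reverse-bias margin (0.75 mmHg) because
compartment pressures move within a step; the only observable artifact
is a single-step opening lag. Halving dt changes the cycle-3 aortic
systolic pressure by <0.5%.

The inner chamber evaluation (per-layer stretch, passive components,
active tension, log-weighted sum) is JIT-compiled with numba; a pure
numpy path implements the identical formulas and the two are asserted
to agree to ~1e-14 relative. Per-point fields are only materialized at
the reporting frames; the solver works on the transmural layers (the
kinematics is depth-only).

## Calibration and scenario protocol

Baseline calibration is a deterministic Nelder–Mead search (two stages,
the second restarted from the best point with a shrunken simplex) over
{log R_system, venous blood-volume offset, t0, Tmax scale,
log C_arterial, passive-scale polish, log R_mitral}, minimizing the
squared mismatch of EF (target 60%), EDV (137 ml), aortic systolic
(113 mmHg) and diastolic (56.5 mmHg) pressures — each in its natural
unit — plus three penalties that are themselves stated properties of
the baseline study condition:

- mean systolic LV–aorta gradient below 2 mmHg at the normal valve
  resistance (excludes a degenerate optimum with a 30 ms explosive
  ejection that matches the pressure targets while producing a large
  gradient);
- cycle-2-to-3 peak-pressure steadiness below ~3% (excludes optima
  that exploit the post-initialization transient; the reported cycle 3
  must represent the limit cycle);
- end-diastolic pressure near the 4 mmHg anchor (keeps end-diastolic
  myofiber stress at the sub-kPa reference level).

Calibration runs at dt = 1 ms (~500 coupled simulations, a few
minutes); scenarios are run at dt = 0.5 ms. The Tmax scale absorbs the
reduced-order kinematics' exaggerated end-systolic deactivation; its
calibrated value is ~1.6-1.8 (i.e. an effective Tmax of ~220-240 kPa).

Stenosis scenarios reuse every calibrated parameter and change only
R_aorta. Because the study holds EF at 60% in all three conditions, a
bounded contractility adjustment ([0.7, 2]x the calibrated Tmax scale,
bisection on EF) is applied to a stenosis scenario whose EF departs
from 60% by more than half a point; with the calibrated model the
departure is small and the adjustment is mild or inactive. Analysis
uses the third cycle; a fourth cycle verifies steadiness (<5% change in
any compartment's peak pressure; measured ~2-3%).

## What the model reproduces, and what it cannot

With one calibration (no per-quantity tuning), the simulator
reproduces: the control hemodynamics (EF ~59-60%, EDV ~137 ml, aorta
~113/56 mmHg), a non-stenotic baseline gradient (<2 mmHg), sub-kPa
end-diastolic myofiber stress (~0.8 kPa), three-cycle steady state,
strictly increasing peak-systolic myofiber stress with AS severity,
and stress-elevation ratios close to the reference (moderate/baseline
~1.25, severe/baseline ~1.55 vs. 1.4 and 1.7).

Two quantities are out of reach of this construction, for reasons that
are themselves informative:

1. **Stenotic mean gradients.** With a purely resistive diode valve,
   the mean systolic gradient is exactly R_aorta x SV / T_w, with T_w
   the LV-above-aorta (ejection) window. At constant stroke volume the
   reference triple (<2, 20, 40 mmHg at R = 1, 5, 10 x 1e-9) requires
   T_w ~0.31 s at baseline but ~0.155 s under stenosis: the window
   would have to halve while the activation waveform is unchanged.
   Resistive valve dynamics cannot do this (the simulated windows are
   0.29-0.31 s in all three conditions), so the model yields ~10 and
   ~20 mmHg for the moderate and severe settings. A valve inertance —
   flow persisting after the LV pressure falls below the aorta —
   would shorten the LV>Ao window and reconcile the triple, but the
   valve here is deliberately purely resistive.

2. **Absolute peak-systolic stress level.** Radial equilibrium of a
   thick shell forces the volume-averaged in-plane stress to be at
   least ~(3 P V / Vw - <sigma_rr>)/2 at the peak-pressure volume;
   with P ~ 15-20 kPa at V ~ 85-120 ml this floor is 15-25 kPa. The
   simulator's global means (~25/31/39 kPa) sit at that floor, above
   the reference FE values (9.31/13.13/16.18 kPa), whose lower level
   reflects full 3-D fibre architecture and a peak-systolic state near
   end-systolic volume. The *relative* elevation with AS severity is
   reproduced; the absolute level is a property of the idealized
   geometry.

Regional (AHA-17) statistics are reported but nearly flat across
sectors: an axisymmetric chamber has no circumferential heterogeneity,
so regional variation comes only from each segment's transmural and
longitudinal sampling. The segment table is a schema-faithful twin of
the reference figure, not a prediction of regional differences.

## Degenerate inputs and tie-breaks

- Non-positive det F, non-positive cavity volume, non-orthonormal
  fibre frames, degenerate geometry (non-positive thickness, base
  plane outside the ellipsoid) and non-positive resistances raise
  typed errors.
- Peak systole is the global argmax of LV pressure; end-diastole is
  the argmax of LV volume before peak systole (first index on ties).
- An empty AHA segment (impossible at default resolution, guarded at
  build time) is excluded from regional tables with a warning.
- If LV pressure never exceeds aortic pressure the gradient is 0 with
  a warning.
- Calibration failure to meet tolerance returns the best-found set
  with diagnostics and a warning, never an exception.

## Reproducibility

All randomness is confined to the azimuthal jitter of the point lattice
in the geometry generator (seeded); the layer-based solver is
deterministic and independent of that jitter, so hemodynamics and
global stresses are identical across seeds, and per-point regional
tables vary only through point placement. Same seed + same
configuration reproduces every output bit-for-bit.
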