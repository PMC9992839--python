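# Methods

## The half-sarcomere equivalent circuit

All mechanics are expressed per functional unit: forces in pN per
half-thick-filament (htf), lengths in nm per half-sarcomere (hs,
lengthening positive), sarcomere length (SL) in µm. One nm of hs length
change moves SL by 2×10⁻³ µm (both halves lengthen). The lattice-geometry
conversion between fiber stress and force per htf uses 5.87×10¹⁴ thick
filaments m⁻², so 144 kPa ↔ 245.3 pN.

### OFF state (rest)

The response to a force change ΔF(t) about a pre-equilibrated baseline is

    x(t) = ΔF(t)/e_pevk + x_Ig(t),
    dx_Ig/dt = ΔF(t) · f(SL(t)),     SL(t) = SL0 + 2e-3 · x(t),

where the tandem-Ig fluidity f(SL) = f_max·(SL_c − SL)/(SL_c − SL_ref) is
linear in SL, clipped at zero for SL ≥ SL_c. Interpretation: each of the
m−1 bent inter-Ig elements contributes 1/η_s of fluidity; k of them are
already straight at a given SL, and k grows linearly from 0 (at SL_ref) to
m−1 (at SL_c), where the segment is at contour length. The
`straightened_fraction` k/(m−1) and the normalized fluidity sum to 1
identically.

Because f is affine in x, the ODE is linear for constant load and the
integrator uses per-sample exact exponential updates (closed form once the
force ramp has completed). The clip at SL_c is enforced during
integration: when the elastic term alone carries SL to or beyond SL_c the
dashpot does not flow backwards, so at SL0 = SL_c the model degenerates
exactly to the pure PEVK spring. Loads that drive SL below SL_ref (large
shortening steps at rest) leave the model's domain and raise a domain
error rather than extrapolating the fluidity law.

Two consequences of this self-consistent SL coupling are worth noting
because they differ from back-of-envelope expectations:

* the *initial* post-step velocity is ΔT·f evaluated at the elastically
  shifted SL (the PEVK extension moves SL by 2e-3·ΔT/e_pevk before the
  Ig creep starts), not ΔT·f(SL0); at 50 pN and 2.7 µm this is ≈4.0×10⁴
  rather than 5×10⁴ nm/s;
* the creep saturates at the contour limit (SL_c − SL0)/2e-3 nm of total
  extension, elastic term included.

### ON state (stimulation under motor inhibition)

    x(t) = ΔF/e1 + x_kv(t) + x_d(t),
    dx_kv/dt = (ΔF − e_b·x_kv)/η_b,   e_b = e1·e2/(e1−e2),  η_b = e_b·τ₂,
    dx_d/dt  = ΔF/η_L(sign ΔT),       η_L = η₃ (ΔT>0) or η_sh (ΔT<0),

so an idealized positive step shows the elastic jump ΔT/e1 (phase 1), an
exponential approach with time constant τ₂ to the back-extrapolated
amplitude ΔT/e2 (phase 2), and a steady creep ΔT/η₃ (phase 3). The
rectifier branch is chosen by the sign of the net step; at ΔT = 0 the
choice is inert (no flow) and the lengthening branch is returned. The ON
path has no SL dependence by construction. The Voigt element is advanced
with an exponential update that is exact for piecewise-linear forcing
(verified against both the analytic ramp solution and a tight-tolerance
LSODA integration); dt ≤ τ₂/10 is enforced so the sampled trace resolves
phase 2. When a stimulation window ends before the record does, the
parameters switch instantaneously to the OFF set with the trajectory kept
continuous.

### Parameters

| symbol | default | units | meaning |
|---|---|---|---|
| e1 | 6.90–7.35 per SL | pN/nm | instantaneous hs stiffness |
| e2 | 2.69–3.51 per SL | pN/nm | ON equilibrium stiffness |
| τ₂ | 0.5 ms | s | phase-2 relaxation; chosen so 4τ₂ ≈ the ~2 ms completion of phase 2; configurable |
| η₃ | 3.94–6.85 per SL | pN s/nm | lengthening viscosity |
| η_sh | 1.60×10⁻³ | pN s/nm | shortening viscosity (measured at 3.0 µm; carried at all SLs) |
| f_max | 2111 | nm s⁻¹ pN⁻¹ | OFF fluidity at SL_ref, calibrated so f(2.7 µm) = 10³ |
| SL_ref / SL_c | 2.2 / 3.15 | µm | slack length / contour length |
| e_pevk | 1/0.65 ≈ 1.54 | pN/nm | PEVK stiffness |
| e_M, e_A | ∞ | pN/nm | filament stiffnesses; rigid by default, their compliance is lumped into e1 |

Force-step protocol: linear ramp over `rise_time` (default 150 µs — a
plausible servo rise; not a measured value), with the step half-time at
the ramp midpoint, the reference time for all back-extrapolated
amplitudes.

## Estimators

* `Vi`: least-squares slope over the first 0.5 ms after the ramp end.
* `L1`: line over the first 0.1 ms after the ramp end, evaluated at the
  half-time. The window must be ≪ τ₂: with a 0.2 ms window the phase-2
  contamination biases e1 by ≈1.8%, with 0.1 ms by ≈0.5%. Configurable.
* `L2`, `V3`: line over 100–200 ms (ON) or 150–250 ms (OFF) after the
  step, evaluated at the half-time / its slope. A warning is raised if the
  window starts within 2 ms of the step (phase 2 incomplete).
* `Vsh`: slope over 1–5 ms after the step end (skipping elastic recoil);
  defined for non-positive steps only.
* Relations are ordinary least squares (statsmodels), pooled or as the
  average of per-fiber fits; the abscissa intercept of the fluidity–SL
  line carries a delta-method standard error.
* Group comparison: Welch two-tailed t-test, significance at p < 0.02.

Numerical choice for idealized (noiseless) recovery runs: the ramp spans
exactly one sample (`rise_time = dt`), so the sampled forcing is exactly
the piecewise-linear ramp the integrator assumes and the discrete
half-time is consistent; a literal zero-width ramp on a discrete grid
shifts the effective step by dt/2 and biases back-extrapolated amplitudes.

Recovery accuracy on noiseless simulations (Table-1 parameter sets, steps
25–100 pN): e2 and η₃ exact to <10⁻⁴, e1 to ≈0.5% (residual phase-2
contamination of the L1 window), η_sh to ≈0.5% (residual phase-2 decay in
the Vsh window). The fluidity–SL intercept is recovered to <10⁻³ µm when
probed with symmetric ±{5,10,20} pN steps: the two quadratic estimator
nonlinearities (the elastic SL shift and the finite-window decay, both
even in ΔT) then cancel out of the fitted slope. Large positive-only
steps leave a real −0.03..−0.05 µm bias in the intercept; this is a
property of the measurement design, reported here rather than hidden.

## Passive curve

`passive_force` is the exponential form A·(exp(r·(SL − SL_slack)) − 1),
zero at and below the slack length (default 2.2 µm). The defaults
calibrate A through the 24.9 pN restoring force at 3.0 µm with r = 18
µm⁻¹, chosen once so that the curve is negligible below ~2.6 µm while its
local stiffness at 3.0 µm (≈0.9 pN/nm per hs) is consistent (within the
deliberately loose factor 2) with the PEVK stiffness that dominates the
resting response there. An inverse-Langevin freely-jointed-chain variant
is exposed behind the same interface and is labelled approximate: it is a
qualitative stand-in, not a fitted entropic-chain model.

## Thick-filament diffraction model

Each half-filament array has 49 equal point-mass crowns, the first at HBZ
(half-bare-zone, default 80 nm — a literature-scale value, configurable;
analyses other than fringe spacing are insensitive to it) and successive
spacings d = 14.3 nm. The second array is the mirror image through the
M-line. Intensity is the coherent modulus-squared sum over both arrays;
for ≤6 crowns it is verified against a direct double sum, and the
resolution guard requires the S grid to sample finer than 1/(4×span).
The interference distance (center-to-center distance of the arrays) is
2·HBZ + 48·d = 846.4 nm for the uniform default.

* **Partial extension**: with onset layer n, spacings up to crown n stay
  at d and the rest take d_ext; the bare zone is fixed. Uniform extension
  (`scaled`) multiplies HBZ and all spacings by a common factor — then the
  whole profile rescales in S, so features analyzed in correspondingly
  scaled windows are exactly invariant (subpeak fractions) or exactly
  scaled (spacings).
* **M3/M6 analysis**: spacing = 1/(intensity-weighted centroid of S) in
  the window (centroid chosen for robustness; the window defaults are
  ±5% around 1/14.35 and its second order). Subpeaks are partitioned at
  the local minimum between the two largest maxima, each integrated
  between its flanking minima, and reported as fractions of the window
  total.
* **Forbidden (M1) intensity**: the triplet perturbation displaces crowns
  12–30 by the pattern (+δ, 0, −δ) repeating every three crowns. The
  forbidden amplitude is isolated as the *difference* between the
  perturbed and unperturbed structure factors, integrated as
  |ΔF(S)|² over the M1 window. For an infinite lattice this equals the
  conventional forbidden-order amplitude; for the finite 49-crown lattice
  it removes the Dirichlet-tail background (~4×10⁻⁴ of the M3 peak) that
  would otherwise contaminate the window and break the δ² law. The result
  is exactly zero at δ = 0 and quadratic in δ (log–log slope 2.01 over
  δ ∈ [0.05, 0.2] nm), so the observed halving of M1 corresponds to δ
  falling by 1/√2.
* **Onset scan**: for each candidate onset, d_ext is matched to each
  observed S_M3 by root-finding (with a cached coarse table for the
  initial bracket) and the squared *relative* residuals of (L_M3, H_M3)
  are summed. Relative residuals are used because the feature errors are
  relative (the generator's noise model, and SEM bars that scale with the
  signal); they weight the small high-angle fraction on an equal footing,
  which is what makes adjacent onset layers distinguishable at 2% noise.
* **Azimuthal order parameter**: a deliberate reduction, not a 2-D
  lattice computation. φ ∈ [0,1] is the motor mass fraction reoriented
  from the ninefold screw disposition toward the sixfold (1,1-plane)
  disposition at fixed radius, so I_1,0 is invariant, I_ML1 = (1−φ)², and
  I_1,1 = 1 + g·φ with g calibrated so the φ that gives the 40% layer-line
  drop (φ = 1−√0.6) yields the 80% equatorial rise. φ(t) rises
  exponentially with τ = 20 ms; halving the step halves φ∞ only.

## Synthetic data

The generator emulates the study design: SLs 2.5/2.7/3.0 µm, steps up to
±50 pN (±0.2 of the 245 pN reference force), Gaussian trace noise of 0.5
nm SD and force noise of 0.5 pN, lognormal fiber-to-fiber parameter
jitter with 5% CV, and — for the diffraction branch — eight (S_M3, L_M3,
H_M3) triplets per replicate (one pre-step, two at the half-amplitude
spacing 14.35 nm, five at 14.40 nm, mimicking the time-resolved
two-amplitude protocol) with 2% relative noise on fractions and 0.005 nm
on spacing. Randomness is split per fiber with `SeedSequence.spawn`, so
identical configurations are bit-identical and adding fibers does not
perturb earlier draws.

What the generator does **not** emulate: correlated (1/f or drift) noise
of real recordings, sarcomere-population inhomogeneity within a fiber,
motor-dependent responses (the study inhibits the motors
pharmacologically), detector statistics or instrumental broadening of the
diffraction profiles, and any Ca²⁺ dependence. Passing tests therefore
demonstrate the internal consistency and identifiability of the analysis
chain under the stated statistical model, not its robustness to every
artifact of real data. The experimentally calibrated magnitudes (the
+70%/−40% subpeak changes, the +80% I_1,1 rise, the measured passive
force–SL points) are covered by directional and property checks, not by
numeric reproduction.

## Problem sizes and determinism

Default simulations use dt = 10 µs and 0.25 s records (25,000 samples);
noiseless recoveries use 4 steps per relation; Monte-Carlo checks use
100–200 seeded replicates; the onset-scan identifiability check uses 100
replicates of 8 observations over onset layers 1–10. The acceptance
script's quantities are all noiseless deterministic recoveries and are
seed-stable by construction.

## Known limitations

* τ₂ and the servo rise time are not measured quantities; defaults are
  stated above and configurable.
* η_sh exists in the data only at 3.0 µm; other SLs inherit it.
* The triplet-perturbation parameterization (displacement pattern and
  zone boundaries) is a documented convention; absolute forbidden
  intensities are therefore arbitrary-scale and only ratios are
  meaningful.
* The subpeak fractions depend on HBZ and window conventions; the
  package reproduces their directions and invariances, not the
  experimental magnitudes.
* The equatorial model is a constraint-encoding reduction; it has no
  predictive content beyond the constraints it encodes.
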