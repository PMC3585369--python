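# Methods

This note documents the scientific and numerical choices behind `tacsim`:
what is modeled, which parameters matter, what the synthetic setup does
and does not emulate, and where the design was genuinely open.

## Volume conductor

Head tissues are purely resistive at stimulation frequencies
(quasi-static approximation), so the potential obeys ∇·(σ∇φ) = 0 with
continuity of φ and of the normal current density σ∂φ/∂r across tissue
boundaries and an insulating outer surface away from the injection
sites.  On concentric spherical shells the solution for a surface point
current source separates into Legendre harmonics; for order *n* the
radial factor a·x^n + b·x^−(n+1) (x = r/R) propagates across shells via
a 2×2 interface matrix, and the insulating boundary with the source's
surface-harmonic expansion fixes the scale:
σ_N (n·a_N − (n+1)·b_N) = (2n+1)/(4πR) per unit current.  Stimulation
pads (7×5 cm, 1.12 mA, centred on PO9/PO10) are discretized as 7×5
grids of point sources with uniform current density; fields superpose
linearly.  E = −∇φ is evaluated by analytic differentiation of the
series; the angular part is written against (cos γ·r̂ − ŝ), which removes
the 1/sin γ singularity on the source axis.

Default shells (m, S/m): brain 0.079/0.33, CSF 0.082/1.79, skull
0.087/0.008, scalp 0.092/0.33 — standard four-shell proportions.  The
EEG forward model uses the conventional three-layer head (brain, skull,
scalp at 0.33/0.008/0.33 S/m, radii 0.082/0.087/0.092 m) without the CSF
layer.  The cortical mesh sits at 0.077 m with ≤1.5 mm radial
perturbation, so all barycenters remain in the brain compartment and
strictly inside the innermost EEG shell.

Series truncation: 120 terms for the pad field.  For the dipole
leadfield, dipoles at 0.85 R converge slowly; `leadfield_3shell` uses
150 terms (the generic `dipole_potential_multishell` default of 60
terms triggers its tail-ratio warning in that configuration by design).
Both solvers are validated against closed forms (homogeneous-sphere
series, central-dipole formula) at machine precision and against an
independent axisymmetric finite-volume Laplace solver to <1 % (surface
sources) and <2 % (interior dipoles), including the resistive-skull
case on a shell-aligned grid.

## Geometry surrogate

The cortical surface is a recursively subdivided icosahedron
(subdivision 4, 5120 triangles by default) with a smooth seeded radial
perturbation (sum of 12 Gaussian bumps) so triangle normals are not all
radial.  Triangles are grouped into 66 spatially contiguous regions by
seeded spherical k-means on barycenter directions with mirror symmetry
across the mid-sagittal plane (33 regions per hemisphere) and a
contiguity repair pass.  Electrode positions follow the idealized
spherical 10-20/10-10 construction (nasion, inion and preauricular
points on the equator; the outer ring at 72° inclination; intermediate
electrodes as great-circle midpoints).  Note that planar-triangle
normals pass through the circumcenter rather than the barycenter, so on
an unperturbed icosphere the normal/barycenter-direction agreement is
limited by triangle size (≈5·10⁻⁵ at subdivision 3), not by round-off.

This surrogate reproduces the topology and scale of a cortical source
space but none of the folding, so absolute field magnitudes, regional
field patterns and EEG topographies differ from a realistic head.  All
quantitative endpoints are therefore relative (percent changes,
argmax frequencies, significance sets), which are robust to the
geometry and to the EEG reference (average reference by default).

## Neural mass model

Subpopulations P (pyramidal), I (fast somatic inhibition), I′ (slow
dendritic inhibition) interact through connectivity constants C_XY
(X→Y): C_PP=55, C_PI=80, C_PI′=90, C_IP=20, C_II=15, C_I′P=25,
C_I′I=20, C_I′I′=40.  Firing rates follow the Wilson–Cowan sigmoid
S(v) = 2e₀/(1+e^{r(v₀−v)}) with e₀=10 s⁻¹, r=0.7 mV⁻¹, v₀=1 mV for P
and 4 mV for both interneuron types.  Each synapse type has a
bi-exponential PSP kernel with rise/decay constants (a₁,a₂)=(40,80),
(g₁,g₂)=(150,200), (b₁,b₂)=(20,60) s⁻¹ and gains A=5.5, G=10, B=8 mV.

**Kernel normalization.**  The kernel prefactor is not determined by
the constants above, and it controls the relative strength of the fast
and slow inhibitory loops.  `tacsim` uses a "scaled-DC" convention:
h(t) = gain·w₁w₂/(w_ref(w₂−w₁))·(e^{−w₁t} − e^{−w₂t}), i.e.
unit-integral kernels with gains read per a common reference rate
w_ref = 400 s⁻¹.  Two alternatives are selectable (`unit_dc`, `biexp`)
but fail to produce alpha-band dynamics with this constant set: the
bare bi-exponential starves the fast loop (a ~5 Hz relaxation cycle
results) and the unit-integral form drives membrane potentials to
unphysiological ±2000 mV.

**Operating point.**  Linear stability analysis of the fixed point
shows that with these constants the model has no limit cycle near
10 Hz under any tested normalization: the slow (P–I′) loop oscillates
at 5–6 Hz and the fast (P–I) loop's Hopf bifurcation sits at 17–20 Hz.
Alpha is instead realized as a *noise-driven damped resonance* of the
mixed mode.  At w_ref = 400 s⁻¹ and mean input 212 s⁻¹ the leading
mode is −10.5 ± 2π·10.3i s⁻¹ and, crucially, the pyramidal operating
point sits at the sigmoid inflection v_P ≈ v₀.  The inflection choice
nulls the quadratic distortion of the stimulated population, which
would otherwise convert 5 or 6 Hz stimulation into second harmonics at
10/12 Hz inside the alpha band; with it, off-band stimulation leaves
8–12 Hz power statistically unchanged, as observed empirically.

**Stochastic input.**  Every population receives an independent
Gaussian input rate per integration step (mean 212 s⁻¹, SD 30 s⁻¹ at
the 1/512 s reference step).  The per-step SD scales as √(dt_ref/dt)
so the continuous-time noise intensity — and hence the dynamics — are
independent of the step size.

**Pacemaker and spindles.**  The 67th population receives a periodic
trapezoid input (period 2.5 s, ramps 0.6 s, plateau 0.5 s, amplitude
250 s⁻¹) and projects to every cortical population with gain 16.  The
projection conveys the pacemaker's rate *fluctuations* about its tonic
rate (computed once, deterministically, from a noise-free warm-up):
physiologically this mimics adaptation in the thalamocortical
projection, and operationally it keeps the cortical operating point —
and therefore the alpha frequency — independent of the coupling gain,
so a single isolated population and a network population are directly
comparable.  The common input synchronizes the regions (mean |corr|
≈ 0.5 versus ≈ 0.02 uncoupled) and modulates the alpha envelope at the
0.4 Hz drive rate; the across-region mean envelope spectrum shows a
0.4 Hz line 40–100× above background.  In this regime the modulation
acts mainly through the resonance damping, so a strong pacemaker swing
is needed for salient spindles — hence the large drive amplitude.

**Integration.**  The linear second-order filters are advanced with
their exact matrix-exponential propagator under a zero-order hold of
the inputs (dt = 1/512 s, 2 s transient discarded).  Plain forward
Euler is *not* used: its artificial negative damping shifts the
resonance by more than 1 Hz at this step size, while under the
exponential scheme halving dt moves the spectral peak by <0.2 Hz.
Trials are integrated in lock-step batches; each trial owns its own
PCG64 stream, so batched and single runs are bit-identical.  A
divergence guard raises if any membrane potential exceeds 1000 mV.

## Stimulation experiments

The field-to-membrane constant Λ (mV per V/m) is fixed by the model's
own calibration procedure: sweep Λ over a grid (default 0–3 in 0.5
steps; the surrogate's field magnitudes put the answer near 2.3),
measure the mean alpha-power change at POz under 10 Hz tACS across 20
trials, and interpolate to the 14 % target.  Λ values are comparable
only within a fixed geometry — a realistic head would need its own
calibration.

Trials are 30 s epochs (plus transient).  Alpha power is the
rectangular-rule integral of the one-sided periodogram over 8–12 Hz,
endpoints inclusive; the plain periodogram satisfies Parseval's
identity to ~1e-9 relative.  Conditions are compared per electrode with
a two-sided Mann–Whitney U test across trials at α = 0.05, uncorrected.
Baseline and stimulation conditions of a comparison share their
per-trial seed streams (common random numbers): this paired design cuts
the sampling error of the percent-change estimate from ~5 percentage
points to ~1, which the ±4-point calibration check requires.  Different
frequencies of the sweep, the calibration session and the validation
run all use disjoint seed streams derived from the master seed by a
counter scheme (SeedSequence over master, condition CRC, replicate,
trial).

## What passing tests do and do not show

The suite establishes that *this model implementation* reproduces the
in-model phenomena: a ~10 Hz single-population peak, desynchronized
uncoupled regions versus pacemaker-synchronized ones, 2.5 s spindle
periodicity, a monotone Λ-response, a ≈14 % calibrated alpha-power
elevation at POz under 10 Hz tACS, maximal response at 10 Hz, and
statistical significance confined to 8–12 Hz stimulation.  Because the
head is spherical, the parcellation arbitrary and the network devoid of
cortico-cortical connectivity, none of this validates predictions about
a specific subject's anatomy or about absolute effect sizes in vivo.

## Known limitations

- The alpha rhythm is a damped noise-driven resonance, not a limit
  cycle; very long simulations average to a Lorentzian-like alpha peak
  rather than a sharp line.
- Off-band stimulation slightly *suppresses* alpha (detuning of the
  resonance by the rectified drive), a small effect never significant
  at 20 trials but systematic in sign.
- The spherical EEG topography has no realistic posterior dominance of
  alpha; midline electrodes differ from a real montage.
- Anisotropic conductivity, capacitive effects, post-stimulation
  plasticity and field effects on interneurons are out of scope.
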