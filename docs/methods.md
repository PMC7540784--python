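# Methods

## Model

The balancer is a single inverted pendulum pivoting on the wire, with two
rotational degrees of freedom: sagittal tilt `q_ap` about the medio-lateral
x-axis and coronal tilt `q_ml` about the along-wire y-axis.  The equation of
motion, linearized about upright equilibrium, is

    J q̈ = T_g(q) − T_s(q, q̇) − T_int(q_δ, q̇_δ) + w_n

with the wire-referenced inertia tensor `J` obtained from the CoM-referenced
body tensor by the parallel-axis theorem plus the pole contribution
`(1/12) m_p l_p² + h_com² m_p` on the yy (coronal) component only; the pole's
inertia about its own long axis is neglected, and `J` is held constant (the
centimetre-scale pole shifts change it negligibly).  Coriolis/centrifugal
terms are dropped (slow, small-amplitude sway), and large-angle gravity,
pole flexibility and pole rotation are out of scope.

Torques:

* gravity: `G_ap = (m_b+m_p) g h_com q_ap`, `G_ml = m_b g h_com q_ml`
  (the pole's coronal gravity is carried by the control channel, below);
* passive ankle impedance: `T_s = K_a q_ap + B_a q̇_ap` in the sagittal plane
  only — ankle muscles cannot act medio-laterally in tandem stance — with
  `K_a = 495.87 N·m·rad⁻¹` deliberately below the critical value
  `(m_b+m_p) g h_com ≈ 890 N·m·rad⁻¹`, so passive stiffness alone cannot
  stabilize even the sagittal plane;
* `w_n`: zero-mean white Gaussian torque noise, one independent sample per
  axis per integration step, the only driving input.

## Intermittent control

Both controllers act on the state delayed by δ = 0.2 s and are switched by
the same phase-plane rule: the point `(q, q̇)` is *unsafe* iff
`q (q̇ + α q) > 0` with α = 0.4 s⁻¹ — the first and third quadrants plus the
triangular slice between the line `q̇ = −α q` and the q-axis.  Boundary
points count as safe so that ties keep the control off (minimum
intervention).  In the safe regions the saddle's stable manifold carries the
state toward equilibrium at no control cost; control engages only in the
unsafe regions:

* **Sagittal (CoP strategy)**: ankle torque `T_ap = P_ap q + D_ap q̇`
  evaluated continuously on the delayed state during the on-phase
  (P_ap = 578.52 N·m·rad⁻¹, D_ap = 20 N·m·s·rad⁻¹).
* **Coronal (CoM strategy)**: commanded pole shift `γ = −(P_ml q + D_ml q̇)`
  (P_ml = 9 m·rad⁻¹, D_ml = 8 m·s·rad⁻¹) during the on-phase, γ = 0
  otherwise.  The discontinuous command is smoothed by a second-order
  low-pass filter `F(s) = 1/((s/ω)² + 2ξ(s/ω) + 1)` with cut-off 2 Hz
  (ω = 2π·2 rad/s) and ξ = 0.7, emulating the arm motor system; the filter
  output is the physical shift Δx_p.  The resulting torque is the static
  gravity effect of the displaced pole CoM,
  `T_ml = −m_p g (h_com q_ml + Δx_p)`: the pole CoM sits at lateral offset
  `h_com q_ml + Δx_p` from the wire, so the pole's whole weight acts through
  this channel.  A configuration switch (`coms_include_tilt_term=False`)
  selects the pure-shift variant `T_ml = −m_p g Δx_p`; the tilt lever is
  roughly a tenth of the shift at the default operating point.  Dynamic
  (reaction/counter-rotation) effects of the pole gesture are intentionally
  ignored.

No hysteresis is added beyond the delay itself: on/off is re-evaluated every
step on the delayed state, which reproduces the delayed on/off transition
timing of the intermittent-control literature.

## Numerics

* Forward Euler at dt = 1 ms; velocities updated with the current
  acceleration, positions with the pre-update velocity.  The integration
  error is first order: against the exact matrix-exponential solution of
  the noise-free off-phase dynamics the angle error stays below 1e-4 rad
  over 0.3 s; over 0.5 s of pure gravitational divergence the relative
  error is ≈ 0.2 % (t·dt/2τ²).
* Delay buffer: exactly round(δ/dt) = 200 samples; until it fills, the
  delayed state is the initial state, so controllers start off.
* Smoothing filter: exact zero-order-hold (matrix-exponential)
  discretization of the two-state companion form — unconditionally stable,
  DC gain exactly 1, and indistinguishable from a 1 ms Euler filter while
  being cleaner to test.
* The 2×2 inertia solve keeps the off-diagonal `J_xy = 0.0344 kg·m²`; the
  planes are therefore weakly coupled (|corr(q_ap, q_ml)| ≈ 0.1 over 240 s).
* The per-step loop is compiled with numba; the uncompiled function is the
  pure-Python reference checked bit-for-bit in the tests.
* Falls: the model is linear and never falls by itself, so a fall is defined
  operationally as |q| > 0.26 rad (≈ 15°, far outside the linearization and
  unrecoverable at the default gains) on either axis, or a non-finite state.

## Noise amplitude and calibration

The model does not pin down the amplitude of `w_n`; the noise is interpreted
as a discrete Gaussian torque sample per Euler step per axis, with the same
SD on both axes.  Because every element of the loop (switching cones, PD
laws, gravity, stiffness, filter) is positively homogeneous of degree 1,
scaling the noise scales all continuous signals exactly proportionally and
leaves switching patterns unchanged — doubling the noise doubles the
trajectory sample-for-sample.  All dimensionless indicators are therefore
amplitude-invariant.  The default SD (17.63 N·m) is calibrated once so the
antero-posterior CoP range (±2σ) is ≈ ±16 mm, a typical quiet-standing
excursion; `calibrate_noise` re-derives it from a probe run (idempotent by
homogeneity).  The calibration matters only for the one class of results
that is not amplitude-invariant: fall-based stability boundaries (parameter
scans, pole sweeps), since the 0.26 rad fall threshold is absolute.

## Statistics

All statistics discard the first 10 s (start-up transient; results are
insensitive to this choice).  Sway ranges are reported as ±2·SD of the angle
(CoP range as ±2·SD of `y_cop = (T_s+T_ap)/((m_b+m_p) g)`); this convention
is consistent with the published torque SDs at the default operating point.
A pulse is a maximal run of consecutive on-samples (edge-touching runs
count); duty = on-fraction, rate = pulses per second, and
duty ≈ rate × mean duration holds identically.  Power spectra use Welch's
method after anti-aliased decimation to 100 Hz: 40 s Hann segments, 50 %
overlap, 0.025 Hz resolution — enough to localize the coronal resonance in
[0.3, 0.4] Hz.  Monte-Carlo replication: statistics are computed per run and
averaged across seeds; the stability gate requires zero falls in three
independent 240 s runs.

## Experiment protocols

* Parameter scans vary one control gain at a time over a sorted grid with
  all other parameters at their defaults, and report the largest contiguous
  sub-grid passing the stability gate; endpoints are meaningful only to one
  grid step.
* Pole sweeps scale length and mass together (shorter poles are
  proportionally lighter).  Outcomes are classed from five seeds: *stable*
  (no falls), *fall* (median survival < 20 s), *limited-time* otherwise —
  an operationalization of "balance only for limited stretches of time".

## Known limitations

* Single-segment body: no hip/multi-joint coordination, no arm kinematics,
  no pole reaction forces or rotation — the coronal mechanism is purely the
  static gravity effect of the shifted pole CoM.
* The synthetic noise is white and enters as torque only; real sensorimotor
  noise is filtered, state-dependent and enters the feedback path too, so
  passing tests demonstrate the control architecture's behaviour, not a fit
  to human data.
* With the default (physically closed) pole-torque channel the simulated
  coronal sway is somewhat tighter relative to sagittal sway (range ratio
  ≈ 4.3) than the ~3 sometimes quoted for this regime; the torque-SD ratios
  (σ(T_s+T_ap)/σ(G_ap) ≈ 1.09, σ(T_ml)/σ(G_ml) ≈ 2.4) are reproduced
  closely.  Fall-based stability boundaries depend on the operational fall
  definition and on the noise calibration; the admissible intervals of
  P_ap, the lower bound of P_ml and the D_ml bound are robust, while the
  upper bounds of P_ml (≈ 11.5 vs ≈ 10) and D_ap (≈ 650 vs ≈ 500) come out
  somewhat wider here.
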