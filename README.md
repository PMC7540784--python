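# tightrope

Simulation and analysis of tightrope balancing as a pair of intermittent
delayed feedback controllers acting on a two-plane inverted pendulum.

A person standing on a wire in tandem stance can shift their centre of
pressure (CoP) back and forth along the wire — so sagittal sway can be
stabilized the way quiet standing is, by intermittent ankle torque (a
*CoP stabilization strategy*, COPS).  Medio-laterally the CoP cannot move
at all, so the roles invert: the walker shifts the centre of mass (CoM)
of a long balance pole sideways to generate a counteracting gravity
torque (a *CoM stabilization strategy*, COMS).  This package implements
that model — a linearized inverted pendulum with two degrees of freedom
`q = [q_ap, q_ml]`, a rigid pole held at CoM height, and two independent
state-triggered controllers — together with the posturographic analysis
needed to characterize the resulting bounded-stability regime.

## Model

Dynamics (forward Euler, 1 ms step):

```
J q̈ = T_g(q) − T_s(q, q̇) − T_int(q_δ, q̇_δ) + w_n
```

* `J`: wire-referenced inertia tensor of body + pole (parallel-axis
  theorem; the 12 m, 13 kg pole nearly triples the coronal inertia, raising
  the falling time constant from 0.35 s to 0.54 s).
* `T_g`: linearized gravity toppling torque.
* `T_s`: passive ankle impedance `K_a q_ap + B_a q̇_ap`, sagittal only, with
  `K_a` below the critical stiffness `(m_b+m_p) g h_com`.
* `T_int`: the intermittent control torque, computed from the state delayed
  by δ = 200 ms.  Each plane's phase plane is split by the lines `q = 0` and
  `q̇ = −α q` (α = 0.4 s⁻¹) into *unsafe* regions — where the saddle dynamics
  diverges — and *safe* regions where the stable manifold brings the state
  back.  Control acts only in the unsafe regions:
  sagittal `T_ap = P_ap q + D_ap q̇` (ankle), coronal pole-shift command
  `γ = −(P_ml q + D_ml q̇)`, smoothed by a 2 Hz second-order low-pass filter
  into the physical shift Δx_p that tips the pole's weight against the fall.
* `w_n`: white Gaussian torque noise, the only driving input.  The closed
  loop is positively homogeneous, so every dimensionless statistic (duty
  cycles, pulse rates, correlations, range ratios, spectral peaks) is
  independent of the noise amplitude.

## Worked example

```python
from tightrope import SimConfig, simulate, summarize

stats = summarize([simulate(SimConfig(seed=s)) for s in (1, 2, 3)])
print(f"sway ranges      ±{stats.R_ap:.2f}° (ap) ±{stats.R_ml:.2f}° (ml)")
print(f"CoP range        ±{stats.R_cop:.1f} mm")
print(f"sagittal duty    {stats.pulse_ap.duty:.1f}% at {stats.pulse_ap.rate:.1f} pulses/s")
print(f"coronal duty     {stats.pulse_ml.duty:.1f}% at {stats.pulse_ml.rate:.1f} pulses/s")
print(f"corr(q_ap, T_ap) {stats.corr_qap_Tap:+.3f}")
print(f"corr(q_ml, Δxp)  {stats.corr_qml_dxp:+.3f}")
print(f"ml spectral peak {stats.psd_peak_ml:.2f} Hz")
```

prints (three 240 s runs, default parameters):

```
sway ranges      ±0.82° (ap) ±0.19° (ml)
CoP range        ±15.4 mm
sagittal duty    65.1% at 5.2 pulses/s
coronal duty     55.3% at 4.0 pulses/s
corr(q_ap, T_ap) +0.882
corr(q_ml, Δxp)  -0.890
ml spectral peak 0.35 Hz
```

Sagittal sway is several times wider than coronal sway (the pole keeps the
critical plane tight), each controller is on slightly more than half the
time in short ~120–140 ms bursts, sway tracks its control signal strongly
within each plane while the two planes stay essentially uncoupled, and the
coronal oscillation resonates between 0.3 and 0.4 Hz.

The same experiments are available from a shell:

```
tightrope simulate --seed 1 --out run1/          # trajectory.csv + summary.json
tightrope gate                                   # 3 × 240 s stability verdict
tightrope scan --param P_ap --min 300 --max 1500 --step 50
tightrope pole-sweep --fractions 1.0 0.9 0.8 0.7 0.6
tightrope calibrate-noise --target-cop-mm 16
```

The parameter scans recover the admissible stability ranges of the control
gains (e.g. P_ap ≈ 450–1300 N·m·rad⁻¹ with everything else at default), and
the pole sweep shows why professionals carry a full-size pole: at 90%
length balance survives with ~35% wider coronal sway, at 70–80% only
limited stretches (tens of seconds) are achievable, and at 60% every run
falls within seconds.

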