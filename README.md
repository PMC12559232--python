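# rosvgic

Simulator of oxidative-stress-driven electrophysiological remodeling in
human cell lines: pulsed reactive oxygen species (ROS) transiently
depolarize the membrane, depolarization gates voltage-gated ion channel
(VGIC) transcription, and the accumulated conductance produces a
standing depolarization that feeds proliferation and genomic
instability — the bioelectric route from a quiescent epithelial cell to
a malignant-like state. The package is for computational/systems
biologists who want a reproducible, calibrated testbed for
redox-bioelectricity hypotheses: dose-escalation experiments,
cross-cell-line comparisons, closed-loop redox control of the membrane
potential, and a trajectory-classification benchmark.

## Model in brief

The slow (hour-scale) loop couples:

- **Forcing** — Gaussian ROS pulse trains,
  `ROS_ext(t) = ROS_0 + d Σ_n A e^{-(t-t_n)^2/2τ^2}` (A = 0.045 µM);
- **Expression** — ratchet ODEs per channel class, e.g.
  `dg_Na/dt = k_Na(ROS) · H(V_m+30) · (g_Na,max − g_Na)`, with a calcium
  window [−50, −30) mV and a potassium gate below −50 mV;
- **Potential** — the linear expression map
  `V_m = −75 + α G_Na − β G_K` (chord-conductance and full
  Hodgkin–Huxley maps selectable), with transcription gated by an
  instantaneous potential that includes the fast TRPV/ROS inward
  currents of the modified HH membrane equation
  `C_m dV/dt = −I_Na − I_K − I_L + I_TRPV + I_ROS(t)`;
- **Signaling** — TF with tiered voltage sensitivity
  (`dTF/dt = k_TF·ROS·f(V_m) − d_TF·TF`), mRNA, mutation load
  (`dMut/dt = k_mut·mRNA`), intracellular ROS and calcium feedback;
- **Phenotype** — proliferation
  `dProlif/dt = α_P P(V_m) TF − β_P ROS_int` and a voltage-gated
  G0/G1→S→G2→M cycle machine;
- **Control** — a PID law `u = K_p e + K_i ∫e + K_d de/dt` actuating
  redox drive to steer V_m to a setpoint.

Free gains per cell line are fitted by a deterministic bisection +
exact-linear-solve calibration so each preset reproduces its documented
plateau potential and proliferation endpoints. See `docs/methods.md`
for assumptions, parameter tables and limitations.

## Worked example

Calibrate the HeLa preset and run the standard 48 h repeated-pulse
protocol:

```python
from rosvgic import get_preset, calibrate_preset, run_open_loop, standard_protocol, plateau_vm

hela = calibrate_preset(get_preset("HELA"))
traj = run_open_loop(hela, standard_protocol(1.0))
print(f"fitted expression gain: {hela.expression.expression_gain:.3f}")
print(f"plateau Vm (final 4 h): {plateau_vm(traj):.3f} mV")
print(f"final proliferation:    {traj.final_proliferation:.3f}")
print(f"final mutation load:    {traj.frame['mutation'].iloc[-1]:.2f}")
```

prints

```
fitted expression gain: 3.364
plateau Vm (final 4 h): -30.000 mV
final proliferation:    20.000
final mutation load:    9.11
```

The fitted gain scales the ROS→expression rate constants; the plateau is
the calibrated HeLa resting potential under sustained pulsing (−30 ± 2
mV is the validated range); proliferation and mutation load are
arbitrary-unit indices of growth signaling and transcription-coupled
genomic damage. A dose ladder on the calibrated healthy-epithelium
preset shows the progressive depolarization toward a pre-malignant
state:

```python
from rosvgic import dose_response
mcf = calibrate_preset(get_preset("MCF10A"))
print(dose_response(mcf, [1, 2, 3, 5]).to_string(index=False))
```

```
 multiplier   final_vm  final_proliferation
          1 -61.999960             6.880000
          2 -55.473864             9.468731
          3 -49.576693            11.387766
          5 -39.000478            10.620000
```

The same library surface is exposed as a CLI:

```bash
rosvgic simulate --cell-line HELA --out hela.csv
rosvgic dose-response --cell-line MCF10A --multipliers 1,2,3,5
rosvgic pid --cell-line MDA_MB_231 --target -30 --duration 24 --out pid.csv
rosvgic dataset --n 250 --jitter 0.10 --seed 42 --out data.csv
rosvgic classify --data data.csv --folds 5 --seed 7 --report report.json
```

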