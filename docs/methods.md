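# Methods

`rosvgic` simulates how pulsed oxidative stress remodels the
electrophysiology of non-excitable human cells: reactive oxygen species
(ROS) transiently depolarize the membrane, depolarization gates the
transcription of voltage-gated ion channels (VGICs), and the accumulated
channel conductance produces a standing depolarization that feeds back
into transcription, proliferation and genomic instability. This note
records the model, its assumptions, the numerical choices, and the
places where the design was genuinely open.

## Model structure

### Forcing

The extracellular ROS signal is a baseline concentration plus a train of
Gaussian pulses:

    ROS_ext(t) = ROS_baseline + d * sum_n A exp(-(t - t_n)^2 / (2 tau^2))

Defaults: amplitude `A = 0.045 uM` (the fitted pulse amplitude), baseline
`0.01 uM`, width `tau = 0.25 h`, pulses every 2 h over a 48 h horizon
(24 pulses), dose multiplier `d` scaling the pulses but never the
baseline. The pulse spacing and width are package choices: the spacing
gives well-separated pulses whose plateaus are well defined, and the
width resolves each pulse within its 2 h slot. Mild hyperthermia enters
as an extra oxidative source `0.01 uM/(h C) * max(0, T - 37)` and as a
thermal arm of TRPV activation (below); the linear transfer gain is a
package choice, since only the qualitative statement that heat acts like
oxidative stress is available.

### Two membrane potentials

The slow transformation loop (hours) tracks the *resting* potential
through the linear expression map

    Vm = -75 + alpha * G_Na - beta * G_K        [mV]

with normalized expression levels `G_Na, G_K in [0,1]`, `beta = 15 mV`,
and a per-line intercept offset so an unexpressed cell sits at its
documented resting potential. `alpha` is a fitted gain (calibration,
below). A chord-conductance alternative (conductance-weighted mean of
reversal potentials) and a full Hodgkin-Huxley steady-state solve are
selectable via `vm_model`; the linear map is the default because the
hour-scale rate constants make millisecond HH integration needless for
the slow loop. The full HH membrane (classical squid-axon gating, with
`E_K = -90 mV` and `E_L = -54.4 mV` adopted where the parameter table is
silent) is available for excitability snapshots.

Transcription, however, is gated by the *instantaneous* potential. ROS
pulses open TRPV channels (sharp logistic in ROS_ext, half-activation
`0.02 uM` = twice the standard baseline, slope `half/32`; plus an
additive thermal arm `max(0,(T-37)/4)`, clipped to [0,1]) and drive a
nonspecific inward current `I_ROS = 10 * ROS_ext uA/cm2`. The gating
potential superposes these on the resting value by the chord rule:

    V_gate = (g_L Vm + g_TRPV a E_Ca + I_ROS) / (g_L + g_TRPV a)

During a pulse `V_gate` swings far above the -30 mV sodium threshold,
opening the transcription gate; between pulses it relaxes to Vm. This is
the loop's ignition mechanism: without it a cell resting at -70 mV could
never begin expressing sodium channels, because the expression equations
gate strictly above -30 mV. The activation edge is kept sharp so the
sub-threshold baseline produces essentially no activation and the
dose-response contrast between 1x and 5x pulse trains is set by the
pulses themselves, not by a dose-independent floor. The thermal arm is
additive rather than multiplicative so that normothermic oxidative
stress activates TRPV on its own.

### Expression dynamics

Each channel class accumulates toward its ceiling at a ROS-proportional
rate inside its voltage window (Na above -30 mV; Ca/TRP in [-50, -30);
K below -50 mV), `k_x(ROS) = 1e-4 /s per uM` times a per-line fitted
gain. As written the equations have no decay: expression is a ratchet,
monotone non-decreasing — an assumption with real consequences (the
controller can depolarize but never repolarize; see below). Inside ODE
right-hand sides the Heaviside gates are logistic-smoothed (eps = 1 mV)
to keep the system Lipschitz; the algebraic tier selector uses the exact
half-open boundaries (-50 to the Ca tier, -30 to the Na tier). A
reversible Michaelis-Menten sodium form is available via
`expression_model: michaelis_menten`.

The ROS seen by every expression and signaling equation is the total
oxidative tone `ROS_ext + ROS_int`.

### Signaling, mutation, phenotype

TF (the lumped transcription/tissue factor), mRNA, intracellular ROS and
calcium are first-order linear ODEs (rates converted from the literature
per-second values to per-hour at load time). TF production is multiplied
by a tiered voltage sensitivity (0.1 / 0.5 / 1.0 below -50 / between /
above -30 mV; the tier multipliers are package choices for the
qualitative labels minimal/moderate/rapid). Two mutually exclusive
transcription scenarios are wired by `scenario`: `ros_first` paces mRNA
by total expressed conductance and accumulates mutation load as
`k_mut * integral(mRNA)`; `dna_first` paces mRNA by a rectangular
DNA-damage signal co-timed with the ROS pulses and grows an aggregate
VGIC conductance at rate `k_VGIC_mRNA * mRNA` (a literal constant-rate
variant is selectable with `eq13_literal`). Intracellular ROS is sourced
by channel activity (`1e-6 /s per mS/cm2`, chosen so the full-expression
steady state is about twice the external baseline — present but not
dominating) and by calcium (`1e-3 /s`); calcium is sourced by the TRPV
current with an influx gain of `1e-3 uM cm2/(uA h)`, a deliberately
small package constant so the calcium arm does not add a
dose-independent floor to the oxidative tone.

The proliferation index integrates `alpha_P P(Vm) TF - beta_P ROS_int`
with `P` a logistic in Vm (midpoint -30 mV, slope 5 mV). Because the
index feeds back into nothing, the simulator integrates the two
quadrature states `A = int P(Vm) TF dt` and `B = int ROS_int dt` and
reports `max(0, alpha_P A - beta_P B)`; the final index is then exactly
linear in the two gains, which is what makes the proliferation
calibration an exact linear solve. The cell cycle is a four-phase
machine (G0/G1 10 h, S 8 h, G2 4 h, M 2 h — typical mammalian dwell
times, package choices); only G1->S is voltage-gated (Vm >= -30 mV) and
hyperpolarization below -50 mV resets to quiescence.

## Calibration

Free gains per cell line: the expression-gain multiplier, the sodium
voltage gain `alpha`, and the two growth gains. The fit is deterministic:

1. bisection on the expression gain so the baseline-dose (1x) run hits
   the line's documented potential — for the malignant lines this is the
   plateau read as the mean over the final 4 h; for MCF10A it is the
   48 h endpoint (-62 mV);
2. for MCF10A only, bisection on `alpha` so the 5x endpoint hits
   -39 mV, re-running stage 1 at each iterate (the two stages interact);
3. an exact linear solve for `(alpha_P, beta_P)` from the stored
   quadrature integrals — 2x2 for MCF10A (endpoints 6.88 at 1x, 10.62 at
   5x), one unknown (with `beta_P` at its default) for lines with a
   single documented endpoint (MDA-MB-231 32.06).

Residuals are below 1e-3 of each target. Proliferation endpoints with no
published value (fibroblast 0.5, HeLa 20, GBM 28, MCF7 9, PC12 15) are
package choices fixed once to realize the documented cross-line ordering
fibroblast < MCF10A < GBM <= MDA-MB-231.

Two calibration caveats are worth stating plainly. First, the MCF10A
2x2 solve returns negative gains: between 1x and 5x the voltage-gated
growth integral rises ~30-fold while the documented endpoints rise only
1.54-fold, so the unique exact solution weights the ROS integral
positively instead. The two endpoints are reproduced exactly, but the
interpolated ladder peaks near 3x — proliferation monotonicity in dose
holds for the single-endpoint lines, not for MCF10A's interpolation.
Second, the membrane-potential ladder is strictly monotone in dose for
every line (higher dose, more depolarized).

## Controller

The PID controller actuates a redox drive from the resting-potential
error at a 0.02 h interval: positive commands add exogenous ROS,
negative commands act as an antioxidant that removes extracellular ROS
and scavenges the intracellular pool (gain 1000 /(uM h) — strong enough
that a full negative command effectively silences it). Implementation
follows standard discrete-PID practice: derivative on the error with a
first-order filter (tau 0.1 h) and a zero first step; conditional
integration (frozen while the command is clamped) plus an integral clamp
at the actuation span; bounds +-0.45 uM (ten pulse amplitudes). The
0.02 h interval is set by the plant: under a saturated command the hot
malignant plants slew ~25 mV/h, and a 0.1 h interval would step past the
setpoint irreversibly (expression cannot decrease). For the same reason
only depolarizing setpoints are reachable from rest; an unreachable
target is flagged in the trajectory metadata, not raised.

## Synthetic dataset and classifier

The labeled dataset draws two populations from the simulator:
`malignant` — the full-amplitude pulse programme applied to the
transformation-prone lines (MDA-MB-231, HeLa, GBM) — and `control` — a
sub-threshold programme (pulse amplitude scaled to 0.2, whose peaks sit
at the TRPV half-activation point) applied to the healthy lines (MCF10A,
fibroblast). Biological variability is multiplicative lognormal jitter
(unit median, CV 0.10 by default) on the expression gain, the pulse
amplitude and the intracellular ROS clearance rate. Labels are the
generating class, never a threshold on a stored feature. Eight summary
features per trajectory (final Vm, late Vm slope over the last quarter,
AUC of g_Na and of ROS_int, final mutation load and proliferation, TF
peak, fraction of time at or above -30 mV) feed a random-forest
benchmark (200 trees) under stratified 5-fold cross-validation.

What the generator does and does not emulate: it produces mechanistic
trajectory variability around two well-separated stress regimes, so the
classification problem is easier than real transcriptomic data — the
two classes barely overlap at the default jitter, and accuracy near 100%
on this benchmark demonstrates that the simulator's class structure is
learnable from trajectory summaries, not that real tumors are this
separable. Measurement noise, batch effects, cell-to-cell heterogeneity
within a dish, and any overlap between pre-malignant and control regimes
are not modeled.

## Numerics

Stiff-capable adaptive integration (LSODA, rtol 1e-6, atol 1e-9) with
the step size capped at 0.125 h so no Gaussian pulse is stepped over;
dense output on a fixed 0.01 h grid (0.05 h during calibration runs and
dataset generation, where only endpoint functionals are needed).
Everything is deterministic given the configuration; repeated runs are
bit-identical. Tightening tolerances to (1e-8, 1e-11) and halving the
step cap moves the 48 h endpoint by well under 0.1 mV. States are
clipped to their physical bounds inside the right-hand side only to
guard against sub-tolerance solver undershoot; monotonicity and
non-negativity asserts in the test suite allow slack at the solver's
interpolation error.

Problem sizes used by the test suite and the reproduction script: 48 h
standard runs (4801 samples), 24 h closed-loop runs, a 500-trajectory
benchmark dataset, and reduced sizes (12-24 h horizons, tens of samples
per class) for property sweeps.

## Known limitations

- Expression has no turnover, so transformation is irreversible by
  construction; repolarizing interventions cannot be studied.
- Units of TF, mRNA and mutation load are arbitrary; only ratios and
  calibrated endpoints are meaningful.
- The fibroblast's stress resistance is imposed (ten-fold lower
  expression gain), not mechanistically derived.
- The MDA-MB-231 plateau follows the fitted-parameter table (-40 +- 5
  mV); the narrative elsewhere quotes ~-30 mV for the same line, a
  divergence we resolve in favor of the table.
- One intercept tension is left as printed: the linear map's -75 mV
  intercept vs. the stated healthy rest near -70 mV; presets differ via
  their calibration offsets.
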