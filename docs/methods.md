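# Methods

This note describes the models and procedures implemented in `vnsim`,
the assumptions behind them, the calibrations that fix their default
parameters, and the limits of what the synthetic-data experiments can
show.

## Scope and study design

The package simulates and analyses the effects of cervical vagus nerve
stimulation (VNS) in the anesthetised mouse on two physiological
readouts: heart rate (HR, the therapeutic proxy) and evoked laryngeal
EMG (the side-effect proxy). Stimulation is delivered as symmetric
biphasic charge-balanced pulses (300 us per phase) whose amplitude is
expressed in multiples of the bradycardia threshold (BCT, the amplitude
producing ~10% HR reduction at 20 Hz). Temporal patterns repeat in 1 s
epochs: constant frequency, bursts (the epoch's pulses compressed to an
intra-burst interval at the epoch start), 50% duty-cycle patterns, and
randomised epochs. The factorial design crosses 8 rates (2-100 Hz) as
intra-burst frequency and mean pulse rate (MPR, pulses per epoch; only
MPR <= frequency is realisable), giving 36 temporal patterns, times 3
amplitudes (0.8, 1.0, 1.2 x BCT): 108 conditions. Trials run 70 s
(10 s baseline, 30 s VNS, 30 s recovery).

No recorded animal data ship with the package; every analysis runs on
synthetic recordings with known ground truth, which makes each pipeline
stage testable end to end.

## Synthetic trial generator

`vnsim.synth` produces 5 kHz two-channel trials (ECG + laryngeal EMG).

*Heart rate.* A ground-truth response surface sets the per-condition
normalised heart rate

    HR_norm(amp, mpr, f) = 1 - A(amp) * S(mpr_eff),   S(x) = x/(x + m50),

where `mpr_eff` is the MPR attenuated by the ganglionic transmission
fraction at the intra-burst inter-pulse interval (computed from the
same synaptic gate as the mechanistic model, so the surface reproduces
the in vivo trend directions: deeper bradycardia with amplitude and
MPR, shallower with intra-burst frequency at fixed MPR). Defaults:
gains A = 0.10/0.25/0.45 at 0.8/1.0/1.2 x BCT (linearly interpolated
through zero), half-saturation m50 = 20 pulses/s, baseline 450 BPM
(anesthetised-mouse range 400-500), respiratory sinus arrhythmia of 3%
at 60 breaths/min, and a 1 s exponential transient at stimulation
onset/offset (the analysis discards the first 5 s of stimulation, so
the residual transient bias is < 0.1%). Beats come from an
integrate-to-threshold process on a 1 ms rate grid; each beat places an
8 ms biphasic QRS-like wavelet.

*EMG.* Each pulse deposits a stimulus artifact (0-1 ms post-trigger)
plus an evoked biphasic wave at 1.5-6 ms whose amplitude is
`recruitment(amplitude) x fatigue`. Recruitment is logistic in xBCT
(centre 0.6, scale 0.07: onset near 0.4, near-saturation by 0.8,
matching the reported dynamic range). Fatigue uses a depletion state
that increments per pulse and recovers with a 0.3 s time constant;
amplitude = floor + (1-floor) * exp(-depletion/30) with floor 0.3. At
100 Hz this gives the observed within-trial amplitude decline; at low
rates recovery keeps amplitudes near maximal. Waveform shapes and the
artifact are conventions constrained only by the analysis windows (the
source experiments do not quantify them).

Band-limited Gaussian noise (10 Hz - 1 kHz) is added to both channels;
the signals themselves are generated in-band. A vagotomy switch zeroes
both the HR response and the evoked EMG, leaving artifact plus noise.
Cohorts draw per-animal log-normal factors on the surface gains (sigma
0.10) and EMG scale (sigma 0.20), creating a realistic "animal" factor,
and randomise condition order per animal.

What the generator does not emulate: anesthesia-depth drift, BCT
re-titration, electrode movement, sympathetic rebound tachycardia, and
EMG waveform shape changes with amplitude. Quantification round-trip
tests on this generator therefore validate the analysis code, not its
robustness to those real-world effects.

## Signal quantification

`vnsim.quant` mirrors standard practice. QRS peaks are detected with an
adaptive threshold (half the rolling 2 s maximum, 50 ms refractory);
instantaneous HR is the mean of 60/RR over beat pairs whose midpoint
falls in a 0.5 s window, evaluated on a 1 ms grid (the window means that
enter HR_baseline and HR_stim are insensitive to refining this grid
further). HR_baseline averages [0, 10) s, HR_stim averages [15, 40) s,
HR_norm is their ratio. The stimulus artifact is removed by template
subtraction (template = mean peri-trigger signal over [-1, +1] ms);
evoked EMG is the average rectified value over [1, w_end] ms post-pulse
(w_end default 6 ms, configurable 5-8 ms), summed over the trial's
pulses and normalised to the animal's 1.0xBCT / 20 Hz reference. The
effect score is (1 - HR_norm)/(1 - HR_norm_ref) - EMG_norm; the
reference maps to 0 by definition. HR_stim averages the instantaneous
HR series (not per-beat rates); trials with too few beats in a window
are flagged invalid and excluded.

## Heart-rate model

The mechanistic chain is vagal efferent -> intrinsic cardiac nervous
system (ICNS) -> acetylcholine (ACh) release -> sinoatrial node (SAN)
network.

*Ganglionic gate.* Each of 100 post-ganglionic ICNS cells is driven by
the shared pulse train; a pulse releases ACh with probability
`clamp(1.028 - 2.183 * dt^-0.7146, 0, 1)` where dt (ms) is the time
since the cell's last post-ganglionic event. The raw curve crosses 0
near 2.87 ms and 1 near 444 ms, so trains at <= 2 Hz transmit fully and
high-rate trains are throttled. Fifty cells also fire intrinsically,
Bernoulli per 50 ms bin, with a half-sine respiratory profile peaking
at 0.6 events/bin over a 1 s cycle; intrinsic events release ACh and
reset the same recovery clock (a modelling choice: the source data do
not resolve whether intrinsic events reset the gate).

*ACh release.* Events commit 5% of the 0.075 mM available presynaptic
ACh to a releasing pool that drains into the neuroeffector junction at
4 s^-1; junction and extra-junctional space exchange at 10 s^-1 and
both hydrolyse at 14 s^-1 (5 and 30 s^-1 selectable). The system is
linear; traces are computed by exact per-mode exponential recursions on
a 1 ms grid. The finite release rate smooths single events so the
respiratory ACh modulation arrives as a slow wave rather than spikes.

*SAN network.* A 10x10 grid of identical pacemaker cells coupled by
6 nS gap junctions between edge neighbours. Each cell is a reduced
three-variable conductance-based relaxation oscillator (25 pF): a fast
inward current with instantaneous tanh activation, a delayed-rectifier
potassium current (tau 25 ms), and a slow depolarising conductance that
activates at diastolic potentials with a 350 ms time constant and
deactivates rapidly during the spike - the diastolic ramp that sets the
pacemaker period and stands in for the funny-current/calcium-clock
mechanisms of full ionic models. ACh acts through
I_KACh = g_KACh * s(ACh) * (V - E_K) with g_KACh = 0.00675 uS (the
published 0.00864 uS at 32 pF scaled by capacitance to 25 pF) and s a
Hill function of junctional ACh. Integration is explicit Euler at a
fixed 0.05 ms step; spikes are rising crossings of -20 mV; the mean
firing rate of the 36 peripheral cells is read out as HR.

*Calibration.* Free shape parameters were fixed once so that (i) the
isolated cell - and hence the synchronised unperturbed network - fires
at 389 BPM at the default step (the slow-conductance density was set by
bisection; an exact time-rescaling of conductances and gate time
constants is also available), and (ii) with intrinsic ICNS drive the
network rate fluctuates by ~0.2% peak-to-trough while graded
VNS responses and quiescence under saturating ACh are preserved, which
fixed the Hill sensitivity (K1/2 = 4.6e-3 mM, coefficient 11) and the
release low-pass (4 s^-1). The steep Hill coefficient is a deliberate
compensation: the reduced cell's graded slowing band is narrow compared
with a full ionic pacemaker, and the steep activation re-creates the
experimentally observed contrast between near-invisible intrinsic
cholinergic drive and strong stimulated drive.

*Amplitude as ACh density.* Stimulation amplitude is represented by how
many of the 100 SAN cells receive VNS-evoked ACh (density 0-100; the
mask is uniformly random per run). The 50 intrinsic-ICNS target cells
receive intrinsic ACh regardless. Density is calibrated against a
target HR_norm-versus-frequency curve by integer bisection on the
signed mean error (monotone in density), ties to the lower density,
with a grid-search fallback if monotonicity fails. Each simulation is
repeated with fresh seeds; the three stochastic elements (transmission
draws, intrinsic firing, mask placement) use independent streams.

*Known limitation (filtering knockout).* Removing the ganglionic gate
(every pulse releases ACh) always deepens the simulated bradycardia,
and the filtered-vs-knockout gap grows with frequency up to ~20-30 Hz.
Above ~50 Hz the reduced cell's ACh response saturates (driven cells
are silenced under both variants), so the gap collapses rather than
continuing to grow as a full ionic model predicts at 100 Hz. The
knockout property is therefore asserted over the model's graded band.

## Muscle model

`vnsim.muscle` implements the canonical two-stage force-fatigue system:
a Ca2+-troponin driver CN excited by the pulse train with doublet
enhancement (R0 = 2, tau_c = 20 ms; both absent from the source tables
and fixed by convention), a force ODE with Michaelis-Menten coupling
(A, Km) and CN-dependent decay (tau1, tau2), and first-order fatigue of
A, Km and tau1 driven by force with recovery time constant tau_fat. CN
uses its exact exponential solution; force and fatigue use RK4 at
0.1 ms (steps above 0.5 ms are rejected). Trial outcomes are
force-time integrals normalised to the 20 Hz constant response
(Force_norm), taken as identical to normalised EMG (the 1:1 EMG-force
assumption for isometric contraction of fast-twitch laryngeal muscle).
The model is deterministic.

Two named parameter sets are shipped: the human-quadriceps reference
values and the swarm-identified set. Under the canonical equations the
swarm-identified set's very large fatigue coefficient for A
(-0.51 ms^-2) drives the model to a force-limited equilibrium whose
normalised rate-response curve is nearly flat; the reference set
reproduces the monotone activation-rate relationship. The equations are
isolated in a single documented unit so an alternative published form
is a one-file change.

## Swarm optimiser

`vnsim.pso` fits the eight muscle parameters to per-pattern normalised
EMG targets: 100 particles in 20 fixed neighbourhoods of 5, positions
scaled to [0,1] per dimension (so the shared random coefficient acts
uniformly across the heterogeneous parameter scales), uniform
initialisation in bounds, 50 iterations, clipping at bounds (several
identified values sit exactly on bounds, consistent with clipping).
The velocity rule is V = r1*(Pbest1 - P) - r2*(Pbest2 - P) with r
uniform on [0, 1.496) drawn per dimension and the three-case
neighbourhood selection (neighbourhood best is pulled by the global
best and the second best; the second best by the best and third best;
all others by the best and second best); the global best is frozen
each iteration. The second term's minus sign is repulsive and there is
no inertia term - unconventional for particle swarms - and a
`velocity_sign` switch selects the conventional attractive form for
comparison; the default follows the printed rule. Ties in neighbourhood
ranking break by particle index. Runs use a 50-50 train/test split of
the 36 patterns; the final model is the run with the lowest total RMSE.

Parameter-recovery experiments show that with the normalised cost, A
and Km are only weakly identifiable when tau1/tau2 are free (a flat
cost valley); the recovery test fixes the fatigue coefficients and the
kinetic time constants at truth and recovers A and Km to within a few
percent.

## Fiber recruitment

`vnsim.recruitment` replaces the finite-element + biophysically
detailed fiber study with a structural equivalent: 180 um
monofascicular nerve cross-section; bipolar point-source contacts
895 um apart, 10 um outside the nerve, in a homogeneous isotropic
medium (0.3 S/m); A fibers 7-11 um and B fibers 2-5 um (truncated
normals within +-2 SD), uniform positions in the disc, node alignment
jitter uniform in +-0.5 internodal lengths (INL = 100 x diameter);
a reduced myelinated cable (21 Hodgkin-Huxley-type nodes at 10x squid
conductance densities, passive internodal axial coupling, perfect
myelin) driven by the biphasic 300 us/phase pulse; thresholds by
bisection to 1% with spike detection (-30 mV rising) at 90% of fiber
length. The published perineurium-thickness fit
(0.01292 * d_fasc + 1.367 um) is retained as a documented helper; the
homogeneous field does not use it.

Because the cuff, perineurium and anisotropic endoneurium are omitted,
absolute thresholds are not comparable to the full model or to in vivo
amplitudes; all claims are structural. The reproduced mechanism: A
fibers' internodal length (700-1100 um) is commensurate with the
contact spacing, so node alignment dominates their threshold variance,
while B fibers (200-500 um INL) sample the field densely and diameter
dominates; the two populations' threshold ranges overlap. In this
simplified geometry B-fiber threshold is not monotone in diameter at
fixed position (the internode stretches with diameter, moving nodes
away from the field hot spot), so dominance is asserted through a
binned sequential sum-of-squares partition of log-thresholds (with a
radial-distance term absorbing the shared geometric falloff), not
through a per-fiber sign.

## Effect-size analysis

`vnsim.effects` partitions response variance over the design factors
(amplitude, intra-burst frequency, MPR, their pairwise interactions,
animal) as the term's sum of squares divided by the corrected total sum
of squares (deviations from the grand mean) - the raw-sum reading would
make percentages depend on the response's offset - with the residual
reported as unaccounted variance. Sequential (Type I) sums of squares
are used; on the balanced synthetic designs generated here they equal
Types II/III. Single-level terms are dropped with a warning.
Post-hoc multiple-comparison machinery is deliberately out of scope.
`ols_fit` provides the line fits (slope, intercept, R^2, F-test p)
used for regressing responses on random-pattern frequency statistics.

## Problem sizes and numerical choices

Default simulations reproduce the full protocol (70 s trials, 0.05 ms
SAN step, 0.1 ms force step, 10 repeated HR runs, 100-particle/50-
iteration swarm fits, 1000 fibers per type). The shipped test suite
exercises the same code paths at reduced sizes chosen as the smallest
that leave the tested contrasts well clear of Monte-Carlo noise:
5-15 s trial segments for SAN trials, 10 seeded runs of 30-50 s for the
baseline calibration checks, 6 s patterns / 50 particles / 30
iterations for swarm recovery, and 200 fibers per type for the
recruitment structure. Degenerate inputs (empty trains, flat signals,
zero references, single-level factors) raise or warn explicitly rather
than propagating NaNs.

## Reproducibility

Every stochastic stage takes an explicit integer seed and derives
independent child streams (`numpy` SeedSequence); identical seeds give
bit-identical trains, trials, cohorts, swarm trajectories and
simulation outputs. The pipeline driver (`vnsim.pipeline`) stamps each
run with a configuration hash and records per-stage timings and seeds.
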