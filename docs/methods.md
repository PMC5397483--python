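# Methods

## Model overview

The model splits auditory streaming into a feature-encoding stage and a
percept-encoding stage. The first stage emulates primary auditory cortex
(A1) responses to ABA_ triplet sequences as deterministic input pulses; the
second is a stochastic three-unit firing-rate competition network whose
attractor dynamics produce the percept. Only the competition stage carries
noise and adaptation on the seconds timescale, so the multisecond build-up
of segregation emerges downstream of A1 even though A1 adaptation itself is
subsecond.

## Stimuli

The triplet grammar is fixed: each 400 ms triplet is A (100 ms), B
(100 ms), A (100 ms), silence (100 ms); B sits DF semitones above A
(12-tone equal temperament, frequency ratio 2^(DF/12)). Sequences of n
triplets last exactly 400 n ms. Perturbations:

- **pause** — 300 or 600 ms of extra silence inserted after a triplet
  boundary (canonically after 7 context triplets, followed by 3 test
  triplets);
- **distractor** — a 50 ms tone centered in the 100 ms inter-triplet gap
  (25 ms silence on each side), at a frequency specified relative to A/B
  (`"B+2"`, `"A-2"`, `"(A+B)/2"` = the geometric mean, i.e. the semitone
  midpoint);
- **deviant** — the B tone of one triplet shifted in frequency (canonically
  +2 st in triplet 3 of 6).

Base (A) frequencies rove across trials over five log-spaced values from
420 to 1060 Hz inclusive (≈ 4 st apart), so B reaches at most
1060·2^(10/12) ≈ 1888 Hz at DF = 10. Times are integer milliseconds
internally; audio synthesis (pure tones, 10 ms linear ramps) is a
convenience output with a digital full-scale level convention, not
calibrated SPL.

## A1 input stage

Units A, AB, B pool A1 activity at tonotopic centers 0, DF/2 and DF
semitones (relative to the A tone). A tone at semitone position p
contributes a rectangular pulse for its duration, with Gaussian weight
exp(−d²/2w²) where d is the distance from the unit's center to the tone's
*effective* position and w is the tuning width.

Two adaptation components share the timescale τ_A1 = 500 ms and are
evaluated at each tone's onset:

- **amplitude**: gain(t) relaxes from `amp_onset_gain` (unadapted) to 1
  (adapted) during stimulation;
- **effective DF**: the fraction f(t) relaxes from `df_onset_frac` to 1,
  and tone positions compress toward the stimulus midpoint:
  p_eff = DF/2 + f·(p − DF/2).

The compression convention encodes "responses driven by an effectively
small DF": a stimulus with separation f·DF is symmetric about the same
midpoint, so at onset both tones drive the region around (A+B)/2 and the AB
unit receives the largest input during *every* tone — this is what makes
the integration unit activate first and is the source of the initial
integration bias. The alternative reading (shrinking tone–unit distances in
place) leaves the A unit with the largest input during the sequence-leading
A tone, which makes the A unit ignite first on essentially every trial and
abolishes the integration bias at any noise level; we therefore reject it.

During silence the adaptation recovers toward the onset state with
τ_rec = 100 ms, but only for silence in excess of the grammar's nominal
100 ms gap (`recovery_grace_ms`). Without this grace period the fast
recovery would undo the adaptation inside every normal triplet gap and the
adapted steady state could never be reached; with it, a 300 ms pause yields
e^(−2) ≈ 0.14 residual adaptation — effectively onset-like inputs — while
unperturbed sequences adapt monotonically. `recover_during_silence` itself
is the pure exponential; the grace convention lives in the trace builder.

Non-triplet events (distractor/deviant labels) follow three rules:
amplitude boosted to the unadapted gain (`boost_to_unadapted`; the event is
detected as novel), the A-center contribution multiplied by
`masking_factor` (forward masking: the event immediately follows an A-tone
offset; only the A location is masked), and, when
`gate_non_triplet_from_ab` is set (the gating hypothesis), no contribution
to the AB unit at all. With boost off, masking 1 and gating off the rule
reduces exactly to the standard-tone rule. Non-triplet events advance the
shared adaptation clock like any other stimulation. "Input static" mode
(`adapting=False`) holds gain = 1, f = 1 from the first tone, giving a
strictly periodic trace.

## Competition stage

Each unit k ∈ {A, AB, B} has rate r_k, NMDA-like excitation e_k,
adaptation a_k and OU noise χ_k:

- τ_r dr_k/dt = −r_k + F(β_e e_k − β_i Σ_j r_j − g a_k + I_k + χ_k)
- τ_e de_k/dt = −e_k + r_k, τ_a da_k/dt = −a_k + r_k
- χ_k: OU process with correlation time `noise_tau` and stationary s.d.
  `noise_sigma`, independent per unit and trial.

Operating point: τ_r = 10 ms, τ_e = 70 ms, τ_a = 1400 ms, β_e = 0.65,
β_i = 0.3 (global, instantaneous, self-inclusive), g = 0.045. F is
logistic with threshold `f_threshold` and slope `f_slope`. Adaptation
relaxes toward r_k at all times (not gated by dominance). Noise enters
inside F only, as the rate equation is written; a consequence worth knowing
is that rates are strictly non-negative, so in fully quiescent periods the
summed peripheral activity (two positive baselines) always exceeds the
single AB baseline and silent bins read as segregated under the standard
readout (see the pause paragraph below).

Integration is Euler–Maruyama with dt = 0.5 τ_r = 5 ms, all derivatives
evaluated at the pre-step state. The OU update uses the exact one-step
discretization (mean-reversion factor e^(−dt/τ) with matched per-step
variance), which is correct at any dt. Noise-free trajectories converge
first-order in dt to an adaptive-integrator reference (≤ 1e−3 everywhere at
dt = 0.025 ms); non-finite state aborts the run naming the variable and
step.

**Frozen noise and seeding.** A master seed spawns per-trial streams
(trial i, stream 0 for the OU path and initial χ, stream 1 for initial
conditions) through `numpy` SeedSequence spawn keys, so trial i's noise is
identical across conditions, ensemble sizes and execution order, and a
longer simulation extends a path without changing its prefix. Paired
conditions are therefore bit-identical up to the moment their inputs
diverge. Initial r, e, a are uniform on [0, 0.1]; initial χ is drawn from
the OU stationary distribution.

## Percept readout and analysis

A trial's percept in a bin is integrated iff the bin-averaged r_AB is at
least the bin-averaged r_A + r_B (ties → integrated); a per-sample majority
mode is available behind a flag. Bins are one triplet (400 ms) wide,
aligned to triplet boundaries; when a timeline contains a pause the model
keeps running and the pause interval forms its own bin, so post-pause bins
remain triplet-aligned. Build-up functions carry binomial standard errors
sqrt(p(1−p)/n). Difference scores are evaluated at the final test
triplet's bin (subjects report the last triplet); positive = promotion of
segregation, negative = reset toward integration. First-switch time is the
center of a trial's first segregated bin; "AB active first" is judged on
the NMDA variable e_k (the sustained-activity measure against which the
activation threshold is drawn) because with strong unadapted onset inputs
several units' rates can cross a threshold within a single 5 ms step.

During a pause the ensemble proportion moves toward 0.5 — downward when
build-up had passed 0.5, upward when it had not. We test this
directionally per DF (no direction is required when the pre-pause value is
already within 2 s.e.m. of 0.5) rather than as an absolute contraction of
|p − 0.5|: because noise enters inside F, quiescent bins are biased toward
the summed peripheral readout, so the silent-interval ensemble value has a
segregation-leaning floor that an absolute contraction test would penalize
regardless of calibration.

## Calibrated constants

The coupling gains and time constants above are the published operating
point. The remaining constants are not determined by it; they were fixed
once by the packaged calibration harness (`streamseg.calibrate`), which
searches until the full battery of qualitative signatures passes (flat
static build-up; adapting build-up starting < 0.2 segregated and reaching
the static level; final proportions ordered DF 4 < 7 < 10; negative pause
deltas; positive gated distractor/deviant deltas at DF 4 and 7; no effect
at B+15; negative ungated midpoint delta at DF 10; directional pause drift;
seconds-scale first switches; AB active first). The chosen set — verified
at n = 500 on eight different master seeds — is the packaged default:

| constant | value | meaning |
| --- | --- | --- |
| `tuning_width_st` | 2.5 st | Gaussian tonotopic pooling width |
| `amp_onset_gain` | 5.0 | unadapted/adapted response amplitude |
| `df_onset_frac` | 0.25 | effective-DF fraction at onset |
| `input_gain` | 0.12 | adapted pulse amplitude (drive units) |
| `masking_factor` | 0.5 | A-center attenuation of non-triplet events |
| `f_threshold`, `f_slope` | 0.26, 0.04 | sigmoid threshold / slope |
| `noise_sigma`, `noise_tau` | 0.065, 100 ms | OU stationary s.d. / correlation time |

The dynamical regime these produce: onset pulses are several-fold larger
than adapted ones and midpoint-centered, so the AB unit ignites within the
first triplet and suppresses the peripheral units; as amplitude adapts and
tonotopy emerges (~2–4 triplets) the AB unit's input falls with DF while
the A unit keeps its full own-tone drive, and rising adaptation plus noise
produce a first switch to segregation after seconds, sooner for larger DF;
thereafter noise-driven alternations set the DF-dependent stationary
proportion that the static-input ensembles show from their first bin.

## Problem sizes and runtime

All shipped analyses use the published ensemble size (500 frozen-noise
trials) at dt = 5 ms; a 10-triplet ensemble is 800 steps and takes well
under a second on one CPU, so the full battery (≈ 30 ensembles, including
a 30-triplet run for switch timing) completes in a few seconds.

## What the synthetic conditions do and do not show

The generator reproduces the experiments' stimulus arithmetic exactly
(tone/triplet durations, pause and distractor placement, factorial
designs, frequency roving). The model is a lumped three-unit caricature:
it has no continuous tonotopic axis, no spiking or conductance dynamics,
no explicit stimulus-specific-adaptation circuit, no attention or delayed
top-down gating, and the percept readout is a hard binary rule. Passing
the battery shows the mechanisms are sufficient to produce the qualitative
phenomena (integration bias, build-up, resets, promotion of segregation,
tonotopic distance dependence) under these idealized inputs; it does not
fit, and should not be read as fitting, any individual listener's
proportions. Absolute proportions segregated run higher than typical group
data (the two segregated units share the readout's summed side); only
signs, orderings and convergence relations are calibrated claims.

## Known limitations

- The pause-interval readout has a segregation-leaning floor (noise inside
  F; see above), so during-pause proportions saturate near ~0.8 rather
  than relaxing to 0.5 exactly.
- Deviant tones reuse the distractor rules; no separate deviance-detection
  process is modeled, and the transmission from A1 to the competition
  stage is idealized as instantaneous.
- The A-tone repetition rate being twice the B rate is not given a
  rate-dependent amplitude penalty; forward masking enters only through
  the static `masking_factor` applied to non-triplet events at the A
  location.
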