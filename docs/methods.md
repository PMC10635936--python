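# Methods

This note documents the models, parameter choices and numerical
decisions behind `tapdyn`, in the spirit of a package methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The stochastic HKB model and its integration

The relative phase φ between the hands evolves as

    dφ/dt = Δω − a·sin φ − 2b·sin 2φ + √Q·ξ(t),

with ξ(t) unit-intensity Gaussian white noise.  We simulate φ directly
(a phase-level model) rather than two coupled limit-cycle oscillators:
the equation itself is phase-level, and hand positions are reconstructed
afterwards from a shared carrier, θ_l = 2πf·t and θ_r = θ_l + φ.  This
is a modelling choice: it cannot represent amplitude dynamics or
per-hand frequency fluctuations, which is acceptable because every
downstream measure is computed from band-limited position signals whose
relevant content is the phase relation.

*Integration.*  Euler–Maruyama with step dt = 1/(10·fs) and decimation
to the output rate fs (59.94 Hz by default).  The sub-frame step keeps
the drift stiff regime (large a, b) accurate; the noise increment per
step is √(Q·dt)·N(0,1), the standard interpretation of unit-intensity
white noise.  A coarse stability guard rejects parameter/step
combinations where |drift|·dt could exceed π.  With Q = 0 the scheme
reduces to deterministic Euler; unit tests compare it against a
100-fold finer independent integrator.

*Analytic oracle.*  Fixed-point stability is computed by hand
differentiation of the drift: λ(φ*) = −a·cos φ* − 4b·cos 2φ*.  At
φ* = π this gives λ = a − 4b, so the anti-phase attractor is stable iff
b/a > 1/4 — the classical HKB boundary.  The test suite checks both the
eigenvalue sign and the simulated convergence against this boundary,
and the pure-diffusion law Var[φ_T − φ_0] = Q·T at a = b = 0.

## Synthetic recordings

Each hand's fingertip position is a point on an ellipse at that hand's
phase, plus low-frequency sinusoidal centre drift, Gaussian measurement
jitter, and a seeded subset of `round(dropout_rate·N)` frames whose
tracking likelihood is drawn uniformly below the 0.95 masking threshold
(only the below-threshold property matters downstream).

*Tap dwell.*  Real tapping trajectories are not symmetric: the
fingertip dwells near drum contact.  We model this with a phase warp
θ → θ − κ·sin θ (default κ = 0.3), which concentrates samples near the
tap point at the positive end of the major axis.  This asymmetry is
load-bearing: a perfectly symmetric ellipse carries no information
about which end of its major axis is the tap, so the rotation stage's
sign convention — and hence the relative phase, which is otherwise only
identified mod π — would be arbitrary.  The warp adds harmonics of the
carrier, but its fundamental component keeps the carrier phase, so the
band-passed signals recover the generating relative phase (verified by
the pipeline-closure tests to within 0.02 LRV).

*What the generator does not emulate:* tap sounds and contact
mechanics, pose-estimator failure modes other than dropouts (identity
swaps, systematic bias), amplitude fatigue, and within-trial tempo
drift.  Passing tests therefore demonstrate correctness of the analysis
chain under the stated model, not robustness to every artefact of real
video tracking.

## Preprocessing

Order: trim → likelihood mask → interpolation → rotation → band-pass,
with the x position of the rotated trajectory used downstream.

- *Trim:* 1 s at each end of a 12-s trial.  The retained window is
  half-open, [trim, duration − trim): first kept frame ceil(trim·fs),
  count floor((duration − 2·trim)·fs) — 599 frames at 59.94 Hz.
- *Masking:* positions with likelihood strictly below 0.95 become
  missing; a value exactly at the threshold is kept.
- *Interpolation:* monotone piecewise-cubic Hermite (PCHIP), which
  preserves shape and overshoots less than splines on tapping data.
  Gaps at window edges have no bracketing sample and are filled with
  the nearest retained value.  A hand with > 50% missing frames fails
  the trial (quality guard).
- *Rotation:* per hand, about its centroid, sending the trajectory's
  principal axis to the x-axis.  Because an axis has no direction, the
  tap end must be identified: the end of the major axis with more
  samples in its outer 25% band (the dwell cluster) is taken as the tap
  side and rotated to positive x; near-ties — symmetric trajectories
  where the convention is genuinely arbitrary — resolve to the positive
  side, so an already-aligned symmetric ellipse is left untouched.
  Whether rotation should be per-hand or global is not determined by
  the problem; per-hand is implemented since the hands' ellipse
  orientations differ.
- *Band-pass:* 4–9 Hz Butterworth of order 4, applied
  forward–backward.  Zero-phase filtering is essential here — any phase
  distortion would bias the relative phase — at the cost of doubling
  the effective magnitude order.

## Relative phase and circular summary

Instantaneous phase is the angle of the analytic signal (Hilbert
transform) of each zero-mean band-limited x signal, unwrapped; the
relative phase is the wrapped difference θ_r − θ_l ∈ (−π, π].  The
summary is the mean resultant vector: LRV = |mean of exp(i·φ_t)| and
its angle in degrees.  The resultant uses the standard circular
convention exp(i·φ) with φ in radians — the only convention under which
a constant φ = 180° gives LRV = 1 at angle 180°.  Phases are unwrapped
before differencing and wrapped after, avoiding spurious ±2π jumps.
The Hilbert phase is computed on the full 10-s window; the 1-s edge
trim has already removed the transients that dominate Hilbert edge
error (for a constant-offset tone pair the edge effects cancel in the
difference, which is why the LRV ceiling is reached to < 1e-3).

## CRQA

Signals are affinely rescaled to [0, 1], delay embedded
(point i = (x_i, x_{i+τ}, …, x_{i+(d−1)τ}), N′ = N − (d−1)τ points), and
compared with the Euclidean norm: matrix[i,j] = dist(x_i, y_j) ≤ r.
Defaults τ = 2 frames (the quarter-cycle rule round(fs/4f) at ~7 Hz
tapping and 59.94 Hz sampling; confirmed by the first local minimum of
the average mutual information), d = 5, r = 0.2 as an absolute radius on
the unit-rescaled data.

- *%REC* = 100 · (recurrent cells)/(N′²).
- *Lmax* = longest run of consecutive recurrent cells along any 45°
  diagonal; runs shorter than lmin = 2 are isolated points, not lines,
  and report 0.  The line of identity is not excluded for
  cross-recurrence between distinct signals (it is an ordinary
  diagonal there); an auto-recurrence mode would exclude it.  No
  Theiler window is applied by default.
- *Diagonal recurrence profile:* recurrence rate per diagonal offset
  k ∈ [−max_lag, max_lag], normalised by diagonal length; its argmax
  indexes lead–lag between the hands.
- *Triangle asymmetry:* recurrences strictly above / strictly below the
  main diagonal; reported as missing (NaN) when the lower triangle is
  empty.
- *Radius scan:* %REC over a radius grid, flagging floor (0) and
  ceiling (100) violations, and reporting the longest contiguous span
  of ≥ 3 usable grid points whose least-squares fit of log %REC on
  log r reaches R² ≥ 0.99 — the "linear scaling" region from which r
  should be chosen.
- *AMI estimator:* equal-width binning with ⌈√(N/5)⌉ bins by default.
  Equal-width histogram MI carries an upward bias of roughly
  (bins−1)²/(2N ln 2) bits for independent data, so independence checks
  should use a modest explicit bin count; the default is intended for
  the short oscillatory signals the delay diagnostic runs on.

Every measure is verified against brute-force enumeration on random
small instances (exact equality), and transpose duality
(CR(x,y) = CR(y,x)ᵀ, reciprocal triangle ratios) is property-tested.

*Why the %REC / Lmax dissociation works.*  Over the full N′×N′ matrix
the recurrence density of two near-periodic signals is governed by
waveform and fast within-cycle jitter — i.e. by Q and measurement noise
— and is nearly invariant to slow wander of the relative phase.  The
longest unbroken diagonal, in contrast, is cut each time the relative
phase wanders far enough to break alignment, so it tracks the
attractor's restoring strength.  The acceptance suite verifies both
monotonicities on simulated trials (median %REC strictly decreasing in
Q at fixed coupling; median Lmax strictly increasing in b/a at fixed
Q = 0.5 — a noise level chosen so diagonals neither saturate at the
matrix size at b/a = 1.5 nor vanish at b/a = 0.3).

## Group statistics

The observation table holds one row per trial (participant, group,
trial, lrv, percent_rec, lmax).  For each metric we fit

    metric ~ group + (1 | participant) + (1 | trial)

by REML (statsmodels MixedLM with variance components), with the trial
intercept crossed — trial index 1–3 shared across participants — which
is the minimal reading of "participants and trials as random effects".
The group contrast (professional − amateur) is tested by Wald χ² on
1 df; singular fits (a variance component at the zero boundary) are
flagged but reported.

*Effect size.*  Partial η² is computed as χ²/(χ² + df_resid) with
df_resid = n_participants − 2: the group contrast is a
between-participant comparison, so the repeated trials contribute no
independent information to its error df.  This is algebraically the
F-statistic form η² = F·df1/(F·df1 + df2) with df2 at the participant
level.

*Blocked cross-validation.*  Two regression models — intercept-only
vs intercept + group, fit by least squares on the training folds — are
compared on held-out squared prediction error, with participants (not
rows) randomised into k = 5 folds so that all trials of a participant
stay together; prediction for held-out participants uses fixed effects
only, since a new participant has no estimated random intercept.  A
repetition counts as a win for the group model only on strictly lower
total error (ties are non-wins).  2000 repetitions by default,
deterministic given the seed.

*Calibration.*  On null tables simulated from the generative model
(16 participants × 3 trials), the Wald test runs slightly hot — the
acceptance suite estimates its rejection rate at the 5% level over
2000 replicates and requires it within 2.5–7.5% — the familiar
small-sample anticonservativeness of Wald χ² with ~14 participant-level
df.  Power and sign recovery are verified under a 3-SD group shift.

## Synthetic cohort presets

The cohort generator mirrors the study design: two groups of 8
participants, three 12-s trials each at 59.94 Hz.  The group presets
are *scenario presets* — parameter regimes producing the qualitative
contrast of interest — not estimates of any real players:

| preset        | a | b   | λ at 180° | Q    | carrier (Hz) |
|---------------|---|-----|-----------|------|--------------|
| professional  | 1 | 1.0 | −3.0 /s   | 0.15 | 7.19         |
| amateur       | 1 | 0.4 | −0.6 /s   | 0.15 | 6.67         |

Both groups share Q so that attractor strength, not noise, separates
them; the stationary phase spread Q/(2|λ|) then differs by a factor of
5.  Participant heterogeneity is lognormal jitter on b (10%) and Q
(15%), plus carrier-frequency jitter (SD 0.25 Hz) and kinematic
variation (amplitude, ellipse orientation); the amateur b jitter keeps
b above the 1/4 stability boundary.  Trial-level seeds derive from the
master seed through a counter-based scheme (participant, trial,
stream), so growing the cohort never reshuffles existing trials.
Detuning is zero in the presets: the detuning estimator operates on
unimanual tapping frequencies and is exercised separately, because a
detuning of realistic magnitude in rad/s would dominate couplings of
order 1/s and unlock the phase entirely — matching detuning to coupling
scales would be an estimation exercise the available data do not
support.

## Problem sizes and determinism

Default analyses use 12-s trials (719 frames), 10-s analysis windows
(599 frames, 591 embedded points), 48-trial cohorts, 2000 CV
repetitions, and 50-seed Monte Carlo sweeps per condition in the
acceptance suite — sizes at which the full test suite and the
acceptance script each complete in a few minutes on a single CPU while
keeping Monte Carlo standard errors well inside the asserted margins.
All randomness flows through explicit integer seeds; identical
configuration and seed reproduce every output bit-exactly.

## Known limitations

- The simulator is phase-level; Δω enters the phase equation but the
  rendered hands share one carrier frequency.
- The LMM uses Wald inference without small-sample df correction,
  matching common practice for this design but slightly hot at n = 16;
  the blocked CV exists precisely to guard such conclusions.
- CRQA measures beyond %REC, Lmax, DRP and triangle asymmetry
  (DET, ENTR, trapping time, windowed variants) are out of scope.
- The pose-CSV reader expects the three-header-row dialect with one
  tracked point per hand; multi-point rigs need upstream reduction.
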