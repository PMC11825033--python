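# Methods

This note documents the models, algorithms and numerical choices behind
`cagelever`, what the synthetic-cage generator does and does not emulate,
and the known limitations of each analysis.

## Task model and scheduler

A trial is a lever pull sampled at 400 Hz over a 0–30° range. The *hold
time* is the duration of the first maximal contiguous run of samples
inside the 6–24° goal range, searched from the first sample at or beyond
the 3° registration threshold, truncated at 5 s. Using the *first* run
(rather than the longest) mirrors an online controller that must decide
the outcome as the hold ends; whether a hold may resume after the lever
re-enters the range is undefined in the task description, and the first-run
rule resolves it conservatively.

Stage 1 rewards any registered pull; a mouse advances to stage 2 the day
after its first ≥100-pull day. In stage 2 the nightly update (applied at
the midnight boundary) takes the 75th percentile — linear-interpolation
(type-7) percentile, the most common default — of *all* of the day's hold
times, successes and failures alike, and adopts it, capped at 1 s, iff it
exceeds the current requirement, the day had ≥100 trials, and its success
rate was ≥30%. A success rate below 10% marks a low day; two consecutive
low days reset the requirement to the *last benchmark*, interpreted as the
value in force immediately before the most recent upward update. A
zero-trial day counts as a low day — the reset rule exists to protect
hydration and motivation, and an absent mouse is the limiting case of an
unmotivated one. Ties at exactly the required duration count as success.
Stage-1 trials are excluded from stage-2 day summaries on the transition
day. Applying the same day summary twice is idempotent for the upward
path (the candidate no longer exceeds the new value); the low-day counter
is deliberately not idempotent, being a counter.

## Synthetic cage

The generator's purpose is verifiability: every analysis in the package
can be run against logs whose generating parameters are known.

**Timing.** Each agent enters the chamber as a Poisson process
(`entry_rate`, default 1.5/h; an arrival during an ongoing visit is
deferred to just after it, preserving daily counts). Each entry contains a
geometric number of trials (`bout_geom_p`; geometric is the discrete
analogue of the observed exponential bout-size decay), spaced uniformly
(10–60 s by default, so that 10-trial bouts can fall inside 5-minute
windows).

**Hold times.** Drawn from the same two-process mixture the analysis
fits: exponential (rate `kappa_schedule(day)`) with probability
`w_schedule(day)`, else Gaussian centered `timed_margin` (0.05 s) above
the current requirement with SD `sigma_t`, truncated at 0 and clipped at
5 s. The truncation is a generator-side nicety the untruncated fitting
model ignores; for fitted regimes (μ ≥ 3σ) the discrepancy is negligible.
The WT-like preset declines w linearly 0.9→0.4 over the run with κ = 4;
the HD-like preset holds w = 0.85 with κ declining 5→4 (hold times
lengthen only through the exponential tail), uses a slightly wider timed
SD (0.12 vs 0.10 s), jerkier trajectories (0.098 vs 0.077°, the scale of
the respective group means), more frequent entries and shorter bouts.
These presets reproduce the qualitative phenotype: the WT-like requirement
ratchets to the 1 s cap; the HD-like one plateaus near 0.4–0.5 s.

**Trajectories.** Each trial's lever trace is synthesized so that
re-scoring it with the task's own hold-time rule returns the sampled hold
to within one sample period — the closed loop is exactly self-consistent.
Three profiles are used, all built from a C³-continuous sigmoid so the
>10 Hz content of the noiseless movement is ≲0.005°:

- *plateau* (holds ≳0.45 s): rise to a plateau (uniform 10–20°), hold,
  mirrored return; the plateau is shortened by exactly the number of ramp
  samples inside the goal range (transit compensation);
- *peek bump* (shorter holds): a smooth bump whose amplitude is solved so
  that exactly `round(hold·fs)` samples lie at or above the 6° floor —
  physically, brief holds come from pulls that barely crest the range, not
  from impossibly fast full transits;
- *sub-goal bump* (zero hold): peaks 1° below the range.

Band-limited noise (white noise passed through the same >10 Hz filter the
jerkiness analysis uses, rescaled to sample SD `jerk_sd`) is added and the
trace clipped to 0–30°. The noise is zeroed where the noiseless trace lies
within `max(0.7°, 6·jerk_sd)` of the 6° floor so that noise can neither
split nor extend the scored run; keep `jerk_sd ≲ 0.3°`, beyond which that
margin falls under 6 SD. Consequences worth knowing: measured daily
jerkiness runs ~15–20% below the nominal `jerk_sd` (short, low-amplitude
trials have much of their length inside the suppressed zone), and relative
comparisons between agents are preserved. What the generator does *not*
emulate: biomechanics of paw movement, circadian structure (entries are
uniform in time), day-to-day autocorrelation beyond the schedules, and
any quantitative model of peer influence (see below). A green test on
simulated data establishes that the analysis recovers the construct it
targets, not that real mice behave this way.

**Peer influence.** Optional and off by default (`influence_gain = 0`).
When an agent starts a bout within 5 minutes of a completed ≥10-trial
bout by a peer whose bout success rate exceeded the agent's previous
bout's, the agent's w is reduced by `influence_gain` for that bout.
Modeling the effect as a w-reduction (more timed trials) rather than a
direct success increment routes it through the same measurement pipeline
used for everything else. This is a stand-in mechanism for testing the
motif detector, not a behavioral claim.

## Hold-time mixture

`p(x) = w·κe^{−κx} + (1−w)·N(x; μ, σ²)`, fit per mouse-day by maximum
likelihood on the raw stage-2 hold times (MLE rather than histogram least
squares: the model is probabilistic and per-day data are modest). The
optimizer is Nelder-Mead over transformed parameters (logit w, log κ, μ,
log σ), multi-started from w ∈ {0.2, 0.5, 0.8} with moment-based κ, μ, σ
guesses plus two perturbed variants, keeping the best; densities are
floored at 1e−300 against underflow. Days with fewer than 30 usable
trials are not fit (a 4-parameter model needs protection against
degenerate days); trials at the 5 s ceiling are censored out and counted.
Recovery at n = 2000 is unbiased to <0.03 in w with individual fits
within ±0.05 in ≥90% of seeds. Identifiability caveat: while the
requirement is near zero (first stage-2 days) the two components overlap
and ŵ is biased upward; it stabilizes once the requirement separates them
(≳0.2 s). The per-day fitted w therefore starts high regardless of
genotype — trends should be read from day ~3 onward.

## Jerkiness

Per trial: subtract the mean (exact DC rejection), apply a minimum-order
elliptic high-pass (10 Hz cutoff, ≥60 dB at and below 5 Hz, 0.1 dB
passband ripple) forward-backward for zero phase, and take the SD (n−1)
of the result. A single forward pass of a linear-phase Kaiser FIR with
its group delay removed is available as `mode="fir"`; SDs are
phase-insensitive, so the two agree within the attenuation bound. Trials
under 20 samples (0.05 s) are excluded as non-representative. The SD is
taken over the whole stored trajectory (the methods leave open whether
only the hold epoch was used; the whole registered pull is the stored
unit here). Edge transients of zero-phase filtering are second-order for
smooth signals but mean the attenuation spec should be probed with
phase-aligned sinusoids.

## Variability

DTW is the classic unconstrained dynamic program (unit match/insert/
delete steps, |Δangle| local cost), O(nm), numba-accelerated with a pure
Python fallback. DTW violates the triangle inequality; only identity and
symmetry are relied on. "Consecutive trials" means temporally adjacent
trials of the same mouse regardless of chamber entries (the event-aligned
windows additionally respect their stated spans). DTW and moving-SD
(centered, window 5, truncated edges, n−1) series are z-scored within
mouse and within analysis, since both scale with trial duration; a
zero-spread series is flagged degenerate rather than z-scored.

Event-aligned analyses: (1) requirement increases — the 5 trials before
and 15 after each upward change (crossing entries and, forward, day
boundaries); mice that never left the initial requirement are excluded;
(2) window bouts — first 10 trials of greedy, non-overlapping maximal
runs in which every trailing 10 trials span ≤300 s; (3) outcome runs —
maximal same-outcome runs of ≥5 trials contribute their first 5-trial
window only (no double counting) if it spans ≤150 s. Pair statistics are
assigned to the later trial of each pair. In replication mode all
analyses use the first 58 days in cage.

## Engagement

Daily trials, entries, mean time in chamber per entrance, trials per
entry, success rate (1-based day reporting, 58-day standardization in
replication mode). *Entry bouts* (trials within one chamber entry; Fig-3
sense) are deliberately distinct from *window bouts* (10-in-5-minutes;
variability sense); both are first-class. Bout-size histograms cap at a
configurable size (default 14) with larger bouts binned at the cap.

## Social motifs

For every ordered (follower, influencer) pair, the detector scans
time-sorted window bouts for baseline → influencer → return with each
bout ≥10 trials inside a 5-minute window and inter-bout gaps (next start
minus previous end) ≤5 minutes. "A similar number of trials" for the
influencer is operationalized as the same ≥10-in-5-minutes criterion.
Overlapping candidates are consumed greedily in time order without bout
reuse within a pair. Bout success rates use the first 10 trials of a
longer run by default (full-run SR is a switch). Influencers are *good*
iff their bout SR strictly exceeds the follower's baseline. Controls are
two consecutive bouts of one mouse with a 5–15 minute gap and no
intervening ≥10-trial bout by another mouse. The effect statistic is
`delta = (SR_after − SR_base)/SR_base`; zero-baseline events are excluded
from means and reported separately.

**Bias warning.** `delta` is a ratio estimator: under a true null with
independent bouts, `E[delta] = E[SR_after]·E[1/SR_base] − 1 > 0` strictly
(Jensen), ≈ `(1−p)/(10p)` for bout success probability p before
conditioning — and conditioning on a better-performing influencer selects
low baselines, inflating the bias several-fold (≈ +0.7 in simulated null
worlds, vs ≈ +0.24 for unconditioned controls). No choice of null world
with binomial bout successes removes it. Absolute mean deltas should
therefore never be read against zero; only contrasts that share the
conditioning (influence-on vs influence-off worlds, or good-influencer vs
matched-control comparisons at equal baseline distributions) are
meaningful. The package's own null-safety test documents this and is
expected to fail against a literal "mean delta ≈ 0" reading.

## Pipeline

`run_pipeline` executes engagement, mixture fits, jerkiness, the three
variability analyses and motif/control detection, writing one CSV per
analysis (9-significant-digit floats, fixed column orders) plus a
manifest (package version, seed, config, SHA-256 fingerprint of the trial
stream). Identical inputs and config reproduce identical bytes; the
session I/O layer likewise round-trips exactly (floats serialized with
`repr`, parsed with round-trip precision).

## Numerical and degenerate-input conventions

- SDs use the n−1 denominator throughout.
- Percentile: NumPy default linear interpolation (type 7).
- Empty data: NLL of an empty sample is 0; moving SD of a singleton
  window is 0; days without trials yield NaN metrics; a mouse with no
  events yields empty aligned series.
- Seeds: one `numpy.random.Generator` per simulation, consumed in a fixed
  agent/chronological order — a fixed seed reproduces the session log
  byte-for-byte after saving.

## Known limitations

- The mixture's Gaussian component is untruncated; fits where μ < 2σ
  (requirement near zero) are biased and flagged only by the reported
  per-day diagnostics (`gaussian_mass_below_zero`).
- The simulator's agents re-aim their timed process at a new requirement
  instantly; success-rate dips after requirement changes (seen in real
  learners with adaptation lags) must be constructed explicitly when
  testing the event-aligned analyses.
- Statistical inference (repeated-measures ANOVA, mixed-effects models,
  ICC) on the produced tables is out of scope; the package emits the
  per-mouse/per-day series those tools consume.
- Hardware-facing concerns (motor torque, tone synthesis, RFID I/O,
  original on-device log dialects) are out of scope; the documented
  CSV/YAML/HDF5 session format is the interface.
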