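# Methods

`ripplenf` simulates and analyses a closed-loop sharp-wave-ripple (SWR)
neurofeedback experiment end to end, entirely on synthetic data with known
ground truth. This note records the models, the parameter choices that
matter, the numerical decisions, and what the synthetic data do and do not
establish.

## The synthetic electrophysiology model

**Background LFP.** Each tetrode's trace is a stationary mixture of 1/f
("pink") noise and white noise, `sigma * (sqrt(f_p) * pink + sqrt(1-f_p) *
white)` with `sigma = 50 µV` and pink fraction `f_p = 0.85`, sampled at
1500 Hz. The pink component comes from a 3-pole/3-zero pinking IIR driven by
white noise, with the filter state carried across chunks so a session's
background is one continuous process however it is consumed. The mixture
guarantees a nonzero stationary ripple-band (150–250 Hz) baseline, which is
what makes SD-unit detection thresholds meaningful. Tetrodes are independent
given the seed; every stochastic element of a session derives from a single
seed, so sessions are bit-reproducible.

**SWR events.** An event is a Gaussian-windowed sinusoid: carrier frequency
drawn uniformly in 150–250 Hz per event, envelope SD equal to a quarter of
the event duration (durations uniform in 40–120 ms; no duration distribution
is established for this preparation, so the range is a free choice), added
coherently on all tetrodes with independent carrier phases (an SWR is a
network event; its envelope, not its phase, is shared).

**Event size calibration.** Ground-truth amplitude is expressed in the
units the *offline consensus detector* measures: SDs of the consensus trace
above its epoch mean. For batch injection the waveform height is solved by
a bracketed root search against the actual local background (the consensus
peak of `background + A*wave` over the event span is matched to
`epoch_mean + amplitude * epoch_sd`), which calibrates away phase
interference with the local in-band noise. The streaming generator inside
the task engine uses the closed-form power-additivity solution
`(A p_unit)^2 = target^2 - mean_power` instead (the future background is
not yet known when an event is drawn); this leaves a small (~+0.4 SD)
upward measurement bias from peak-picking over the event window, immaterial
for rate and ordering analyses. In both paths `p_unit` is the consensus
peak of the unit-height waveform *after* the offline band-pass, because the
filter attenuates off-center carriers by up to ~20%.

Single-event measurement noise is irreducible: at a fixed SD size the
event's power is independent of tetrode count, while the in-band background
it interferes with scales the same way, leaving ~±1–2 SD of scatter per
realization. Calibration accuracy is therefore a statement about the mean
over realizations.

**Event sizes and rates.** Sizes follow a shifted lognormal
(`2.5 + 5.0 * exp(1.7 Z)`): long-tailed, with larger events ever rarer. The
tail is deliberately heavy so that the *online* detector's envelope-SD
scale reproduces the regime the task presupposes — detection thresholds
ramping from 4 up to 16–20 envelope-SD units must remain reachable, with
trigger waits growing from seconds to tens of seconds. (The online SD scale
is compressed relative to consensus SD because the baseline deviation
statistic is inflated by the SWRs present in the rest-box calibration
stream, exactly as in a real system.) Event times are an inhomogeneous
Poisson process with state-dependent rates (defaults: moving 0.01/s,
pre-reward stillness 0.4/s, post-reward stillness 0.6/s, rest 0.3/s) and a
100 ms minimum inter-event gap enforced by thinning — note the thinning
reduces a configured rate `r` to `r/(1 + r*gap)`, which the task engine's
rate-equalization logic compensates for explicitly.

**Place cells and marks.** Thirty cells by default, Gaussian tuning curves
(width 8 cm, peak rates 10–25 Hz) whose centers tile the track bins. Tuning
falls off with *graph* distance, not linearized distance, so a field at the
end of one arm does not bleed onto the neighboring arm's linear
coordinates. Marks (4-channel waveform peak amplitudes) are multivariate
normal per cell, SD 20 µV per channel, with mean vectors rejection-sampled
to a minimum pairwise Mahalanobis separation of 6 so clusterless decoding
is feasible. Replay spiking traverses a path of track bins at
`compression × run speed` (20 × 30 cm/s by default) with rates boosted 8×
to emulate in-ripple bursting; fragmented ("no content") events get spikes
at random times with marks from random cells.

## Online detection (the closed loop)

The streaming detector reproduces the real-time computation: a causal
4th-order Butterworth band-pass (100–400 Hz), then two recursions on the
rectified filtrate `|x|` per tetrode:

* baseline: `mu(n) = mu(n-1)(N-1)/N + |x|/N` and
  `sigma(n) = (||x| - mu(n-1)| - sigma(n-1))/N + sigma(n-1)`, `N = 10000`
  samples. `sigma` is a smoothed absolute deviation, not a true standard
  deviation; "SD units" for online thresholds mean units of this statistic.
  The baseline runs on a rest-box stream, is frozen, and defines the
  epoch's thresholds `mu + k sigma`.
* envelope: `v(n) = v(n-1) + g (|x| - v(n-1))`, with `g = 0.2` while the
  envelope decreases and the mean of {1.2} ∪ {last 19 gains} while it
  increases — fast attack, slow decay. The envelope equation is read with
  its grouping restored (`v + g(|x| - v)`); the alternative literal reading
  (apply the previous step's gain) is available as a configuration switch.

Detection triggers when ≥ 2 tetrodes' envelopes exceed threshold at the
same sample. Initialization: gain history filled with 0.2, `v` and `mu`
seeded from the first sample, `sigma` from 0, so calibration is not
dominated by a startup transient. The batch driver replays the per-sample
recursion exactly: any chunking of the input yields bit-identical triggers
(the streaming kernel and the single-step reference implementation use the
same summation order).

## Offline detection

All analyses use the consensus trace: per-tetrode 150–250 Hz zero-phase
filtrate (forward-backward IIR; offline has no causality constraint and
unbiased boundaries matter), squared, summed over tetrodes, smoothed with a
4 ms SD Gaussian, square-rooted. Events are ≥ 15 ms excursions above
`epoch_mean + 2 epoch_sd`, extended to the nearest epoch-mean crossings;
overlapping extended spans are merged. Size is the maximum threshold at
which the event would still have been detected; length is end minus start.

Epoch statistics are, by default, iterated with detected event spans
excluded (to stability, ≤ 6 passes). With a long-tailed size distribution
the event-inclusive SD is inflated severalfold and detection of small
events collapses; the iterated exclusion converges to the clean-background
SD and restores recovery. The single-pass all-samples statistics remain
available (`exclude_events_from_stats=False`).

Two measured properties of this detector on the synthetic background are
worth knowing. First, Gaussian band noise with the 4 ms kernel produces
≥ 15 ms suprathreshold excursions at ~0.2–0.25/s — a genuine false-event
floor of the 2 SD / 15 ms rule, insensitive to tetrode count or the pink
fraction. Analyses that recover configured generator rates either restrict
to events ≥ 4 SD (which the floor cannot reach) or subtract a floor
estimate measured on event-free stretches. Second, detected boundaries are
systematically wider than the injected ±2-envelope-SD support (the
baseline-crossing rule extends into the envelope tails); the median
boundary error stays under 10 ms for events ≥ 5 SD.

## Task engine

The trial state machine follows the behavioral protocol: home poke →
center-port poke → pre-reward period → reward → post-reward dwell → arm
choice. On neurofeedback trials the pre-reward period ends at the first
online trigger, with reward following after the per-subject feedback delay
(75 ms default, range 50–100 ms). Delay trials draw their wait uniformly
from the last 8 neurofeedback trigger latencies (bootstrap: uniform 2–10 s
before any history exists), yoking total waiting time across port types.
The detection threshold ramps linearly across days from 4 SD to the day
maximum (itself ramping to 16–20 SD across 14–20 days, then stable) and
within each epoch over the first 10 neurofeedback trials. One of eight arms
pays a large reward; after a drawn quota of 4–12 rewarded visits the goal
moves to a different arm. Behavior comes from a parametric agent policy
(probability of returning to a known goal, probability of re-sampling a
searched arm, post-reward dwell distributions, head-speed levels per trial
type) whose knobs give the performance metrics controllable ground truth.

The simulator streams everything through one continuous clock: background
noise, the event overlay (waveforms may straddle chunk boundaries; events
are drawn one waveform-half ahead so no emitted sample is ever revisited),
the causal online filter, and the envelope recursion all carry state across
chunks. Two small discretization effects follow and are accepted: events
within ~90 ms of a period boundary are drawn at the neighboring period's
rate, and the streamed period may overrun a trigger by up to one chunk
(250 ms); both are <5% effects on period rates.

The wait-time prediction analysis bins center-port SWRs by size (1 SD bins,
bins with < 10 events dropped) into occurrence rates over total port time;
the predicted wait for a trigger of a given size is the reciprocal of the
summed rate of all tabulated bins at or above its bin (a threshold fires on
the first event at-or-above it; the per-bin alternative is available), with
a 200-trial moving average for trend curves.

## Decoding

Clusterless decoding on the linearized maze (5 cm bins over home segment,
central corridor, and eight arms; 2-D positions project to the nearest
skeleton segment, ties to the lower-indexed segment). Per tetrode the
encoding model is a product-Gaussian KDE of the joint mark×position
intensity (mark bandwidth 20 µV, position bandwidth 5 cm, graph distances),
built only from movement samples (> 4 cm/s); the ground intensity is spike
density over occupancy. The 2 ms-bin likelihood is the Poisson
marked-point-process form; a `1e-10` uniform intensity floor prevents
zero-likelihood collapse for marks outside training support.

The latent movement model has two states: *continuous* (equal probability
of staying or stepping to any graph-adjacent bin — junction bins have 3+
neighbors) and *fragmented* (uniform over all bins). The 2×2 state coupling
defaults to diagonally dominant (stay 0.98): a literal uniform coupling
makes sustained-state classification meaningless, so the uniform 0.5/0.5
matrix is a configuration option rather than the default. The posterior is
acausal (forward-backward) by default; each forward/backward step exploits
the kernel structure (sparse one-bin walk; rank-one uniform jump) so the
smoother is O(n_bins) per time bin and matches exhaustive path enumeration
to 1e-10 on small instances. Priors are uniform; every time bin is
normalized.

Movement-decoding validation excludes each decoded spike's own kernel
contribution from the joint-intensity evaluation (leave-one-spike-out). The
occupancy and ground-intensity terms retain the spike — a 1/n effect that
is negligible at the spike counts used and keeps the fold evaluation O(1).

## Replay classification and the GLM

An event is *interpretable* if the time-averaged probability of the
continuous state exceeds 0.8 (strict) and at least 30% (inclusive) of the
time-averaged posterior density lies in one maze segment; a
pointwise-minimum variant of the 0.8 rule is available. Interpretable
events are *local* if the dominant segment is the animal's current segment,
*remote* otherwise. Remote-replay rates per trial period exclude the NF
trigger event by default, consistent with the timewise rules.

The arm-category model is a Poisson GLM of per-trial, per-arm replay counts
on three binary predictors — previous arm (preceding trial's choice),
future arm (current trial's choice), previous goal arm (preceding block's
goal) — over search and repeat trials from the second goal block on (so a
previous goal always exists). Categories overlap additively. Coefficients
exponentiate to fold changes with exponentiated Wald intervals; a predictor
with no variation is reported non-estimable rather than fitted.

## Statistics layer

Within-subject comparisons use two-sided rank-sum tests with
Benjamini-Hochberg step-up correction across the comparison family.
Groupwise comparisons fit a mixed model with fixed cohort-group effects
(control as reference) and a subject random intercept: Gaussian for rates,
dwell times, amplitudes and proportions (a known simplification for bounded
proportions), Poisson (variational Bayes, normal-approximation p-values)
for counts. When the between-subject variance is near zero the mixed
optimizer can fail or go singular; the model then falls back to OLS with
subject-clustered standard errors and says so in its flags. Sign tests are
exact binomial; pre/post correlations are Pearson with t-based p. Head
speed is smoothed with a 250 ms SD Gaussian before averaging; speed
quartiles are rank-based with ties broken by trial index. Events map to
trial periods by peak time.

## The two-cohort experiment

The end-to-end study runs a manipulation cohort (interleaved NF and yoked
delay trials) against a control cohort (random delays), 4 subjects each, 60
trials per session, with per-subject lognormal rate multipliers (SD 0.08).
Configured pre-reward injection rates are 1.2 / 0.6 / 0.3 events/s for
NF / delay / control — a 2× NF-over-delay effect, with absolute levels set
well above the detector's ~0.25/s false-event floor so the contrast is
resolvable at these session lengths. Total center-port rates are equalized
*by construction*: after each pre-reward period the post-reward injection
rate is solved per trial so the trial's total injected rate hits the common
target (0.8/s), with the thinning compensation above. The NF pre-reward
duration is set by the closed loop; its expectation is estimated from a
short open-loop calibration at the experiment threshold (10 online-SD) and
used to give the control cohort a comparable delay range.

The recovered effect is estimated per subject as the ratio of NF to delay
pre-reward rates of events measured ≥ 4 SD with the suprathreshold
exclusion applied to both trial types (removing the structural bias that
every completed NF trial ends with exactly one suprathreshold event), then
averaged. The ≥ 4 SD restriction removes the false-event floor without
floor arithmetic; because the size distribution is common to both trial
types, the restriction cancels in the ratio. The expected recovered value
is slightly below the configured 2.0 — the minimum-gap thinning compresses
the higher NF rate a little more (`thinned(1.2)/thinned(0.6) ≈ 1.89`).

## Problem sizes

Validation studies use: 10-minute sessions with 150 injected events for
detector recovery; ~600 closed-loop trials per threshold and a 12000 s
open-loop stream for the renewal comparison (a power choice: ~5% standard
error on each mean-wait/renewal ratio). The renewal study shares a single
rest-box calibration between its closed-loop and open-loop halves: per-epoch
recalibration — the default, and what the real system does — moves the
frozen thresholds by a few percent in µV per epoch, which the steep size
tail amplifies into double-digit trigger-rate differences, and the
waits-versus-prediction comparison is only meaningful at a common threshold.
Decoding validation uses a 30-cell, ~8-arm-traversal session
(~10 min of movement) for decoding; 100 replay and 100 scrambled events for
classification; 100 GLM simulations at 500 trials; 150 null simulations for
mixed-model calibration. The reproduction script (`scripts/acceptance.py`)
uses moderately smaller sizes of the same designs.

## What passing tests do and do not show

The generator emulates the statistical skeleton the analyses rely on —
state-dependent long-tailed event rates, in-band transients on a stationary
1/f background, place-field spiking with separable marks, time-compressed
replay, the task's trial structure. It does not emulate: nonstationary or
artifact-laden LFP, electrode drift, theta/movement rhythms, bursting and
refractory spike statistics, overlapping mark clusters, or an agent that
*learns* the neurofeedback contingency (rates are imposed, not learned).
Passing the suite therefore certifies the computations — the detectors, the
closed loop, the decoder, the statistics — not the biology; real-data
effect sizes, false-positive floors and classification accuracies will
differ. The mixed-model Wald tests are also known to be slightly
anticonservative at few subjects (type-I ≈ 0.07–0.10 at 8 clusters), which
is why the calibration check runs at 16 clusters.
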