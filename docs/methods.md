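# Methods

## Task model and geometry

The maze is a 75 × 75 cm square with two 20 × 20 cm reward ROIs at opposite
corners and two 8 × 20 cm threat ROIs at the other corners; each path
between the reward sites passes through exactly one threat ROI. ROI
rectangles are half-open (closed on the lower edges, open on the upper), so
no point can belong to two adjacent rectangles; ROI entry is the first
tracked sample strictly inside the rectangle. The standard schedule is
fifteen daily sessions: pre-training T1–T5 (no threats), probabilistic
P1–P5 (75 % / 25 % per path), random R1–R5 (50 % / 50 %); a deterministic
variant uses 100 % / 0 %.

## Behavioral measures

**Laps.** A full lap runs reward exit → threat-site pass → the other
reward site; a half lap returns to the same reward site. A reward-to-reward
excursion that never enters a threat ROI is not a lap. Re-entries into the
same threat ROI within 2 s of exiting it are merged into one visit
(tracking jitter at ROI borders; configurable). Puff/LED log timestamps
are attributed to the nearest threat-site entry within ±500 ms — wide
relative to the 100-ms hardware delay between entry and puff, tight
relative to inter-lap intervals. Half laps count in the adaptive-choice
denominator and are included in speed analyses (the latter is an
assumption; source descriptions do not state it).

**Speeds.** Speed is the first-order finite difference of position with no
smoothing — the 500-ms averaging windows already suppress frame jitter; an
optional moving-average flag exists for noisier tracking. Approach
(pre-entry) and reaction (post-entry) speeds average the 500 ms before and
after threat-site entry. The fast/slow median split is computed per
session over laps with valid speeds; ties at the median go to "fast" so
that "slow" is strictly sub-median. Whether the split should instead pool
sessions was an open choice; per-session matches the session-wise framing
of the behavioral analyses and is the default.

**Expectation labels.** Slow approach ⇒ threat expected. Hence
fast + threat and slow + omission are *surprising*; slow + threat and
fast + omission are *expected*.

## Event-aligned calcium analysis

Traces (nominally 20 Hz) are aligned to threat-site entries over −1…+2 s in
half-open 100-ms bins (bin 11 is the first post-entry bin and spans
entry → puff onset). Per lap type, binned activity is averaged across laps
*first* and then z-scored by the mean and SD (ddof = 1, i.e. the sample SD)
of the 10 baseline bins of that average; a per-lap z variant is available
behind a flag for sensitivity analyses. Cells whose baseline SD is zero
for a required lap type are excluded from that analysis, not imputed.
Response magnitude = mean z over bins 11–15. Outcome responders use
magnitude > 2 strictly (a symmetric < −2 criterion for suppressed cells is
available; the positive-going criterion is the stated one, symmetry is an
assumption). Threat lap types exclude LED-stimulation laps so that
learning-related activity is not confounded with direct stimulation
effects; the LED-effect analysis itself uses the omission / puff /
puff+LED triple and compares per-cell evoked changes between cohorts with
a two-sample KS test. Differential activity d_threat and d_omission
subtract expected-outcome from surprising-outcome magnitudes; thresholding
both at ±2 yields the signed-PE (Up–Down, Down–Up) and unsigned-PE
(Up–Up, Down–Down) classes, with Threat-only / Omission-only when a single
outcome differentiates and "none" otherwise. Category proportions carry
exact Clopper–Pearson limits (α = 0.05); the between-group comparison
tests one group's count against the other group's proportion as the null
rate with an exact binomial test.

## Choice-history analyses

Post-outcome switching: per session, among threat-delivered laps on the
conditioning path that have a following lap, the proportion whose next lap
is on the low-threat path; sessions with fewer than two qualifying laps
are discarded, and cohort tables use only mice with usable data in all
five probabilistic sessions. History correlation: laps are concatenated
across the five probabilistic sessions with no window reset at session
boundaries; for each path, the rolling threat probability at lap *i* is
the mean outcome over the last k visits to that path strictly before *i*
(undefined until k visits exist), and Pearson r with the standard
two-sided t-transform p-value is computed between choice code and
estimate, per k = 1…50 and per path (path-specific estimates, since threat
probability is a property of a path). No multiplicity correction is
applied across k — the criterion is "significant at any window length" —
so the per-window false-positive rate, not the familywise rate, is the
calibrated 5 % quantity; both are reported by the acceptance script. The
group contrast counts significant mice per group and compares them with a
1-df chi-square without continuity correction.

## Statistics

RM and mixed ANOVA use the classical univariate split-plot decomposition
(documented in `stats.py`): each within-subject effect is tested against
its own subject-interaction stratum; between-group sizes may differ
(weighted-means solution, matching `aov`-style strata). Sphericity is
assessed per within factor with Mauchly's test (chi-square approximation
with the second-order term); Greenhouse–Geisser ε (bounded to
[1/(k−1), 1]) always accompanies the table, and the corrected p supersedes
the uncorrected one when Mauchly p < 0.05 — the common package default;
the trigger is configurable since sources rarely state theirs. Note that
the correction raises p only when F ≥ 1; for F < 1 shrinking both dfs can
lower p, which is why the monotonicity property is only asserted for
detectable effects. Tukey HSD post hocs use the RM error mean square with
the studentized-range distribution. The 2×2 chi-square omits the Yates
correction by default (flag available).

## Synthetic data generator

The generator is a test harness with known ground truth, not a claim about
mice.

**Agent.** Rescorla–Wagner per-path threat values V ∈ [0, 1], V ← V + α·PE
with PE = outcome − V (positive for unexpected threats, negative for
unexpected omissions), separate learning rates per PE sign (default 0.3
each, the canonical mid-range rate); softmax choice
p(path) ∝ exp(−V/τ) with τ = 0.25 (produces ~85–90 % low-threat preference
at asymptote under 75/25, in the range adaptive cohorts reach); approach
speed = 30 − 20·V + N(0, 2²) cm/s, floored at 5 cm/s, so expectation and
speed are linked with comfortably separable fast/slow modes; reaction
speed = 30 + 10·PE + noise, giving faster escapes after surprising threats
and sluggish re-acceleration after surprising omissions; 60 laps per
session (sessions ran 15–20 min or until 60 laps); 5 % half laps. The
*override* mode models choice decoupled from integrated history: switch
paths after every threat, coin-flip otherwise; its stationary low-threat
preference is ≈ 0.58, and its stay-after-surprising-threat probability is
0 — the qualitative contrast between control and terminal-stimulated
cohorts.

**Tracking.** Laps are rendered as piecewise-linear trajectories through
ROI centers at 30 Hz, running at base speed except for an
approach-speed stretch covering the 500-ms pre-entry window (plus margin)
and a reaction-speed stretch after entry, with a ~2-s jittered dwell at
reward sites between laps. Puff/LED events are stamped 100 ms after
entry. Re-segmenting the rendered tracking reproduces the planted lap
structure exactly, and the speed windows recover the scheduled speeds to
within the 33-ms sampling discretization.

**Calcium.** Each cell is Gaussian baseline noise (SD 0.25) plus
event-locked double-exponential transients (rise 50 ms, decay 500 ms —
GCaMP6f-like; only relative amplitudes matter after z-scoring). Amplitude
laws: outcome cells fire a fixed amplitude on their path × outcome laps
(scaled by an LED gain on stimulated laps in "opsin-like" cohorts);
signed-PE cells scale with PE (negative PE ⇒ a dip); unsigned-PE cells
with |PE|; expectation cells ramp over the pre-entry second in proportion
to V. Every cell also replays a fixed, smooth "approach-corridor tuning"
template at each entry (SD 0.0625, tapering with τ = 150 ms after entry).
This models the stereotyped spatial/locomotor activity of prefrontal cells
on the run-up to a maze corner, and it is load-bearing for realism: with
purely independent noise the baseline SD of a lap-averaged trace collapses
as 1/√laps, z magnitudes become implausibly large, and the 10-bin SD
estimate injects multiplicative noise that can cancel or even flip the
surprising-minus-expected differential when lap counts differ between
types. A repeated template keeps the baseline scale finite and shared
between the lap types of a cell, as in real recordings.

**What the generator does not emulate:** photon/shot noise and motion
artifacts, cross-session cell registration drift, biophysical calcium
dynamics or spiking, within-session nonstationarity of coding, and
correlated noise across cells. Passing planted-truth tests therefore shows
the analysis chain is correct and well-calibrated under realistic
amplitude/noise structure — not that real-data effect sizes will match.

## Problem sizes and calibration runs

Cohort analyses use 10 simulated mice per group at 60 laps per session.
Planted-PE recovery uses 100-cell populations (20 % signed-PE, 10 %
unsigned, 30 % outcome, 10 % expectation, 30 % silent) at transient
SNR 4, on five probabilistic sessions of 80 laps from a balanced-sampling
agent (τ = 5, α = 0.1) so that every expectation × outcome lap type has at
least 15 laps — the regime in which the ±2 differential criterion is
well-posed. Null calibration of the any-k rule uses 3,000–5,000
outcome-independent mice at 300 laps; integration-window recovery uses 60
mice at 2,000 laps with a planted k★ = 5 rule and asserts the peak of the
group-averaged |r|(k) within k★ ± 1. Value-convergence checks average
eight 2,000-lap runs after a one-session burn-in.

## Known limitations

- The lap segmenter assumes at most one threat-ROI excursion between a
  reward exit and the next reward entry (guaranteed by the generator;
  real tracking with pathological mid-lap reversals across both threat
  sites would attach the lap to the first threat visit).
- The mixed ANOVA supports one between-subject factor (with unequal group
  sizes) and up to two within-subject factors — the designs used here;
  it is not a general factorial engine.
- Pearson-based history correlation is linear; a logistic lag-regression
  would be the model-based alternative and is deliberately out of scope.
- With very unequal lap counts across lap types, the per-type z scaling
  makes differential activity conservative; the classifier is validated
  in the ≥ 15 laps/type regime.
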