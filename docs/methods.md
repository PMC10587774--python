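# Methods

`hfoprime` implements an inter-ictal analysis chain for intracranial EEG
(iEEG): detection and classification of high-frequency oscillations (HFOs)
and epileptiform spikes, statistics of HFO→spike temporal coupling
("priming"), peri-event unit firing models, and resection-cohort
localization metrics. Because clinical recordings of this kind are not
openly deposited, the package ships a synthetic-cohort generator with known
ground truth; every stage is validated against that ground truth or against
an independent oracle.

## Signal model and event taxonomy

Events fall into five classes. Ripples (80–200 Hz) and fast ripples (FR,
200–600 Hz) occur either on the background oscillation (`RonO`, `fRonO`) or
superimposed on an epileptiform spike (`RonS`, `fRonS`); spikes without an
HFO are `SharpSpike`. A fast ripple on oscillation *primes* a spike when
its onset precedes the spike onset by strictly less than 300 ms; `fRonS`
and `RonS` are *followed* when a `fRonO`/`RonO` onset lies strictly within
300 ms before them. Times are seconds, intervals half-open `[start, end)`,
sample `i` covering `[i/fs, (i+1)/fs)`.

## Stage-1 detection (`detect`)

Each channel is band-passed with a zero-phase FIR filter (windowed-sinc,
transition width 15% of the low band edge, applied as a single centred pass
of the symmetric kernel) in the ripple and FR bands, plus a 20–70 Hz band
used only to seed sharp-transient candidates. The analytic envelope is
converted to a robust z-score against the median/MAD of the envelope inside
artifact-free epochs. A candidate is an envelope excursion above `z_mid`
(default 1.4) that reaches a peak above `z_hi = 3` and advances at least
`min_cycles = 3` oscillation cycles of analytic phase; its boundaries are
then extended outward to the surrounding `z_lo = 1` excursion so onset
timing is not biased by the peak threshold. Candidates within 10 ms merge.
The peak criterion cannot carry the cycle count itself: at realistic
signal-to-noise ratios a Gaussian burst stays above three MAD-scaled z for
only a fraction of its duration, so requiring three cycles strictly above
`z_hi` rejects most genuine events. Counting cycles over the `z_mid`
excursion keeps the false-positive rate on event-free 1/f noise below
0.3 candidates/min per band while recovering ≈ 91% of injected HFOs at a
12 dB in-band SNR (≈ 99% at 15 dB); these two figures are frozen as
regression bounds in the test suite.

Artifact rejection masks samples whose broadband MAD-z exceeds 8 or whose
slew rate exceeds 300 µV/ms, each with a 50 ms guard; flat or saturated
channels (MAD = 0) are excluded entirely, and 250 ms at each record edge is
ignored against filter transients.

## Stage-2 wavelet-contour classification (`tfclassify`)

Each candidate is windowed ±500 ms and transformed with L1-normalised
Morlet wavelets (7 cycles) on a 64-point log-spaced 60–650 Hz grid; with L1
normalisation a sinusoid of amplitude *a* yields power ≈ a²/4 at any centre
frequency, so ripple- and FR-band events are compared on one scale. The
contour analysis runs on the map cropped to the candidate ±100 ms so that
the power threshold reflects this event rather than a stronger neighbour
inside the analysis window.

Iso-power contours are traced at ten evenly spaced levels starting at
`0.2·(max − min) + min` of the (cropped) map. A contour is a closed-loop
contour (CLC) exactly when its first and last vertices coincide, otherwise
an open-loop contour (OLC). Closed contours are grouped by mutual nesting
(point-in-polygon containment, transitively closed); each group surrounds
one local power maximum and is equivalent to a connected component of the
suprathreshold mask whenever that component's outermost contour is closed —
the test suite asserts this equivalence exactly against an independent
pixel-labelling oracle. A CLC group is accepted as an HFO only if its mean
vertex frequency is ≥ 80 Hz and it spans at least 4 of the 10 ladder levels
(a blob that merely grazes the threshold is background).

Classification rules:

* CLC group present and no qualifying spike OLC earlier → `RonO`/`fRonO`;
* CLC group present and a spike OLC starting > 10 ms before the group's
  outermost-contour onset, reaching within 50 ms of it → `RonS`/`fRonS`;
* only OLCs → `SharpSpike`.

A spike-qualifying OLC must be rooted at low frequency (minimum vertex
frequency ≤ 80 Hz): epileptiform sharp transients are broadband with power
rising toward the low-frequency map edge, which cuts all their contours
open, whereas an edge-truncated HFO's open fragment stays in-band. "Onset"
of a contour is the minimum time coordinate of its vertices. Ripples and
fast ripples split at exactly 200 Hz on the CLC-group mean frequency;
peak frequency and power come from the largest iso-power contour value in
the group, duration and onset/offset from the group's outermost contour.
When several CLC groups qualify, the group with the largest iso-power
contour value wins. Duplicate events from overlapping candidate windows
are collapsed (same channel and class, > 50% overlap; a `SharpSpike` fully
explained by an overlapping `RonS`/`fRonS` is dropped).

At a 15 dB SNR the full stage-1 + stage-2 chain labels synthetic events
with ≈ 95% five-way accuracy; residual ripple/FR confusions occur only for
events within one frequency-grid step (≈ 3.9%) of the 200 Hz boundary.

## Coincidence statistics (`coincidence`)

For each HFO on oscillation the latency to the next spike is the minimum
strictly positive `spike_onset − hfo_onset` within the channel (a spike at
exactly the HFO onset does not count). The coincidence statistic is the
number of HFOs with latency < 300 ms. Its null distribution is obtained by
redrawing the channel's HFO onsets uniformly within that channel's
artifact-free epochs — spike onsets fixed, per-channel HFO counts
preserved, surrogates unrestricted with respect to overlaps — 500 times by
default; the pooled statistic sums per-channel counts, with surrogates
drawn independently per channel. Reported are `z = (obs − mean)/sd` of the
surrogate distribution and a two-sided empirical p with add-one correction,
`p = (1 + #{|surr − mean| ≥ |obs − mean|})/(n + 1)`. Only onsets are
resampled since only onsets enter the statistic. Under the independence
generator the test's type-I rate at |z| > 1.96 is within 3 percentage
points of 5% over 200 cohorts; injected coupling at `p_prime = 0.5` yields
pooled z far above 3.

## Event-locked unit firing (`unitfiring`)

Each (event, unit-on-the-same-contact-bundle) pair yields a trial: a 2 s
binary raster at 1 ms resolution centred on event onset (trials that would
overrun the recording are dropped), convolved with a unit-area Gaussian
kernel with σ = 100 ms truncated at ±4σ (so the series is in Hz and the
pre-decimation integral equals the spike count exactly), then downsampled
to 40 Hz by taking every 25th sample. From the 40 Hz series: `bl_fr` is
the mean over [−750, 0) ms, `hfo_fr` the maximum over [0, duration]
(inclusive; clamped to the window end with a logged warning), and
`hfodiff_fr = hfo_fr − bl_fr`. The kernel width is read as σ = 100 ms
(not FWHM): the method targets event-scale rate modulation, not fine
temporal structure. Flat series resolve their argmax to the earliest
sample.

Units that do not modulate their firing during a given event class are
excluded before modelling: a paired t-test of `bl_fr` vs `hfo_fr` across
trials within each unit, Holm–Bonferroni step-down across units within the
class at α = 0.001 (zero-variance differences give p = 1 and exclusion).
The step-down is verified exactly against a brute-force implementation.

Note that `hfo_fr` is a maximum over a noisy series, so `hfodiff_fr` has a
positive bias even for unmodulated Poisson trains; group contrasts and the
mixed models, not the raw value, carry inferential weight. The firing-rate
recovery test quantifies this: its oracle is the closed-form mean and
covariance of the smoothed, 40 Hz-sampled Poisson rate (Gaussian kernel
integrals of a piecewise-constant intensity), with the expectation of the
in-window maximum evaluated from that normal law.

## Mixed models (`glmm`)

Responses (`hfodiff_fr` or `bl_fr`) are fit with a Gaussian identity-link
linear mixed model: fixed intercept, up to three fixed effects among
log10 event power, pre-spike status, followed-by flags and unit type, up to
four interaction terms, and crossed random intercepts for unit, contact and
patient (identifiers are globally unique, so crossed and nested coincide).
Estimation is maximum likelihood through `statsmodels` MixedLM with one
variance component per identifier; constant factors are dropped with a
warning, and with no random terms the model reduces to ordinary least
squares (verified against a direct solve to 1e-6). Parameter recovery on
simulated trials at n = 5000 gives 95% CI coverage ≥ 90% over 20 seeds for
both the power slope and the prespike×power interaction. Fixed-effect
p-values are Wald tests; variance components estimated at the boundary are
reported as such via the convergence flag.

## Localization (`localization`)

Within each patient, the SOZ (resection) ratio of an event class is the
fraction of its events on SOZ-flagged (resected) contacts. The
rate-distance graph takes per-contact rates (events/min over artifact-free
minutes) of `fRonS` plus `fRonO` with peak frequency above 350 Hz; the
edge weight between two contacts is the mean of their rates times their
Euclidean distance in mm. An edge exists only when **both** contacts have
positive rate: under the alternative (either-positive) reading any quiet
contact near the active focus acquires the graph's minimum eccentricity
and the radius difference below becomes systematically undefined, so the
both-positive reading is the only one under which the construct behaves as
intended. The weight matrix is read directly as a distance matrix;
eccentricity is the maximum finite entry per node, the radius the minimum
eccentricity, computed once over all contacts and once over resected
contacts only, and
`radius_difference = √(radius_all − radius_resected)` (negative arguments
return missing with a flag — the measure presumes the resected set contains
the graph's central node). Smaller values mean less residual FR-generating
tissue after resection. Group comparisons between seizure-free (Engel 1)
and not-seizure-free patients use Wilcoxon rank-sum tests.

## Synthetic cohorts (`synth`)

Background is unit-normalised 1/f (pink) noise scaled to 25 µV broadband
SD plus a 50 µV slow wave at 0.5–2 Hz, emulating non-REM sleep iEEG.
Events per channel are homogeneous Poisson streams: background `fRonO`
(1.5/min), `RonO` (2/min) and epileptiform spikes (3/min, split 20%
`fRonS` / 70% `RonS` / 10% sharp, close to the clinically observed
proportions). HFO bursts are Gaussian-windowed sinusoids (window σ =
duration/5) whose duration is drawn as 8–16 oscillation cycles clipped to
20–100 ms; centre frequencies are uniform on 80–200 Hz (ripples) and
250–500 Hz (fast ripples) so that a burst's spectral mass stays inside its
nominal band. Spikes are biphasic difference-of-Gaussians transients
(sharp lobe σ = 4 ms, rebound σ = 16 ms, 50–100 ms overall) at 14 dB above
the broadband SD; `fRonS`/`RonS` add an HFO burst 5–20 ms after spike
onset. HFO amplitude is `10^(snr_db/20)` times the median analytic
envelope of the band-filtered background — the detector's own scale — so
`snr_db` is honoured where it matters.

Priming: with probability `p_prime` a spike receives an extra `fRonO` at a
latency uniform on (0, 300] ms (optionally locked below a few ms),
amplitude-multiplied by `power_gain_prespike`; `soz_priming_enrichment`
concentrates priming on SOZ contacts while preserving the cohort mean, and
`nonsoz_suppression` deletes chance pre-spike `fRonO` on non-SOZ contacts
to emulate below-chance coupling outside the SOZ. Spike and background-fRonO
rates accept analogous SOZ enrichments. Under `focal_topology` the non-SOZ
share of spikes and background fast ripples concentrates on a compact
secondary cluster mirrored across the origin from the primary SOZ focus
(epileptogenic networks are multifocal; intervening tissue is quiet), which
is what gives the rate-distance radius its discriminating geometry.
`resection_coverage` sets the fraction of SOZ contacts inside the
resection. Unit trains are inhomogeneous Poisson: baseline rate everywhere,
scaled inside HFO windows by `1 + gain·log10(power)` and inside spike
windows by `unit_spike_gain`, implemented by additive extras/thinning so
the baseline marginal is exact. One `numpy` Generator drives everything;
a fixed seed reproduces the cohort bit for bit.

What the generator does **not** emulate: measured iEEG spectra, sleep
architecture, muscle/electrode artifacts (beyond optional test pulses),
spatial propagation of HFOs across channels, non-Poisson event clustering,
and AP waveform shape (spike sorting is upstream of this package). Passing
tests therefore demonstrate correctness of the analysis under the stated
statistical model, not detector performance on real recordings.

## Problem sizes

The validation suite runs at desk scale, chosen to keep every Monte-Carlo
estimate's standard error well inside its acceptance margin: surrogate
calibration uses 200 cohorts of 96 contacts × 10 min at event level;
coupling power 50 seeds of 16 contacts; classifier fidelity two rendered
cohorts of 4 channels × 5 min (≈ 260 events); firing recovery 500 trials;
mixed-model recovery 20 seeds at n = 5000; the localization cohort 20
patients × 24 contacts. The full suite completes in about two minutes on
one CPU.

## Known limitations

* Stage-1 thresholds are config defaults calibrated on the generator, not
  a re-implementation of any specific published detector.
* Sharp spikes closely preceded (< ~100 ms) by a fRonO can be absorbed
  into the HFO's analysis window and lost as separate events; pre-spike
  fRonO at latencies under ~15 ms may classify as `fRonS` (physically they
  are on the spike).
* The surrogate z is reported with a two-sided empirical p; discreteness
  of small counts makes the normal z slightly conservative at low event
  rates.
* MixedLM variance components with few levels (patients) are weakly
  identified; fixed-effect inference is the supported use.
* The rate-distance radius is presence-driven: a single remote active
  contact dominates it regardless of rate magnitude. This is a property of
  the construct, inherited by design.
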