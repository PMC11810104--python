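# Methods

## Scope and shape

The package re-implements, as a seeded and tested pipeline, the analysis
chain used to detect sensorimotor mismatch responses in layer-2/3 calcium
imaging and to test multimodal supralinearity. It starts from extracted
per-neuron fluorescence: image registration, ROI selection, neuropil
correction and spike inference are out of scope. Because the original raw
recordings are not bundled, a first-class synthetic generator produces
closed-loop VR sessions with ground-truth neuron labels; all claims the test
suite makes are therefore claims about *recovery of known structure*, not
about any particular biological dataset.

## Synthetic sessions (`synthgen`)

**Behavior.** Running bouts start as a Poisson process (default 3/min),
last Gamma-distributed ~12 s, ramp up/down within 0.7 s and hold a plateau
speed drawn from 5–40 cm/s with slow ±20% fluctuation; stationary periods
are 0 cm/s. These defaults give roughly half the session spent running,
enough running onsets for onset-triggered averages, and ~15–20 eligible
mismatches per 600-s session.

**Coupling.** Sound level follows running speed through one of two maps,
both satisfying map(0) = 0 (silence) and map(30 cm/s) = 60 dB SPL:
`linear_pressure` (sound *pressure* proportional to speed, so
dB = 60 + 20·log₁₀(v/30), floored at 0) — the default — and `linear_db`
(dB proportional to speed). Both are exposed because "amplitude
proportional to speed" and the reported dB endpoints are not mutually
consistent on one scale; no claim is made that either is the original
apparatus map. Visual flow is proportional to speed (gain 1 per cm/s).
Loop delays are realized as nearest-frame shifts at 15 Hz: 260 ms → 4
frames (audiomotor), 90 ms → 1 frame (visuomotor); optional Gaussian jitter
is off by default.

**Mismatches.** Candidate halt commands form a homogeneous Poisson process
with a 15-s mean interval. A candidate becomes an event only if the animal
ran (> 0.3 cm/s) throughout the 1-s window preceding the halt onset, so
every logged halt removes an actually present input; halts force the coupled
trace to 0 for 1 s and never overlap. Concurrent [AM+VM] halts issue one
command to both streams, each delayed by its own loop lag, so the visual
halt leads the auditory one by 3 frames (~200 ms at 15 Hz, the discretized
version of the ~170 ms lag difference); events are timestamped at the AM
halt onset and carry the lead.

**Open-loop replay** copies the sensory traces verbatim (halts relabelled
as playback halts), generates fresh uncoupled behavior, and regenerates
fluorescence from the same ground-truth neurons under the replayed traces.

**Neurons.** Rate model per neuron:
`rate = ⌊b + w_run·v − w_sound·s + w_vis·f + m⌋₊` where the explicit
prediction-error drive `m` is `mm_amp_am` during closed-loop AM halts,
`mm_amp_vm` during closed-loop VM halts, and `g·(mm_amp_am + mm_amp_vm)`
where both halts co-occur. Two deliberate asymmetries: (i) subtractive
prediction-error units (`am_mismatch` class) get both an emergent relief
response — the −w_sound·s term disappears during any halt, including
playback — and the explicit closed-loop drive; playback halts get the
relief only, because the motor-based prediction does not exist without the
coupling. This is what makes mismatch > playback, as a pure linear
subtraction cannot distinguish the two once baselines are subtracted.
(ii) the drive is sustained for the whole halt rather than gated frame-wise
on running; eligibility is already enforced at injection, and frame-wise
gating only injected session-level behavioral variance into amplitude
estimates. Class defaults (rates in Hz, jittered ±20% across neurons):
silent b≈0.5; motor w_run≈0.1; sound-excited w_sound≈−0.03, b≈0.4;
sound-inhibited w_sound≈0.03, b≈1.5; visual w_vis≈0.08; subtractive
prediction-error w_run≈0.1, w_sound=w_run/2 (so inhibition roughly balances
excitation at coupled levels), b≈1.5, mm_amp≈2.5; concurrent-selective
mm_amp=0.05 with g=60 (undetectable unimodal, strong concurrent).

**Fluorescence.** Poisson spikes per frame (rate/fs) convolved with a
single-exponential kernel, τ = 0.6 s (a GCaMP6f-like decay; the indicator's
kinetics are not otherwise specified), plus a slow additive drift (Gaussian
random walk low-passed below ~0.05 Hz, amplitude 2 F-units — slow enough
that the 66-s percentile filter must remove it), Gaussian noise
(SD 0.2 F-units) and an offset of 100 F-units. ΔF/F responses of ~1 Hz rate
changes are then ~0.3–3%·s, a realistic regime for the drift filter and
trial averaging to matter.

## Preprocessing (`preprocess`)

The drift baseline is the moving 8th percentile of the raw trace in a
centered 66-s (990-frame) window, truncated (not padded) at the session
edges; percentiles interpolate linearly between order statistics, the numpy
convention, which the brute-force test oracle shares. ΔF/F is
`(F − baseline(t)) / median(F)`. The denominator uses the raw-trace median
(not the baseline trace): it makes F₀ a single per-neuron number, and the
result is invariant under per-neuron gain. The same filter with a 62.5-s
window drives the widefield variant, which labels the top few percent of
pixels per stimulus with their argmax stimulus. The numerator-choice is
logged in each bundle's manifest so results are auditable. The rolling
percentile is computed by an incrementally maintained sorted window (numba,
with a plain-numpy fallback); both paths are exact, not approximations.

## Events and inclusion (`events`)

All windows in the package are half-open `[start, end)` at frame
resolution; frame k covers `[k/fs, (k+1)/fs)`. A running onset is the first
frame at or above 3 cm/s (previous frame below) whose preceding 3-s mean is
below 1.8 cm/s; no extra refractory period is imposed beyond what that
pre-mean implies. Trials are `running` if the mean speed in the 1-s
pre-onset window exceeds 0.3 cm/s (strictly; exactly 0.3 is `sitting`).
Events are excluded if they lack 2 s of preceding or 3 s of following
recording, if fewer than two events of their type survive in a session, or
— for running onsets — if the mean speed over the following second is below
3 cm/s ("short bout"). Every event ends up included or excluded with a
named reason.

## Responses (`responses`)

Trial tensors span [−2, 5) s around each included event at frame
resolution; each trial × neuron is baseline-subtracted by its own mean over
[−0.5, 0) s, so the baseline-zero invariant holds by construction (asserted
at 1e-9). Windows select frames whose centers fall inside them; the scalar
response is the mean over [0.5, 2.5) s, averaged over trials. Concurrent
[AM+VM] trials are aligned to the AM halt onset. Split-half displays sort
neurons by odd-trial responses and show even-trial means (interleaved
halves cancel slow drift), smoothed over 10 adjacent neurons. Top
responders are the ⌈fraction·N⌉ neurons with the largest |response|, ties
broken by index; nested fractions (5/10/20%) are supported. Open-loop
correlations are plain Pearson correlations of ΔF/F with the stimulus and
running traces over all frames, no lag compensation. The behavioral control
compares trace means in [0.5, 1) s vs [−0.5, 0) s per trial. Note one
generator-borne subtlety: because halts are only injected after 1 s of
running, the post-onset speed regresses slightly downward by selection, so
the running-speed "control" can reach significance on long runs without any
planted coupling — on real data the same selection effect exists.

## Hierarchical bootstrap (`hierboot`, `calibration`)

Each replicate draws S sites with replacement (S = number of sites), then
within each drawn site as many neurons with replacement as the site
contributed (an equal-counts variant is available by flag), and records the
grand mean. p is the fraction of replicates violating the directional
hypothesis; ties (difference exactly 0) count as violations, so degenerate
all-zero comparisons give p = 1 rather than a spurious 0. Two-sided p is
2·min(p_gt, p_lt) capped at 1. Paired comparisons bootstrap the per-neuron
differences; unpaired comparisons resample each group independently with a
content-keyed stream, which makes swapping the groups mirror the p-values
exactly. Time-resolved tests average traces in consecutive 5-frame (333 ms)
bins, share the resample draws across bins, and apply no multiplicity
correction across bins — faithful to per-bin significance bars, and
deliberately liberal; treat isolated significant bins accordingly.

Measured calibration under a two-group two-level null (5 sites × 40
neurons, 1000 datasets, n_boot = 1000): rejection at α = 0.05 is ~0.011 at
τ = 0 (conservative: with flat data the site level double-counts sampling
noise), ~0.08–0.10 at τ = 0.5·σ, and ~0.10–0.13 at τ = σ (the bootstrap
underestimates the 5-site variance by the (S−1)/S factor). A flat
neuron-level bootstrap on the same τ = σ data rejects ~0.65–0.69 — the
hierarchy is not optional. Power at τ = 0.5·σ rises from ~0.19 (0.25σ
effect) through ~0.36 (0.5σ) to ~0.88 (1σ). With only five clusters no
resampling scheme is perfectly calibrated; the residual miscalibration at
the τ extremes is reported, not hidden.

## Supralinearity (`nonlinearity`)

The linear-sum prediction is the pointwise sum of each neuron's mean [AM]
and [VM] traces. Because concurrent trials are aligned to the AM onset
while the VM halt leads by 3 frames, summing own-onset-aligned traces
mismatches the timing and biases the measured ratio low by ~15% (the VM
drive partly leaves the response window and enters the baseline); the
pipeline therefore shifts the unimodal VM tensor 3 frames earlier
(re-baselining afterwards) before summing — a lag-compensation choice
exposed as `RunConfig.lag_compensation` and in
`linear_sum_traces(vm_lead_frames=...)`, with the uncompensated sum
available by turning it off. Population supralinearity is tested pairwise
(concurrent vs AM, vs VM, vs sum) with the hierarchical bootstrap, and the
interaction gain is estimated as mean(R_concurrent)/mean(R_sum). Per-neuron
selectivity uses a trial-level percentile bootstrap of the windowed response
against 0 (two-sided, α = 0.05, 1000 draws); [AM] and [VM] trials are not
naturally paired, so summed per-trial responses use a seeded random pairing
truncated to the smaller trial count. At ~15 trials per condition this
bootstrap is mildly anti-conservative (~8–13% false positives instead of
5%), which inflates every selectivity category symmetrically; the planted
concurrent-selective fraction is still recovered within a few percentage
points. The per-neuron significance rule behind published selective-fraction
figures is not specified anywhere authoritative; this rule is one reasonable
choice, and the fractions it yields are not treated as reproduction targets.

## Problem sizes and determinism

Default study conditions: 15 Hz, 600-s sessions, 5 sites × 40 neurons
(10 sites × 50 for the supralinearity recovery, which averages over weaker
per-neuron signals), n_boot = 1000 for Monte-Carlo calibration loops and
pipeline presets — the scalar tests are insensitive to raising this, and
10⁴ replicates remain the single-test default in `hboot_test`. Every stage
seeds its own `numpy` generator through `SeedSequence` fan-out from one
run-level seed; identical config + seed ⇒ byte-identical stats JSON.

## Known limitations

The generator's neurons are linear-rectified rate units with iid noise: no
within-site correlated variability beyond what the hierarchical test is
being calibrated against (site effects enter the calibration module, not
the VR generator), no adaptation, no tuning curves beyond a single gain per
modality, no pupil model (the pupil channel is a passthrough), and no
mouse-generated ambient sound. Passing recovery tests therefore shows the
*analysis* is correct and well-calibrated under the model's assumptions; it
does not certify behavior on real data with motion artifacts, neuropil
contamination, or non-Poisson firing. ΔF/F nonlinearity of the indicator is
not modeled, so supralinearity recovered at the rate level translates to
fluorescence only approximately — the same caveat the calcium-imaging
literature attaches to spiking nonlinearity claims.
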