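# Methods

## Scope and data model

`meanet` analyzes one well of an 8×8 multiwell-MEA plate.  The central
object is the `SpikeTrainSet`: 64 sorted per-electrode timestamp arrays
(seconds) with a recording duration, as produced by acquisition-software
spike exports or by the package's own detector.  Derived objects —
`BurstSet`, `ConnectivityGraph`, `StimulationLog`, `PSTH` — carry the
results of the successive stages.  All estimators operate per well; plates
are lists of wells, and no cross-well statistic is computed.

## Estimator conventions

**Active electrodes.** An electrode is active when it fires at least
`min_rate` = 5 spikes/min (the common multiwell-MEA convention).  The
criterion is a parameter everywhere it is used.

**MFR and MBR denominators.** Mean firing rate (Hz) and mean bursting rate
(burst/min) are *network-wide* means over all 64 electrodes unless an
explicit electrode mask is given.  This choice is forced by arithmetic: any
electrode passing the 5 spikes/min criterion fires at ≥ 0.083 Hz, so a mean
over criterion-passing electrodes can never equal the ~0.06 Hz network
rate characteristic of an immature well.  Network-wide means describe a
sparse well with a few strongly firing electrodes correctly; per-active
means are available by passing the active mask.

**Burst detection.** Max-interval method: a burst is a maximal run of
consecutive spikes with all inter-spike intervals ≤ `max_isi` = 100 ms and
at least `min_spikes` = 5 spikes.  Both parameters are exposed; the
implementation is pinned to an exhaustive run-scan oracle in the tests.

**Network bursts.** The recording is binned at 25 ms; a network burst is a
maximal run of bins in which ≥ 25 % of the active electrodes are inside a
single-electrode burst, reported with its distinct participant count.

**Connectivity.** Spike counts are binned at `bin` = 25 ms (exposed; short
against burst time-scales, long against spike jitter) and correlated with
Pearson's r.  Zero-variance rows (silent electrodes) get r = 0 by
convention, avoiding undefined divisions; the diagonal is 1.  Edges join
distinct active electrodes with r ≥ 0.3, a fixed-threshold binarization.
A shuffle-calibrated threshold was considered and rejected for the default:
a fixed r keeps developmental comparisons on a common scale, and the
threshold is a single exposed parameter.

**Topology.** Degree, edge count and nodal clustering
`C_i = 2·T_i/(k_i(k_i−1))` (0 for degree < 2) are computed directly from
the adjacency matrix.  Hubs are nodes with degree above mean + 1 SD of the
degrees of connected nodes (population SD); a regular graph has no hubs.
The rich-club coefficient φ(k) is the edge density among nodes of degree
> k, reported where at least two such nodes exist; the normalization
divides by the mean φ over 100 degree-preserving double-edge-swap
randomizations (10·E attempted swaps each, seeded).  Graphs whose swap
space is exhausted (e.g. complete graphs) use the original graph as its own
null, which preserves the degree sequence trivially.

**Evoked responses.** Spikes in a window of [−0.1 s, +0.5 s] around each
stimulation onset are pooled over electrodes and re-referenced; spikes in
the artifact window [0, 2 ms] are removed.  The PSTH bins each event's
network spike count at 5 ms, converts to rate, and reports the across-event
mean with an across-event 5th/95th-percentile envelope per bin (the
percentile envelope is computed across events, the natural reading for
event-to-event variability).  The network response duration uses a
baseline-return rule: the cutoff is mean + 2 SD of the pre-onset bin rates,
and the duration runs from onset to the first post-peak bin at or below the
cutoff that opens ≥ 3 consecutive sub-baseline bins (persistence guards
against single-bin dips).  A PSTH that never exceeds the cutoff has
duration 0; one that never returns within the window reports the window
end.  Because spontaneous synchrony can merge into the evoked tail of a
single session, the headline duration is reported as the mean over five
independent 60-stimulus sessions.

**Assay utilities.** Relative expression uses the 2^−ΔΔCt convention with
the mean ΔCt per condition before exponentiation; per-sample folds against
the control-mean ΔCt are returned as well, so either dispersion convention
(SD of folds, or propagated ΔΔCt error) can be reported.  Intensity
thresholding subtracts mean + 2 SD of pooled background samples and clips
at zero; co-expression is the percentage of a-positive cells that are also
b-positive.  Image segmentation is upstream of these functions.

## Spike detection

Detection is adaptive threshold crossing.  The noise SD is estimated per
non-overlapping 10 s window as `median(|x − median(x)|)/0.6745`, the
MAD-based estimator consistent for Gaussian noise and insensitive to the
spikes themselves.  A spike is the extremum time of each excursion beyond
±6× the local SD (extremum rather than first-crossing timestamping is
stable against threshold jitter); both polarities are detected, and events
within a 1 ms dead time of an accepted spike are discarded, which also
collapses the two phases of a biphasic waveform.  The contract is fixed by
a round-trip property — ≥ 95 % recall and ≤ 5 % spurious detections on
synthesized 12.5 kHz traces with waveforms at 10× the noise SD — rather
than bit-compatibility with any vendor implementation, whose window and
dead-time parameters are not public; both parameters are exposed.

## The synthetic generator

The generator emulates the statistics the pipeline assumes, not biophysics:
no membrane dynamics, no electrical field model of the stimulation pulse.

Each developmental preset drives, per active electrode, a superposition of

1. a homogeneous Poisson background (`rate_active`, Hz);
2. an independent Poisson burst process (`burst_rate`/min; a burst is 5
   spikes at 5 ms intervals) — these carry the detected bursting rate;
3. **network bursts**: a global Poisson process (`netburst_rate`/min) whose
   events recruit each active electrode with probability `participation`;
   recruited electrodes fire a simultaneous 12-spike burst.  These create
   the epochs the network-burst detector finds;
4. **synchronous volleys**: a faster global Poisson process
   (`sync_rate`/min) recruiting electrodes with probability
   `sync_participation · w_e`, where `w_e` is a persistent per-electrode
   propensity (2·Beta(2,2), mean 1).  A volley is 2 spikes — deliberately
   below the 5-spike burst criterion — so volleys shape the pairwise
   correlation structure (and, through `w_e`, the degree heterogeneity that
   produces hubs) without inflating burst counts.

Separating synchrony into channels 3 and 4 is the key design decision.  A
single network-burst process strong enough to push pairwise correlations
past the 0.3 edge threshold contributes a shared burst-count variance that
scales with the square of the recruited population, swamping the
between-stage MBR differences; sub-burst volleys decouple the correlation
structure from the burst statistics.  Intra-burst intervals are regular by
default (simple oracle arithmetic); Gaussian ISI jitter is an exposed
option.  Inactive electrodes fire Poisson noise at 0.02 Hz, so the
active-electrode criterion is exercised rather than trivially satisfied.

**One seed, one culture.** All randomness flows through per-purpose streams
keyed by (seed, purpose, electrode/event): the electrode permutation that
orders activation, the propensities `w_e`, the global event-time pools and
the per-event recruitment draws, with counts drawn by inverse-CDF.  Two
presets simulated under the same seed therefore describe the same virtual
culture at two ages — active sets nest, event pools share prefixes,
recruitment sets nest as participation grows — so developmental
trajectories are coherent realization by realization, as they are when one
well is recorded repeatedly.

**Calibration.** The DAI8 and DAI21 presets solve the analytic identities

    MFR = [n_active · (λ + (burst spikes)/60) + (64 − n_active) · 0.02] / 64
    MBR = n_active · (burst_rate + netburst_rate · participation) / 64

for the endpoint statistics (DAI8: 5 active, 0.06 Hz, 0.17 burst/min;
DAI21: 64 active, 0.89 Hz, 1.13 burst/min), where burst spikes sum the
per-electrode spike budgets of channels 2–4.  DAI14 and DAI17 interpolate
every parameter linearly between the endpoints (the trajectory between the
endpoints is only qualitatively constrained, so the interpolated presets
are conventions, not fits); DAI5 is a sparser, slower stage below DAI8.
The volley channel (`sync_rate` 0.5 → 20/min, `sync_participation`
0.1 → 0.45) was set so the thresholded graph is empty at DAI8 and reaches a
few hundred edges at DAI21, with the intermediate stages in between.

**Stimulation model.** Onsets at 0.2 Hz; after onset + 5 ms latency every
active electrode's rate is raised by `response_peak · exp(−t/τ)` with
`response_peak` = 50 Hz and τ = 15 ms (the kernel decays below 5 % of its
peak within 45 ms, so the modeled network response resolves well inside
100 ms); spikes within 2 ms of an onset are blanked as the stimulation
artifact.  The biphasic pulse shape (500 µs per phase, 160 µA peak-to-peak)
is carried as metadata only.  Raw traces are rendered at 12.5 kHz as
Gaussian noise plus a stereotyped biphasic waveform (dominant trough,
0.4×-amplitude rebound) inserted at each spike time, with the
sample-quantized insertion times kept as ground truth.

**What the generator does not emulate.** Real recordings have
non-stationary rates, electrode drift, irregular burst envelopes,
propagation delays within network bursts, waveform diversity and unit
overlap; the generator's processes are stationary, its bursts regular and
its network events instantaneous.  Passing tests therefore demonstrate that
the estimators recover the statistics of a network with the stated
first- and second-order structure — not that they are robust to every
artifact of real data.

## Numerical choices and degenerate inputs

Timestamps are float seconds throughout; converters for integer sample
indices at a given sampling rate live in the I/O layer.  Binning is
half-open `[t, t + bin)` with a final-bin clip, so totals are conserved.
Pearson correlations are computed from centered sums with a symmetrization
and a [−1, 1] clip to suppress floating-point asymmetry; the zero-variance
convention r = 0 keeps silent electrodes edge-free.  Empty masks give MFR
and MBR of 0; fewer than two spikes give an empty ISI list and a NaN pooled
mean; a graph with no qualifying degree level yields an empty rich-club
map.  The response-duration rule requires pre-onset bins and raises
otherwise.

## Problem sizes

The test suite and the acceptance script use 10-minute, 64-electrode
recordings (the recording length the presets are calibrated for), 20 seeds
per endpoint, 20-seed developmental sweeps, and five 60-stimulus
sessions; the whole suite runs in well under a minute of compute plus
statistical checks.

## Known limitations

* The intermediate presets (DAI5, DAI14, DAI17) are linear conventions
  between calibrated endpoints, not fitted stages.
* The per-electrode burst rate of the immature preset is higher than the
  mature one's (2.17 vs 1.13 burst/min): with only 5 of 64 electrodes
  active, matching the 0.17 burst/min *network* rate requires concentrated
  activity.  Network-level statistics order correctly; per-electrode ones
  need not.
* The rich-club normalization uses independent swap chains per replicate;
  for very dense or very sparse graphs the swap space is explored unevenly
  and φ_norm is noisy at extreme k.
* The evoked-response duration estimator measures the network's return to
  baseline, so strong spontaneous synchrony shortly after a stimulus is
  attributed to the response; the across-session mean is the stable
  summary.
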