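# Methods

`clasdelta` implements the signal-processing core of closed-loop auditory
stimulation (CLAS) for anesthesia: a real-time δ-wave detector that
phase-locks brief sounds to ongoing slow activity on a single frontal EEG
channel, the stimulus itself, a synthetic propofol-like EEG generator with
exact ground truth, and the offline analysis suite (δ-wave morphology,
evoked-response sham subtraction, wPLI/dPLI connectivity, graph metrics,
EEG microstates). This note records the models, the numerical choices, and
the places where the design was genuinely open.

Throughout, "δ-waves" covers slow oscillations (<1 Hz) and slow waves
(1–4 Hz) together, spanning 0.1–4 Hz; times are in seconds, samples are
0-based, condition intervals are half-open `[onset, onset + duration)`, and
amplitudes are in μV.

## Online detection

### Filter chain

The detector sees the raw channel through a causal chain: a linear-phase
(symmetric) FIR low-pass followed by a short moving average, collapsed into
a single kernel for streaming. The budget is a combined group delay of at
most 20 ms at 500 Hz (≤10 samples). With the default 8 ms moving average
(4 samples, 1.5 samples delay) the longest odd FIR is 17 taps (8 samples
delay), giving 19 ms total.

A kernel this short cannot place a −3 dB corner anywhere near 4 Hz — the
impulse response spans only 40 ms, so the mainlobe is ≳11 Hz wide no matter
the design. The `lowpass_cutoff_hz` parameter (default 4 Hz) is therefore
the *equiripple passband edge*, with a stopband edge defaulting to 22 Hz
above it; the realized chain passes the δ band essentially untouched
(|H| = 0.9995 at 0.5 Hz, exactly 1 at DC after kernel normalization) and
attenuates 30 Hz to 0.8%. What matters for phase-targeting is the delay
bound, which is met with a 1 ms margin; the chain is not, and cannot be, a
brick-wall δ filter.

### Trigger criteria

In-phase mode (peak-locked) fires when, on the filtered signal:

1. the signal falls below −40 μV (arming); the trough is the running
   minimum since arming, refined to sub-sample precision by a parabolic
   fit through the minimum sample and its neighbours;
2. the signal crosses 0 μV upward (crossing time linearly interpolated);
3. the current value exceeds the tracked trough by more than 75 μV
   (strict inequality; evaluated on the filtered signal);
4. the wave's trough-to-peak latency lies in [500, 2000] ms.

Condition 4 is the one place where the criterion as stated refers to an
event (the peak) that has not happened yet at trigger time. Evaluating the
*elapsed* time at the trigger instead would make the upper bound bind at
the wrong place: on a downward frequency sweep, symmetric waves would
still trigger at their zero-crossing until the quarter-period exceeded
2000 ms, accepting half-periods up to 4000 ms and breaking the intended
0.25–1 Hz selectivity. The implementation instead *projects* the peak
latency causally from wave symmetry: predicted trough-to-peak time =
2 × (trough → upward zero-crossing), checked once at the crossing. On
symmetric waves this equals the true half-period exactly, so the window
binds at 500 and 2000 ms precisely; the trigger still fires on the
up-slope (first sample after a valid crossing that clears the swing
criterion and the 500 ms minimum elapsed time). A ±0.25 ms tolerance (an
eighth of a sample at 500 Hz) guards the window comparisons against
floating-point jitter in the sub-sample estimates; it is a numerical
guard, not a loosening of the criterion.

After a trigger, detection is suspended until the filtered signal next
crosses 0 μV, and re-arming requires a fresh excursion past the arming
threshold — together these enforce at most one trigger per wave.

Anti-phase mode (trough-locked) is the exact mirror image and is
implemented by running the same machine on the negated stream, restoring
the extremum's physical sign in the emitted event. Sham mode runs the
in-phase machine identically but marks events *virtual* and delivers no
sound. The protocol's sham is silent; virtual markers are logged anyway
because the evoked-response analysis subtracts sham-locked averages from
stimulus-locked averages, which is impossible without time-locked sham
markers.

The machine is strictly sample-driven: its event stream is invariant to
chunk size (tested at 1, 7, 64, and whole-signal chunks), and a separate
vectorized offline implementation of the same criteria serves as the
equivalence oracle in the tests.

Phase annotation is post hoc: the raw channel is zero-phase filtered to
0.1–4 Hz (Butterworth order 4, forward–backward, 20 s padding) and Hilbert
transformed (10 s reflection padding — both paddings matter, the 0.1 Hz
edge has multi-second transients); convention 0° = upward zero-crossing,
90° = positive peak, 180° = downward crossing, 270° = trough. On clean
sinusoids in-phase triggers land at ~4° (crossing plus 19 ms filter delay);
on noisy waves phases scatter a few degrees either side of 0°, still
inside the 270°–90° delivery window. Because the trigger fires at the
zero-crossing-plus-swing moment rather than at the peak, the machine
realizes the [0°, 90°] part of the nominal 270°–90° window (the pre-crossing
part is unreachable once a zero-crossing is required first).

## Stimulus

The auditory stimulus is a 50 ms diotic burst of pink noise (power ∝ 1/f,
synthesized by spectral shaping of seeded random phases) with 5 ms
raised-cosine onset/offset ramps; the interior spectrum falls 10 dB/decade
over 100 Hz–10 kHz. "Binaural" is implemented as two identical channels:
no interaural difference is specified. The 65 dB SPL ceiling is carried as
metadata only — SPL depends on the transducer chain — while the digital
peak is governed by `level_dbfs` (default −3 dBFS). Ramp shape was open
("rising and falling slope"); raised-cosine was chosen for its continuous
derivative at the boundaries. WAV output is 16-bit PCM stereo.

## Synthetic EEG generator

The generator produces a δ process as a chain of alternating
negative/positive half-sine half-waves. Each half-period is drawn uniformly
from [1/(2·f_high), 1/(2·f_low)] so the wave frequency 1/d lies in
`delta_freq_range`; each half-wave's extremum amplitude is drawn lognormal
with arithmetic mean `delta_amp_mean_uv` and coefficient of variation
`delta_amp_cv`. A half-wave chain rather than filtered noise was chosen so
that every wave has *exact* zero-crossings and extrema — the generator's
wave table is an exact oracle for the offline segmenter (boundaries agree
to within one sample on noise-free input) and for detector scoring.

The per-channel amplitude gradient (default linear 1.0 → 0.3 across the
montage) emulates the frontal predominance of anesthetic slow activity.
The background is 1/f^exponent noise (spectral shaping of seeded white
noise, exact slope control — a log-log PSD fit over 1–40 Hz recovers the
exponent to ±0.1), scaled to `noise_rms_uv` per channel, independent
across channels.

Defaults describe a desk-scale propofol-like regime chosen once: 32
channels at 500 Hz (the clinical rig records 128 channels; channel count
is fully configurable and tests run with fewer), waves of 0.25–1 Hz, 80 μV
mean extremum amplitude with CV 0.25 (peak-to-peak ≈ 160 μV, comfortably
above the 75 μV online gate), pink background (exponent 1.0) at 10 μV RMS.

Nociceptive arousal is modelled as a multiplicative suppression of the δ
component inside a time window (`1 − suppression`, default suppression
0.6): nociception transiently disrupts slow-wave dynamics, but no
quantitative nociception model is published, so the magnitude is a free
parameter. The protocol scenario lays out the full block schedule —
in-phase 180 s, pause 20 s, anti-phase 180 s, pause 20 s, sham 180 s, then
pre-pain 60 s, pain 30 s (δ suppressed), post-pain 300 s; 970 s total.

What the generator does *not* emulate: traveling-wave propagation and
channel-to-channel lags (all channels share one δ chain at zero lag),
evoked responses to the stimulus (triggers do not feed back into the
signal), burst suppression, artifacts, and non-stationarity beyond the
pain window. Passing tests therefore demonstrate the correctness of the
detection and analysis machinery against known ground truth, not clinical
performance on real anesthesia EEG; in particular the connectivity
analyses see a null (common-drive) network by construction.

## Offline preprocessing

Channels listed in the drop list are removed (bad-channel detection is
manual; no automatic criterion is published), the data are zero-phase
band-passed 0.1–50 Hz (Butterworth order 6 forward–backward — order chosen
so mains-range content at 60 Hz is attenuated >20 dB in steady state while
the δ passband is flat to 0.2%), and re-referenced to the common average.
Zero-phase filtering offline is deliberate: morphology and phase metrics
must not inherit a filter delay (the online chain is causal by necessity).
Average referencing is idempotent and leaves the per-sample channel mean
at numerical zero. Segmentation cuts one sub-recording per labelled
condition (pauses excluded) on half-open sample intervals, so segments
never overlap or fabricate samples.

EDF I/O: recordings are written as EDF+C (16-bit, 1 s records, per-channel
symmetric physical scaling, conditions encoded as a standard TAL
annotation signal) by the package's own writer, and read back through
MNE's EDF reader — reader and writer are independent implementations, so
the round-trip test cross-checks both. EDF stores whole records;
non-integer-second recordings are zero-padded to the next full second on
write.

## δ-wave morphology

A wave is delimited by three consecutive zero-crossings of the δ-filtered
trace — downward, upward, downward — enclosing a negative then a positive
half-wave (matching the in-phase detector's trough-then-peak polarity).
Crossing times are linearly interpolated between samples; a transition
onto an exact zero that then holds (an isolated wave in silence) counts as
a crossing at the zero sample; extrema are taken at the sample-level
extremum. With V_e1, V_e2 the extremum values, t_e1, t_e2 their times
relative to the first crossing, and d the wave duration:

* amplitude A = |V_e1 − V_e2|
* frequency F = 1/d
* slopes |V_e1|/t_e1, A/|t_e1 − t_e2|, |V_e2|/(d − t_e2)
* transition frequency F_trans = 1/(2|t_e2 − t_e1|)
* density = waves per second over the full duration.

On a pure sinusoid of amplitude A₀ and frequency f these reduce to
closed forms (amplitude 2A₀, frequency and transition frequency f, all
three slopes 4A₀f), which the tests verify to <1%.

The retention gate keeps waves of 0.25–10 s (inclusive, with a half-sample
guard so grid-aligned boundary durations are not lost to rounding). No
amplitude gate is applied by default — the 75 μV swing criterion belongs
to the online detector, and the morphology formulas apply to every
detected wave — but an optional peak-to-peak gate is available. The
pre-segmentation filter band defaults to 0.1–4 Hz and may be disabled
(`band=None`) when the input is already δ-limited; note that the 0.1 Hz
zero-phase corner visibly reshapes waves of ≥8 s, whose fundamental sits
at or below the corner, so gate-boundary measurements on synthetic waves
are made with the filter disabled.

Band power is a Welch estimate (20 s segments, Hann) integrated over the
topography bands δ 0.1–4, θ 4–8, α 8–13, β 13–30 Hz; bands whose low edge
cannot fit two cycles in the segment are reported absent with a warning.
ROI aggregation averages any per-channel table over a channel→ROI map.
Evoked-response isolation averages stimulus-locked epochs (−0.5 to +1.0 s)
and subtracts the virtual-sham-locked average; epochs crossing the
recording bounds are dropped and counted; baseline correction is off by
default (a flag enables it) since the subtraction already removes the
shared ongoing component.

## Connectivity and graphs

Both phase indices are computed from the analytic signal: each epoch is
zero-phase band-passed (Butterworth order 4) and Hilbert transformed, and
the expectation is pooled over all time points and epochs — the Hilbert
route is used for both estimators so that wPLI and dPLI describe the same
phase series. Connectivity bands are δ 1–4, θ 4–8, α 8–14, β 14–30 Hz
(the α edge differs from the 8–13 Hz topography table; both tables are
exposed).

* wPLI_ij = |E{ℑ(C_ij)}| / E{|ℑ(C_ij)|}, with C_ij(t) = Z_i(t)·conj(Z_j(t));
  symmetric, in [0, 1], insensitive to zero-lag coupling. Pairs with
  identically zero imaginary cross-spectrum (e.g. identical signals) are
  undefined and reported 0 with a flag.
* dPLI_ij = E{H(φ_i − φ_j)} with H the Heaviside step (H(0) = 0.5), phase
  differences wrapped to (−π, π]; dPLI_ij + dPLI_ji = 1, diagonal exactly
  0.5; >0.5 means channel i leads.

A statistical caveat the tests respect: 60 s of 1–4 Hz band-limited data
contains only ≈ B·T ≈ 180 effective complex samples, so a single null
wPLI draw has mean ≈ 0.08 but scatters up to ≈ 0.3. The null checks
therefore bound the Monte-Carlo *level* (mean across seeds < 0.15 for
wPLI; within [0.45, 0.55] for dPLI), with wider per-seed sanity limits.

wPLI matrices are thresholded into binary undirected graphs by keeping the
top `keep_proportion` of off-diagonal weights (default 0.2 — no published
threshold exists, so a sensitivity sweep over 0.1–0.5 is provided); the
edge count is round(p·n(n−1)/2) and ties break lexicographically, so the
graph is deterministic. Graph metrics (networkx): global efficiency (mean
inverse shortest path over ordered pairs, disconnected pairs contribute
0), mean local clustering (0 for degree <2), greedy-modularity Q,
small-worldness σ = (C/C_rand)/(L/L_rand) against seeded degree-preserving
surrogates (≈100 double edge swaps per edge; L is averaged over connected
pairs), node degree, and betweenness (raw unnormalized pair counts, so the
brute-force oracle comparison is exact). Tests verify efficiency,
clustering, and betweenness against exhaustive brute force on *every*
labeled graph of ≤5 nodes plus 2000 seeded 6-node graphs (full 6-node
enumeration is 32768 graphs and adds nothing but runtime), and confirm by
exhaustive partition search that the two-triangle graph's maximal
modularity is 0.5 and that the greedy search attains it.

## Microstates

Global field power is the across-channel standard deviation of the
average-referenced topography; GFP peaks (local maxima ≥10 ms apart by
default) supply the maps for clustering. Templates come from a modified
k-means that ignores polarity: assignment maximizes squared spatial
correlation, and each cluster's template is the dominant eigenvector of
its members' covariance (the polarity-invariant analogue of the mean).
Four classes, 20 restarts, best by global explained variance, fully
seeded; runs that empty a cluster (e.g. identical input maps) are flagged
degenerate. Classes are numbered in GEV order — no attempt is made to
identify them with the canonical A–D topographies, which would require a
reference atlas. Back-fitting labels every sample by squared spatial
correlation with no temporal smoothing (ties go to the lowest class);
negating the recording changes nothing. Temporal statistics come from
runs of identical labels: mean duration, occurrence (runs/s), coverage
(sums to 1), and a transition matrix over consecutive distinct runs (rows
with any outgoing transition sum to 1; a single-run sequence has an
undefined matrix, returned as None with a flag). The GFP band was
unspecified; the module operates on whatever filtering the input carries
(the pipeline feeds it the 0.1–50 Hz preprocessed recording).

## Pipeline and reproducibility

A YAML config with one global seed drives simulate → detect → preprocess →
analyze; the seed fans out to per-stage seeds through a counter, stage
outputs land in a run directory with a manifest of input hashes and a log,
and re-running a config reproduces every output bit-exactly (EDF headers
use a fixed date for this reason). Block-wise detection maps each
condition to its detector mode (the pain-phase blocks run in-phase, as in
the protocol's second part). The pipeline's end-to-end test runs the full
970 s schedule at desk scale (4–8 channels, δ band, reduced null-model
count) twice and compares output hashes.

## Known limitations

* The detector's condition-4 projection assumes trough→peak ≈
  2×(trough→crossing); strongly asymmetric waves are accepted or rejected
  by their projected, not realized, half-period — the only causal option.
* The generator's zero-lag common drive makes wPLI on synthetic data a
  null case by construction; directed propagation is out of scope.
* dB SPL calibration, audio hardware latency, and amplifier integration
  are out of scope; the stimulus module guarantees the digital waveform
  only.
* EDF output quantizes to 16 bits over each channel's own range
  (relative error ≤ ~3·10⁻⁵ of full scale per channel).
* Microstate class identities (A–D) are not assigned; cross-recording
  comparison requires matching templates externally.
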