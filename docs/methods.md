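# Methods

This note documents the models and procedures implemented in `callnet`, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical conventions.

## PSTH analysis of dyadic calling interactions

**Model.** The unit of analysis is the ordered dyad: an initiator stream of
call onsets (one bird, one call type) and a responder stream. Every
(trigger, response) onset pair with lag in [−4, +4) s contributes one count
to a peristimulus time histogram with 50 ms bins (160 bins). A response
event lying within ±4 s of several triggers is counted once per trigger;
there is no per-trigger normalisation. Bins are half-open [left, right);
the lag −4 s edge is inclusive, +4 s exclusive. Counts at exact bin-edge
multiples are snapped to their nominal bin via a 10⁻⁹-bin epsilon, which
keeps decimal onsets (e.g. a lag of exactly 0.2 s) out of the neighbouring
bin despite binary floating-point cancellation; the snap moves only lags
within 5·10⁻¹¹ s of an edge, far below any meaningful timing precision.

**Index.** `N_base` is the count in the earliest 0.5 s of the window
(lag ∈ [−4.0, −3.5) s) — the block maximally distant from the trigger, where
any direct influence of the trigger has decayed. `N_response` is the count
in lag ∈ [0.05, 0.5) s: the first 50 ms after onset are discarded because
with on-bird microphones the same vocalisation can be picked up by two
birds' transmitters (crosstalk); the exclusion shrinks the response block
rather than shifting it, and simultaneous onsets (lag 0) therefore never
count as responses. The correlation index is
`R = (N_response − N_base)/(N_response + N_base)`, undefined when both
counts are zero.

An alternative baseline (`baseline_mode="all-pre-blocks"`) averages over all
eight pre-onset 0.5-s blocks; the index then uses the per-block mean while
the significance test uses the full pre-onset count with a correspondingly
longer baseline duration in the null. The single-far-block default is less
contaminated by short-lag structure around the trigger; the averaged variant
trades that for lower baseline variance.

**Validity.** A dyad enters the analysis only if its PSTH holds strictly
more than 160 events — one per bin on average. Below this the index is too
noisy to gate reliably; such cells are reported as *missing*, which is
distinct from *non-significant*.

**Significance.** The gate conditions on the total `n = N_base +
N_response`: under the null hypothesis of a rate constant across the two
blocks, each of the n events falls in the response block independently with
probability `p₀ = 0.45/(0.45 + 0.5) ≈ 0.474` — the response block is 50 ms
shorter after crosstalk exclusion, and ignoring that (p₀ = 0.5, available
via `null_model="symmetric"`) would bias the gate toward spurious
suppression calls. A two-sided exact binomial test at α = 0.05 yields +1
(excess), −1 (deficit) or 0. The conditional construction uses exactly the
two counts the index is built from, is exact at small counts, and needs no
rate estimate. For PSTH counts pooled over well-separated triggers the
two block counts are close to independent Poisson, so the conditional
binomial null is accurate; occasional trigger-window overlap introduces
mild dependence that leaves the realised type-I rate near nominal (measured
empirically, see below).

No multiple-testing correction is applied across the cells of a matrix:
each dyad is gated at its own 95% level, so on fully independent streams
about 5% of valid dyads are expected to be flagged. The test suite measures
this pooled rate over 200 independent 8-bird groups and requires it to lie
in [2.5%, 7.5%].

**Matrices.** For a group of n birds the axes are all (bird, call type)
combinations over the five analysable types; all n·25 within-bird cells are
excluded (self-interaction is not interpretable with a shared vocal
apparatus, and within-bird timing is dominated by call-bout structure).
Display semantics: significant cells show R, non-significant valid cells
show 0, invalid cells are missing; the raw index is preserved internally
for every valid cell.

## Synthetic call streams

The generator produces the structure the analysis assumes, under control:

- Baseline: each (bird, type) stream is a homogeneous Poisson process over
  the recording (default 4 h). Per-type rates of 0.01–0.1 ev/s give
  ~150–1500 events per stream per recording, the range over which the
  validity rule starts to admit dyads.
- Coupling: a call by bird X of type a triggers a call by bird Y of type b
  with probability p at a latency drawn uniformly from [0.05, 0.45] s —
  matching the analysis response window after crosstalk exclusion, since
  the latency distribution of real birds is not known beyond "within half
  a second". Coupling is **single-generation**: triggered calls do not
  trigger further calls. This keeps the process subcritical and makes the
  expected response-block excess analytically transparent (per initiator
  event, ≈ p extra response events); full self-exciting cascades add
  nothing for validating the index.
- Refractory period: a triggered call is suppressed if it would fall within
  0.1 s (default) of the responder's previous call, avoiding unphysical
  event pile-up. Baseline events are never suppressed.

What this does *not* emulate: non-stationary calling rates over a morning,
bout structure within streams, amplitude or directionality, overlapping
noise, or more than one response step. Passing tests therefore show that
the pipeline recovers excitatory dyadic structure of the assumed form at
realistic event counts — not that real recordings meet those assumptions.

The stage-series generator concatenates independent recordings with
stage-specific configs (e.g. no within-pair coupling when unpaired, strong
coupling during nest building, both at per-type baseline 0.05 ev/s over
4 h), which is the regime shift used to test specificity-ratio and
combination-count recovery.

## Synthetic syllables and the audio stage

Each call type maps to an archetype: harmonic stack (amplitudes 1/h) on a
fundamental drawn from N(f0_mean, f0_sd), linear frequency modulation of
`fm_depth` across the syllable, broadband-noise admixture, raised-cosine
attack/decay (15% of the syllable each), peak-normalised to 0.5 full scale.
Durations are truncated-normal (non-positive draws rejected). The five
defaults differ strongly in duration (40–160 ms), fundamental (1–4.2 kHz),
harmonic count and noisiness — chosen for feature-space separability, not
acoustic realism; they only loosely follow the relative character of the
real call types (distance calls long, tets/stacks short, whines long and
low).

Rendering places syllables at event onsets over Gaussian noise whose RMS
sits `noise_floor_db` (default −40 dB) below the syllable peak; overlapping
syllables of one bird are forward-shifted, and the realised onsets go into
a truth table, which — not the audio — is what the interaction analysis
consumes.

Analysis stage conventions:

- High-pass: zero-phase 4th-order Butterworth at 200 Hz (equipment-noise
  removal; >20 dB one octave below cutoff, ripple-free passband).
- Segmentation: RMS envelope smoothed over 5 ms; noise floor estimated as
  the envelope's 20th percentile; threshold 12 dB above it; gaps < 5 ms
  merged, crossings < 5 ms discarded. This replaces manual onset editing
  with two explicit filters.
- STFT: Hann window, 512 samples at 44.1 kHz, 50% hop, power spectra,
  band-limited to [200 Hz, Nyquist].
- Features (per frame, then mean and SD across the syllable's frames):
  spectral centroid ("mean frequency"), frequency of the power maximum
  ("mode frequency"), Wiener entropy `log(gmean/amean)` (≤ 0; 0 for white
  noise), and "first peak" — the lowest-frequency local spectral maximum
  exceeding 5% of the frame maximum, a fundamental-frequency proxy. The
  per-frame definition is what gives every spectral feature a meaningful
  SD companion; duration completes the nine. All features are ratio-based
  or frequency-valued, hence amplitude-invariant.
- Classification: k-means on per-dimension z-scored features, best of 10
  restarts by within-cluster sum of squares, deterministic given the seed
  (scikit-learn backend). Clusters map to call types by majority vote
  against a reference labelling; clusters below 50% majority map to
  "other", mirroring the demotion of unclassifiable calls. k is user-set;
  tests use k = 5 for the five analysed types (song is out of scope).
- Crosstalk ranking (optional, used when two channels capture one call):
  the channel with the larger fraction of spectral power below 1 kHz is
  ranked focal, reflecting the extra low-frequency body noise of on-bird
  microphones.

## Repertoire and pair-level statistics

Counts per (bird, recording, type) are extrapolated to the longest-recording
reference of 243 min (`count × 243/duration`); fractional values are kept —
rounding is display-side. Proportions divide by the bird's total raw count
in that recording and are invariant under extrapolation; zero-total rows
carry undefined (empty) proportions rather than 0/0. Stage summaries are
descriptive only (medians, quartiles, bird and row counts) — the mixed-model
inference layer of the original analyses is deliberately out of scope.

Pair statistics take significance-gated matrices as input:

- *Within-pair combination percentages*: for each pair, ordered call-type
  combination and responder sex, the share of possible (valid) within-pair
  cells flagged significant-positive. Both directions are always tallied.
- *Specificity*: per bird, % of possible partner-involving dyads significant
  (either sign, both roles) vs the same over non-partners; their ratio is
  undefined when the non-partner percentage is 0, and stage aggregates
  average per-bird ratios over birds with defined ratios (per-bird-first
  matches per-focal-bird sample-size reporting; pooled counting is a flag).
- *Combination counts by success*: per recording and pair, an ordered
  call-type combination counts once if significant-positive in either
  responder direction (a `per_direction` switch counts the two directions
  separately, max 50 instead of 25); counts are averaged over recordings
  within a (pair, nest stage) and summarised as mean ± SD by egg-laying
  success. The later nest stage is restricted to nest-building because its
  later sub-stages exist only for successful pairs, which would otherwise
  build success into the comparison.

"Possible" excludes invalid cells by default (they are missing data, not
observed absences); `include_invalid=True` restores them for sensitivity
analysis.

## Problem sizes and determinism

Monte-Carlo test conditions: type-I error uses 8-bird groups with per-type
rates uniform in [0.01, 0.05] ev/s over 4 h, 200 replicates; power uses a
single dyad at 0.1 ev/s baselines with p = 0.8, 100 replicates, and a
50-replicate R-vs-p curve over p ∈ {0, 0.2, …, 0.8}; stage-regime recovery
uses 4 pairs at 0.05 ev/s, coupling 0 → 0.8 on five combinations per pair,
50 replicates. The acceptance script recomputes the same quantities at
reduced replicate counts (60/40/20) chosen as its own runtime/precision
trade-off, and reports each measured value with the size it was measured
at. Every stochastic operation takes an explicit seed or Generator; the
acceptance script derives all of its streams from a single `--seed` via
`SeedSequence.spawn`.

## Known limitations

- The binomial gate assumes block counts that are conditionally binomial;
  strong within-stream bout structure (absent from the generator) would
  overdisperse them and inflate the realised false-positive rate.
- The index conflates excitation magnitude with baseline rate at very low
  counts; the validity rule is the only guard.
- Feature extraction assumes syllables at least two STFT frames long
  (≈ 17 ms at the defaults); shorter calls need a smaller window.
- The synthetic archetypes are separable by construction; classifier
  performance on them is an upper bound, not an estimate for real calls.
- Cluster-to-type mapping requires a reference labelling; fully
  unsupervised type discovery is out of scope.
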