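# Methods

This note documents the models, conventions and numerical choices behind
`chimeratrf`, and what the synthetic-data checks do and do not establish.

## Melody representation and downbeats

A melody is an ordered tuple of notes (onset in seconds, duration in
seconds, MIDI pitch) with a time signature and a fixed quarter-note tempo
resolved when the MIDI file is read. Onsets are absolute, strictly
increasing (monophony is enforced at read time by truncating a sounding
note at the next onset; onsets closer than 1 ms are rejected as
polyphonic), and note intervals are half-open `[onset, onset + duration)`.
Note indexing is 0-based everywhere.

The measure grid is anchored at the first note's onset (t = 0); an
optional anacrusis offset shifts it for pieces with a pickup measure,
since symbolic corpora differ in how they notate pickups. A note is a
downbeat iff its onset lies within a tolerance (default 1 ms — symbolic
input is exact; raise it for humanized performances) of a measure
boundary. The tolerance must stay below half the beat period or the
annotation is ambiguous and is rejected.

Supported time signatures are those of the two beat-structure families the
chimera design crosses: triple (3/4, 3/8, 6/8) and duple/quadruple (2/4,
4/4, 4/8).

## Chimera construction

Pieces are paired across the two beat groups with close to the same number
of notes. The pairing considers all cross-group candidates in order of
increasing note-count difference and accepts greedily (each piece used at
most once, difference ≤ 5 notes by default). Fusion is positional and
starts at the beginning: note *i* of the chimera takes pitch *i* of the
pitch source and onset *and duration* *i* of the time source, truncated to
the shorter piece. Durations travel with the rhythm so the time source's
temporal envelope is preserved; the time signature and tempo are inherited
from the time source because downbeats are temporally defined. These
choices make two identities exact by construction: the chimera's pitch
viewpoint equals a prefix of the pitch source's, and its IOI viewpoint a
prefix of the time source's.

## Expectation model

Prediction uses a variable-order n-gram model with PPM escape method C and
*interpolated* back-off. At a context suffix with symbol counts `c(s)`
(total `n`, `d` distinct symbols),

    P_k(s) = c(s) / (n + d) + d / (n + d) · P_{k−1}(s),

interpolating from the longest stored suffix (order bound 10 by default)
down to the uniform distribution over the alphabet K at order −1; never-
seen suffixes escape with probability one. This yields strictly positive
distributions that sum to one exactly, verified against an independent
recursive implementation to 1e−12. The escape method and the combination
scheme below are this package's documented contract — the IDyOM family
admits several variants and the literature often leaves them unstated.

The short-term model (STM) starts empty and is updated online: note *t* is
predicted from notes < *t*, then counted. The long-term model (LTM) is
trained on a corpus beforehand. The combined "both" prediction is a
weight-normalized geometric mean (arithmetic optionally) with certainty
weights `w = (ln|K| / H)^b`, `b = 1`, where `H` is each prediction's
entropy; explicit weights can override this.

Surprisal and entropy are in nats. The IOI viewpoint is discretized to
integer multiples of a grid unit — by default the sequence's minimum IOI,
so symbols read as "multiples of the shortest note" and are tempo-
invariant; deviations beyond 1% of the unit warn. When a whole stimulus
set is analyzed, the alphabet (union over both originals plus the LTM) and
the IOI unit are shared across the four melodies, which makes the
chimera's features *bitwise identical* to its sources' on the common
prefix. Per-sequence analyses use per-sequence alphabets instead.

## Regressors

All signals live on the EEG grid (default 125 samples/s). Onsets map to
samples by round-half-up (bins are 8 ms wide; two notes in one bin are an
error, not a merge). Expectation features become impulse trains whose
amplitudes are the per-note values; IOI-aligned features start at note 2
with note 1 at zero. By default the per-note expectation values are
z-scored per trial before train construction (common practice; can be
disabled). Downbeat indicators are unit impulse trains: DBo (originals),
and for chimeras DBct (time-source downbeats — the chimera's actual
downbeats), DBcp (pitch-source downbeats) and DBcpt (their conjunction,
the pitch × time interaction). Their nonzero samples are subsets of the
onset train, and DBcpt is the elementwise minimum of DBcp and DBct.

Spectral flux uses 1024-sample Hann windows with 50% overlap, half-wave-
rectified frame-to-frame magnitude differences summed over frequency,
linear interpolation onto the output grid, and per-trial z-scoring. The
tone renderer sums damped harmonics (1/h partial amplitudes) at equal
velocity and normalizes the waveform to RMS 0.01, mirroring the loudness
normalization of typical experimental stimuli; it is a deliberately simple
renderer whose purpose is to give the flux regressor realistic onset
structure, not to sound like a piano.

## TRF estimation

The lagged design holds one column per feature × lag (feature-major,
lag-minor), zero-padded at trial edges. The default lag window is −100 to
+800 ms — wide enough for the ~650 ms downbeat dip; analyses on shorter
windows (−50…450 ms for the expectation models in the examples and
checks) are a problem-size choice and are stated where used.

**Ridge (expectation models).** Columns are z-scored with training-fold
statistics, the intercept is handled by centering, and kernels are
reported back on the original feature scale. `fit_ridge` applies λ as an
absolute penalty, so λ → 0 reduces exactly to least squares (and a noiseless
simulation is recovered to machine precision at λ = 1e−6). Cross-
validation (`loo_crossval`) instead scales λ by the mean Gram diagonal —
the mTRF-style normalization that makes the 10⁻³…10³ grid span under- to
over-regularized regardless of trial length; λ is selected per participant
and model by the mean Pearson r between predicted and held-out EEG,
computed per channel over the held-out trial and averaged (constant
channels contribute r = 0 with a warning). Per-trial Gram statistics are
precomputed once and reused across folds, subjects and nested feature
subsets; this is exact, not an approximation.

**OLS (downbeat models).** Impulse regressors are left unscaled so kernels
read as evoked-response differences per event. All trials are pooled;
rank-deficient designs raise an error naming the collinear columns (via
pivoted QR). With non-overlapping response windows the OLS kernel equals
the epoch-averaged evoked response exactly (verified to 1e−8). Subjects
sharing the same stimuli are fitted jointly by stacking their channels —
algebraically identical to separate fits.

## Statistics

Δr tables contrast each expectation model against the acoustic baseline
within participant and stimulus category. The linear mixed-effects models
of the wider analysis are intentionally not fitted here; `mixed_model_table`
exports the long-format table (r/Δr, model, category, musicianship,
preference, participant, stimulus set) that standard mixed-model software
consumes. Paired t tests are Holm–Bonferroni corrected; peak-amplitude
correlations are Benjamini–Hochberg corrected across channels (both via
statsmodels).

TFCE uses E = 0.5, H = 2, and a threshold grid `h = dh, 2dh, …` with
`dh = max|t|/50` by default — all configurable, since published analyses
typically inherit library defaults. Clusters form on a spatiotemporal
graph: neighboring sensors at the same lag plus consecutive lags at the
same sensor. A schematic 32-channel 10–20 montage with a distance-based
neighbor graph ships with the package and is injectable for other
montages. Two-sided testing enhances the +t and −t maps separately
(implemented as one sweep over |t| with cluster edges restricted to
same-sign points — exactly equivalent); the sign-flip permutation null is
the distribution of the maximum |TFCE| over the map, giving family-wise
corrected `p = (1 + #{null ≥ observed}) / (1 + n_perm)`, never zero. `dh`
is fixed from the observed map and reused for every permutation so scores
are comparable. Permutation t maps are computed in a vectorized pass (the
per-point sum of squares is sign-invariant) and all permutations are
enhanced jointly per threshold on a block-diagonal graph; this is an exact
speedup. Family-wise error calibrates to 0.01–0.10 at nominal 0.05 on null
data (checked at 200 repetitions × 199 permutations).

## Synthetic studies

The generator emulates the statistical structure the analysis assumes.
Melodies: IOIs drawn from {½, 1, 1½, 2} beats on a half-beat grid, with
intervals clipped to land on barlines (every measure starts with a note,
the folk-song norm — this also gives the downbeat regressors realistic
density); pitches follow a first-order Markov chain over two diatonic
octaves favouring small steps. Kernels: Gaussian bumps placed at the
canonical latencies — onset P1 (80 ms, amp 0.6) and P2 (185 ms, amp 1.0);
downbeat peak (185 ms, 0.8) and dip (650 ms, −0.5); smooth biphasic
expectation kernels (amp 1.0); a pitch-only downbeat kernel of zero; an
optional interaction kernel at 185 ms. Channel weights follow a
frontocentral Gaussian over the montage, maximum 1. EEG per trial is the
lag-convolved sum of regressor × kernel, projected through the channel
map, plus 1/f noise (exponent 1) with a shared spatial component
(pairwise correlation 0.3), scaled so the channel-averaged clean/noise
variance ratio equals the requested SNR exactly.

Default study conditions: 10 subjects × 3 stimulus sets (12 trials of
~25–30 s, 56–60 notes) at 125 Hz, 32 channels, SNR 0 dB; musicianship
years uniform on 0–11 with P2 gain 1 + 0.05·years; chimeric expectation
kernels attenuated by 0.5 (the generative analogue of a weaker expectation
effect for chimeric music); interaction kernel on at amplitude 0.5. The
verification runs scale these down for tractability — e.g. 4 subjects ×
8 trials per run for the Δr direction checks, 8 subjects for the
interaction and permutation checks — and the downbeat-encoding checks use
studies whose EEG is generated by the downbeat forward model alone
(`active_kernels`). That last choice matters: when all subjects hear
identical stimuli, responses omitted from a fitted model (e.g. the
entropy kernel) do not average out across subjects and bias the sparse
DBcpt estimate; isolating the forward model makes "planted latency
recovered / zero kernel declared null" a well-posed check. With the full
generative model this omitted-feature bias is a genuine property of the
analysis — worth remembering when interpreting sparse interaction
regressors on real data.

What the simulations do **not** emulate: realistic head geometry or source
mixing (a single spatial pattern per study), artifacts (blinks, ICA),
trial-order or fatigue effects, performance timing jitter, and listeners'
actual expectation processes (EEG is generated *from* the model's own
features, so passing recovery checks demonstrates correctness of the
estimation machinery, not validity of the cognitive model on real brains).

## Known limitations

* The SMF codec covers the monophonic subset (type 0/1, note events, tempo
  and time-signature meta); other events are skipped.
* PPM here uses interpolated escape C without exclusion; IDyOM
  configurations with update exclusion or other escape methods will give
  different absolute surprisal values.
* OLS downbeat models need enough interaction events to be identifiable;
  with very sparse DBcpt trains (or lag windows extending before an
  always-shared first downbeat) the design can be rank deficient, which is
  reported as an error rather than silently regularized.
* The expectation-vs-acoustic Δr depends on the generator's kernel
  amplitude balance; the defaults give each feature class a comparable
  variance share, which is larger than the small effects typical of real
  EEG.
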