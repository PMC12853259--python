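# chimeratrf

Analysis tools for studying how the brain encodes the pitch and time
dimensions of melody — and their interaction — with EEG encoding models.
The central experimental device is **chimeric music**: given two monophonic
pieces from different meter families (triple vs duple/quadruple), a chimera
takes the pitch sequence of one and the note-onset-time sequence of the
other. This decouples pitch and temporal structure while preserving each
dimension's marginal statistics, so differences in neural tracking between
original and chimeric stimuli isolate the contribution of their joint
structure.

The package is aimed at auditory/music cognition researchers who want a
tested, fully synthetic-verifiable reimplementation of this analysis:
every stage can be exercised end to end by parameter recovery on simulated
EEG, without any data download.

## What it implements

* **Melody handling** (`melody_io`) — monophonic Standard MIDI File
  read/write (self-contained codec), pitch (`cpitch`) and inter-onset
  interval (`ioi`) viewpoint extraction, and metrical downbeat annotation.
* **Chimera construction** (`chimera`) — beat-group classification,
  note-count-matched cross-meter pairing, and pitch/time fusion into
  four-melody stimulus sets.
* **Melodic expectation** (`expectation`) — a variable-order n-gram model
  (PPM escape method C with interpolated back-off) producing per-note
  surprisal and entropy in nats,

      S(x_t) = −ln P(x_t | x_{t−n}…x_{t−1}),
      E(x_t) = Σ_{x∈K} P(x | context) · (−ln P(x | context)),

  for pitch (Sp, Ep) and IOI (St, Et) viewpoints, with short-term (STM,
  trained online on the current piece), long-term (LTM, corpus-trained) and
  entropy-weighted combined ("both") configurations. By construction, a
  chimera's Sp/Ep equal its pitch source's and its St/Et equal its time
  source's — the control that makes the original-vs-chimeric comparison
  well posed.
* **Regressors** (`features`) — note-onset impulse trains,
  expectation-scaled trains, the downbeat indicators (DBo for originals;
  DBct/DBcp/DBcpt for chimeras, marking time-source downbeats, pitch-source
  downbeats and their conjunction), spectral flux of rendered audio, and a
  damped-harmonic tone renderer (RMS-normalized to 0.01).
* **TRF estimation** (`trf`) — lagged-design temporal response functions:
  ridge regression with leave-one-trial-out cross-validation over
  λ ∈ 10⁻³…10³ and Pearson-r prediction accuracy averaged over channels
  (expectation models A, AM, AMp, AMt), and ordinary least squares for the
  impulse-only downbeat models, whose kernels read as ERP-like evoked
  responses.
* **Statistics** (`stats`) — Δr expectation-effect tables, paired t tests
  with Holm–Bonferroni correction, two-sided one-sample sign-flip
  permutation tests with threshold-free cluster enhancement (TFCE) over a
  channel × lag adjacency, peak-amplitude/musicianship correlations with
  Benjamini–Hochberg FDR, and long-format exports for mixed-model software.
* **Synthetic studies** (`synthetic_data`, `pipeline`) — a seeded generator
  of folk-song-like melodies, ground-truth kernel banks (P1 ~80 ms,
  P2 ~185 ms onset response; downbeat peak ~185 ms with a ~650 ms dip;
  optional pitch × time interaction kernel) and 32-channel EEG with
  1/f-shaped noise at a requested SNR, plus the orchestration that fits all
  models on a simulated study.

## Worked example

Build a chimeric stimulus set and verify the feature-identity control:

```python
import numpy as np
from chimeratrf import (
    generate_melody, build_stimulus_set, viewpoints, train,
    stimulus_set_expectations, ExpectationConfig, quantize_iois,
)

waltz = generate_melody((3, 4), n_notes=40, tempo_bpm=120, seed=1, label="waltz")
march = generate_melody((4, 4), n_notes=40, tempo_bpm=120, seed=2, label="march")
sset = build_stimulus_set(waltz, march)

corpus = [generate_melody((4, 4), 40, 120, seed=s) for s in range(10, 16)]
ltm_pitch = train([viewpoints(m).pitch_seq for m in corpus], order_bound=10)
ltm_ioi = train([quantize_iois(viewpoints(m).ioi_seq) for m in corpus], order_bound=10)

feats = stimulus_set_expectations(sset, ltm_pitch, ltm_ioi, ExpectationConfig(mode="both"))
for name in ("original_1", "chimeric_a"):
    f = feats[name]
    print(f"{name}: mean Sp={f.Sp.mean():.3f} nats, mean St={f.St.mean():.3f} nats")
print("pitch features identical:", np.array_equal(feats["chimeric_a"].Sp, feats["original_1"].Sp))
```

prints

```
original_1: mean Sp=2.363 nats, mean St=1.827 nats
chimeric_a: mean Sp=2.363 nats, mean St=1.856 nats
pitch features identical: True
```

— the chimera's pitch surprisal is *identical* to its pitch source's
(shared context, shared alphabet), while its time surprisal equals the time
source's on the common prefix (1.856 vs original_2's values; original_1's
1.827 differs because its rhythm differs).

Simulate a small study in which chimeric stimuli evoke attenuated
expectation responses, and measure the Δr expectation effect:

```python
from chimeratrf import simulate_study, StudyConfig, fit_expectation_models, delta_r_table

study = simulate_study(StudyConfig(n_subjects=4, n_sets=2, n_notes=56), seed=0)
reports = fit_expectation_models(study, model_tags=("A", "AM"), lags_ms=(-50, 450))
print(delta_r_table(reports).groupby("stim_category").delta_r.mean())
```

prints

```
stim_category
chimeric    0.011025
original    0.069265
Name: delta_r, dtype: float64
```

Adding the expectation features improves held-out EEG prediction for both
categories (Δr > 0), and the improvement is markedly smaller for chimeric
stimuli — recovering the generative attenuation (0.5) planted by the
simulator.

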