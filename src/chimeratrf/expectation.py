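"""Variable-order n-gram melodic expectation (surprisal and entropy).

For each note the model predicts a distribution over the viewpoint alphabet
K given the preceding context and emits two information-theoretic features,
in nats:

* surprisal  ``S(x_t) = -ln P(x_t | context)`` -- the unexpectedness of the
  note that actually occurred, and
* entropy    ``E(x_t) = sum_{x in K} P(x | context) * (-ln P(x | context))``
  -- the uncertainty of the context before the note occurred.

Prediction uses PPM-style escape method C with *interpolated* back-off: at
a context with symbol counts ``c(s)`` (total ``n``, ``d`` distinct symbols),

    P_k(s) = c(s) / (n + d)  +  d / (n + d) * P_{k-1}(s),

recursing through successively shorter context suffixes down to the uniform
distribution over K at order -1.  Unseen contexts escape with probability 1.
This yields strictly positive distributions that sum to one exactly.

Both a short-term model (STM, trained online on the current piece) and a
long-term model (LTM, trained on a corpus) are supported; the combined
"both" configuration merges their predictions with entropy-based weights.
Viewpoints are chromatic pitch and the inter-onset interval, the latter
quantized to multiples of a grid unit so that its symbols are discrete.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chimera import StimulusSet
from .melody_io import NoteSequence, ViewpointSequences, viewpoints

__all__ = [
    "NGramModel",
    "ProbDist",
    "ExpectationFeatures",
    "ExpectationConfig",
    "train",
    "predict",
    "info_measures",
    "combine",
    "sequence_expectations",
    "stimulus_set_expectations",
    "quantize_iois",
    "feature_table_tsv",
]


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbDist:
    """A normalized, strictly positive distribution over a finite alphabet."""

    probs: dict

    def __post_init__(self) -> None:
        vals = np.array(list(self.probs.values()), dtype=float)
        if len(vals) == 0:
            raise ValueError("empty distribution")
        if np.any(vals <= 0):
            raise ValueError("probabilities must be strictly positive (smoothed)")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {vals.sum()}, not 1")

    @property
    def alphabet(self) -> tuple:
        return tuple(self.probs.keys())

    def __getitem__(self, symbol) -> float:
        return self.probs[symbol]

    def entropy(self) -> float:
        p = np.array(list(self.probs.values()), dtype=float)
        return float(-(p * np.log(p)).sum())


def info_measures(dist: ProbDist, observed) -> tuple[float, float]:
    """Surprisal of the observed symbol and entropy of the distribution (nats)."""
    if observed not in dist.probs:
        raise ValueError(f"observed symbol {observed!r} not in alphabet")
    s = -math.log(dist.probs[observed])
    return s, dist.entropy()


# ---------------------------------------------------------------------------
# N-gram counts and prediction
# ---------------------------------------------------------------------------


@dataclass
class NGramModel:
    """Counts over contexts of length 0..order_bound with PPM-C smoothing."""

    order_bound: int
    counts: dict = field(default_factory=dict)  # context tuple -> {symbol: count}
    alphabet: set = field(default_factory=set)
    smoothing: str = "ppm-c-interpolated"

    def observe(self, context, symbol) -> None:
        """Record one symbol after its context (all suffixes up to the bound)."""
        ctx = tuple(context)
        for k in range(min(len(ctx), self.order_bound) + 1):
            suffix = ctx[len(ctx) - k :]
            table = self.counts.setdefault(suffix, {})
            table[symbol] = table.get(symbol, 0) + 1
        self.alphabet.add(symbol)

    def add_sequence(self, sequence) -> None:
        seq = list(sequence)
        for t, sym in enumerate(seq):
            self.observe(seq[:t], sym)


def train(sequences, order_bound: int) -> NGramModel:
    """Train an n-gram model on a corpus of symbol sequences."""
    if order_bound < 0:
        raise ValueError("order_bound must be >= 0")
    model = NGramModel(order_bound=order_bound)
    for seq in sequences:
        model.add_sequence(seq)
    return model


def predict(model: NGramModel, context, alphabet=()) -> ProbDist:
    """Escape-smoothed predictive distribution over the (combined) alphabet.

    The alphabet is the union of the model's observed symbols and the
    supplied viewpoint alphabet.  The context is truncated to the model's
    order bound (longest matching suffix first); suffixes never observed
    escape with probability one, so they leave the distribution unchanged.
    """
    symbols = sorted(set(model.alphabet) | set(alphabet))
    if not symbols:
        raise ValueError("alphabet must be nonempty")
    index = {s: i for i, s in enumerate(symbols)}
    p = np.full(len(symbols), 1.0 / len(symbols))  # order -1: uniform over K
    ctx = tuple(context)
    if model.order_bound >= 0:
        ctx = ctx[len(ctx) - min(len(ctx), model.order_bound) :]
    # interpolate from the shortest suffix (order 0) up to the full context
    for k in range(len(ctx) + 1):
        suffix = ctx[len(ctx) - k :]
        table = model.counts.get(suffix)
        if not table:
            continue
        n = sum(table.values())
        d = len(table)
        counts_vec = np.zeros(len(symbols))
        for s, c in table.items():
            counts_vec[index[s]] = c
        p = counts_vec / (n + d) + (d / (n + d)) * p
    return ProbDist({s: float(p[index[s]]) for s in symbols})


def combine(
    stm_dist: ProbDist,
    ltm_dist: ProbDist,
    mode: str = "geometric",
    bias: float = 1.0,
    weights: tuple[float, float] | None = None,
) -> ProbDist:
    """Merge STM and LTM predictions into the "both" distribution.

    Each source is weighted by its certainty: ``w_m = (1 / Hrel_m)^bias``
    where ``Hrel = H / ln|K|`` is the entropy of the prediction relative to
    its maximum.  ``mode="geometric"`` combines as a weight-normalized
    geometric mean (renormalized); ``mode="arithmetic"`` as a weighted
    average.  Explicit ``weights`` override the entropy weighting.
    """
    if set(stm_dist.alphabet) != set(ltm_dist.alphabet):
        raise ValueError("alphabet mismatch between STM and LTM distributions")
    symbols = sorted(stm_dist.alphabet)
    k = len(symbols)
    ps = np.array([stm_dist[s] for s in symbols])
    pl = np.array([ltm_dist[s] for s in symbols])
    if k == 1:
        return ProbDist({symbols[0]: 1.0})
    if weights is None:
        hmax = math.log(k)
        eps = 1e-12
        w = np.array(
            [
                (hmax / max(-(ps * np.log(ps)).sum(), eps)) ** bias,
                (hmax / max(-(pl * np.log(pl)).sum(), eps)) ** bias,
            ]
        )
    else:
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError("weights must have positive sum")
    w = w / w.sum()
    if mode == "geometric":
        logp = w[0] * np.log(ps) + w[1] * np.log(pl)
        p = np.exp(logp - logp.max())
    elif mode == "arithmetic":
        p = w[0] * ps + w[1] * pl
    else:
        raise ValueError("mode must be 'geometric' or 'arithmetic'")
    p = p / p.sum()
    return ProbDist(dict(zip(symbols, map(float, p))))


# ---------------------------------------------------------------------------
# IOI quantization
# ---------------------------------------------------------------------------


def quantize_iois(iois, unit: float | None = None, tolerance: float = 0.01):
    """Quantize IOIs (seconds) to integer multiples of a grid unit.

    If ``unit`` is None the minimum IOI of the sequence is used, so symbols
    read as "multiples of the shortest note".  Ratios farther than
    ``tolerance`` from an integer are rounded with a warning (humanized
    input).
    """
    arr = np.asarray(list(iois), dtype=float)
    if arr.size == 0:
        return tuple()
    if np.any(arr <= 0):
        raise ValueError("IOIs must be positive")
    if unit is None:
        unit = float(arr.min())
    ratio = arr / unit
    sym = np.maximum(np.round(ratio).astype(int), 1)
    if np.any(np.abs(ratio - np.round(ratio)) > tolerance):
        warnings.warn("IOIs deviate from the quantization grid beyond tolerance", stacklevel=2)
    return tuple(int(s) for s in sym)


# ---------------------------------------------------------------------------
# Per-sequence expectation features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpectationConfig:
    """Configuration of the expectation model.

    mode: "both" (STM+LTM combination, the default), "stm", "ltm".
    order_bound: maximum context length (longest-match back-off below it).
    combination/bias: how STM and LTM predictions are merged.
    ioi_unit: quantization grid for the IOI viewpoint (None = per-sequence
    minimum IOI).  pitch_alphabet/ioi_alphabet extend the prediction
    alphabets beyond the symbols seen by the models.
    """

    mode: str = "both"
    order_bound: int = 10
    combination: str = "geometric"
    bias: float = 1.0
    combination_weights: tuple[float, float] | None = None
    ioi_unit: float | None = None
    ioi_tolerance: float = 0.01
    pitch_alphabet: tuple = ()
    ioi_alphabet: tuple = ()

    def __post_init__(self) -> None:
        if self.mode not in ("both", "stm", "ltm"):
            raise ValueError("mode must be 'both', 'stm' or 'ltm'")


@dataclass(frozen=True)
class ExpectationFeatures:
    """Per-note surprisal/entropy for pitch (length n) and IOI (length n-1).

    The IOI features are aligned to notes 2..n; the first note has no IOI.
    All values are in nats and non-negative.
    """

    Sp: np.ndarray
    Ep: np.ndarray
    St: np.ndarray
    Et: np.ndarray

    def __post_init__(self) -> None:
        for name in ("Sp", "Ep", "St", "Et"):
            v = getattr(self, name)
            if np.any(np.asarray(v) < -1e-12):
                raise ValueError(f"{name} contains negative values")
        if len(self.Sp) != len(self.Ep) or len(self.St) != len(self.Et):
            raise ValueError("mismatched feature lengths")
        if len(self.St) != len(self.Sp) - 1:
            raise ValueError("IOI features must have n-1 entries")


def _viewpoint_expectations(symbols, ltm: NGramModel | None, config: ExpectationConfig, extra_alphabet):
    """Run the online STM / static LTM prediction loop over one symbol sequence."""
    stm = NGramModel(order_bound=config.order_bound)
    alphabet = set(extra_alphabet) | set(symbols)
    if ltm is not None:
        alphabet |= set(ltm.alphabet)
    S = np.empty(len(symbols))
    E = np.empty(len(symbols))
    seq = list(symbols)
    for t, sym in enumerate(seq):
        ctx = seq[:t]
        if config.mode == "stm":
            dist = predict(stm, ctx, alphabet)
        elif config.mode == "ltm":
            dist = predict(ltm, ctx, alphabet)
        else:
            dist = combine(
                predict(stm, ctx, alphabet),
                predict(ltm, ctx, alphabet),
                mode=config.combination,
                bias=config.bias,
                weights=config.combination_weights,
            )
        S[t], E[t] = info_measures(dist, sym)
        stm.observe(ctx, sym)
    return S, E


def sequence_expectations(
    seq: ViewpointSequences | NoteSequence,
    ltm_pitch: NGramModel | None = None,
    ltm_ioi: NGramModel | None = None,
    config: ExpectationConfig = ExpectationConfig(),
) -> ExpectationFeatures:
    """Compute Sp/Ep/St/Et for one melody.

    The STM is built incrementally: each note is predicted from the notes
    before it, then added to the short-term counts.  For the "ltm" and
    "both" modes the corresponding LTM model(s) must be supplied.
    """
    if isinstance(seq, NoteSequence):
        seq = viewpoints(seq)
    if config.mode in ("ltm", "both") and (ltm_pitch is None or ltm_ioi is None):
        raise ValueError(f"mode '{config.mode}' requires trained LTM models")
    Sp, Ep = _viewpoint_expectations(seq.pitch_seq, ltm_pitch, config, config.pitch_alphabet)
    ioi_syms = quantize_iois(seq.ioi_seq, unit=config.ioi_unit, tolerance=config.ioi_tolerance)
    St, Et = _viewpoint_expectations(ioi_syms, ltm_ioi, config, config.ioi_alphabet)
    return ExpectationFeatures(Sp=Sp, Ep=Ep, St=St, Et=Et)


def stimulus_set_expectations(
    sset: StimulusSet,
    ltm_pitch: NGramModel | None = None,
    ltm_ioi: NGramModel | None = None,
    config: ExpectationConfig = ExpectationConfig(),
) -> dict[str, ExpectationFeatures]:
    """Expectation features for all four melodies of a stimulus set.

    The pitch and IOI alphabets and the IOI grid unit are shared across the
    set (union over the two originals), so the per-note features of a
    chimeric melody are *identical* to those of its pitch source (Sp/Ep) and
    its time source (St/Et) on the common prefix -- the control that makes
    the original-vs-chimeric TRF comparison well posed.
    """
    vps = {name: viewpoints(mel) for name, mel in sset.melodies.items()}
    pitch_alpha = set(config.pitch_alphabet)
    all_iois: list[float] = []
    for name in ("original_1", "original_2"):
        pitch_alpha |= set(vps[name].pitch_seq)
        all_iois.extend(vps[name].ioi_seq)
    unit = config.ioi_unit if config.ioi_unit is not None else float(min(all_iois))
    ioi_alpha = set(config.ioi_alphabet) | set(
        quantize_iois(all_iois, unit=unit, tolerance=config.ioi_tolerance)
    )
    shared = ExpectationConfig(
        mode=config.mode,
        order_bound=config.order_bound,
        combination=config.combination,
        bias=config.bias,
        combination_weights=config.combination_weights,
        ioi_unit=unit,
        ioi_tolerance=config.ioi_tolerance,
        pitch_alphabet=tuple(sorted(pitch_alpha)),
        ioi_alphabet=tuple(sorted(ioi_alpha)),
    )
    return {
        name: sequence_expectations(vp, ltm_pitch, ltm_ioi, shared)
        for name, vp in vps.items()
    }


def feature_table_tsv(
    seq: NoteSequence, feats: ExpectationFeatures, mask=None
) -> str:
    """Per-note TSV: note_index, onset_s, Sp, Ep, St, Et, is_downbeat."""
    lines = ["note_index\tonset_s\tSp\tEp\tSt\tEt\tis_downbeat"]
    onsets = seq.onsets
    for i in range(len(seq)):
        st = f"{feats.St[i - 1]:.6f}" if i >= 1 else ""
        et = f"{feats.Et[i - 1]:.6f}" if i >= 1 else ""
        db = "" if mask is None else str(int(mask.is_downbeat[i]))
        lines.append(
            f"{i}\t{onsets[i]:.6f}\t{feats.Sp[i]:.6f}\t{feats.Ep[i]:.6f}\t{st}\t{et}\t{db}"
        )
    return "\n".join(lines) + "\n"
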