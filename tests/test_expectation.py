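"""Variable-order expectation model: counts, smoothing, surprisal/entropy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chimeratrf.expectation import (
    ExpectationConfig,
    NGramModel,
    ProbDist,
    combine,
    info_measures,
    predict,
    quantize_iois,
    sequence_expectations,
    train,
)
from chimeratrf.melody_io import ViewpointSequences


# ---------------------------------------------------------------------------
# Independent oracle: recursive top-down PPM-C with interpolated back-off
# ---------------------------------------------------------------------------


def ppm_oracle(corpus, order_bound, context, symbol, alphabet):
    """Brute-force P(symbol | context): recompute counts from scratch and
    interpolate recursively from the longest context suffix down to uniform."""
    counts = {}
    for seq in corpus:
        for t in range(len(seq)):
            for k in range(min(t, order_bound) + 1):
                ctx = tuple(seq[t - k : t])
                counts.setdefault(ctx, {}).setdefault(seq[t], 0)
                counts[ctx][seq[t]] += 1

    def p(ctx, s):
        if len(ctx) < 0:
            raise AssertionError
        shorter = p(ctx[1:], s) if ctx else 1.0 / len(alphabet)
        table = counts.get(tuple(ctx), {})
        n = sum(table.values())
        d = len(table)
        if n == 0:
            return shorter
        return table.get(s, 0) / (n + d) + d / (n + d) * shorter

    ctx = tuple(context)[-order_bound:] if order_bound > 0 else ()
    return p(ctx, symbol)


class TestTrain:
    def test_hand_counts_abab(self):
        model = train(["ABAB"], order_bound=1)
        assert model.counts[("A",)] == {"B": 2}
        assert model.counts[("B",)] == {"A": 1}
        assert model.counts[()] == {"A": 2, "B": 2}
        assert model.alphabet == {"A", "B"}

    def test_hand_counts_aaaa(self):
        model = train(["AAAA"], order_bound=1)
        assert model.counts[("A",)] == {"A": 3}
        assert model.counts[()] == {"A": 4}

    def test_empty_corpus(self):
        model = train([], order_bound=2)
        assert model.counts == {}
        assert model.alphabet == set()


class TestPredict:
    def test_untrained_uniform(self):
        model = train([], order_bound=2)
        dist = predict(model, "AB", alphabet="ABCD")
        assert all(dist[s] == pytest.approx(0.25) for s in "ABCD")

    def test_abab_escape_arithmetic(self):
        # hand-computed PPM-C interpolation for corpus "ABAB", order 1:
        # P0(B) = 2/6 + 2/6 * 1/2 = 1/2;  P(B|A) = 2/3 + 1/3 * 1/2 = 5/6
        model = train(["ABAB"], order_bound=1)
        dist = predict(model, "A", alphabet="AB")
        assert dist["B"] == pytest.approx(5 / 6, abs=1e-12)
        assert dist["A"] == pytest.approx(1 / 6, abs=1e-12)

    def test_context_truncation(self):
        model = train(["ABAB", "BBA"], order_bound=1)
        long = predict(model, "ABBBA", alphabet="AB")
        short = predict(model, "A", alphabet="AB")
        assert long.probs == short.probs

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = tuple("ABCDE"[: rng.integers(2, 6)])
        order = int(rng.integers(0, 3))
        corpus = [
            "".join(rng.choice(alphabet, size=rng.integers(3, 8)))
            for _ in range(rng.integers(1, 3))
        ]  # <= 20 symbols total
        model = train(corpus, order_bound=order)
        context = "".join(rng.choice(alphabet, size=rng.integers(0, 5)))
        dist = predict(model, context, alphabet)
        for s in alphabet:
            expected = ppm_oracle(corpus, order, context, s, alphabet)
            assert dist[s] == pytest.approx(expected, abs=1e-12)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_distribution_invariants(self, data):
        alphabet = tuple("WXYZ")
        corpus = data.draw(
            st.lists(st.text(alphabet="WXYZ", min_size=1, max_size=8), max_size=3)
        )
        context = data.draw(st.text(alphabet="WXYZ", max_size=4))
        order = data.draw(st.integers(0, 3))
        model = train(corpus, order_bound=order)
        dist = predict(model, context, alphabet)
        p = np.array([dist[s] for s in alphabet])
        assert abs(p.sum() - 1.0) <= 1e-9
        assert np.all(p > 0)
        _, entropy = info_measures(dist, alphabet[0])
        assert -1e-12 <= entropy <= math.log(len(alphabet)) + 1e-12


class TestInfoMeasures:
    def test_uniform_closed_form(self):
        dist = ProbDist({s: 0.25 for s in "ABCD"})
        s, e = info_measures(dist, "B")
        assert s == pytest.approx(math.log(4))
        assert e == pytest.approx(math.log(4))

    def test_degenerate(self):
        dist = ProbDist({"A": 1.0})
        s, e = info_measures(dist, "A")
        assert s == 0.0 and e == pytest.approx(0.0)

    def test_half_quarter_quarter(self):
        dist = ProbDist({"A": 0.5, "B": 0.25, "C": 0.25})
        s, e = info_measures(dist, "A")
        assert s == pytest.approx(math.log(2))
        assert e == pytest.approx(1.5 * math.log(2))

    def test_unknown_symbol(self):
        with pytest.raises(ValueError, match="not in alphabet"):
            info_measures(ProbDist({"A": 1.0}), "B")


class TestCombine:
    def test_idempotent(self):
        d = ProbDist({"A": 0.5, "B": 0.3, "C": 0.2})
        merged = combine(d, d)
        for s in "ABC":
            assert merged[s] == pytest.approx(d[s], abs=1e-12)

    def test_entropy_weighting_favors_peaked(self):
        uniform = ProbDist({"A": 1 / 3, "B": 1 / 3, "C": 1 / 3})
        peaked = ProbDist({"A": 0.9, "B": 0.05, "C": 0.05})
        merged = combine(uniform, peaked)
        # hand check: w_uniform = 1, w_peaked = ln3/H(peaked) ~ 2.79
        h_peaked = -(0.9 * math.log(0.9) + 2 * 0.05 * math.log(0.05))
        w = np.array([1.0, math.log(3) / h_peaked])
        w = w / w.sum()
        expected = np.array([1 / 3, 1 / 3, 1 / 3]) ** w[0] * np.array([0.9, 0.05, 0.05]) ** w[1]
        expected /= expected.sum()
        assert merged["A"] == pytest.approx(expected[0], abs=1e-12)
        assert merged["A"] > (uniform["A"] + peaked["A"]) / 2

    def test_forced_weights(self):
        a = ProbDist({"A": 0.7, "B": 0.3})
        b = ProbDist({"A": 0.2, "B": 0.8})
        assert combine(a, b, weights=(1, 0)).probs == pytest.approx(a.probs)
        assert combine(a, b, weights=(0, 1)).probs == pytest.approx(b.probs)

    def test_alphabet_mismatch(self):
        with pytest.raises(ValueError, match="alphabet"):
            combine(ProbDist({"A": 1.0}), ProbDist({"B": 1.0}))


class TestQuantizeIois:
    def test_multiples_of_minimum(self):
        assert quantize_iois([0.25, 0.5, 0.75, 0.25]) == (1, 2, 3, 1)

    def test_explicit_unit(self):
        assert quantize_iois([0.5, 1.0], unit=0.25) == (2, 4)

    def test_off_grid_warns(self):
        with pytest.warns(UserWarning, match="tolerance"):
            quantize_iois([0.25, 0.34])


class TestSequenceExpectations:
    def test_ltm_only_reduces_to_static_prediction(self):
        ltm = train([(60, 62, 60, 62, 64)], order_bound=2)
        vp = ViewpointSequences(pitch_seq=(60, 62, 64), ioi_seq=(0.5, 0.5))
        cfg = ExpectationConfig(mode="ltm", order_bound=2)
        feats = sequence_expectations(vp, ltm, train([(1, 1)], 2), cfg)
        alphabet = sorted(ltm.alphabet | {60, 62, 64})
        for t, sym in enumerate(vp.pitch_seq):
            dist = predict(ltm, vp.pitch_seq[:t], alphabet)
            s, e = info_measures(dist, sym)
            assert feats.Sp[t] == pytest.approx(s, abs=1e-12)
            assert feats.Ep[t] == pytest.approx(e, abs=1e-12)

    def test_stm_learning_repeating_melody(self):
        # ABAB...: surprisal of B-after-A should fall as the STM learns
        pitches = (60, 62) * 6
        vp = ViewpointSequences(pitch_seq=pitches, ioi_seq=(0.5,) * 11)
        cfg = ExpectationConfig(mode="stm", order_bound=1)
        feats = sequence_expectations(vp, config=cfg)
        b_events = feats.Sp[3:10:2]  # B-after-A events after the first
        assert np.all(np.diff(b_events) < 0)

    def test_requires_ltm_for_both(self):
        vp = ViewpointSequences(pitch_seq=(60, 62), ioi_seq=(0.5,))
        with pytest.raises(ValueError, match="requires trained LTM"):
            sequence_expectations(vp, config=ExpectationConfig(mode="both"))

    def test_monotone_stm_learning_statistical(self):
        # mean held-out surprisal is non-increasing in training length,
        # averaged over seeded i.i.d. streams
        alphabet = (0, 1, 2, 3)
        probs = np.array([0.5, 0.25, 0.15, 0.1])
        lengths = (4, 16, 64)
        mean_s = np.zeros(len(lengths))
        for seed in range(15):
            rng = np.random.default_rng(seed)
            stream = rng.choice(alphabet, size=max(lengths), p=probs)
            held = rng.choice(alphabet, size=30, p=probs)
            for li, n in enumerate(lengths):
                model = train([tuple(stream[:n])], order_bound=2)
                s_sum = 0.0
                for sym in held:
                    dist = predict(model, (), alphabet)
                    s_sum += -math.log(dist[sym])
                mean_s[li] += s_sum / len(held)
        assert mean_s[0] >= mean_s[1] >= mean_s[2]
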