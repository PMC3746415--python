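"""Repetition coding, channel simulators, flip thresholds, verdicts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cilithermo import (
    K_B,
    LN2,
    bsc_transmit,
    erasure_transmit,
    flip_threshold_entropy,
    majority_decode,
    repetition_error_probability,
    threshold_comparison,
)
from cilithermo.errors import InvalidSpecError


class TestRepetitionCode:
    @pytest.mark.parametrize("p,pe", [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0), (0.1, 0.028)])
    def test_error_probability(self, p, pe):
        assert repetition_error_probability(p) == pytest.approx(pe)

    def test_fixed_points_are_exactly_zero_half_one(self):
        # roots of 3p^2 - 2p^3 - p = -p(2p - 1)(p - 1)
        roots = np.roots([-2.0, 3.0, -1.0, 0.0])
        assert sorted(np.round(roots.real, 12)) == [0.0, 0.5, 1.0]

    def test_coding_gain_region(self, rng):
        p = rng.uniform(1e-3, 0.5 - 1e-3, 200)
        assert (repetition_error_probability(p) < p).all()
        p = rng.uniform(0.5 + 1e-3, 1 - 1e-3, 200)
        assert (repetition_error_probability(p) > p).all()

    def test_domain_error(self):
        with pytest.raises(ValueError):
            repetition_error_probability(1.5)


class TestChannels:
    def test_bsc_identity_and_complement(self):
        bits = np.array([0, 1, 1, 0, 1])
        assert np.array_equal(bsc_transmit(bits, 0.0, seed=1), bits)
        assert np.array_equal(bsc_transmit(bits, 1.0, seed=1), 1 - bits)

    def test_bsc_flip_fraction(self):
        n = 100_000
        bits = np.zeros(n, dtype=int)
        frac = bsc_transmit(bits, 0.5, seed=2).mean()
        assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / n)

    @pytest.mark.parametrize("word,bit", [((1, 1, 0), 1), ((0, 0, 0), 0), ((0, 1, 0), 0)])
    def test_majority_decode(self, word, bit):
        assert majority_decode(np.array(word)) == bit

    def test_even_length_rejected(self):
        with pytest.raises(InvalidSpecError):
            majority_decode(np.array([0, 1]))

    @pytest.mark.parametrize("p", [0.05, 0.1, 0.3])
    def test_monte_carlo_majority_beats_raw_channel(self, p):
        n = 100_000
        words = np.zeros((n, 3), dtype=int)
        received = bsc_transmit(words.ravel(), p, seed=17).reshape(n, 3)
        errors = (received.sum(axis=1) > 1).mean()
        expected = repetition_error_probability(p)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(errors - expected) <= 3 * se
        assert errors < p - 3 * math.sqrt(p * (1 - p) / n)

    def test_erasure_identity_and_forced_replacement(self):
        sym = np.array([3, 1, 4, 1, 5])
        assert np.array_equal(erasure_transmit(sym, 0.0, 7, seed=1), sym)
        assert (erasure_transmit(sym, 1.0, 7, seed=1) == 7).all()

    def test_erasure_replacement_fraction(self):
        n = 100_000
        out = erasure_transmit(np.zeros(n, dtype=int), 0.3, 1, seed=5)
        assert abs(out.mean() - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / n)


class TestFlipThreshold:
    def test_symmetric_half(self):
        # flipping 0.5 leaves the product at 0.125 -> H = 0.375 bits
        s = flip_threshold_entropy(0.5, 0.5, 0.5)
        assert s == pytest.approx(0.375 * K_B * LN2)
        assert s == pytest.approx(3.589e-24, rel=1e-3)

    def test_deterministic_plan_zero(self):
        assert flip_threshold_entropy(1.0, 1.0, 1.0) == 0.0

    def test_hand_value_point_nine(self):
        # each flipped product is 0.1*0.9*0.9 = 0.081; H(0.081) = 0.29367 bits
        s = flip_threshold_entropy(0.9, 0.9, 0.9)
        assert s == pytest.approx(-0.081 * math.log2(0.081) * K_B * LN2)
        assert s == pytest.approx(2.811e-24, rel=1e-3)

    @settings(derandomize=True, max_examples=40)
    @given(
        x=st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)),
    )
    def test_permutation_symmetry_and_nonnegativity(self, x):
        import itertools

        base = flip_threshold_entropy(*x)
        assert base >= 0.0
        for perm in itertools.permutations(x):
            assert flip_threshold_entropy(*perm) == pytest.approx(base, rel=1e-12, abs=1e-40)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            flip_threshold_entropy(1.1, 0.5, 0.5)


class TestThresholdComparison:
    @staticmethod
    def _table(thr, exe, strategy=0):
        m = len(thr)
        return pd.DataFrame(
            {
                "strategy_id": strategy,
                "window": np.arange(1, m + 1),
                "S_threshold": thr,
                "S_executed": exe,
            }
        )

    def test_identical_series_at_threshold(self):
        thr = np.linspace(1e-24, 2e-24, 20)
        out = threshold_comparison(self._table(thr, thr.copy()))
        assert out.loc[0, "verdict"] == "at_threshold"

    def test_constant_deficit_below_threshold(self, rng):
        thr = np.linspace(1e-24, 2e-24, 30)
        exe = thr - 2e-25 + rng.normal(0, 1e-26, 30)
        out = threshold_comparison(self._table(thr, exe))
        assert out.loc[0, "verdict"] == "below_threshold"

    def test_constant_excess_above_threshold(self, rng):
        thr = np.linspace(1e-24, 2e-24, 30)
        exe = thr + 2e-25 + rng.normal(0, 1e-26, 30)
        out = threshold_comparison(self._table(thr, exe))
        assert out.loc[0, "verdict"] == "above_threshold"

    def test_single_pair_insufficient(self):
        out = threshold_comparison(self._table([1e-24], [2e-24]))
        assert out.loc[0, "verdict"] == "insufficient_data"
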