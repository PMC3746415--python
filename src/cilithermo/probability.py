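"""Planned and executed Bayesian probability distributions over strategies.

At every window n of a session two distributions over the 2^d strategies
are maintained:

* the *planned* (expected) distribution — the cell's plan given its history:
  per-trial response probabilities are Beta-posterior means computed from
  the trials *before* the current one (Laplace's rule of succession with a
  Beta(a, b) prior), and a strategy's planned probability is the product of
  its per-position probabilities, p_P(s) = prod_k x_k where x_k is the
  expected probability of the bit the strategy specifies at that position;

* the *executed* (observed) distribution — the add-alpha-smoothed cumulative
  empirical frequency of each strategy among windows 1..n.

Both are proper Bayesian point estimates, strictly positive (so entropy
terms are finite), and genuinely different stages: expectation versus
realization.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .constants import EMBEDDING_DIM
from .errors import InsufficientDataError, InvalidSpecError
from .strategies import StrategyWindowSeries, strategy_table


def estimate_position_probabilities(
    bits: np.ndarray, prior_a: float = 1.0, prior_b: float = 1.0
) -> np.ndarray:
    """Predictive response probability at each trial from the preceding trials.

    q_i = (a + sum_{j<i} bits_j) / (a + b + (i - 1)); q_1 = a / (a + b).
    Strictly inside (0, 1) for positive priors.
    """
    if prior_a <= 0 or prior_b <= 0:
        raise InvalidSpecError("Beta prior parameters must be positive")
    bits = np.asarray(bits, dtype=float)
    n = bits.shape[0]
    prefix = np.concatenate([[0.0], np.cumsum(bits)[:-1]])
    return (prior_a + prefix) / (prior_a + prior_b + np.arange(n))


def planned_distribution(q: np.ndarray, d: int = EMBEDDING_DIM) -> np.ndarray:
    """Planned probabilities of all 2^d strategies at every window.

    Returns an (m, 2^d) array; row n is the product-Bernoulli distribution
    built from the expected per-position probabilities q_{n..n+d-1}, so each
    row sums to 1 exactly (up to float rounding).
    """
    q = np.asarray(q, dtype=float)
    if q.shape[0] < d:
        raise InsufficientDataError("fewer position probabilities than window length")
    if np.any((q < 0) | (q > 1)):
        raise InvalidSpecError("position probabilities must lie in [0, 1]")
    Q = sliding_window_view(q, d)  # (m, d)
    B = strategy_table(d)  # (2^d, d)
    probs = np.where(B[None, :, :] == 1, Q[:, None, :], 1.0 - Q[:, None, :])
    return probs.prod(axis=2)


def executed_distribution(
    series: StrategyWindowSeries | np.ndarray,
    smoothing: float = 1.0,
    d: int | None = None,
) -> np.ndarray:
    """Executed probabilities of all strategies at every window.

    p_E(s, n) = (alpha + #{s among windows 1..n}) / (2^d * alpha + n):
    cumulative empirical frequency with add-alpha smoothing, updated through
    the current window.  Rows sum to 1 and all entries are positive.
    """
    if smoothing <= 0:
        raise InvalidSpecError("smoothing constant must be positive")
    if isinstance(series, StrategyWindowSeries):
        sids = series.strategy_ids
        d = series.d
    else:
        sids = np.asarray(series)
        if d is None:
            raise InvalidSpecError("d required when passing a raw label sequence")
    m = sids.shape[0]
    if m < 1:
        raise InsufficientDataError("empty window series")
    k = 2**d
    onehot = np.zeros((m, k))
    onehot[np.arange(m), sids] = 1.0
    cum = np.cumsum(onehot, axis=0)
    n = np.arange(1, m + 1, dtype=float)[:, None]
    return (smoothing + cum) / (k * smoothing + n)
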