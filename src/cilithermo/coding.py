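"""Repetition coding, noisy channels, and bit-flip error thresholds.

Three-bit repetition coding sends a logical bit as (0,0,0) or (1,1,1) and
decodes by majority voting; over a binary symmetric channel with flip
probability p the decoded error probability is p_E = 3p^2 - 2p^3, an
improvement over the raw channel exactly for p < 1/2 (fixed points of the
map are 0, 1/2 and 1).

The *error-threshold entropy* of a planned strategy introduces a single
bit-flip at each of its d positions in expectation — the position's
expected probability x_i is replaced by its complement f_i = 1 - x_i — and
averages the resulting single-probability entropy terms:

    S_sn = mean_i H(prod with position i flipped) * k_B ln 2.

Executed strategies whose Boltzmann entropies do not significantly exceed
these thresholds are protected by the repetition code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import K_B, LN2
from .errors import InvalidSpecError
from .engine import shannon_term
from .stats import paired_t

VERDICT_BELOW = "below_threshold"
VERDICT_AT = "at_threshold"
VERDICT_ABOVE = "above_threshold"


def repetition_error_probability(p):
    """Decoded error probability of the 3-bit repetition code, 3p^2 - 2p^3."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("flip probability outside [0, 1]")
    out = 3.0 * p**2 - 2.0 * p**3
    return out if out.ndim else float(out)


def bsc_transmit(bits: np.ndarray, p: float, seed: int) -> np.ndarray:
    """Transmit a binary word through a binary symmetric channel.

    Each bit is independently flipped with probability p; reproducible for
    a fixed seed.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("flip probability outside [0, 1]")
    bits = np.asarray(bits, dtype=np.int8)
    rng = np.random.default_rng(seed)
    flips = rng.random(bits.shape) < p
    return np.where(flips, 1 - bits, bits).astype(np.int8)


def majority_decode(word: np.ndarray) -> int:
    """Majority-voting decoder for an odd-length binary codeword."""
    word = np.asarray(word)
    if word.shape[-1] % 2 == 0:
        raise InvalidSpecError("majority decoding requires an odd code length")
    return int(word.sum(axis=-1) > word.shape[-1] // 2)


def erasure_transmit(
    symbols: np.ndarray,
    p: float,
    replacement_source,
    seed: int,
) -> np.ndarray:
    """Pass symbols through a memory (erasure) channel.

    Each symbol is transmitted intact with probability 1 - p and replaced
    with probability p by a symbol drawn from ``replacement_source`` — a
    scalar (deterministic replacement, e.g. a stored reference code) or a
    callable ``(rng, size) -> array``.  Memory-less across symbols.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("erasure probability outside [0, 1]")
    symbols = np.asarray(symbols)
    rng = np.random.default_rng(seed)
    replace = rng.random(symbols.shape) < p
    if callable(replacement_source):
        repl = np.asarray(replacement_source(rng, symbols.shape))
    else:
        repl = np.broadcast_to(np.asarray(replacement_source), symbols.shape)
    return np.where(replace, repl, symbols)


def flip_threshold_entropy(x1, x2, x3):
    """Flip-averaged threshold Boltzmann entropy S_sn of a planned triplet.

    x_i are the expected probabilities of the bit values the strategy
    specifies at its three positions; each is flipped in turn to
    f_i = 1 - x_i, and the three single-flip entropy terms are averaged and
    converted via Landauer.  Symmetric under permutation of the x_i, zero
    for deterministic plans (any x_i = 1 makes every flipped product 0 or
    the unflipped factors 1).
    """
    x = np.stack(np.broadcast_arrays(
        np.asarray(x1, dtype=float),
        np.asarray(x2, dtype=float),
        np.asarray(x3, dtype=float),
    ), axis=-1)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("position probabilities outside [0, 1]")
    f = 1.0 - x
    total = np.zeros(x.shape[:-1])
    for i in range(3):
        prod = f[..., i].copy()
        for j in range(3):
            if j != i:
                prod = prod * x[..., j]
        total = total + shannon_term(prod)
    out = (total / 3.0) * K_B * LN2
    return out if out.ndim else float(out)


def flip_threshold_series(position_probs: np.ndarray) -> np.ndarray:
    """S_sn per window from an (m, 3) array of per-position probabilities."""
    x = np.asarray(position_probs, dtype=float)
    return flip_threshold_entropy(x[:, 0], x[:, 1], x[:, 2])


def threshold_comparison(
    table: pd.DataFrame,
    by: tuple[str, ...] = ("strategy_id",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired comparison of executed entropies against flip thresholds.

    ``table`` must have columns ``window``, ``S_threshold``, ``S_executed``
    plus the grouping columns in ``by`` (typically ``strategy_id``, often
    with responsiveness group and behavior).  Observations are first
    averaged across cells within each (group, window) pair, then a
    two-tailed paired t-test is run over windows.  Verdicts:

    * ``below_threshold`` — executed significantly lower (p < alpha, mean
      difference negative);
    * ``above_threshold`` — executed significantly higher;
    * ``at_threshold`` — no significant difference (including the
      zero-variance all-equal case resolved by the zero-difference rule).

    Strategies with fewer than 2 paired windows are flagged
    ``insufficient_data`` with NaN statistics.
    """
    rows = []
    for keys, grp in table.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        per_window = grp.groupby("window")[["S_threshold", "S_executed"]].mean()
        thr = per_window["S_threshold"].to_numpy()
        exe = per_window["S_executed"].to_numpy()
        base = dict(zip(by, keys))
        base.update(
            n_pairs=len(per_window),
            mean_flip=float(np.mean(thr)) if len(thr) else np.nan,
            sem_flip=float(np.std(thr, ddof=1) / np.sqrt(len(thr))) if len(thr) > 1 else np.nan,
            mean_executed=float(np.mean(exe)) if len(exe) else np.nan,
            sem_executed=float(np.std(exe, ddof=1) / np.sqrt(len(exe))) if len(exe) > 1 else np.nan,
        )
        if len(per_window) < 2:
            base.update(t=np.nan, df=np.nan, p_value=np.nan, verdict="insufficient_data")
        else:
            res = paired_t(exe, thr)
            verdict = VERDICT_AT
            if res.flag is None and res.p_value < alpha:
                verdict = VERDICT_ABOVE if res.mean_difference > 0 else VERDICT_BELOW
            elif res.flag == "degenerate_constant_difference":
                verdict = VERDICT_ABOVE if res.mean_difference > 0 else VERDICT_BELOW
            base.update(t=res.statistic, df=res.df, p_value=res.p_value, verdict=verdict)
        rows.append(base)
    return pd.DataFrame(rows)
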