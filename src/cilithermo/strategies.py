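"""Sequential-series embedding of binary response series into serial strategies.

A 60-trial all-or-none response series is embedded as the m x d matrix of
overlapping d-bit windows (step 1), each window being one serial behavioral
strategy — a Cartesian coordinate of the d-dimensional binary state space.
For d = 3 there are exactly 2^3 = 8 strategies, from (0,0,0) (ideal low
responsiveness, "prudent savings") to (1,1,1) (ideal high responsiveness,
"conspicuous consumption"), and a 60-trial series yields m = 58 windows.

The strategy occurring most often across a cell's windows is its *modal*
strategy; all others are non-modal.  Responsiveness Omega of a strategy is
the fraction of responses among its d bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .constants import EMBEDDING_DIM
from .errors import InsufficientDataError, InvalidSpecError


def strategy_table(d: int = EMBEDDING_DIM) -> np.ndarray:
    """All 2^d strategies as a (2^d, d) binary array; row index = strategy id.

    Ids are the big-endian binary value of the triplet, e.g. for d = 3:
    (0,0,0) -> 0, (0,0,1) -> 1, ..., (1,1,1) -> 7.
    """
    ids = np.arange(2**d)
    return (ids[:, None] >> np.arange(d - 1, -1, -1)) & 1


def strategy_id(triplet: np.ndarray, d: int | None = None) -> int:
    """Big-endian integer id of a strategy word."""
    triplet = np.asarray(triplet)
    if d is None:
        d = triplet.shape[-1]
    weights = 2 ** np.arange(d - 1, -1, -1)
    return int(triplet @ weights)


def strategy_responsiveness(triplet: np.ndarray) -> float:
    """Responsiveness Omega: fraction of responses in the strategy word."""
    triplet = np.asarray(triplet)
    if not np.isin(triplet, (0, 1)).all():
        raise InvalidSpecError(f"strategy word must be binary, got {triplet!r}")
    return float(triplet.mean())


@dataclass(eq=False)
class StrategyWindowSeries:
    """Overlapping d-bit windows of one response series.

    Attributes
    ----------
    windows : (m, d) int array, row i = bits of window i (1-based index i+1)
    strategy_ids : (m,) int array of big-endian strategy ids
    omega : (m,) float array, per-window responsiveness
    d : embedding dimension
    """

    windows: np.ndarray
    strategy_ids: np.ndarray
    omega: np.ndarray
    d: int

    @property
    def m(self) -> int:
        return self.windows.shape[0]

    def reconstruct_bits(self) -> np.ndarray:
        """Recover the original series from the overlapping windows."""
        return np.concatenate([self.windows[0], self.windows[1:, -1]])


@dataclass(eq=False)
class StrategyCatalog:
    """Occurrence counts over the full 2^d strategy set, with the modal one."""

    counts: np.ndarray
    modal_id: int
    is_modal: np.ndarray  # per-window flag


def embed_sequential_series(bits: np.ndarray, d: int = EMBEDDING_DIM) -> StrategyWindowSeries:
    """Embed a binary series into its m = n - d + 1 overlapping d-bit windows."""
    bits = np.asarray(bits)
    if d < 1:
        raise InvalidSpecError("embedding dimension d must be >= 1")
    if bits.ndim != 1 or bits.shape[0] < d:
        raise InsufficientDataError(
            f"series of length {bits.shape[0] if bits.ndim == 1 else '?'} "
            f"is shorter than embedding dimension {d}"
        )
    if not np.isin(bits, (0, 1)).all():
        raise InvalidSpecError("response series must be binary (0/1)")
    windows = sliding_window_view(bits, d).astype(np.int8)
    weights = 2 ** np.arange(d - 1, -1, -1)
    sids = windows @ weights
    return StrategyWindowSeries(
        windows=windows,
        strategy_ids=sids.astype(np.int64),
        omega=windows.mean(axis=1),
        d=d,
    )


def find_modal(series: StrategyWindowSeries) -> StrategyCatalog:
    """Catalog strategy counts and flag the modal strategy's windows.

    Ties between equally frequent strategies break toward the one whose
    first occurrence is earliest in the session (deterministic,
    data-driven).  Unobserved strategies carry count 0.
    """
    if series.m < 1:
        raise InsufficientDataError("empty window series")
    counts = np.bincount(series.strategy_ids, minlength=2**series.d)
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if candidates.shape[0] == 1:
        modal = int(candidates[0])
    else:
        first_occurrence = {
            int(s): int(np.argmax(series.strategy_ids == s)) for s in candidates
        }
        modal = min(first_occurrence, key=first_occurrence.get)
    return StrategyCatalog(
        counts=counts,
        modal_id=modal,
        is_modal=series.strategy_ids == modal,
    )
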