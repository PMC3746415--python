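"""Szilard-engine metrics of strategy planning-execution corrective cycles.

The entropy bookkeeping treats a cell's planning and execution stages as the
two information reservoirs of a Szilard engine.  Per strategy and window the
entropy is the single-probability Shannon term H(p) = -p log2 p (not the
full-distribution entropy, which is provided separately as a diagnostic),
converted to physical units by Landauer's principle without the temperature
factor: S = H * k_B * ln 2 [J/K].

Engine indices per corrective cycle:

    work        W   = S_planned - |S_executed|          [J/K]
    power       P   = dW / dt                           [J/K per s]
    efficiency  eps = W / S_planned                     (heat engine)
    COP             = S_executed / W                    (refrigeration)
    fidelity    F   = sqrt(p_P * p_E)                   in [0, 1]

Negative W/P/eps denote refrigeration cycles, positive denote power strokes,
W = 0 a null cycle.  Undefined ratios (W = 0 or S_planned = 0) are returned
as NaN, never silent zeros, and are excluded pairwise downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import K_B, LN2
from .errors import InsufficientDataError

CYCLE_POWER_STROKE = "power_stroke"
CYCLE_REFRIGERATION = "refrigeration"
CYCLE_NULL = "null"


def shannon_term(p):
    """Per-strategy Shannon entropy term -p log2 p (0 log 0 = 0), in bits."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability outside [0, 1]")
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = -p[nz] * np.log2(p[nz])
    return out if out.ndim else float(out)


def distribution_entropy(p: np.ndarray, axis: int = -1):
    """Full Shannon entropy of a distribution, in bits (diagnostic)."""
    p = np.asarray(p, dtype=float)
    terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=axis)


def boltzmann_entropy(h_bits):
    """Landauer conversion S = H * k_B * ln 2 (temperature dropped), J/K."""
    h = np.asarray(h_bits, dtype=float)
    if np.any(h < 0):
        raise ValueError("entropy must be non-negative")
    out = h * K_B * LN2
    return out if out.ndim else float(out)


def fidelity(p_planned, p_executed):
    """Planning-execution agreement F = sqrt(p_P * p_E), in [0, 1]."""
    p_p = np.asarray(p_planned, dtype=float)
    p_e = np.asarray(p_executed, dtype=float)
    if np.any((p_p < 0) | (p_p > 1)) or np.any((p_e < 0) | (p_e > 1)):
        raise ValueError("probabilities outside [0, 1]")
    out = np.sqrt(p_p * p_e)
    return out if out.ndim else float(out)


@dataclass(eq=False)
class EngineMetrics:
    """Vectorized per-window engine indices."""

    W: np.ndarray
    P: np.ndarray
    eff: np.ndarray
    cop: np.ndarray
    cycle: np.ndarray  # array of cycle-type strings


def engine_metrics(
    S_planned: np.ndarray, S_executed: np.ndarray, dt_s: float
) -> EngineMetrics:
    """Work, power, efficiency, COP and cycle type for a window series.

    Power is the first difference of work between consecutive windows over
    the inter-window time step dt_s; the first window uses W_1 / dt_s.
    """
    S_p = np.asarray(S_planned, dtype=float)
    S_e = np.asarray(S_executed, dtype=float)
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    W = S_p - np.abs(S_e)
    P = np.empty_like(W)
    P[0] = W[0] / dt_s
    P[1:] = np.diff(W) / dt_s
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(S_p > 0, W / np.where(S_p > 0, S_p, 1.0), np.nan)
        cop = np.where(W != 0, S_e / np.where(W != 0, W, 1.0), np.nan)
    cycle = np.where(W > 0, CYCLE_POWER_STROKE, np.where(W < 0, CYCLE_REFRIGERATION, CYCLE_NULL))
    return EngineMetrics(W=W, P=P, eff=eff, cop=cop, cycle=cycle)


def mutual_information(labels_x: np.ndarray, labels_y: np.ndarray, k: int = 8) -> float:
    """Mutual information (bits) of the empirical joint of two label sequences."""
    x = np.asarray(labels_x)
    y = np.asarray(labels_y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("label sequences must have equal length")
    n = x.shape[0]
    if n == 0:
        raise InsufficientDataError("empty label sequences")
    joint = np.zeros((k, k))
    np.add.at(joint, (x, y), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    denom = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / denom[nz])))


@dataclass(eq=False)
class ChannelCapacityEstimate:
    """Per-prefix mutual information of the planning->execution channel."""

    mi_per_prefix: np.ndarray
    max_mi: float
    argmax_prefix: int  # 1-based prefix length attaining the maximum


def channel_capacity(
    planned_labels: np.ndarray, executed_labels: np.ndarray, k: int = 8
) -> ChannelCapacityEstimate:
    """Erasure-channel capacity of planning -> execution, per window prefix.

    For every prefix length n the MI of the empirical joint of
    (planned-argmax strategy, executed strategy) pairs over windows 1..n is
    computed in bits; the maximum over prefixes estimates the channel
    capacity.  Bounded by log2(k) = d bits.
    """
    x = np.asarray(planned_labels)
    y = np.asarray(executed_labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("label sequences must have equal length")
    if x.shape[0] == 0:
        raise InsufficientDataError("empty label sequences")
    mi = np.array([mutual_information(x[:n], y[:n], k=k) for n in range(1, x.shape[0] + 1)])
    best = int(np.argmax(mi))
    return ChannelCapacityEstimate(
        mi_per_prefix=mi, max_mi=float(mi[best]), argmax_prefix=best + 1
    )
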