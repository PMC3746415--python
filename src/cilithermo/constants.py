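"""Physical and experimental constants of the vibration-stimulation paradigm.

The behavioral sessions this package analyses deliver mechanical stimuli
(percussion-driven shock waves) to individually housed *Spirostomum
ambiguum* at 0.1 Hz for 10 minutes, i.e. 60 stimuli spaced 10 s apart.
Each all-or-none response series is embedded as overlapping 3-bit serial
strategies, so one strategy "state" spans three consecutive inter-stimulus
intervals (30 s).
"""

import math

#: Boltzmann constant, J/K (CODATA, exact by SI definition).
K_B = 1.380649e-23

#: Natural log of 2 — the Landauer factor converting bits to nats.
LN2 = math.log(2.0)

#: Stimulation rate of the percussion piston, Hz.
STIMULUS_RATE_HZ = 0.1

#: Inter-stimulus interval, seconds (1 / STIMULUS_RATE_HZ).
ISI_S = 1.0 / STIMULUS_RATE_HZ

#: Session duration, seconds (10 min of stimulation).
SESSION_S = 600.0

#: Embedding dimension of the serial-strategy state space.
EMBEDDING_DIM = 3

#: Number of stimuli per session.
N_TRIALS = 60

#: Number of first trials used to stratify initial responsiveness.
N_INITIAL_TRIALS = 5


def n_stimuli(rate_hz: float = STIMULUS_RATE_HZ, duration_s: float = SESSION_S) -> int:
    """Number of stimuli delivered in a session (rate x duration)."""
    return round(rate_hz * duration_s)


def state_period_s(d: int = EMBEDDING_DIM, isi_s: float = ISI_S) -> float:
    """Duration of one d-bit strategy state: d consecutive inter-stimulus intervals."""
    return d * isi_s


def response_rate_hz(probability: float, rate_hz: float = STIMULUS_RATE_HZ) -> float:
    """Map a per-stimulus response probability to an absolute response rate.

    A cell answering every 0.1-Hz stimulus (probability 1.0) responds at
    0.1 Hz; probability intervals 0.0-0.2 / 0.4-0.6 / 0.8-1.0 map to rate
    intervals 0.00-0.02 / 0.04-0.06 / 0.08-0.10 Hz.
    """
    return probability * rate_hz
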