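"""Closed-form collision and translocation kinetics.

These are the back-of-envelope relations that connect the simulation
parameters to directly interpretable quantities: the competing-exponential
pause statistics at a replisome block, the memory-zone width implied by a
memory duration and fork speed, and simple traversal-time arithmetic.
"""

from __future__ import annotations

import numpy as np


def competing_pause_stats(tau_unload: float, tau_bypass: float) -> tuple[float, float, float]:
    """(mean pause, P(unload), P(bypass)) for independent exponential clocks.

    The first clock to fire wins: the pause is Exp with mean
    ``1/(1/tau_unload + 1/tau_bypass)`` and the unloading probability is
    ``tau_bypass / (tau_unload + tau_bypass)``.  Infinite means are allowed
    (a disabled clock); if both are infinite the pause is infinite and the
    split undefined (returned as nan).
    """
    tu, tb = float(tau_unload), float(tau_bypass)
    if np.isinf(tu) and np.isinf(tb):
        return np.inf, np.nan, np.nan
    if tu == 0:
        return 0.0, 1.0, 0.0
    if tb == 0:
        return 0.0, 0.0, 1.0
    rate = (0.0 if np.isinf(tu) else 1.0 / tu) + (0.0 if np.isinf(tb) else 1.0 / tb)
    mean = 1.0 / rate
    p_unload = (0.0 if np.isinf(tu) else 1.0 / tu) / rate
    return mean, p_unload, 1.0 - p_unload


def memory_distance_kb(t_memory_s: float, fork_speed_kb_min: float) -> float:
    """Width of the fork-memory zone in kb: t_memory × v_fork."""
    return t_memory_s / 60.0 * fork_speed_kb_min


def traversal_time_min(distance_kb: float, speed_kb_min: float) -> float:
    """Minutes for a motor to cover ``distance_kb`` at ``speed_kb_min``."""
    if speed_kb_min <= 0:
        raise ValueError("speed must be > 0")
    return distance_kb / speed_kb_min


def time_to_reach_min(distance_kb: float, speed_kb_min: float, loading_lag_min: float = 5.0) -> float:
    """Loading lag plus traversal time: when a freshly induced SMC arrives."""
    return loading_lag_min + traversal_time_min(distance_kb, speed_kb_min)


def chasing_speed_kb_min(arm_speed_ratio: float, v_reference_kb_min: float) -> float:
    """Speed of the slower (fork-chasing) motor from the arc speed ratio
    times the reference (origin-directed) motor speed."""
    return arm_speed_ratio * v_reference_kb_min
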