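"""Stochastic per-cell replisome dynamics for a synchronized replication round.

Five behavioural parameters govern the population (:class:`ReplisomeParams`):
a fraction of cells that escaped G1 arrest and carry a pre-existing fork
pair; an exponential replisome-loading delay that runs only while initiation
is permitted (30 °C); elongation speeds at 30 °C and 42 °C; and a small
per-fork rate of irreversible spontaneous stalling.  A single initiation
clock simultaneously produces the sub-unity initiation fraction (cells whose
clock does not fire inside the permissive window never initiate) and the
gradual origin-proximal rise of mid-course marker-frequency profiles.

Replication is represented on a single-sister coordinate: each initiated
cell has a left fork on [−L/2, 0] and a right fork on [0, +L/2]; the
replicated set is the interval between them, so per-cell copy number is 1 or
2 everywhere and population MFA lies in [1, 2].  HPUra freezes all forks in
place without removing them; there is no restart, degradation, or
re-initiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeSpec
from .protocol import EnvState, Protocol, env_at


@dataclass(frozen=True)
class ReplisomeParams:
    """Population replication parameters.

    f_pre        fraction of cells with a pre-existing fork pair at T=0
    t_init_mean  mean (minutes) of the exponential replisome-loading delay;
                 the default 15/ln 20 ≈ 5.0 min makes 95% of cells initiate
                 within a 15-min permissive window
    v30, v42     elongation speed (kb/min) at 30 °C and 42 °C
    p_stall      per-fork probability per minute of irreversible stalling
    """

    f_pre: float = 0.18
    t_init_mean: float = 15.0 / np.log(20.0)
    v30: float = 40.0
    v42: float = 66.0
    p_stall: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_pre <= 1.0:
            raise ValueError("f_pre must be in [0, 1]")
        if self.v30 <= 0 or self.v42 <= 0:
            raise ValueError("elongation speeds must be > 0")
        if not 0.0 <= self.p_stall < 1.0:
            raise ValueError("p_stall must be in [0, 1)")
        if self.t_init_mean < 0:
            raise ValueError("t_init_mean must be >= 0")

    def speed(self, temperature: float) -> float:
        """Elongation speed (kb/min) at the given temperature."""
        return self.v30 if temperature == 30.0 else self.v42


@dataclass
class ForkEnsemble:
    """Vectorized fork state for a population of cells (the CellState fork part).

    left_pos/right_pos are signed bp; left forks move toward −L/2, right
    forks toward +L/2.  Positions are meaningful only where ``initiated``.
    """

    initiated: np.ndarray      # bool (n,)
    pending_delay: np.ndarray  # float (n,): permissive minutes left on the initiation clock
    left_pos: np.ndarray       # float (n,)
    right_pos: np.ndarray      # float (n,)
    left_stalled: np.ndarray   # bool (n,)
    right_stalled: np.ndarray  # bool (n,)
    pre_existing: np.ndarray   # bool (n,)
    time_min: float = 0.0

    @property
    def n_cells(self) -> int:
        return self.initiated.size

    def completed(self, genome: GenomeSpec) -> np.ndarray:
        half = genome.length / 2
        return self.initiated & (self.left_pos <= -half) & (self.right_pos >= half)

    def copy(self) -> "ForkEnsemble":
        return ForkEnsemble(
            initiated=self.initiated.copy(),
            pending_delay=self.pending_delay.copy(),
            left_pos=self.left_pos.copy(),
            right_pos=self.right_pos.copy(),
            left_stalled=self.left_stalled.copy(),
            right_stalled=self.right_stalled.copy(),
            pre_existing=self.pre_existing.copy(),
            time_min=self.time_min,
        )

    def copy_number(self, positions: np.ndarray) -> np.ndarray:
        """Per-cell copy number (1 or 2) at signed positions: (n_cells, n_pos)."""
        pos = np.asarray(positions, dtype=float)[None, :]
        covered = (
            self.initiated[:, None]
            & (pos >= self.left_pos[:, None])
            & (pos <= self.right_pos[:, None])
        )
        return 1 + covered.astype(np.int8)

    def to_table(self):
        """Snapshot as a tidy table (cell id, time, positions, flags)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "cell": np.arange(self.n_cells),
                "time_min": self.time_min,
                "initiated": self.initiated,
                "left_pos": self.left_pos,
                "right_pos": self.right_pos,
                "left_stalled": self.left_stalled,
                "right_stalled": self.right_stalled,
                "pre_existing": self.pre_existing,
            }
        )


def init_population(
    params: ReplisomeParams,
    genome: GenomeSpec,
    n_cells: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ForkEnsemble:
    """Population at T=0: a fraction ``f_pre`` carries a pre-existing fork pair
    whose arm-progress fraction is uniform on (0, 1) (equal on both arms);
    the remainder is unreplicated with a fresh exponential initiation clock."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    half = genome.length / 2
    pre = rng.random(n_cells) < params.f_pre
    progress = rng.uniform(0.0, 1.0, size=n_cells)
    left = np.where(pre, -progress * half, 0.0)
    right = np.where(pre, progress * half, 0.0)
    if params.t_init_mean > 0:
        delay = rng.exponential(params.t_init_mean, size=n_cells)
    else:
        delay = np.zeros(n_cells)
    return ForkEnsemble(
        initiated=pre.copy(),
        pending_delay=np.where(pre, np.inf, delay),
        left_pos=left,
        right_pos=right,
        left_stalled=np.zeros(n_cells, dtype=bool),
        right_stalled=np.zeros(n_cells, dtype=bool),
        pre_existing=pre,
    )


def step_forks(
    state: ForkEnsemble,
    env: EnvState,
    params: ReplisomeParams,
    dt: float,
    rng: np.random.Generator,
    genome: GenomeSpec,
) -> ForkEnsemble:
    """Advance the population by ``dt`` minutes in place (returns ``state``).

    Initiation clocks run only while ``env.initiation_allowed``; active,
    unstalled forks move at the temperature-specific speed; HPUra
    (``env.forks_stalled``) freezes every fork without removing it; each
    active fork stalls irreversibly with probability ``p_stall * dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    half = genome.length / 2

    if env.initiation_allowed:
        state.pending_delay -= np.where(state.initiated, 0.0, dt)
        fire = (~state.initiated) & (state.pending_delay <= 0.0)
        state.initiated |= fire
        # new fork pairs start at the origin
        state.left_pos[fire] = 0.0
        state.right_pos[fire] = 0.0

    if not env.forks_stalled:
        v_bp = params.speed(env.temperature) * 1000.0 * dt  # bp per step
        mov_l = state.initiated & ~state.left_stalled
        mov_r = state.initiated & ~state.right_stalled
        state.left_pos = np.where(mov_l, np.maximum(state.left_pos - v_bp, -half), state.left_pos)
        state.right_pos = np.where(mov_r, np.minimum(state.right_pos + v_bp, half), state.right_pos)
        if params.p_stall > 0:
            p = params.p_stall * dt
            state.left_stalled |= mov_l & (state.left_pos > -half) & (rng.random(state.n_cells) < p)
            state.right_stalled |= mov_r & (state.right_pos < half) & (rng.random(state.n_cells) < p)

    state.time_min += dt
    return state


def simulate_replication(
    protocol: Protocol,
    params: ReplisomeParams,
    genome: GenomeSpec,
    n_cells: int,
    seed: int,
    sample_times: tuple[float, ...] | None = None,
    dt: float = 0.1,
) -> list[tuple[float, ForkEnsemble]]:
    """Run the fork-only simulation and return snapshots at the sample times.

    ``sample_times`` defaults to the protocol's SAMPLE events and must be a
    subset of them when both are given.  Deterministic for a given seed.
    """
    if sample_times is None:
        sample_times = protocol.sample_times
    elif protocol.sample_times and not set(sample_times) <= set(protocol.sample_times):
        raise ValueError("sample_times must be a subset of the protocol's SAMPLE events")
    if not sample_times:
        raise ValueError("no sample times requested")
    rng = np.random.default_rng(seed)
    state = init_population(params, genome, n_cells, rng=rng)

    snapshots: list[tuple[float, ForkEnsemble]] = []
    pending = sorted(sample_times)
    if pending[0] <= 0.0:
        while pending and pending[0] <= 0.0:
            snapshots.append((pending.pop(0), state.copy()))
    t = 0.0
    horizon = max(sample_times)
    # align steps to protocol breakpoints so env changes land exactly on a step
    cuts = sorted({*(b for b in protocol.breakpoints() if 0 < b <= horizon), *pending, horizon})
    for cut in cuts:
        while t < cut - 1e-9:
            step = min(dt, cut - t)
            env = env_at(protocol, t)
            step_forks(state, env, params, step, rng, genome)
            t += step
        while pending and pending[0] <= t + 1e-9:
            snap = state.copy()
            snap.time_min = pending[0]
            snapshots.append((pending.pop(0), snap))
    return snapshots
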