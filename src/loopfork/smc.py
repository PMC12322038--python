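"""Two-motor SMC loop-extrusion dynamics with replisome collisions.

Each SMC complex (loop-extruding unit) loads at a single position — most
often a parS site — and its two motors translocate away from the loading
site in opposite directions along the circle, zipping the flanking DNA.
Motors move at a direction-dependent base speed (terminus-directed vs
origin-directed), scaled by a "fork memory" factor on recently replicated
DNA, and stop at the terminus.  Complexes dissociate spontaneously with an
exponential residence time and re-load from a fixed pool, keeping at most
``n_smc`` complexes bound per chromosome.

When a motor meets a replication fork it is blocked at (and carried with)
the fork.  A blocked motor then resolves by competing exponential clocks:
an unloading clock that removes the whole complex and a bypass clock that
places the motor just past the fork.  The pure bypassing / blocking /
unloading models are the limits of this engine with one or both clocks
switched off.

The fork-memory factor is linear in time-since-replication:
``m = clip(age / t_memory, 0, 1)`` with ``age = now − replication time`` of
the locus under the motor; unreplicated DNA (and DNA replicated before the
current round) has ``m = 1``, and the locus at a moving fork has age ≈ 0,
so ``m = 0`` exactly at the fork.  For a fork moving at constant speed this
is identical to a linear ramp over the distance ``t_memory × v_fork``
behind the fork, and it resolves on its own behind a stalled fork once the
local age exceeds ``t_memory``.

:func:`simulate_arc2` is the stand-alone reduced model used for the
fork-chasing arc: independent motor pairs against a deterministic fork,
with the memory slowdown but no blocking clocks, pushing, or unloading.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .genome import GenomeSpec
from .protocol import Protocol, env_at
from .replisome import ForkEnsemble, ReplisomeParams, init_population, step_forks

#: resolution of the per-cell replication-time grid (bp)
MEM_BIN = 1000
#: a bypassing motor is placed this far past the fork, in its own direction (bp)
BYPASS_OFFSET = 1000

ENGAGEMENT_MODELS = ("combined", "bypass_only", "block_only", "unload_only")


class Encounter(enum.Enum):
    NONE = "none"
    HEAD_ON = "head_on"
    HEAD_TO_TAIL = "head_to_tail"


class Outcome(enum.IntEnum):
    BLOCK = 0   # no clock fires: blocked until the fork state changes
    UNLOAD = 1
    BYPASS = 2


@dataclass(frozen=True)
class SMCParams:
    """Loop-extrusion parameters.

    n_smc          complexes per chromosome (pool size and bound-count cap)
    v_to_ter       motor speed toward the terminus, kb/min
    v_to_ori       motor speed toward the origin, kb/min (equal to v_to_ter
                   in origin-proximal parS scenarios)
    tau_dissoc     mean spontaneous residence time, seconds
    parS_weight    loading propensity of one parS site relative to
                   ``background_weight`` per bp of non-parS DNA; the default
                   puts >95% of loading events at a single parS
    tau_unload     mean of the unloading clock at a block, seconds
    tau_bypass     mean of the bypass clock at a block, seconds
    engagement_model  one of combined | bypass_only | block_only | unload_only
    t_memory       fork-memory duration, seconds (0 disables the slowdown)
    k_load         loading rate per unbound pool complex, per second
    """

    n_smc: int = 40
    v_to_ter: float = 71.5
    v_to_ori: float = 49.0
    tau_dissoc: float = 1200.0
    parS_weight: float = 1.0e8
    background_weight: float = 1.0
    tau_unload: float = 30.0
    tau_bypass: float = 120.0
    engagement_model: str = "combined"
    t_memory: float = 700.0
    k_load: float = 1.0 / 60.0

    def __post_init__(self) -> None:
        if self.engagement_model not in ENGAGEMENT_MODELS:
            raise ValueError(f"unknown engagement_model {self.engagement_model!r}")
        for name in ("v_to_ter", "v_to_ori", "tau_dissoc", "k_load"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t_memory < 0 or self.tau_unload < 0 or self.tau_bypass < 0:
            raise ValueError("times must be >= 0")

    def effective_taus(self) -> tuple[float, float]:
        """(tau_unload, tau_bypass) with the single-rule models embedded as limits."""
        if self.engagement_model == "combined":
            return self.tau_unload, self.tau_bypass
        if self.engagement_model == "block_only":
            return np.inf, np.inf
        if self.engagement_model == "unload_only":
            return self.tau_unload, np.inf
        return np.inf, self.tau_bypass  # bypass_only


def memory_factor(age_seconds, t_memory: float):
    """Linear-ramp memory factor, clip(age/t_memory, 0, 1); 1 when disabled.

    A non-finite age means the locus was not replicated this round
    (unreplicated DNA ahead of the fork, or DNA whose replication predates
    the observation window): the motor is unhindered there, factor 1.
    """
    age = np.asarray(age_seconds, dtype=float)
    if t_memory <= 0:
        return np.ones_like(age)
    return np.where(np.isfinite(age), np.clip(age / t_memory, 0.0, 1.0), 1.0)


def motor_speed(pos, direction, params: SMCParams, age_seconds=np.inf) -> float | np.ndarray:
    """Speed (kb/min) of an unblocked motor at signed position ``pos``.

    ``direction`` is the motor's coordinate direction (−1 counter-clockwise,
    +1 clockwise).  The motor travels toward the origin iff it is decreasing
    its |position| (pos·direction < 0); at the origin itself it is
    terminus-directed.  The base speed is scaled by the memory factor for
    the supplied time-since-replication.
    """
    pos = np.asarray(pos, dtype=float)
    toward_ori = pos * direction < 0
    base = np.where(toward_ori, params.v_to_ori, params.v_to_ter)
    out = base * memory_factor(age_seconds, params.t_memory)
    return float(out) if out.ndim == 0 else out


def detect_encounter(
    motor_old: float,
    motor_new: float,
    motor_dir: int,
    fork_old: float,
    fork_new: float,
    fork_dir: int,
) -> Encounter:
    """Classify a motor/fork interval crossing within one step.

    HEAD_ON when motor and fork travel in opposite coordinate directions,
    HEAD_TO_TAIL when they travel in the same direction (either party may
    close the gap).  NONE when their paths do not cross.  Interval crossing
    means no tunnelling at any speed or time step.
    """
    s0 = motor_old - fork_old
    s1 = motor_new - fork_new
    crossed = (s0 > 0 and s1 <= 0) or (s0 < 0 and s1 >= 0)
    if not crossed:
        return Encounter.NONE
    return Encounter.HEAD_TO_TAIL if motor_dir == fork_dir else Encounter.HEAD_ON


def resolve_block(params: SMCParams, rng: np.random.Generator, size=None):
    """Draw the scheduled outcome(s) for freshly blocked motor(s).

    Returns ``(kind, wait)``: kind is an :class:`Outcome` code array and
    ``wait`` the waiting time in seconds (inf for a permanent block).  In
    the combined model, unload and bypass clocks are independent
    exponentials with means ``tau_unload`` and ``tau_bypass``; the earlier
    one wins, so the mean pause is the harmonic combination
    ``1/(1/tau_unload + 1/tau_bypass)`` and
    ``P(unload) = tau_bypass/(tau_unload + tau_bypass)``.
    """
    tu, tb = params.effective_taus()
    n = 1 if size is None else int(size)
    u = np.full(n, np.inf) if np.isinf(tu) else tu * rng.standard_exponential(n)
    b = np.full(n, np.inf) if np.isinf(tb) else tb * rng.standard_exponential(n)
    wait = np.minimum(u, b)
    kind = np.where(
        np.isinf(wait), Outcome.BLOCK, np.where(u <= b, Outcome.UNLOAD, Outcome.BYPASS)
    ).astype(np.int8)
    if size is None:
        return Outcome(int(kind[0])), float(wait[0])
    return kind, wait


# ---------------------------------------------------------------------------
# joint simulator
# ---------------------------------------------------------------------------


@dataclass
class SMCSnapshot:
    """Bound complexes at one sample time, flattened over cells."""

    time_min: float
    cell: np.ndarray      # int, one entry per bound complex
    load_pos: np.ndarray  # signed bp
    pos_ccw: np.ndarray   # signed bp, counter-clockwise motor
    pos_cw: np.ndarray    # signed bp, clockwise motor
    n_cells: int = 0

    @property
    def anchors(self) -> np.ndarray:
        """(n_bound, 2) array of (pos_ccw, pos_cw) anchor pairs."""
        return np.column_stack([self.pos_ccw, self.pos_cw])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cell": self.cell,
                "time_min": self.time_min,
                "load_pos": self.load_pos,
                "pos_ccw": self.pos_ccw,
                "pos_cw": self.pos_cw,
            }
        )


@dataclass
class JointSnapshot:
    time_min: float
    forks: ForkEnsemble
    smc: SMCSnapshot


@dataclass
class JointResult:
    snapshots: list[JointSnapshot]
    events: "object | None" = None  # pandas.DataFrame when collected

    def at(self, time_min: float) -> JointSnapshot:
        for s in self.snapshots:
            if abs(s.time_min - time_min) < 1e-6:
                return s
        raise KeyError(f"no snapshot at t={time_min}")


class _SMCState:
    """Vectorized SMC pool state, shape (n_cells, n_smc)."""

    def __init__(self, n_cells: int, n_smc: int):
        shape = (n_cells, n_smc)
        self.bound = np.zeros(shape, dtype=bool)
        self.load_pos = np.zeros(shape)
        self.load_time = np.full(shape, np.nan)
        self.pos = {s: np.zeros(shape) for s in ("ccw", "cw")}
        self.blocked = {s: np.zeros(shape, dtype=bool) for s in ("ccw", "cw")}
        self.evt_time = {s: np.full(shape, np.inf) for s in ("ccw", "cw")}
        self.evt_kind = {s: np.zeros(shape, dtype=np.int8) for s in ("ccw", "cw")}
        self.bfork = {s: np.full(shape, -1, dtype=np.int8) for s in ("ccw", "cw")}

    def clear(self, mask: np.ndarray) -> None:
        self.bound[mask] = False
        self.load_time[mask] = np.nan
        for s in ("ccw", "cw"):
            self.blocked[s][mask] = False
            self.evt_time[s][mask] = np.inf
            self.evt_kind[s][mask] = 0
            self.bfork[s][mask] = -1


_DIR = {"ccw": -1.0, "cw": 1.0}
_FORK_DIR = {0: -1.0, 1: 1.0}  # left fork moves ccw, right fork cw


def _log(events, t_s, kind, cells, smcs, motor="", extra=None):
    if events is None:
        return
    for i in range(len(cells)):
        events.append(
            {
                "time_s": t_s,
                "kind": kind,
                "cell": int(cells[i]),
                "smc": int(smcs[i]),
                "motor": motor,
                "extra": float(extra[i]) if extra is not None else np.nan,
            }
        )


def simulate_joint(
    protocol: Protocol,
    rep_params: ReplisomeParams,
    smc_params: SMCParams,
    genome: GenomeSpec,
    n_cells: int,
    seed: int,
    sample_times: tuple[float, ...] | None = None,
    dt: float = 1.0,
    constitutive_loading: bool = False,
    collect_events: bool = False,
) -> JointResult:
    """Run forks and SMC complexes together; emit snapshots at sample times.

    ``dt`` is in seconds (the fork sub-step is dt/60 minutes).  The run is
    reproducible for a given seed.  Snapshots carry every bound complex's
    (motor_ccw, motor_cw) anchor pair plus the full fork state, feeding the
    observables module.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    max_kb_min = max(smc_params.v_to_ter, smc_params.v_to_ori, rep_params.v30, rep_params.v42)
    if max_kb_min * 1000.0 / 60.0 * dt > 10 * MEM_BIN:
        raise ValueError("dt too large for stable encounter/memory resolution")
    if sample_times is None:
        sample_times = protocol.sample_times
    if not sample_times:
        raise ValueError("no sample times requested")

    rng = np.random.default_rng(seed)
    half = genome.length / 2
    n_mem = int(np.ceil(genome.length / MEM_BIN))
    forks = init_population(rep_params, genome, n_cells, rng=rng)
    smc = _SMCState(n_cells, smc_params.n_smc)
    events: list | None = [] if collect_events else None

    # replication times per 1-kb bin; +inf = not replicated this round.
    # Pre-existing fork pairs replicated their interval before T=0: extrapolate
    # arrival times backwards at v42 so the memory ramp behind them is sensible.
    rep_time = np.full((n_cells, n_mem), np.inf, dtype=np.float64)
    v42_bp_s = rep_params.v42 * 1000.0 / 60.0
    mem_idx = lambda x: np.clip(((np.asarray(x) + half) // MEM_BIN).astype(np.int64), 0, n_mem - 1)
    bin_center = (np.arange(n_mem) + 0.5) * MEM_BIN - half
    for c in np.flatnonzero(forks.pre_existing):
        lo, hi = mem_idx(forks.left_pos[c]), mem_idx(forks.right_pos[c])
        centers = bin_center[lo : hi + 1]
        dist_to_fork = np.where(centers < 0, centers - forks.left_pos[c], forks.right_pos[c] - centers)
        rep_time[c, lo : hi + 1] = -np.abs(dist_to_fork) / v42_bp_s

    rows = np.arange(n_cells)[:, None]
    # parS loading distribution
    sites = genome.parS_sites
    if sites:
        w_sites = np.array([s.weight for s in sites]) * smc_params.parS_weight
        site_pos = np.array([s.pos for s in sites], dtype=float)
        w_bg = smc_params.background_weight * genome.length
        p_parS = w_sites.sum() / (w_sites.sum() + w_bg) if (w_sites.sum() + w_bg) > 0 else 0.0
        p_site = w_sites / w_sites.sum() if w_sites.sum() > 0 else None
    else:
        p_parS, p_site, site_pos = 0.0, None, np.empty(0)

    p_dis = -np.expm1(-dt / smc_params.tau_dissoc)
    p_load = -np.expm1(-smc_params.k_load * dt)

    snapshots: list[JointSnapshot] = []
    pending = sorted(sample_times)

    def take_snapshot(t_min: float) -> None:
        b = smc.bound
        cells, idx = np.nonzero(b)
        fork_copy = forks.copy()
        fork_copy.time_min = t_min
        snapshots.append(
            JointSnapshot(
                time_min=t_min,
                forks=fork_copy,
                smc=SMCSnapshot(
                    time_min=t_min,
                    cell=cells,
                    load_pos=smc.load_pos[b].copy(),
                    pos_ccw=smc.pos["ccw"][b].copy(),
                    pos_cw=smc.pos["cw"][b].copy(),
                    n_cells=n_cells,
                ),
            )
        )

    while pending and pending[0] <= 0.0:
        take_snapshot(pending.pop(0))

    horizon_s = max(sample_times) * 60.0
    n_steps = int(np.ceil(horizon_s / dt - 1e-9))
    max_cross = int(max_kb_min * 1000.0 / 60.0 * dt // MEM_BIN) + 2

    t = 0.0
    for _ in range(n_steps):
        env = env_at(protocol, t / 60.0, constitutive_loading)
        t_next = t + dt

        # --- forks advance; stamp newly replicated memory bins -------------
        l0, r0 = forks.left_pos.copy(), forks.right_pos.copy()
        was_init = forks.initiated.copy()
        step_forks(forks, env, rep_params, dt / 60.0, rng, genome)
        l1, r1 = forks.left_pos, forks.right_pos
        ori_bin = int((0.0 + half) // MEM_BIN)
        il0 = np.where(was_init, mem_idx(l0), ori_bin)
        ir0 = np.where(was_init, mem_idx(r0), ori_bin)
        il1, ir1 = mem_idx(l1), mem_idx(r1)
        newly = forks.initiated
        cell_ids = rows[:, 0]
        for k in range(max_cross + 1):
            bl = np.minimum(il1 + k, n_mem - 1)
            ml = newly & (il1 + k <= il0) & np.isinf(rep_time[cell_ids, bl])
            rep_time[cell_ids[ml], bl[ml]] = t_next
            br = np.maximum(ir1 - k, 0)
            mr = newly & (ir1 - k >= ir0) & np.isinf(rep_time[cell_ids, br])
            rep_time[cell_ids[mr], br[mr]] = t_next

        completed = forks.completed(genome)
        fork_exists = forks.initiated & ~completed
        fork_pos = {0: l1, 1: r1}

        # --- release motors whose blocking fork vanished --------------------
        for s in ("ccw", "cw"):
            gone = smc.blocked[s] & ~fork_exists[:, None]
            if gone.any():
                smc.blocked[s][gone] = False
                smc.evt_time[s][gone] = np.inf
                smc.evt_kind[s][gone] = 0
                smc.bfork[s][gone] = -1

        # --- fire scheduled unload / bypass events --------------------------
        for s in ("ccw", "cw"):
            due = smc.blocked[s] & (smc.evt_time[s] <= t_next)
            if not due.any():
                continue
            unload = due & (smc.evt_kind[s] == Outcome.UNLOAD)
            bypass = due & (smc.evt_kind[s] == Outcome.BYPASS)
            if unload.any():
                c, i = np.nonzero(unload)
                _log(events, t_next, "unload", c, i, s)
                smc.clear(unload)
            if bypass.any():
                c, i = np.nonzero(bypass)
                fp = fork_pos[0][c].copy()
                right = smc.bfork[s][bypass] == 1
                fp[right] = fork_pos[1][c[right]]
                newpos = np.clip(fp + _DIR[s] * BYPASS_OFFSET, -half, half)
                smc.pos[s][bypass] = newpos
                smc.blocked[s][bypass] = False
                smc.evt_time[s][bypass] = np.inf
                smc.evt_kind[s][bypass] = 0
                smc.bfork[s][bypass] = -1
                _log(events, t_next, "bypass", c, i, s, extra=newpos)

        # --- spontaneous dissociation ---------------------------------------
        dis = smc.bound & (rng.random(smc.bound.shape) < p_dis)
        if dis.any():
            c, i = np.nonzero(dis)
            _log(events, t_next, "dissociate", c, i, extra=t_next - smc.load_time[dis])
            smc.clear(dis)

        # --- loading ---------------------------------------------------------
        if env.smc_loading_active:
            new = (~smc.bound) & (rng.random(smc.bound.shape) < p_load)
            if new.any():
                k = int(new.sum())
                at_parS = rng.random(k) < p_parS
                pos_new = rng.uniform(-half, half, size=k)
                if p_site is not None and at_parS.any():
                    pos_new[at_parS] = site_pos[rng.choice(len(site_pos), size=int(at_parS.sum()), p=p_site)]
                smc.bound[new] = True
                smc.load_pos[new] = pos_new
                smc.load_time[new] = t_next
                for s in ("ccw", "cw"):
                    smc.pos[s][new] = pos_new
                c, i = np.nonzero(new)
                _log(events, t_next, "load", c, i, extra=pos_new)

        # --- motor motion and encounters -------------------------------------
        for s in ("ccw", "cw"):
            d = _DIR[s]
            act = smc.bound & ~smc.blocked[s]
            pos0 = smc.pos[s]
            bins = mem_idx(pos0)
            age = t_next - rep_time[rows, bins]
            m = memory_factor(age, smc_params.t_memory)
            toward_ori = pos0 * d < 0
            base = np.where(toward_ori, smc_params.v_to_ori, smc_params.v_to_ter)
            prop = np.clip(pos0 + d * base * m * (1000.0 / 60.0) * dt, -half, half)
            newpos = np.where(act, prop, pos0)
            # carry blocked motors with their fork
            for f in (0, 1):
                bl = smc.blocked[s] & (smc.bfork[s] == f)
                if bl.any():
                    c, i = np.nonzero(bl)
                    newpos[bl] = fork_pos[f][c]
            # detect fresh crossings against each existing fork
            for f in (0, 1):
                fe = fork_exists[:, None]
                f_old = np.where(was_init, {0: l0, 1: r0}[f], np.nan)[:, None]
                f_new = fork_pos[f][:, None]
                s0_ = pos0 - f_old
                s1_ = newpos - f_new
                crossed = act & fe & (((s0_ > 0) & (s1_ <= 0)) | ((s0_ < 0) & (s1_ >= 0)))
                if not crossed.any():
                    continue
                kk = int(crossed.sum())
                kind, wait = resolve_block(smc_params, rng, size=kk)
                c, i = np.nonzero(crossed)
                newpos[crossed] = fork_pos[f][c]
                smc.blocked[s][crossed] = True
                smc.evt_time[s][crossed] = t_next + wait
                smc.evt_kind[s][crossed] = kind
                smc.bfork[s][crossed] = f
                _log(events, t_next, "block_head_to_tail" if d == _FORK_DIR[f] else "block_head_on", c, i, s)
            smc.pos[s] = newpos

        t = t_next
        while pending and pending[0] * 60.0 <= t + 1e-9:
            take_snapshot(pending.pop(0))
    while pending:  # guard against float accumulation at the horizon
        take_snapshot(pending.pop(0))

    ev_df = None
    if collect_events:
        import pandas as pd

        ev_df = pd.DataFrame(events, columns=["time_s", "kind", "cell", "smc", "motor", "extra"])
    return JointResult(snapshots=snapshots, events=ev_df)


# ---------------------------------------------------------------------------
# stand-alone fork-chasing (arc 2) model
# ---------------------------------------------------------------------------


def simulate_arc2(
    smc_params: SMCParams,
    fork_speed: float,
    t_memory: float,
    protocol: Protocol,
    genome: GenomeSpec,
    n_pairs: int,
    seed: int,
    parS_deg: float = -59.0,
    sample_time: float = 30.0,
    dt: float = 1.0,
    constitutive_loading: bool = True,
) -> np.ndarray:
    """Reduced model for the arc traced by fork-chasing SMCs.

    Independent motor pairs load at the parS at times spread uniformly over
    the loading-active part of the protocol; a single deterministic fork
    pair starts at the origin at T=0 and moves at ``fork_speed`` (kb/min)
    until HPUra or the terminus.  Motors move at the direction-dependent
    base speed scaled by the memory factor computed from the fork
    trajectory in closed form.  There is no blocking, pushing, unloading,
    or SMC–SMC interaction; a motor simply cannot pass a *moving* fork
    (its speed falls to zero there), and passes a stalled fork freely once
    the local memory has aged out.

    Returns the (n_pairs, 2) array of final (motor_ccw, motor_cw) signed
    positions at ``sample_time`` minutes — the simulated arc points.
    """
    from .genome import deg_to_bp

    rng = np.random.default_rng(seed)
    half = genome.length / 2
    v_f = fork_speed * 1000.0 / 60.0  # bp/s
    stall_t = protocol.hpura_time * 60.0 if protocol.hpura_time is not None else np.inf
    t_ter = half / v_f
    t_end = sample_time * 60.0

    # earliest loading time under the protocol
    if constitutive_loading:
        t_load0 = 0.0
    else:
        if protocol.iptg_time is None:
            raise ValueError("protocol has no IPTG event and loading is not constitutive")
        t_load0 = (protocol.iptg_time + protocol.loading_lag) * 60.0
    # the fork-chasing subpopulation loads on newly replicated DNA, i.e.
    # only once the fork has passed the parS site
    parS_abs = abs(deg_to_bp(parS_deg, genome))
    t_pass = parS_abs / v_f
    t_load0 = max(t_load0, min(t_pass, t_end))
    load_times = rng.uniform(t_load0, t_end, size=n_pairs)

    parS = float(deg_to_bp(parS_deg, genome))
    pos = np.full((n_pairs, 2), parS)  # [:,0]=ccw, [:,1]=cw

    def fork_progress(t_s: float) -> float:
        return v_f * min(t_s, stall_t, t_ter)

    n_steps = int(round(t_end / dt))
    t = 0.0
    for _ in range(n_steps):
        t_next = t + dt
        prog = fork_progress(t)
        fork_moving = t < min(stall_t, t_ter)
        for j, d in ((0, -1.0), (1, 1.0)):
            p = pos[:, j]
            active = load_times <= t
            absx = np.abs(p)
            replicated = absx <= prog
            age = t - absx / v_f
            m = np.where(replicated, memory_factor(age, t_memory), 1.0)
            toward_ori = p * d < 0
            base = np.where(toward_ori, smc_params.v_to_ori, smc_params.v_to_ter)
            step = d * base * m * (1000.0 / 60.0) * dt
            newp = np.clip(np.where(active, p + step, p), -half, half)
            if fork_moving:
                # a motor currently behind the moving fork cannot overtake it
                prog_next = fork_progress(t_next)
                if d < 0:
                    chasing = (p < 0) & (np.abs(p) <= prog)
                    newp = np.where(chasing, np.maximum(newp, -prog_next), newp)
                else:
                    chasing = (p > 0) & (p <= prog)
                    newp = np.where(chasing, np.minimum(newp, prog_next), newp)
            pos[:, j] = newp
        t = t_next
    return pos
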