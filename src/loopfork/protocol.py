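"""Experimental timelines and the instantaneous environment they imply.

A :class:`Protocol` is a time-ordered list of events on a clock whose zero
is the onset of replication initiation (the shift to the permissive 30 °C).
Three perturbations matter to the simulators:

* temperature — a dnaB(ts) allele permits new initiation only at 30 °C;
  elongation continues at either temperature with temperature-specific speed;
* HPUra — PolC inhibitor that stalls replication forks in place while the
  replisome stays bound (irreversible within an experiment);
* IPTG — induces the ParB loader; SMC loading becomes active a fixed lag
  (~5 min) after addition, or is always active for constitutive strains.

``env_at`` collapses a protocol to the piecewise-constant :class:`EnvState`
the stochastic simulators consume at a given minute.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class EventKind(enum.Enum):
    SET_TEMP = "set_temp"
    ADD_IPTG = "add_iptg"
    ADD_HPURA = "add_hpura"
    SAMPLE = "sample"


@dataclass(frozen=True)
class Event:
    time: float  # minutes relative to T=0 (onset of replication initiation)
    kind: EventKind
    value: float | None = None  # temperature for SET_TEMP, else None


#: Temperature assumed before any SET_TEMP event (G1-arrest condition).
DEFAULT_TEMP = 42.0

#: Dead time between IPTG addition and the first SMC loading events, minutes.
DEFAULT_LOADING_LAG = 5.0


@dataclass(frozen=True)
class EnvState:
    temperature: float
    initiation_allowed: bool
    forks_stalled: bool
    smc_loading_active: bool
    loading_lag: float = DEFAULT_LOADING_LAG


@dataclass(frozen=True)
class Protocol:
    events: tuple[Event, ...]
    loading_lag: float = DEFAULT_LOADING_LAG

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError("protocol events must be sorted by time")
        for kind in (EventKind.ADD_IPTG, EventKind.ADD_HPURA):
            if sum(e.kind is kind for e in self.events) > 1:
                raise ValueError(f"at most one {kind.value} event allowed")
        for e in self.events:
            if e.kind is EventKind.SET_TEMP and e.value not in (30.0, 42.0):
                raise ValueError("SET_TEMP value must be 30 or 42")

    # -- event accessors ----------------------------------------------------

    @property
    def sample_times(self) -> tuple[float, ...]:
        return tuple(e.time for e in self.events if e.kind is EventKind.SAMPLE)

    @property
    def iptg_time(self) -> float | None:
        for e in self.events:
            if e.kind is EventKind.ADD_IPTG:
                return e.time
        return None

    @property
    def hpura_time(self) -> float | None:
        for e in self.events:
            if e.kind is EventKind.ADD_HPURA:
                return e.time
        return None

    def breakpoints(self) -> list[float]:
        """Times at which env_at can change value (event times + loading lag)."""
        pts = sorted({e.time for e in self.events if e.kind is not EventKind.SAMPLE})
        if self.iptg_time is not None:
            pts.append(self.iptg_time + self.loading_lag)
        return sorted(set(pts))


def env_at(protocol: Protocol, t: float, constitutive_loading: bool = False) -> EnvState:
    """Instantaneous environment at minute ``t`` (deterministic, piecewise-constant)."""
    temp = DEFAULT_TEMP
    for e in protocol.events:
        if e.kind is EventKind.SET_TEMP and e.time <= t:
            temp = float(e.value)
    hpura = protocol.hpura_time
    stalled = hpura is not None and t >= hpura
    if constitutive_loading:
        loading = True
    else:
        iptg = protocol.iptg_time
        loading = iptg is not None and t >= iptg + protocol.loading_lag
    return EnvState(
        temperature=temp,
        initiation_allowed=(temp == 30.0),
        forks_stalled=stalled,
        smc_loading_active=loading,
        loading_lag=protocol.loading_lag,
    )


# -- protocol builders ------------------------------------------------------

def synchronized_protocol(
    permissive_window: float = 15.0,
    iptg_time: float | None = None,
    hpura_time: float | None = None,
    sample_times: tuple[float, ...] = (),
    loading_lag: float = DEFAULT_LOADING_LAG,
) -> Protocol:
    """One synchronized replication round: 30 °C from T=0 for ``permissive_window``
    minutes, then back to 42 °C, with optional IPTG / HPUra additions."""
    events = [
        Event(0.0, EventKind.SET_TEMP, 30.0),
        Event(permissive_window, EventKind.SET_TEMP, 42.0),
    ]
    if iptg_time is not None:
        events.append(Event(iptg_time, EventKind.ADD_IPTG))
    if hpura_time is not None:
        events.append(Event(hpura_time, EventKind.ADD_HPURA))
    events.extend(Event(t, EventKind.SAMPLE) for t in sample_times)
    return Protocol(events=tuple(sorted(events, key=lambda e: e.time)), loading_lag=loading_lag)


def g1_arrest_protocol(
    iptg_time: float | None = 0.0,
    hpura_time: float | None = None,
    sample_times: tuple[float, ...] = (),
    loading_lag: float = DEFAULT_LOADING_LAG,
) -> Protocol:
    """Constant 42 °C (no initiation ever): the no-replication control."""
    events = []
    if iptg_time is not None:
        events.append(Event(iptg_time, EventKind.ADD_IPTG))
    if hpura_time is not None:
        events.append(Event(hpura_time, EventKind.ADD_HPURA))
    events.extend(Event(t, EventKind.SAMPLE) for t in sample_times)
    return Protocol(events=tuple(sorted(events, key=lambda e: e.time)), loading_lag=loading_lag)
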