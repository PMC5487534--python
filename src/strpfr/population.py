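"""Stochastic cell-distribution model of the STR-PFR loop.

Three first-order events act on the cells of the stirred tank:

* **PFR entry** at rate ``a1 = n_str * q_pfr / v_str`` — a uniformly
  chosen STR cell enters the plug-flow loop, its entry time is logged as
  an induction flag, and it returns deterministically ``tau_pfr`` later;
* **washout** at rate ``a2 = n_str * q_feed / v_str`` — a uniformly
  chosen STR cell leaves through the harvest line;
* **division** at the constant rate ``a3 = n0 * D`` — a new default
  daughter (no flags, no expression history) appears in the STR; the
  mother is untouched.

The division rate is deliberately tied to the *initial* census ``n0``
rather than the current count: together with washout this makes the
population self-stabilizing near ``n0 * D * v_str / q_feed`` cells in
the STR.  Waiting times between stochastic events are exponential with
the summed rate; deterministic PFR returns are interleaved exactly by
re-drawing the waiting time whenever a scheduled return comes first
(the exponential clock is memoryless, so this is exact).

Cells in transit through the PFR are subject to none of the three
events — the rates are written in terms of the STR census only.
"""

from __future__ import annotations

import math
import random
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ReactorConfig

__all__ = [
    "CellRecord",
    "PopulationState",
    "PopulationTrace",
    "event_rates",
    "gillespie_step",
    "run_population",
    "compartment_census",
]

STR, PFR = "STR", "PFR"


@dataclass
class CellRecord:
    """One tracked cell and its induction history."""

    id: int
    born_at: float = 0.0
    flags: list[float] = field(default_factory=list)  # PFR entry times, s
    location: str = STR
    pfr_exit_due: float | None = None  # scheduled return time while in PFR
    removed_at: float = math.inf       # washout time, inf while alive

    @property
    def alive(self) -> bool:
        return math.isinf(self.removed_at)


class PopulationState:
    """Mutable state of the cell-distribution simulation."""

    def __init__(self, reactor: ReactorConfig, seed: int = 0):
        self.reactor = reactor
        self.rng = random.Random(seed)
        self.t = 0.0
        self.cells: list[CellRecord] = [CellRecord(i) for i in range(reactor.n0)]
        # ids of STR residents, unordered; O(1) uniform pick via swap-pop
        self._str_ids: list[int] = list(range(reactor.n0))
        self._pfr_queue: deque[tuple[float, int]] = deque()  # FIFO, fixed delay
        self.event_log: list[tuple[float, str, int]] = []

    @property
    def n_str(self) -> int:
        return len(self._str_ids)

    @property
    def n_pfr(self) -> int:
        return len(self._pfr_queue)

    @property
    def next_return(self) -> float:
        return self._pfr_queue[0][0] if self._pfr_queue else math.inf

    def _pop_random_str_cell(self) -> int:
        idx = self.rng.randrange(len(self._str_ids))
        ids = self._str_ids
        ids[idx], ids[-1] = ids[-1], ids[idx]
        return ids.pop()


def event_rates(
    state: PopulationState, reactor: ReactorConfig | None = None
) -> tuple[float, float, float]:
    """(PFR entry, washout, division) rates in events per second."""
    reactor = state.reactor if reactor is None else reactor
    n_str = state.n_str
    return (
        n_str * reactor.pfr_entry_rate_per_cell,
        n_str * reactor.washout_rate_per_cell,
        reactor.division_rate,
    )


def gillespie_step(state: PopulationState) -> PopulationState:
    """Execute exactly one event (stochastic or scheduled PFR return).

    Draws ``tau = ln(1/r1) / sum(alpha)``; if a scheduled PFR return
    falls inside the waiting time, that return executes instead and the
    exponential clock restarts afterwards.  Otherwise the event class is
    chosen by the cumulative-rate rule with a second uniform draw.
    """
    reactor = state.reactor
    a1, a2, a3 = event_rates(state)
    total = a1 + a2 + a3
    next_ret = state.next_return

    if total <= 0.0:
        if math.isinf(next_ret):
            raise RuntimeError("no feasible event: all rates zero, PFR empty")
        t_event = next_ret
    else:
        t_event = state.t + state.rng.expovariate(total)

    if t_event >= next_ret:
        ret_time, cid = state._pfr_queue.popleft()
        state.t = ret_time
        cell = state.cells[cid]
        cell.location = STR
        cell.pfr_exit_due = None
        state._str_ids.append(cid)
        state.event_log.append((ret_time, "pfr_return", cid))
        return state

    state.t = t_event
    r2 = state.rng.random() * total
    if r2 < a1:
        cid = state._pop_random_str_cell()
        cell = state.cells[cid]
        cell.flags.append(t_event)
        cell.location = PFR
        cell.pfr_exit_due = t_event + reactor.tau_pfr
        state._pfr_queue.append((cell.pfr_exit_due, cid))
        state.event_log.append((t_event, "pfr_entry", cid))
    elif r2 < a1 + a2:
        cid = state._pop_random_str_cell()
        state.cells[cid].removed_at = t_event
        state.cells[cid].location = STR
        state.event_log.append((t_event, "washout", cid))
    else:
        cid = len(state.cells)
        state.cells.append(CellRecord(cid, born_at=t_event))
        state._str_ids.append(cid)
        state.event_log.append((t_event, "division", cid))
    return state


@dataclass
class PopulationTrace:
    """Event log, per-cell flag history and sampled compartment counts."""

    reactor: ReactorConfig
    seed: int
    duration: float
    times: np.ndarray   # regular sample grid, s
    n_str: np.ndarray   # STR census on the grid
    n_pfr: np.ndarray   # PFR census on the grid
    cells: list[CellRecord]
    event_log: list[tuple[float, str, int]]

    # -- flattened views used by the coupling layer --------------------

    @property
    def born_at(self) -> np.ndarray:
        if not hasattr(self, "_born"):
            self._born = np.array([c.born_at for c in self.cells])
        return self._born

    @property
    def removed_at(self) -> np.ndarray:
        if not hasattr(self, "_removed"):
            self._removed = np.array([c.removed_at for c in self.cells])
        return self._removed

    @property
    def flag_times(self) -> np.ndarray:
        """All PFR-entry flags, chronological."""
        self._ensure_flat_flags()
        return self._flag_times

    @property
    def flag_cells(self) -> np.ndarray:
        """Cell id per entry of :attr:`flag_times`."""
        self._ensure_flat_flags()
        return self._flag_cells

    def _ensure_flat_flags(self) -> None:
        if hasattr(self, "_flag_times"):
            return
        times, cids = [], []
        for time, kind, cid in self.event_log:
            if kind == "pfr_entry":
                times.append(time)
                cids.append(cid)
        self._flag_times = np.asarray(times)
        self._flag_cells = np.asarray(cids, dtype=np.int64)

    def live_mask(self, t: float) -> np.ndarray:
        """Boolean mask over all ever-existing cells: alive at ``t``."""
        return (self.born_at <= t) & (self.removed_at > t)

    # -- exports --------------------------------------------------------

    def events_to_tsv(self, path: Path | str) -> None:
        frame = pd.DataFrame(self.event_log, columns=["time_s", "event", "cell_id"])
        frame.to_csv(path, sep="\t", index=False)

    def flags_to_tsv(self, path: Path | str) -> None:
        frame = pd.DataFrame(
            {"cell_id": self.flag_cells, "flag_time_s": self.flag_times}
        )
        frame.to_csv(path, sep="\t", index=False)


def run_population(
    reactor: ReactorConfig,
    duration: float,
    seed: int = 0,
    sample_dt: float = 10.0,
) -> PopulationTrace:
    """Simulate the cell distribution for ``duration`` seconds.

    Returns the full event log, each cell's flag list, and compartment
    counts sampled every ``sample_dt`` seconds.  Identical seeds give
    identical event logs.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0 s")
    state = PopulationState(reactor, seed)
    grid = np.arange(0.0, duration + sample_dt / 2, sample_dt)

    while state.t <= duration:
        a1, a2, a3 = event_rates(state)
        if a1 + a2 + a3 <= 0.0 and math.isinf(state.next_return):
            break  # nothing can ever happen again
        gillespie_step(state)
    # the final draw may overshoot the simulated window; it is invisible
    # to any query at t <= duration, so drop it from the log
    state.event_log = [e for e in state.event_log if e[0] <= duration]

    # fill the census grid properly by replay (cheap and unambiguous)
    ns, npfr = _census_series(state, grid)
    return PopulationTrace(
        reactor=reactor,
        seed=seed,
        duration=duration,
        times=grid,
        n_str=ns,
        n_pfr=npfr,
        cells=state.cells,
        event_log=state.event_log,
    )


def _census_series(
    state: PopulationState, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Compartment counts on ``grid`` replayed from the event log."""
    n0 = state.reactor.n0
    ns = np.empty(grid.size, dtype=np.int64)
    npfr = np.empty(grid.size, dtype=np.int64)
    cur_ns, cur_np = n0, 0
    gi = 0
    for time, kind, _ in state.event_log:
        while gi < grid.size and grid[gi] < time:
            ns[gi], npfr[gi] = cur_ns, cur_np
            gi += 1
        if kind == "pfr_entry":
            cur_ns -= 1
            cur_np += 1
        elif kind == "pfr_return":
            cur_ns += 1
            cur_np -= 1
        elif kind == "washout":
            cur_ns -= 1
        else:  # division
            cur_ns += 1
    while gi < grid.size:
        ns[gi], npfr[gi] = cur_ns, cur_np
        gi += 1
    return ns, npfr


def compartment_census(
    trace: PopulationTrace, t: float
) -> tuple[int, int, tuple[float, float], tuple[float, float]]:
    """Counts and fractions at time ``t`` plus the volumetric reference.

    Returns ``(n_str, n_pfr, (frac_str, frac_pfr), (vol_str, vol_pfr))``
    where the last pair is the liquid-volume split of the reactor
    system, the deterministic expectation the simulated census is
    compared against.
    """
    if t < trace.times[0] or t > trace.times[-1] + 1e-9:
        raise ValueError(f"t={t} s outside the simulated span")
    idx = int(np.searchsorted(trace.times, t + 1e-12)) - 1
    idx = max(idx, 0)
    n_str = int(trace.n_str[idx])
    n_pfr = int(trace.n_pfr[idx])
    live = n_str + n_pfr
    fracs = (n_str / live, n_pfr / live) if live else (math.nan, math.nan)
    return n_str, n_pfr, fracs, trace.reactor.volumetric_fractions
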