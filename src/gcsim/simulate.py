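"""Orchestration of the 21-day germinal-center reaction.

A run starts at day 0 with three founder centroblasts of distinct low
affinity, alternates 6-h ODE intervals with discrete SHM sweeps (SHM and the
affinity-dependent survival signals switch on at day 4, before which both
signals are clamped to let the founders expand monoclonally), prunes
subclones whose CB+CC falls below 0.1 cell, and records a per-step
trajectory table plus a genealogy/events table.  Replicates differ only in
the seed of their random stream.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import compute_signals, integrate_interval
from .params import ModelParams, ParameterError
from .shm import apply_shm_step
from .state import GCState

__all__ = ["SimulationResult", "initialize", "step", "run",
           "run_replicates", "parameter_sweep"]

log = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["step", "time", "subclone_id", "sigma", "n_mutations",
                      "cb", "cc", "mem", "plasma"]
EVENT_COLUMNS = ["event", "step", "time", "subclone_id", "parent_id",
                 "n_mutations_added", "delta_sigma", "sigma",
                 "n_silent", "n_fwr_lethal", "n_fwr_viable",
                 "n_cdr_neutral", "n_cdr_affinity", "n_cells",
                 "mem_removed", "plasma_removed"]


@dataclass
class SimulationResult:
    """Complete record of one replicate.

    ``trajectory`` holds one row per living subclone per 6-h step;
    ``events`` records founders, spawns, lethal deaths (aggregated per parent
    per step) and prunes, so every subclone id in the trajectory appears
    exactly once as a founder or spawn event.
    """

    seed: int
    replicate: int
    params: ModelParams
    trajectory: pd.DataFrame
    events: pd.DataFrame
    extinct: bool = False

    def final_state(self) -> pd.DataFrame:
        last = self.trajectory["step"].max()
        return self.trajectory[self.trajectory["step"] == last]

    def all_subclone_sigmas(self) -> pd.DataFrame:
        """(subclone_id, sigma, n_mutations) for every subclone ever created,
        founders included, pruned ones too -- each exactly once."""
        born = self.events[self.events["event"].isin(["founder", "spawn"])]
        return born[["subclone_id", "sigma", "n_mutations_added"]].reset_index(drop=True)

    def save(self, outdir) -> None:
        from .config import save_run_dir  # local import to avoid a cycle
        save_run_dir(self, outdir)


def initialize(params: ModelParams) -> GCState:
    """Founder population: n_founders single centroblasts, no mutations."""
    sched = params.schedule
    aff = sched.founder_affinities
    if len(set(aff)) < len(aff):
        warnings.warn("duplicate founder affinities: founders will not "
                      "compete at distinct relative affinities", stacklevel=2)
    if any(a < params.affinity.min_affinity for a in aff):
        raise ParameterError("founder affinities must be >= affinity.min_affinity")
    state = GCState()
    state.add_subclones(sigma=np.asarray(aff, dtype=float), n_mutations=0,
                        parent_ids=GCState.NO_PARENT, cb=1.0)
    return state


class _EventLog:
    """Accumulates event rows cheaply; materialized once per run."""

    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def founders(self, state: GCState) -> None:
        for i in range(state.n_subclones):
            self.rows.append(("founder", 0, 0.0, int(state.ids[i]), -1, 0, 0.0,
                              float(state.sigma[i]), 0, 0, 0, 0, 0, 1, 0.0, 0.0))

    def shm(self, rec, step: int, time: float) -> None:
        lc = rec.child_leaf_counts
        for j in range(rec.n_spawned):
            self.rows.append(("spawn", step, time, int(rec.child_ids[j]),
                              int(rec.parent_of_child[j]), int(rec.child_m[j]),
                              float(rec.child_delta[j]), float(rec.child_sigma[j]),
                              int(lc[j, 0]), int(lc[j, 1]), int(lc[j, 2]),
                              int(lc[j, 3]), int(lc[j, 4]), 1, 0.0, 0.0))
        if rec.n_lethal:
            ids, counts = np.unique(rec.lethal_parent_ids, return_counts=True)
            for pid, c in zip(ids, counts):
                self.rows.append(("lethal", step, time, int(pid), -1, 0, 0.0,
                                  np.nan, 0, int(c), 0, 0, 0, int(c), 0.0, 0.0))

    def prune(self, state: GCState, mask: np.ndarray, step: int, time: float) -> None:
        for i in np.flatnonzero(mask):
            self.rows.append(("prune", step, time, int(state.ids[i]),
                              int(state.parent_ids[i]), 0, 0.0,
                              float(state.sigma[i]), 0, 0, 0, 0, 0, 1,
                              float(state.mem[i]), float(state.plasma[i])))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=EVENT_COLUMNS)


def step(state: GCState, rng: np.random.Generator, params: ModelParams,
         events: _EventLog | None = None) -> GCState:
    """One 6-h cycle: integrate the ODEs, then SHM (from day 4), then prune.

    The survival-signal clamp applies to intervals *starting* before
    ``clamp_days``; SHM applies at the end of every interval starting at or
    after ``shm_start_day``.
    """
    sched = params.schedule
    start_time = state.time
    s_d, s_a = compute_signals(state, params.signals)
    integrate_interval(state, sched.dt, params.rates, s_d, s_a,
                       rtol=params.rtol, atol=params.atol)
    state.step += 1
    if start_time >= sched.shm_start_day - 1e-12:
        rec = apply_shm_step(state, rng, params)
        if events is not None:
            events.shm(rec, state.step, state.time)
    # prune vanishing subclones, banking their memory/plasma output
    doomed = state.cb + state.cc < sched.removal_threshold
    if doomed.any():
        if events is not None:
            events.prune(state, doomed, state.step, state.time)
        state.removed_mem += float(state.mem[doomed].sum())
        state.removed_plasma += float(state.plasma[doomed].sum())
        state.keep(~doomed)
    return state


def run(params: ModelParams, seed: int, replicate: int = 0) -> SimulationResult:
    """Run one full replicate; fully determined by (params, seed)."""
    rng = np.random.default_rng(seed)
    state = initialize(params)
    events = _EventLog()
    events.founders(state)

    snap: list[np.ndarray] = []

    def record(st: GCState) -> None:
        n = st.n_subclones
        snap.append(np.column_stack([
            np.full(n, st.step), np.full(n, st.time), st.ids, st.sigma,
            st.n_mutations, st.cb, st.cc, st.mem, st.plasma]))

    record(state)
    extinct = False
    for _ in range(params.schedule.n_steps):
        state = step(state, rng, params, events)
        record(state)
        if state.n_subclones == 0:
            extinct = True
            log.warning("population extinct at t=%.2f d (seed %d)", state.time, seed)
            break
        if state.step % 8 == 0:
            log.info("t=%5.2f d: %5d subclones, CB=%9.1f CC=%9.1f",
                     state.time, state.n_subclones, state.cb_total, state.cc_total)

    traj = pd.DataFrame(np.concatenate(snap), columns=TRAJECTORY_COLUMNS)
    for col in ("step", "subclone_id", "n_mutations"):
        traj[col] = traj[col].astype(np.int64)
    return SimulationResult(seed=seed, replicate=replicate, params=params,
                            trajectory=traj, events=events.frame(),
                            extinct=extinct)


def run_replicates(params: ModelParams, seeds) -> list[SimulationResult]:
    """Independent replicates with identical parameters, one per seed."""
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ParameterError("replicate seeds must be distinct")
    return [run(params, s, replicate=i) for i, s in enumerate(seeds)]


def parameter_sweep(params: ModelParams, grid: dict, seeds) -> pd.DataFrame:
    """Cartesian sweep over dotted parameter paths.

    ``grid`` maps e.g. ``"rates.mu_cc"`` to a list of values.  Every path is
    validated before any simulation runs.  Returns one summary row per grid
    point x seed (see :func:`gcsim.analysis.replicate_summary`).
    """
    from .analysis import replicate_summary

    for path in grid:
        params.with_path(path, next(iter(grid[path])))  # validate path
    names = list(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)) if names else [()]:
        p = params
        for name, value in zip(names, combo):
            p = p.with_path(name, value)
        for seed in seeds:
            result = run(p, seed)
            row = dict(zip(names, combo))
            row["seed"] = seed
            row.update(replicate_summary(result))
            rows.append(row)
    return pd.DataFrame(rows)
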