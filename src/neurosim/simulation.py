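"""Backward-Euler time stepping and current-clamp protocols.

Each step advances the gates with the exact exponential update at the
current voltage, rebuilds the quasi-tridiagonal current-balance system (the
axial part is precomputed once; membrane conductances change with the
gates), and solves it with the chosen solver.  Backward Euler is implicit
and unconditionally stable, so any step size yields bounded voltages.

Multi-sweep current-clamp protocols inject ``amp0 + k * damp`` nA during
``[delay, delay + duration)`` and record one segment's voltage every step.
Sweeps, and cells within a population, are mutually independent: running
them in any order, or batched, reproduces the standalone runs bit for bit
at fixed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import assemble_system, axial_conductances
from .mechanisms import BiophysParams, GateState, advance_gates
from .morphology import Morphology
from .solvers import AncestorTable, build_ancestor_table, solve

PRECISIONS = {"single": np.float32, "double": np.float64}
DEFAULT_V0 = -65.0  # mV


@dataclass
class StimulusProtocol:
    """Multi-sweep current-clamp definition.

    Defaults: dt 0.1 ms, 5000 steps (t_stop 500 ms), a -1 nA first sweep
    incremented by 0.3 nA per sweep, stimulus and recording at the soma
    (segment 0).
    """

    dt: float = 0.1            # ms
    t_stop: float = 500.0      # ms
    delay: float = 10.0        # ms
    duration: float = 400.0    # ms
    amp0: float = -1.0         # nA
    damp: float = 0.3          # nA per sweep
    n_sweeps: int = 1
    stim_segment: int = 0
    record_segment: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.t_stop < self.delay + self.duration:
            raise ValueError("t_stop must be >= delay + duration")

    @property
    def n_samples(self) -> int:
        return int(round(self.t_stop / self.dt)) + 1

    @property
    def amplitudes(self) -> np.ndarray:
        return self.amp0 + self.damp * np.arange(self.n_sweeps)

    def amplitude(self, sweep_index: int) -> float:
        return float(self.amp0 + self.damp * sweep_index)


@dataclass
class SimState:
    """Membrane potential, gate variables, and simulation clock."""

    v: np.ndarray      # mV
    gates: GateState
    t: float = 0.0     # ms

    def copy(self) -> "SimState":
        return SimState(self.v.copy(), self.gates.copy(), self.t)


@dataclass
class TraceSet:
    """Voltage-trace matrix of a multi-sweep protocol: row k is the sweep at
    amplitude ``amplitudes[k]``, sampled every ``dt`` ms at one segment."""

    voltages: np.ndarray   # (n_sweeps, n_samples) mV
    dt: float              # ms
    amplitudes: np.ndarray  # nA per sweep
    record_segment: int = 0

    @property
    def n_sweeps(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


def init_state(m: Morphology, p: BiophysParams, v0: float = DEFAULT_V0,
               precision: str = "double") -> SimState:
    """Uniform voltage ``v0`` with gates at their steady state for ``v0``."""
    dtype = PRECISIONS[precision]
    v = np.full(m.n_segments, v0, dtype=dtype)
    return SimState(v=v, gates=GateState.steady(v, dtype=dtype), t=0.0)


class Simulator:
    """Per-morphology stepping context.

    Caches everything that is static across steps: the axial conductance of
    every edge, the ancestor jump table (pointer-jumping solver), and the
    temperature rate scale.  ``skip_solve`` omits the linear solve, leaving
    the voltage unchanged — the ablation hook used for workload profiling.
    """

    def __init__(self, m: Morphology, p: BiophysParams, *,
                 solver: str = "serial", precision: str = "double",
                 skip_solve: bool = False):
        if precision not in PRECISIONS:
            raise ValueError(f"precision must be one of {tuple(PRECISIONS)}")
        self.m = m
        self.p = p
        self.solver = solver
        self.precision = precision
        self.dtype = PRECISIONS[precision]
        self.skip_solve = skip_solve
        self.g_axial = axial_conductances(m, p.Ra).astype(self.dtype)
        self.table: AncestorTable | None = (
            build_ancestor_table(m) if solver == "stone" else None)
        self.q = p.q

    def init_state(self, v0: float = DEFAULT_V0) -> SimState:
        return init_state(self.m, self.p, v0, self.precision)

    def step(self, state: SimState, i_stim: np.ndarray, dt: float) -> SimState:
        """One backward-Euler step: gates -> membrane terms -> assembly ->
        solve; returns the new state (input unmodified)."""
        gates = advance_gates(state.gates, state.v, dt, self.q)
        sys = assemble_system(self.m, self.p, gates, state.v, i_stim, dt,
                              g_axial=self.g_axial, dtype=self.dtype)
        if self.skip_solve:
            v = state.v.copy()
        else:
            v = solve(sys, self.m, self.solver, table=self.table)
        return SimState(v=v, gates=gates, t=state.t + dt)

    def run_sweep(self, protocol: StimulusProtocol, sweep_index: int = 0,
                  state: SimState | None = None,
                  v0: float = DEFAULT_V0) -> np.ndarray:
        n_seg = self.m.n_segments
        if not (0 <= protocol.stim_segment < n_seg
                and 0 <= protocol.record_segment < n_seg):
            raise ValueError("stimulus/record segment index out of range")
        state = self.init_state(v0) if state is None else state.copy()
        amp = self.dtype(protocol.amplitude(sweep_index))
        zero = np.zeros(n_seg, dtype=self.dtype)
        pulse = zero.copy()
        pulse[protocol.stim_segment] = amp
        dt = protocol.dt
        trace = np.empty(protocol.n_samples, dtype=self.dtype)
        trace[0] = state.v[protocol.record_segment]
        t_on, t_off = protocol.delay, protocol.delay + protocol.duration
        for k in range(1, protocol.n_samples):
            t = (k - 1) * dt  # stimulus gated on the step's start time
            i_stim = pulse if (t_on <= t < t_off) else zero
            state = self.step(state, i_stim, dt)
            trace[k] = state.v[protocol.record_segment]
        return trace


def step(m: Morphology, p: BiophysParams, state: SimState, i_stim, dt: float,
         *, solver: str = "serial", precision: str = "double",
         skip_solve: bool = False) -> SimState:
    """Functional one-step wrapper (see :meth:`Simulator.step`)."""
    sim = Simulator(m, p, solver=solver, precision=precision, skip_solve=skip_solve)
    return sim.step(state, np.asarray(i_stim, dtype=sim.dtype), dt)


def run_sweep(m: Morphology, p: BiophysParams, protocol: StimulusProtocol,
              sweep_index: int = 0, *, solver: str = "serial",
              precision: str = "double", skip_solve: bool = False,
              v0: float = DEFAULT_V0) -> np.ndarray:
    """Simulate one sweep and return the recorded voltage trace (mV)."""
    sim = Simulator(m, p, solver=solver, precision=precision, skip_solve=skip_solve)
    return sim.run_sweep(protocol, sweep_index, v0=v0)


def run_protocol(m: Morphology, p: BiophysParams, protocol: StimulusProtocol,
                 *, solver: str = "serial", precision: str = "double",
                 skip_solve: bool = False, v0: float = DEFAULT_V0) -> TraceSet:
    """Simulate every sweep of the protocol; sweeps are independent, so the
    result is identical to stacking standalone :func:`run_sweep` calls."""
    sim = Simulator(m, p, solver=solver, precision=precision, skip_solve=skip_solve)
    voltages = np.empty((protocol.n_sweeps, protocol.n_samples), dtype=sim.dtype)
    for k in range(protocol.n_sweeps):
        voltages[k] = sim.run_sweep(protocol, k, v0=v0)
    return TraceSet(voltages=voltages, dt=protocol.dt,
                    amplitudes=protocol.amplitudes,
                    record_segment=protocol.record_segment)


def run_population(cells, protocol: StimulusProtocol, *,
                   solver: str = "serial", precision: str = "double") -> list[TraceSet]:
    """Simulate a batch of (morphology, parameters) cells under one protocol.

    Cells are independent; each entry equals the standalone
    :func:`run_protocol` result for that cell.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("population must contain at least one cell")
    return [run_protocol(m, p, protocol, solver=solver, precision=precision)
            for (m, p) in cells]
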