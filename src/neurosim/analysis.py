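"""Trace error metrics, spike diagnostics, parallel-cost formulas, and the
workload-ablation breakdown.

Error statistics follow the squared-error convention: the per-sample squared
difference between two traces (mV^2) with its maximum and mean.  Spike-based
diagnostics detect upward threshold crossings (default 0 mV, linearly
interpolated) and fit a straight line to the per-spike timing differences
between two runs — the signature of accumulated rounding (e.g. a single-
versus double-precision pair) is a finite slope in ms per spike.

Two theoretical per-time-step cost formulas accompany the scheduled solvers:

* branch-based: sum over levels of the largest branch length plus, for
  levels >= 2, the largest branch degree (junction work),
* segment-based: (N / W) log2(m), with N segments, warp width W (default
  32 SIMD lanes), and m the maximal root-leaf distance in segments.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np

from .mechanisms import BiophysParams
from .morphology import Morphology
from .simulation import StimulusProtocol, run_sweep
from .solvers import _level_schedule, build_ancestor_table


@dataclass
class ErrorReport:
    """Squared-error statistics (mV^2) and optional spike-shift fields."""

    squared_error_trace: np.ndarray
    max_sq_error: float
    mean_sq_error: float
    per_spike_shift: list | None = None   # [(spike index, dt_ms), ...]
    shift_slope: float | None = None      # ms per spike


def squared_error(a, b) -> ErrorReport:
    """Pointwise squared difference of two equal-length traces."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"trace length mismatch: {a.shape} vs {b.shape}")
    sq = (a - b) ** 2
    return ErrorReport(squared_error_trace=sq,
                       max_sq_error=float(sq.max()),
                       mean_sq_error=float(sq.mean()))


def detect_spikes(trace, dt: float, threshold: float = 0.0) -> np.ndarray:
    """Times (ms) of upward crossings of ``threshold``, linearly interpolated
    between the bracketing samples; one event per crossing."""
    v = np.asarray(trace, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("trace contains non-finite samples")
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        return np.empty(0, dtype=np.float64)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return (idx + frac) * dt


def spike_time_shift(a, b, dt: float, threshold: float = 0.0
                     ) -> tuple[np.ndarray, float]:
    """Per-spike timing differences t_k(a) - t_k(b) and their least-squares
    slope versus spike index (ms per spike)."""
    ta = detect_spikes(a, dt, threshold)
    tb = detect_spikes(b, dt, threshold)
    if ta.size != tb.size:
        raise ValueError(
            f"unequal spike counts: {ta.size} vs {tb.size}; cannot match spikes")
    deltas = ta - tb
    if deltas.size == 0:
        return deltas, 0.0
    if deltas.size == 1:
        return deltas, 0.0
    slope = float(np.polyfit(np.arange(deltas.size), deltas, 1)[0])
    return deltas, slope


def error_report(a, b, dt: float, threshold: float = 0.0) -> ErrorReport:
    """Squared-error statistics plus, when both traces spike equally often,
    the per-spike shift sequence and its slope."""
    rep = squared_error(a, b)
    try:
        deltas, slope = spike_time_shift(a, b, dt, threshold)
    except ValueError:
        return rep
    rep.per_spike_shift = list(enumerate(deltas.tolist()))
    rep.shift_slope = slope
    return rep


# ----------------------------------------------------------------------
# theoretical per-step costs
# ----------------------------------------------------------------------

@dataclass
class ScheduleReport:
    """Theoretical and observed parallel-step accounting for one morphology."""

    method: str
    rounds: int
    per_level_max_L: np.ndarray
    per_level_max_D: np.ndarray
    branch_cost: float
    segment_cost: float
    N: int
    m: int
    W: int
    depth: int


def cost_branch(m: Morphology) -> int:
    """Per-step cost of the branch-based schedule: for each level the largest
    branch segment count, plus for levels >= 2 the largest branch degree."""
    L = m.branch_L()
    D = m.branch_D()
    total = 0
    for lvl in range(1, m.depth + 1):
        branches = m.branches_at_level(lvl)
        total += int(L[branches].max())
        if lvl >= 2:
            total += int(D[branches].max())
    return total


def cost_stone(m: Morphology, W: int = 32) -> float:
    """Per-step cost of the segment-based schedule: (N / W) log2(m)."""
    if W < 1:
        raise ValueError("warp size W must be >= 1")
    dist = m.max_root_leaf_distance
    if dist < 1:
        raise ValueError("m (max root-leaf distance) must be >= 1")
    return (m.n_segments / W) * math.log2(dist)


def schedule_report(m: Morphology, method: str, W: int = 32) -> ScheduleReport:
    """Cost bookkeeping for one morphology and solver schedule; ``rounds``
    is the observed logical round count of the chosen back-substitution."""
    sched = _level_schedule(m)
    if method == "branch":
        rounds = sched.rounds
    elif method == "stone":
        rounds = build_ancestor_table(m).rounds
    elif method == "serial":
        rounds = m.n_segments
    else:
        raise ValueError(f"unknown method {method!r}")
    return ScheduleReport(
        method=method, rounds=rounds,
        per_level_max_L=sched.max_L, per_level_max_D=sched.max_D,
        branch_cost=cost_branch(m), segment_cost=cost_stone(m, W),
        N=m.n_segments, m=m.max_root_leaf_distance, W=W, depth=m.depth)


# ----------------------------------------------------------------------
# workload ablation
# ----------------------------------------------------------------------

def workload_breakdown(m: Morphology, p: BiophysParams,
                       protocol: StimulusProtocol, *, solver: str = "serial",
                       repeats: int = 1) -> dict:
    """Ablation-by-subtraction runtime breakdown of one sweep.

    Four variants are timed: the full simulation, the same morphology with a
    purely passive membrane, the full membrane without the linear solve, and
    passive without the solve.  Matrix-solve time is estimated as
    full - no_solve and membrane-model time as full - passive; the remainder
    is everything else (assembly, bookkeeping).  The reported fractions are
    hardware-dependent; only their structure (each within [0, 1]) is stable.
    """
    passive = m.with_mech("pas")

    def timed(morph, skip):
        best = math.inf
        for _ in range(repeats):
            t0 = time.perf_counter()
            run_sweep(morph, p, protocol, solver=solver, skip_solve=skip)
            best = min(best, time.perf_counter() - t0)
        return best

    t_full = timed(m, False)
    t_passive = timed(passive, False)
    t_noslv = timed(m, True)
    t_passive_noslv = timed(passive, True)

    frac = lambda x: float(min(max(x / t_full, 0.0), 1.0))
    matrix = frac(t_full - t_noslv)
    model = frac(t_full - t_passive)
    rest = float(min(max(1.0 - matrix - model, 0.0), 1.0))
    return {
        "t_full_s": t_full, "t_passive_s": t_passive,
        "t_no_solve_s": t_noslv, "t_passive_no_solve_s": t_passive_noslv,
        "frac_matrix_solve": matrix, "frac_mechanisms": model, "frac_rest": rest,
    }
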