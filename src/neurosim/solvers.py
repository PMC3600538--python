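"""Three interchangeable solvers for the quasi-tridiagonal system H x = b.

* :func:`serial_solve` — the classic two-sweep elimination: a bottom-up scan
  (triangularization, which fuses the LU factorization with the forward
  solve) followed by a top-down back-substitution.
* branch-based — :func:`triangularize_levels` + :func:`backsub_branch`:
  branches at the same level of the tree are independent, so both sweeps are
  scheduled level by level; levels run serially, all branches within a level
  form one logical parallel round.
* segment-based — :func:`triangularize_levels` + :func:`backsub_stone`:
  back-substitution is the first-order recurrence x_i = c_i + e_i x_parent(i),
  solved in ceil(log2(m)) synchronous pointer-jumping rounds (recursive
  doubling over a precomputed 2^j-ancestor table), m being the maximal
  root-leaf distance in segments.

The parallel schedules run as deterministic vectorized rounds on one CPU;
parallelism is expressed through round counts and strict read-before-write
(SIMD) semantics within a round, which is the hardware-independent content
of the schedules.  All solvers operate on copies and honor the input dtype,
so single-precision systems are solved entirely in single precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assembly import HinesSystem
from .morphology import Morphology


class SingularSystemError(ArithmeticError):
    """A pivot vanished during elimination."""


def _pivot_floor(dtype) -> float:
    # doubles: the spec'd 1e-300 guard; singles: the representable analogue
    return 1e-300 if np.dtype(dtype).itemsize >= 8 else float(np.finfo(dtype).tiny)


def _check_pivots(d: np.ndarray) -> None:
    if np.any(np.abs(d) < _pivot_floor(d.dtype)):
        raise SingularSystemError("zero or near-zero pivot on the diagonal")


# ----------------------------------------------------------------------
# serial reference path
# ----------------------------------------------------------------------

def serial_solve(sys: HinesSystem) -> np.ndarray:
    """Solve H x = b by the serial two-sweep elimination.

    Bottom-up, for i = n-1 .. 1:  f = a_i/d_i; d_p -= f b_i; rhs_p -= f rhs_i.
    Top-down: x_0 = rhs_0/d_0; x_i = (rhs_i - a_i x_parent)/d_i.
    The input system is not modified.
    """
    d = sys.d.copy()
    rhs = sys.rhs.copy()
    a, b, par = sys.a, sys.b_sup, sys.parent
    n = sys.n
    _check_pivots(d)
    for i in range(n - 1, 0, -1):
        f = a[i] / d[i]
        p = par[i]
        d[p] -= f * b[i]
        rhs[p] -= f * rhs[i]
    _check_pivots(d)
    x = np.empty_like(d)
    x[0] = rhs[0] / d[0]
    for i in range(1, n):
        x[i] = (rhs[i] - a[i] * x[par[i]]) / d[i]
    return x


def dense_oracle_solve(sys: HinesSystem) -> np.ndarray:
    """Reference solution via the materialized dense matrix and standard
    partially pivoted elimination (test oracle; O(n^3))."""
    H = sys.to_dense()
    try:
        x = np.linalg.solve(H, sys.rhs.astype(np.float64))
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(str(exc)) from None
    return x.astype(sys.dtype)


# ----------------------------------------------------------------------
# branch-based (level-scheduled) path
# ----------------------------------------------------------------------

@dataclass
class LevelSchedule:
    """Round accounting for the level-scheduled sweeps.

    ``max_L[lvl-1]`` is the largest branch segment count at level ``lvl`` and
    ``max_D[lvl-1]`` the largest branch child count; ``rounds`` equals the
    tree depth.  The theoretical per-step cost of the branch-based method is
    ``sum(max_L) + sum(max_D[1:])`` (junction work is attributed to levels
    >= 2, matching the cost formula evaluated in :mod:`neurosim.analysis`).
    """

    rounds: int
    max_L: np.ndarray
    max_D: np.ndarray

    @property
    def work(self) -> int:
        return int(self.max_L.sum() + self.max_D[1:].sum())


def _level_schedule(m: Morphology) -> LevelSchedule:
    depth = m.depth
    L = m.branch_L()
    D = m.branch_D()
    max_L = np.zeros(depth, dtype=np.int64)
    max_D = np.zeros(depth, dtype=np.int64)
    for lvl in range(1, depth + 1):
        branches = m.branches_at_level(lvl)
        max_L[lvl - 1] = L[branches].max()
        max_D[lvl - 1] = D[branches].max()
    return LevelSchedule(rounds=depth, max_L=max_L, max_D=max_D)


def triangularize_levels(sys: HinesSystem, m: Morphology
                         ) -> tuple[HinesSystem, LevelSchedule]:
    """Bottom-up elimination scheduled by branch level (depth -> 1).

    All branches of a level form one logical round; within a branch the scan
    runs distal to proximal, and junction contributions from sibling branches
    accumulate in ascending child order.  The reduced (d, rhs) equal the
    serial triangularization up to rounding.  The input is not modified.
    """
    out = sys.copy()
    d, rhs, a, b, par = out.d, out.rhs, out.a, out.b_sup, out.parent
    _check_pivots(d)
    sched = _level_schedule(m)
    segments = m.branch_segments()
    for lvl in range(m.depth, 0, -1):
        for br in m.branches_at_level(lvl):
            for i in segments[br][::-1]:
                if par[i] < 0:
                    continue
                f = a[i] / d[i]
                d[par[i]] -= f * b[i]
                rhs[par[i]] -= f * rhs[i]
    _check_pivots(d)
    return out, sched


def backsub_branch(reduced: HinesSystem, m: Morphology) -> np.ndarray:
    """Top-down back-substitution scheduled by branch level (1 -> depth);
    branches within a level form one logical round."""
    d, rhs, a, par = reduced.d, reduced.rhs, reduced.a, reduced.parent
    _check_pivots(d)
    x = np.empty_like(d)
    segments = m.branch_segments()
    for lvl in range(1, m.depth + 1):
        for br in m.branches_at_level(lvl):
            for i in segments[br]:
                if par[i] < 0:
                    x[i] = rhs[i] / d[i]
                else:
                    x[i] = (rhs[i] - a[i] * x[par[i]]) / d[i]
    return x


def branch_solve(sys: HinesSystem, m: Morphology) -> np.ndarray:
    reduced, _ = triangularize_levels(sys, m)
    return backsub_branch(reduced, m)


# ----------------------------------------------------------------------
# segment-based (Stone pointer-jumping) path
# ----------------------------------------------------------------------

@dataclass
class AncestorTable:
    """Precomputed 2^j-ancestor jump table for recursive doubling.

    ``jump[j][i]`` is the 2^j-th ancestor of segment i along its unique path
    to the root (the root maps to itself); ``rounds = ceil(log2(m))`` with
    ``m`` the maximal root-leaf distance in segments.  Built once per
    morphology, before the simulation runs.
    """

    jump: np.ndarray  # (rounds, n) int64
    rounds: int
    m: int

    def __post_init__(self):
        assert self.jump.shape[0] == self.rounds


def build_ancestor_table(m: Morphology) -> AncestorTable:
    dist = m.max_root_leaf_distance
    rounds = int(math.ceil(math.log2(dist))) if dist > 1 else 0
    n = m.n_segments
    jump = np.empty((rounds, n), dtype=np.int64)
    anc = m.parent.copy()
    anc[0] = 0  # root points to itself
    for j in range(rounds):
        jump[j] = anc
        anc = anc[anc]
    return AncestorTable(jump=jump, rounds=rounds, m=dist)


def backsub_stone(reduced: HinesSystem, table: AncestorTable) -> np.ndarray:
    """Back-substitution by recursive doubling (modified Stone scheme).

    Initialize c_i = rhs_i/d_i and e_i = -a_i/d_i (root: e = 0), so that
    x_i = c_i + e_i x_parent(i).  Each of the ``rounds`` synchronous rounds
    substitutes the ancestor's own recurrence and squares the jump distance:
    c_i <- c_i + e_i c_anc;  e_i <- e_i e_anc, with all segments reading the
    previous round's state (SIMD contract).  Afterwards every e_i has
    absorbed a zero from the root and x = c.
    """
    d, rhs, a = reduced.d, reduced.rhs, reduced.a
    _check_pivots(d)
    c = rhs / d
    e = -a / d
    e[0] = 0.0
    for j in range(table.rounds):
        anc = table.jump[j]
        c_anc = c[anc]
        e_anc = e[anc]
        c = c + e * c_anc
        e = e * e_anc
    return c


def stone_residual(reduced: HinesSystem, table: AncestorTable) -> float:
    """Max |e_i| remaining after the final round (should be exactly 0: every
    multiplier chain reaches the root, whose e is 0)."""
    d, a = reduced.d, reduced.a
    e = -a / d
    e[0] = 0.0
    for j in range(table.rounds):
        e = e * e[table.jump[j]]
    return float(np.abs(e).max())


def stone_solve(sys: HinesSystem, m: Morphology,
                table: AncestorTable | None = None) -> np.ndarray:
    reduced, _ = triangularize_levels(sys, m)
    if table is None:
        table = build_ancestor_table(m)
    return backsub_stone(reduced, table)


# ----------------------------------------------------------------------
# dispatch
# ----------------------------------------------------------------------

SOLVERS = ("serial", "branch", "stone")


def solve(sys: HinesSystem, m: Morphology | None = None, method: str = "serial",
          table: AncestorTable | None = None) -> np.ndarray:
    """Solve with the chosen method; ``m`` is required for the scheduled
    methods, ``table`` optionally caches the ancestor table for ``stone``."""
    if method == "serial":
        return serial_solve(sys)
    if m is None:
        raise ValueError(f"method {method!r} needs the morphology")
    if method == "branch":
        return branch_solve(sys, m)
    if method == "stone":
        return stone_solve(sys, m, table)
    raise ValueError(f"unknown method {method!r}; allowed: {SOLVERS}")
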