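"""Assembly of the per-time-step current-balance system H v(t+dt) = b.

Backward-Euler discretization of the cable equation on a Hines-ordered tree
yields a quasi-tridiagonal, structurally symmetric, strictly diagonally
dominant system.  Row i:

    (C_i/dt + G_i + sum_adj g_ax) v_i(t+dt) - sum_adj g_ax v_adj(t+dt)
        = (C_i/dt) v_i(t) + GE_i + I_stim,i

with C_i the segment capacitance (nF), G_i / GE_i the membrane conductance
(uS) and reversal-weighted sum (nA) from :mod:`neurosim.mechanisms`, and
g_ax the axial coupling conductances (uS).

Unit system (fixed package-wide): mV, ms, nA, uS, nF, Mohm, um, ohm*cm,
S/cm^2, uF/cm^2.  The two conversion constants are
``uS = S/cm^2 * um^2 * 1e-2`` and ``nF = uF/cm^2 * um^2 * 1e-5``, so that
uS*mV = nA and nF*mV/ms = nA identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mechanisms import BiophysParams, GateState, membrane_densities
from .morphology import Morphology

US_PER_SCM2_UM2 = 1e-2   # S/cm^2 * um^2 -> uS
NF_PER_UFCM2_UM2 = 1e-5  # uF/cm^2 * um^2 -> nF


@dataclass
class HinesSystem:
    """One time step's quasi-tridiagonal system.

    ``a[i]`` is the sub-element of row i at column parent(i) and ``b_sup[i]``
    the super-element of row parent(i) at column i; both live on the edge
    (i, parent(i)) and are equal for resistive coupling.  ``a[0]`` and
    ``b_sup[0]`` are zero (the root has no parent edge).
    """

    d: np.ndarray
    a: np.ndarray
    b_sup: np.ndarray
    rhs: np.ndarray
    parent: np.ndarray

    @property
    def n(self) -> int:
        return self.d.shape[0]

    @property
    def dtype(self):
        return self.d.dtype

    def copy(self) -> "HinesSystem":
        return HinesSystem(self.d.copy(), self.a.copy(), self.b_sup.copy(),
                           self.rhs.copy(), self.parent)

    def to_dense(self) -> np.ndarray:
        """Materialize the full matrix H (test/debug use)."""
        H = np.zeros((self.n, self.n), dtype=np.float64)
        H[np.arange(self.n), np.arange(self.n)] = self.d
        for i in range(1, self.n):
            p = self.parent[i]
            H[i, p] = self.a[i]
            H[p, i] = self.b_sup[i]
        return H

    def dump(self, path) -> None:
        """Write (index, parent, d, a, b_sup, rhs) as a delimited text table."""
        with open(path, "w") as fh:
            fh.write("index\tparent\td\ta\tb_sup\trhs\n")
            for i in range(self.n):
                fh.write(f"{i}\t{self.parent[i]}\t{self.d[i]:.12g}\t"
                         f"{self.a[i]:.12g}\t{self.b_sup[i]:.12g}\t{self.rhs[i]:.12g}\n")


def half_axial_resistance(length_um: float, diam_um: float, Ra: float) -> float:
    """Resistance of half a cylindrical segment, in Mohm:
    0.01 * Ra * (L/2) / (pi * (d/2)^2)."""
    if length_um <= 0 or diam_um <= 0:
        raise ValueError("segment length and diameter must be > 0")
    return 0.01 * Ra * (length_um / 2.0) / (math.pi * (diam_um / 2.0) ** 2)


def axial_conductance(length_i, diam_i, length_j, diam_j, Ra) -> float:
    """Coupling conductance (uS) between two adjacent segments: the series
    combination of each segment's half-cylinder axial resistance."""
    r = half_axial_resistance(length_i, diam_i, Ra) + \
        half_axial_resistance(length_j, diam_j, Ra)
    return 1.0 / r


def axial_conductances(m: Morphology, Ra: float) -> np.ndarray:
    """Per-edge coupling conductances: entry i couples segment i to its
    parent (entry 0, the root, is 0).  Precompute once; geometry is static."""
    r_half = 0.01 * Ra * (m.length_um / 2.0) / (np.pi * (m.diam_um / 2.0) ** 2)
    g = np.zeros(m.n_segments, dtype=np.float64)
    if m.n_segments > 1:
        g[1:] = 1.0 / (r_half[1:] + r_half[m.parent[1:]])
    return g


def assemble_system(m: Morphology, p: BiophysParams, s: GateState,
                    v_now: np.ndarray, i_stim: np.ndarray, dt: float,
                    *, g_axial: np.ndarray | None = None,
                    dtype=np.float64) -> HinesSystem:
    """Build H and b for one backward-Euler step of size ``dt`` (ms).

    ``v_now`` is the membrane potential at the current time level (mV) and
    ``i_stim`` the injected current per segment (nA).  Gates in ``s`` must
    already be advanced to the target time level.  ``g_axial`` may carry the
    precomputed output of :func:`axial_conductances`.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    dtype = np.dtype(dtype).type
    v_now = np.asarray(v_now, dtype=dtype)
    i_stim = np.asarray(i_stim, dtype=dtype)
    if not (np.all(np.isfinite(v_now)) and np.all(np.isfinite(i_stim))):
        raise ValueError("non-finite state passed to assembly")
    if g_axial is None:
        g_axial = axial_conductances(m, p.Ra)
    g_ax = np.asarray(g_axial, dtype=dtype)

    area = m.area_um2.astype(dtype)
    g_den, ge_den = membrane_densities(m, p, s)
    G = g_den.astype(dtype) * area * dtype(US_PER_SCM2_UM2)      # uS
    GE = ge_den.astype(dtype) * area * dtype(US_PER_SCM2_UM2)    # nA
    C_dt = (dtype(p.Cm) * area * dtype(NF_PER_UFCM2_UM2)) / dtype(dt)  # nF/ms = uS

    d = C_dt + G
    if m.n_segments > 1:
        d[1:] += g_ax[1:]
        np.add.at(d, m.parent[1:], g_ax[1:])
    a = -g_ax
    a[0] = 0.0
    rhs = C_dt * v_now + GE + i_stim
    return HinesSystem(d=d, a=a, b_sup=a.copy(), rhs=rhs, parent=m.parent)
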