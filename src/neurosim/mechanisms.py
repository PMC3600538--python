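"""Membrane mechanisms: passive leak and Hodgkin-Huxley gating kinetics.

Each time step, every segment contributes a membrane conductance and a
reversal-weighted driving term to the current-balance system.  The passive
model is a single ohmic relation, I = g (v - e).  The Hodgkin-Huxley model
adds voltage-gated sodium (m^3 h) and potassium (n^4) conductances whose
gate variables relax exponentially toward voltage-dependent steady states
(the classic squid-axon rate functions, resting shift -65 mV).  Gates are
advanced with the exact exponential ("cnexp"-style) update, which is
unconditionally stable at any step size.

Units: mV, ms, S/cm^2 for densities; conversion to absolute uS / nA happens
in :mod:`neurosim.assembly` via segment areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import Morphology


@dataclass
class BiophysParams:
    """Biophysical parameters; conductance densities may be scalars or
    per-segment arrays (broadcast against the morphology).

    Defaults follow the common squid-axon conventions: ``gl``/``el`` are the
    HH leak, ``g_pas``/``e_pas`` the purely passive membrane, ``Ra`` the
    axial resistivity and ``Cm`` the specific capacitance.  ``celsius``
    scales the gate rates by q10 = 3 per 10 degC above 6.3 degC.
    """

    Ra: float = 100.0          # axial resistivity, ohm*cm
    Cm: float = 1.0            # specific capacitance, uF/cm^2
    g_pas: float = 0.001       # passive conductance density, S/cm^2
    e_pas: float = -70.0       # passive reversal, mV
    gbar_na: float | np.ndarray = 0.12   # max Na+ density, S/cm^2
    gbar_k: float | np.ndarray = 0.036   # max K+ density, S/cm^2
    gl: float = 0.0003         # HH leak density, S/cm^2
    ena: float = 50.0          # reversals, mV
    ek: float = -77.0
    el: float = -54.3
    celsius: float = 6.3       # degC

    def __post_init__(self):
        for name in ("g_pas", "gl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if np.any(np.asarray(self.gbar_na) < 0) or np.any(np.asarray(self.gbar_k) < 0):
            raise ValueError("conductance densities must be >= 0")
        if self.Cm <= 0 or self.Ra <= 0:
            raise ValueError("Cm and Ra must be > 0")

    @property
    def q(self) -> float:
        """Temperature rate scale q10 = 3^((celsius - 6.3)/10)."""
        return 3.0 ** ((self.celsius - 6.3) / 10.0)


def soma_dendrite_params(m: Morphology, *,
                         soma_gbar_na: float = 24.0, soma_gbar_k: float = 2.88,
                         dend_gbar_na: float = 0.12, dend_gbar_k: float = 0.036,
                         **overrides) -> BiophysParams:
    """Hot-soma / excitable-dendrite parameter set.

    Builds per-segment Na+/K+ density arrays from the morphology's soma mask:
    somatic segments get the high densities (defaults 24 and 2.88 S/cm^2)
    and dendritic segments the low ones (0.12 and 0.036 S/cm^2), the
    configuration used for the action-potential-train benchmarks.
    """
    gna = np.where(m.is_soma, soma_gbar_na, dend_gbar_na).astype(np.float64)
    gk = np.where(m.is_soma, soma_gbar_k, dend_gbar_k).astype(np.float64)
    return BiophysParams(gbar_na=gna, gbar_k=gk, **overrides)


def passive_current(v, g, e):
    """Ohmic membrane current density I = g (v - e) (mA/cm^2 for S/cm^2, mV)."""
    return g * (v - e)


# ----------------------------------------------------------------------
# Hodgkin-Huxley rates
# ----------------------------------------------------------------------

def _vtrap(x, y):
    # x / (1 - exp(-x/y)) with its removable singularity at x = 0 (limit y)
    x = np.asarray(x)
    small = np.abs(x) < 1e-6 * y
    safe = np.where(small, 1.0, x)
    out = safe / (-np.expm1(-safe / y))
    return np.where(small, y + x / 2.0, out)


def hh_rates(v):
    """Gate opening/closing rates (alpha_m, beta_m, alpha_h, beta_h,
    alpha_n, beta_n) in 1/ms at membrane potential ``v`` (mV)."""
    v = np.asarray(v)
    am = 0.1 * _vtrap(v + 40.0, 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _vtrap(v + 55.0, 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def gate_steady_state(v):
    """Steady-state gate values (m_inf, h_inf, n_inf) at ``v``."""
    am, bm, ah, bh, an, bn = hh_rates(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


@dataclass
class GateState:
    """Per-segment Hodgkin-Huxley gate variables, each in [0, 1]."""

    m: np.ndarray
    h: np.ndarray
    n: np.ndarray

    @classmethod
    def steady(cls, v, dtype=np.float64) -> "GateState":
        m, h, n = gate_steady_state(np.asarray(v, dtype=dtype))
        return cls(m.astype(dtype), h.astype(dtype), n.astype(dtype))

    def copy(self) -> "GateState":
        return GateState(self.m.copy(), self.h.copy(), self.n.copy())


def advance_gates(s: GateState, v, dt: float, q: float = 1.0) -> GateState:
    """Advance all gates by ``dt`` (ms) at fixed voltage ``v``.

    Exact exponential relaxation toward the steady state:
    ``x <- x_inf + (x - x_inf) exp(-dt q (alpha + beta))``; the clip guards
    round-off only, since the exact update cannot leave [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    v = np.asarray(v)
    am, bm, ah, bh, an, bn = hh_rates(v)

    def relax(x, a, b):
        inf = a / (a + b)
        out = inf + (x - inf) * np.exp(-dt * q * (a + b))
        return np.clip(out, 0.0, 1.0).astype(x.dtype, copy=False)

    return GateState(relax(s.m, am, bm), relax(s.h, ah, bh), relax(s.n, an, bn))


def membrane_densities(m: Morphology, p: BiophysParams, s: GateState):
    """Per-segment conductance density (S/cm^2) and reversal-weighted sum
    (mA/cm^2-equivalent) for the assembled current balance.

    HH segments: g = gbar_na m^3 h + gbar_k n^4 + gl, with the matching
    g*e sum; passive segments: g_pas and g_pas * e_pas.
    """
    dtype = s.m.dtype
    hh = m.mech_tag == "hh"
    gna = np.broadcast_to(np.asarray(p.gbar_na, dtype=dtype), (m.n_segments,))
    gk = np.broadcast_to(np.asarray(p.gbar_k, dtype=dtype), (m.n_segments,))
    gna = gna * s.m ** 3 * s.h
    gk = gk * s.n ** 4
    g_hh = gna + gk + dtype.type(p.gl)
    ge_hh = gna * dtype.type(p.ena) + gk * dtype.type(p.ek) + dtype.type(p.gl * p.el)
    g = np.where(hh, g_hh, dtype.type(p.g_pas))
    ge = np.where(hh, ge_hh, dtype.type(p.g_pas * p.e_pas))
    return g.astype(dtype, copy=False), ge.astype(dtype, copy=False)
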