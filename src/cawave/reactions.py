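"""Pointwise reaction terms: buffering, SERCA pump, and balancing leak.

All buffers (the fluorescent dye included) are stationary: only free
calcium diffuses.  Buffering follows mass-action kinetics

    d[CaB]/dt = k_plus * C * (B_total - [CaB]) - k_minus * [CaB],

the pump is a Hill function V_max C^n / (K^n + C^n), and the SR leak is
the constant pump rate at the resting concentration, so the resting state
is an exact fixed point of the full reaction system.
"""

from __future__ import annotations

import numpy as np

from .model_core import BufferSpec, ModelParameters, PumpParams


def equilibrium_bound(C0, buffer: BufferSpec):
    """Bound-buffer concentration in equilibrium with free calcium C0 (uM)."""
    if np.any(np.asarray(C0) < 0):
        raise ValueError("C0 must be nonnegative")
    return buffer.B_total * C0 / (C0 + buffer.Kd)


def buffer_rate(C, bound, buffer: BufferSpec):
    """d[CaB]/dt (uM/ms); the free-calcium flux term is its negative."""
    return buffer.k_plus * C * (buffer.B_total - bound) - buffer.k_minus * bound


def pump_rate(C, pump: PumpParams):
    """SERCA pump rate (uM/ms), monotone in C and bounded by V_max."""
    Cn = np.power(np.maximum(C, 0.0), pump.n_pump)
    return pump.V_max * Cn / (pump.K_pump**pump.n_pump + Cn)


def leak_rate(pump: PumpParams, C0: float) -> float:
    """Constant SR leak balancing the pump at rest: pump_rate(C0)."""
    return float(pump_rate(C0, pump))


def reaction_arrays(params: ModelParameters):
    """Pack buffer constants into arrays for the stepping kernel.

    Returns (k_plus, k_minus, B_total) as float arrays ordered as
    params.buffers.
    """
    kp = np.array([b.k_plus for b in params.buffers])
    km = np.array([b.k_minus for b in params.buffers])
    bt = np.array([b.B_total for b in params.buffers])
    return kp, km, bt
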