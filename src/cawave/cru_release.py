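"""Calcium release unit (CRU) lattice, stochastic firing law, point sources.

CRUs sit on a regular lattice with spacings lx (longitudinal) by ly
(transverse), commensurate with the grid.  Each CRU is closed, open, or
spent: it fires at most once, stays open for exactly T_open ms while
injecting calcium at a fixed molar rate sigma = I_cru / (2 F), and then
never reopens (the simulated horizons are short compared to the CRU
refractory period).

Within one time step dt, a closed CRU fires with probability
p = dt * P_max * C^n / (K^n + C^n) evaluated at its node's free-calcium
concentration at the start of the step; draws are independent across CRUs.
When background firing is suppressed (the default), a CRU whose local
concentration has not risen above the resting level cannot fire, so only
the wave initiated by the forced openings propagates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import CRUParams, GridSpec, ValidationError

logger = logging.getLogger(__name__)

CLOSED, OPEN, SPENT = 0, 1, 2


@dataclass
class CRULattice:
    """Positions, lifecycle state, and firing log of every release unit."""

    x: np.ndarray            # um
    y: np.ndarray            # um
    ix: np.ndarray           # grid indices
    iy: np.ndarray
    lx: float
    ly: float
    state: np.ndarray = field(default=None)  # type: ignore[assignment]
    t_fire: np.ndarray = field(default=None)  # type: ignore[assignment]
    t_close: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.x)
        if self.state is None:
            self.state = np.full(n, CLOSED, dtype=np.int8)
        if self.t_fire is None:
            self.t_fire = np.full(n, np.nan)
        if self.t_close is None:
            self.t_close = np.full(n, np.nan)

    def __len__(self) -> int:
        return len(self.x)

    def index_at(self, pos: tuple[float, float]) -> int:
        """Index of the CRU at position (x, y); raises if absent."""
        hit = np.flatnonzero((np.abs(self.x - pos[0]) < 1e-9)
                             & (np.abs(self.y - pos[1]) < 1e-9))
        if len(hit) != 1:
            raise ValidationError(f"no CRU at position {pos}")
        return int(hit[0])

    def force_open(self, positions, t: float = 0.0) -> None:
        """Open the CRUs at the given positions (the initial stimulus).

        Bypasses the probability law; the units close T_open later via the
        normal lifecycle.
        """
        for pos in positions:
            i = self.index_at(pos)
            self.state[i] = OPEN
            self.t_fire[i] = t

    def firing_log(self) -> pd.DataFrame:
        """Fired CRUs as a table: cru_index, x_um, y_um, t_fire_ms, t_close_ms."""
        fired = np.flatnonzero(~np.isnan(self.t_fire))
        order = fired[np.argsort(self.t_fire[fired], kind="stable")]
        return pd.DataFrame({
            "cru_index": order,
            "x_um": self.x[order],
            "y_um": self.y[order],
            "t_fire_ms": self.t_fire[order],
            "t_close_ms": self.t_close[order],
        })


def build_lattice(grid: GridSpec, lx: float, ly: float,
                  origin_offset: tuple[float, float] = (0.0, 0.0)) -> CRULattice:
    """Rectangular CRU lattice {(offset + i*lx, offset + j*ly)} in the interior.

    Every position must coincide with a grid node (spacings commensurate
    with dx, dy).  Positions on the x=0 / y=0 lines are excluded: the
    lattice starts one spacing in from the origin.
    """
    for sp, h, name in ((lx, grid.dx, "lx"), (ly, grid.dy, "ly")):
        r = sp / h
        if abs(r - round(r)) > 1e-9:
            raise ValidationError(f"{name}={sp} is not commensurate with the grid spacing {h}")
    ox, oy = origin_offset
    xs = []
    v = ox + lx
    while v < grid.length_x - 1e-9:
        xs.append(v)
        v += lx
    ys = []
    v = oy + ly
    while v < grid.length_y - 1e-9:
        ys.append(v)
        v += ly
    if not xs or not ys:
        logger.warning("CRU spacing exceeds the domain: empty lattice")
    X, Y = np.meshgrid(np.asarray(xs), np.asarray(ys), indexing="ij")
    x = X.ravel()
    y = Y.ravel()
    ix = np.array([grid.node_index(v, "x") for v in x], dtype=np.intp)
    iy = np.array([grid.node_index(v, "y") for v in y], dtype=np.intp)
    return CRULattice(x=x, y=y, ix=ix, iy=iy, lx=lx, ly=ly)


def firing_probability(C_local, cru: CRUParams, dt: float,
                       state=CLOSED, suppress_below: float | None = None):
    """Per-step firing probability of a CRU at local concentration C_local.

    p = dt * P_max * C^n / (K^n + C^n), clamped to [0, 1]; zero for open or
    spent CRUs, and zero whenever C_local <= suppress_below (the resting
    concentration) if background-firing suppression is active.
    """
    C = np.maximum(np.asarray(C_local, dtype=float), 0.0)
    Cn = C**cru.n_cru
    p = dt * cru.P_max * Cn / (cru.K_sens**cru.n_cru + Cn)
    p = np.clip(p, 0.0, 1.0)
    p = np.where(np.asarray(state) == CLOSED, p, 0.0)
    if suppress_below is not None:
        p = np.where(C <= suppress_below * (1.0 + 1e-9), 0.0, p)
    return p if p.ndim else float(p)


def step_crus(lattice: CRULattice, C_field: np.ndarray, rng: np.random.Generator,
              t: float, dt: float, cru: CRUParams,
              suppress_below: float | None = None):
    """Advance CRU lifecycles over one step; return indices of open CRUs.

    Open CRUs whose open time has elapsed become spent; each closed CRU
    then fires independently with `firing_probability` at its node's
    concentration (the field at the start of the step).
    """
    expiring = np.flatnonzero((lattice.state == OPEN)
                              & (t - lattice.t_fire >= cru.T_open - 1e-9))
    if len(expiring):
        lattice.state[expiring] = SPENT
        lattice.t_close[expiring] = t

    closed = np.flatnonzero(lattice.state == CLOSED)
    if len(closed):
        C_local = C_field[lattice.ix[closed], lattice.iy[closed]]
        p = firing_probability(C_local, cru, dt, suppress_below=suppress_below)
        fires = closed[rng.random(len(closed)) < p]
        if len(fires):
            lattice.state[fires] = OPEN
            lattice.t_fire[fires] = t
    return np.flatnonzero(lattice.state == OPEN)


def source_amplitude(I_cru: float, faraday: float, grid: GridSpec,
                     depth: float) -> float:
    """Concentration rate (uM/ms) a single open CRU deposits at its node.

    The molar release rate sigma = I_cru / (2 F) (divalent calcium) is
    spread over one grid cell of volume dx*dy*depth; 1 uM*um^3 = 1e-21 mol,
    and 1 pA = 1e-15 C/ms, so sigma[uM*um^3/ms] = I[pA] * 1e6 / (2 F).
    """
    if I_cru < 0:
        raise ValidationError("I_cru must be nonnegative")
    sigma = I_cru * 1.0e6 / (2.0 * faraday)      # uM*um^3/ms
    return sigma / (grid.dx * grid.dy * depth)   # uM/ms at the source node
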