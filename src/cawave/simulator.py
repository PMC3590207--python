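"""Time stepping of the 2-D fractional reaction-diffusion calcium model.

Each step of size dt advances, in order:

1. CRU lifecycle — open units past T_open become spent; closed units draw
   Bernoulli firings at the start-of-step concentration field.
2. Part of the step's point-source deposit from every open CRU.
3. Diffusion — the two directional fractional operators Lx, Ly act on the
   rows/columns of the field through their exact matrix exponentials
   e^{dt Lx}, e^{dt Ly}.  As Kronecker factors the two commute, so the
   directional split is exact and unconditionally stable; the only time
   error in the scheme is the first-order coupling to reactions/sources.
4. The remainder of the source deposit.  The pre/post weights are chosen so
   a constant source reproduces the exact one-step response at the source
   node's decay rate, which removes the leading dt sensitivity of the
   source-node balance.
5. Explicit-Euler reactions: buffers, pump, leak (compiled kernel).

The diffusion/reaction split order alternates between consecutive steps
(diffusion first on even steps, reactions first on odd ones), which cancels
the leading splitting error over each pair of steps at no extra cost.

Operators are precomputed once per parameter set and reused for all steps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import cru_release
from ._kernels import (PUMP_TABLE_CMAX, PUMP_TABLE_DC, build_pump_table,
                       pump_eval, react_step)
from .frac_diffusion import riesz_matrix
from .model_core import ModelParameters
from .reactions import equilibrium_bound, reaction_arrays

logger = logging.getLogger(__name__)


class NumericalError(RuntimeError):
    """The solution left the physical range (NaN or negative concentration)."""


@dataclass
class Operators:
    """Everything precomputable for a fixed parameter set."""

    Lx: np.ndarray
    Ly: np.ndarray
    Ex: np.ndarray           # e^{dt Lx}
    EyT: np.ndarray          # (e^{dt Ly})^T, contiguous for right-multiplication
    kp: np.ndarray
    km: np.ndarray
    bt: np.ndarray
    ptab: np.ndarray
    leak: float              # uM/ms, pump at C0 through the same table path
    src_rate: float          # uM/ms at an open CRU's node
    w_pre: float = 0.5       # fraction of the deposit applied before diffusion
    reactions_enabled: bool = True


def build_operators(params: ModelParameters, reactions: bool = True) -> Operators:
    grid, dif, cru = params.grid, params.diffusion, params.cru
    Lx = riesz_matrix(dif.beta, grid.nx, grid.dx, dif.Dx)
    Ly = riesz_matrix(dif.beta, grid.ny, grid.dy, dif.Dy)
    Ex = expm(params.dt * Lx)
    EyT = np.ascontiguousarray(expm(params.dt * Ly).T)
    # flush the propagators' far tails to zero: below ~1e-30 they are
    # numerically irrelevant but subnormal entries make BLAS crawl
    Ex[np.abs(Ex) < 1e-30] = 0.0
    EyT[np.abs(EyT) < 1e-30] = 0.0
    kp, km, bt = reaction_arrays(params)
    pump = params.pump
    ptab = build_pump_table(pump.V_max, pump.K_pump, pump.n_pump)
    leak = pump_eval(params.C0, ptab, 1.0 / PUMP_TABLE_DC, PUMP_TABLE_CMAX,
                     pump.V_max, pump.K_pump**pump.n_pump, pump.n_pump)
    src = cru_release.source_amplitude(cru.I_cru, cru.faraday, grid, cru.depth)
    # Split each step's source deposit around the diffusion solve so that a
    # constant source reproduces the exact response dt*phi1(dt*L)*S at both
    # z = 0 (total mass) and z = -x0, the source node's own decay rate: this
    # removes the leading dt-dependence of the source-node balance.
    x0 = -params.dt * (Lx[grid.nx // 2, grid.nx // 2]
                       + Ly[grid.ny // 2, grid.ny // 2])
    if x0 > 1e-12:
        phi1 = (1.0 - math.exp(-x0)) / x0
        w_pre = (1.0 - phi1) / (1.0 - math.exp(-x0))
    else:
        w_pre = 0.5
    return Operators(Lx=Lx, Ly=Ly, Ex=Ex, EyT=EyT, kp=kp, km=km, bt=bt,
                     ptab=ptab, leak=leak, src_rate=src, w_pre=w_pre,
                     reactions_enabled=reactions)


@dataclass
class SimState:
    """The spatial fields at one instant."""

    t: float
    C: np.ndarray                      # free calcium, (nx, ny), uM
    bound: np.ndarray                  # (nx, ny, n_buffers), uM
    lattice: cru_release.CRULattice
    _tmp: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self._tmp is None:
            self._tmp = np.empty_like(self.C)


def make_initial_state(params: ModelParameters,
                       forced: Sequence[tuple[float, float]] = ()) -> SimState:
    """Resting state: C = C0 everywhere, buffers at binding equilibrium,
    all CRUs closed except the forced ones (opened at t = 0)."""
    grid = params.grid
    C = np.full((grid.nx, grid.ny), float(params.C0))
    bound = np.empty((grid.nx, grid.ny, len(params.buffers)))
    for b, spec in enumerate(params.buffers):
        bound[:, :, b] = equilibrium_bound(params.C0, spec)
    lattice = cru_release.build_lattice(grid, params.cru.lx, params.cru.ly)
    if len(forced):
        lattice.force_open(forced, t=0.0)
    return SimState(t=0.0, C=C, bound=bound, lattice=lattice)


def step(state: SimState, params: ModelParameters, ops: Operators,
         rng: np.random.Generator) -> float:
    """Advance one step of dt in place; returns the post-step max free Ca."""
    cru = params.cru
    suppress = (max(params.C0, cru.C_gate)
                if params.suppress_background_firing else None)
    open_idx = cru_release.step_crus(state.lattice, state.C, rng, state.t,
                                     params.dt, cru, suppress_below=suppress)
    C = state.C
    deposit = params.dt * ops.src_rate
    reactions_first = ops.reactions_enabled and \
        (int(round(state.t / params.dt)) % 2 == 1)

    def _react():
        pump = params.pump
        return react_step(C, state.bound, ops.kp, ops.km, ops.bt, params.dt,
                          ops.leak, ops.ptab, 1.0 / PUMP_TABLE_DC,
                          PUMP_TABLE_CMAX, pump.V_max,
                          pump.K_pump**pump.n_pump, pump.n_pump)

    if reactions_first:
        _react()
    if len(open_idx):
        C[state.lattice.ix[open_idx], state.lattice.iy[open_idx]] += \
            ops.w_pre * deposit

    np.dot(ops.Ex, C, out=state._tmp)
    np.dot(state._tmp, ops.EyT, out=C)

    if len(open_idx):
        C[state.lattice.ix[open_idx], state.lattice.iy[open_idx]] += \
            (1.0 - ops.w_pre) * deposit

    if ops.reactions_enabled and not reactions_first:
        cmax = _react()
    else:
        if reactions_first:  # clip the fractional kernel's undershoot
            np.maximum(C, 0.0, out=C)
        cmax = float(C.max())
    state.t += params.dt
    return cmax


@dataclass
class Trajectory:
    """Output of one simulation run."""

    times: np.ndarray                       # snapshot times, ms
    snapshots: list[np.ndarray]             # free-Ca fields at those times
    firing_log: pd.DataFrame
    peak_t: np.ndarray                      # per-step clock, ms
    peak_c: np.ndarray                      # per-step max free Ca, uM
    probes: dict[float, tuple[np.ndarray, np.ndarray]]  # y_um -> (times, rows)
    probes_dye: dict[float, np.ndarray]  # y_um -> dye-complex rows (same times)
    params: ModelParameters
    lattice: cru_release.CRULattice
    scenario_name: str = ""
    seed: int | None = None


@dataclass
class Linescan:
    """Space-time image of concentration along one grid line."""

    image: np.ndarray       # (n_positions, n_times), uM
    times: np.ndarray       # ms
    positions: np.ndarray   # um
    axis: str
    coordinate: float


def run(scenario, params: ModelParameters | None = None, seed: int = 0,
        probe_rows: Sequence[float] = (), probe_every: int = 20,
        stop_condition: Callable[[SimState], bool] | None = None,
        check_every: int = 100, t_end: float | None = None) -> Trajectory:
    """Run a scenario to completion; deterministic given (scenario, params, seed).

    probe_rows: y coordinates (um) whose x-profiles are recorded every
    `probe_every` steps (dense linescan data).  stop_condition, if given,
    is evaluated every `check_every` steps and ends the run early.
    """
    if params is None:
        params = scenario.build_parameters()
    if t_end is None:
        t_end = params.t_end
    rng = np.random.default_rng(seed)
    state = make_initial_state(params, forced=scenario.forced_crus)
    grid, dt = params.grid, params.dt
    ops = build_operators(params)
    logger.info("run '%s': seed=%s beta=%s I=%s pA t_end=%s ms",
                scenario.name, seed, params.diffusion.beta,
                params.cru.I_cru, t_end)

    n_steps = int(round(t_end / dt))
    snap_steps = {int(round(ts / dt)): ts for ts in scenario.snapshot_times
                  if ts <= t_end + 1e-9}
    snap_steps.setdefault(0, 0.0)

    peak_t = np.empty(n_steps + 1)
    peak_c = np.empty(n_steps + 1)
    peak_t[0], peak_c[0] = 0.0, float(state.C.max())
    times: list[float] = []
    snapshots: list[np.ndarray] = []
    if 0 in snap_steps:
        times.append(0.0)
        snapshots.append(state.C.copy())

    dye_idx = next((i for i, b in enumerate(params.buffers) if b.is_dye), None)
    probe_iy = {y: grid.node_index(y, "y") for y in probe_rows}
    probe_data = {y: ([], []) for y in probe_rows}  # (times, rows)
    probe_dye = {y: [] for y in probe_rows}
    for y, (ts, rows) in probe_data.items():
        ts.append(0.0)
        rows.append(state.C[:, probe_iy[y]].copy())
        if dye_idx is not None:
            probe_dye[y].append(state.bound[:, probe_iy[y], dye_idx].copy())

    last = 0
    for s in range(1, n_steps + 1):
        cmax = step(state, params, ops, rng)
        peak_t[s], peak_c[s] = state.t, cmax
        if not np.isfinite(cmax) or cmax > 1e9:
            raise NumericalError(f"non-finite concentration at step {s} (t={state.t} ms)")
        if s in snap_steps:
            times.append(snap_steps[s])
            snapshots.append(state.C.copy())
        if probe_rows and s % probe_every == 0:
            for y, (ts, rows) in probe_data.items():
                ts.append(state.t)
                rows.append(state.C[:, probe_iy[y]].copy())
                if dye_idx is not None:
                    probe_dye[y].append(state.bound[:, probe_iy[y], dye_idx].copy())
        if s % check_every == 0 or s == n_steps:
            cmin = float(state.C.min())
            if cmin < -1e-6 or np.isnan(cmin):
                i, j = np.unravel_index(int(np.nanargmin(state.C)), state.C.shape)
                raise NumericalError(
                    f"negative concentration {cmin:.3e} uM at node ({i},{j}), "
                    f"step {s} (t={state.t} ms)")
            if stop_condition is not None and stop_condition(state):
                last = s
                break
        last = s

    probes = {y: (np.asarray(ts), np.asarray(rows))
              for y, (ts, rows) in probe_data.items()}
    probes_dye = {y: np.asarray(rows) for y, rows in probe_dye.items()
                  if dye_idx is not None}
    return Trajectory(times=np.asarray(times), snapshots=snapshots,
                      firing_log=state.lattice.firing_log(),
                      peak_t=peak_t[:last + 1], peak_c=peak_c[:last + 1],
                      probes=probes, probes_dye=probes_dye, params=params,
                      lattice=state.lattice, scenario_name=scenario.name,
                      seed=seed)


def linescan(trajectory: Trajectory, axis: str = "x",
             coordinate: float = 0.8) -> Linescan:
    """Space-time image along a grid line, one column per recorded instant.

    Uses the dense probe recording when the run captured one at this
    coordinate, otherwise the snapshot sequence.  Axes follow the linescan
    convention: horizontal = time, vertical = position.
    """
    grid = trajectory.params.grid
    if axis == "x":
        j = grid.node_index(coordinate, "y")
        positions = np.arange(grid.nx) * grid.dx
        if coordinate in trajectory.probes:
            t, rows = trajectory.probes[coordinate]
            return Linescan(np.asarray(rows).T, t, positions, axis, coordinate)
        img = np.stack([s[:, j] for s in trajectory.snapshots], axis=1)
    elif axis == "y":
        i = grid.node_index(coordinate, "x")
        positions = np.arange(grid.ny) * grid.dy
        img = np.stack([s[i, :] for s in trajectory.snapshots], axis=1)
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return Linescan(img, trajectory.times, positions, axis, coordinate)
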