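"""Wave metrics: velocity, amplitude, FWHM, FDHM, wall arrival, collisions.

Velocities are estimated from CRU firing onsets rather than from
concentration-front thresholds: onsets are noise-free observables of the
fire-diffuse-fire chain, and the linescan signature of the wave is a
near-straight line of onsets.  The first onsets (default two) are excluded
from the fit because the delay from the initiating spark to its first
triggered neighbour is systematically longer than the steady spark-to-spark
interval.  A concentration-front threshold estimator is provided as a
cross-check.

Metrics that cannot be computed (too few onsets, no peak above resting,
fronts that never meet) return NaN — callers test with `math.isnan` /
``defined`` flags rather than catching exceptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ValidationError
from .simulator import Trajectory

_TOL = 1e-6


@dataclass(frozen=True)
class WaveMetrics:
    """Seed-aggregated metrics of one scenario: mean and dispersion (SD)."""

    vx: float = math.nan            # um/s
    vy: float = math.nan            # um/s
    amplitude: float = math.nan     # uM
    fwhm_x: float = math.nan        # um
    fdhm: float = math.nan          # ms
    time_to_boundary: dict | None = None  # wall -> ms
    n_seeds: int = 1
    dispersion: dict | None = None  # metric name -> SD across seeds


def _onsets_along(firing_log: pd.DataFrame, axis: str, origin: tuple[float, float]):
    """First-firing (distance-from-origin, onset-time) pairs on one lattice line."""
    x0, y0 = origin
    if axis == "x":
        line = firing_log[np.abs(firing_log["y_um"] - y0) < _TOL]
        dist = np.abs(line["x_um"].to_numpy() - x0)
    elif axis == "y":
        line = firing_log[np.abs(firing_log["x_um"] - x0) < _TOL]
        dist = np.abs(line["y_um"].to_numpy() - y0)
    else:
        raise ValidationError("axis must be 'x' or 'y'")
    t = line["t_fire_ms"].to_numpy()
    order = np.argsort(t, kind="stable")
    return dist[order], t[order]


def wave_velocity(firing_log: pd.DataFrame, axis: str = "x",
                  origin: tuple[float, float] = (2.0, 0.8),
                  exclude_first: int = 2) -> float:
    """Wave velocity (um/s) along one axis from CRU firing onsets.

    Least-squares slope of first-firing distance-from-origin versus onset
    time over the CRUs on the lattice line through `origin`, after dropping
    the first `exclude_first` onsets.  NaN when fewer than 3 usable onsets
    remain.
    """
    dist, t = _onsets_along(firing_log, axis, origin)
    dist, t = dist[exclude_first:], t[exclude_first:]
    if len(t) < 3:
        return math.nan
    slope = np.polyfit(t, dist, 1)[0]       # um/ms
    return float(slope * 1000.0)


def front_velocity(trajectory: Trajectory, axis: str = "x",
                   origin: tuple[float, float] = (2.0, 0.8),
                   threshold: float = 1.0, exclude_first: int = 2) -> float:
    """Cross-check velocity estimator from concentration-front arrival.

    Arrival time at each CRU position = first snapshot/probe instant when
    the local concentration exceeds `threshold` (uM); fitted like
    `wave_velocity`.
    """
    lat = trajectory.lattice
    if axis == "x":
        sel = np.abs(lat.y - origin[1]) < _TOL
        dist = np.abs(lat.x[sel] - origin[0])
    else:
        sel = np.abs(lat.x - origin[0]) < _TOL
        dist = np.abs(lat.y[sel] - origin[1])
    ixs, iys = lat.ix[sel], lat.iy[sel]
    series = np.stack([s[ixs, iys] for s in trajectory.snapshots], axis=1)
    arrived = series > threshold
    t_arr = np.array([trajectory.times[row.argmax()] if row.any() else np.nan
                      for row in arrived])
    ok = ~np.isnan(t_arr)
    d, t = dist[ok], t_arr[ok]
    order = np.argsort(t, kind="stable")
    d, t = d[order][exclude_first:], t[order][exclude_first:]
    if len(t) < 3 or np.ptp(t) == 0:
        return math.nan
    return float(np.polyfit(t, d, 1)[0] * 1000.0)


def amplitude(trajectory: Trajectory, region=None) -> float:
    """Wave amplitude: maximum free Ca (uM) over the run in a region.

    region = (x_lo, x_hi, y_lo, y_hi) in um, or None for the whole domain.
    For the whole domain the per-step peak history is used (full time
    resolution); for a sub-region the snapshot sequence is scanned.
    """
    if region is None:
        return float(trajectory.peak_c.max())
    grid = trajectory.params.grid
    x = np.arange(grid.nx) * grid.dx
    y = np.arange(grid.ny) * grid.dy
    x_lo, x_hi, y_lo, y_hi = region
    mx = (x >= x_lo) & (x <= x_hi)
    my = (y >= y_lo) & (y <= y_hi)
    if not mx.any() or not my.any():
        raise ValidationError("empty region")
    return float(max(s[np.ix_(mx, my)].max() for s in trajectory.snapshots))


def _half_crossings(values: np.ndarray, coords: np.ndarray, resting: float):
    """Positions of the two half-maximum crossings around the global peak."""
    elev = values - resting
    k = int(np.argmax(elev))
    peak = elev[k]
    if peak <= 0:
        return None
    half = peak / 2.0
    left = None
    for i in range(k, 0, -1):
        if elev[i - 1] <= half < elev[i] or (elev[i - 1] <= half and elev[i] > half):
            f = (half - elev[i - 1]) / (elev[i] - elev[i - 1])
            left = coords[i - 1] + f * (coords[i] - coords[i - 1])
            break
    right = None
    for i in range(k, len(elev) - 1):
        if elev[i] > half >= elev[i + 1] or (elev[i] > half and elev[i + 1] <= half):
            f = (elev[i] - half) / (elev[i] - elev[i + 1])
            right = coords[i] + f * (coords[i + 1] - coords[i])
            break
    # peak touching the window edge: half-crossing undefined on that side
    if left is None:
        left = coords[0] if elev[0] <= half else None
    if right is None:
        right = coords[-1] if elev[-1] <= half else None
    if left is None or right is None:
        return None
    return left, right


def fwhm(profile: np.ndarray, resting_level: float,
         coords: np.ndarray | None = None, spacing: float = 0.1) -> float:
    """Full width at half maximum (um) of a spatial elevation profile.

    Crossings of resting + (peak - resting)/2 are located by linear
    interpolation between grid nodes.  NaN when the peak does not rise
    above the resting level or a crossing is missing.
    """
    profile = np.asarray(profile, dtype=float)
    if coords is None:
        coords = np.arange(len(profile)) * spacing
    res = _half_crossings(profile, np.asarray(coords, dtype=float), resting_level)
    if res is None:
        return math.nan
    return float(res[1] - res[0])


def fdhm(timecourse: np.ndarray, resting_level: float,
         times: np.ndarray | None = None, dt: float = 1.0) -> float:
    """Full duration at half maximum (ms) of a local time course."""
    timecourse = np.asarray(timecourse, dtype=float)
    if times is None:
        times = np.arange(len(timecourse)) * dt
    res = _half_crossings(timecourse, np.asarray(times, dtype=float), resting_level)
    if res is None:
        return math.nan
    return float(res[1] - res[0])


_WALLS = ("left", "right", "bottom", "top")


def time_to_boundary(trajectory: Trajectory, wall: str,
                     criterion: str = "firing", threshold: float = 1.0) -> float:
    """Earliest time (ms) the wave reaches a wall; NaN if it never does.

    criterion 'firing' (default): first firing of a CRU on the wall-adjacent
    lattice line.  criterion 'concentration': first recorded instant the
    concentration on the wall's node line exceeds `threshold` uM.
    """
    if wall not in _WALLS:
        raise ValidationError(f"unknown wall '{wall}' (use one of {_WALLS})")
    lat = trajectory.lattice
    if len(lat) == 0:
        return math.nan
    if criterion == "firing":
        coord = {"left": lat.x, "right": lat.x, "bottom": lat.y, "top": lat.y}[wall]
        edge = coord.min() if wall in ("left", "bottom") else coord.max()
        on_line = np.abs(coord - edge) < _TOL
        t = lat.t_fire[on_line]
        t = t[~np.isnan(t)]
        return float(t.min()) if len(t) else math.nan
    if criterion == "concentration":
        for ts, snap in zip(trajectory.times, trajectory.snapshots):
            line = {"left": snap[0, :], "right": snap[-1, :],
                    "bottom": snap[:, 0], "top": snap[:, -1]}[wall]
            if line.max() > threshold:
                return float(ts)
        return math.nan
    raise ValidationError(f"unknown criterion '{criterion}'")


def detect_collision(trajectory: Trajectory,
                     origins: tuple[tuple[float, float], tuple[float, float]]):
    """Collision of two counter-propagating waves on one lattice row.

    Returns (meet_x um, meet_t ms, quiescent flag): the fronts 'meet' at the
    first firing after which the most advanced CRUs of the two waves are
    adjacent lattice sites; `quiescent` is True when no CRU on the row fires
    after the meet time.  (NaN, NaN, False) if the fronts never meet.
    """
    (xa, ya), (xb, yb) = origins
    if abs(ya - yb) > _TOL or abs(xa - xb) < _TOL:
        raise ValidationError("origins must be two distinct sites on one lattice row")
    if xa > xb:
        xa, xb = xb, xa
    log = trajectory.firing_log
    row = log[np.abs(log["y_um"] - ya) < _TOL].sort_values("t_fire_ms")
    lx = trajectory.lattice.lx
    mid = 0.5 * (xa + xb)
    front_a, front_b = -np.inf, np.inf
    for _, ev in row.iterrows():
        x, t = float(ev["x_um"]), float(ev["t_fire_ms"])
        if x <= mid + _TOL:
            front_a = max(front_a, x)
        if x >= mid - _TOL:
            front_b = min(front_b, x)
        if front_b - front_a <= lx + _TOL:
            meet_x = 0.5 * (front_a + front_b)
            later = row[row["t_fire_ms"] > t + _TOL]
            return meet_x, t, len(later) == 0
    return math.nan, math.nan, False


def single_spark_fwhm(beta: float = 2.0, I_cru: float = 2.0,
                      signal: str = "fluorescence",
                      params=None) -> tuple[float, float, float]:
    """FWHM of one deterministic spark: (fwhm um, peak free Ca uM, peak time ms).

    Runs the centered single-spark protocol (stochastic firing disabled) and
    measures the x-profile through the source at the time of peak central
    concentration.  signal='fluorescence' (default) measures the Ca-bound
    dye profile — the quantity confocal linescans report and the one spark
    widths in the literature refer to; signal='free' measures free calcium.
    """
    from . import scenarios, simulator  # local import to avoid a cycle
    from .reactions import equilibrium_bound

    sc = scenarios.single_spark(beta=beta, I_cru=I_cru)
    if params is None:
        params = sc.build_parameters()
    y0 = sc.forced_crus[0][1]
    traj = simulator.run(sc, params=params, seed=0, probe_rows=[y0],
                         probe_every=4)
    t, rows = traj.probes[y0]
    i_src = params.grid.node_index(sc.forced_crus[0][0], "x")
    k = int(np.argmax(rows[:, i_src]))
    x = np.arange(params.grid.nx) * params.grid.dx
    if signal == "fluorescence":
        dye = next(b for b in params.buffers if b.is_dye)
        prof = traj.probes_dye[y0][k]
        rest = equilibrium_bound(params.C0, dye)
    elif signal == "free":
        prof, rest = rows[k], params.C0
    else:
        raise ValidationError("signal must be 'fluorescence' or 'free'")
    return fwhm(prof, rest, coords=x), float(rows[k, i_src]), float(t[k])


def aggregate_metrics(per_seed: list[dict]) -> WaveMetrics:
    """Seed-mean +- SD aggregation of per-seed metric dictionaries."""
    keys = sorted({k for d in per_seed for k in d})
    means, sds = {}, {}
    for k in keys:
        vals = np.array([d[k] for d in per_seed if k in d and not math.isnan(d[k])])
        means[k] = float(vals.mean()) if len(vals) else math.nan
        sds[k] = float(vals.std(ddof=1)) if len(vals) > 1 else math.nan
    return WaveMetrics(
        vx=means.get("vx", math.nan), vy=means.get("vy", math.nan),
        amplitude=means.get("amplitude", math.nan),
        fwhm_x=means.get("fwhm_x", math.nan), fdhm=means.get("fdhm", math.nan),
        n_seeds=len(per_seed), dispersion=sds,
    )
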