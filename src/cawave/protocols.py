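"""Measurement protocols for the headline wave metrics.

These functions wrap scenario + simulation + metric into the exact
procedures used for the reported numbers, so that tests, the CLI, and the
reproduction script all measure the same way:

* corner-wave velocity/amplitude sweep over the fractional order beta
  (10 ms forced opening at (2, 0.8), onset regression along the initiation
  row, first two onsets excluded, amplitude = max free Ca over the run);
* wall-arrival times for the middle-initiation and reduced-spacing waves
  (first firing of a CRU on the wall-adjacent lattice line);
* the deterministic single-spark FWHM.

Runs that only need an arrival or traversal event stop shortly after the
event to keep the cost proportionate.  The sweep horizon is 300 ms: the
ignition transient of the chain occupies the first ~100-150 ms, and the
regression needs several steady onsets beyond it.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from . import scenarios, simulator, wave_analysis

logger = logging.getLogger(__name__)

SWEEP_HORIZON_MS = 300.0


def _wall_fired(lattice, wall: str) -> bool:
    coord = lattice.x if wall in ("left", "right") else lattice.y
    edge = coord.min() if wall in ("left", "bottom") else coord.max()
    on_line = np.abs(coord - edge) < 1e-9
    return bool((~np.isnan(lattice.t_fire[on_line])).any())


def stop_after_walls(walls, grace_ms: float = 0.0):
    """Stop condition: every named wall-adjacent line has fired (+ grace)."""
    state = {"t_hit": None}

    def cond(sim_state):
        if state["t_hit"] is None:
            if all(_wall_fired(sim_state.lattice, w) for w in walls):
                state["t_hit"] = sim_state.t
        return state["t_hit"] is not None and \
            sim_state.t >= state["t_hit"] + grace_ms
    return cond


def corner_wave_metrics(beta: float, seed: int,
                        t_end: float = SWEEP_HORIZON_MS) -> dict:
    """One corner-wave run: longitudinal/transverse velocity and amplitude."""
    sc = scenarios.corner_wave(beta=beta)
    traj = simulator.run(sc, seed=seed, t_end=t_end,
                         stop_condition=stop_after_walls(("right",),
                                                         grace_ms=10.0))
    origin = sc.forced_crus[0]
    return {
        "beta": beta, "seed": seed,
        "vx": wave_analysis.wave_velocity(traj.firing_log, "x", origin),
        "vy": wave_analysis.wave_velocity(traj.firing_log, "y", origin),
        "amplitude": wave_analysis.amplitude(traj),
        "n_fired": len(traj.firing_log),
    }


def corner_sweep(betas, seeds) -> dict[float, dict[str, float]]:
    """Seed-averaged corner-wave sweep: beta -> mean vx, vy, amplitude."""
    out = {}
    for beta in betas:
        rows = [corner_wave_metrics(beta, s) for s in seeds]
        out[beta] = {
            "vx": float(np.nanmean([r["vx"] for r in rows])),
            "vy": float(np.nanmean([r["vy"] for r in rows])),
            "amplitude": float(np.mean([r["amplitude"] for r in rows])),
            "vx_sd": float(np.nanstd([r["vx"] for r in rows], ddof=1))
            if len(rows) > 1 else math.nan,
            "n_seeds": len(rows),
        }
        logger.info("corner sweep beta=%s: vx=%.1f um/s amp=%.0f uM",
                    beta, out[beta]["vx"], out[beta]["amplitude"])
    return out


def middle_wall_arrival(seed: int, t_end: float = SWEEP_HORIZON_MS) -> float:
    """Later of the left-/bottom-wall first-firing times (ms) for the
    middle-initiation wave; NaN if either wall is never reached."""
    sc = scenarios.middle_wave()
    traj = simulator.run(sc, seed=seed, t_end=t_end,
                         stop_condition=stop_after_walls(("left", "bottom")))
    t_left = wave_analysis.time_to_boundary(traj, "left")
    t_bottom = wave_analysis.time_to_boundary(traj, "bottom")
    return max(t_left, t_bottom)


def reduced_spacing_left_arrival(seed: int) -> float:
    """Left-wall first-firing time (ms) for the physiological-current,
    lx = 1 um single-spark wave; NaN if never reached."""
    sc = scenarios.physiological(1, lx=1.0)
    traj = simulator.run(sc, seed=seed,
                         stop_condition=stop_after_walls(("left",)))
    return wave_analysis.time_to_boundary(traj, "left")


def traverses_domain(n_initial: int, seed: int, lx: float = 2.0) -> bool:
    """Whether a physiological-current wave reaches any domain wall."""
    sc = scenarios.physiological(n_initial, lx=lx)
    any_wall = {"hit": False}

    def cond(state):
        any_wall["hit"] = any(_wall_fired(state.lattice, w)
                              for w in ("left", "right", "bottom", "top"))
        return any_wall["hit"]

    simulator.run(sc, seed=seed, stop_condition=cond)
    return any_wall["hit"]


def fickian_spark_fwhm() -> float:
    """Fluorescence-profile FWHM (um) of one deterministic Fickian spark."""
    w, _, _ = wave_analysis.single_spark_fwhm(beta=2.0, I_cru=2.0,
                                              signal="fluorescence")
    return w
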