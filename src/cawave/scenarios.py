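"""The study scenarios: wave initiation protocols as data, not code.

Each scenario names the CRUs forced open at t = 0 (the 10 ms initial
stimulus), the fractional order, the CRU current, the lattice spacing, the
horizon and the snapshot schedule.  Scenarios serialize to the same flat
key-value format as the main config, so a run is fully scripted from text.

The pathological current used by the corner/middle/collision scenarios is
the CRUParams default (see docs for its calibration); the physiological
scenarios fix I = 2 pA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace, asdict
from pathlib import Path

import yaml

from .model_core import (ModelParameters, ValidationError, default_parameters)

MAX_HORIZON_MS = 500.0


@dataclass(frozen=True)
class Scenario:
    name: str
    forced_crus: tuple[tuple[float, float], ...]
    beta: float = 2.25
    I_cru: float | None = None      # pA; None = parameter-set default
    lx: float = 2.0
    ly: float = 0.8
    t_end: float = 200.0
    snapshot_times: tuple[float, ...] = ()
    length_x: float = 20.0
    length_y: float = 10.0
    stochastic: bool = True         # False: only the forced CRUs ever open

    def __post_init__(self) -> None:
        if self.t_end > MAX_HORIZON_MS + 1e-9:
            raise ValidationError(f"t_end {self.t_end} exceeds the {MAX_HORIZON_MS} ms horizon")
        for x, y in self.forced_crus:
            if not (0 < x < self.length_x and 0 < y < self.length_y):
                raise ValidationError(f"forced CRU {(x, y)} outside the domain")
            for v, sp, nm in ((x, self.lx, "lx"), (y, self.ly, "ly")):
                r = v / sp
                if abs(r - round(r)) > 1e-9:
                    raise ValidationError(
                        f"forced CRU {(x, y)} is not on the {nm}={sp} lattice")

    def build_parameters(self, base: ModelParameters | None = None) -> ModelParameters:
        """Resolve into a full parameter set (defaults + scenario overrides)."""
        p = base if base is not None else default_parameters()
        cru = dc_replace(p.cru, lx=self.lx, ly=self.ly,
                         **({"I_cru": self.I_cru} if self.I_cru is not None else {}),
                         **({"P_max": 0.0} if not self.stochastic else {}))
        return dc_replace(
            p,
            grid=dc_replace(p.grid, length_x=self.length_x, length_y=self.length_y),
            diffusion=dc_replace(p.diffusion, beta=self.beta),
            cru=cru,
            t_end=self.t_end,
        )

    # -- flat key-value (de)serialization --------------------------------
    def to_config(self) -> str:
        d = asdict(self)
        d["forced_crus"] = "; ".join(f"{x},{y}" for x, y in self.forced_crus)
        d["snapshot_times"] = ", ".join(repr(float(t)) for t in self.snapshot_times)
        d["I_cru"] = "" if self.I_cru is None else self.I_cru
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_config(cls, text: str) -> "Scenario":
        d = yaml.safe_load(text)
        forced = tuple(
            tuple(float(v) for v in pair.split(","))
            for pair in str(d["forced_crus"]).split(";") if pair.strip()
        )
        snaps = tuple(float(v) for v in str(d["snapshot_times"]).split(",") if v.strip())
        icru = d.get("I_cru", "")
        return cls(name=d["name"], forced_crus=forced, beta=float(d["beta"]),
                   I_cru=None if icru in ("", None) else float(icru),
                   lx=float(d["lx"]), ly=float(d["ly"]), t_end=float(d["t_end"]),
                   snapshot_times=snaps, length_x=float(d["length_x"]),
                   length_y=float(d["length_y"]), stochastic=bool(d["stochastic"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_config())

    @classmethod
    def load(cls, path: str | Path) -> "Scenario":
        return cls.from_config(Path(path).read_text())


def corner_wave(beta: float = 2.25, I_cru: float | None = None) -> Scenario:
    """Wave from a 10 ms opening of the corner CRU at (2, 0.8).

    The configuration behind the fractional-order sweep of wave velocity
    and amplitude (run it at beta = 2.00, 2.05, 2.15, 2.25).
    """
    return Scenario(
        name="corner_wave", forced_crus=((2.0, 0.8),), beta=beta, I_cru=I_cru,
        lx=2.0, t_end=200.0,
        snapshot_times=(10, 30, 50, 70, 90, 110, 130, 150, 170, 190, 200),
    )


def middle_wave(beta: float = 2.25, I_cru: float | None = None) -> Scenario:
    """Wave from a 10 ms opening of the mid-top CRU at (10, 9.6)."""
    return Scenario(
        name="middle_wave", forced_crus=((10.0, 9.6),), beta=beta, I_cru=I_cru,
        lx=2.0, t_end=120.0,
        snapshot_times=tuple(float(t) for t in range(10, 121, 10)),
    )


def collision(beta: float = 2.25, I_cru: float | None = None) -> Scenario:
    """Two waves from 10 ms openings at (2, 9.6) and (18, 9.6), colliding."""
    return Scenario(
        name="collision", forced_crus=((2.0, 9.6), (18.0, 9.6)), beta=beta,
        I_cru=I_cru, lx=2.0, t_end=150.0,
        snapshot_times=(10, 70, 110, 120, 130, 150),
    )


# Literal initiation sets for the physiological (2 pA) protocols, keyed by
# (n_initial, lx): the published sub-panels place the initiating block at
# slightly different x positions for the two spacings.
_PHYSIO_FORCED = {
    (1, 2.0): ((10.0, 9.6),),
    (4, 2.0): ((10.0, 9.6), (12.0, 9.6), (10.0, 10.4), (12.0, 10.4)),
    (1, 1.0): ((10.0, 9.6),),
    (4, 1.0): ((9.0, 9.6), (10.0, 9.6), (9.0, 10.4), (10.0, 10.4)),
    (9, 1.0): ((9.0, 9.6), (10.0, 9.6), (11.0, 9.6),
               (9.0, 10.4), (10.0, 10.4), (11.0, 10.4),
               (9.0, 11.2), (10.0, 11.2), (11.0, 11.2)),
}
_PHYSIO_SNAPSHOTS = {
    (1, 2.0): (10.0, 330.0, 490.0),
    (4, 2.0): (10.0, 330.0, 490.0),
    (1, 1.0): (10.0, 60.0, 110.0),
    (4, 1.0): (10.0, 50.0, 90.0),
    (9, 1.0): (10.0, 40.0, 70.0),
}


def physiological(n_initial: int = 1, lx: float = 2.0) -> Scenario:
    """Physiological-current (2 pA) waves from 1, 4, or 9 adjacent sparks.

    The domain is 20 x 20 um here: initiation sits mid-domain, away from
    the reflecting walls, and the horizon extends to 500 ms because the
    weaker waves travel slowly.
    """
    key = (int(n_initial), float(lx))
    if key not in _PHYSIO_FORCED:
        raise ValidationError(
            f"unsupported physiological protocol n_initial={n_initial}, lx={lx}")
    return Scenario(
        name=f"physiological_{n_initial}spark_lx{lx:g}",
        forced_crus=_PHYSIO_FORCED[key], beta=2.25, I_cru=2.0, lx=float(lx),
        t_end=500.0, snapshot_times=_PHYSIO_SNAPSHOTS[key],
        length_x=20.0, length_y=20.0,
    )


def single_spark(beta: float = 2.0, I_cru: float = 2.0) -> Scenario:
    """One isolated deterministic spark at the domain center.

    Stochastic firing is disabled: only the forced CRU opens, giving the
    clean spatial/temporal profile used for FWHM / FDHM measurements.
    """
    return Scenario(
        name="single_spark", forced_crus=((10.0, 4.8),), beta=beta,
        I_cru=I_cru, lx=2.0, t_end=30.0,
        snapshot_times=(5.0, 10.0, 15.0, 20.0, 30.0), stochastic=False,
    )


def mini_fixture(beta: float = 2.25, stochastic: bool = True) -> Scenario:
    """Miniature 4 x 4 um domain with a 3 x 3 CRU block; completes in seconds."""
    return Scenario(
        name="mini_fixture", forced_crus=((2.0, 2.0),), beta=beta, lx=1.0,
        ly=1.0, t_end=20.0, snapshot_times=(5.0, 10.0, 20.0),
        length_x=4.0, length_y=4.0, stochastic=stochastic,
    )
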