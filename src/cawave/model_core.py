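"""Model parameters, units, and validation.

Single source of truth for every physical constant of the calcium-wave
model: grid geometry, anisotropic fractional diffusion, buffer kinetics,
SERCA pump, balancing SR leak, and the calcium-release-unit (CRU) lattice.

Internal unit system
--------------------
Concentration in uM, length in um, time in ms.  Config files and the
published tables quote rate constants per second and the pump V_max in
uM/s; those are converted to the ms system on load and converted back on
emission, so config documents always read like the printed tables.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import yaml

logger = logging.getLogger(__name__)

FARADAY = 96500.0  # C/mol


class ConfigError(ValueError):
    """Malformed config document (syntax or unknown key)."""


class ValidationError(ValueError):
    """A parameter violates a model invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectangular grid.

    Nodes sit at ``x_i = i*dx`` (i = 0..nx-1); the reflecting walls lie half
    a cell outside the first/last node so that zero-flux reflection is the
    mirror image about the wall.  ``nx*dx`` equals the domain length.
    """

    length_x: float = 20.0  # um
    length_y: float = 10.0  # um
    dx: float = 0.1         # um
    dy: float = 0.1         # um

    def __post_init__(self) -> None:
        _require(self.dx > 0 and self.dy > 0, "grid: dx and dy must be positive")
        _require(self.length_x > 0 and self.length_y > 0,
                 "grid: domain lengths must be positive")
        for L, h, name in ((self.length_x, self.dx, "x"), (self.length_y, self.dy, "y")):
            n = L / h
            _require(abs(n - round(n)) < 1e-9,
                     f"grid: length_{name} must be an integer multiple of d{name}")

    @property
    def nx(self) -> int:
        return int(round(self.length_x / self.dx))

    @property
    def ny(self) -> int:
        return int(round(self.length_y / self.dy))

    def node_index(self, coord: float, axis: str) -> int:
        """Grid index of an on-grid coordinate; raises if off-grid."""
        h = self.dx if axis == "x" else self.dy
        n = self.nx if axis == "x" else self.ny
        i = coord / h
        _require(abs(i - round(i)) < 1e-6,
                 f"coordinate {coord} um is not on the {axis} grid (spacing {h})")
        i = int(round(i))
        _require(0 <= i < n, f"coordinate {coord} um lies outside the domain along {axis}")
        return i


@dataclass(frozen=True)
class DiffusionParams:
    """Anisotropic space-fractional diffusion: order beta, coefficients in um^beta/ms.

    beta = 2 is the classical Fickian limit; 2 < beta < 3 is the anomalous
    regime.  D is held numerically fixed while beta varies (units um^beta/ms),
    the convention under which the wave-speed sweep over beta is defined.
    """

    beta: float = 2.25
    Dx: float = 0.30
    Dy: float = 0.15

    def __post_init__(self) -> None:
        _require(2.0 <= self.beta < 3.0, "diffusion: beta must satisfy 2 <= beta < 3")
        _require(self.Dx > 0, "diffusion: Dx must be positive")
        _require(self.Dy > 0, "diffusion: Dy must be positive")


@dataclass(frozen=True)
class BufferSpec:
    """One calcium buffer species (mass-action, stationary).

    Rates are stored in the ms system: k_plus in /uM/ms, k_minus in /ms.
    """

    name: str
    k_plus: float
    k_minus: float
    B_total: float
    is_dye: bool = False

    def __post_init__(self) -> None:
        _require(self.k_plus > 0, f"buffer {self.name}: k_plus must be positive")
        _require(self.k_minus > 0, f"buffer {self.name}: k_minus must be positive")
        _require(self.B_total > 0, f"buffer {self.name}: B_total must be positive")

    @property
    def Kd(self) -> float:
        """Dissociation constant k_minus/k_plus, uM."""
        return self.k_minus / self.k_plus


@dataclass(frozen=True)
class PumpParams:
    """SERCA pump Hill kinetics. V_max in uM/ms, K_pump in uM."""

    V_max: float = 0.208
    K_pump: float = 0.184
    n_pump: float = 3.9

    def __post_init__(self) -> None:
        _require(self.V_max > 0, "pump: V_max must be positive")
        _require(self.K_pump > 0, "pump: K_pump must be positive")
        _require(self.n_pump > 0, "pump: n_pump must be positive")


@dataclass(frozen=True)
class CRUParams:
    """Calcium release unit lattice geometry, source strength, and firing law.

    lx/ly: CRU spacings (um); I_cru: channel-cluster current (pA);
    T_open: open duration (ms); P_max (/ms), K_sens (uM), n_cru: the Hill
    firing-probability law; depth: thickness of the 2-D sheet (um) used to
    convert the point-source molar flux to a concentration rate; C_gate:
    concentration (uM) a closed CRU must see before it counts as recruited
    by the wave — below it a firing would be a spontaneous spark, which is
    suppressed when suppress_background_firing is on.
    """

    lx: float = 2.0
    ly: float = 0.8
    I_cru: float = 3.3
    T_open: float = 10.0
    P_max: float = 0.3
    K_sens: float = 15.0
    n_cru: float = 1.6
    faraday: float = FARADAY
    depth: float = 0.06
    C_gate: float = 0.5

    def __post_init__(self) -> None:
        _require(self.lx > 0 and self.ly > 0, "cru: spacings must be positive")
        _require(self.T_open > 0, "cru: T_open must be positive")
        _require(self.P_max >= 0, "cru: P_max must be nonnegative")
        _require(self.K_sens > 0, "cru: K_sens must be positive")
        _require(self.n_cru > 0, "cru: n_cru must be positive")
        _require(self.I_cru >= 0, "cru: I_cru must be nonnegative")
        _require(self.depth > 0, "cru: depth must be positive")
        _require(self.C_gate >= 0, "cru: C_gate must be nonnegative")


@dataclass(frozen=True)
class ModelParameters:
    """Fully resolved parameter set in the internal uM/um/ms unit system."""

    grid: GridSpec = field(default_factory=GridSpec)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    buffers: tuple[BufferSpec, ...] = ()
    pump: PumpParams = field(default_factory=PumpParams)
    cru: CRUParams = field(default_factory=CRUParams)
    C0: float = 0.1        # uM resting free calcium
    dt: float = 0.005      # ms
    t_end: float = 200.0   # ms
    seed: int = 0
    suppress_background_firing: bool = True

    def __post_init__(self) -> None:
        _require(self.C0 > 0, "C0 must be positive")
        _require(self.dt > 0, "dt must be positive")
        _require(self.t_end >= 0, "t_end must be nonnegative")
        _require(0.0 <= self.cru.P_max * self.dt <= 1.0,
                 f"P_max*dt = {self.cru.P_max * self.dt} must lie in (0, 1]"
                 if self.cru.P_max > 0 else "P_max*dt out of range")
        for sp, h, name in ((self.cru.lx, self.grid.dx, "lx"),
                            (self.cru.ly, self.grid.dy, "ly")):
            r = sp / h
            _require(abs(r - round(r)) < 1e-9,
                     f"cru: {name} must be an integer multiple of the grid spacing")

    def buffer(self, name: str) -> BufferSpec:
        for b in self.buffers:
            if b.name == name:
                return b
        raise KeyError(name)


# Printed-units table rows: (name, k+ /uM/s, k- /s, B_total uM, is_dye)
_BUFFER_TABLE = (
    ("dye", 80.0, 90.0, 50.0, True),
    ("Calmodulin", 100.0, 38.0, 24.0, False),
    ("Troponin", 39.0, 20.0, 70.0, False),
    ("SR", 115.0, 100.0, 47.0, False),
    ("SL", 115.0, 1000.0, 1124.0, False),
)


def default_parameters() -> ModelParameters:
    """The standard parameter set, converted to the internal uM/um/ms system.

    Buffer rate constants and the pump V_max are quoted per second in the
    published tables and are divided by 1000 here; everything else is
    already in ms-based units.
    """
    buffers = tuple(
        BufferSpec(name=n, k_plus=kp / 1000.0, k_minus=km / 1000.0,
                   B_total=bt, is_dye=dye)
        for n, kp, km, bt, dye in _BUFFER_TABLE
    )
    return ModelParameters(buffers=buffers)


# Config keys, their target (section, field), and the printed->internal scale.
_SCALAR_KEYS: dict[str, tuple[str, str, float]] = {
    "beta": ("diffusion", "beta", 1.0),
    "Dx": ("diffusion", "Dx", 1.0),
    "Dy": ("diffusion", "Dy", 1.0),
    "length_x": ("grid", "length_x", 1.0),
    "length_y": ("grid", "length_y", 1.0),
    "dx": ("grid", "dx", 1.0),
    "dy": ("grid", "dy", 1.0),
    "V_max": ("pump", "V_max", 1000.0),   # uM/s -> uM/ms
    "K_pump": ("pump", "K_pump", 1.0),
    "n_pump": ("pump", "n_pump", 1.0),
    "lx": ("cru", "lx", 1.0),
    "ly": ("cru", "ly", 1.0),
    "I_cru": ("cru", "I_cru", 1.0),
    "T_open": ("cru", "T_open", 1.0),
    "P_max": ("cru", "P_max", 1.0),       # already /ms in the tables
    "K_sens": ("cru", "K_sens", 1.0),
    "n_cru": ("cru", "n_cru", 1.0),
    "faraday": ("cru", "faraday", 1.0),
    "depth": ("cru", "depth", 1.0),
    "C_gate": ("cru", "C_gate", 1.0),
    "C0": ("", "C0", 1.0),
    "dt": ("", "dt", 1.0),
    "t_end": ("", "t_end", 1.0),
}
_INT_KEYS = {"seed": ("", "seed")}
_BOOL_KEYS = {"suppress_background_firing": ("", "suppress_background_firing")}
_BUFFER_FIELDS = {"kplus": ("k_plus", 1000.0), "kminus": ("k_minus", 1000.0),
                  "btotal": ("B_total", 1.0)}


def _buffer_key(key: str) -> tuple[str, str] | None:
    """Split keys like 'dye_kplus' into (buffer name, field tag)."""
    if "_" not in key:
        return None
    name, _, tail = key.rpartition("_")
    if tail in _BUFFER_FIELDS and name:
        return name, tail
    return None


def load_parameters(config: str | Mapping[str, Any] | None = None) -> ModelParameters:
    """Build a ModelParameters from a flat key-value config document.

    ``config`` may be a YAML string of flat scalars, a mapping, or None.
    Unspecified keys take the standard defaults.  Values are in the printed
    units of the tables (per-second rates, V_max in uM/s) and are converted
    to the internal ms system.  All model invariants are re-checked; the
    resolved set is echoed to the log.
    """
    if config is None:
        doc: Mapping[str, Any] = {}
    elif isinstance(config, Mapping):
        doc = config
    else:
        try:
            loaded = yaml.safe_load(config)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse config document: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config document must be a flat key-value mapping")
        doc = loaded

    base = default_parameters()
    sections: dict[str, dict[str, Any]] = {"grid": {}, "diffusion": {}, "pump": {},
                                           "cru": {}, "": {}}
    buffer_over: dict[str, dict[str, float]] = {}

    for key, raw in doc.items():
        if key in _SCALAR_KEYS:
            sec, fld, scale = _SCALAR_KEYS[key]
            try:
                val = float(raw)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"key '{key}': expected a number, got {raw!r}") from exc
            sections[sec][fld] = val / scale
        elif key in _INT_KEYS:
            sec, fld = _INT_KEYS[key]
            try:
                sections[sec][fld] = int(raw)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"key '{key}': expected an integer, got {raw!r}") from exc
        elif key in _BOOL_KEYS:
            sec, fld = _BOOL_KEYS[key]
            if not isinstance(raw, bool):
                raise ConfigError(f"key '{key}': expected true/false, got {raw!r}")
            sections[sec][fld] = raw
        elif (bk := _buffer_key(key)) is not None:
            name, tag = bk
            if name not in {b.name for b in base.buffers}:
                raise ConfigError(f"key '{key}': unknown buffer '{name}'")
            fld, scale = _BUFFER_FIELDS[tag]
            try:
                buffer_over.setdefault(name, {})[fld] = float(raw) / scale
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"key '{key}': expected a number, got {raw!r}") from exc
        else:
            raise ConfigError(f"unknown config key '{key}'")

    buffers = tuple(
        replace(b, **buffer_over[b.name]) if b.name in buffer_over else b
        for b in base.buffers
    )
    params = ModelParameters(
        grid=replace(base.grid, **sections["grid"]),
        diffusion=replace(base.diffusion, **sections["diffusion"]),
        buffers=buffers,
        pump=replace(base.pump, **sections["pump"]),
        cru=replace(base.cru, **sections["cru"]),
        **sections[""],
    )
    logger.info("resolved parameters:\n%s", emit_config(params))
    return params


def _fmt(x: float, scale: float = 1.0) -> Any:
    """Emitted value p such that p/scale reloads to exactly the stored float."""
    p = x * scale
    if p / scale != x:  # fix the last-ulp rounding of the unit conversion
        for q in (math.nextafter(p, math.inf), math.nextafter(p, -math.inf)):
            if q / scale == x:
                p = q
                break
    if p == int(p) and abs(p) < 1e15:
        return int(p)
    return p


def emit_config(params: ModelParameters) -> str:
    """Serialize to the flat key-value (YAML) config format, printed units."""
    out: dict[str, Any] = {}
    for key, (sec, fld, scale) in _SCALAR_KEYS.items():
        obj = params if sec == "" else getattr(params, sec)
        out[key] = _fmt(getattr(obj, fld), scale)
    out["seed"] = params.seed
    out["suppress_background_firing"] = params.suppress_background_firing
    for b in params.buffers:
        out[f"{b.name}_kplus"] = _fmt(b.k_plus, 1000.0)
        out[f"{b.name}_kminus"] = _fmt(b.k_minus, 1000.0)
        out[f"{b.name}_btotal"] = _fmt(b.B_total)
    buf = io.StringIO()
    yaml.safe_dump(out, buf, sort_keys=True, default_flow_style=False)
    return buf.getvalue()
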