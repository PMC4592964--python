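"""Run configuration: bench-unit YAML in, SI objects out.

Configs are written in the units the device is operated in (cm, rpm,
ml/min, mm); conversion to SI happens once, at the boundary, when the
simulation objects are built.  Unknown keys are rejected, defaults are
logged, and ``dumps(loads(x)) == x`` for every preset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dynamics import ParticleProps
from .flowfields import FluidProps, field_for
from .geometry import TankGeometry

logger = logging.getLogger("rolltank")

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "loads_config",
    "dump_config",
    "dumps_config",
    "PRESETS",
    "get_preset",
    "config_hash",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content; names the offending key."""


@dataclass
class GeometryConfig:
    design: str = "closed"
    radius_cm: float = 4.5
    length_cm: float = 27.0
    rpm: float = 1.8
    flow_ml_min: float = 0.0


@dataclass
class FluidConfig:
    density_kg_m3: float = 1000.0
    kinematic_viscosity_m2_s: float = 1.0e-6


@dataclass
class ParticleConfig:
    diameter_mm: float = 1.0
    density_kg_m3: float = 1005.0
    drag_law: str = "stokes"
    model: str = "inertial"


@dataclass
class SeedingConfig:
    mode: str = "explicit"  # explicit | ring | random
    positions_cm: list = field(default_factory=lambda: [[2.0, 0.0, 13.5]])
    count: int = 15
    radius_cm: float = 2.0
    z_cm: float = 13.5
    seed: int = 0


@dataclass
class IntegrationConfig:
    dt_s: float = 0.01
    t_max_s: float = 30.0


@dataclass
class OutputConfig:
    directory: str = "rolltank_out"
    sample_interval_s: float = 1.0


_SECTIONS = {
    "geometry": GeometryConfig,
    "fluid": FluidConfig,
    "particle": ParticleConfig,
    "seeding": SeedingConfig,
    "integration": IntegrationConfig,
    "output": OutputConfig,
}


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    particle: ParticleConfig = field(default_factory=ParticleConfig)
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    # -- SI views ---------------------------------------------------------

    def tank_geometry(self) -> TankGeometry:
        g = self.geometry
        return TankGeometry.from_bench_units(
            g.design, g.radius_cm, g.length_cm, g.rpm, g.flow_ml_min
        )

    def fluid_props(self) -> FluidProps:
        return FluidProps(self.fluid.density_kg_m3, self.fluid.kinematic_viscosity_m2_s)

    def particle_props(self) -> ParticleProps:
        p = self.particle
        return ParticleProps(p.diameter_mm * 1e-3, p.density_kg_m3, p.drag_law)

    def flow_field(self):
        return field_for(self.tank_geometry())

    def seeding_spec(self):
        s = self.seeding
        if s.mode == "explicit":
            return np.asarray(s.positions_cm, dtype=float) / 100.0
        if s.mode == "ring":
            return {
                "mode": "ring",
                "count": s.count,
                "radius": s.radius_cm / 100.0,
                "z": s.z_cm / 100.0,
            }
        if s.mode == "random":
            return {"mode": "random", "count": s.count}
        raise ConfigError(f"seeding.mode: unknown mode {s.mode!r}")

    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS}

    def validate(self) -> "RunConfig":
        self.tank_geometry()  # raises on non-physical geometry
        self.fluid_props()
        if self.particle.model != "massless":
            self._check_positive("particle.diameter_mm", self.particle.diameter_mm)
            self._check_positive("particle.density_kg_m3", self.particle.density_kg_m3)
            self.particle_props()
        if self.particle.model not in ("massless", "overdamped", "inertial"):
            raise ConfigError(f"particle.model: unknown model {self.particle.model!r}")
        self._check_positive("integration.dt_s", self.integration.dt_s)
        self._check_positive("integration.t_max_s", self.integration.t_max_s)
        self._check_positive("output.sample_interval_s", self.output.sample_interval_s)
        self.seeding_spec()
        return self

    @staticmethod
    def _check_positive(key: str, value) -> None:
        if not value > 0:
            raise ConfigError(f"{key}: must be positive, got {value}")


def _build_section(name: str, cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{name}.{sorted(unknown)[0]}: unknown key")
    for key, f in fields.items():
        if key not in data:
            default = (
                f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
            )
            logger.info("config: %s.%s defaulted to %r", name, key, default)
    try:
        return cls(**data)
    except TypeError as exc:  # missing required key (none currently, but future-proof)
        raise ConfigError(f"{name}: {exc}") from exc


def loads_config(text: str) -> RunConfig:
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a mapping of config sections")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"{sorted(unknown)[0]}: unknown section")
    sections = {
        name: _build_section(name, cls, data.get(name, {}) or {})
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**sections).validate()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (bench units)."""
    return loads_config(Path(path).read_text())


def dumps_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.to_dict(), sort_keys=False)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(dumps_config(cfg))


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical (sorted-keys) YAML serialisation."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# -- scenario presets ------------------------------------------------------
#
# Reference operating point: Q = 9 ml/min, omega = 1.8 rpm; single default
# particle released at (2 cm, 0, 13.5 cm); 1000 s of integration.  The
# bottle-effect comparison runs at 2 rpm with 5 ml/min through-flow.  The
# displacement-validation scenario mirrors the 30-images-in-30-s protocol
# with 15 particles seeded on a ring in the mid plane.


def _reference(design: str, model: str) -> RunConfig:
    flow = 0.0 if design == "closed" else 9.0
    return RunConfig(
        geometry=GeometryConfig(design=design, rpm=1.8, flow_ml_min=flow),
        particle=ParticleConfig(model=model, drag_law="schiller_naumann"),
        seeding=SeedingConfig(mode="explicit", positions_cm=[[2.0, 0.0, 13.5]]),
        integration=IntegrationConfig(dt_s=0.02, t_max_s=1000.0),
        output=OutputConfig(sample_interval_s=1.0),
    )


def _presets() -> dict:
    p = {}
    for design in ("closed", "design1", "design2"):
        p[f"{design}_reference"] = _reference(design, "inertial")
        p[f"{design}_streamline"] = _reference(design, "massless")
    p["bottle_effect"] = RunConfig(
        geometry=GeometryConfig(design="design1", rpm=2.0, flow_ml_min=5.0),
        particle=ParticleConfig(model="inertial", drag_law="schiller_naumann"),
        seeding=SeedingConfig(mode="explicit", positions_cm=[[2.0, 0.0, 13.5]]),
        integration=IntegrationConfig(dt_s=0.02, t_max_s=1000.0),
        output=OutputConfig(sample_interval_s=1.0),
    )
    p["displacement_validation"] = RunConfig(
        geometry=GeometryConfig(design="design1", rpm=1.8, flow_ml_min=9.0),
        particle=ParticleConfig(model="inertial", drag_law="schiller_naumann"),
        seeding=SeedingConfig(mode="ring", count=15, radius_cm=2.0, z_cm=13.5),
        integration=IntegrationConfig(dt_s=0.01, t_max_s=30.0),
        output=OutputConfig(sample_interval_s=1.0),
    )
    return p


PRESETS = _presets()


def get_preset(name: str) -> RunConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    # return a deep copy so callers can mutate freely
    return loads_config(dumps_config(cfg))
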