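"""Lagrangian particle dynamics in a tank flow field.

Three particle models are integrated with fixed-step classical RK4:

* ``massless`` — a fluid tracer, dx/dt = u(x, t) (a streamline of a steady
  field, a pathline otherwise);
* ``overdamped`` — tracer plus terminal settling, dx/dt = u + w_s * (-yhat),
  valid when the Stokes response time is short against the flow timescale;
* ``inertial`` — Newtonian drag + buoyant gravity + (by default) the
  buoyant fluid pressure-gradient force,
  dv/dt = f(Re_p) * (u - v)/tau_p + (1 - beta) * g * (-yhat) + beta * Du/Dt,
  beta = rho_f/rho_p, with f = 1 for Stokes drag or the Schiller-Naumann
  correction f = 1 + 0.15 Re_p^0.687.

Added mass, history and lift forces are neglected (see docs/methods.md).
Integration terminates at t_max, on wall contact, or on exit through an
outlet port.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence  # noqa: F401

import numpy as np

from .flowfields import Design1Field, FlowDomainError, FlowField, FluidProps
from .geometry import TankGeometry

__all__ = [
    "GRAVITY",
    "ParticleProps",
    "ParticleState",
    "Trajectory",
    "settling_velocity",
    "relaxation_time",
    "particle_reynolds",
    "simulate_trajectory",
    "simulate_ensemble",
    "ring_positions",
]

GRAVITY = 9.81  # m/s^2, along -y

STATUS_INTERIOR = "interior"
STATUS_WALL = "wall_contact"
STATUS_EXITED = "exited_outlet"

_DRAG_LAWS = ("stokes", "schiller_naumann")
_MODELS = ("massless", "overdamped", "inertial")


@dataclass(frozen=True)
class ParticleProps:
    """A spherical aggregate: diameter m, density kg/m^3, drag law."""

    diameter: float = 1.0e-3
    density: float = 1005.0
    drag_law: str = "stokes"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("particle diameter must be positive")
        if self.density <= 0:
            raise ValueError("particle density must be positive")
        if self.drag_law not in _DRAG_LAWS:
            raise ValueError(f"unknown drag law {self.drag_law!r}; expected {_DRAG_LAWS}")


@dataclass(frozen=True)
class ParticleState:
    time: float
    position: np.ndarray
    velocity: np.ndarray
    status: str = STATUS_INTERIOR


@dataclass
class Trajectory:
    """Time-stamped particle states plus integration metadata.

    ``positions`` and ``velocities`` are (n, 3); times strictly increase;
    only the final sample may carry a non-interior status.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    status: str = STATUS_INTERIOR
    termination_reason: str = "t_max"
    particle: ParticleProps | None = None
    fluid: FluidProps | None = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final_state(self) -> ParticleState:
        return ParticleState(
            float(self.times[-1]), self.positions[-1], self.velocities[-1], self.status
        )

    def position_at(self, t) -> np.ndarray:
        """Linearly interpolated position at time(s) *t*."""
        t = np.asarray(t, dtype=float)
        out = np.stack([np.interp(t, self.times, self.positions[:, i]) for i in range(3)], axis=-1)
        return out

    def cylindrical_radius(self) -> np.ndarray:
        return np.hypot(self.positions[:, 0], self.positions[:, 1])


def settling_velocity(particle: ParticleProps, fluid: FluidProps) -> float:
    """Terminal settling speed, m/s, positive downward.

    Stokes: w_s = (rho_p - rho_f) g d^2 / (18 mu).  Schiller-Naumann: the
    fixed point of w = w_stokes / (1 + 0.15 Re_p^0.687), Re_p = w d / nu,
    solved to 1e-10 relative.  Neutrally buoyant particles settle at 0;
    buoyant particles rise (negative).
    """
    mu = fluid.dynamic_viscosity
    w_stokes = (particle.density - fluid.density) * GRAVITY * particle.diameter**2 / (18.0 * mu)
    if particle.drag_law == "stokes" or w_stokes == 0.0:
        return w_stokes
    w = w_stokes
    for _ in range(200):
        re = abs(w) * particle.diameter / fluid.kinematic_viscosity
        w_new = w_stokes / (1.0 + 0.15 * re**0.687)
        if abs(w_new - w) <= 1e-10 * max(abs(w_new), 1e-300):
            return w_new
        w = w_new
    raise RuntimeError("settling-velocity fixed point did not converge")


def relaxation_time(particle: ParticleProps, fluid: FluidProps) -> float:
    """Stokes response time tau_p = rho_p d^2 / (18 mu), s."""
    return particle.density * particle.diameter**2 / (18.0 * fluid.dynamic_viscosity)


def particle_reynolds(slip_speed: float, particle: ParticleProps, fluid: FluidProps) -> float:
    """Slip-velocity Reynolds number Re_p = |u - v| d / nu."""
    return abs(slip_speed) * particle.diameter / fluid.kinematic_viscosity


def ring_positions(n: int, radius: float, z: float, phase: float = 0.0) -> np.ndarray:
    """(n, 3) seed positions evenly spaced on a circle about the axis."""
    a = phase + 2.0 * math.pi * np.arange(n) / max(n, 1)
    return np.stack([radius * np.cos(a), radius * np.sin(a), np.full(n, z)], axis=1)


def _drag_factor(particle: ParticleProps, fluid: FluidProps, slip: np.ndarray) -> float:
    if particle.drag_law == "stokes":
        return 1.0
    re = particle_reynolds(float(np.linalg.norm(slip)), particle, fluid)
    return 1.0 + 0.15 * re**0.687


def _outlet_positions_fn(field: FlowField, exit_radius: float):
    """None, or a callable t -> (m, 3) outlet positions for exit detection."""
    if exit_radius <= 0:
        return None
    if isinstance(field, Design1Field):
        return field.layout.outlets_at
    geom = getattr(field, "geometry", None)
    if geom is not None and geom.design == "design2" and geom.flow_rate > 0:
        from .geometry import build_port_layout

        fixed = build_port_layout(geom).outlets_at(0.0)
        return lambda t: fixed
    return None


def _terminate_status(
    pos: np.ndarray,
    time: float,
    geom: TankGeometry,
    half_d: float,
    outlets_fn,
    exit_radius: float,
) -> tuple[str, str] | None:
    if outlets_fn is not None:
        outlets = outlets_fn(time)
        d2 = np.sum((outlets - pos[None, :]) ** 2, axis=1)
        if np.any(d2 <= exit_radius**2):
            return STATUS_EXITED, "exited_outlet"
    r = math.hypot(pos[0], pos[1])
    if r >= geom.inner_radius - half_d or not (
        half_d <= pos[2] <= geom.interior_length - half_d
    ):
        return STATUS_WALL, "wall_contact"
    return None


def simulate_trajectory(
    field: FlowField,
    geom: TankGeometry,
    particle: ParticleProps | None,
    fluid: FluidProps,
    initial_position: Sequence[float],
    model: str = "inertial",
    dt: float = 0.01,
    t_max: float = 30.0,
    record_every: int = 1,
    exit_radius: float = 3e-3,
    initial_velocity: Sequence[float] | None = None,
    pressure_gradient: bool = True,
) -> Trajectory:
    """Integrate one particle with fixed-step classical RK4.

    Terminates at ``t_max``, on wall contact (centre within one particle
    radius of any wall), or within ``exit_radius`` of an outlet port.
    Under the inertial model a dt >= tau_p/2 is stiff for the explicit
    integrator; it is halved (with a warning) until stable.

    ``pressure_gradient`` (inertial model) adds the buoyant fluid
    pressure-gradient force (rho_f/rho_p) * Du/Dt.  For near-neutral
    aggregates in a rotating tank this term supplies most of the
    centripetal force; without it the particle's outward drift is
    overestimated by a factor ~rho_p/(rho_p - rho_f).  Disable to recover
    a pure drag + buoyant-gravity model.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown particle model {model!r}; expected {_MODELS}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    x0 = np.asarray(initial_position, dtype=float)
    if not geom.contains(x0):
        raise ValueError(f"initial position {tuple(x0)} outside the cylinder")

    if model == "massless":
        particle = None
    half_d = 0.5 * particle.diameter if particle is not None else 0.0

    w_s = 0.0
    tau_p = math.inf
    if particle is not None:
        w_s = settling_velocity(particle, fluid)
        tau_p = relaxation_time(particle, fluid)
        re_term = particle_reynolds(w_s, particle, fluid)
        if particle.drag_law == "stokes" and re_term > 1.0:
            warnings.warn(
                f"particle Reynolds number at terminal velocity is {re_term:.2f} > 1; "
                "Stokes drag may be inaccurate, consider drag_law='schiller_naumann'",
                UserWarning,
                stacklevel=2,
            )

    if model == "inertial" and dt >= tau_p / 2.0:
        n_half = math.ceil(math.log2(dt / (tau_p / 2.0))) + 1
        new_dt = dt / 2**n_half
        warnings.warn(
            f"dt={dt} is stiff for tau_p={tau_p:.3g}; reduced to {new_dt:.3g}",
            UserWarning,
            stacklevel=2,
        )
        record_every *= 2**n_half
        dt = new_dt

    grav = np.array([0.0, -GRAVITY, 0.0])

    if model == "inertial":
        beta = fluid.density / particle.density
        buoy = (1.0 - beta) * grav

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            u = field.velocity(y[:3], t)
            slip = u - y[3:]
            acc = _drag_factor(particle, fluid, slip) * slip / tau_p + buoy
            if pressure_gradient:
                acc = acc + beta * field.fluid_acceleration(y[:3], t)
            return np.concatenate([y[3:], acc])

        if initial_velocity is None:
            v0 = field.velocity(x0, 0.0) + w_s * np.array([0.0, -1.0, 0.0])
        else:
            v0 = np.asarray(initial_velocity, dtype=float)
        y = np.concatenate([x0, v0])
    else:
        sink = w_s * np.array([0.0, -1.0, 0.0]) if model == "overdamped" else 0.0

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            return field.velocity(y, t) + sink

        y = x0.copy()

    outlets_fn = _outlet_positions_fn(field, exit_radius)
    n_steps = max(1, round(t_max / dt))
    inertial = model == "inertial"
    times = [0.0]
    ys = [y.copy()]
    k1 = rhs(0.0, y)
    vels = [y[3:].copy() if inertial else k1.copy()]
    status = STATUS_INTERIOR
    reason = "t_max"
    t = 0.0
    for k in range(1, n_steps + 1):
        try:
            k2 = rhs(t + 0.5 * dt, y + 0.5 * dt * k1)
            k3 = rhs(t + 0.5 * dt, y + 0.5 * dt * k2)
            k4 = rhs(t + dt, y + dt * k3)
        except FlowDomainError:
            # an RK stage left the domain: the particle is at the wall
            status, reason = STATUS_WALL, "wall_contact"
            if times[-1] < t:
                times.append(t)
                ys.append(y.copy())
                vels.append(y[3:].copy() if inertial else k1.copy())
            break
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = k * dt
        pos = y[:3] if inertial else y
        term = _terminate_status(pos, t, geom, half_d, outlets_fn, exit_radius)
        if term is None:
            k1 = rhs(t, y)  # reused as next step's first stage
        if term is not None or k % record_every == 0 or k == n_steps:
            times.append(t)
            ys.append(y.copy())
            if inertial:
                vels.append(y[3:].copy())
            else:
                # at a terminated state the field may be undefined; carry the
                # last in-domain velocity forward
                vels.append(k1.copy() if term is None else vels[-1].copy())
        if term is not None:
            status, reason = term
            break

    ys_arr = np.array(ys)
    positions = ys_arr[:, :3] if inertial else ys_arr
    velocities = np.array(vels)
    return Trajectory(
        times=np.array(times),
        positions=positions,
        velocities=velocities,
        status=status,
        termination_reason=reason,
        particle=particle,
        fluid=fluid,
        metadata={
            "dt": dt,
            "integrator": "rk4",
            "model": model,
            "t_max": t_max,
            "pressure_gradient": pressure_gradient and model == "inertial",
        },
    )


def simulate_ensemble(
    field: FlowField,
    geom: TankGeometry,
    particle: ParticleProps | None,
    fluid: FluidProps,
    seeding,
    model: str = "inertial",
    dt: float = 0.01,
    t_max: float = 30.0,
    rng_seed: int | None = None,
    **kwargs,
) -> list[Trajectory]:
    """Integrate independent trajectories from a seeding specification.

    ``seeding`` is either an (n, 3) array of explicit positions, or a dict:
    ``{"mode": "ring", "count": n, "radius": r, "z": z}`` or
    ``{"mode": "random", "count": n, "max_radius": r, "z_range": (a, b)}``
    (uniform over the sub-cylinder; reproducible under ``rng_seed``).
    """
    if isinstance(seeding, dict):
        spec = dict(seeding)
        mode = spec.pop("mode")
        if mode == "ring":
            positions = ring_positions(
                spec["count"], spec["radius"], spec["z"], spec.get("phase", 0.0)
            )
        elif mode == "random":
            rng = np.random.default_rng(rng_seed)
            n = spec["count"]
            rmax = spec.get("max_radius", 0.8 * geom.inner_radius)
            z_lo, z_hi = spec.get(
                "z_range", (0.1 * geom.interior_length, 0.9 * geom.interior_length)
            )
            r = rmax * np.sqrt(rng.random(n))
            a = 2.0 * math.pi * rng.random(n)
            positions = np.stack(
                [r * np.cos(a), r * np.sin(a), rng.uniform(z_lo, z_hi, n)], axis=1
            )
        else:
            raise ValueError(f"unknown seeding mode {mode!r}")
    else:
        positions = np.atleast_2d(np.asarray(seeding, dtype=float))
        if positions.size == 0:
            positions = positions.reshape(0, 3)
    for p in positions:
        if not geom.contains(p):
            raise ValueError(f"seed position {tuple(p)} outside the cylinder")
    return [
        simulate_trajectory(field, geom, particle, fluid, p, model, dt, t_max, **kwargs)
        for p in positions
    ]
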