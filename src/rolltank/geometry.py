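"""Tank geometry and inlet/outlet port layouts.

Coordinate convention (fixed project-wide): origin at the inlet-end interior
face on the central axis; ``z`` along the axis, ``y`` opposite gravity, ``x``
completing a right-handed frame.  All quantities SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DESIGNS",
    "TankGeometry",
    "Port",
    "PortLayout",
    "build_port_layout",
    "rotation_z",
]

DESIGNS = ("closed", "design1", "design2")

ML_PER_MIN = 1e-6 / 60.0  # m^3/s per ml/min
RPM = 2.0 * math.pi / 60.0  # rad/s per rpm


def rotation_z(angle: float) -> np.ndarray:
    """Rotation matrix about the z-axis by *angle* radians."""
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class TankGeometry:
    """A rolling-tank incubator: a horizontal rotating cylinder.

    Parameters
    ----------
    design
        ``"closed"`` (sealed tank), ``"design1"`` (flow-through with two
        co-rotating wall channels of 6 holes each) or ``"design2"``
        (flow-through with 20 stationary peripheral holes at each end cap).
    inner_radius
        Interior cylinder radius, m.  Default 0.045 (9 cm inner diameter).
    interior_length
        Wetted axial length, m.  Default 0.27: particles are released at the
        mid-plane z = 13.5 cm, implying 27 cm of wetted length inside the
        30 cm device.
    rotation_rate
        Angular speed about z, rad/s (use :meth:`from_bench_units` for rpm).
    flow_rate
        Through-flow, m^3/s (must be 0 for the closed design).
    inlet_angle
        Wall angle of the design-1 inlet channel at t = 0, rad.
    outlet_angle_offset
        Design-1 outlet channel angle relative to the inlet channel, rad.
        The two channels sit 90 degrees apart; the sign is configurable
        because the viewing direction of "clockwise" is not fixed.
    """

    design: str
    inner_radius: float = 0.045
    interior_length: float = 0.27
    rotation_rate: float = 0.0
    flow_rate: float = 0.0
    inlet_angle: float = 0.0
    outlet_angle_offset: float = math.pi / 2.0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        if self.inner_radius <= 0:
            raise ValueError("inner_radius must be positive")
        if self.interior_length <= 0:
            raise ValueError("interior_length must be positive")
        if self.flow_rate < 0:
            raise ValueError("flow_rate must be non-negative")
        if self.design == "closed" and self.flow_rate != 0.0:
            raise ValueError("closed tank must have flow_rate = 0")

    @classmethod
    def from_bench_units(
        cls,
        design: str,
        radius_cm: float = 4.5,
        length_cm: float = 27.0,
        rpm: float = 0.0,
        flow_ml_min: float = 0.0,
        **kwargs,
    ) -> "TankGeometry":
        """Build from the bench units the device is operated in."""
        return cls(
            design=design,
            inner_radius=radius_cm / 100.0,
            interior_length=length_cm / 100.0,
            rotation_rate=rpm * RPM,
            flow_rate=flow_ml_min * ML_PER_MIN,
            **kwargs,
        )

    @property
    def omega(self) -> float:
        return self.rotation_rate

    @property
    def volume(self) -> float:
        """Interior water volume, m^3."""
        return math.pi * self.inner_radius**2 * self.interior_length

    def contains(self, point) -> bool:
        """Whether *point* lies strictly inside the wetted cylinder."""
        x, y, z = point
        return (x * x + y * y) < self.inner_radius**2 and 0.0 < z < self.interior_length

    def with_flow(self, flow_rate: float) -> "TankGeometry":
        return replace(self, flow_rate=flow_rate)


@dataclass(frozen=True)
class Port:
    """A point inlet or outlet on the cylinder wall.

    ``strength`` is the signed volumetric rate, m^3/s: positive for an inlet
    (source), negative for an outlet (sink).
    """

    position: np.ndarray
    strength: float
    role: str  # "inlet" | "outlet"


@dataclass(frozen=True)
class PortLayout:
    """The full set of ports of a flow-through design.

    ``co_rotating`` is True for design 1 (holes drilled in the rotating
    cylinder wall) and False for design 2 (holes served by stationary end
    caps).
    """

    ports: tuple[Port, ...]
    co_rotating: bool
    geometry: TankGeometry = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.ports)

    @property
    def strengths(self) -> np.ndarray:
        return np.array([p.strength for p in self.ports])

    @property
    def base_positions(self) -> np.ndarray:
        """(n, 3) port positions at t = 0."""
        return np.array([p.position for p in self.ports])

    def positions_at(self, time: float) -> np.ndarray:
        """(n, 3) port positions at *time*, rotated by omega*t if co-rotating."""
        pos = self.base_positions
        if not self.co_rotating or self.geometry is None or self.geometry.rotation_rate == 0.0:
            return pos
        return pos @ rotation_z(self.geometry.rotation_rate * time).T

    def outlets_at(self, time: float) -> np.ndarray:
        """(m, 3) positions of the outlet ports at *time*."""
        pos = self.positions_at(time)
        mask = np.array([p.role == "outlet" for p in self.ports])
        return pos[mask]


def build_port_layout(
    geom: TankGeometry,
    axial_margin: float = 0.05,
    axial_positions: tuple[np.ndarray, np.ndarray] | None = None,
) -> PortLayout:
    """Generate the port layout of a flow-through design.

    Design 1: 6 inlet holes evenly spaced along the first half of the wall
    (axial span ``[axial_margin*L, (0.5-axial_margin)*L]``) on the inlet
    channel, 6 outlet holes mirrored on the second half on a channel 90
    degrees away; each hole carries Q/6; co-rotating.

    Design 2: 20 inlet holes evenly spaced around the wall circle at z = 0
    and 20 outlet holes at z = L; each carries Q/20; stationary.

    Parameters
    ----------
    axial_margin
        Design-1 end margin as a fraction of L (default 5%); exact hole
        stations may be overridden with *axial_positions* (inlet_z, outlet_z).
    """
    if geom.design == "closed":
        raise ValueError("closed tank has no ports")
    R, L, Q = geom.inner_radius, geom.interior_length, geom.flow_rate
    ports: list[Port] = []
    if geom.design == "design1":
        if axial_positions is not None:
            z_in, z_out = (np.asarray(a, dtype=float) for a in axial_positions)
        else:
            z_in = np.linspace(axial_margin * L, (0.5 - axial_margin) * L, 6)
            z_out = np.linspace((0.5 + axial_margin) * L, (1.0 - axial_margin) * L, 6)
        q_in = Q / len(z_in)
        q_out = Q / len(z_out)
        a_in, a_out = geom.inlet_angle, geom.inlet_angle + geom.outlet_angle_offset
        for z in z_in:
            ports.append(Port(np.array([R * math.cos(a_in), R * math.sin(a_in), z]), q_in, "inlet"))
        for z in z_out:
            ports.append(
                Port(np.array([R * math.cos(a_out), R * math.sin(a_out), z]), -q_out, "outlet")
            )
        co_rotating = True
    else:  # design2
        n = 20
        angles = 2.0 * math.pi * np.arange(n) / n
        for a in angles:
            ports.append(Port(np.array([R * math.cos(a), R * math.sin(a), 0.0]), Q / n, "inlet"))
        for a in angles:
            ports.append(Port(np.array([R * math.cos(a), R * math.sin(a), L]), -Q / n, "outlet"))
        co_rotating = False
    return PortLayout(ports=tuple(ports), co_rotating=co_rotating, geometry=geom)
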