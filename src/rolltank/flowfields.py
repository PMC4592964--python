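"""Reduced-order velocity fields for closed and flow-through rolling tanks.

The interior of a slowly rotating closed cylinder settles into solid-body
rotation, v = omega x r.  The flow-through designs superpose a through-flow
on that base state:

* design 2 (stationary end-cap ports): an axial profile, by default plug
  flow u_z = Q/(pi R^2), optionally parabolic;
* design 1 (co-rotating wall ports): free-space point sources/sinks at the
  hole positions (rotating with the wall) plus an axisymmetric, exactly
  divergence-free through-flow correction that restores the net axial flux
  a wall-bounded device must carry (free-space monopoles at the wall radiate
  most of their volume flux radially through the absent wall, so on their
  own they carry only a small fraction of Q down the axis).

Fields are queried in the lab frame; gravity is fixed along -y.  The full
pressure/velocity boundary-value problem is out of scope — an externally
computed solution can be imported on a regular grid via :class:`GriddedField`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator

from .geometry import PortLayout, TankGeometry, build_port_layout, rotation_z

__all__ = [
    "FluidProps",
    "FlowDomainError",
    "PortSingularityError",
    "FlowField",
    "SolidBodyField",
    "Design2Field",
    "Design1Field",
    "GriddedField",
    "field_for",
    "solid_body_velocity",
    "design2_velocity",
    "design1_velocity",
    "load_gridded_field",
    "cross_section_flux",
    "divergence",
]


@dataclass(frozen=True)
class FluidProps:
    """Ambient water: density kg/m^3 and kinematic viscosity m^2/s."""

    density: float = 1000.0
    kinematic_viscosity: float = 1.0e-6

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("fluid density must be positive")
        if self.kinematic_viscosity <= 0:
            raise ValueError("kinematic viscosity must be positive")

    @property
    def dynamic_viscosity(self) -> float:
        """mu = rho * nu, Pa s."""
        return self.density * self.kinematic_viscosity


class FlowDomainError(ValueError):
    """Query point outside the field's domain."""


class PortSingularityError(FlowDomainError):
    """Query point inside the exclusion radius of a point port."""


class FlowField:
    """Queryable velocity field over the tank interior.

    Subclasses implement :meth:`_velocity` on validated interior points;
    :meth:`velocity` adds the domain check.
    """

    is_steady: bool = True

    def __init__(self, geometry: TankGeometry):
        self.geometry = geometry

    def _check_domain(self, point: np.ndarray) -> None:
        x, y, z = point
        g = self.geometry
        if x * x + y * y > g.inner_radius**2 or not (0.0 <= z <= g.interior_length):
            raise FlowDomainError(
                f"point {tuple(point)} outside the cylinder "
                f"(R={g.inner_radius}, L={g.interior_length})"
            )

    def velocity(self, point, time: float = 0.0) -> np.ndarray:
        """Velocity (m/s) at *point* (m) and *time* (s)."""
        p = np.asarray(point, dtype=float)
        self._check_domain(p)
        return self._velocity(p, time)

    def _velocity(self, point: np.ndarray, time: float) -> np.ndarray:
        raise NotImplementedError

    def fluid_acceleration(self, point, time: float = 0.0, h: float = 1e-4) -> np.ndarray:
        """Material acceleration Du/Dt = du/dt + (u . grad) u, m/s^2.

        Central-difference default; rotation-dominated subclasses override
        with the analytic centripetal term.
        """
        p = np.asarray(point, dtype=float)
        u = self.velocity(p, time)
        jac = np.empty((3, 3))
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            jac[:, i] = (self.velocity(p + e, time) - self.velocity(p - e, time)) / (2.0 * h)
        acc = jac @ u
        if not self.is_steady:
            dt = 1e-3
            acc = acc + (self.velocity(p, time + dt) - self.velocity(p, time - dt)) / (2.0 * dt)
        return acc


class SolidBodyField(FlowField):
    """Closed-tank interior state: rigid rotation (-omega*y, omega*x, 0)."""

    def _velocity(self, point: np.ndarray, time: float) -> np.ndarray:
        w = self.geometry.rotation_rate
        return np.array([-w * point[1], w * point[0], 0.0])

    def fluid_acceleration(self, point, time: float = 0.0, h: float = 1e-4) -> np.ndarray:
        w = self.geometry.rotation_rate
        p = np.asarray(point, dtype=float)
        return np.array([-w * w * p[0], -w * w * p[1], 0.0])


class Design2Field(FlowField):
    """Solid-body rotation plus an axial through-flow profile.

    The 20 peripheral holes at each end cap are stationary, so the field is
    steady in the lab frame.  The true axial profile between the hole rings
    is unknown; the default is plug flow u_z = Q/(pi R^2), with an optional
    parabolic (Poiseuille) profile u_z(r) = 2*Q/(pi R^2)*(1 - r^2/R^2).
    """

    def __init__(self, geometry: TankGeometry, profile: str = "plug"):
        if geometry.design != "design2":
            raise ValueError("Design2Field requires a design2 geometry")
        if profile not in ("plug", "poiseuille"):
            raise ValueError(f"unknown axial profile {profile!r}")
        super().__init__(geometry)
        self.profile = profile

    def axial_velocity(self, r: float) -> float:
        g = self.geometry
        mean = g.flow_rate / (math.pi * g.inner_radius**2)
        if self.profile == "plug":
            return mean
        return 2.0 * mean * (1.0 - (r / g.inner_radius) ** 2)

    def _velocity(self, point: np.ndarray, time: float) -> np.ndarray:
        w = self.geometry.rotation_rate
        r = math.hypot(point[0], point[1])
        return np.array([-w * point[1], w * point[0], self.axial_velocity(r)])

    def fluid_acceleration(self, point, time: float = 0.0, h: float = 1e-4) -> np.ndarray:
        # the axial profile is advected along itself: only the centripetal
        # term survives (u_r = 0, so u.grad u_z = 0 for both profiles)
        w = self.geometry.rotation_rate
        p = np.asarray(point, dtype=float)
        return np.array([-w * w * p[0], -w * w * p[1], 0.0])


class Design1Field(FlowField):
    """Solid-body rotation, co-rotating wall monopoles, and flux correction.

    Each of the 12 wall holes is a free-space monopole of strength q_i
    contributing q_i/(4 pi) * (x - x_i(t)) / |x - x_i(t)|^3, with hole
    positions x_i(t) rotating with the cylinder; the field is therefore
    unsteady in the lab frame.  Queries closer than ``exclusion_radius``
    to a hole raise :class:`PortSingularityError` rather than returning
    near-singular velocities.

    Because free-space monopoles do not see the wall, their disc flux falls
    far short of the imposed through-flow Q.  With ``flux_correction`` on
    (default) an axisymmetric correction

        u_z = f(z) / (pi R^2),   u_r = -(r/2) * f'(z) / (pi R^2)

    is added, exactly divergence-free for any smooth f, with f chosen so
    that the total flux through the disc at height z matches the cumulative
    port-strength profile (smoothed over ``ramp_width``).  Between the inlet
    and outlet bands the cross-section flux then equals Q.
    """

    is_steady = False

    def __init__(
        self,
        geometry: TankGeometry,
        layout: PortLayout | None = None,
        exclusion_radius: float = 2e-3,
        flux_correction: bool = True,
        ramp_width: float = 5e-3,
    ):
        if geometry.design != "design1":
            raise ValueError("Design1Field requires a design1 geometry")
        super().__init__(geometry)
        self.layout = layout if layout is not None else build_port_layout(geometry)
        self.exclusion_radius = exclusion_radius
        self.flux_correction = flux_correction
        self.ramp_width = ramp_width
        self._base_positions = self.layout.base_positions
        self._strengths = self.layout.strengths
        self._port_z = self._base_positions[:, 2]
        self._correction = self._build_correction() if flux_correction else None

    # -- through-flow correction ------------------------------------------

    def _cumulative_target(self, z: np.ndarray) -> np.ndarray:
        """Smoothed sum of port strengths below height z (the flux a wall-
        bounded device carries across that disc)."""
        from scipy.special import erf

        z = np.atleast_1d(np.asarray(z, dtype=float))
        steps = 0.5 * (1.0 + erf((z[:, None] - self._port_z[None, :]) / self.ramp_width))
        return steps @ self._strengths

    def _monopole_disc_flux(self, z: float, n_r: int = 60, n_th: int = 120) -> float:
        """Flux of the bare monopole superposition through the disc at z
        (midpoint polar quadrature; rotation-invariant, so t = 0 suffices)."""
        R = self.geometry.inner_radius
        r = (np.arange(n_r) + 0.5) * (R / n_r)
        th = (np.arange(n_th) + 0.5) * (2.0 * math.pi / n_th)
        rr, tt = np.meshgrid(r, th, indexing="ij")
        pts = np.stack(
            [rr * np.cos(tt), rr * np.sin(tt), np.full_like(rr, z)], axis=-1
        ).reshape(-1, 3)
        d = pts[:, None, :] - self._base_positions[None, :, :]
        dist3 = np.sum(d * d, axis=-1) ** 1.5
        uz = np.sum(self._strengths / (4.0 * math.pi) * d[:, :, 2] / dist3, axis=1)
        dA = (rr * (R / n_r) * (2.0 * math.pi / n_th)).reshape(-1)
        return float(np.sum(uz * dA))

    def _build_correction(self) -> PchipInterpolator:
        L = self.geometry.interior_length
        zs = np.linspace(0.0, L, 81)
        target = self._cumulative_target(zs)
        mono = np.array([self._monopole_disc_flux(z) for z in zs])
        # f(z): flux deficit the axisymmetric component must carry
        return PchipInterpolator(zs, target - mono)

    def _correction_velocity(self, point: np.ndarray) -> np.ndarray:
        area = math.pi * self.geometry.inner_radius**2
        z = point[2]
        f = float(self._correction(z)) / area
        fp = float(self._correction(z, nu=1)) / area
        return np.array([-0.5 * point[0] * fp, -0.5 * point[1] * fp, f])

    # -- field evaluation --------------------------------------------------

    def port_positions(self, time: float) -> np.ndarray:
        return self.layout.positions_at(time)

    def _velocity(self, point: np.ndarray, time: float) -> np.ndarray:
        w = self.geometry.rotation_rate
        v = np.array([-w * point[1], w * point[0], 0.0])
        d = point[None, :] - self.port_positions(time)
        dist2 = np.sum(d * d, axis=1)
        if np.any(dist2 < self.exclusion_radius**2):
            raise PortSingularityError(
                f"point {tuple(point)} within {self.exclusion_radius} m of a port"
            )
        v = v + (self._strengths / (4.0 * math.pi * dist2**1.5)) @ d
        if self._correction is not None:
            v = v + self._correction_velocity(point)
        return v

    def fluid_acceleration(self, point, time: float = 0.0, h: float = 1e-4) -> np.ndarray:
        # through-flow velocities are O(Q/(pi R^2)) ~ 1e-5 m/s; their
        # contribution to Du/Dt is negligible against the centripetal term
        w = self.geometry.rotation_rate
        p = np.asarray(point, dtype=float)
        return np.array([-w * w * p[0], -w * w * p[1], 0.0])


class GriddedField(FlowField):
    """Velocity samples on a regular grid, trilinearly interpolated.

    Import path for externally computed (e.g. finite-element) solutions.
    """

    def __init__(
        self,
        axes: Sequence[np.ndarray],
        values: np.ndarray,
        geometry: TankGeometry | None = None,
        order: int = 1,
    ):
        axes = [np.asarray(a, dtype=float) for a in axes]
        for a in axes:
            if a.ndim != 1 or len(a) < 2 or np.any(np.diff(a) <= 0):
                raise ValueError("grid axes must be strictly increasing 1-D arrays")
        values = np.asarray(values, dtype=float)
        if values.shape != tuple(len(a) for a in axes) + (3,):
            raise ValueError(
                f"sample array shape {values.shape} does not match axes "
                f"{tuple(len(a) for a in axes)} + (3,)"
            )
        if geometry is None:
            # bounding geometry: only used for axial extent in flux queries
            geometry = TankGeometry(
                design="closed",
                inner_radius=float(math.hypot(np.abs(axes[0]).max(), np.abs(axes[1]).max())),
                interior_length=float(max(axes[2][-1], axes[2][-1] - axes[2][0])),
            )
        super().__init__(geometry)
        method = "linear" if order == 1 else "cubic"
        self._interp = RegularGridInterpolator(axes, values, method=method, bounds_error=True)
        self.axes = axes

    def _check_domain(self, point: np.ndarray) -> None:
        for c, a in zip(point, self.axes):
            if c < a[0] or c > a[-1]:
                raise FlowDomainError(f"point {tuple(point)} outside the grid hull")

    def _velocity(self, point: np.ndarray, time: float) -> np.ndarray:
        return self._interp(point[None, :])[0]

    @classmethod
    def from_table(cls, path, geometry: TankGeometry | None = None) -> "GriddedField":
        """Read a plain-text table with header ``x y z u v w`` (SI units) on
        a complete regular grid; comma or whitespace delimited."""
        df = pd.read_csv(path, sep=None, engine="python")
        expected = ["x", "y", "z", "u", "v", "w"]
        cols = [c.strip().lower() for c in df.columns]
        if cols != expected:
            raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
        df.columns = cols
        axes = [np.unique(df[c].to_numpy()) for c in ("x", "y", "z")]
        nx, ny, nz = (len(a) for a in axes)
        if nx * ny * nz != len(df):
            raise ValueError("incomplete regular grid: row count does not match axes")
        idx = [np.searchsorted(a, df[c].to_numpy()) for a, c in zip(axes, ("x", "y", "z"))]
        values = np.full((nx, ny, nz, 3), np.nan)
        values[idx[0], idx[1], idx[2]] = df[["u", "v", "w"]].to_numpy()
        if np.any(np.isnan(values)):
            raise ValueError("incomplete regular grid: missing nodes")
        return cls(axes, values, geometry=geometry)


def field_for(geom: TankGeometry, **kwargs) -> FlowField:
    """The default field for a geometry's design."""
    if geom.design == "closed":
        return SolidBodyField(geom)
    if geom.design == "design2":
        return Design2Field(geom, **kwargs)
    return Design1Field(geom, **kwargs)


# -- functional conveniences ----------------------------------------------


def solid_body_velocity(point, geom: TankGeometry) -> np.ndarray:
    return SolidBodyField(geom).velocity(point)


def design2_velocity(point, geom: TankGeometry, profile: str = "plug") -> np.ndarray:
    return Design2Field(geom, profile=profile).velocity(point)


def design1_velocity(
    point, time: float, geom: TankGeometry, layout: PortLayout | None = None
) -> np.ndarray:
    return Design1Field(geom, layout=layout).velocity(point, time)


def load_gridded_field(path, geometry: TankGeometry | None = None) -> GriddedField:
    return GriddedField.from_table(path, geometry=geometry)


def cross_section_flux(
    field: FlowField, z: float, quadrature_n: int = 64, time: float = 0.0
) -> float:
    """Volumetric flux (m^3/s) of *field* through the disc at height *z*,
    by midpoint polar quadrature with ``quadrature_n`` radial shells."""
    g = field.geometry
    if not (0.0 < z < g.interior_length):
        raise FlowDomainError(f"z={z} outside (0, {g.interior_length})")
    R = g.inner_radius
    n_r = quadrature_n
    n_th = 2 * quadrature_n
    r = (np.arange(n_r) + 0.5) * (R / n_r)
    th = (np.arange(n_th) + 0.5) * (2.0 * math.pi / n_th)
    flux = 0.0
    for ri in r:
        dA = ri * (R / n_r) * (2.0 * math.pi / n_th)
        for ti in th:
            p = (ri * math.cos(ti), ri * math.sin(ti), z)
            flux += field.velocity(p, time)[2] * dA
    return flux


def divergence(field: FlowField, point, time: float = 0.0, h: float = 1e-4) -> float:
    """Central-difference estimate of div(v) (1/s) at *point*."""
    p = np.asarray(point, dtype=float)
    div = 0.0
    for i in range(3):
        e = np.zeros(3)
        e[i] = h
        div += (field.velocity(p + e, time)[i] - field.velocity(p - e, time)[i]) / (2.0 * h)
    return div
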