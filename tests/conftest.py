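"""Shared fixtures: geometries, fields and the heavier simulated ensembles.

The reference operating point throughout is Q = 9 ml/min, omega = 1.8 rpm,
R = 4.5 cm, L = 27 cm, with ambient water (rho = 1000 kg/m^3,
nu = 1e-6 m^2/s) and a 1 mm aggregate-density (1005 kg/m^3) sphere.
"""

import numpy as np
import pytest

from rolltank import (
    Design1Field,
    Design2Field,
    FluidProps,
    ParticleProps,
    SolidBodyField,
    TankGeometry,
    simulate_ensemble,
)

RPM18 = 1.8
Q9 = 9.0


@pytest.fixture(scope="session")
def fluid():
    return FluidProps()


@pytest.fixture(scope="session")
def particle():
    return ParticleProps()


@pytest.fixture(scope="session")
def particle_sn():
    return ParticleProps(drag_law="schiller_naumann")


@pytest.fixture(scope="session")
def geom_closed():
    return TankGeometry.from_bench_units("closed", rpm=RPM18)


@pytest.fixture(scope="session")
def geom_d1():
    return TankGeometry.from_bench_units("design1", rpm=RPM18, flow_ml_min=Q9)


@pytest.fixture(scope="session")
def geom_d2():
    return TankGeometry.from_bench_units("design2", rpm=RPM18, flow_ml_min=Q9)


@pytest.fixture(scope="session")
def field_closed(geom_closed):
    return SolidBodyField(geom_closed)


@pytest.fixture(scope="session")
def field_d1(geom_d1):
    return Design1Field(geom_d1)


@pytest.fixture(scope="session")
def field_d2(geom_d2):
    return Design2Field(geom_d2)


@pytest.fixture(scope="session")
def ring_ensemble_30s(field_d1, geom_d1, particle_sn, fluid):
    """15 particles evenly spaced on the r = 2 cm mid-plane circle,
    integrated 30 s in the design-1 field (the displacement-validation
    protocol)."""
    return simulate_ensemble(
        field_d1,
        geom_d1,
        particle_sn,
        fluid,
        {"mode": "ring", "count": 15, "radius": 0.02, "z": 0.135},
        model="inertial",
        dt=0.01,
        t_max=30.0,
    )


@pytest.fixture(scope="session")
def scattered_ensemble_30s(field_d1, geom_d1, particle_sn, fluid):
    """15 particles staggered along the axis (distinct z stations) on a
    circle about the orbit centre, integrated 30 s in the design-1 field.

    Used for the imaging closed loop: the stations keep every projected
    spot pair separated in the y-z view (the sparse-scene regime the
    greedy linker assumes), while each particle still orbits in x-y.
    """
    n = 15
    a = 2.0 * np.pi * np.arange(n) / n
    z = 0.105 + np.arange(n) * (0.06 / (n - 1))
    # circle of radius 1.5 cm about the settling-displaced orbit centre
    seeds = np.stack(
        [0.0115 + 0.015 * np.cos(a), 0.015 * np.sin(a), z], axis=1
    )
    return simulate_ensemble(
        field_d1,
        geom_d1,
        particle_sn,
        fluid,
        seeds,
        model="inertial",
        dt=0.01,
        t_max=30.0,
    )
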