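"""Shared fixtures: small vessels and meshes reused across the suite."""

import numpy as np
import pytest

from coroflow import (BloodProperties, FlowBC, VesselSpec, build_vessel,
                      mesh_lumen, mesh_vessel)


@pytest.fixture(scope="session")
def blood():
    return BloodProperties()


@pytest.fixture(scope="session")
def straight_spec():
    return VesselSpec(length=10.0, base_radius=1.5, stenosis_severity=0.0,
                      stenosis_center=5.0, stenosis_length=4.0,
                      wall_thickness=0.5)


@pytest.fixture(scope="session")
def stenosed_spec():
    return VesselSpec(length=10.0, base_radius=1.5, stenosis_severity=0.4,
                      stenosis_center=5.0, stenosis_length=4.0,
                      wall_thickness=0.5)


@pytest.fixture(scope="session")
def straight_surface(straight_spec):
    return build_vessel(straight_spec)


@pytest.fixture(scope="session")
def stenosed_surface(stenosed_spec):
    return build_vessel(stenosed_spec)


@pytest.fixture(scope="session")
def coarse_straight_mesh(straight_surface):
    # ~20 circumferential divisions: cheap enough for solver unit tests
    return mesh_lumen(straight_surface, face_size=0.45, axial_factor=2.0)


@pytest.fixture(scope="session")
def coarse_stenosed_mesh(stenosed_surface):
    return mesh_lumen(stenosed_surface, face_size=0.45, axial_factor=2.0)


@pytest.fixture(scope="session")
def coarse_fsi_meshes(stenosed_surface):
    return mesh_vessel(stenosed_surface, face_size=0.45, wall_face_size=0.45,
                       n_layers=3, layer_thickness=0.1, axial_factor=2.0)


@pytest.fixture(scope="session")
def steady_bc():
    return FlowBC(inlet_pressure=100.0, outlet_velocity_measured=0.2,
                  velocity_ratio=1.0)


@pytest.fixture(scope="session")
def coarse_straight_solution(coarse_straight_mesh, blood, steady_bc):
    from coroflow import solve_steady

    return solve_steady(coarse_straight_mesh, blood, steady_bc)
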