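"""Shared fixtures: canonical phantoms reused across test modules."""

import numpy as np
import pytest

from ciliomorph.phantoms import (
    MembranePrimitive,
    PhantomSpec,
    build_phantom,
    _docked_sphere,
)


def docked_sphere_spec(standoff_nm, radius_nm=60.0, voxel_size_nm=9.0, theta_deg=0.0):
    """Default scene plus one sphere at an analytic standoff from DA tip 0."""
    spec = PhantomSpec(voxel_size_nm=voxel_size_nm)
    spec.membranes.append(_docked_sphere(spec, theta_deg, radius_nm, standoff_nm))
    return spec


def arc_spec(gap_deg, arc_start_deg=10.0, major_radius_nm=255.0, tube_radius_nm=30.0):
    """Default scene plus one azimuthal arc torus with a prescribed gap."""
    spec = PhantomSpec()
    if gap_deg <= 0:
        membrane = MembranePrimitive(
            kind="toroid",
            major_radius_nm=major_radius_nm,
            tube_radius_nm=tube_radius_nm,
            z_offset_nm=-20.0,
        )
    else:
        membrane = MembranePrimitive(
            kind="arc_torus",
            major_radius_nm=major_radius_nm,
            tube_radius_nm=tube_radius_nm,
            arc_start_deg=arc_start_deg,
            arc_span_deg=360.0 - gap_deg,
            z_offset_nm=-20.0,
        )
    spec.membranes.append(membrane)
    return spec


@pytest.fixture(scope="session")
def default_phantom():
    """Bare MC + 9 DAs, no membranes, axis-aligned."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def ccv_phantom():
    """One docked arc torus with a 153 degree gap."""
    return build_phantom(arc_spec(153.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
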