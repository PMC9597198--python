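"""Shared fixtures.

The default (reference-setup) simulation is expensive enough that it is run
once per session and shared between the pipeline, field-property and
acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from atflap import (
    FACIAL_SKIN,
    SolverConfig,
    build_domain,
    design_flap,
    generate_mesh,
)
from atflap.solver import run_suture_then_release

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_mesh():
    """3 mm mesh of the reference setup (r = 10 mm, 60 deg, 90 x 100 mm)."""
    return generate_mesh(build_domain(design_flap(10.0, 60.0)), 3.0)


@pytest.fixture(scope="session")
def default_solutions(default_mesh):
    """(suture, release) FieldSolutions of the reference simulation."""
    return run_suture_then_release(default_mesh, FACIAL_SKIN, SolverConfig())


@pytest.fixture(scope="session")
def mini_mesh():
    """Coarse A-T mesh small enough for fast solver tests."""
    from atflap.fixtures import patch_meshes

    return patch_meshes()["mini_at"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251002)
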