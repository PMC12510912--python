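"""Shared fixtures: small seeded geometries, meshes and images.

Everything is generated programmatically; expensive objects are
session-scoped so independent tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from grom import cohort as co
from grom import experiments as ex


@pytest.fixture(scope="session")
def tiny_spec() -> co.CohortSpec:
    """Desk-top cohort: 3 healthy-like + 2 iNPH-like subjects, coarse meshes."""
    return co.CohortSpec(n_healthy=3, n_inph=2, master_seed=11, mesh_h=3.0)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec) -> list[co.GeometryParams]:
    return co.sample_cohort(tiny_spec)


@pytest.fixture(scope="session")
def geom_pair(tiny_cohort):
    """Two healthy-like geometries (a registration/mapping test pair)."""
    return tiny_cohort[0], tiny_cohort[1]


@pytest.fixture(scope="session")
def coarse_mesh(tiny_cohort, tiny_spec):
    return co.build_mesh(tiny_cohort[0], tiny_spec.mesh_h)


@pytest.fixture(scope="session")
def tiny_subjects(tiny_cohort, tiny_spec) -> list[ex.Subject]:
    return [ex.Subject(p, co.build_mesh(p, tiny_spec.mesh_h))
            for p in tiny_cohort]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
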