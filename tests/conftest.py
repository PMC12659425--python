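"""Shared fixtures: cached meshes and pipeline runs (the dense solves on the
larger fixtures are the slow part, so each configuration runs once per
session)."""

from __future__ import annotations

import numpy as np
import pytest

from cosmosol.pipeline import CosmoResult, RunConfig, run_cosmo
from cosmosol.tessellation import pentakisdodecahedron, subdivide


@pytest.fixture(scope="session")
def seed_mesh():
    return pentakisdodecahedron()


@pytest.fixture(scope="session")
def fine_mesh(seed_mesh):
    return subdivide(seed_mesh, 1)


@pytest.fixture(scope="session")
def pipeline_cache():
    """Memoized run_cosmo keyed by the RunConfig fields."""
    cache: dict[tuple, CosmoResult] = {}

    def run(**kwargs) -> CosmoResult:
        key = tuple(sorted(kwargs.items()))
        if key not in cache:
            cache[key] = run_cosmo(RunConfig(**kwargs))
        return cache[key]

    return run


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
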