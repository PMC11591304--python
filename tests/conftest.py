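"""Shared fixtures.

The expensive simulation products (the three-case sweep, the mesh study and
the analytic benchmarks) are session-scoped so that the physics-invariant,
trend and convergence tests all read from one deterministic run each.
"""

from __future__ import annotations

import pytest

import dissectflow as df
from dissectflow.benchmarks import poiseuille_benchmark, womersley_benchmark
from dissectflow.config import (build_bc, build_fluid, build_numerics,
                                load_config)
from dissectflow.mesh import convergence_study, short_study_geometry
from dissectflow.sweep import run_sweep


@pytest.fixture(scope="session")
def cfg():
    return load_config()


@pytest.fixture(scope="session")
def bc(cfg):
    return build_bc(cfg)


@pytest.fixture(scope="session")
def fluid(cfg):
    return build_fluid(cfg)


@pytest.fixture(scope="session")
def numerics(cfg):
    return build_numerics(cfg)


@pytest.fixture(scope="session")
def ci_sweep(cfg):
    """Three-case sweep (entry-only, most-distal and most-proximal re-entry)
    at the default 1 mm resolution and four cardiac cycles."""
    return run_sweep(cfg, case_ids=[1, 2, 11])


@pytest.fixture(scope="session")
def case2_run(bc, fluid, numerics):
    """One full-resolution simulation kept with its grid and fields, for
    checks that need the raw snapshots (no-slip, divergence, flux balance)."""
    geom = df.make_case(2)
    return df.simulate(geom, 1.0, bc, fluid, n_cycles=2, numerics=numerics,
                       case_id=2)


@pytest.fixture(scope="session")
def branch_audit(bc, fluid, numerics):
    """One-cycle coarse audit of the branch flow split for the entry-only
    case."""
    return df.flow_split_audit(df.make_case(1), 2.0, bc, fluid, n_cycles=1,
                               numerics=numerics)


@pytest.fixture(scope="session")
def mesh_table(bc, fluid, numerics):
    """Desk-scale grid-sensitivity study on the shortened entry-only
    geometry at four refinement levels."""
    return convergence_study(short_study_geometry(), [2.0, 1.4, 1.0, 0.7],
                             bc, fluid, n_cycles=2, numerics=numerics)


@pytest.fixture(scope="session")
def poiseuille_pair():
    return (poiseuille_benchmark(spacing=1.0),
            poiseuille_benchmark(spacing=0.5))


@pytest.fixture(scope="session")
def womersley_result():
    return womersley_benchmark(spacing=0.5)
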