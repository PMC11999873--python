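"""Shared ensembles for the test suite.

The expensive ground-truth ensembles (critical-percolation interfaces and
fields, forward-SLE and loop-erased-walk traces, the scaled-down continuum
run) are generated once per session at fixed seeds and shared across tests.
Problem sizes are chosen so the full suite runs in well under half an hour
on one CPU while each statistical check retains the precision its tolerance
needs.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hsettings

from flowsle import (
    SimulationParams,
    cluster_geometries,
    label_clusters,
    loop_erased_walk,
    percolation_interface,
    run_simulation,
    sample_percolation_field,
    sample_sle_trace,
)

SEED = 20260929

_hsettings.register_profile("deterministic", derandomize=True)
_hsettings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng_factory():
    def make(offset: int = 0) -> np.random.Generator:
        return np.random.default_rng(SEED + offset)

    return make


@pytest.fixture(scope="session")
def perc_traces(rng_factory):
    """1500 chordal percolation interfaces on 500-wide triangular lattices.

    The driving-function variance fit needs the large ensemble (its
    effective degrees of freedom are the trace count); winding and
    left-passage statistics use subsets.
    """
    rng = rng_factory(1)
    return [percolation_interface(500, 500, rng=rng)[0] for _ in range(1500)]


@pytest.fixture(scope="session")
def perc_dfs(perc_traces):
    """Loewner driving functions of the percolation interfaces."""
    from flowsle import compute_driving_function

    return [compute_driving_function(t, max_points=1500, trace_id=i)
            for i, t in enumerate(perc_traces)]


@pytest.fixture(scope="session")
def perc_geoms(rng_factory):
    """Cluster geometry table from 16 critical-percolation fields (2048^2).

    The accessible-perimeter exponent converges slowly from below, so the
    ensemble must populate the bins around R_g ~ 100-200 lattice units
    well; large fields with a moderate minimum cluster size do that at
    ~1 minute of tracing.
    """
    rng = rng_factory(2)
    geoms = []
    for _ in range(16):
        sign = sample_percolation_field((2048, 2048), rng=rng)
        lab = label_clusters(sign, "triangular")
        geoms.extend(cluster_geometries(lab, min_size=25))
    return geoms


@pytest.fixture(scope="session")
def sle2_traces(rng_factory):
    """300 forward SLE traces at kappa = 2 (capacity 2.0 each)."""
    rng = rng_factory(3)
    return [sample_sle_trace(2.0, 2000, 1e-3, rng=rng) for _ in range(300)]


@pytest.fixture(scope="session")
def lerw_traces(rng_factory):
    """300 loop-erased-walk traces (exact SLE_2 class, lattice-resolved)."""
    rng = rng_factory(4)
    return [loop_erased_walk(250, 250, rng=rng) for _ in range(300)]


@pytest.fixture(scope="session")
def nematic_snapshots():
    """Scaled-down continuum-model run: 256^2, 24 velocity snapshots."""
    params = SimulationParams(lattice=(256, 256), seed=SEED, n_steps=7200,
                              snapshot_interval=300)
    return run_simulation(params, warmup=4000)
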