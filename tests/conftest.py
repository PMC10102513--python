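"""Shared fixtures: small deterministic series and the default cohort run.

The full default cohort (20 subjects x 4 tasks with null-model small-
worldness) is expensive, so it is computed once per session and shared
by every test that checks cohort-level architecture claims.
"""

import numpy as np
import pandas as pd
import pytest

from gazenet import (
    CohortSpec,
    GazeSeries,
    RunConfig,
    build_gcn,
    preprocess,
    simulate_cohort,
    simulate_subject,
)
from gazenet.pipeline import process_recording
from gazenet.simulate import SimulationConfig


def make_series(x, y, rate=90.0, t=None, valid=None, **kw):
    x = np.asarray(x, dtype=float)
    if t is None:
        t = np.arange(len(x)) * 1000.0 / rate
    if valid is None:
        valid = np.ones(len(x), dtype=bool)
    return GazeSeries(t=t, x=x, y=np.asarray(y, dtype=float), valid=valid, rate=rate, **kw)


@pytest.fixture
def hold_series():
    """Two 200 ms holds 300 px apart with mild jitter."""
    rng = np.random.default_rng(0)
    n = 19
    x = np.concatenate([100 + rng.normal(0, 2, n), 400 + rng.normal(0, 2, n)])
    y = np.concatenate([100 + rng.normal(0, 2, n), 100 + rng.normal(0, 2, n)])
    return make_series(x, y)


@pytest.fixture(scope="session")
def default_subject():
    """One default simulated recording (N-num profile, seed 7)."""
    cfg = SimulationConfig(seed=7).with_task("N-num")
    return simulate_subject(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 20 subjects x 4 tasks."""
    return simulate_cohort(CohortSpec(n_subjects=20, seed=1))


@pytest.fixture(scope="session")
def cohort_profiles(default_cohort):
    """Full per-recording profiles (with small-worldness) for the
    default cohort; the single most expensive computation of the suite."""
    cfg = RunConfig(simulation=CohortSpec(n_subjects=20, seed=1), seed=1)
    rows = []
    for (sid, task), res in default_cohort.items():
        row, _, _ = process_recording(res.series, cfg)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def random_graphs():
    """200 assorted small random graphs for bounds / oracle sweeps."""
    import networkx as nx

    from gazenet.network import GazeGraph

    graphs = []
    rng = np.random.default_rng(42)
    for i in range(200):
        n = int(rng.integers(5, 40))
        p = float(rng.uniform(0.08, 0.6))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        graphs.append(GazeGraph.from_networkx(g))
    return graphs
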