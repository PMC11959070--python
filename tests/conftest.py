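"""Shared fixtures: trees, inflows and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pulsesv.arterial1d import build_tree, synthesize_inflow
from pulsesv.arterial1d.tree import (
    ArterialTree,
    Segment,
    SegmentGeometry,
    WallLaw,
    WindkesselTerminal,
)
from pulsesv.cohort import CohortConfig, generate_cohort
from pulsesv.population import load_population_spec


@pytest.fixture(scope="session")
def default_tree():
    return build_tree()


@pytest.fixture(scope="session")
def population_spec():
    return load_population_spec()


def make_tube(
    length=20.0,
    din=2.0,
    dout=None,
    distensibility=5.0,
    r1=0.2,
    r2=0.8,
    compliance=0.5,
    pout=0.0,
    sites=None,
    n_grid_points=None,
) -> ArterialTree:
    """Single-segment tube closed by a Windkessel, for physics checks."""
    seg = Segment(
        "tube",
        SegmentGeometry(length, din, dout if dout is not None else din,
                        n_grid_points),
        WallLaw(distensibility),
    )
    return ArterialTree(
        segments=[seg],
        topology={},
        root="tube",
        terminals={"tube": WindkesselTerminal(r1, r2, compliance, pout)},
        named_sites=sites or {"inlet": ("tube", 0.0), "outlet": ("tube", 1.0)},
    )


@pytest.fixture(scope="session")
def reference_inflow():
    """The reference hemodynamic state: CO 5.5 L/min at 75 bpm."""
    return synthesize_inflow(5500.0 / 75.0, 75.0, 0.23)


@pytest.fixture(scope="session")
def mini_cohort(population_spec, default_tree):
    """Small simulated cohort (6 subjects/stratum) shared across tests."""
    return generate_cohort(
        population_spec,
        default_tree,
        cohort_config=CohortConfig(n_per_group=6, seed=42),
    )


@pytest.fixture(scope="session")
def analytic_dataset():
    """Cohort-schema dataset with a known smooth feature->SV map, for
    estimator unit tests that should not pay for simulations."""
    rng = np.random.default_rng(5)
    n = 400
    df = pd.DataFrame(
        {
            "age": rng.choice([24.5, 34.5, 44.5, 54.5, 64.5, 75.0], n),
            "gender": rng.choice(["M", "F"], n),
            "weight": rng.normal(75, 12, n),
            "height": rng.normal(172, 10, n),
            "dbp": rng.normal(70, 10, n),
            "pp": rng.normal(50, 12, n),
            "cfpwv": rng.normal(9, 2.5, n).clip(4, 18),
            "map": rng.normal(90, 8, n),
        }
    )
    df["sbp"] = df["dbp"] + df["pp"]
    df["sv"] = (
        0.9 * df["pp"] + 600.0 / df["cfpwv"] + 0.2 * df["map"]
        - 0.1 * df["weight"] + rng.normal(0, 2, n)
    )
    return df
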