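"""Shared fixtures: a session-wide case runner so the expensive 24 h
simulations are computed once and reused across test modules."""

from __future__ import annotations

import warnings

import pytest

from macropore.runner import CaseRunner

warnings.filterwarnings("ignore", category=FutureWarning)

#: reduced sweep populating both transport regimes (chosen a priori:
#: high-angle/moderate-velocity rows sit below channel Pe = 1, in-line
#: high-velocity rows above it)
LOW_PE_CASES = [
    (200.0, 90.0, 115.0),
    (300.0, 90.0, 1150.0),
    (400.0, 90.0, 115.0),
    (400.0, 75.0, 115.0),
    (200.0, 75.0, 1150.0),
    (600.0, 90.0, 1150.0),
]
HIGH_PE_CASES = [
    (300.0, 0.0, 1150.0),
    (400.0, 0.0, 1150.0),
    (600.0, 0.0, 1150.0),
    (600.0, 0.0, 115.0),
    (400.0, 30.0, 1150.0),
    (600.0, 30.0, 1150.0),
]


@pytest.fixture(scope="session")
def runner() -> CaseRunner:
    """Memoising pipeline runner at the documented test resolution
    (40 um boundary mesh, 12 s step)."""
    return CaseRunner(scale="test")


@pytest.fixture(scope="session")
def semi_fixtures():
    """One channel-bearing synthetic micrograph per angle, with truth."""
    from macropore.synth import SyntheticImageSpec, generate_micrograph

    out = {}
    for angle in (0.0, 30.0, 60.0, 90.0):
        spec = SyntheticImageSpec(
            channel_width_um=400.0, channel_angle_deg=angle, seed=int(3 + angle)
        )
        out[angle] = (spec, *generate_micrograph(spec))
    return out


@pytest.fixture(scope="session")
def baseline_tables():
    """Colony tables of eight segmented solid-disc control replicates."""
    from macropore.imaging import classify_disc, segment_colonies
    from macropore.synth import SyntheticImageSpec, generate_baseline_set

    spec = SyntheticImageSpec(channel_width_um=400.0, channel_angle_deg=90.0, seed=42)
    tables = []
    for img, _ in generate_baseline_set(spec, 8, seed=100):
        cls = classify_disc(img, spec.pixel_size_um)
        tables.append(segment_colonies(img, cls.mask, spec.pixel_size_um))
    return tables


@pytest.fixture(scope="session")
def dt_convergence_pair(runner):
    """Solid-disc runs at the reference time step (2.4 s) and at half of
    it, for the temporal-convergence check."""
    from macropore.growth import simulate_growth

    mesh = runner.mesh(0.0, 0.0)
    flow = runner.flow(0.0, 0.0, 115.0)
    return tuple(
        simulate_growth(mesh, flow, params=runner.params, dt=dt) for dt in (2.4, 1.2)
    )


@pytest.fixture(scope="session")
def sweep_table(runner):
    """Metrics rows for the reduced two-regime sweep (solid controls
    first so relative biomass increases are defined)."""
    import pandas as pd

    for u in (115.0, 1150.0):
        runner.state(0.0, 0.0, u)
    rows = [
        runner.metrics_row(w, a, u) for (w, a, u) in LOW_PE_CASES + HIGH_PE_CASES
    ]
    return pd.DataFrame(rows)
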