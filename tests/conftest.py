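"""Shared fixtures: presets, a memoizing steady-state runner, and the
standard sweep endpoints reused across the experiment and acceptance
tests (steady-state runs are the expensive part of this suite)."""

from __future__ import annotations

import pytest

from shuntsim import SimConfig, SweepSpec, load_preset, run_sweep, simulate_to_steady_state
from shuntsim.experiments import default_grid
from shuntsim.presets import PRESET_NAMES

#: Published endpoint pairs and percent reductions:
#: (scenario, swept quantity) -> (Qp/Qs at low end, at high end, reduction %).
PAPER_ENDPOINTS = {
    ("vsd", "pvr_wu"): (4.4, 2.0, 53.0),
    ("asd", "pvr_wu"): (2.0, 1.6, 20.0),
    ("asd_vsd", "pvr_wu"): (5.3, 2.1, 60.0),
    ("vsd", "ebrv"): (4.6, 3.7, 19.0),
    ("asd", "ebrv"): (2.0, 0.2, 91.0),
    ("asd_vsd", "ebrv"): (6.4, 3.8, 40.0),
    ("vsd", "trrv_frac"): (4.5, 4.0, 12.0),
    ("asd", "trrv_frac"): (2.2, 0.8, 62.0),
    ("asd_vsd", "trrv_frac"): (5.3, 5.2, 3.0),
}

#: Sweeps whose point-to-point monotone decrease is asserted; these get
#: a denser grid.
MONOTONE_SWEEPS = {("vsd", "pvr_wu"), ("asd_vsd", "pvr_wu"), ("asd", "ebrv")}


@pytest.fixture(scope="session")
def presets():
    return {name: load_preset(name).params for name in PRESET_NAMES}


@pytest.fixture(scope="session")
def steady():
    """Memoized ``simulate_to_steady_state``: repeated identical runs
    across test modules cost one integration."""
    cache = {}

    def run(params, cfg: SimConfig | None = None):
        key = (
            params.model_dump_json(),
            None if cfg is None else cfg.model_dump_json(),
        )
        if key not in cache:
            cache[key] = simulate_to_steady_state(params, cfg)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def sweep_results():
    """One converged sweep per published endpoint pair (endpoint-only
    grids except where monotonicity is asserted)."""
    out = {}
    for (preset, quantity) in PAPER_ENDPOINTS:
        n = 5 if (preset, quantity) in MONOTONE_SWEEPS else 2
        spec = SweepSpec(preset=preset, quantity=quantity, grid=default_grid(quantity, n))
        out[(preset, quantity)] = run_sweep(spec)
    return out
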