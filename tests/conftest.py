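"""Shared fixtures: reduced-grid synthetic vessels and cached long runs.

The stochastic whole-simulation checks run on a 150 x 150 lattice with a
proportionally thinner wall; the expensive 60-day trajectories are computed
once per session and shared between tests.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from restenosim.abm import run_plane
from restenosim.params import SimulationConfig
from restenosim.stimuli import uniform_wss_source
from restenosim.synthetic import (VesselSpec, generate_damage,
                                  generate_vessel, generate_wss)

SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def reduced_config() -> SimulationConfig:
    return SimulationConfig(n_rows=150, n_cols=150)


@pytest.fixture(scope="session")
def synthetic_vessel():
    """Default reduced vessel: 11 planes, eccentric plaque, lacerations."""
    spec = VesselSpec.scaled_down(seed=11)
    sections = generate_vessel(spec)
    damage, masks, plaque_masks, opened = generate_damage(sections, spec=spec,
                                                          seed=11)
    wss = generate_wss(opened, masks)
    return {"spec": spec, "sections": sections, "damage": damage,
            "masks": masks, "plaque_masks": plaque_masks, "opened": opened,
            "wss": wss}


@pytest.fixture(scope="session")
def laceration_plane(synthetic_vessel):
    """The central plane, which carries the plaque and its lacerations."""
    p = 5
    v = synthetic_vessel
    assert v["masks"][p].sum() > 0, "central plane should be lacerated"
    return {"cs": v["opened"][p], "damage": v["damage"][p],
            "mask": v["masks"][p]}


@pytest.fixture(scope="session")
def stimulated_runs(laceration_plane, reduced_config):
    """60-day default-stimulus runs of the lacerated plane, one per seed."""
    return [
        run_plane(laceration_plane["cs"], laceration_plane["damage"],
                  config=reduced_config, seed=s, duration_days=60,
                  deleted_plaque_mask=laceration_plane["mask"])
        for s in SEEDS
    ]


@pytest.fixture(scope="session")
def homeostatic_runs(reduced_config):
    """60-day runs with no damage and saturating WSS (zero stimuli)."""
    spec = VesselSpec.scaled_down(n_planes=1, plaque_max_thickness=0.0,
                                  seed=12)
    cs = generate_vessel(spec)[0]
    zero = np.zeros(cs.grid.n_sites)
    source = uniform_wss_source(10.0)   # far above L2: D(WSS) ~ 0
    return [
        run_plane(cs, zero, wss_source=source, config=reduced_config,
                  seed=s, duration_days=60)
        for s in SEEDS
    ]


def media_ecm_smc_ratio(composition_row) -> float:
    ecm = composition_row["media_collagen"] + composition_row["media_elastin"]
    return ecm / composition_row["media_smc"]
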