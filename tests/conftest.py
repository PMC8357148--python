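import numpy as np
import pytest

from cholnet import (DriveConfig, NoiseConfig, SimConfig, build_default_topology,
                     run_simulation)
from cholnet.gks_map import generate_map
from cholnet.rhythm_analysis import classify_raster


@pytest.fixture(scope="session")
def topology():
    return build_default_topology()


def simulate(topology, gmap, seed, duration=3500.0, noise=True, **kw):
    """Shared short-simulation helper for scenario tests."""
    raster, _ = run_simulation(
        topology, gmap, DriveConfig(), NoiseConfig(enabled=noise),
        cfg=SimConfig(duration=duration, seed=seed), **kw)
    return raster


@pytest.fixture(scope="session")
def double_hotspot_map():
    """The two-hotspot alternation scenario map (r = 6.1, d = 8)."""
    return generate_map([(6, 10), (14, 10)], target_radius=6.1)


@pytest.fixture(scope="session")
def double_hotspot_rasters(topology, double_hotspot_map):
    """Three replicate runs of the alternation scenario (5 s each)."""
    return [simulate(topology, double_hotspot_map, seed, duration=5000.0)
            for seed in (601, 602, 603)]


@pytest.fixture(scope="session")
def radius_scan(topology):
    """Single-hotspot radius scan: {radius: [(raster, report), ...]} over two
    initial-condition seeds per radius."""
    out = {}
    for r in (4.2, 5.5, 6.5):
        gmap = generate_map([(10, 10)], target_radius=r)
        runs = []
        for seed in (11, 22):
            raster = simulate(topology, gmap, seed, duration=4500.0)
            runs.append((raster, classify_raster(raster)))
        out[r] = {"map": gmap, "runs": runs}
    return out
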