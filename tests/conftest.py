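"""Shared fixtures: a standard four-zone device and seeded simulation runs.

The heavy end-to-end simulations (a noiseless 20-cell run and a noisy
100-cell run) are session-scoped so the pipeline, rheology and acceptance
tests all score against the same ground truth without re-simulating.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from npsrheo import DeviceGeometry, PoreSpec, ZoneSpec, detect_events
from npsrheo.rheology import analyze_events, results_to_frame
from npsrheo.simulate import SimConfig, generate_trace, typical_pulse_heights

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_four_zone_geometry(L_zone: float = 6000.0) -> DeviceGeometry:
    """Four-zone device: L_p 500/250/167/125 µm, w = 11.25 + 2.75 cos."""
    zones = tuple(
        ZoneSpec(index=i, L_zone=L_zone, L_p=lp, w0=11.25, a=2.75, w_node=21.0)
        for i, lp in enumerate([500.0, 250.0, 167.0, 125.0])
    )
    return DeviceGeometry(pore=PoreSpec(L_pore=1000.0, D_eff=25.0), zones=zones)


@pytest.fixture(scope="session")
def four_zone_geometry() -> DeviceGeometry:
    return make_four_zone_geometry()


def _run_pipeline(geometry, sim_config):
    trace, truth = generate_trace(sim_config)
    events = detect_events(trace, geometry)
    results, excluded = analyze_events(events, geometry)
    frame = results_to_frame(results, geometry)
    return {
        "trace": trace,
        "truth": truth,
        "events": events,
        "results": frame,
        "excluded": excluded,
        "config": sim_config,
    }


@pytest.fixture(scope="session")
def noiseless_run(four_zone_geometry):
    """20 cells, no noise: the self-consistency (inverse-crime) fixture."""
    cfg = SimConfig(
        geometry=four_zone_geometry,
        seed=7,
        n_cells=20,
        noise_sd=0.0,
        event_rate_per_hour=1440.0,
    )
    return _run_pipeline(four_zone_geometry, cfg)


@pytest.fixture(scope="session")
def noisy_run(four_zone_geometry):
    """100 cells with white noise at 5% of the zone-pulse height plus 1%
    baseline drift: the realistic-recovery fixture."""
    probe = SimConfig(geometry=four_zone_geometry, seed=0, n_cells=1)
    _, zone_height = typical_pulse_heights(probe)
    cfg = SimConfig(
        geometry=four_zone_geometry,
        seed=11,
        n_cells=100,
        noise_sd=0.05 * zone_height,
        baseline_drift_amp=0.01,
        event_rate_per_hour=1440.0,
    )
    return _run_pipeline(four_zone_geometry, cfg)


def truth_indexed(run):
    """Truth table indexed by cell id, aligned to the results frame order."""
    return run["truth"].set_index("cell_id")


def zone_relative_errors(run, quantity: str, n_zones: int = 4) -> np.ndarray:
    """|relative error| of a per-zone quantity for every fitted (cell, zone).

    ``quantity`` is e.g. ``Gp_Pa``; truth columns are ``zone{j}_{quantity}``
    except pre-stress, which is per-cell in the truth table.
    """
    df = run["results"]
    truth = truth_indexed(run)
    cell_ids = df["cell_id"].to_numpy()
    errs = []
    for j in range(1, n_zones + 1):
        est = df[f"zone{j}_{quantity}"].to_numpy(dtype=float)
        if quantity == "sigma_p_Pa":
            true = truth["sigma_p_Pa"].to_numpy(dtype=float)[cell_ids]
        else:
            true = truth[f"zone{j}_{quantity}"].to_numpy(dtype=float)[cell_ids]
        errs.append(np.abs(est / true - 1.0))
    return np.concatenate(errs)
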