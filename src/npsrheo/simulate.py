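"""Forward model: synthesize multi-channel resistance traces with ground truth.

Each simulated cell produces a cascade of resistive pulses: a top-hat pulse
in the sizing pore whose height follows the Coulter sizing relation, then
one pulse per contraction zone whose in-pulse oscillation encodes the
cell's viscoelastic stress response.  The zone waveform is built by running
the stress model *forwards*:

    sigma(t) = sigma_p + G'*eps0*cos(phi) + G''*eps0*sin(phi),  phi = omega*t' + pi
    dP(t)    = sigma * mu_f * pi * D_d(t) / (2 * w(t))          (stress relation, inverted)
    dR(t)    = R_base * (dP/P) / (1 - dP/P)                     (pressure partition)

The pressure-partition step ties the hydraulic pressure drop across the
cell to its fractional electrical blockage, ``dP/P = dR/(R_base + dR)``,
on the grounds that the electrical and hydraulic constrictions co-scale in
a series channel; it is the model choice that makes this generator and the
analysis pipeline exact inverses of each other.

White Gaussian noise and a slow sinusoidal baseline drift can be added on
top.  A :class:`SimTruth` table records every generated parameter and pulse
window so the downstream pipeline can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .device_model import (
    DeviceGeometry,
    StrainWave,
    contraction_width,
    deformed_diameter,
    forward_blockage,
    strain_wave,
)
from .errors import ConfigError, GeometryError
from .signal_pipeline import RawTrace

__all__ = [
    "SimCell",
    "SimConfig",
    "synth_stress",
    "stress_to_blockage",
    "generate_trace",
    "typical_pulse_heights",
]

#: zone-to-zone velocity multipliers reproducing the frequency drift seen in
#: four-zone devices (a cell speeds up slightly as it advances through the
#: device); used by default when the geometry has exactly four zones.
FOUR_ZONE_VELOCITY_FACTORS = (1.0, 1.154, 1.207, 1.25)


@dataclass
class SimCell:
    """Ground-truth parameters of one simulated cell (per-zone arrays)."""

    cell_id: int
    D_cell: float
    Gp_true: np.ndarray
    Gpp_true: np.ndarray
    sigma_p_true: float
    v_zone: np.ndarray
    arrival_time: float

    def __post_init__(self) -> None:
        self.Gp_true = np.asarray(self.Gp_true, dtype=float)
        self.Gpp_true = np.asarray(self.Gpp_true, dtype=float)
        self.v_zone = np.asarray(self.v_zone, dtype=float)
        if np.any(self.Gp_true <= 0) or np.any(self.Gpp_true < 0):
            raise ConfigError("need Gp_true > 0 and Gpp_true >= 0")
        if np.any(self.v_zone <= 0):
            raise ConfigError("zone velocities must be positive")


@dataclass
class SimConfig:
    """Study conditions for a simulated population.

    Defaults emulate an untreated MCF-7-like population in a four-zone
    device at 13.8 kPa driving pressure: diameters 18.4 ± 0.9 µm, mean
    transit velocity ~15 mm/s (≈30 Hz strain in an L_p = 500 µm zone),
    log-normal elastic moduli around 500 Pa with viscous moduli an order
    of magnitude lower, and a pre-stress comfortably above the oscillatory
    stress amplitude so the walls never pull on the cell.  ``noise_sd`` is
    the white-noise standard deviation relative to the channel baseline
    resistance; ``modulus_exponent`` lets both moduli scale as
    ``(f/f_ref)**exponent`` across zones (0 = frequency-independent).
    """

    geometry: DeviceGeometry
    seed: int
    n_cells: int = 20
    diameter_mean: float = 18.4
    diameter_sd: float = 0.9
    gp_median: float = 500.0
    gp_sigma_log: float = 0.3
    gpp_median: float = 50.0
    gpp_sigma_log: float = 0.3
    sigma_p_mean: float = 150.0
    sigma_p_sd: float = 15.0
    modulus_exponent: float = 0.0
    v_mean: float = 15000.0
    v_sd: float = 750.0
    velocity_zone_factors: tuple[float, ...] | None = None
    noise_sd: float = 0.0
    baseline_drift_amp: float = 0.0
    baseline_drift_period_s: float = 120.0
    event_rate_per_hour: float = 600.0
    arrival_jitter: float = 0.1
    base_resistance: float = 5.0e5
    lead_in_s: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.noise_sd < 0 or self.baseline_drift_amp < 0:
            raise ConfigError("noise and drift amplitudes must be non-negative")
        if self.event_rate_per_hour <= 0:
            raise ConfigError("event_rate_per_hour must be positive")
        if self.seed is None:
            raise ConfigError("a seed is mandatory for reproducibility")

    @property
    def zone_factors(self) -> np.ndarray:
        if self.velocity_zone_factors is not None:
            f = np.asarray(self.velocity_zone_factors, dtype=float)
            if len(f) != self.geometry.n_zones:
                raise ConfigError("velocity_zone_factors must match zone count")
            return f
        if self.geometry.n_zones == 4:
            return np.asarray(FOUR_ZONE_VELOCITY_FACTORS)
        return np.ones(self.geometry.n_zones)


def synth_stress(wave: StrainWave, sigma_p: float, Gp: float, Gpp: float, t) -> np.ndarray:
    """Oscillatory stress ``sigma_p + Gp*eps0*cos(phi) + Gpp*eps0*sin(phi)``.

    ``t`` is time from zone entry; the phase convention (``phi = omega*t +
    phase0``) comes from the wave, whose ``phase0 = pi`` places zone entry
    at the widest point (minimum strain).
    """
    phi = wave.phase(t)
    out = sigma_p + wave.eps0 * (Gp * np.cos(phi) + Gpp * np.sin(phi))
    return out if np.ndim(out) else float(out)


def stress_to_blockage(
    sigma, w, D_d, mu_f: float, P_applied: float, R_base: float
) -> np.ndarray:
    """Excess resistance (Ω) produced by a cell under stress ``sigma``.

    Forward counterpart of the analysis chain: the stress relation gives
    the pressure drop across the cell, ``dP = sigma*mu_f*pi*D_d/(2*w)``,
    and the pressure-partition model converts its fraction of the driving
    pressure into a fractional resistance rise,
    ``dR = R_base * (dP/P)/(1 - dP/P)``.
    """
    sigma = np.asarray(sigma, dtype=float)
    dP = sigma * mu_f * np.pi * np.asarray(D_d, dtype=float) / (2.0 * np.asarray(w, dtype=float))
    q = dP / P_applied
    if np.any(q >= 1.0):
        raise GeometryError("dP >= applied pressure: cell would stall (unphysical stress)")
    if np.any(q < 0):
        raise GeometryError("negative stress is unphysical here")
    out = R_base * q / (1.0 - q)
    return out if out.ndim else float(out)


def typical_pulse_heights(config: SimConfig) -> tuple[float, float]:
    """Characteristic relative pulse heights ``(pore, zone)`` for the
    generator's mean-parameter cell.

    Useful for expressing a noise level relative to the signal of interest
    (e.g. ``noise_sd = 0.05 * zone_height``).  The zone height is the
    pulse-average blockage of a cell with the mean diameter and mean
    pre-stress in the first zone.
    """
    geo = config.geometry
    D = config.diameter_mean
    pore_h = float(forward_blockage(D, geo.pore.D_eff, geo.pore.L_pore))
    zone = geo.zones[0]
    x = np.linspace(0.0, zone.L_p, 256, endpoint=False)
    w = contraction_width(zone, x)
    D_d = deformed_diameter(D, w)
    dP = config.sigma_p_mean * geo.mu_f * np.pi * D_d / (2.0 * w)
    q = dP / geo.applied_pressure
    zone_h = float(np.mean(q / (1.0 - q)))
    return pore_h, zone_h


def _draw_population(config: SimConfig, rng: np.random.Generator) -> list[SimCell]:
    geo = config.geometry
    nz = geo.n_zones
    factors = config.zone_factors
    spacing = 3600.0 / config.event_rate_per_hour
    # truncate diameters to the physically meaningful range
    lo = max(z.w0 + z.a for z in geo.zones) + 0.5
    hi = geo.pore.D_eff - 0.5
    cells = []
    for i in range(config.n_cells):
        for _ in range(1000):
            D = rng.normal(config.diameter_mean, config.diameter_sd)
            if lo < D < hi:
                break
        else:
            raise ConfigError("diameter distribution incompatible with geometry")
        v = max(rng.normal(config.v_mean, config.v_sd), 0.2 * config.v_mean)
        v_zone = v * factors
        f_nom = v_zone / np.array([z.L_p for z in geo.zones])
        scale = (f_nom / f_nom[0]) ** config.modulus_exponent
        Gp = rng.lognormal(np.log(config.gp_median), config.gp_sigma_log) * scale
        Gpp = rng.lognormal(np.log(config.gpp_median), config.gpp_sigma_log) * scale
        sigma_p = max(rng.normal(config.sigma_p_mean, config.sigma_p_sd), 1.0)
        # keep the stress strictly positive over the whole oscillation
        eps0 = max(z.a for z in geo.zones) / D
        amp = eps0 * np.hypot(Gp, Gpp).max()
        if amp >= sigma_p:
            sigma_p = amp * 1.2
        arrival = config.lead_in_s + spacing * (
            i + config.arrival_jitter * (rng.uniform() - 0.5)
        )
        cells.append(
            SimCell(
                cell_id=i,
                D_cell=float(D),
                Gp_true=Gp,
                Gpp_true=Gpp,
                sigma_p_true=float(sigma_p),
                v_zone=v_zone,
                arrival_time=float(arrival),
            )
        )
    cells.sort(key=lambda c: c.arrival_time)
    for i, c in enumerate(cells):
        c.cell_id = i
    return cells


def _cell_schedule(cell: SimCell, geo: DeviceGeometry) -> dict:
    """Pulse windows (s) for one cell: pore then each zone, nodes in between."""
    v0 = float(cell.v_zone[0])
    pore_start = cell.arrival_time
    pore_end = pore_start + geo.pore.L_pore / v0
    windows = {"pore": (pore_start, pore_end)}
    t = pore_end
    for j, zone in enumerate(geo.zones):
        vj = float(cell.v_zone[j])
        t += geo.node_length / vj
        windows[f"zone{j + 1}"] = (t, t + zone.L_zone / vj)
        t += zone.L_zone / vj
    return windows


def generate_trace(config: SimConfig) -> tuple[RawTrace, pd.DataFrame]:
    """Simulate a population transit and return ``(trace, truth_table)``.

    The truth table has one row per cell with its generated parameters,
    per-zone true frequencies/strain amplitudes/moduli, every pulse window,
    and a ``coincident`` flag for cells whose device occupancy overlaps a
    neighbour's.  Identical config (including seed) gives byte-identical
    output.
    """
    geo = config.geometry
    rng = np.random.default_rng(config.seed)
    cells = _draw_population(config, rng)
    schedules = [_cell_schedule(c, geo) for c in cells]

    t_end = max(s[f"zone{geo.n_zones}"][1] for s in schedules) + config.lead_in_s
    n = int(np.ceil(t_end * geo.sample_rate))
    t = np.arange(n) / geo.sample_rate
    R0 = config.base_resistance
    names = geo.channel_names
    channels = {name: np.full(n, R0) for name in names}

    truth_rows = []
    for cell, sched in zip(cells, schedules):
        row: dict = {
            "cell_id": cell.cell_id,
            "D_cell_um": cell.D_cell,
            "sigma_p_Pa": cell.sigma_p_true,
            "arrival_time_s": cell.arrival_time,
            "pore_t_start": sched["pore"][0],
            "pore_t_end": sched["pore"][1],
        }
        # pore: top-hat of height forward_blockage * R_base
        s, e = sched["pore"]
        i0, i1 = np.searchsorted(t, [s, e])
        channels[names[0]][i0:i1] += forward_blockage(cell.D_cell, geo.pore.D_eff, geo.pore.L_pore) * R0
        unstrained_any = False
        for j, zone in enumerate(geo.zones):
            s, e = sched[f"zone{j + 1}"]
            i0, i1 = np.searchsorted(t, [s, e])
            tp = t[i0:i1] - s
            vj = float(cell.v_zone[j])
            row[f"zone{j + 1}_t_start"] = s
            row[f"zone{j + 1}_t_end"] = e
            row[f"zone{j + 1}_v_um_s"] = vj
            row[f"zone{j + 1}_f_Hz"] = vj / zone.L_p
            try:
                wave = strain_wave(zone, cell.D_cell, vj)
            except Exception:
                # unstrained cell: plain volume blockage, no oscillation
                unstrained_any = True
                blk = forward_blockage(cell.D_cell, geo.zone_D_eff[j], zone.L_zone)
                channels[names[j + 1]][i0:i1] += blk * R0
                row[f"zone{j + 1}_eps0"] = 0.0
                row[f"zone{j + 1}_Gp_Pa"] = np.nan
                row[f"zone{j + 1}_Gpp_Pa"] = np.nan
                continue
            x = vj * tp
            w = contraction_width(zone, np.clip(x, 0, zone.L_zone))
            D_d = deformed_diameter(cell.D_cell, w)
            sigma = synth_stress(wave, cell.sigma_p_true, cell.Gp_true[j], cell.Gpp_true[j], tp)
            dR = stress_to_blockage(sigma, w, D_d, geo.mu_f, geo.applied_pressure, R0)
            channels[names[j + 1]][i0:i1] += dR
            row[f"zone{j + 1}_eps0"] = wave.eps0
            row[f"zone{j + 1}_Gp_Pa"] = cell.Gp_true[j]
            row[f"zone{j + 1}_Gpp_Pa"] = cell.Gpp_true[j]
        row["unstrained"] = unstrained_any
        truth_rows.append(row)

    # coincidence: device-occupancy overlap between neighbours
    spans = [(s["pore"][0], s[f"zone{geo.n_zones}"][1]) for s in schedules]
    for i, row in enumerate(truth_rows):
        coinc = any(
            spans[i][0] < spans[j][1] and spans[j][0] < spans[i][1]
            for j in range(len(spans))
            if j != i
        )
        row["coincident"] = coinc

    # drift and noise (drawn after the deterministic signal, per channel)
    for k, name in enumerate(names):
        if config.baseline_drift_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            channels[name] += (
                config.baseline_drift_amp
                * R0
                * np.sin(2 * np.pi * t / config.baseline_drift_period_s + phase)
            )
        if config.noise_sd > 0:
            channels[name] += rng.normal(0.0, config.noise_sd * R0, size=n)

    trace = RawTrace(
        t=t,
        channels=channels,
        sample_rate=geo.sample_rate,
        metadata={
            "device_id": "simulated",
            "applied_pressure_Pa": geo.applied_pressure,
            "seed": config.seed,
            "units": "ohm",
        },
    )
    truth = pd.DataFrame(truth_rows)
    return trace, truth
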