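"""Device geometry and the physical relations shared by the simulator and the pipeline.

A multi-zone node-pore device consists of a Coulter sizing pore followed by a
series of sinusoidal contraction zones separated by wide relaxation nodes.  A
zone's width varies with position as ``w(x) = w0 + a*cos(2*pi*x / L_p)``, so a
cell moving at constant velocity ``v`` experiences an oscillatory compressive
strain at frequency ``f = v / L_p``.  This module holds:

* the geometry containers (:class:`ZoneSpec`, :class:`PoreSpec`,
  :class:`DeviceGeometry`),
* the strain waveform seen by a transiting cell (:class:`StrainWave`),
* the Coulter sizing relation between a cell's free diameter and its relative
  resistance blockage, with the standard ``0.8*(D/D_eff)**3`` non-linearity
  correction, in both directions,
* the volume-conserving deformed (wall-contact) diameter of a squeezed cell.

All lengths are micrometres, times seconds, frequencies Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigError, GeometryError, SaturationError, UnstrainedCellError

__all__ = [
    "ZoneSpec",
    "PoreSpec",
    "DeviceGeometry",
    "StrainWave",
    "contraction_width",
    "strain_wave",
    "applied_frequency",
    "deformed_diameter",
    "coulter_diameter",
    "forward_blockage",
    "fit_effective_diameter",
]


@dataclass(frozen=True)
class ZoneSpec:
    """One sinusoidal contraction zone.

    Parameters
    ----------
    index
        Ordinal position of the zone (0-based, in flow order).
    L_zone
        Total zone length, µm.
    L_p
        Period length of the width oscillation, µm.  Sets the strain
        frequency ``f = v / L_p`` for a cell moving at velocity ``v``.
    w0
        Mean contraction width, µm.
    a
        Width oscillation amplitude, µm; the wall oscillates between
        ``w0 - a`` and ``w0 + a``.
    w_node
        Width of the relaxation node downstream of the zone, µm.  Must be
        wide enough that cells fully relax between zones.
    """

    index: int
    L_zone: float
    L_p: float
    w0: float
    a: float
    w_node: float

    def __post_init__(self) -> None:
        if self.L_zone <= 0 or self.L_p <= 0:
            raise ConfigError("zone and period lengths must be positive")
        if not (0 < self.a < self.w0):
            raise ConfigError("width amplitude must satisfy 0 < a < w0")
        if self.L_zone / self.L_p < 1.0 - 1e-12:
            raise ConfigError("zone must contain at least one full strain period")
        if self.w_node <= self.w0 + self.a:
            raise ConfigError("node must be wider than the widest part of the zone")

    @property
    def n_periods(self) -> float:
        """Number of strain periods a cell experiences in this zone."""
        return self.L_zone / self.L_p


@dataclass(frozen=True)
class PoreSpec:
    """The Coulter sizing pore.

    ``D_eff`` is the empirical effective diameter mapping the rectangular
    channel to the equivalent cylindrical pore of the sizing equation; it is
    calibrated per device design and must exceed the largest expected cell.
    """

    L_pore: float
    D_eff: float

    def __post_init__(self) -> None:
        if self.L_pore <= 0 or self.D_eff <= 0:
            raise ConfigError("pore length and effective diameter must be positive")


@dataclass(frozen=True)
class DeviceGeometry:
    """Full device: sizing pore plus ordered contraction zones.

    Zone ordering matches the electrode/channel ordering of the recorded
    trace.  ``zone_D_eff`` carries per-zone effective-diameter calibration
    constants (distinct from the pore's ``D_eff`` because the geometries
    differ); the stress model itself derives the deformed diameter from
    volume conservation and does not consume them, but they are part of the
    device calibration record.  ``node_length`` is the pore-to-zone and
    zone-to-zone node length used for transit timing.  ``mu_f`` is the
    cell-wall friction coefficient of the stress model.
    """

    pore: PoreSpec
    zones: tuple[ZoneSpec, ...]
    zone_D_eff: tuple[float, ...] = ()
    sample_rate: float = 1.0e4
    applied_pressure: float = 13.8e3
    node_length: float = 500.0
    mu_f: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "zones", tuple(self.zones))
        if not self.zones:
            raise ConfigError("device needs at least one contraction zone")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.applied_pressure <= 0 or self.node_length <= 0 or self.mu_f <= 0:
            raise ConfigError("applied_pressure, node_length and mu_f must be positive")
        zde = tuple(self.zone_D_eff) or tuple(self.pore.D_eff for _ in self.zones)
        if len(zde) != len(self.zones):
            raise ConfigError("zone_D_eff must have one entry per zone")
        if any(d <= 0 for d in zde):
            raise ConfigError("zone_D_eff entries must be positive")
        object.__setattr__(self, "zone_D_eff", zde)
        for i, z in enumerate(self.zones):
            if z.index != i:
                raise ConfigError("zone indices must be 0..n-1 in channel order")

    @property
    def n_zones(self) -> int:
        return len(self.zones)

    @property
    def channel_names(self) -> tuple[str, ...]:
        """Trace channel names, in recording order: pore first, then zones."""
        return ("R_pore",) + tuple(f"R_{i + 1}" for i in range(self.n_zones))


@dataclass(frozen=True)
class StrainWave:
    """Oscillatory strain experienced by one cell in one zone.

    The strain is ``eps(t) = eps_mean + eps0 * cos(omega*t + phase0)`` with
    ``t`` measured from zone entry.  Because a zone is entered at its widest
    point (``w(0) = w0 + a``), the strain there is minimal, i.e.
    ``phase0 = pi``.
    """

    eps_mean: float
    eps0: float
    f: float
    omega: float
    phase0: float = np.pi

    def __post_init__(self) -> None:
        if not (0 <= self.eps_mean < 1):
            raise ConfigError("mean strain must lie in [0, 1)")
        if self.eps0 < 0 or (self.eps0 > 0 and self.eps0 >= self.eps_mean):
            raise ConfigError(
                "strain amplitude must satisfy 0 <= eps0 < eps_mean "
                "(cell must stay in wall contact)"
            )
        if abs(self.omega - 2 * np.pi * self.f) > 1e-9 * max(1.0, self.omega):
            raise ConfigError("omega must equal 2*pi*f")

    def phase(self, t):
        """Strain phase at time ``t`` after zone entry."""
        return self.omega * np.asarray(t, dtype=float) + self.phase0


def contraction_width(zone: ZoneSpec, x):
    """Channel width at position ``x`` (µm from zone entry) inside a zone.

    ``w(x) = w0 + a*cos(2*pi*x/L_p)``; the zone is entered at its widest
    point, ``w(0) = w0 + a``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-9) or np.any(x > zone.L_zone + 1e-9):
        raise GeometryError("position outside zone")
    w = zone.w0 + zone.a * np.cos(2 * np.pi * x / zone.L_p)
    return w if w.ndim else float(w)


def applied_frequency(v: float, L_p: float) -> float:
    """Strain frequency ``f = v / L_p`` (Hz) for velocity v (µm/s)."""
    if v <= 0 or L_p <= 0:
        raise ConfigError("velocity and period length must be positive")
    return v / L_p


def strain_wave(zone: ZoneSpec, D_cell: float, v: float) -> StrainWave:
    """Strain waveform for a cell of free diameter ``D_cell`` at velocity ``v``.

    Raises
    ------
    UnstrainedCellError
        If ``D_cell <= w0 + a`` the cell loses wall contact at the widest
        point and the oscillatory-strain model does not apply; callers flag
        such cells and exclude them from rheology.
    """
    if v <= 0:
        raise ConfigError("velocity must be positive")
    if D_cell <= zone.w0 + zone.a:
        raise UnstrainedCellError(
            f"cell of diameter {D_cell:.2f} µm not strained everywhere in zone "
            f"(needs D > {zone.w0 + zone.a:.2f} µm)"
        )
    f = applied_frequency(v, zone.L_p)
    return StrainWave(
        eps_mean=(D_cell - zone.w0) / D_cell,
        eps0=zone.a / D_cell,
        f=f,
        omega=2 * np.pi * f,
    )


def deformed_diameter(D_cell, w):
    """Wall-contact diameter of a cell squeezed to width ``w``.

    Volume conservation of a sphere flattened into a disk of height ``w``
    with a rounded rim gives ``D_d = sqrt(2*D_cell**3 / (3*w))``.  The
    relation is the identity at ``w = 2*D_cell/3`` and exceeds ``D_cell``
    for narrower gaps.  Where ``w > D_cell`` the cell is not deformed and
    ``D_cell`` is returned unchanged.
    """
    D_cell = np.asarray(D_cell, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise GeometryError("width must be positive")
    dd = np.sqrt(2.0 * D_cell**3 / (3.0 * w))
    out = np.where(w > D_cell, D_cell, dd)
    return out if out.ndim else float(out)


def forward_blockage(D_cell, D_eff: float, L: float):
    """Relative resistance blockage ``dR/R`` of a cell in a pore.

    Volume-ratio sizing with the standard shape-factor correction::

        dR/R = (D**3 / (D_eff**2 * L)) * 1 / (1 - 0.8*(D/D_eff)**3)

    which reduces to plain volume proportionality for ``D << D_eff``.
    """
    D = np.asarray(D_cell, dtype=float)
    if D_eff <= 0 or L <= 0:
        raise ConfigError("D_eff and L must be positive")
    if np.any(D < 0):
        raise GeometryError("diameter must be non-negative")
    if np.any(D >= D_eff):
        raise GeometryError("cell diameter must be smaller than D_eff")
    denom = L * (D_eff**2 - 0.8 * D**3 / D_eff)
    if np.any(denom <= 0):  # cannot occur for D < D_eff, guarded anyway
        raise SaturationError("blockage correction out of validity range")
    out = D**3 / denom
    return out if out.ndim else float(out)


def coulter_diameter(dR_over_R, D_eff: float, L: float):
    """Free cell diameter from relative blockage ``dR/R`` (inverse sizing).

    Exact algebraic inverse of :func:`forward_blockage`::

        D = (dR/R * L * D_eff**2 / (1 + 0.8 * dR/R * L / D_eff)) ** (1/3)

    Returns 0 for zero blockage and is strictly increasing in ``dR/R``.
    """
    h = np.asarray(dR_over_R, dtype=float)
    if D_eff <= 0 or L <= 0:
        raise ConfigError("D_eff and L must be positive")
    if np.any(h < 0):
        raise SaturationError("negative blockage is unphysical")
    D = (h * L * D_eff**2 / (1.0 + 0.8 * h * L / D_eff)) ** (1.0 / 3.0)
    return D if D.ndim else float(D)


def fit_effective_diameter(
    diameters: Sequence[float],
    blockages: Sequence[float],
    L: float,
    D_eff0: float | None = None,
) -> float:
    """Calibrate ``D_eff`` from (reference diameter, observed dR/R) pairs.

    Least-squares fit of the forward sizing relation, mirroring the wet-lab
    calibration of a device against a reference particle counter.
    """
    D = np.asarray(diameters, dtype=float)
    h = np.asarray(blockages, dtype=float)
    if D.shape != h.shape or D.size < 1:
        raise ConfigError("need matching, non-empty diameter/blockage arrays")
    if D_eff0 is None:
        # small-blockage guess: h ~ D^3/(D_eff^2 L)
        D_eff0 = float(np.sqrt(np.median(D**3 / (h * L))))
    lo = float(D.max()) * (1 + 1e-6)

    def resid(p):
        return forward_blockage(D, float(p[0]), L) - h

    sol = least_squares(resid, x0=[max(D_eff0, lo * 1.01)], bounds=([lo], [np.inf]))
    return float(sol.x[0])
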