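"""Uptake and production fluxes from cell growth and medium concentrations.

Cultured cells deplete medium glucose and accumulate lactate while growing
exponentially.  The per-cell consumption rate therefore has to account for the
changing cell number: integrating dC/dt = -v * n0 * exp(k t) over the
incubation gives

    v = dC * ln(nt/n0) / ((nt - n0) * t)        [umol / 10^6 cells / min]

which is converted to an intracellular concentration change (mM/min) by
dividing by the aqueous volume of 10^6 cells (0.05 mL by default), so that
uptake fluxes are directly comparable with intracellular fluxes of the
kinetic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GrowthMeasurement",
    "growth_rate",
    "consumption_rate",
    "normalize_to_cell_volume",
    "uptake_flux",
]

#: aqueous volume of 10^6 cells, mL
DEFAULT_CELL_VOLUME_ML = 0.05


@dataclass(frozen=True)
class GrowthMeasurement:
    """One growth/medium measurement over an incubation.

    Cell counts are in 10^6 cells per mL of medium, concentrations in mM
    (equivalently umol per mL of medium), time in minutes.
    """

    n0: float
    nt: float
    t: float
    c_start: float
    c_end: float
    volume_per_1e6_cells: float = DEFAULT_CELL_VOLUME_ML

    def __post_init__(self) -> None:
        if self.n0 <= 0 or self.nt <= 0:
            raise ValueError("cell counts must be positive")
        if self.t <= 0:
            raise ValueError("incubation time must be positive")
        if self.volume_per_1e6_cells <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def delta_c(self) -> float:
        """Magnitude of the medium concentration change, umol/mL."""
        return abs(self.c_start - self.c_end)


def growth_rate(n0: float, nt: float, t: float) -> float:
    """Exponential growth rate k (1/min) from cell counts n0 -> nt over t minutes."""
    if n0 <= 0 or nt <= 0:
        raise ValueError("cell counts must be positive")
    if t <= 0:
        raise ValueError("time must be positive")
    return math.log(nt / n0) / t


def consumption_rate(delta_c: float, n0: float, nt: float, t: float) -> float:
    """Metabolite consumption (or production) rate per 10^6 cells.

    Parameters
    ----------
    delta_c:
        Medium concentration change over the incubation, umol/mL.
    n0, nt:
        Cell density at start/end, 10^6 cells/mL.
    t:
        Incubation time, min.

    Returns
    -------
    float
        Rate in umol / 10^6 cells / min.  The nt -> n0 limit (no growth)
        reduces to delta_c / (n0 * t).
    """
    if n0 <= 0 or nt <= 0:
        raise ValueError("cell counts must be positive")
    if t <= 0:
        raise ValueError("time must be positive")
    if nt == n0:
        return delta_c / (n0 * t)
    return delta_c * math.log(nt / n0) / ((nt - n0) * t)


def normalize_to_cell_volume(v: float, volume: float = DEFAULT_CELL_VOLUME_ML) -> float:
    """Convert umol/10^6 cells/min to mM/min of intracellular volume."""
    if volume <= 0:
        raise ValueError("cell volume must be positive")
    return v / volume


def uptake_flux(measurement: GrowthMeasurement) -> float:
    """End-to-end uptake flux in mM/min for one measurement."""
    v = consumption_rate(
        measurement.delta_c, measurement.n0, measurement.nt, measurement.t
    )
    return normalize_to_cell_volume(v, measurement.volume_per_1e6_cells)
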