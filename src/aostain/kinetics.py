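"""First-order decay kinetics for the azo initiator AAPH.

AAPH decomposes thermally by first-order kinetics, each decomposition
nominally releasing two carbon-centered radicals (which add oxygen to give
peroxyl radicals in air).  The half-life is obtained from a log-linear fit
of absorbance vs time — absorbance is taken proportional to concentration
(Beer–Lambert, linear range), so the proportionality constant cancels in
the fit.  The cumulative radical yield over an exposure of duration t is

    yield = n_rad * c0 * V * (1 - 2**(-t / t_half))   [mol]

with n_rad the radicals released per decomposition (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, NotDecayingError, ParameterError

__all__ = ["DecaySeries", "fit_half_life", "radical_yield"]


@dataclass
class DecaySeries:
    """Absorbance time series: times in h (strictly increasing), absorbance in AU."""

    times: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise DataError("times and absorbance must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if np.any(self.absorbance < 0):
            raise DataError("absorbance must be non-negative")

    def __len__(self) -> int:
        return self.times.size


def fit_half_life(series: DecaySeries) -> float:
    """Half-life (h) from a least-squares fit of ln(absorbance) vs time.

    Raises
    ------
    DataError
        Fewer than 3 points, or non-positive absorbance (log undefined).
    NotDecayingError
        If the fitted slope is not negative.
    """
    if len(series) < 3:
        raise DataError(f"need at least 3 points, got {len(series)}")
    if np.any(series.absorbance <= 0):
        raise DataError("absorbance must be strictly positive for a log-linear fit")
    slope, _ = np.polyfit(series.times, np.log(series.absorbance), 1)
    if slope >= 0:
        raise NotDecayingError(f"fitted slope {slope:.3g} is not negative")
    return float(np.log(2.0) / -slope)


def radical_yield(c0: float, volume: float, t: float, half_life: float,
                  radicals_per_decomposition: float = 2.0) -> float:
    """Cumulative radicals generated (mol) after time t of first-order decay.

    Parameters
    ----------
    c0 : float
        Initial initiator concentration, mol/L.
    volume : float
        Solution volume, L.
    t : float
        Exposure duration, h (same unit as half_life).
    half_life : float
        First-order half-life, h.
    radicals_per_decomposition : float
        Radicals released per decomposed molecule (2 for azo initiators).
    """
    if half_life <= 0:
        raise ParameterError(f"half_life must be positive, got {half_life}")
    if c0 < 0 or volume < 0 or t < 0 or radicals_per_decomposition <= 0:
        raise ParameterError("c0, volume, t must be >= 0 and radicals_per_decomposition > 0")
    return radicals_per_decomposition * c0 * volume * (1.0 - 2.0 ** (-t / half_life))
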