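"""Conductometric titration analysis (Scallan-style three-segment fit).

Titrating an acidic substrate suspension with dilute NaOH while logging
conductivity yields three linear regimes: a falling branch while mobile
protons of strong acid groups are replaced by sodium, a near-flat plateau
while weak (carboxyl) groups are neutralized, and a steeply rising branch
once excess base accumulates.  The weak-acid (carboxyl) content follows
from the titrant volume spanned by the plateau:

    acid content (umol/g) = (V2 - V1) * c_titrant / m_sample

where V1 and V2 are the intersections of the fitted neighbouring lines.

The fit places the two segment boundaries on a grid of inter-point
positions (each segment keeps >= 4 points), fits each segment by ordinary
least squares, and picks the split minimizing the total squared residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, FitDegeneracyError, ParameterError

__all__ = ["TitrationCurve", "AcidContentResult", "analyze_conductometric",
           "read_curve_csv"]

MIN_SEGMENT_POINTS = 4


@dataclass
class TitrationCurve:
    """Conductivity vs added-base record.

    added_volume in L (strictly increasing), conductivity in uS/cm,
    titrant_conc in mol/L, sample_mass in g (dry).
    """

    added_volume: np.ndarray
    conductivity: np.ndarray
    titrant_conc: float
    sample_mass: float

    def __post_init__(self) -> None:
        self.added_volume = np.asarray(self.added_volume, dtype=float)
        self.conductivity = np.asarray(self.conductivity, dtype=float)
        if self.added_volume.shape != self.conductivity.shape:
            raise DataError("volume and conductivity lists must have equal length")
        if np.any(np.diff(self.added_volume) <= 0):
            raise DataError("added_volume must be strictly increasing")
        if self.sample_mass <= 0:
            raise ParameterError(f"sample_mass must be > 0, got {self.sample_mass}")
        if self.titrant_conc <= 0:
            raise ParameterError(f"titrant_conc must be > 0, got {self.titrant_conc}")

    def __len__(self) -> int:
        return self.added_volume.size


@dataclass(frozen=True)
class AcidContentResult:
    """Result of the three-segment analysis.

    acid_content is the weak-acid (carboxyl) content in umol/g;
    breakpoints are the two line-intersection volumes (L); slopes are in
    uS/cm per L; fit_residual is the rms residual of the piecewise fit.
    """

    acid_content: float
    breakpoints: tuple[float, float]
    segment_slopes: tuple[float, float, float]
    segment_intercepts: tuple[float, float, float]
    split_indices: tuple[int, int]
    fit_residual: float


def _prefix_sums(x: np.ndarray, y: np.ndarray):
    z = np.zeros(1)
    return (np.concatenate([z, np.cumsum(x)]),
            np.concatenate([z, np.cumsum(y)]),
            np.concatenate([z, np.cumsum(x * x)]),
            np.concatenate([z, np.cumsum(x * y)]),
            np.concatenate([z, np.cumsum(y * y)]))


def _segment_stats(sums, i, j):
    """OLS slope/intercept/SSR for points i..j-1, O(1) via prefix sums.

    ``i`` and ``j`` may be integers or integer arrays (broadcast).
    """
    sx, sy, sxx, sxy, syy = sums
    n = np.asarray(j) - np.asarray(i)
    Sx = sx[j] - sx[i]
    Sy = sy[j] - sy[i]
    Sxx = sxx[j] - sxx[i] - Sx * Sx / n
    Sxy = sxy[j] - sxy[i] - Sx * Sy / n
    Syy = syy[j] - syy[i] - Sy * Sy / n
    slope = Sxy / Sxx
    intercept = (Sy - slope * Sx) / n
    ssr = np.maximum(Syy - slope * Sxy, 0.0)
    return slope, intercept, ssr


def _intersection(line_a, line_b, fallback: float,
                  slope_scale: float) -> float:
    """Volume where two fitted lines cross.

    Nearly parallel (or coincident) neighbouring lines mean the segment
    between them is degenerate; the fallback volume (the data boundary
    between the segments) is used instead.
    """
    (sa, ia), (sb, ib) = line_a, line_b
    if abs(sa - sb) <= 1e-9 * max(slope_scale, 1.0):
        return fallback
    return (ib - ia) / (sa - sb)


def analyze_conductometric(curve: TitrationCurve) -> AcidContentResult:
    """Fit the three-segment conductometric model and report carboxyl content.

    Requires at least 12 points (>= 4 per segment).  The two segment
    boundaries are chosen by exhaustive search over inter-point positions
    to minimize the total squared residual of the three per-segment OLS
    fits.  V1 and V2 are the intersections of neighbouring fitted lines;
    when neighbouring lines are indistinguishable (a vanishing plateau),
    the corresponding breakpoints collapse and the content is zero.
    """
    n = len(curve)
    if n < 3 * MIN_SEGMENT_POINTS:
        raise DataError(
            f"need at least {3 * MIN_SEGMENT_POINTS} points spanning all three "
            f"regimes, got {n}"
        )
    x = curve.added_volume
    y = curve.conductivity
    sums = _prefix_sums(x, y)

    best = None
    for i in range(MIN_SEGMENT_POINTS, n - 2 * MIN_SEGMENT_POINTS + 1):
        _, _, ssr1 = _segment_stats(sums, 0, i)
        js = np.arange(i + MIN_SEGMENT_POINTS, n - MIN_SEGMENT_POINTS + 1)
        _, _, ssr2 = _segment_stats(sums, i, js)
        _, _, ssr3 = _segment_stats(sums, js, n)
        totals = ssr1 + ssr2 + ssr3
        k = int(np.argmin(totals))
        if best is None or totals[k] < best[0]:
            best = (float(totals[k]), i, int(js[k]))
    if best is None:  # unreachable given the length check; guard anyway
        raise FitDegeneracyError("no admissible three-segment split")
    total, i, j = best
    s1 = _segment_stats(sums, 0, i)
    s2 = _segment_stats(sums, i, j)
    s3 = _segment_stats(sums, j, n)

    slopes = (s1[0], s2[0], s3[0])
    intercepts = (s1[1], s2[1], s3[1])
    slope_scale = max(abs(s) for s in slopes)

    # Boundary volumes between segments serve as fallbacks for parallel lines.
    fb1 = 0.5 * (x[i - 1] + x[i])
    fb2 = 0.5 * (x[j - 1] + x[j])
    v1 = _intersection((slopes[0], intercepts[0]), (slopes[1], intercepts[1]),
                       fb1, slope_scale)
    v2 = _intersection((slopes[1], intercepts[1]), (slopes[2], intercepts[2]),
                       fb2, slope_scale)
    # A middle segment collinear with a neighbour means the plateau is absent:
    # both breakpoints collapse onto the single real kink.
    if _collinear(slopes[0], intercepts[0], slopes[1], intercepts[1], x, y):
        v1 = v2
    elif _collinear(slopes[1], intercepts[1], slopes[2], intercepts[2], x, y):
        v2 = v1
    if v2 < v1:
        v1 = v2 = 0.5 * (v1 + v2)

    content = (v2 - v1) * curve.titrant_conc / curve.sample_mass * 1e6
    return AcidContentResult(
        acid_content=max(content, 0.0),
        breakpoints=(float(v1), float(v2)),
        segment_slopes=tuple(float(s) for s in slopes),
        segment_intercepts=tuple(float(b) for b in intercepts),
        split_indices=(i, j),
        fit_residual=float(np.sqrt(total / n)),
    )


def _collinear(sa, ia, sb, ib, x, y) -> bool:
    """Are two fitted lines indistinguishable at the scale of the data?"""
    yscale = max(np.ptp(y), 1e-12)
    span = x[-1] - x[0]
    dy0 = abs(ia - ib)
    dy1 = abs((ia + sa * span) - (ib + sb * span))
    return max(dy0, dy1) < 1e-6 * yscale


def read_curve_csv(path: str | Path, titrant_conc: float,
                   sample_mass: float) -> TitrationCurve:
    """Read a curve from CSV with columns volume_mL, conductivity_uS_cm."""
    df = pd.read_csv(path)
    return TitrationCurve(
        added_volume=df["volume_mL"].to_numpy(float) * 1e-3,
        conductivity=df["conductivity_uS_cm"].to_numpy(float),
        titrant_conc=titrant_conc,
        sample_mass=sample_mass,
    )
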