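"""Masked red/green ratiometrics for AO-stained micrographs.

The oxidation readout is the pixel-wise ratio of dark-subtracted red to
green counts over cell-wall pixels.  A threshold mask on the green channel
removes lumina (buffer) and other non-wall structures; within the mask the
red/green ratio is computed pixel by pixel, per-image mean ratios are the
replicate observations, and image sets are summarized by an arithmetic
mean with a Student-t 95% confidence interval.  Channel brightness is
summarized by the mode of the integer-binned intensity histogram.

Higher ratios indicate more oxidation: mild oxidation suppresses the
green (monomer) emission while leaving the red (dimer) emission largely
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .exceptions import (
    DimensionError,
    EmptyMaskError,
    ParameterError,
    SampleSizeError,
)

__all__ = [
    "Mask",
    "MaskedRatios",
    "RatioSummary",
    "build_mask",
    "otsu_threshold",
    "ratio_map",
    "channel_mode",
    "percent_decrease",
    "autofluorescence_fraction",
    "electron_equivalents",
    "summarize_set",
]

# Pooled ratio histogram: fixed bins of width 0.01 on [0, 5]; out-of-range
# high values accumulate in the last bin.
RATIO_HIST_EDGES = np.round(np.arange(0.0, 5.0 + 0.01, 0.01), 10)


@dataclass(frozen=True)
class Mask:
    """Boolean pixel mask produced by green-channel thresholding."""

    values: np.ndarray
    threshold_used: float
    coverage_fraction: float

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class MaskedRatios:
    """Per-image ratio result: masked ratio values plus the channel pixels
    they came from, and the count of green-zero pixels dropped."""

    ratios: np.ndarray          # 1-D, masked pixels only
    red_values: np.ndarray      # 1-D, same pixels
    green_values: np.ndarray    # 1-D, same pixels
    mask: Mask                  # effective mask after green-zero exclusion
    n_green_zero_dropped: int


@dataclass(frozen=True)
class RatioSummary:
    """Set-level summary: mean of per-image mean ratios, t-based 95% CI,
    pooled ratio histogram and pooled channel modes."""

    mean_ratio: float
    ci95_halfwidth: float
    n_images: int
    per_image_means: np.ndarray
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    red_mode: int | None
    green_mode: int | None


def build_mask(green: np.ndarray, threshold: float) -> Mask:
    """Mask of pixels whose (dark-subtracted) green value is >= threshold.

    The threshold is a per-image-set analyst choice separating cell-wall
    green levels from lumina/background; see ``otsu_threshold`` for an
    optional automatic suggestion (never applied implicitly).
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    values = np.asarray(green, dtype=float) >= threshold
    return Mask(values=values, threshold_used=float(threshold),
                coverage_fraction=float(values.mean()) if values.size else 0.0)


def otsu_threshold(green: np.ndarray) -> float:
    """Otsu's threshold on the green channel — a suggestion helper only."""
    return float(threshold_otsu(np.asarray(green, dtype=float)))


def ratio_map(red: np.ndarray, green: np.ndarray, mask: Mask) -> MaskedRatios:
    """Pixel-wise red/green ratio over the masked region.

    Pixels where green is exactly zero after dark subtraction are dropped
    from the mask (rather than mapped to infinity) and counted in
    ``n_green_zero_dropped``.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape or red.shape != mask.values.shape:
        raise DimensionError(
            f"shape mismatch: red {red.shape}, green {green.shape}, "
            f"mask {mask.values.shape}"
        )
    effective = mask.values & (green > 0)
    n_dropped = int(mask.values.sum() - effective.sum())
    eff_mask = Mask(values=effective, threshold_used=mask.threshold_used,
                    coverage_fraction=float(effective.mean()) if effective.size else 0.0)
    return MaskedRatios(
        ratios=red[effective] / green[effective],
        red_values=red[effective],
        green_values=green[effective],
        mask=eff_mask,
        n_green_zero_dropped=n_dropped,
    )


def channel_mode(channel: np.ndarray, mask: Mask | None = None) -> int:
    """Mode of the integer-binned (width 1 count) intensity histogram.

    Computed over masked pixels when a mask is given.  Ties break to the
    lowest intensity bin.
    """
    values = np.asarray(channel, dtype=float)
    if mask is not None:
        values = values[mask.values]
    values = values.ravel()
    if values.size == 0:
        raise EmptyMaskError("cannot compute a mode over zero pixels")
    counts = np.bincount(np.rint(values).astype(np.int64))
    return int(np.argmax(counts))  # argmax returns the first (lowest) tied bin


def percent_decrease(control_value: float, treated_value: float) -> int:
    """Percent decrease from control to treated, to the nearest integer.

    ``100 * (control - treated) / control``; e.g. channel modes 75 -> 66
    give 12%.
    """
    if control_value <= 0:
        raise ParameterError(
            f"control_value must be positive, got {control_value}"
        )
    return int(round(100.0 * (control_value - treated_value) / control_value))


def autofluorescence_fraction(unstained_mean: float, stained_mean: float) -> float:
    """Unstained (autofluorescence) intensity as a percent of the stained one."""
    if stained_mean <= 0:
        raise ParameterError(f"stained_mean must be positive, got {stained_mean}")
    if unstained_mean < 0:
        raise ParameterError(f"unstained_mean must be >= 0, got {unstained_mean}")
    return 100.0 * unstained_mean / stained_mean


def electron_equivalents(dose_mmol_per_g: float,
                         electrons_per_mole: float = 5.0) -> float:
    """Oxidant dose expressed as electron equivalents, mmol e-/g.

    Complete reduction of chlorine dioxide to chloride transfers five
    electron equivalents per mole, so a chlorite dose of 1 mmol/g of dry
    wood corresponds to 5 mmol electrons/g — the scale against which the
    fungal oxidant flux is compared.
    """
    if dose_mmol_per_g < 0 or electrons_per_mole <= 0:
        raise ParameterError("dose must be >= 0 and electrons_per_mole > 0")
    return dose_mmol_per_g * electrons_per_mole


def _pooled_mode(arrays: Sequence[np.ndarray]) -> int | None:
    pooled = np.concatenate([np.asarray(a, dtype=float).ravel() for a in arrays])
    if pooled.size == 0:
        return None
    counts = np.bincount(np.rint(pooled).astype(np.int64))
    return int(np.argmax(counts))


def summarize_set(images: Sequence[MaskedRatios]) -> RatioSummary:
    """Summarize a set of masked ratio images.

    The replication unit is the image: per-image mean ratios are the
    observations, and the 95% CI half-width is ``t(0.975, n-1) * s / sqrt(n)``
    with ``n`` the number of images.  Pixels are spatially correlated
    within an image, so pixel-level CIs would be spuriously narrow.  The
    pooled pixel histogram and pooled channel modes are attached for
    inspection.
    """
    if len(images) < 2:
        raise SampleSizeError(
            f"need at least 2 images for a set summary, got {len(images)}"
        )
    for img in images:
        if img.ratios.size == 0:
            raise EmptyMaskError("an image in the set retains no masked pixels")
    means = np.array([float(img.ratios.mean()) for img in images])
    n = len(means)
    sd = float(means.std(ddof=1))
    halfwidth = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))

    pooled = np.concatenate([img.ratios for img in images])
    clipped = np.minimum(pooled, RATIO_HIST_EDGES[-1] - 1e-9)
    hist_counts, _ = np.histogram(clipped, bins=RATIO_HIST_EDGES)

    return RatioSummary(
        mean_ratio=float(means.mean()),
        ci95_halfwidth=halfwidth,
        n_images=n,
        per_image_means=means,
        hist_edges=RATIO_HIST_EDGES.copy(),
        hist_counts=hist_counts,
        red_mode=_pooled_mode([img.red_values for img in images]),
        green_mode=_pooled_mode([img.green_values for img in images]),
    )
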