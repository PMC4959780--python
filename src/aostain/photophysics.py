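"""Acridine orange monomer/dimer photophysics.

Acridine orange (AO) is metachromatic: isolated (monomeric) adsorbed
molecules emit green, while stacked dimers emit red.  In aqueous solution
the dye self-associates,

    2 M  <=>  D,      K = [D] / [M]^2   (L/mol),

so the partition of molecules between the two emitting species — and hence
the red/green balance of a stained specimen — is governed by the
association constant and the total dye concentration.  This module solves
that equilibrium in closed form and provides the linear spectral
channel-mixing model that maps monomer/dimer emitter densities onto the
red, green and blue counts of a Bayer-sensor colour camera.  The mixing
model is the forward model used by :mod:`aostain.synthetic_data`.

Conventions
-----------
* ``c_total`` is the total dye concentration expressed in monomer
  equivalents, so mass balance reads ``m + 2 d = c_total``.
* ``fraction_dimer`` is the fraction of dye *molecules* residing in dimers,
  ``2 d / c_total`` — not the mole fraction of the dimer species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "EquilibriumState",
    "ChannelResponse",
    "dimer_equilibrium",
    "channel_intensities",
    "default_response",
    "densities_for_channel_targets",
]


@dataclass(frozen=True)
class EquilibriumState:
    """Solution of the dimerization equilibrium at one (K, c_total) point.

    Attributes
    ----------
    K : float
        Association constant, L/mol.
    c_total : float
        Total dye concentration in monomer equivalents, mol/L.
    monomer : float
        Equilibrium monomer concentration, mol/L.
    dimer : float
        Equilibrium dimer concentration, mol/L.
    fraction_dimer : float
        Fraction of dye molecules bound in dimers, ``2*dimer/c_total``
        (0 when ``c_total`` is 0).
    """

    K: float
    c_total: float
    monomer: float
    dimer: float
    fraction_dimer: float

    def as_dict(self) -> dict:
        return {
            "K_L_per_mol": self.K,
            "c_total_mol_per_L": self.c_total,
            "monomer_mol_per_L": self.monomer,
            "dimer_mol_per_L": self.dimer,
            "fraction_dimer": self.fraction_dimer,
        }


def dimer_equilibrium(K: float, c_total: float) -> EquilibriumState:
    """Solve the 2M <=> D association equilibrium.

    Substituting the law of mass action ``d = K m**2`` into the mass
    balance ``m + 2 d = c_total`` gives the quadratic

        2 K m**2 + m - c_total = 0,

    whose positive root is taken in the cancellation-free form
    ``m = 2 c / (1 + sqrt(1 + 8 K c))``.

    Parameters
    ----------
    K : float
        Association constant, L/mol.  ``K = 0`` means no association.
    c_total : float
        Total dye in monomer equivalents, mol/L.

    Returns
    -------
    EquilibriumState

    Raises
    ------
    ParameterError
        If ``K`` or ``c_total`` is negative.

    Examples
    --------
    At K = 5000 L/mol and 1000 umol/L total dye, roughly three quarters of
    the molecules are associated:

    >>> st = dimer_equilibrium(5000.0, 1e-3)
    >>> round(st.fraction_dimer, 2)
    0.73
    """
    if K < 0 or c_total < 0:
        raise ParameterError(
            f"K and c_total must be non-negative, got K={K}, c_total={c_total}"
        )
    if K == 0.0 or c_total == 0.0:
        return EquilibriumState(K=K, c_total=c_total, monomer=c_total,
                                dimer=0.0, fraction_dimer=0.0)
    m = 2.0 * c_total / (1.0 + np.sqrt(1.0 + 8.0 * K * c_total))
    d = K * m * m
    return EquilibriumState(K=K, c_total=c_total, monomer=m, dimer=d,
                            fraction_dimer=2.0 * d / c_total)


def _gaussian(x: np.ndarray, center: float, sigma: float, amplitude: float = 1.0) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


@dataclass(frozen=True)
class ChannelResponse:
    """Spectral forward model: species emission spectra and camera QE curves.

    The 3x2 ``mixing_matrix`` (rows red/green/blue, columns monomer/dimer)
    holds the per-unit-density channel response, computed as the sum over
    the wavelength grid of emission spectrum times quantum efficiency.
    """

    wavelengths: np.ndarray
    monomer_spectrum: np.ndarray
    dimer_spectrum: np.ndarray
    qe_red: np.ndarray
    qe_green: np.ndarray
    qe_blue: np.ndarray
    mixing_matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("monomer_spectrum", "dimer_spectrum", "qe_red", "qe_green", "qe_blue"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != np.asarray(self.wavelengths).shape:
                raise ParameterError(f"{name} must share the wavelength grid shape")
            if np.any(arr < 0):
                raise ParameterError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)
        mix = np.empty((3, 2), dtype=float)
        for i, qe in enumerate((self.qe_red, self.qe_green, self.qe_blue)):
            mix[i, 0] = float(np.sum(self.monomer_spectrum * qe))
            mix[i, 1] = float(np.sum(self.dimer_spectrum * qe))
        object.__setattr__(self, "mixing_matrix", mix)


def default_response() -> ChannelResponse:
    """Synthetic, non-calibrated default spectral response.

    Gaussian stand-ins for the AO emission spectra (monomer peak 530 nm,
    dimer peak 640 nm, width 30 nm) and for the camera quantum-efficiency
    curves.  The published curves for this dye/camera pair exist only as
    graphics, so these defaults reproduce the qualitative structure — the
    green channel is dominated by monomer emission and the red channel by
    dimer emission, with enough spectral overlap that pixel ratios occupy a
    limited dynamic range — without claiming radiometric calibration.
    """
    wl = np.arange(400.0, 751.0, 1.0)
    return ChannelResponse(
        wavelengths=wl,
        monomer_spectrum=_gaussian(wl, 530.0, 30.0),
        dimer_spectrum=_gaussian(wl, 640.0, 30.0),
        qe_red=_gaussian(wl, 610.0, 45.0, 0.9),
        qe_green=_gaussian(wl, 540.0, 40.0, 0.8),
        qe_blue=_gaussian(wl, 470.0, 35.0, 0.7),
    )


def channel_intensities(monomer_density, dimer_density,
                        response: ChannelResponse | None = None):
    """Expected red/green/blue counts for given emitter densities.

    Linear mixing: ``counts_ch = M[ch, 0]*monomer + M[ch, 1]*dimer`` with
    ``M`` the response's mixing matrix.  Densities may be scalars or
    arrays (broadcast together).

    Returns
    -------
    (red, green, blue) : tuple of ndarray or float
        Expected counts per channel, same shape as the broadcast inputs.
    """
    if response is None:
        response = default_response()
    m = np.asarray(monomer_density, dtype=float)
    d = np.asarray(dimer_density, dtype=float)
    if np.any(m < 0) or np.any(d < 0):
        raise ParameterError("emitter densities must be non-negative")
    mix = response.mixing_matrix
    out = tuple(mix[i, 0] * m + mix[i, 1] * d for i in range(3))
    if np.isscalar(monomer_density) and np.isscalar(dimer_density):
        return tuple(float(v) for v in out)
    return out


def densities_for_channel_targets(red_counts: float, green_counts: float,
                                  response: ChannelResponse | None = None
                                  ) -> tuple[float, float]:
    """Invert the red/green rows of the mixing model.

    Solves the 2x2 linear system for the (monomer, dimer) densities that
    produce the requested expected red and green counts.  Used by the
    synthetic generator to plant exact region-wise red/green ratios.

    Raises
    ------
    ParameterError
        If the target is outside the cone spanned by the two species
        (a negative density would be required), or the system is singular.
    """
    if response is None:
        response = default_response()
    A = response.mixing_matrix[:2, :]  # rows red, green
    if abs(np.linalg.det(A)) < 1e-12 * np.abs(A).max() ** 2:
        raise ParameterError("mixing matrix red/green rows are singular")
    m, d = np.linalg.solve(A, np.array([red_counts, green_counts], dtype=float))
    if m < 0 or d < 0:
        raise ParameterError(
            f"targets (R={red_counts}, G={green_counts}) need negative densities "
            f"(m={m:.3g}, d={d:.3g}); ratio outside the feasible range"
        )
    return float(m), float(d)
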