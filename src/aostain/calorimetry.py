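"""ITC dilution-heat modelling for AO injections.

When a concentrated AO solution (hundreds of umol/L, substantially
dimerized) is injected into a dilute cell, dimers dissociate on dilution
and absorb heat.  This dilution signal is comparable to the binding heats
of interest and must be modelled and subtracted before the thermogram can
be interpreted.  The model here is first-principles: the dimerization
equilibrium (fixed K and ΔH) is solved in the syringe and in the cell
mixture after every injection, and the per-injection heat is ΔH times the
change in moles of dimer not accounted for by delivery.

Perfusion bookkeeping (overfilled cell): each injection of volume v
displaces an equal volume of the pre-injection cell mixture before
equilibration, so the cell volume V is constant and

    c_after = (c_before * (V - v) + c_syringe * v) / V.

Sign convention: positive heat = endothermic.  With exothermic dimer
formation (ΔH < 0), dissociation on dilution yields positive model heats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DimensionError, ParameterError
from .photophysics import dimer_equilibrium

__all__ = [
    "ITCExperiment",
    "ThermogramCorrection",
    "BindingSummary",
    "dilution_heat_model",
    "correct_thermogram",
    "strong_site_fraction",
    "absorbance_to_conc",
    "read_heats_csv",
    "write_corrected_csv",
]


def _default_schedule() -> tuple[float, ...]:
    # 28 injections of 10 uL — a typical VP-ITC style schedule.
    return tuple([10e-6] * 28)


@dataclass
class ITCExperiment:
    """Injection schedule, concentrations and dimer constants for one run.

    Units: volumes in L, concentrations in mol/L (AO as monomer
    equivalents), K in L/mol, ΔH in J per mol of dimer formed, heats in J.

    ``syringe_equilibrated`` selects whether the syringe contents are
    treated as an equilibrated monomer/dimer mixture at ``syringe_conc``
    (default) or as nominally all-monomer.
    """

    cell_volume: float = 1.4e-3
    syringe_conc: float = 800e-6
    injection_volumes: tuple[float, ...] = field(default_factory=_default_schedule)
    K_dimer: float = 3040.0
    dH_dimer: float = -44400.0
    measured_heats: tuple[float, ...] | None = None
    cell_analyte_conc: float = 50e-6
    cell_initial_dye_conc: float = 0.0
    syringe_equilibrated: bool = True

    def __post_init__(self) -> None:
        vols = np.asarray(self.injection_volumes, dtype=float)
        if vols.size == 0 or np.any(vols <= 0):
            raise ParameterError("injection volumes must all be positive")
        if vols.sum() >= self.cell_volume:
            raise ParameterError(
                "cumulative injected volume must stay below the cell volume"
            )
        if self.cell_volume <= 0 or self.syringe_conc < 0:
            raise ParameterError("cell_volume must be > 0 and syringe_conc >= 0")
        if self.K_dimer < 0:
            raise ParameterError("K_dimer must be >= 0")


@dataclass(frozen=True)
class ThermogramCorrection:
    """Measured, modelled and corrected per-injection heats (J)."""

    measured_heats: np.ndarray
    model_heats: np.ndarray
    corrected_heats: np.ndarray
    rms_residual: float


@dataclass(frozen=True)
class BindingSummary:
    """Strong-site accounting: dye adsorbed vs acid groups available."""

    adsorbed_amount: float   # mol dye
    acid_content: float      # mol acid groups
    strong_site_fraction: float  # percent


def dilution_heat_model(exp: ITCExperiment) -> np.ndarray:
    """Per-injection dilution (dimer-dissociation) heats, J.

    For injection i the heat is

        q_i = ΔH_dimer * (n_dimer_after - n_dimer_delivered - n_dimer_before)

    where "before" counts the dimers in the retained (V - v) of cell
    liquid, "delivered" the dimers in the injected syringe aliquot, and
    "after" the dimers once the mixed cell re-equilibrates.  With K = 0 no
    dimers exist anywhere and all heats are zero.
    """
    V = exp.cell_volume
    K = exp.K_dimer
    if exp.syringe_equilibrated:
        d_syr = dimer_equilibrium(K, exp.syringe_conc).dimer
    else:
        d_syr = 0.0

    heats = np.empty(len(exp.injection_volumes), dtype=float)
    c_cell = exp.cell_initial_dye_conc
    for i, v in enumerate(exp.injection_volumes):
        d_before_conc = dimer_equilibrium(K, c_cell).dimer
        n_before = d_before_conc * (V - v)
        n_delivered = d_syr * v
        c_after = (c_cell * (V - v) + exp.syringe_conc * v) / V
        n_after = dimer_equilibrium(K, c_after).dimer * V
        heats[i] = exp.dH_dimer * (n_after - n_delivered - n_before)
        c_cell = c_after
    return heats


def correct_thermogram(exp: ITCExperiment) -> ThermogramCorrection:
    """Subtract the dilution-heat model from the measured thermogram.

    Only the dilution contribution is modelled; the AO/carboxylate binding
    signal that remains in the corrected heats is reported as-is, not
    fitted.
    """
    if exp.measured_heats is None:
        raise ParameterError("experiment has no measured_heats to correct")
    measured = np.asarray(exp.measured_heats, dtype=float)
    if measured.shape != (len(exp.injection_volumes),):
        raise DimensionError(
            f"measured_heats length {measured.size} != "
            f"{len(exp.injection_volumes)} injections"
        )
    model = dilution_heat_model(exp)
    corrected = measured - model
    return ThermogramCorrection(
        measured_heats=measured,
        model_heats=model,
        corrected_heats=corrected,
        rms_residual=float(np.sqrt(np.mean(corrected**2))),
    )


def strong_site_fraction(adsorbed_dye: float, acid_groups: float) -> float:
    """Percent of acid groups engaged in strong dye association.

    ``100 * adsorbed_dye / acid_groups`` (both in mol).
    """
    if acid_groups <= 0:
        raise ParameterError(f"acid_groups must be positive, got {acid_groups}")
    if adsorbed_dye < 0:
        raise ParameterError(f"adsorbed_dye must be >= 0, got {adsorbed_dye}")
    return 100.0 * adsorbed_dye / acid_groups


def absorbance_to_conc(absorbance: float, epsilon: float = 33016.0,
                       path: float = 1.0) -> float:
    """Beer–Lambert: concentration (mol/L) from absorbance.

    Default extinction coefficient is the dye's 467 nm value,
    33,016 L/(mol cm), with a 1 cm path.
    """
    if absorbance < 0:
        raise ParameterError(f"absorbance must be >= 0, got {absorbance}")
    if epsilon <= 0 or path <= 0:
        raise ParameterError("epsilon and path must be positive")
    return absorbance / (epsilon * path)


def read_heats_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read (volume_uL, measured_heat_uJ) columns; returns SI (L, J) arrays."""
    df = pd.read_csv(path)
    return (df["volume_uL"].to_numpy(float) * 1e-6,
            df["measured_heat_uJ"].to_numpy(float) * 1e-6)


def write_corrected_csv(correction: ThermogramCorrection,
                        injection_volumes, path: str | Path) -> Path:
    """Write the corrected thermogram as CSV (heats in uJ, volumes in uL)."""
    path = Path(path)
    df = pd.DataFrame({
        "injection_index": np.arange(1, len(correction.measured_heats) + 1),
        "volume_uL": np.asarray(injection_volumes, float) * 1e6,
        "measured_heat_uJ": correction.measured_heats * 1e6,
        "model_heat_uJ": correction.model_heats * 1e6,
        "corrected_heat_uJ": correction.corrected_heats * 1e6,
    })
    df.to_csv(path, index=False)
    return path
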