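"""Synthetic fixtures with known ground truth for every pipeline stage.

Nothing in this package requires instrument data: micrographs, titration
curves, ITC thermograms and decay series can all be generated here with
the planted quantities recorded alongside, so each analysis stage has a
round-trip test against a known answer.

The micrograph generator emulates the relevant physics of the acquisition
chain rather than wood anatomy: a periodic "honeycomb" of cell lumina,
secondary walls and middle lamellae; region-wise monomer/dimer emitter
densities mapped to expected RGB counts through the spectral mixing model
(:func:`aostain.photophysics.channel_intensities`); Bayer-tile resolution
emulated by drawing one Poisson sample per colour per 2x2 group and
nearest-neighbour copying it across the group; a fixed dark offset added
after the shot noise; quantization to 8 bits.  Secondary walls are
greener, middle lamellae redder, lumina nearly dark — the colour structure
of a stained softwood transverse section.

An ``green_loss`` (oxidation) knob scales the monomer density only,
reproducing the empirical signature of mild oxidation: green emission
falls, red stays comparatively constant, and the red/green ratio rises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calorimetry import ITCExperiment, dilution_heat_model
from .camera_io import CameraConfig, save_image
from .exceptions import DimensionError, ParameterError
from .kinetics import DecaySeries
from .photophysics import (
    ChannelResponse,
    channel_intensities,
    default_response,
    densities_for_channel_targets,
)
from .titration import TitrationCurve

__all__ = [
    "SceneSpec",
    "MicrographTruth",
    "default_region_densities",
    "generate_micrograph",
    "generate_image_set",
    "generate_titration_curve",
    "generate_itc_thermogram",
    "generate_decay_series",
]

REGION_LABELS = {"lumen": 0, "secondary_wall": 1, "middle_lamella": 2}


def default_region_densities(response: ChannelResponse | None = None,
                             wall_ratio: float = 0.97,
                             wall_green: float = 140.0,
                             lamella_ratio: float = 1.8,
                             lamella_green: float = 90.0,
                             ) -> dict[str, tuple[float, float]]:
    """Region (monomer, dimer) densities planting exact red/green ratios.

    Default levels emulate a stained sound-wood section: secondary walls
    green-dominant near ratio 1, middle lamellae red-shifted, lumina
    almost dark.  Densities are obtained by inverting the mixing model so
    the planted ratios are exact at the expected-signal level.
    """
    response = response or default_response()
    return {
        "lumen": densities_for_channel_targets(2.0, 3.0, response),
        "secondary_wall": densities_for_channel_targets(
            wall_ratio * wall_green, wall_green, response),
        "middle_lamella": densities_for_channel_targets(
            lamella_ratio * lamella_green, lamella_green, response),
    }


@dataclass
class SceneSpec:
    """Scene description for one synthetic micrograph.

    ``shape`` is the full-resolution image size (even); geometry is defined
    on the half-resolution (true chromatic) grid, where ``cell_period`` is
    the tile pitch, ``wall_thickness`` the secondary-wall ring width and
    ``lamella_thickness`` the middle-lamella border width, all in
    half-resolution pixels.  ``green_loss`` in [0, 1) scales down the
    monomer density of every region (the oxidation knob).
    """

    shape: tuple[int, int] = (192, 192)
    cell_period: int = 20
    wall_thickness: int = 3
    lamella_thickness: int = 1
    region_densities: dict[str, tuple[float, float]] | None = None
    green_loss: float = 0.0
    noise: bool = True
    seed: int = 0
    camera: CameraConfig = field(default_factory=CameraConfig)
    response: ChannelResponse = field(default_factory=default_response)

    def __post_init__(self) -> None:
        h, w = self.shape
        if h % 2 or w % 2:
            raise DimensionError(f"image dimensions must be even, got {h}x{w}")
        if not (0.0 <= self.green_loss < 1.0):
            raise ParameterError(f"green_loss must be in [0, 1), got {self.green_loss}")
        if self.region_densities is None:
            self.region_densities = default_region_densities(self.response)
        for name, (m, d) in self.region_densities.items():
            if m < 0 or d < 0:
                raise ParameterError(f"densities for {name} must be non-negative")


@dataclass(frozen=True)
class MicrographTruth:
    """A generated micrograph plus its ground truth."""

    image: np.ndarray                     # (H, W, 3) uint8
    labels: np.ndarray                    # (H/2, W/2) int, REGION_LABELS codes
    region_truth: dict                    # per-region densities / signals / ratio
    suggested_green_threshold: float      # separates wall from everything else
    seed: int
    paths: dict | None = None


def _label_raster(spec: SceneSpec) -> np.ndarray:
    """Half-resolution region labels: periodic tiles with lamella borders,
    wall rings and lumen interiors."""
    h2, w2 = spec.shape[0] // 2, spec.shape[1] // 2
    p = spec.cell_period
    yy = np.arange(h2) % p
    xx = np.arange(w2) % p
    ey = np.minimum(yy, p - 1 - yy)[:, None]
    ex = np.minimum(xx, p - 1 - xx)[None, :]
    edge_dist = np.minimum(ey, ex)
    labels = np.full((h2, w2), REGION_LABELS["lumen"], dtype=np.int8)
    labels[edge_dist < spec.lamella_thickness + spec.wall_thickness] = \
        REGION_LABELS["secondary_wall"]
    labels[edge_dist < spec.lamella_thickness] = REGION_LABELS["middle_lamella"]
    return labels


def _region_signals(spec: SceneSpec) -> dict:
    """Expected per-channel signal (dark excluded) and true ratio per region."""
    out = {}
    for name, (m, d) in spec.region_densities.items():
        m_eff = m * (1.0 - spec.green_loss)
        r, g, b = channel_intensities(m_eff, d, spec.response)
        out[name] = {
            "monomer_density": m_eff,
            "dimer_density": d,
            "expected_red": r,
            "expected_green": g,
            "expected_blue": b,
            "true_ratio": r / g if g > 0 else float("nan"),
        }
    return out


def generate_micrograph(spec: SceneSpec, out_dir: str | Path | None = None,
                        stem: str = "micrograph") -> MicrographTruth:
    """Render one synthetic micrograph and its ground-truth bundle.

    Expected counts are computed per half-resolution pixel from the region
    densities, one shot-noise (Poisson) sample is drawn per colour per 2x2
    group, the fixed dark offset is added, values are quantized to 8 bits,
    and the half-resolution raster is nearest-neighbour upsampled to full
    resolution — emulating the camera firmware's Bayer interpolation.

    When ``out_dir`` is given, the image is saved as an uncompressed RGB
    TIFF with a JSON truth file and a CSV label raster alongside.
    """
    labels = _label_raster(spec)
    signals = _region_signals(spec)
    rng = np.random.default_rng(spec.seed)

    h2, w2 = labels.shape
    half = np.zeros((h2, w2, 3), dtype=float)
    for name, code in REGION_LABELS.items():
        region = labels == code
        for c, key in enumerate(("expected_red", "expected_green", "expected_blue")):
            half[:, :, c][region] = signals[name][key]
    sampled = rng.poisson(half).astype(float) if spec.noise else np.rint(half)
    counts = sampled + spec.camera.dark_level
    counts = np.clip(np.rint(counts), 0, spec.camera.bit_depth).astype(np.uint8)
    image = np.repeat(np.repeat(counts, 2, axis=0), 2, axis=1)

    wall_g = signals["secondary_wall"]["expected_green"]
    other_g = max(signals["middle_lamella"]["expected_green"],
                  signals["lumen"]["expected_green"])
    threshold = 0.5 * (wall_g + other_g)

    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tiff_path = out_dir / f"{stem}.tif"
        save_image(image, tiff_path)
        labels_path = out_dir / f"{stem}_labels.csv"
        np.savetxt(labels_path, labels, fmt="%d", delimiter=",")
        truth_path = out_dir / f"{stem}_truth.json"
        truth_path.write_text(json.dumps({
            "seed": spec.seed,
            "green_loss": spec.green_loss,
            "dark_level": spec.camera.dark_level,
            "suggested_green_threshold": threshold,
            "regions": signals,
        }, indent=2))
        paths = {"image": str(tiff_path), "truth": str(truth_path),
                 "labels": str(labels_path)}

    return MicrographTruth(image=image, labels=labels, region_truth=signals,
                           suggested_green_threshold=threshold,
                           seed=spec.seed, paths=paths)


def generate_image_set(spec: SceneSpec, n_images: int, seed: int | None = None,
                       location_jitter_rel: float = 0.02,
                       out_dir: str | Path | None = None
                       ) -> list[MicrographTruth]:
    """Generate a replicate image set emulating different section locations.

    Each image gets independent multiplicative jitter (relative sd
    ``location_jitter_rel``, common to all regions) on the monomer and on
    the dimer densities, mimicking the section-to-section and
    location-to-location brightness/composition variation that makes
    images — not pixels — the replication unit.
    """
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    if location_jitter_rel < 0:
        raise ParameterError("location_jitter_rel must be >= 0")
    base_seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n_images)
    jit_rng = np.random.default_rng(ss.spawn(1)[0])

    out = []
    for i, child in enumerate(children):
        fm = max(1.0 + location_jitter_rel * jit_rng.standard_normal(), 0.05)
        fd = max(1.0 + location_jitter_rel * jit_rng.standard_normal(), 0.05)
        densities = {name: (m * fm, d * fd)
                     for name, (m, d) in spec.region_densities.items()}
        child_seed = int(child.generate_state(1)[0] % (2**31))
        sub = SceneSpec(shape=spec.shape, cell_period=spec.cell_period,
                        wall_thickness=spec.wall_thickness,
                        lamella_thickness=spec.lamella_thickness,
                        region_densities=densities,
                        green_loss=spec.green_loss, noise=spec.noise,
                        seed=child_seed, camera=spec.camera,
                        response=spec.response)
        out.append(generate_micrograph(sub, out_dir=out_dir,
                                       stem=f"micrograph_{i:02d}"))
    return out


def generate_titration_curve(acid_umol_per_g: float,
                             strong_acid_umol: float = 10.0,
                             sample_mass: float | None = None,
                             titrant_conc: float = 0.0125,
                             noise_rel: float = 0.0,
                             seed: int = 0,
                             pulse_volume: float = 20e-6,
                             base_conductivity: float = 300.0,
                             slopes: tuple[float, float, float] = (-3.0e4, 2.0e3, 2.5e4),
                             total_volume: float = 18e-3,
                             ) -> tuple[TitrationCurve, dict]:
    """Piecewise-linear conductometric curve with planted breakpoints.

    When ``sample_mass`` is omitted it is set to give 50 umol of weak acid
    groups in the vessel (the practice of adjusting mass to a fixed
    titratable amount).  Titrant is delivered in ``pulse_volume`` steps
    (20 uL, a diaphragm-pump pulse) with one conductivity reading per
    pulse, up to ``total_volume`` — 18 mL, a ~90 min run at 10 pulses/min,
    which carries the curve well past equivalence.  Slopes are in uS/cm
    per L of 12.5 mmol/L NaOH: falling during strong-acid exchange, gently
    rising across the weak-acid plateau, steeply rising in excess base.
    Optional relative Gaussian noise is applied multiplicatively.
    """
    if acid_umol_per_g < 0 or strong_acid_umol < 0:
        raise ParameterError("acid contents must be non-negative")
    if noise_rel < 0:
        raise ParameterError(f"noise_rel must be >= 0, got {noise_rel}")
    if sample_mass is None:
        if acid_umol_per_g <= 0:
            raise ParameterError("sample_mass required when acid_umol_per_g is 0")
        sample_mass = 50.0 / acid_umol_per_g
    weak_umol = acid_umol_per_g * sample_mass
    v1 = strong_acid_umol * 1e-6 / titrant_conc
    dv = weak_umol * 1e-6 / titrant_conc
    v2 = v1 + dv
    vmax = max(total_volume, 1.25 * max(v2, v1, 1e-4))
    n_points = max(int(np.floor(vmax / pulse_volume)) + 1, 13)
    volumes = np.arange(n_points) * pulse_volume
    s1, s2, s3 = slopes
    cond = (base_conductivity
            + s1 * np.minimum(volumes, v1)
            + s2 * np.clip(volumes - v1, 0.0, dv)
            + s3 * np.maximum(volumes - v2, 0.0))
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        cond = cond * (1.0 + noise_rel * rng.standard_normal(cond.shape))
    curve = TitrationCurve(added_volume=volumes, conductivity=cond,
                           titrant_conc=titrant_conc, sample_mass=sample_mass)
    truth = {"acid_umol_per_g": acid_umol_per_g,
             "strong_acid_umol": strong_acid_umol,
             "sample_mass_g": sample_mass,
             "v1_L": v1, "v2_L": v2, "slopes": slopes,
             "noise_rel": noise_rel, "seed": seed}
    return curve, truth


def generate_itc_thermogram(exp: ITCExperiment,
                            binding_pulse_heat: float = -250e-6,
                            n_pulse_injections: int = 3,
                            ion_exchange_heat: float = -5e-6,
                            noise_abs: float = 0.0,
                            seed: int = 0,
                            ) -> tuple[ITCExperiment, dict]:
    """Synthetic measured thermogram: dilution model + binding pulse + ion
    exchange + optional Gaussian noise (all heats in J, positive = endo).

    The binding pulse is a square exothermic contribution over the first
    ``n_pulse_injections`` injections, emulating strong association of the
    dye with a small population of sites; the constant ion-exchange term
    extends over every injection.
    """
    if noise_abs < 0:
        raise ParameterError(f"noise_abs must be >= 0, got {noise_abs}")
    if n_pulse_injections < 0 or n_pulse_injections > len(exp.injection_volumes):
        raise ParameterError("n_pulse_injections out of range")
    model = dilution_heat_model(exp)
    measured = model + ion_exchange_heat
    measured[:n_pulse_injections] += binding_pulse_heat
    if noise_abs > 0:
        rng = np.random.default_rng(seed)
        measured = measured + noise_abs * rng.standard_normal(measured.shape)
    new_exp = ITCExperiment(
        cell_volume=exp.cell_volume, syringe_conc=exp.syringe_conc,
        injection_volumes=tuple(exp.injection_volumes),
        K_dimer=exp.K_dimer, dH_dimer=exp.dH_dimer,
        measured_heats=tuple(measured),
        cell_analyte_conc=exp.cell_analyte_conc,
        cell_initial_dye_conc=exp.cell_initial_dye_conc,
        syringe_equilibrated=exp.syringe_equilibrated,
    )
    truth = {"binding_pulse_heat_J": binding_pulse_heat,
             "n_pulse_injections": n_pulse_injections,
             "ion_exchange_heat_J": ion_exchange_heat,
             "noise_abs_J": noise_abs, "seed": seed}
    return new_exp, truth


def generate_decay_series(a0: float = 1.0, half_life: float = 436.0,
                          times: np.ndarray | None = None,
                          noise_rel: float = 0.0, seed: int = 0,
                          ) -> tuple[DecaySeries, dict]:
    """Exponential absorbance decay with optional relative Gaussian noise."""
    if a0 <= 0 or half_life <= 0:
        raise ParameterError("a0 and half_life must be positive")
    if noise_rel < 0:
        raise ParameterError(f"noise_rel must be >= 0, got {noise_rel}")
    if times is None:
        times = np.linspace(0.0, 18.0, 10)
    times = np.asarray(times, dtype=float)
    absorbance = a0 * 2.0 ** (-times / half_life)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance * (1.0 + noise_rel * rng.standard_normal(times.shape))
        absorbance = np.maximum(absorbance, 1e-12)
    series = DecaySeries(times=times, absorbance=absorbance)
    truth = {"a0": a0, "half_life_h": half_life, "noise_rel": noise_rel,
             "seed": seed}
    return series, truth
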