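import json

import numpy as np
import pytest

from aostain.calorimetry import ITCExperiment
from aostain.exceptions import DimensionError, ParameterError
from aostain.synthetic_data import (
    SceneSpec,
    generate_decay_series,
    generate_image_set,
    generate_itc_thermogram,
    generate_micrograph,
    generate_titration_curve,
)


class TestMicrographGenerator:
    def test_zero_densities_give_constant_dark_image(self, camera):
        spec = SceneSpec(shape=(16, 16), seed=1,
                         region_densities={k: (0.0, 0.0) for k in
                                           ("lumen", "secondary_wall",
                                            "middle_lamella")})
        truth = generate_micrograph(spec)
        np.testing.assert_array_equal(truth.image, camera.dark_level)

    def test_same_seed_same_image(self):
        a = generate_micrograph(SceneSpec(shape=(64, 64), seed=42))
        b = generate_micrograph(SceneSpec(shape=(64, 64), seed=42))
        np.testing.assert_array_equal(a.image, b.image)

    def test_different_seeds_differ(self):
        a = generate_micrograph(SceneSpec(shape=(64, 64), seed=1))
        b = generate_micrograph(SceneSpec(shape=(64, 64), seed=2))
        assert (a.image != b.image).any()

    def test_bayer_groups_are_constant(self):
        """Nearest-neighbour filled 2x2 groups hold one chromatic sample."""
        img = generate_micrograph(SceneSpec(shape=(32, 32), seed=5)).image
        for c in range(3):
            ch = img[:, :, c]
            blocks = ch.reshape(16, 2, 16, 2)
            assert (blocks == blocks[:, :1, :, :1]).all()

    def test_odd_dimensions_rejected(self):
        with pytest.raises(DimensionError):
            SceneSpec(shape=(15, 16))

    def test_truth_files_written(self, tmp_path):
        truth = generate_micrograph(SceneSpec(shape=(16, 16), seed=0),
                                    out_dir=tmp_path)
        recorded = json.loads((tmp_path / "micrograph_truth.json").read_text())
        assert recorded["regions"]["secondary_wall"]["true_ratio"] == \
            pytest.approx(truth.region_truth["secondary_wall"]["true_ratio"])
        labels = np.loadtxt(truth.paths["labels"], delimiter=",", dtype=int)
        np.testing.assert_array_equal(labels, truth.labels)

    def test_green_loss_suppresses_green_not_dimer_signal(self):
        base = generate_micrograph(SceneSpec(shape=(16, 16), seed=0))
        oxid = generate_micrograph(SceneSpec(shape=(16, 16), seed=0,
                                             green_loss=0.34))
        w0 = base.region_truth["secondary_wall"]
        w1 = oxid.region_truth["secondary_wall"]
        green_drop = 1 - w1["expected_green"] / w0["expected_green"]
        red_drop = 1 - w1["expected_red"] / w0["expected_red"]
        assert green_drop > red_drop > 0
        assert w1["dimer_density"] == w0["dimer_density"]

    def test_image_set_is_deterministic(self):
        a = generate_image_set(SceneSpec(shape=(32, 32)), 3, seed=9)
        b = generate_image_set(SceneSpec(shape=(32, 32)), 3, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.image, y.image)


class TestTitrationGenerator:
    def test_planted_breakpoints_consistent_with_content(self):
        curve, truth = generate_titration_curve(186.0)
        planted = (truth["v2_L"] - truth["v1_L"]) * curve.titrant_conc \
            / curve.sample_mass * 1e6
        assert planted == pytest.approx(186.0, rel=1e-12)

    def test_seeded_noise_reproducible(self):
        a, _ = generate_titration_curve(79.0, noise_rel=0.01, seed=3)
        b, _ = generate_titration_curve(79.0, noise_rel=0.01, seed=3)
        np.testing.assert_array_equal(a.conductivity, b.conductivity)

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            generate_titration_curve(79.0, noise_rel=-0.1)


class TestITCGenerator:
    def test_measured_equals_model_without_extras(self):
        exp, _ = generate_itc_thermogram(ITCExperiment(), binding_pulse_heat=0.0,
                                         ion_exchange_heat=0.0)
        from aostain.calorimetry import dilution_heat_model
        np.testing.assert_allclose(np.asarray(exp.measured_heats),
                                   dilution_heat_model(exp), rtol=1e-12)

    def test_seeded_determinism(self):
        a, _ = generate_itc_thermogram(ITCExperiment(), noise_abs=1e-6, seed=4)
        b, _ = generate_itc_thermogram(ITCExperiment(), noise_abs=1e-6, seed=4)
        np.testing.assert_array_equal(np.asarray(a.measured_heats),
                                      np.asarray(b.measured_heats))

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            generate_itc_thermogram(ITCExperiment(), noise_abs=-1e-6)


class TestDecayGenerator:
    def test_noiseless_series_is_exact_exponential(self):
        series, truth = generate_decay_series(a0=2.0, half_life=100.0)
        expected = 2.0 * 2.0 ** (-series.times / 100.0)
        np.testing.assert_allclose(series.absorbance, expected, rtol=1e-12)

    def test_seeded_determinism(self):
        a, _ = generate_decay_series(noise_rel=0.01, seed=8)
        b, _ = generate_decay_series(noise_rel=0.01, seed=8)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            generate_decay_series(a0=0.0)
        with pytest.raises(ParameterError):
            generate_decay_series(noise_rel=-0.5)
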