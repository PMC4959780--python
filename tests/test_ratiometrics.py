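import numpy as np
import pytest
from scipy import stats

from aostain.exceptions import (
    DimensionError,
    EmptyMaskError,
    ParameterError,
    SampleSizeError,
)
from aostain.ratiometrics import (
    MaskedRatios,
    autofluorescence_fraction,
    build_mask,
    channel_mode,
    electron_equivalents,
    percent_decrease,
    ratio_map,
    summarize_set,
)


def masked_ratios_from(values):
    """Wrap plain ratio values as a MaskedRatios for summarize_set tests."""
    arr = np.asarray(values, dtype=float)
    mask = build_mask(np.ones_like(arr), 0.0)
    return MaskedRatios(ratios=arr, red_values=arr, green_values=np.ones_like(arr),
                        mask=mask, n_green_zero_dropped=0)


class TestBuildMask:
    def test_zero_threshold_keeps_everything(self, rng):
        green = rng.uniform(0, 200, size=(8, 8))
        assert build_mask(green, 0.0).values.all()

    def test_threshold_above_max_keeps_nothing(self):
        assert not build_mask(np.full((4, 4), 10.0), 11.0).values.any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            build_mask(np.zeros((2, 2)), -1.0)

    def test_monotone_in_threshold(self, rng):
        green = rng.uniform(0, 255, size=(32, 32))
        prev = None
        for thr in np.linspace(0, 260, 14):
            n = build_mask(green, thr).n_pixels
            if prev is not None:
                assert n <= prev
            prev = n


class TestRatioMap:
    def test_identity_when_channels_equal(self, rng):
        ch = rng.uniform(1, 200, size=(8, 8))
        res = ratio_map(ch, ch, build_mask(ch, 0.0))
        np.testing.assert_allclose(res.ratios, 1.0)

    def test_green_zero_pixels_dropped_and_counted(self):
        green = np.array([[0.0, 10.0], [5.0, 0.0]])
        red = np.full((2, 2), 7.0)
        res = ratio_map(red, green, build_mask(green, 0.0))
        assert res.n_green_zero_dropped == 2
        assert res.ratios.size == 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            ratio_map(np.zeros((2, 2)), np.zeros((2, 3)),
                      build_mask(np.zeros((2, 3)), 0.0))

    def test_scale_invariance(self, rng):
        """Multiplying both channels by the same positive constant leaves
        every masked ratio pixel unchanged."""
        red = rng.uniform(10, 200, size=(16, 16))
        green = rng.uniform(10, 200, size=(16, 16))
        mask = build_mask(green, 50.0)
        base = ratio_map(red, green, mask).ratios
        scaled = ratio_map(3.7 * red, 3.7 * green, mask).ratios
        np.testing.assert_allclose(scaled, base, rtol=1e-12)


class TestChannelMode:
    def test_constant_image(self):
        assert channel_mode(np.full((5, 5), 75.0)) == 75

    def test_dominant_peak(self, rng):
        values = np.concatenate([np.full(500, 43.0),
                                 rng.integers(60, 200, 300).astype(float)])
        assert channel_mode(values) == 43

    def test_tie_breaks_to_lowest_bin(self):
        assert channel_mode(np.array([10.0, 20.0, 10.0, 20.0])) == 10

    def test_empty_mask_rejected(self):
        mask = build_mask(np.zeros((2, 2)), 1.0)
        with pytest.raises(EmptyMaskError):
            channel_mode(np.zeros((2, 2)), mask)


class TestScalarStatistics:
    @pytest.mark.parametrize("control,treated,expected", [
        (75, 66, 12), (65, 43, 34), (100, 100, 0)])
    def test_percent_decrease(self, control, treated, expected):
        assert percent_decrease(control, treated) == expected

    def test_percent_decrease_zero_control_rejected(self):
        with pytest.raises(ParameterError):
            percent_decrease(0, 10)

    @pytest.mark.parametrize("unstained,stained,expected", [
        (4.0, 100.0, 4.0), (0.0, 100.0, 0.0), (0.13, 100.0, 0.13)])
    def test_autofluorescence_fraction(self, unstained, stained, expected):
        assert autofluorescence_fraction(unstained, stained) == pytest.approx(expected)

    def test_autofluorescence_zero_stained_rejected(self):
        with pytest.raises(ParameterError):
            autofluorescence_fraction(1.0, 0.0)

    def test_electron_equivalents(self):
        # 1 mmol chlorite/g at 5 electron equivalents per mole
        assert electron_equivalents(1.0, 5.0) == 5.0


class TestSummarizeSet:
    def test_identical_images_have_zero_ci(self):
        images = [masked_ratios_from(np.full(50, 1.3)) for _ in range(15)]
        summary = summarize_set(images)
        assert summary.mean_ratio == pytest.approx(1.3)
        assert summary.ci95_halfwidth == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_t_interval(self):
        images = [masked_ratios_from([m]) for m in (0.9, 1.0, 1.1)]
        summary = summarize_set(images)
        sd = np.std([0.9, 1.0, 1.1], ddof=1)
        expected = stats.t.ppf(0.975, 2) * sd / np.sqrt(3)
        assert summary.mean_ratio == pytest.approx(1.0)
        assert summary.ci95_halfwidth == pytest.approx(expected, rel=1e-12)

    def test_matches_naive_loop_oracle(self, rng):
        images = [masked_ratios_from(rng.uniform(0.5, 2.5, size=200))
                  for _ in range(6)]
        summary = summarize_set(images)
        means = []
        for img in images:
            total = 0.0
            for v in img.ratios:
                total += v
            means.append(total / img.ratios.size)
        assert summary.mean_ratio == pytest.approx(np.mean(means), rel=1e-12)

    def test_histogram_counts_sum_to_masked_pixels(self, rng):
        images = [masked_ratios_from(rng.uniform(0, 8, size=300)) for _ in range(3)]
        summary = summarize_set(images)
        assert summary.hist_counts.sum() == 900

    def test_too_few_images_rejected(self):
        with pytest.raises(SampleSizeError):
            summarize_set([masked_ratios_from([1.0])])
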