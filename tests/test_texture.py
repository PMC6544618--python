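"""Histogram construction and the seven first-order texture parameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import osteotex as ot
from osteotex.texture import (
    DegenerateHistogramError,
    EmptyRoiError,
    GrayHistogram,
    N_LEVELS,
)

pixel_lists = st.lists(st.integers(0, 255), min_size=2, max_size=300)


def loop_moment(p, order, about=None):
    """Independent plain-Python oracle: Σ (k-about)^order · p[k]."""
    if about is None:
        about = sum(k * pk for k, pk in enumerate(p))
    return sum((k - about) ** order * pk for k, pk in enumerate(p)), about


class TestBuildHistogram:
    def test_single_level_concentrates_all_mass(self):
        h = ot.build_histogram(np.full(256, 128))
        assert h.p[128] == 1.0 and h.p.sum() == 1.0 and h.n_pixels == 256

    def test_two_extreme_levels_split_mass(self):
        h = ot.build_histogram([0, 255])
        assert h.p[0] == 0.5 and h.p[255] == 0.5

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(42)
        img = rng.integers(0, 256, size=(16, 16))
        h = ot.build_histogram(img.ravel())
        for k in range(N_LEVELS):
            assert h.p[k] == sum(1 for v in img.ravel() if v == k) / img.size

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyRoiError):
            ot.build_histogram([])

    def test_out_of_range_value_named_in_error(self):
        with pytest.raises(ValueError, match="300"):
            ot.build_histogram([10, 300])


class TestTwoPointAnalytics:
    """Half mass at 0, half at 255: every parameter has a closed form."""

    def test_all_parameters(self, two_point_histogram):
        h = two_point_histogram
        assert ot.hist_mean(h) == 127.5
        assert ot.hist_sigma(h) == 127.5
        assert abs(ot.hist_skewness(h)) < 1e-12
        assert ot.hist_kurtosis(h) == pytest.approx(-2.0, abs=1e-12)
        assert ot.hist_energy(h) == 0.5
        assert ot.nakagami_parameter(h) == pytest.approx(1.0, abs=1e-12)

    def test_profile_consistent_with_individual_ops(self):
        pixels = np.array([0] * 30 + [255] * 30)
        p = ot.texture_profile(pixels)
        assert (p.mean, p.sigma, p.energy) == (127.5, 127.5, 0.5)
        assert p.kurtosis == pytest.approx(-2.0, abs=1e-12)
        assert p.nakagami == pytest.approx(1.0, abs=1e-12)
        assert p.quartile_fraction == 0.5


class TestMomentsAgainstAnalyticDensities:
    def test_gaussian25_mean_is_128(self):
        h = ot.discretize(ot.analytic_distribution("gaussian_25"), renormalize=True)
        assert ot.hist_mean(h) == pytest.approx(128.0, abs=1e-5)

    def test_gaussian25_sigma_matches_loop_oracle(self):
        h = ot.discretize(ot.analytic_distribution("gaussian_25"), renormalize=True)
        m2, _ = loop_moment(h.p, 2)
        assert ot.hist_sigma(h) == pytest.approx(math.sqrt(m2), abs=1e-9)
        assert ot.hist_sigma(h) == pytest.approx(25.0, abs=1e-3)

    def test_rayleigh_skewness_positive_and_matches_oracle(self):
        h = ot.discretize(ot.analytic_distribution("rayleigh_100"), renormalize=True)
        m3, about = loop_moment(h.p, 3)
        sigma = ot.hist_sigma(h)
        assert ot.hist_skewness(h) > 0
        assert ot.hist_skewness(h) == pytest.approx(m3 / sigma**3, abs=1e-9)

    def test_gaussian25_excess_kurtosis_near_zero(self):
        h = ot.discretize(ot.analytic_distribution("gaussian_25"), renormalize=True)
        assert ot.hist_kurtosis(h) == pytest.approx(0.0, abs=0.01)

    def test_rayleigh_kurtosis_matches_oracle(self):
        h = ot.discretize(ot.analytic_distribution("rayleigh_100"), renormalize=True)
        m4, _ = loop_moment(h.p, 4)
        assert ot.hist_kurtosis(h) == pytest.approx(
            m4 / ot.hist_sigma(h) ** 4 - 3.0, abs=1e-9
        )

    def test_degenerate_histogram_rejected(self):
        h = ot.build_histogram(np.full(10, 7))
        with pytest.raises(DegenerateHistogramError):
            ot.hist_skewness(h)
        with pytest.raises(DegenerateHistogramError):
            ot.hist_kurtosis(h)


class TestEnergyEntropy:
    def test_uniform_image_has_maximal_energy(self):
        h = ot.build_histogram(np.full((16, 16), 200).ravel())
        assert ot.hist_energy(h) == 1.0
        assert ot.hist_entropy(h) == 0.0

    def test_flat_histogram_values(self):
        h = ot.build_histogram(np.arange(256))
        assert ot.hist_energy(h) == pytest.approx(1 / 256)
        assert ot.hist_entropy(h) == pytest.approx(math.log(256))
        assert ot.hist_entropy(h, base="log2") == pytest.approx(8.0)

    def test_gaussian25_entropy_near_printed_value(self):
        h = ot.discretize(ot.analytic_distribution("gaussian_25"), renormalize=True)
        assert ot.hist_entropy(h) == pytest.approx(4.63, abs=0.05)


class TestNakagami:
    def test_constant_population_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            ot.nakagami_parameter(np.full(100, 77))

    def test_discretized_gaussian_matches_closed_form(self):
        mu, sd = 100.0, 15.0
        from scipy import stats

        p = stats.norm.pdf(np.arange(256), mu, sd)
        h = GrayHistogram(p=p / p.sum(), n_pixels=0)
        expected = (mu**2 + sd**2) ** 2 / (4 * mu**2 * sd**2 + 2 * sd**4)
        assert ot.nakagami_parameter(h) == pytest.approx(expected, rel=0.005)


class TestQuartileFraction:
    def test_mass_above_cutoff_counts_zero(self):
        h = ot.build_histogram(np.full(10, 128))
        assert ot.quartile_fraction(h) == 0.0

    @pytest.mark.parametrize(
        "family, expected, tol",
        [("gaussian_25", 0.0055, 0.0005), ("gaussian_50", 0.0969, 0.002)],
    )
    def test_unrenormalized_analytic_mass(self, family, expected, tol):
        h = ot.discretize(ot.analytic_distribution(family), renormalize=False)
        assert ot.quartile_fraction(h) == pytest.approx(expected, abs=tol)

    def test_cutoff_bounds_checked(self):
        h = ot.build_histogram([1, 2, 3])
        with pytest.raises(ValueError):
            ot.quartile_fraction(h, max_level=300)


class TestProfileRecoversGaussianMoments:
    def test_seeded_sample_moments(self):
        rng = np.random.default_rng(7)
        pixels = np.clip(np.rint(rng.normal(128, 20, size=200_000)), 0, 255).astype(int)
        p = ot.texture_profile(pixels)
        assert p.mean == pytest.approx(128, abs=0.2)
        assert p.sigma == pytest.approx(20, abs=0.15)
        assert p.skewness == pytest.approx(0, abs=0.03)
        assert p.kurtosis == pytest.approx(0, abs=0.06)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(pixel_lists)
def test_pixel_and_histogram_paths_agree(pixels):
    """Raw-pixel moments equal histogram-path moments (population convention)."""
    arr = np.asarray(pixels, dtype=float)
    h = ot.build_histogram(pixels)
    assert ot.hist_mean(h) == pytest.approx(arr.mean(), abs=1e-9)
    assert ot.hist_sigma(h) == pytest.approx(arr.std(), abs=1e-9)
    if arr.std() > 0:
        z = (arr - arr.mean()) / arr.std()
        assert ot.hist_skewness(h) == pytest.approx((z**3).mean(), abs=1e-9)
        assert ot.hist_kurtosis(h) == pytest.approx((z**4).mean() - 3, abs=1e-9)
    sq = arr**2
    if sq.var() > 0:
        assert ot.nakagami_parameter(h) == pytest.approx(
            ot.nakagami_parameter(pixels), abs=1e-9
        )
        assert ot.nakagami_parameter(pixels) == pytest.approx(
            sq.mean() ** 2 / sq.var(), rel=1e-9
        )


@settings(deadline=None, max_examples=60, derandomize=True)
@given(pixel_lists)
def test_energy_entropy_bounds_and_reorder_invariance(pixels):
    h = ot.build_histogram(pixels)
    energy, entropy = ot.hist_energy(h), ot.hist_entropy(h)
    occupied = int(np.count_nonzero(h.p))
    assert energy <= 1.0 + 1e-12
    assert 0.0 <= entropy <= math.log(256) + 1e-12
    assert (energy == 1.0) == (occupied == 1) == (entropy == 0.0)
    h2 = ot.build_histogram(pixels[::-1])
    np.testing.assert_array_equal(h.p, h2.p)
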