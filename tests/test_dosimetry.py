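import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ctsize import dosimetry
from ctsize.dosimetry import (
    DwResult,
    mean_dw,
    percent_diff_dw,
    percent_diff_ssde,
    size_conversion_factor,
    ssde,
    water_equivalent_diameter,
)


def uniform_case(mean_hu, area_cm2, spacing=(1.0, 1.0)):
    """Constant-HU grid whose full mask has (almost) the requested area.

    Returns the actual pixel-quantized area alongside the grid.
    """
    px_area = spacing[0] * spacing[1] / 100.0
    n = int(round(area_cm2 / px_area))
    hu = np.full((16, -(-n // 16)), float(mean_hu))  # >= n cells
    mask = np.zeros_like(hu, dtype=bool)
    mask.flat[:n] = True
    return hu, mask, spacing, n * px_area


class TestWaterEquivalentDiameter:
    @pytest.mark.parametrize(
        "mean_hu,area_cm2,expected_dw",
        [
            # HU=0 reduces D_w to the area-equivalent diameter
            (0.0, math.pi * 100.0, 20.0),
            # hand evaluation: 2*sqrt(1.1*400/pi) = 23.669 cm
            (100.0, 400.0, 2.0 * math.sqrt(1.1 * 400.0 / math.pi)),
            # pure air has zero water-equivalent area
            (-1000.0, 400.0, 0.0),
        ],
    )
    def test_uniform_regions(self, mean_hu, area_cm2, expected_dw):
        hu, mask, spacing, actual_area = uniform_case(mean_hu, area_cm2)
        r = water_equivalent_diameter(hu, mask, spacing)
        assert r.area_cm2 == pytest.approx(actual_area, rel=1e-12)
        assert r.mean_hu == pytest.approx(mean_hu)
        # closed form on the pixel-quantized area, and the requested target
        exact = 2.0 * math.sqrt(max(mean_hu / 1000.0 + 1.0, 0.0) * actual_area / math.pi)
        assert r.dw_cm == pytest.approx(exact, rel=1e-9, abs=1e-12)
        assert r.dw_cm == pytest.approx(expected_dw, rel=1e-3, abs=1e-12)

    def test_empty_mask_is_fatal(self):
        hu = np.zeros((32, 32))
        with pytest.raises(ValueError, match="empty mask"):
            water_equivalent_diameter(hu, np.zeros_like(hu, dtype=bool), (0.8, 0.8))

    def test_mean_below_minus_1000_is_fatal(self):
        hu = np.full((32, 32), -1200.0)
        with pytest.raises(ValueError, match="negative water-equivalent"):
            water_equivalent_diameter(hu, np.ones_like(hu, dtype=bool), (0.8, 0.8))

    def test_non_square_pixels_use_physical_area(self):
        hu = np.zeros((100, 50))
        mask = np.ones_like(hu, dtype=bool)
        r = water_equivalent_diameter(hu, mask, (2.0, 1.0))
        assert r.area_cm2 == pytest.approx(100 * 50 * 2.0 / 100.0)

    @given(
        hnp.arrays(
            np.float64,
            (12, 12),
            elements=st.floats(min_value=-1000.0, max_value=2000.0),
        )
    )
    def test_dw_satisfies_defining_equation(self, hu):
        """dw^2 * pi / 4 == (mean_hu/1000 + 1) * area, to float tolerance."""
        mask = np.ones_like(hu, dtype=bool)
        r = water_equivalent_diameter(hu, mask, (0.8, 0.8))
        lhs = r.dw_cm**2 * math.pi / 4.0
        rhs = (r.mean_hu / 1000.0 + 1.0) * r.area_cm2
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    @given(
        hnp.arrays(
            np.float64,
            (10, 10),
            elements=st.floats(min_value=-999.0, max_value=2000.0),
        )
    )
    def test_air_cells_leave_dw_exactly_unchanged(self, hu):
        """Growing the mask by HU=-1000 cells changes D_w by exactly zero."""
        padded = np.full((10, 20), -1000.0)
        padded[:, :10] = hu
        small = np.zeros_like(padded, dtype=bool)
        small[:, :10] = True
        big = np.ones_like(padded, dtype=bool)
        r_small = water_equivalent_diameter(padded, small, (0.8, 0.8))
        r_big = water_equivalent_diameter(padded, big, (0.8, 0.8))
        assert r_big.dw_cm == r_small.dw_cm

    @given(st.integers(min_value=0, max_value=63))
    def test_adding_tissue_cell_strictly_increases_dw(self, flat_index):
        hu = np.full((8, 8), 40.0)
        mask = np.ones_like(hu, dtype=bool)
        mask.flat[flat_index] = False
        partial = water_equivalent_diameter(hu, mask, (0.8, 0.8))
        full = water_equivalent_diameter(hu, np.ones_like(mask), (0.8, 0.8))
        assert full.dw_cm > partial.dw_cm


class TestMeanDw:
    def test_mean_over_slices(self):
        results = [DwResult(i, 1.0, 0.0, d) for i, d in enumerate([20.0, 30.0])]
        assert mean_dw(results) == pytest.approx(25.0)
        assert mean_dw(results[:1]) == pytest.approx(20.0)

    def test_constant_series(self):
        results = [DwResult(i, 1.0, 0.0, 24.56) for i in range(100)]
        assert mean_dw(results) == pytest.approx(24.56)

    def test_empty_is_fatal(self):
        with pytest.raises(ValueError):
            mean_dw([])


class TestSizeConversionFactor:
    @pytest.mark.parametrize(
        "phantom,a,b",
        [
            ("body-32cm", 3.704369, 0.03671937),
            ("head-16cm", 1.874799, 0.03871313),
        ],
    )
    def test_unity_crossing(self, phantom, a, b):
        """f = 1 exactly where a*exp(-b*d) = 1, i.e. d = ln(a)/b."""
        d_unity = math.log(a) / b
        assert size_conversion_factor(d_unity, phantom) == pytest.approx(1.0, rel=1e-9)

    def test_strictly_decreasing_in_dw(self):
        ds = np.linspace(8.0, 50.0, 30)
        fs = [size_conversion_factor(d, "body-32cm") for d in ds]
        assert all(f1 > f2 for f1, f2 in zip(fs, fs[1:]))

    def test_head_factor_exceeds_body_factor(self):
        # the 16-cm reference phantom absorbs less, so f_head < f_body... check
        # against the curve shapes at a typical adult head size
        assert size_conversion_factor(16.0, "head-16cm") < size_conversion_factor(
            16.0, "body-32cm"
        )

    def test_out_of_range_warns_but_extrapolates(self):
        with pytest.warns(UserWarning, match="extrapolating"):
            f = size_conversion_factor(60.0, "body-32cm")
        assert f > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            size_conversion_factor(0.0)
        with pytest.raises(KeyError):
            size_conversion_factor(20.0, "body-48cm")


class TestSSDE:
    def test_product(self):
        assert ssde(10.0, 1.5) == pytest.approx(15.0)
        assert ssde(10.0, 1.0) == pytest.approx(10.0)

    def test_nonpositive_inputs_are_fatal(self):
        with pytest.raises(ValueError):
            ssde(0.0, 1.5)
        with pytest.raises(ValueError):
            ssde(10.0, 0.0)


class TestPercentDiffs:
    @pytest.mark.parametrize(
        "new,old,expected",
        [
            (20.0, 20.0, 0.0),
            (22.0, 11.0, 100.0),
            # hand arithmetic on series means
            (27.81, 25.47, (27.81 - 25.47) / 25.47 * 100.0),
        ],
    )
    def test_dw_diff(self, new, old, expected):
        assert percent_diff_dw(new, old) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "new,old,expected",
        [
            (21.47, 21.47, 0.0),
            (15.0, 30.0, -50.0),
            (25.20, 31.92, (25.20 - 31.92) / 31.92 * 100.0),
        ],
    )
    def test_ssde_diff(self, new, old, expected):
        assert percent_diff_ssde(new, old) == pytest.approx(expected)

    def test_value_of_hand_examples(self):
        assert percent_diff_dw(27.81, 25.47) == pytest.approx(9.19, abs=0.005)
        assert percent_diff_ssde(25.20, 31.92) == pytest.approx(-21.05, abs=0.005)

    def test_nonpositive_reference_is_fatal(self):
        with pytest.raises(ValueError):
            percent_diff_dw(20.0, 0.0)
        with pytest.raises(ValueError):
            percent_diff_ssde(20.0, -1.0)
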