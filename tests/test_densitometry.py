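import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feulgen.densitometry import (
    NucleusMask,
    measure_image,
    measure_nucleus,
    measurements_to_frame,
    segment_nuclei,
)
from feulgen.image import AbsorbanceImage

from conftest import brute_force_measure, random_absorbance_image


def _img(values, pitch=0.5):
    return AbsorbanceImage(np.asarray(values, dtype=float), pixel_pitch_um=pitch, source="synthetic")


def _full_mask(shape):
    return NucleusMask.from_bool_array(np.ones(shape, dtype=bool))


class TestSegmentation:
    def test_background_rule_is_inclusive_at_threshold(self):
        # OD exactly 0.020 is background ("no higher than"); 0.021 is retained
        values = np.zeros((12, 12))
        values[2:10, 2:10] = 0.020
        assert segment_nuclei(_img(values), min_area_px=10) == []
        values[2:10, 2:10] = 0.021
        masks = segment_nuclei(_img(values), min_area_px=10)
        assert len(masks) == 1 and masks[0].area_px == 64

    def test_all_zero_image_yields_empty_list(self):
        assert segment_nuclei(_img(np.zeros((8, 8)))) == []

    def test_components_split_and_min_area_filter(self):
        values = np.zeros((20, 20))
        values[1:8, 1:8] = 0.2  # 49 px, below default 50 px filter
        values[10:19, 10:19] = 0.2  # 81 px, kept
        masks = segment_nuclei(_img(values))
        assert [m.area_px for m in masks] == [81]
        masks = segment_nuclei(_img(values), min_area_px=10)
        assert sorted(m.area_px for m in masks) == [49, 81]

    def test_eight_connectivity_joins_diagonal_touch(self):
        values = np.zeros((6, 6))
        values[0:3, 0:3] = 0.2
        values[3:6, 3:6] = 0.2
        masks = segment_nuclei(_img(values), min_area_px=1)
        assert len(masks) == 1


class TestMeasureNucleus:
    def test_four_pixel_worked_example(self):
        # ODs {0.30, 0.30, 0.05, 0.05} at 0.5 µm pitch, cutoff 0.100
        img = _img([[0.30, 0.30], [0.05, 0.05]])
        m = measure_nucleus(img, _full_mask((2, 2)))
        assert m.a_t == pytest.approx(0.70)
        assert m.s_t_um2 == pytest.approx(1.0)
        assert m.a_c == pytest.approx(0.60)
        assert m.s_c_um2 == pytest.approx(0.5)
        assert m.sc_pct == pytest.approx(50.0)
        assert m.ac_pct == pytest.approx(100 * 0.60 / 0.70)
        assert m.aar == pytest.approx((0.60 / 0.5) / (0.70 / 1.0))

    def test_homogeneous_nucleus_has_unit_aar(self):
        img = _img(np.full((10, 10), 0.15))
        m = measure_nucleus(img, _full_mask((10, 10)))
        assert m.s_t_um2 == pytest.approx(25.0)
        assert m.sc_pct == 100.0
        assert m.aar == 1.0  # exactly, by construction
        assert m.a_t == pytest.approx(15.0)

    def test_all_subcutoff_nucleus_has_undefined_aar(self):
        img = _img(np.full((8, 8), 0.05))
        m = measure_nucleus(img, _full_mask((8, 8)))
        assert m.s_c_um2 == 0.0 and m.sc_pct == 0.0
        assert math.isnan(m.aar) and not m.aar_defined

    def test_cutoff_is_strict_inequality(self):
        img = _img(np.full((4, 4), 0.100))
        m = measure_nucleus(img, _full_mask((4, 4)), cutoff=0.100)
        assert m.n_condensed_pixels == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            NucleusMask(np.empty((0, 2), dtype=int), (4, 4))


class TestOracleEquivalence:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_loop_exactly(self, seed):
        rng = np.random.default_rng(seed)
        img, mask = random_absorbance_image(rng)
        cutoff = float(rng.uniform(0.02, 0.3))
        m = measure_nucleus(img, NucleusMask.from_bool_array(mask), cutoff)
        ref = brute_force_measure(img.values, mask, cutoff, img.pixel_pitch_um)
        for name, expected in ref.items():
            got = getattr(m, name)
            if isinstance(expected, float) and math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == expected, f"{name}: {got} != {expected}"


class TestInvariants:
    def _random_case(self, rng):
        img, mask = random_absorbance_image(rng, max_side=24)
        return img, NucleusMask.from_bool_array(mask)

    def test_additivity_of_integrated_absorbance(self, rng):
        for _ in range(50):
            img, mask = self._random_case(rng)
            m = measure_nucleus(img, mask, 0.1)
            od = img.values[mask.pixels[:, 0], mask.pixels[:, 1]]
            non_condensed = math.fsum(od[od <= 0.1])
            assert m.a_t == pytest.approx(m.a_c + non_condensed, abs=1e-12)

    def test_cutoff_monotonicity(self, rng):
        for _ in range(30):
            img, mask = self._random_case(rng)
            prev = None
            for cutoff in np.linspace(0.02, 0.35, 10):
                m = measure_nucleus(img, mask, float(cutoff))
                if prev is not None:
                    assert m.s_c_um2 <= prev.s_c_um2
                    assert m.a_c <= prev.a_c
                    if m.aar_defined and prev.aar_defined:
                        assert m.aar >= prev.aar - 1e-12
                prev = m

    def test_permutation_invariance(self, rng):
        for _ in range(30):
            img, mask = self._random_case(rng)
            m1 = measure_nucleus(img, mask, 0.1)
            perm = rng.permutation(mask.area_px)
            m2 = measure_nucleus(img, NucleusMask(mask.pixels[perm], mask.image_shape), 0.1)
            assert (m1.a_t, m1.a_c, m1.s_t_um2, m1.s_c_um2) == (m2.a_t, m2.a_c, m2.s_t_um2, m2.s_c_um2)
            assert (m1.aar == m2.aar) or (math.isnan(m1.aar) and math.isnan(m2.aar))

    def test_aar_at_least_one_whenever_defined(self, rng):
        for _ in range(100):
            img, mask = self._random_case(rng)
            m = measure_nucleus(img, mask, float(rng.uniform(0.02, 0.3)))
            if m.aar_defined:
                assert m.aar >= 1.0


class TestTables:
    def test_measurement_frame_layout(self):
        img = _img(np.full((10, 10), 0.2))
        ms = measure_image(img, min_area_px=10)
        frame = measurements_to_frame(ms, image_ids=["img0"])
        assert list(frame.columns) == [
            "image_id", "nucleus_id", "A_T", "A_C", "Ac_pct", "S_T_um2",
            "S_C_um2", "Sc_pct", "AAR", "cutoff", "background_threshold",
        ]
        assert frame.loc[0, "Sc_pct"] == 100.0
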