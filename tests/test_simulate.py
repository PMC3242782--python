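import numpy as np
import pytest

from feulgen.densitometry import measure_nucleus
from feulgen.simulate import (
    DegenerateGeometryError,
    NucleusSimParams,
    PopulationPreset,
    draw_ploidy_iods,
    generate_nucleus,
    generate_population,
    generate_tunel_cell,
    truth_table,
)
from feulgen.tunel import luminance_8bit


def _params(**kw):
    defaults = dict(nucleus_radius_px=32.0, condensed_fraction=0.5, seed=42)
    defaults.update(kw)
    return NucleusSimParams(**defaults)


class TestGenerateNucleus:
    def test_determinism_bit_identical(self):
        img1, m1, t1 = generate_nucleus(_params())
        img2, m2, t2 = generate_nucleus(_params())
        np.testing.assert_array_equal(img1.values, img2.values)
        np.testing.assert_array_equal(m1.pixels, m2.pixels)
        assert t1 == t2

    def test_different_seeds_differ(self):
        img1, _, _ = generate_nucleus(_params(seed=1))
        img2, _, _ = generate_nucleus(_params(seed=2))
        assert not np.array_equal(img1.values, img2.values)

    def test_zero_fraction_noise_free_is_uniform_diffuse(self):
        img, mask, truth = generate_nucleus(
            _params(condensed_fraction=0.0, od_diffuse=0.05, od_noise_sd=0.0)
        )
        in_mask = img.values[mask.to_bool_array()]
        assert np.all(in_mask == 0.05)
        assert truth.true_condensed_fraction == 0.0
        m = measure_nucleus(img, mask)
        assert m.sc_pct == 0.0

    def test_full_fraction_noise_free_is_uniform_condensed(self):
        img, mask, truth = generate_nucleus(
            _params(condensed_fraction=1.0, od_condensed=0.30, od_noise_sd=0.0)
        )
        in_mask = img.values[mask.to_bool_array()]
        assert np.all(in_mask == 0.30)
        assert truth.true_condensed_fraction == 1.0
        m = measure_nucleus(img, mask)
        assert m.sc_pct == 100.0 and m.aar == 1.0

    def test_out_of_mask_pixels_are_zero(self):
        img, mask, _ = generate_nucleus(_params())
        assert np.all(img.values[~mask.to_bool_array()] == 0.0)

    @pytest.mark.parametrize("fraction", [0.2, 0.5, 0.8])
    def test_realized_fraction_tracks_request(self, fraction):
        _, _, truth = generate_nucleus(_params(condensed_fraction=fraction))
        assert abs(truth.true_condensed_fraction - fraction) <= 0.02

    def test_truth_fraction_is_realized_count(self):
        img, mask, truth = generate_nucleus(_params(od_noise_sd=0.0))
        in_mask = img.values[mask.to_bool_array()]
        realized = np.mean(in_mask == 0.30)
        assert truth.true_condensed_fraction == realized

    def test_target_iod_rescaling_within_tolerance(self):
        img, mask, truth = generate_nucleus(_params(target_iod=123.4))
        got = img.values[mask.to_bool_array()].sum()
        assert abs(got - 123.4) / 123.4 < 1e-3
        assert truth.true_iod == pytest.approx(123.4, rel=1e-3)

    def test_nuclear_area_in_um2(self):
        _, mask, truth = generate_nucleus(_params())
        assert truth.true_nuclear_area_um2 == mask.area_px * 0.25

    def test_degenerate_radius_raises(self):
        with pytest.raises(DegenerateGeometryError):
            generate_nucleus(_params(nucleus_radius_px=1.5))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            _params(condensed_fraction=1.2)
        with pytest.raises(ValueError):
            _params(od_diffuse=0.3, od_condensed=0.2)
        with pytest.raises(ValueError):
            _params(target_iod=-1.0)


class TestGeneratePopulation:
    def test_reproducible_and_sized(self):
        pop1 = generate_population("control", 3, seed=1)
        pop2 = generate_population("control", 3, seed=1)
        assert len(pop1) == 3
        for (i1, _, t1), (i2, _, t2) in zip(pop1, pop2):
            np.testing.assert_array_equal(i1.values, i2.values)
            assert t1 == t2

    def test_preset_ordering_of_condensed_fraction(self):
        ctrl = generate_population("control", 60, seed=5)
        dec = generate_population("decondensed", 60, seed=6)
        mean = lambda pop: np.mean([t.true_condensed_fraction for _, _, t in pop])
        assert mean(dec) < mean(ctrl)

    def test_n_zero_and_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            generate_population("control", 0, seed=1)
        with pytest.raises(ValueError, match="unknown preset"):
            generate_population("loosened", 3, seed=1)

    def test_overrides_and_explicit_recipe(self):
        pop = generate_population(
            "control", 5, seed=2, overrides={"radius_mean_px": 32.0, "od_noise_sd": 0.0}
        )
        assert all(t.params.od_noise_sd == 0.0 for _, _, t in pop)
        recipe = PopulationPreset(condensed_fraction_median=0.5)
        assert len(generate_population(recipe, 2, seed=3)) == 2

    def test_target_iods_are_honored(self):
        iods = [100.0, 150.0, 200.0]
        pop = generate_population("control", 3, seed=4, target_iods=iods)
        for (img, mask, truth), want in zip(pop, iods):
            assert truth.true_iod == pytest.approx(want, rel=1e-3)

    def test_truth_table_layout(self):
        pop = generate_population("control", 4, seed=9)
        table = truth_table([t for _, _, t in pop])
        assert list(table.columns) == [
            "id", "seed", "true_condensed_fraction", "true_iod", "true_nuclear_area_um2",
        ]
        assert len(table) == 4


class TestPloidyMixture:
    def test_mixture_components_and_spread(self):
        rng = np.random.default_rng(0)
        iods = draw_ploidy_iods(3000, 100.0, rng)
        ratios = iods / 100.0
        assert iods.min() > 0
        # 70/20/10 weights at multipliers {1, 1.5, 2} with 5% relative spread
        assert np.mean(np.abs(ratios - 1.0) < 0.25) == pytest.approx(0.70, abs=0.05)
        assert np.mean(np.abs(ratios - 2.0) < 0.35) == pytest.approx(0.10, abs=0.03)


class TestTunelCell:
    def test_spot_luminance_inside_window_nucleus_outside(self):
        img, rel, rank = generate_tunel_cell(0.3, 30, seed=1)
        lum = luminance_8bit(img)
        spot_lums = np.unique(lum[(lum >= 60) & (lum <= 100)])
        assert spot_lums.size == 1  # single flat spot tone
        assert rank == "moderate"

    def test_zero_coverage_is_negative_with_no_window_pixels(self):
        img, rel, rank = generate_tunel_cell(0.0, 30, seed=2)
        lum = luminance_8bit(img)
        assert rel == 0.0 and rank == "negative"
        assert not np.any((lum >= 60) & (lum <= 100))

    @pytest.mark.parametrize(
        "coverage,expected_rank",
        [(0.03, "weak"), (0.2, "moderate"), (0.6, "strong")],
    )
    def test_true_rank_follows_classification_rule(self, coverage, expected_rank):
        _, rel, rank = generate_tunel_cell(coverage, 30, seed=3)
        assert rank == expected_rank
        assert abs(rel / 100.0 - coverage) <= 0.02

    def test_determinism(self):
        img1, *_ = generate_tunel_cell(0.4, 30, seed=7)
        img2, *_ = generate_tunel_cell(0.4, 30, seed=7)
        np.testing.assert_array_equal(img1, img2)

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            generate_tunel_cell(1.5, 30, seed=0)
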