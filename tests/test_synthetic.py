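"""Simulator contracts: determinism, geometry, composition, rendering,
cohorts and nerve sections."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from fibremorph.synthetic import (
    CohortDesign,
    FibreMap,
    FibreSpec,
    IntensityModel,
    NerveSpec,
    assign_fibre_types,
    collagen_band_for_fraction,
    generate_cohort,
    generate_fibre_geometry,
    generate_nerve_image,
    random_nerve_spec,
    render_channels,
    simulate_image,
    simulate_metric_table,
)


def square_map(n: int, side: float = 5.0, gap: float = 5.0) -> FibreMap:
    """Grid of n small square fibres (cheap stand-in for a tessellation)."""
    per_row = int(np.ceil(np.sqrt(n)))
    pitch = side + gap
    fibres = []
    for k in range(n):
        r, c = divmod(k, per_row)
        x0, y0 = gap + c * pitch, gap + r * pitch
        fibres.append(FibreSpec(Polygon([(x0, y0), (x0 + side, y0),
                                         (x0 + side, y0 + side), (x0, y0 + side)])))
    extent = int(np.ceil(gap + per_row * pitch))
    return FibreMap(fibres=fibres, width_px=max(extent, 64), height_px=max(extent, 64),
                    pixel_size=1.0, collagen_band=gap, seed=0)


class TestGeometry:
    def test_deterministic_for_fixed_seed(self):
        kwargs = dict(width_px=256, height_px=256, mean_fibre_diameter=60.0,
                      pixel_size=0.5, collagen_band=4.0, seed=1)
        a = generate_fibre_geometry(**kwargs)
        b = generate_fibre_geometry(**kwargs)
        assert [f.polygon.wkt for f in a.fibres] == [f.polygon.wkt for f in b.fibres]

    def test_zero_band_covers_interior(self):
        fmap = generate_fibre_geometry(256, 256, 40.0, 1.0, collagen_band=0.0, seed=2)
        assign_fibre_types(fmap, 0.5, seed=0)
        _, truth = render_channels(fmap, IntensityModel(noise_sd=0, blur_sigma=0), seed=0)
        assert (truth.label_image > 0).mean() >= 0.99

    def test_collagen_fraction_monotone_in_band_width(self):
        fractions = []
        for band in (2.0, 4.0, 8.0):
            fmap = generate_fibre_geometry(256, 256, 50.0, 1.0, band, seed=3)
            assign_fibre_types(fmap, 0.5, seed=0)
            _, truth = render_channels(fmap, IntensityModel(noise_sd=0, blur_sigma=0),
                                       seed=0)
            fractions.append(truth.collagen_pct)
        assert fractions[0] < fractions[1] < fractions[2]

    def test_preconditions_rejected(self):
        with pytest.raises(ValueError):
            generate_fibre_geometry(32, 256, 40.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            generate_fibre_geometry(256, 256, 3.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            generate_fibre_geometry(256, 256, 40.0, 1.0, collagen_band=25.0)


class TestAssignTypes:
    def test_all_fast_when_slow_and_hybrid_zero(self):
        fmap = square_map(50)
        assign_fibre_types(fmap, slow_fraction=0.0, hybrid_fraction=0.0, seed=1)
        assert fmap.class_counts() == {"slow": 0, "fast": 50, "hybrid": 0}
        assert fmap.true_ftr == 0.0

    def test_all_hybrid_gives_undefined_ftr(self):
        fmap = square_map(30)
        assign_fibre_types(fmap, slow_fraction=0.0, hybrid_fraction=1.0, seed=1)
        counts = fmap.class_counts()
        assert counts["hybrid"] == 30
        assert np.isnan(fmap.true_ftr)

    def test_realised_slow_proportion_within_binomial_band(self):
        # 99% binomial interval at n = 10000, p = 0.5 is +/- 0.013
        fmap = square_map(10_000, side=2.0, gap=1.0)
        assign_fibre_types(fmap, slow_fraction=0.5, hybrid_fraction=0.0, seed=7)
        counts = fmap.class_counts()
        assert abs(counts["slow"] / 10_000 - 0.5) <= 0.015

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError):
            assign_fibre_types(square_map(4), 0.8, 0.4)


class TestRendering:
    def test_noiseless_slow_fibre_pixels_equal_class_mean(self, noiseless_sim):
        image, truth = noiseless_sim
        model = IntensityModel()
        slow_ids = truth.fibres.loc[truth.fibres.true_class == "slow", "fibre_id"]
        region = np.isin(truth.label_image, slow_ids)
        assert (image["slow"][region] == model.slow_mean).all()
        assert (image["fast"][region] == model.background).all()

    def test_pixel_partition_is_exact(self, noiseless_sim):
        _, truth = noiseless_sim
        fibre_mask = truth.label_image > 0
        assert not (fibre_mask & truth.collagen_mask).any()
        assert (fibre_mask | truth.collagen_mask).all()

    def test_ground_truth_ftr_matches_label_counting(self, noiseless_sim):
        _, truth = noiseless_sim
        counts = truth.fibres["true_class"].value_counts()
        assert truth.ftr() == counts.get("slow", 0) / counts.get("fast", 1)

    def test_fibre_mean_intensities_separate_classes(self, default_sim):
        image, truth = default_sim
        means = {
            cls: [image["slow"][truth.label_image == fid].mean()
                  for fid in truth.fibres.loc[truth.fibres.true_class == cls, "fibre_id"]]
            for cls in ("slow", "fast")
        }
        assert min(means["slow"]) > max(means["fast"])

    def test_unresolvable_contrast_refused(self):
        fmap = square_map(9)
        assign_fibre_types(fmap, 0.5, seed=0)
        weak = IntensityModel(slow_mean=20, fast_mean=20, collagen_mean=20,
                              background=10, noise_sd=15)
        with pytest.raises(ValueError, match="unresolvable contrast"):
            render_channels(fmap, weak)

    def test_simulate_image_bitwise_deterministic(self):
        a, ta = simulate_image(128, 128, 0.4, 0.05, seed=5, mean_fibre_diameter=30.0)
        b, tb = simulate_image(128, 128, 0.4, 0.05, seed=5, mean_fibre_diameter=30.0)
        for name in a.channels:
            np.testing.assert_array_equal(a[name], b[name])
        np.testing.assert_array_equal(ta.label_image, tb.label_image)
        pd.testing.assert_frame_equal(ta.fibres, tb.fibres)


class TestCohort:
    small = dict(width_px=64, height_px=64, mean_fibre_diameter=12.0,
                 pixel_size=1.0, intensity=IntensityModel(blur_sigma=0.5))

    def test_metadata_row_count(self):
        design = CohortDesign(groups={"A": 2, "B": 2}, sides=("nPCA",),
                              regions=("PCA+",), images_per_condition=2,
                              seed=1, **self.small)
        bundle = generate_cohort(design)
        assert len(bundle.metadata) == 2 * 2 * 2
        assert set(bundle.images) == set(bundle.metadata.image_id)

    def test_zero_animal_sd_gives_common_expected_ftr(self):
        design = CohortDesign(groups={"A": 3}, sides=("nPCA",), regions=("PCA+",),
                              images_per_condition=1, animal_sd=0.0, base_ftr=0.8,
                              seed=2, **self.small)
        bundle = generate_cohort(design)
        assert np.allclose(bundle.metadata["target_ftr"], 0.8)

    def test_animal_sd_recovered_from_intercepts(self):
        # chi-square 99% interval for the sd at n = 20 and sigma = 0.3
        design = CohortDesign(groups={"A": 20}, sides=("nPCA",), regions=("PCA+",),
                              images_per_condition=1, animal_sd=0.3, base_ftr=0.5,
                              seed=3, **self.small)
        bundle = generate_cohort(design)
        intercepts = np.log(bundle.metadata["target_ftr"] / 0.5)
        assert 0.18 <= intercepts.std(ddof=1) <= 0.45

    def test_cohort_reproducible_from_seed(self):
        design = CohortDesign(groups={"A": 1}, sides=("nPCA",), regions=("PCA+",),
                              images_per_condition=1, seed=9, **self.small)
        m1 = generate_cohort(design).metadata
        m2 = generate_cohort(design).metadata
        pd.testing.assert_frame_equal(m1, m2)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(groups={"A": 0})
        with pytest.raises(ValueError):
            CohortDesign(hybrid_fraction=1.5)
        with pytest.raises(ValueError):
            CohortDesign(base_ftr=-1.0)


class TestNerve:
    def test_overall_diameter_identity(self):
        spec = NerveSpec(axons=[(20.0, 20.0, 6.0, 2.0)], width_um=40, height_um=40)
        assert spec.table.loc[0, "od_um"] == pytest.approx(10.0)

    def test_zero_myelin_renders_no_annulus(self):
        spec = NerveSpec(axons=[(20.0, 20.0, 6.0, 0.0)], width_um=40, height_um=40)
        img, gt = generate_nerve_image(spec, pixel_size=0.1, seed=0)
        assert gt.loc[0, "od_um"] == gt.loc[0, "ad_um"]
        assert not (img < 100).any()  # no myelin-dark pixels

    def test_annulus_area_matches_closed_form(self):
        ad, mt = 6.0, 2.0
        spec = NerveSpec(axons=[(20.0, 20.0, ad, mt)], width_um=40, height_um=40)
        from fibremorph.synthetic import NerveIntensityModel
        img, _ = generate_nerve_image(spec, pixel_size=0.1, seed=0,
                                      model=NerveIntensityModel(noise_sd=0))
        od = ad + 2 * mt
        annulus_px = int((img == 60).sum())
        expected = np.pi * ((od / 2) ** 2 - (ad / 2) ** 2) / 0.1 ** 2
        assert annulus_px == pytest.approx(expected, rel=0.05)

    def test_overlapping_axons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            NerveSpec(axons=[(20.0, 20.0, 6.0, 2.0), (25.0, 20.0, 6.0, 2.0)],
                      width_um=40, height_um=40)

    def test_out_of_bounds_axon_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            NerveSpec(axons=[(2.0, 2.0, 6.0, 2.0)], width_um=40, height_um=40)

    def test_random_spec_is_valid_and_sized(self):
        spec = random_nerve_spec(n_axons=20, seed=1)
        assert len(spec.axons) == 20


class TestMetricTable:
    def test_shape_and_conditions(self):
        t = simulate_metric_table(n_conditions=3, animals_per_condition=4,
                                  images_per_animal=2, seed=0)
        assert len(t) == 3 * 4 * 2
        assert t["condition"].nunique() == 3

    def test_crossed_design_shares_animals(self):
        t = simulate_metric_table(n_conditions=2, animals_per_condition=4,
                                  images_per_animal=2, crossed=True, seed=0)
        per_cond = t.groupby("condition")["animal"].unique()
        assert set(per_cond.iloc[0]) == set(per_cond.iloc[1])

    def test_effect_shifts_condition_mean(self):
        t = simulate_metric_table(2, 50, 4, effect=1.0, animal_sd=0.1,
                                  residual_sd=0.1, seed=1)
        means = t.groupby("condition")["value"].mean()
        assert means["G2"] - means["G1"] == pytest.approx(1.0, abs=0.1)


def test_collagen_band_inverts_fraction():
    assert collagen_band_for_fraction(0.1, 60.0) == pytest.approx(3.0)
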