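"""Imaging pipeline against generator ground truth: classification,
channel measurement, segmentation, profiles, biomass estimator."""

import numpy as np
import pandas as pd
import pytest

from macropore.imaging import (
    INVALID,
    SEMI_DISC,
    SOLID,
    ChannelExtractionError,
    add_entrance_distance,
    biomass_increase_from_images,
    classify_disc,
    colony_size_profile,
    extract_channel,
    segment_colonies,
)
from macropore.synth import (
    SyntheticImageSpec,
    generate_baseline_set,
    generate_micrograph,
    mean_area_model,
)

PX = SyntheticImageSpec().pixel_size_um


@pytest.fixture(scope="module")
def solid_fixture():
    spec = SyntheticImageSpec(seed=5)
    img, truth, _ = generate_micrograph(spec)
    return spec, img, truth


class TestClassification:
    def test_perfect_solid_disc(self, solid_fixture):
        _, img, _ = solid_fixture
        cls = classify_disc(img, PX)
        assert cls.label == SOLID
        assert cls.circularity > 0.95
        assert cls.elongation < 1.05

    def test_all_bisected_discs_classified_as_semi(self, semi_fixtures):
        for angle, (spec, img, truth, chan) in semi_fixtures.items():
            cls = classify_disc(img, PX)
            assert cls.label == SEMI_DISC, f"angle {angle}"

    def test_blank_frame_is_invalid(self):
        rng = np.random.default_rng(0)
        blank = rng.normal(3000, 60, (400, 400)).astype(np.uint16)
        cls = classify_disc(blank, PX)
        assert cls.label == INVALID

    def test_merged_shifted_semi_discs_are_invalid(self, semi_fixtures):
        spec, img, _, _ = semi_fixtures[0.0]
        # slide the lower half up so the semi-discs merge
        merged = img.copy()
        shift = int(round(spec.channel_width_um / PX))
        merged[shift:, :] = np.maximum(merged[shift:, :], img[:-shift, :])
        cls = classify_disc(merged, PX)
        assert cls.label == INVALID


class TestChannel:
    def test_angle_width_and_length_recovered(self, semi_fixtures):
        errors = []
        for angle, (spec, img, truth, chan_truth) in semi_fixtures.items():
            cls = classify_disc(img, PX)
            m = extract_channel(img, cls, PX)
            errors.append(abs(m.angle_deg - angle))
            assert m.width_um == pytest.approx(400.0, rel=0.10)
        assert np.mean(errors) <= 5.0  # mean absolute angle error

    def test_narrow_inline_channel_spans_the_disc(self):
        spec = SyntheticImageSpec(channel_width_um=200.0, channel_angle_deg=0.0, seed=11)
        img, _, _ = generate_micrograph(spec)
        cls = classify_disc(img, PX)
        m = extract_channel(img, cls, PX)
        assert m.length_um == pytest.approx(spec.disc_diameter_um, rel=0.10)

    def test_ninety_degrees_folds_to_ninety(self, semi_fixtures):
        spec, img, _, _ = semi_fixtures[90.0]
        cls = classify_disc(img, PX)
        m = extract_channel(img, cls, PX)
        assert m.angle_deg == pytest.approx(90.0, abs=5.0)

    def test_solid_disc_rejected(self, solid_fixture):
        _, img, _ = solid_fixture
        cls = classify_disc(img, PX)
        with pytest.raises(ChannelExtractionError):
            extract_channel(img, cls, PX)


class TestSegmentation:
    def test_count_and_total_area_within_tolerance(self):
        # non-overlapping colonies of uniform mean size
        spec = SyntheticImageSpec(
            colony_density_per_mm2=30.0, decay_length_um=1e9, base_area_um2=1500.0, seed=21
        )
        img, truth, _ = generate_micrograph(spec)
        cls = classify_disc(img, PX)
        col = segment_colonies(img, cls.mask, PX)
        assert len(col) == pytest.approx(len(truth), rel=0.05)
        assert col.area_um2.sum() == pytest.approx(truth.area_um2.sum(), rel=0.10)

    def test_blank_background_has_no_colonies(self):
        spec = SyntheticImageSpec(colony_density_per_mm2=0.0, seed=13)
        img, _, _ = generate_micrograph(spec)
        cls = classify_disc(img, PX)
        col = segment_colonies(img, cls.mask, PX)
        assert len(col) == 0

    def test_intensity_scale_invariance(self, solid_fixture):
        _, img, _ = solid_fixture
        cls = classify_disc(img, PX)
        a = segment_colonies(img.astype(float), cls.mask, PX)
        b = segment_colonies(img.astype(float) * 1.7, cls.mask, PX)
        assert len(a) == len(b)

    def test_touching_equal_colonies_are_split_by_watershed(self):
        img = np.full((200, 200), 3000.0)
        yy, xx = np.mgrid[0:200, 0:200]
        for cx in (88, 112):  # two discs touching at x = 100
            img[np.hypot(xx - cx, yy - 100) <= 12.5] = 30000.0
        mask = np.ones_like(img, dtype=bool)
        col = segment_colonies(img, mask, pixel_size_um=1.0, background_radius_um=40.0)
        assert len(col) == 2


class TestProfiles:
    def test_uniform_sizes_give_flat_profile(self):
        spec = SyntheticImageSpec(
            channel_width_um=400.0,
            channel_angle_deg=0.0,
            decay_length_um=1e9,
            base_area_um2=1500.0,
            colony_density_per_mm2=30.0,
            seed=31,
        )
        img, truth, _ = generate_micrograph(spec)
        cls = classify_disc(img, PX)
        chan = extract_channel(img, cls, PX)
        col = add_entrance_distance(segment_colonies(img, cls.mask, PX), chan)
        prof = colony_size_profile(col, bin_width_um=750.0)
        good = prof[prof.n >= 8]
        assert good.mean_area_um2.max() < 1.35 * good.mean_area_um2.min()

    def test_perpendicular_channel_gives_u_shaped_profile(self):
        # exposed walls, no skew: large at both mouths, small mid-disc
        spec = SyntheticImageSpec(
            channel_width_um=400.0,
            channel_angle_deg=90.0,
            channel_walls_exposed=True,
            colony_density_per_mm2=80.0,
            seed=33,
        )
        img, truth, _ = generate_micrograph(spec)
        cls = classify_disc(img, PX)
        chan = extract_channel(img, cls, PX)
        col = add_entrance_distance(segment_colonies(img, cls.mask, PX), chan)
        prof = colony_size_profile(col, bin_width_um=600.0)
        v = prof.mean_area_um2.to_numpy()
        assert v[0] > v[len(v) // 2] and v[-1] > v[len(v) // 2]

    def test_inline_channel_profile_decays_from_the_entrance(self):
        spec = SyntheticImageSpec(
            channel_width_um=400.0,
            channel_angle_deg=0.0,
            entrance_skew=2.5,
            channel_walls_exposed=True,
            colony_density_per_mm2=80.0,
            seed=35,
        )
        img, truth, _ = generate_micrograph(spec)
        cls = classify_disc(img, PX)
        chan = extract_channel(img, cls, PX)
        col = add_entrance_distance(segment_colonies(img, cls.mask, PX), chan)
        prof = colony_size_profile(col, bin_width_um=600.0)
        v = prof.mean_area_um2.to_numpy()
        half = len(v) // 2 + 1
        assert all(a > b for a, b in zip(v[:half], v[1:half]))

    def test_empty_table_gives_empty_profile(self):
        assert colony_size_profile(pd.DataFrame()).empty


def _implanted_fixture(excess_total, seed=42):
    spots = [(900, 150), (1200, 250), (1500, 120), (1000, 300), (1800, 200), (1350, 100)]
    anoms = (
        tuple((s, off, excess_total / len(spots)) for s, off in spots)
        if excess_total > 0
        else ()
    )
    return SyntheticImageSpec(
        channel_width_um=400.0, channel_angle_deg=90.0, anomalous=anoms, seed=seed
    )


def _ground_truth_pct(spec, truth):
    mu = mean_area_model(spec, truth.x_um.to_numpy(), truth.y_um.to_numpy())
    excess = np.where(truth.anomalous, truth.area_um2 - mu, 0.0).sum()
    total = truth.area_um2.sum()
    return 100.0 * total / (total - excess) - 100.0


class TestBiomassEstimator:
    @pytest.mark.parametrize("excess_total", [0.0, 7000.0, 14000.0, 28000.0])
    def test_recovery_within_two_points(self, excess_total, baseline_tables):
        spec = _implanted_fixture(excess_total)
        img, truth, _ = generate_micrograph(spec)
        cls = classify_disc(img, PX)
        semi = segment_colonies(img, cls.mask, PX)
        res = biomass_increase_from_images(semi, baseline_tables)
        assert res.percent == pytest.approx(_ground_truth_pct(spec, truth), abs=2.0)

    def test_flag_precision_on_default_fixture(self, baseline_tables):
        spec = _implanted_fixture(14000.0)
        img, truth, _ = generate_micrograph(spec)
        cls = classify_disc(img, PX)
        semi = segment_colonies(img, cls.mask, PX)
        res = biomass_increase_from_images(semi, baseline_tables)
        flagged = res.colonies[res.colonies.anomalous]
        assert len(flagged) > 0
        half_um = 0.6 * spec.disc_diameter_um
        implanted = truth[truth.anomalous]
        hits = 0
        for _, row in flagged.iterrows():
            d = np.hypot(
                implanted.x_um + half_um - row.x_um, implanted.y_um + half_um - row.y_um
            )
            hits += int(d.min() < 60.0)
        assert hits / len(flagged) >= 0.8

    def test_null_case_is_near_zero(self, baseline_tables):
        spec = _implanted_fixture(0.0, seed=55)
        img, _, _ = generate_micrograph(spec)
        cls = classify_disc(img, PX)
        semi = segment_colonies(img, cls.mask, PX)
        res = biomass_increase_from_images(semi, baseline_tables)
        assert abs(res.percent) < 1.0

    def test_multi_depth_average(self, baseline_tables):
        from macropore.imaging import biomass_increase_multi_depth

        spec = _implanted_fixture(14000.0)
        img, _, _ = generate_micrograph(spec)
        cls = classify_disc(img, PX)
        semi = segment_colonies(img, cls.mask, PX)
        single = biomass_increase_from_images(semi, baseline_tables).percent
        avg = biomass_increase_multi_depth(
            [semi, semi], [baseline_tables, baseline_tables]
        )
        assert avg == pytest.approx(single, rel=1e-12)

    def test_insufficient_baselines_rejected(self):
        with pytest.raises(ValueError):
            biomass_increase_from_images(
                pd.DataFrame({"dist_edge_um": [1.0], "area_um2": [10.0]}),
                [pd.DataFrame({"dist_edge_um": [1.0], "area_um2": [10.0]})],
            )
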