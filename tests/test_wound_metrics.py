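"""Cluster detection and metrics, vessel partition, homogeneity, time series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumiwound.roi_tools import ROI
from lumiwound.synthetic_wound import (
    WoundSimConfig,
    simulate_droplet_matrix,
    simulate_ros_field,
    simulate_wound,
)
from lumiwound.wound_metrics import (
    Cluster,
    ClusterSet,
    MetricsError,
    avg_integrated_density,
    cluster_density,
    detect_clusters,
    droplet_grid_analysis,
    intensity_time_series,
    vessel_association,
    vessel_mask_from_whitelight,
    vessel_partition,
)

from conftest import make_image


def _gauss(shape, center, amp, sigma):
    rr, cc = np.indices(shape)
    return amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


def _full_roi(shape):
    return ROI(mask=np.ones(shape, bool))


class TestDetectClusters:
    def test_three_gaussian_peaks(self):
        shape = (60, 60)
        field = np.full(shape, 5.0)
        for center, amp in (((15, 15), 100), ((15, 45), 95), ((45, 30), 90)):
            field += _gauss(shape, center, amp, 3.0)
        cs = detect_clusters(make_image(field), _full_roi(shape))
        assert len(cs) == 3
        assert cs.threshold_au == pytest.approx(0.7 * field.max())

    def test_uniform_image_is_one_cluster(self):
        shape = (20, 20)
        cs = detect_clusters(make_image(np.full(shape, 8.0)), _full_roi(shape))
        assert len(cs) == 1
        assert cs.clusters[0].mask.sum() == 400

    def test_flat_zero_flags_no_signal(self):
        cs = detect_clusters(make_image(np.zeros((10, 10))), _full_roi((10, 10)))
        assert len(cs) == 0
        assert cs.no_signal
        assert cs.threshold_au == 0.0

    def test_min_area_suppresses_specks(self):
        field = np.zeros((20, 20))
        field[5, 5] = 100.0  # single-pixel spike
        field[10:13, 10:13] = 90.0  # 9-px block above 70
        cs = detect_clusters(make_image(field), _full_roi((20, 20)), min_area_px=4)
        assert len(cs) == 1
        assert cs.clusters[0].mask[11, 11]

    def test_threshold_outside_unit_interval_rejected(self):
        img = make_image(np.ones((5, 5)))
        with pytest.raises(MetricsError):
            detect_clusters(img, _full_roi((5, 5)), threshold_fraction=1.0)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.01, 100.0), st.integers(0, 10**6))
    def test_scale_invariance(self, a, seed):
        rng = np.random.default_rng(seed)
        field = rng.uniform(0, 50, (25, 25))
        roi = _full_roi((25, 25))
        cs1 = detect_clusters(make_image(field), roi)
        cs2 = detect_clusters(make_image(field * a), roi)
        assert len(cs1) == len(cs2)
        for c1, c2 in zip(cs1.clusters, cs2.clusters):
            np.testing.assert_array_equal(c1.mask, c2.mask)

    @pytest.mark.parametrize("seed", range(3))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        field = rng.uniform(0, 50, (30, 30))
        roi = _full_roi((30, 30))
        areas = []
        for frac in (0.5, 0.6, 0.7, 0.8, 0.9):
            cs = detect_clusters(make_image(field), roi, threshold_fraction=frac, min_area_px=1)
            areas.append(sum(c.mask.sum() for c in cs.clusters))
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_masks_disjoint_and_inside_wound(self, one_wound):
        lum = one_wound.images[3][1]
        cs = detect_clusters(lum, one_wound.wound_roi)
        total = np.zeros(lum.shape, int)
        for c in cs.clusters:
            total += c.mask
            assert np.all(one_wound.wound_roi.mask[c.mask])
        assert total.max() <= 1


class TestClusterMetrics:
    def _cs(self, clusters, area_cm2=7.07):
        return ClusterSet(
            clusters=tuple(clusters),
            wound_area_cm2=area_cm2,
            threshold_au=70.0,
            threshold_fraction=0.7,
        )

    def _cluster(self, total, area):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        return Cluster(
            mask=mask, area_mm2=area, total_intensity_au=total, peak_au=total, centroid_mm=(0, 0)
        )

    def test_density_on_three_cm_wound(self):
        cs = self._cs([self._cluster(1, 1)] * 6, area_cm2=np.pi * 1.5**2)
        assert cluster_density(cs) == pytest.approx(6 / 7.0686, abs=1e-3)
        assert cluster_density(cs) == pytest.approx(0.849, abs=1e-3)

    def test_density_of_empty_set_is_zero(self):
        assert cluster_density(self._cs([])) == 0.0

    def test_density_halves_with_double_area(self):
        cs1 = self._cs([self._cluster(1, 1)] * 4, area_cm2=5.0)
        cs2 = self._cs([self._cluster(1, 1)] * 4, area_cm2=10.0)
        assert cluster_density(cs1) == pytest.approx(2 * cluster_density(cs2))

    def test_integrated_density_single(self):
        assert avg_integrated_density(self._cs([self._cluster(500.0, 2.0)])) == 250.0

    def test_integrated_density_unweighted_mean(self):
        cs = self._cs([self._cluster(100.0, 1.0), self._cluster(900.0, 3.0)])
        assert avg_integrated_density(cs) == pytest.approx(200.0)
        assert avg_integrated_density(cs, area_weighted=True) == pytest.approx(250.0)

    def test_uniform_cluster_closed_form(self):
        # uniform intensity v over n pixels of area a: density = v / a
        field = np.zeros((10, 10))
        field[2:6, 2:6] = 40.0
        cs = detect_clusters(make_image(field, pixel_size_mm=0.5), _full_roi((10, 10)))
        assert avg_integrated_density(cs) == pytest.approx(40.0 / 0.25)

    def test_empty_set_errors(self):
        with pytest.raises(MetricsError):
            avg_integrated_density(self._cs([]))


class TestVesselPartition:
    def test_empty_vessel_mask_all_far(self):
        wound = _full_roi((10, 10))
        part = vessel_partition(np.zeros((10, 10), bool), wound, 1.0)
        assert part.far_mask.sum() == 100
        assert part.near_mask.sum() == 0

    def test_vertical_line_cutoff_in_pixels(self):
        vessel = np.zeros((11, 21), bool)
        vessel[:, 10] = True
        part = vessel_partition(vessel, _full_roi((11, 21)), pixel_size_mm=0.5)
        # 2.5 mm at 0.5 mm/px: far begins 5 px from the vessel column
        assert not part.far_mask[:, 10:15].any()
        assert part.far_mask[:, 15:].all()
        assert np.all(part.distance_map_mm[vessel] == 0)

    def test_partition_tiles_wound_exactly(self, one_wound):
        part = vessel_partition(
            one_wound.vessel_mask, one_wound.wound_roi, one_wound.config.pixel_size_mm
        )
        np.testing.assert_array_equal(
            part.far_mask | part.near_mask, one_wound.wound_roi.mask
        )
        assert not (part.far_mask & part.near_mask).any()

    @pytest.mark.parametrize("seed", range(3))
    def test_distance_map_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        vessel = rng.random((15, 15)) > 0.9
        if not vessel.any():
            vessel[7, 7] = True
        part = vessel_partition(vessel, _full_roi((15, 15)), 1.0)
        vr, vc = np.nonzero(vessel)
        for r in range(15):
            for c in range(15):
                d = np.min(np.hypot(r - vr, c - vc))
                assert part.distance_map_mm[r, c] == pytest.approx(d, rel=1e-9)


class TestVesselAssociation:
    def test_constant_intensity_ratio_one(self):
        vessel = np.zeros((20, 20), bool)
        vessel[:, 0] = True
        part = vessel_partition(vessel, _full_roi((20, 20)), 1.0)
        near, far, ratio = vessel_association(make_image(np.full((20, 20), 6.0)), part)
        assert (near, far, ratio) == (6.0, 6.0, 1.0)

    def test_zero_near_signal_is_degenerate(self):
        vessel = np.zeros((20, 20), bool)
        vessel[:, 0] = True
        part = vessel_partition(vessel, _full_roi((20, 20)), 1.0)
        field = np.where(part.far_mask, 5.0, 0.0)
        with pytest.raises(MetricsError):
            vessel_association(make_image(field), part)

    def test_noiseless_enhancement_recovered_exactly(self):
        cfg = WoundSimConfig(noise_sd_au=0.0)
        rng = np.random.default_rng(0)
        vessel = np.zeros(cfg.grid_shape, bool)
        vessel[:, 84] = True
        img, _ = simulate_ros_field(cfg, vessel, day=3, rng=rng, peaks=())
        wound = ROI(mask=cfg.wound_mask())
        part = vessel_partition(vessel, wound, cfg.pixel_size_mm, cfg.capillary_cutoff_mm)
        _, _, ratio = vessel_association(img, part)
        assert ratio == pytest.approx(2.0, rel=1e-9)


class TestVesselSegmentation:
    def test_dark_line_detected(self):
        rng = np.random.default_rng(0)
        px = np.full((100, 100), 150.0)
        px[:, 48:50] = 80.0  # 2 px = 0.5 mm at 0.25 mm/px
        px += rng.normal(0, 4, (100, 100))
        img = make_image(np.clip(px, 0, None), pixel_size_mm=0.25, modality="whitelight")
        mask = vessel_mask_from_whitelight(img)
        line = np.zeros((100, 100), bool)
        line[:, 48:50] = True
        assert (mask & line).sum() / line.sum() >= 0.8
        assert (mask & ~line).sum() / (~line).sum() <= 0.05

    def test_constant_image_empty_mask(self):
        img = make_image(np.full((50, 50), 100.0), modality="whitelight")
        assert not vessel_mask_from_whitelight(img).any()

    def test_luminescence_input_rejected(self):
        with pytest.raises(MetricsError):
            vessel_mask_from_whitelight(make_image(np.ones((10, 10))))

    def test_dice_against_generator_ground_truth(self, one_wound):
        mask = vessel_mask_from_whitelight(one_wound.images[3][0])
        truth = one_wound.vessel_mask
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.6


class TestDropletGrid:
    def test_uniform_matrix_is_homogeneous(self):
        img = simulate_droplet_matrix(3, 3, noise_sd_au=0.0, spot_intensity_cv=0.0)
        rep = droplet_grid_analysis(img, 3, 3)
        assert rep.edge_mean_pct == pytest.approx(100.0, abs=0.5)
        assert rep.p_value == pytest.approx(1.0, abs=0.05)

    def test_dimmer_edge_reported(self):
        img = simulate_droplet_matrix(4, 5, edge_factor=0.9, noise_sd_au=0.0, spot_intensity_cv=0.0)
        rep = droplet_grid_analysis(img, 4, 5)
        assert rep.edge_mean_pct == pytest.approx(90.0, abs=1.0)

    def test_spot_count_mismatch_signaled(self):
        img = simulate_droplet_matrix(3, 3, seed=1)
        with pytest.raises(MetricsError):
            droplet_grid_analysis(img, 4, 4)

    def test_seeded_uniform_matrix_not_significant(self):
        img = simulate_droplet_matrix(4, 5, seed=11)
        rep = droplet_grid_analysis(img, 4, 5)
        assert not rep.significant


class TestTimeSeries:
    def test_constant_images_flat_series(self):
        roi = _full_roi((8, 8))
        recs = [(d, make_image(np.full((8, 8), 5.0)), roi) for d in (1, 3, 7)]
        ts = intensity_time_series(recs, "control")
        assert ts.mean_intensity_au == (5.0, 5.0, 5.0)
        assert ts.days == (1, 3, 7)

    def test_duplicate_days_rejected(self):
        roi = _full_roi((8, 8))
        recs = [(3, make_image(np.ones((8, 8))), roi)] * 2
        with pytest.raises(MetricsError):
            intensity_time_series(recs, "control")

    def test_infected_peaks_between_day3_and_day10(self):
        cfg = WoundSimConfig(infected=True)
        wound = simulate_wound(cfg, np.random.default_rng(21))
        ts = intensity_time_series(
            [(d, wound.images[d][1], wound.wound_roi) for d in wound.days], "infected"
        )
        assert 3 <= ts.peak_day <= 10

    def test_control_declines_after_day3(self):
        cfg = WoundSimConfig()
        wound = simulate_wound(cfg, np.random.default_rng(22))
        ts = intensity_time_series(
            [(d, wound.images[d][1], wound.wound_roi) for d in wound.days], "control"
        )
        after = [m for d, m in zip(ts.days, ts.mean_intensity_au) if d >= 3]
        assert all(a > b for a, b in zip(after, after[1:]))
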