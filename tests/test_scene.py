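"""Tests for the synthetic scene simulator (illumination, flights, rendering)."""

import numpy as np
import pytest

from bednettrack.scene import (
    ContrastTable,
    FlightModel,
    IlluminationField,
    NoiseModel,
    SceneConfig,
    SceneGeometry,
    ScheduleEntry,
    illumination_profile,
    render_illumination,
    render_video,
    simulate_flights,
    simulate_scene,
)


def _corner_centre_ratio(img, patch=8):
    h, w = img.shape
    corners = np.concatenate([
        img[:patch, :patch].ravel(), img[:patch, -patch:].ravel(),
        img[-patch:, :patch].ravel(), img[-patch:, -patch:].ravel(),
    ])
    c0, c1 = h // 2 - patch // 2, w // 2 - patch // 2
    centre = img[c0:c0 + patch, c1:c1 + patch]
    return corners.mean() / centre.mean()


class TestIllumination:
    def test_bednet_attenuated_by_double_pass(self):
        geo = SceneGeometry(
            image_size=(128, 128),
            bednet_polygon=[[10, 60], [118, 60], [118, 110], [10, 110]],
            bednet_attenuation_per_pass=0.45,
            n_passes=2,
        )
        field = IlluminationField(mode="rrs", corner_falloff_fraction=1.0, band_amplitude=0.0)
        img = render_illumination(field, geo)
        net = geo.net_mask()
        assert img[net].mean() == pytest.approx(200 * 0.45**2, abs=0.5)
        assert img[net].mean() < img[~net].mean()

    def test_flat_backlit_field_is_constant(self):
        field = IlluminationField(mode="backlit", corner_falloff_fraction=1.0)
        img = illumination_profile(field, (128, 128))
        assert np.ptp(img) < 1e-9

    def test_backlit_corner_falloff_below_half(self):
        field = IlluminationField(
            mode="backlit", corner_falloff_fraction=0.5, ring_modulation_amplitude=0.0
        )
        ratio = _corner_centre_ratio(illumination_profile(field, (256, 256)))
        assert ratio <= 0.55

    def test_backlit_ratio_bound_holds_with_rings(self):
        field = IlluminationField(
            mode="backlit", corner_falloff_fraction=0.45, ring_modulation_amplitude=25.0
        )
        ratio = _corner_centre_ratio(illumination_profile(field, (256, 256)))
        assert ratio <= 0.45 + 0.05

    def test_rrs_background_stays_uniform(self):
        field = IlluminationField(mode="rrs", corner_falloff_fraction=0.97)
        ratio = _corner_centre_ratio(illumination_profile(field, (256, 256)))
        assert ratio >= 0.8

    def test_levels_stay_within_8bit_range(self):
        field = IlluminationField(mode="backlit", base_level=240.0,
                                  corner_falloff_fraction=0.4,
                                  ring_modulation_amplitude=30.0)
        img = illumination_profile(field, (128, 128))
        assert img.min() >= 0.0 and img.max() <= 255.0

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SceneGeometry(bednet_polygon=[[10, 10], [10, 10], [10, 10]])

    def test_out_of_bounds_polygon_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SceneGeometry(image_size=(64, 64), bednet_polygon=[[0, 0], [999, 0], [10, 10]])

    def test_occluders_near_black(self):
        geo = SceneGeometry(
            image_size=(64, 64),
            occluder_polygons=[[[10, 10], [30, 10], [30, 30], [10, 30]]],
        )
        field = IlluminationField(mode="rrs", corner_falloff_fraction=1.0, band_amplitude=0.0)
        img = render_illumination(field, geo)
        assert img[geo.occluder_mask()].max() < 10.0


class TestFlights:
    geo = SceneGeometry(image_size=(128, 128),
                        bednet_polygon=[[10, 60], [118, 60], [118, 110], [10, 110]])

    def test_zero_speed_is_stationary(self):
        model = FlightModel(n_mosquitoes=3, speed_mean_mm_s=0.0, seed=1)
        truth = simulate_flights(model, self.geo, 20)
        for _, g in truth.table.groupby("id"):
            assert g["x_px"].nunique() == 1 and g["y_px"].nunique() == 1

    def test_same_seed_reproduces_truth_exactly(self):
        model = FlightModel(n_mosquitoes=4, seed=9)
        a = simulate_flights(model, self.geo, 50).table
        b = simulate_flights(model, self.geo, 50).table
        assert a.equals(b)

    def test_zero_mosquitoes_gives_empty_truth(self):
        truth = simulate_flights(FlightModel(n_mosquitoes=0), self.geo, 10)
        assert len(truth.table) == 0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            FlightModel(n_mosquitoes=-1)

    def test_one_entry_per_mosquito_per_frame_inside_bounds(self):
        model = FlightModel(n_mosquitoes=5, seed=2)
        truth = simulate_flights(model, self.geo, 100)
        assert len(truth.table) == 5 * 100
        assert truth.table.groupby(["frame", "id"]).size().max() == 1
        assert truth.table["x_px"].between(0, 127).all()
        assert truth.table["y_px"].between(0, 127).all()
        assert not truth.table[["x_px", "y_px"]].isna().any().any()

    def test_region_labels_match_point_in_polygon_oracle(self):
        shapely = pytest.importorskip("shapely.geometry")
        poly = shapely.Polygon(self.geo.bednet_polygon)
        model = FlightModel(n_mosquitoes=6, seed=3)
        truth = simulate_flights(model, self.geo, 120)
        checked = 0
        for row in truth.table.itertuples(index=False):
            p = shapely.Point(row.x_px, row.y_px)
            if abs(poly.exterior.distance(p)) < 1.5:
                continue  # rasterisation boundary: half-pixel label slack
            inside = poly.contains(p)
            assert inside == (row.region in ("front_net", "behind_net"))
            checked += 1
        assert checked > 500

    def test_schedule_forces_behind_net_passage(self):
        sched = [ScheduleEntry(mosquito_id=0, frame_start=20, frame_end=60, layer="behind")]
        model = FlightModel(n_mosquitoes=1, seed=4, region_schedule=sched)
        truth = simulate_flights(model, self.geo, 80)
        window = truth.table.query("20 <= frame <= 60")
        assert (window["region"] == "behind_net").all()

    def test_home_range_tether_limits_excursions(self):
        model = FlightModel(n_mosquitoes=2, seed=8, home_range_px=25.0)
        truth = simulate_flights(model, self.geo, 300)
        step = model.speed_mean_mm_s / model.frame_rate_hz / self.geo.px_scale_mm
        for _, g in truth.table.groupby("id"):
            x0, y0 = g.iloc[0]["x_px"], g.iloc[0]["y_px"]
            d = np.hypot(g["x_px"] - x0, g["y_px"] - y0)
            assert d.max() < 25.0 + 3 * step  # range plus turnaround overshoot


class TestRenderVideo:
    def test_static_noise_free_scene_has_zero_difference(self, flat_rrs_field, open_geometry):
        cfg = SceneConfig(
            n_frames=10,
            illumination=flat_rrs_field,
            geometry=open_geometry,
            flight=FlightModel(n_mosquitoes=1, speed_mean_mm_s=0.0, seed=0),
            contrast=ContrastTable(background=(4.0, 4.0), front_of_net=(4.0, 4.0),
                                   behind_net=(4.0, 4.0)),
            noise=NoiseModel(relative_sd=0.0),
        )
        frames, _ = simulate_scene(cfg)
        assert (np.diff(frames.astype(int), axis=0) == 0).all()

    def test_behind_net_blob_depth_is_contrast_below_net_level(self):
        # net at 200*0.5^2 = 50 greyscales; fixed behind-net contrast 1 -> 49
        geo = SceneGeometry(image_size=(96, 96),
                            bednet_polygon=[[0, 0], [96, 0], [96, 96], [0, 96]],
                            bednet_attenuation_per_pass=0.5, n_passes=2)
        field = IlluminationField(mode="rrs", corner_falloff_fraction=1.0, band_amplitude=0.0)
        flight = FlightModel(n_mosquitoes=1, speed_mean_mm_s=0.0, seed=1)
        contrast = ContrastTable(background=(1.0, 1.0), front_of_net=(1.0, 1.0),
                                 behind_net=(1.0, 1.0))
        truth = simulate_flights(flight, geo, 5)
        assert (truth.table["region"] == "behind_net").any() or \
               (truth.table["region"] == "front_net").any()
        frames = render_video(truth, field, geo, contrast, NoiseModel(relative_sd=0.0), 5)
        assert frames.min() == 49
        assert frames.max() == 50

    def test_noise_recovery_at_default_setting(self, flat_rrs_field):
        geo = SceneGeometry(image_size=(64, 64), bednet_polygon=[])
        truth = simulate_flights(FlightModel(n_mosquitoes=0), geo, 1)
        frames = render_video(truth, flat_rrs_field, geo, ContrastTable(),
                              NoiseModel(relative_sd=0.0184, seed=0), 250)
        f = frames.astype(float)
        rel = (f.std(axis=0, ddof=1) / f.mean(axis=0)).mean()
        assert rel == pytest.approx(0.0184, rel=0.10)

    def test_temporal_mean_recovers_noise_free_render(self, flat_rrs_field):
        geo = SceneGeometry(image_size=(32, 32), bednet_polygon=[])
        truth = simulate_flights(FlightModel(n_mosquitoes=0), geo, 1)
        clean = render_illumination(flat_rrs_field, geo)
        frames = render_video(truth, flat_rrs_field, geo, ContrastTable(),
                              NoiseModel(relative_sd=0.0184, seed=3), 1500)
        err = np.abs(frames.mean(axis=0) - clean)
        assert err.max() < 0.5

    def test_render_is_bit_identical_under_fixed_seed(self, flat_rrs_field, open_geometry):
        cfg = SceneConfig(
            n_frames=15,
            illumination=flat_rrs_field,
            geometry=open_geometry,
            flight=FlightModel(n_mosquitoes=2, seed=6),
            noise=NoiseModel(relative_sd=0.0184, seed=6),
        )
        a, _ = simulate_scene(cfg)
        b, _ = simulate_scene(cfg)
        assert np.array_equal(a, b)

    def test_region_contrast_ordering_in_expectation(self):
        # measured blob depth: background > front-of-net > behind-net
        geo = SceneGeometry(image_size=(96, 96),
                            bednet_polygon=[[0, 40], [96, 40], [96, 96], [0, 96]],
                            bednet_attenuation_per_pass=0.45, n_passes=2)
        field = IlluminationField(mode="rrs", corner_falloff_fraction=1.0, band_amplitude=0.0)
        clean = render_illumination(field, geo)
        depths = {}
        for region, y, layer_seed in (("background", 20.0, 0), ("front_net", 70.0, 0),
                                      ("behind_net", 70.0, 1)):
            flight = FlightModel(n_mosquitoes=1, speed_mean_mm_s=0.0,
                                 seed=layer_seed)
            truth = simulate_flights(flight, geo, 150)
            truth.table["x_px"] = 48.0
            truth.table["y_px"] = y
            truth.table["region"] = region
            frames = render_video(truth, field, geo, ContrastTable(),
                                  NoiseModel(relative_sd=0.0), 150)
            local_bg = clean[int(y), 48]
            depths[region] = np.mean([local_bg - f.min() for f in frames.astype(float)])
        assert depths["background"] > depths["front_net"] > depths["behind_net"]

    def test_contrast_clipped_at_zero_on_dark_background(self, caplog):
        # blob depth exceeding the local level cannot produce negative pixels
        geo = SceneGeometry(image_size=(64, 64),
                            bednet_polygon=[[0, 0], [64, 0], [64, 64], [0, 64]],
                            bednet_attenuation_per_pass=0.1, n_passes=2)
        field = IlluminationField(mode="rrs", corner_falloff_fraction=1.0, band_amplitude=0.0)
        flight = FlightModel(n_mosquitoes=1, speed_mean_mm_s=0.0, seed=1)
        contrast = ContrastTable(background=(5.0, 5.0), front_of_net=(5.0, 5.0),
                                 behind_net=(5.0, 5.0))
        truth = simulate_flights(flight, geo, 3)
        frames = render_video(truth, field, geo, contrast, NoiseModel(relative_sd=0.0), 3)
        assert frames.min() == 0

    def test_contrast_table_ordering_enforced(self):
        with pytest.raises(ValueError):
            ContrastTable(background=(1.0, 5.0), front_of_net=(2.0, 3.0),
                          behind_net=(1.0, 2.0))
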