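"""Synthetic scene generation: determinism, placement rules, renderers."""

import math

import numpy as np
import pytest

import urbantree as ut
from urbantree.scene_sim import (
    SceneConfig,
    SceneDetector,
    default_spectral_params,
    generate_scene,
    render_ortho,
    render_point_cloud,
    simulate_detections,
)
from urbantree.spectral import BAND_NAMES, NOT_TREE, TREE
from urbantree.street_geoloc import locate_trees


def street_cfg(**kw):
    defaults = dict(
        area_width=100.0,
        area_height=40.0,
        street_axes=[[(0.0, 20.0), (100.0, 20.0)]],
        street_tree_spacing=10.0,
        seed=0,
    )
    defaults.update(kw)
    return SceneConfig(**defaults)


class TestGenerateScene:
    def test_seeded_determinism(self):
        a = generate_scene(street_cfg(seed=42), render=False)
        b = generate_scene(street_cfg(seed=42), render=False)
        assert [(t.x, t.y, t.height, t.crown_radius) for t in a.trees] == [
            (t.x, t.y, t.height, t.crown_radius) for t in b.trees
        ]

    def test_straight_street_tree_count(self):
        # 100 m axis, 10 m spacing, both endpoints carry a tree -> 11 trees
        scene = generate_scene(street_cfg(), render=False)
        assert len(scene.trees) == 11
        assert all(t.zone == "street" for t in scene.trees)

    def test_buildings_exclude_trees(self):
        cfg = street_cfg(
            street_axes=[],
            park_tree_density=200.0,
            building_rects=[(-1.0, -1.0, 101.0, 41.0)],
        )
        scene = generate_scene(cfg, render=False)
        assert scene.trees == []

    def test_min_tree_spacing_respected(self):
        cfg = street_cfg(park_tree_density=300.0, min_tree_spacing=4.0)
        scene = generate_scene(cfg, render=False)
        pts = scene.truth_positions()
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 4.0

    def test_trees_within_bounds_and_ids_unique(self):
        scene = generate_scene(street_cfg(park_tree_density=100.0), render=False)
        ids = [t.id for t in scene.trees]
        assert len(ids) == len(set(ids))
        for t in scene.trees:
            assert 0 <= t.x <= 100 and 0 <= t.y <= 40

    def test_station_spacing_and_heading(self):
        scene = generate_scene(street_cfg(station_spacing=15.0), render=False)
        xs = [s.x for s in scene.stations]
        assert xs == pytest.approx([7.5 + 15 * k for k in range(len(xs))])
        assert all(s.heading == 90.0 for s in scene.stations)

    def test_degenerate_area_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(area_width=0.0)


class TestRenderPointCloud:
    def test_density_within_ten_percent(self):
        cfg = street_cfg(area_width=100.0, area_height=100.0, point_density=14.0)
        scene = generate_scene(cfg, render=False)
        cloud = render_point_cloud(scene)
        assert 126000 <= len(cloud) <= 154000

    def test_single_tree_apex_bounded(self):
        cfg = street_cfg(height_range=(10.0, 10.0), street_axes=[[(40.0, 20.0), (60.0, 20.0)]],
                         street_tree_spacing=50.0)
        scene = generate_scene(cfg, render=False)
        scene.trees = scene.trees[:1]
        cloud = render_point_cloud(scene)
        zmax = cloud.xyz[:, 2].max()
        assert 9.0 < zmax <= 10.5  # paraboloid apex +- clipped noise

    def test_empty_scene_all_ground(self):
        scene = generate_scene(street_cfg(street_axes=[]), render=False)
        cloud = render_point_cloud(scene, density=2.0)
        assert np.all(cloud.xyz[:, 2] == 0.0)

    def test_nonpositive_density_rejected(self):
        scene = generate_scene(street_cfg(), render=False)
        with pytest.raises(ValueError):
            render_point_cloud(scene, density=0.0)


class TestRenderOrtho:
    def test_raster_shape_is_ceil_area_over_cell(self):
        cfg = street_cfg(area_width=10.1, area_height=7.9)
        scene = generate_scene(cfg, render=False)
        ortho = render_ortho(scene)
        assert ortho.grid.values.shape == (
            math.ceil(7.9 / 0.25),
            math.ceil(10.1 / 0.25),
        )

    def test_tree_center_pixels_from_tree_distribution(self):
        scene = generate_scene(street_cfg(), render=False)
        ortho = render_ortho(scene)
        params = default_spectral_params()
        t = scene.trees[5]
        for k, band in enumerate(BAND_NAMES):
            i, j = ortho.grid.index_of(t.x, t.y)
            val = ortho.bands[band].values[i, j]
            assert abs(val - params[TREE]["mean"][k]) <= 4 * params[TREE]["sd"][k]

    def test_treeless_scene_entirely_background(self):
        scene = generate_scene(street_cfg(street_axes=[]), render=False)
        ortho = render_ortho(scene)
        params = default_spectral_params()
        for k, band in enumerate(BAND_NAMES):
            mean = ortho.bands[band].values.mean()
            assert abs(mean - params[NOT_TREE]["mean"][k]) < 1.0

    def test_spectral_separability_on_nir(self):
        # class means are >= 10 sds apart on NIR: a mid threshold on one band
        # classifies rendered pixels essentially perfectly
        scene = generate_scene(street_cfg(), render=False)
        ortho = render_ortho(scene)
        params = default_spectral_params()
        thr = (params[TREE]["mean"][6] + params[NOT_TREE]["mean"][6]) / 2
        nir = ortho.bands["NIR17"].values
        X, Y = ortho.grid.center_grids()
        truth = np.zeros(nir.shape, dtype=bool)
        for t in scene.trees:
            truth |= (X - t.x) ** 2 + (Y - t.y) ** 2 <= t.crown_radius**2
        pred = nir > thr
        assert (pred != truth).mean() < 1e-6


class TestSimulateDetections:
    def test_zero_noise_single_tree_exact_inverse(self):
        cfg = street_cfg()
        scene = generate_scene(cfg, render=False)
        st = scene.stations[0]
        scene.trees = scene.trees[:1]
        scene.trees[0].x, scene.trees[0].y = st.x, st.y + 10.0  # due north
        dets = [d for d in simulate_detections(scene) if d.station_id == st.id]
        assert len(dets) == 1
        (cand,) = locate_trees([st], dets, cfg.pixel_model)
        assert (cand.x, cand.y) == pytest.approx((st.x, st.y + 10.0), abs=1e-9)

    def test_full_miss_rate_leaves_only_spurious(self):
        cfg = street_cfg(detection_miss_rate=1.0, false_detection_rate=0.5)
        scene = generate_scene(cfg, render=False)
        dets = simulate_detections(scene)
        cands = locate_trees(scene.stations, dets, cfg.pixel_model)
        truth = scene.truth_positions()
        for c in cands:
            assert np.hypot(truth[:, 0] - c.x, truth[:, 1] - c.y).min() > 1e-6

    def test_seeded_detections_repeatable(self):
        cfg = street_cfg(bearing_noise_sd=0.3, distance_noise_sd=0.5,
                         detection_miss_rate=0.2, false_detection_rate=1.0)
        a = simulate_detections(generate_scene(cfg, render=False))
        b = simulate_detections(generate_scene(cfg, render=False))
        assert [(d.station_id, d.u, d.v) for d in a] == [
            (d.station_id, d.u, d.v) for d in b
        ]

    def test_buildings_occlude_line_of_sight(self):
        # a wall between the single station and the single tree
        cfg = street_cfg(street_axes=[[(0.0, 20.0), (30.0, 20.0)]],
                         street_tree_spacing=100.0, station_spacing=60.0)
        scene = generate_scene(cfg, render=False)
        assert len(scene.trees) == 2 and len(scene.stations) == 1
        st = scene.stations[0]
        t = scene.trees[1]
        from shapely.geometry import box

        mid_x = (st.x + t.x) / 2
        scene.buildings = [box(mid_x - 1, 15.0, mid_x + 1, 30.0)]
        ids_seen = {d.station_id for d in simulate_detections(scene)}
        dets = simulate_detections(scene)
        cands = locate_trees([st], [d for d in dets if d.station_id == st.id], cfg.pixel_model)
        hit = [
            c for c in cands if math.hypot(c.x - t.x, c.y - t.y) < 1e-6
        ]
        assert hit == []

    def test_zero_noise_locate_recovers_all_street_trees(self, street_scene):
        dets = simulate_detections(street_scene)
        cands = locate_trees(street_scene.stations, dets, street_scene.config.pixel_model)
        truth = street_scene.truth_positions("street")
        for tx, ty in truth:
            d = min(math.hypot(c.x - tx, c.y - ty) for c in cands)
            assert d < 1e-6
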