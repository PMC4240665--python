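"""Damage polygons: lattice geometry, volumes and specimen summaries."""

import numpy as np
import pytest

from conftest import make_raster, outer_perimeter_oracle
from percmorph.hotspot import COLD, HOT, INVALID, NONE, HotspotRaster
from percmorph.polygons import (
    attach_volume_metrics,
    extract_polygons,
    p2v_ratio,
    polygon_volume,
    polygons_to_dataframe,
    summarize_specimen,
)
from percmorph.polygons import polygon_geojson, polygon_wkt


def hotspot_from_classes(cls, cell_size=1.0):
    """Build a classified HotspotRaster directly from a class-code array."""
    cls = np.asarray(cls, dtype=np.int8)
    valid = cls != INVALID
    return HotspotRaster(
        gi_z=np.where(valid, cls * 5.0, np.nan),
        p_two_tailed=np.where(valid, 1e-8, np.nan),
        cls=cls,
        valid_mask=valid,
        origin=(0.0, 0.0),
        cell_size=cell_size,
        alpha=0.001,
        global_mean=0.0,
        global_sd=1.0,
    )


def test_two_by_two_block_geometry():
    cls = np.zeros((5, 5), dtype=np.int8)
    cls[1:3, 1:3] = HOT
    polys = extract_polygons(hotspot_from_classes(cls), "hot", min_cells=1)
    assert len(polys) == 1
    p = polys[0]
    assert p.cell_count == 4
    assert p.area == pytest.approx(4.0)
    assert p.perimeter == pytest.approx(8.0)
    assert p.max_length == pytest.approx(2 * np.sqrt(2))
    # extent perpendicular to the diagonal axis: the other diagonal
    assert p.max_width == pytest.approx(2 * np.sqrt(2))


def test_diagonal_connectivity_rules():
    cls = np.zeros((4, 4), dtype=np.int8)
    cls[1, 1] = HOT
    cls[2, 2] = HOT
    hs = hotspot_from_classes(cls)
    assert len(extract_polygons(hs, "hot", connectivity=4, min_cells=1)) == 2
    assert len(extract_polygons(hs, "hot", connectivity=8, min_cells=1)) == 1


def test_empty_classification_gives_empty_list():
    cls = np.full((4, 4), NONE, dtype=np.int8)
    assert extract_polygons(hotspot_from_classes(cls), "hot") == []


def test_min_cells_drops_speckle():
    cls = np.zeros((6, 6), dtype=np.int8)
    cls[0, 0] = HOT  # single-cell speckle
    cls[3:5, 3:5] = HOT
    polys = extract_polygons(hotspot_from_classes(cls), "hot", min_cells=3)
    assert len(polys) == 1 and polys[0].cell_count == 4


def test_area_perimeter_match_flood_fill_oracle(rng):
    """Random masks: per-component area = count * cs^2 and perimeter =
    outer exposed-edge count * cs (holes excluded on both sides)."""
    for _ in range(5):
        cls = np.where(rng.uniform(size=(15, 15)) < 0.4, HOT, NONE).astype(
            np.int8
        )
        hs = hotspot_from_classes(cls, cell_size=0.5)
        polys = extract_polygons(hs, "hot", connectivity=4, min_cells=1)
        assert sum(p.cell_count for p in polys) == (cls == HOT).sum()
        for p in polys:
            comp = np.zeros(cls.shape, dtype=bool)
            comp[p.cells[:, 0], p.cells[:, 1]] = True
            assert p.area == pytest.approx(p.cell_count * 0.25)
            assert p.perimeter == pytest.approx(
                outer_perimeter_oracle(comp, 0.5)
            )


def test_polygon_ordering_deterministic(rng):
    cls = np.where(rng.uniform(size=(12, 12)) < 0.35, HOT, NONE).astype(np.int8)
    hs = hotspot_from_classes(cls)
    a = extract_polygons(hs, "hot", min_cells=1)
    b = extract_polygons(hs, "hot", min_cells=1)
    firsts = [tuple(p.cells[np.lexsort((p.cells[:, 1], p.cells[:, 0]))][0]) for p in a]
    assert firsts == sorted(firsts)
    for pa, pb in zip(a, b):
        np.testing.assert_array_equal(pa.cells, pb.cells)


def test_perimeter_lower_bound_and_area_budget(rng):
    cls = np.where(rng.uniform(size=(20, 20)) < 0.3, HOT, NONE).astype(np.int8)
    hs = hotspot_from_classes(cls, cell_size=0.2)
    polys = extract_polygons(hs, "hot", min_cells=1)
    total_area = sum(p.area for p in polys)
    assert total_area <= 400 * 0.04
    for p in polys:
        assert p.area > 0
        assert p.perimeter >= 4 * 0.2 - 1e-12


def test_plateau_volume_is_height_times_area():
    """Flat-topped 3x3 plateau of height 2 on a flat surround: the
    reference plane fits the surrounding ring at 0, volume = 2 * 9 = 18."""
    z = np.zeros((9, 9))
    z[3:6, 3:6] = 2.0
    dem = make_raster(z)
    cls = np.where(z > 0, HOT, NONE).astype(np.int8)
    poly = extract_polygons(hotspot_from_classes(cls), "hot")[0]
    assert polygon_volume(poly, dem) == pytest.approx(18.0, abs=2.0)


def test_tilted_plane_volume_absorbed_by_fit():
    rows, cols = np.mgrid[0:10, 0:10]
    dem = make_raster(0.5 * cols - 0.2 * rows)
    cls = np.full((10, 10), NONE, dtype=np.int8)
    cls[3:6, 4:8] = HOT
    poly = extract_polygons(hotspot_from_classes(cls), "hot")[0]
    assert polygon_volume(poly, dem) == pytest.approx(0.0, abs=1e-9)


def test_cold_polygon_volume_counts_void_below_plane():
    z = np.zeros((9, 9))
    z[3:6, 3:6] = -1.5
    dem = make_raster(z)
    cls = np.where(z < 0, COLD, NONE).astype(np.int8)
    poly = extract_polygons(hotspot_from_classes(cls), "cold")[0]
    assert polygon_volume(poly, dem) == pytest.approx(1.5 * 9, abs=1.5)


def test_p2v_arithmetic_and_floor():
    cls = np.zeros((5, 5), dtype=np.int8)
    cls[1:3, 1:3] = HOT
    poly = extract_polygons(hotspot_from_classes(cls), "hot")[0]
    import dataclasses

    poly = dataclasses.replace(poly, volume=4.0)
    assert p2v_ratio(poly) == pytest.approx(16.0)  # 8^2 / 4
    starved = dataclasses.replace(poly, volume=1e-9)
    assert p2v_ratio(starved) is None


def test_p2v_scales_inversely_with_feature_size():
    """Scaling a feature by k in all three axes: P -> kP, V -> k^3 V,
    so perimeter^2/volume scales by 1/k."""

    def feature(k):
        n = int(9 * k)
        z = np.zeros((n + 6, n + 6))
        z[3 : 3 + n, 3 : 3 + n] = 2.0 * k
        dem = make_raster(z, cell_size=1.0)
        cls = np.where(z > 0, HOT, NONE).astype(np.int8)
        poly = extract_polygons(hotspot_from_classes(cls), "hot")[0]
        return attach_volume_metrics([poly], dem)[0].p2v

    assert feature(2) == pytest.approx(feature(1) / 2, rel=0.05)


def test_jagged_rim_exceeds_smooth_rim_at_equal_volume():
    """Two plateaus of identical cell count and height: the dendritic one
    has a longer perimeter, hence the larger perimeter^2/volume."""
    smooth = np.zeros((13, 13), dtype=np.int8)
    smooth[4:8, 4:8] = HOT  # 16 cells, compact
    jagged = np.zeros((13, 13), dtype=np.int8)
    jagged[6, 2:10] = HOT  # 16 cells, plus shape
    jagged[2:10, 6] = HOT
    jagged[6, 6] = HOT
    assert (jagged == HOT).sum() == 15
    smooth[4, 4] = NONE  # equalise to 15 cells
    results = {}
    for name, cls in (("smooth", smooth), ("jagged", jagged)):
        z = np.where(cls == HOT, 1.0, 0.0)
        poly = extract_polygons(hotspot_from_classes(cls), "hot")[0]
        poly = attach_volume_metrics([poly], make_raster(z))[0]
        results[name] = poly
    assert results["jagged"].volume == pytest.approx(
        results["smooth"].volume, rel=0.2
    )
    assert results["jagged"].p2v > results["smooth"].p2v


def test_summarize_specimen_modes_and_flags():
    import dataclasses

    cls = np.zeros((8, 8), dtype=np.int8)
    cls[0, 0:3] = HOT
    hs = hotspot_from_classes(cls)
    base = extract_polygons(hs, "hot")[0]

    def fake(cls_name, area):
        return dataclasses.replace(
            base, cls=cls_name, area=area, specimen_id="s1"
        )

    polys = [fake("hot", 3.0), fake("hot", 5.0), fake("cold", 2.0), fake("cold", 2.0)]
    s = summarize_specimen(polys, "mean_area")
    assert s.hot_cold_area_ratio == pytest.approx(2.0)  # mean 4 / mean 2
    assert s.n_hot == 2 and s.n_cold == 2
    t = summarize_specimen(polys, "total_area")
    assert t.hot_cold_area_ratio == pytest.approx(2.0)  # 8 / 4
    no_cold = summarize_specimen(polys[:2], "mean_area")
    assert no_cold.hot_cold_area_ratio is None and not no_cold.ratio_defined
    equal = summarize_specimen(
        [fake("hot", 2.0), fake("cold", 2.0)], "mean_area"
    )
    assert equal.hot_cold_area_ratio == pytest.approx(1.0)
    with pytest.raises(ValueError):
        summarize_specimen(polys, "median_area")


def test_polygon_table_and_exports():
    cls = np.zeros((6, 6), dtype=np.int8)
    cls[1:4, 1:4] = HOT
    z = np.where(cls == HOT, 1.0, 0.0)
    polys = attach_volume_metrics(
        extract_polygons(hotspot_from_classes(cls), "hot", specimen_id="sp"),
        make_raster(z),
    )
    df = polygons_to_dataframe(polys)
    assert list(df["specimen_id"]) == ["sp"]
    assert df["perimeter_area_ratio"][0] == pytest.approx(12.0 / 9.0)
    gj = polygon_geojson(polys[0])
    assert gj["geometry"]["type"] == "Polygon"
    assert polygon_wkt(polys[0]).startswith("POLYGON")
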