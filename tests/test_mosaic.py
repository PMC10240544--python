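"""Expanding-spiral mosaics, the persistent tile store, and rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simscope import (
    MacroPosition,
    MosaicTile,
    TileStore,
    ValidationError,
    list_marked,
    mark_point,
    read_dv,
    render_region,
    run_mosaic,
    save_mosaic,
    spiral_offsets,
)
from simscope.stage import axes_from_depot, current_position


def ring_walk_oracle(n):
    """Independent spiral enumerator: walk forward, turning left whenever
    the cell on the left is unvisited (classic square-spiral turtle)."""
    pos = (0, 0)
    heading = (1, 0)
    out = [pos]
    visited = {pos}
    while len(out) < n:
        left = (-heading[1], heading[0])
        if len(out) > 1 and (pos[0] + left[0], pos[1] + left[1]) not in visited:
            heading = left
        pos = (pos[0] + heading[0], pos[1] + heading[1])
        out.append(pos)
        visited.add(pos)
    return out


def test_spiral_trivial_and_errors():
    assert spiral_offsets(1) == [(0, 0)]
    with pytest.raises(ValidationError):
        spiral_offsets(0)


def test_spiral_nine_covers_the_3x3_ring_with_unit_steps():
    offs = spiral_offsets(9)
    assert offs[0] == (0, 0)
    assert set(offs) == {(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)}
    for a, b in zip(offs, offs[1:]):
        assert abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1
    assert offs == ring_walk_oracle(9)


def test_spiral_25_is_the_5x5_grid_max_ring_2():
    offs = spiral_offsets(25)
    assert set(offs) == {(i, j) for i in range(-2, 3) for j in range(-2, 3)}
    assert max(max(abs(i), abs(j)) for i, j in offs) == 2
    assert offs == ring_walk_oracle(25)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(m=st.integers(1, 200), n=st.integers(1, 200))
def test_spiral_prefix_property(m, n):
    m, n = sorted((m, n))
    assert spiral_offsets(n)[:m] == spiral_offsets(m)


def test_single_tile_mosaic_is_centred_at_start(sim_depot):
    store = TileStore()
    start = MacroPosition(500.0, 500.0, 0.0)
    result = run_mosaic(store, start, 1, 0.0, sim_depot)
    assert result.n_acquired == 1 and result.error is None
    assert store.tiles[0].centre.as_tuple() == pytest.approx(start.as_tuple())


def test_nine_tiles_form_a_lattice_spaced_by_sensor_extent(sim_depot):
    store = TileStore()
    start = MacroPosition(1000.0, 1000.0, 0.0)
    run_mosaic(store, start, 9, 0.0, sim_depot)
    extent = 512.0  # 512 px x 1.0 um
    expected = {
        (start.x_um + i * extent, start.y_um + j * extent)
        for i, j in spiral_offsets(9)
    }
    got = {(t.centre.x_um, t.centre.y_um) for t in store.tiles}
    assert got == expected
    # stage returned home afterwards
    pos = current_position(axes_from_depot(sim_depot))
    assert pos.as_tuple() == pytest.approx(start.as_tuple())


def test_successive_mosaics_preserve_earlier_tiles_and_marks(sim_depot):
    store = TileStore()
    mark_point(store, MacroPosition(1.0, 2.0, 3.0), "site-a")
    first = run_mosaic(store, MacroPosition(400.0, 400.0, 0.0), 4, 0.0, sim_depot)
    first_tiles = list(store.tiles_of(first.mosaic_id))
    second = run_mosaic(store, MacroPosition(700.0, 650.0, 0.0), 5, 0.0, sim_depot)
    assert store.mosaic_ids() == [first.mosaic_id, second.mosaic_id]
    assert store.tiles_of(first.mosaic_id) == first_tiles
    assert len(store.tiles) == 9
    assert [p.label for p in list_marked(store)] == ["site-a"]


def test_soft_limit_stops_mosaic_cleanly_keeping_partial(sim_depot):
    # shrink the X axis so the spiral's eastward step is rejected
    for ax in axes_from_depot(sim_depot):
        if ax.dimension == "x":
            ax.limits_um = (-100.0, 100.0)
    store = TileStore()
    result = run_mosaic(store, MacroPosition(0.0, 0.0, 0.0), 9, 0.0, sim_depot)
    assert result.error is not None
    assert result.n_acquired == len(store.tiles) == 1


def test_sidecar_round_trips_tile_positions(sim_depot, tmp_path):
    store = TileStore()
    result = run_mosaic(store, MacroPosition(800.0, 800.0, 2.0), 9, 0.1, sim_depot)
    dv_path, sidecar = save_mosaic(store, result.mosaic_id, tmp_path / "m.dv")
    rows = [
        line.split("\t")
        for line in sidecar.read_text().splitlines()
        if not line.startswith("#")
    ]
    assert len(rows) == 9
    tiles = store.tiles_of(result.mosaic_id)
    for row, tile in zip(rows, tiles):
        assert int(row[0]) == tile.seq
        assert float(row[1]) == pytest.approx(tile.centre.x_um, abs=1e-3)
        assert float(row[2]) == pytest.approx(tile.centre.y_um, abs=1e-3)
        assert float(row[3]) == pytest.approx(tile.centre.z_um, abs=1e-3)
    back = read_dv(dv_path)
    assert back.shape[2] == 9
    for k, tile in enumerate(tiles):
        assert np.array_equal(back.data[0, 0, k], tile.image)


def test_save_unknown_mosaic_id_raises(sim_depot, tmp_path):
    with pytest.raises(LookupError):
        save_mosaic(TileStore(), 99, tmp_path / "x.dv")


def test_render_empty_store_is_zero():
    out = render_region(TileStore(), (0.0, 100.0, 0.0, 100.0), 1.0)
    assert out.shape == (100, 100)
    assert not out.any()


def test_render_single_tile_identity():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 65535, size=(40, 60)).astype(np.uint16)
    store = TileStore()
    store.tiles.append(
        MosaicTile(img, MacroPosition(30.0, 20.0, 0.0), 1.0, 0, 0)
    )
    out = render_region(store, (0.0, 60.0, 0.0, 40.0), 1.0)
    assert np.array_equal(out, img)


def test_later_tile_overpaints_earlier_in_overlap():
    low = np.full((40, 40), 100, dtype=np.uint16)
    high = np.full((20, 20), 60000, dtype=np.uint16)
    store = TileStore()
    store.tiles.append(MosaicTile(low, MacroPosition(20.0, 20.0, 0.0), 1.0, 0, 0))
    store.tiles.append(MosaicTile(high, MacroPosition(20.0, 20.0, 0.0), 1.0, 1, 0))
    out = render_region(store, (0.0, 40.0, 0.0, 40.0), 1.0)
    assert (out[15:25, 15:25] == 60000).all()
    assert (out[:5, :5] == 100).all()


def test_render_is_idempotent(sim_depot):
    store = TileStore()
    run_mosaic(store, MacroPosition(600.0, 600.0, 0.0), 4, 0.0, sim_depot)
    bounds = (300.0, 900.0, 300.0, 900.0)
    a = render_region(store, bounds, 2.0)
    b = render_region(store, bounds, 2.0)
    assert np.array_equal(a, b)


def test_marks_are_append_only_and_ordered():
    store = TileStore()
    mark_point(store, MacroPosition(0.0, 0.0, 0.0), "a")
    mark_point(store, MacroPosition(0.0, 0.0, 0.0), "b")
    assert [p.label for p in list_marked(store)] == ["a", "b"]
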