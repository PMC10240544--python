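"""Mosaic acquisition: expanding-spiral tile scans over the sample plane.

Tiles are acquired in an expanding square spiral around a start position —
first step +i (east, stage +x), then a counter-clockwise ring walk — so the
field of interest is covered from the centre outwards.  All tiles from all
mosaics live in one append-only store together with user/algorithm marked
points: starting a new mosaic never removes earlier tiles, so several
(possibly overlapping) regions stay navigable without re-imaging.

A saved mosaic is a .dv stack (one plane per tile) plus a plain-text
sidecar listing each tile's acquisition order and stage XYZ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .devices import Depot, HandlerKind
from .dvfile import DVDataset, write_dv
from .errors import SoftLimitError, ValidationError
from .simulated import snap
from .stage import MacroPosition, axes_from_depot, current_position, move_to

__all__ = [
    "MosaicTile",
    "MarkedPoint",
    "TileStore",
    "MosaicResult",
    "spiral_offsets",
    "run_mosaic",
    "save_mosaic",
    "render_region",
    "mark_point",
    "list_marked",
    "write_points_file",
]


@dataclass(frozen=True)
class MosaicTile:
    """One positioned snapshot: image plus the stage position of its centre."""

    image: np.ndarray
    centre: MacroPosition
    pixel_size_um: float
    mosaic_id: int
    seq: int  # acquisition order within the mosaic

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValidationError("tile pixel size must be positive")


@dataclass(frozen=True)
class MarkedPoint:
    position: MacroPosition
    label: str


@dataclass
class TileStore:
    """Append-only store of every tile and marked point across all mosaics."""

    tiles: list[MosaicTile] = field(default_factory=list)
    marked_points: list[MarkedPoint] = field(default_factory=list)
    _next_mosaic_id: int = 0

    def new_mosaic_id(self) -> int:
        mid = self._next_mosaic_id
        self._next_mosaic_id = mid + 1
        return mid

    def mosaic_ids(self) -> list[int]:
        return sorted({t.mosaic_id for t in self.tiles})

    def tiles_of(self, mosaic_id: int) -> list[MosaicTile]:
        return sorted(
            (t for t in self.tiles if t.mosaic_id == mosaic_id),
            key=lambda t: t.seq,
        )


def spiral_offsets(n: int) -> list[tuple[int, int]]:
    """First ``n`` grid offsets of the expanding square spiral.

    Starts at (0, 0), first step +i, then walks counter-clockwise ring by
    ring; consecutive offsets differ by one unit step, and the first
    (2k+1)^2 offsets tile the square {-k..k}^2 exactly.
    """
    if n < 1:
        raise ValidationError("spiral needs at least one tile")
    out = [(0, 0)]
    i = j = 0
    di, dj = 1, 0  # east; turns are counter-clockwise: E -> N -> W -> S
    leg = 1
    while len(out) < n:
        for _ in range(2):
            for _ in range(leg):
                i, j = i + di, j + dj
                out.append((i, j))
                if len(out) == n:
                    return out
            di, dj = -dj, di
        leg += 1
    return out


@dataclass
class MosaicResult:
    """Outcome of one mosaic run; ``error`` set if it stopped early."""

    mosaic_id: int
    n_acquired: int
    error: str | None = None


def run_mosaic(
    store: TileStore,
    start: MacroPosition,
    n_tiles: int,
    overlap_fraction: float,
    depot: Depot,
    *,
    exposure_ms: float = 100.0,
    on_tile: Callable[[MosaicTile], None] | None = None,
    should_stop: Callable[[], bool] | None = None,
) -> MosaicResult:
    """Acquire ``n_tiles`` tiles in an expanding spiral around ``start``.

    Tile k sits at ``start + spiral_offsets[k] * step`` where ``step`` is
    the sensor extent scaled by (1 - overlap); Z is held at ``start.z``.
    A move rejected by the soft limits stops the mosaic cleanly: tiles
    already acquired are kept and the error is reported in the result.
    The stage returns to ``start`` afterwards.
    """
    if n_tiles < 1:
        raise ValidationError("n_tiles must be >= 1")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValidationError("overlap_fraction must be in [0, 1)")
    cameras = depot.of_kind(HandlerKind.CAMERA)
    if not cameras:
        raise ValidationError("depot has no camera")
    cam = depot.device_for(cameras[0])
    h, w = cam.state.sensor_shape
    px = cam.state.pixel_size_um
    step_x = w * px * (1.0 - overlap_fraction)
    step_y = h * px * (1.0 - overlap_fraction)
    axes = axes_from_depot(depot)
    mosaic_id = store.new_mosaic_id()
    error: str | None = None
    acquired = 0
    try:
        for seq, (i, j) in enumerate(spiral_offsets(n_tiles)):
            if should_stop is not None and should_stop():
                error = "aborted"
                break
            target = MacroPosition(
                start.x_um + i * step_x, start.y_um + j * step_y, start.z_um
            )
            try:
                move_to(axes, target)
            except SoftLimitError as exc:
                error = str(exc)
                break
            image = snap(depot, exposure_ms=exposure_ms)
            tile = MosaicTile(
                image=image,
                centre=current_position(axes),
                pixel_size_um=px,
                mosaic_id=mosaic_id,
                seq=seq,
            )
            store.tiles.append(tile)
            acquired += 1
            if on_tile is not None:
                on_tile(tile)
    finally:
        try:
            move_to(axes, start)
        except SoftLimitError:  # pragma: no cover - start was reachable
            pass
    return MosaicResult(mosaic_id=mosaic_id, n_acquired=acquired, error=error)


def save_mosaic(
    store: TileStore, mosaic_id: int, path: str | Path
) -> tuple[Path, Path]:
    """Write a mosaic as a .dv stack (one plane per tile) plus a text
    sidecar: one tab-separated line per tile — seq, x_um, y_um, z_um
    (3 decimal places).  Returns (dv_path, sidecar_path)."""
    tiles = store.tiles_of(mosaic_id)
    if not tiles:
        raise LookupError(f"no mosaic with id {mosaic_id}")
    path = Path(path)
    stack = np.stack([t.image for t in tiles])[None, None]  # (1, 1, N, H, W)
    meta = np.zeros((len(tiles), 8), dtype="<f4")
    for k, t in enumerate(tiles):
        meta[k, :3] = t.centre.as_tuple()
        meta[k, 4:7] = (t.image.min(), t.image.max(), t.image.mean())
    dataset = DVDataset(
        data=stack.astype(np.uint16),
        pixel_size_um=(tiles[0].pixel_size_um, tiles[0].pixel_size_um, 1.0),
        stage_origin_um=tiles[0].centre,
        plane_metadata=meta,
    )
    dv_path = write_dv(dataset, path)
    sidecar = path.with_suffix(path.suffix + ".txt")
    lines = ["# seq\tx_um\ty_um\tz_um"]
    for t in tiles:
        lines.append(
            f"{t.seq}\t{t.centre.x_um:.3f}\t{t.centre.y_um:.3f}\t{t.centre.z_um:.3f}"
        )
    sidecar.write_text("\n".join(lines) + "\n")
    return dv_path, sidecar


def render_region(
    store: TileStore,
    bounds_um: tuple[float, float, float, float],
    out_pixel_size_um: float,
) -> np.ndarray:
    """CPU composite of the store over ``bounds_um`` = (x_min, x_max,
    y_min, y_max).  Tiles are painted in acquisition order (later over
    earlier) with nearest-neighbour resampling; uncovered pixels are 0."""
    x_min, x_max, y_min, y_max = bounds_um
    if not (np.isfinite(bounds_um).all() and x_max > x_min and y_max > y_min):
        raise ValidationError("bounds must be finite with positive extent")
    if not out_pixel_size_um > 0:
        raise ValidationError("out_pixel_size_um must be positive")
    out_w = max(1, round((x_max - x_min) / out_pixel_size_um))
    out_h = max(1, round((y_max - y_min) / out_pixel_size_um))
    out = np.zeros((out_h, out_w), dtype=np.uint16)
    # sample-plane x of output column c: x_min + (c + 0.5) * out_pixel_size
    xs = x_min + (np.arange(out_w) + 0.5) * out_pixel_size_um
    ys = y_min + (np.arange(out_h) + 0.5) * out_pixel_size_um
    for tile in store.tiles:
        th, tw = tile.image.shape
        px = tile.pixel_size_um
        # tile pixel (r, c) centre sits at centre + ((c + 0.5) - w/2) * px
        x0 = tile.centre.x_um - tw * px / 2.0
        y0 = tile.centre.y_um - th * px / 2.0
        cols = np.floor((xs - x0) / px).astype(int)
        rows = np.floor((ys - y0) / px).astype(int)
        c_ok = (cols >= 0) & (cols < tw)
        r_ok = (rows >= 0) & (rows < th)
        if not (c_ok.any() and r_ok.any()):
            continue
        rr = np.where(r_ok)[0]
        cc = np.where(c_ok)[0]
        out[np.ix_(rr, cc)] = tile.image[np.ix_(rows[rr], cols[cc])]
    return out


def mark_point(store: TileStore, position: MacroPosition, label: str) -> TileStore:
    """Append a marked stage location; order is preserved."""
    store.marked_points.append(MarkedPoint(position=position, label=label))
    return store


def list_marked(store: TileStore) -> list[MarkedPoint]:
    return list(store.marked_points)


def write_points_file(store: TileStore, path: str | Path) -> Path:
    """Marked points as tab-separated text: label, x_um, y_um, z_um."""
    path = Path(path)
    lines = ["# label\tx_um\ty_um\tz_um"]
    for p in store.marked_points:
        lines.append(
            f"{p.label}\t{p.position.x_um:.3f}\t{p.position.y_um:.3f}"
            f"\t{p.position.z_um:.3f}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
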