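"""Acquire an expanding-spiral mosaic and render a composite overview.

Nine tiles are collected spiralling outwards from the start position; the
tile store keeps every tile from every mosaic, and the saved .dv stack
comes with a text sidecar giving each tile's stage XYZ.
"""

from pathlib import Path

from simscope import (
    MacroPosition,
    TileStore,
    build_depot,
    default_sim_config,
    render_region,
    run_mosaic,
    save_mosaic,
    spiral_offsets,
)

depot = build_depot(default_sim_config(seed=0))
store = TileStore()
start = MacroPosition(512.0, 512.0, 0.0)

print("spiral order (first 9 offsets):", spiral_offsets(9))
result = run_mosaic(store, start, n_tiles=9, overlap_fraction=0.0, depot=depot)
print(f"mosaic {result.mosaic_id}: acquired {result.n_acquired} tiles of "
      f"{store.tiles[0].image.shape} px at 1.0 um/px")

dv_path, sidecar = save_mosaic(store, result.mosaic_id, Path("scratch_mosaic.dv"))
print(f"saved stack -> {dv_path}, positions sidecar -> {sidecar}:")
print("\n".join(sidecar.read_text().splitlines()[:4]), "\n  ...")

overview = render_region(store, (-256.0, 1280.0, -256.0, 1280.0), 4.0)
covered = (overview > 0).mean()
print(f"rendered {overview.shape} overview at 4 um/px; "
      f"{covered:.0%} of the region is covered by tiles")
print("Later tiles paint over earlier ones, so re-scanning a region at "
      "higher detail refines the overview in place.")
for p in (dv_path, sidecar):
    p.unlink()
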