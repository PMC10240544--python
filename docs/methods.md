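# Methods

This note documents the models, conventions and numerical choices behind
`simscope`, in the spirit of a software methods section: what is modelled,
what the tunable parameters mean, what the synthetic data does and does
not emulate, and where genuinely open design points were settled by
decision rather than derivation.

## Device model

A device is any object exposing `handlers()`; handlers are frozen records
(name, kind, owning device, optional digital/analogue trigger-line
indices). Handler names follow `<device>:<facet>`, which makes uniqueness
mechanical. The depot construction validates the whole configuration up
front: unknown device types, duplicate handler names, missing required
settings, and two handlers claiming the same trigger line are all
configuration errors at build time, not at run time. A device exposing
zero handlers is legal but produces a warning — it is usually a
configuration mistake.

The device registry is an in-process mapping populated at import.
Network-distributed devices and real hardware adaptors are out of scope;
the registry ships only simulated device types, which is the point: every
code path runs hardware-free.

## Simulated optics

The simulated camera images a stored `(channel, Y, X)` uint16 sample.
Conventions, used consistently by the mosaic and detection modules:

* stage +x → increasing image columns, +y → increasing rows;
* pixel (0, 0) is top-left; the stage position addresses the **centre**
  of the sensor, so sensor pixel (h/2, w/2) sits at the stage position;
* regions outside the sample are zero-filled (not an error), so mosaics
  may overrun the sample edge;
* defocus is an isotropic Gaussian blur with σ = `blur_coeff`·|z −
  z_focus| in pixels. `blur_coeff` defaults to 0.5 px/µm. σ = 0 means a
  bit-exact crop. The linear-Gaussian law is the simplest model that is
  monotone in defocus; it is a stated choice, not a physical PSF.
* blur is computed on a crop padded by 4σ so tile edges see real
  neighbouring sample content rather than filter boundary artefacts;
* intensity scales linearly with light power (and, optionally, with
  exposure relative to a reference exposure) and clips at the 16-bit
  ceiling. By default an in-focus exposure reproduces the source pixels
  exactly, which gives the crop-exactness invariant its bite.

Not modelled: photon (Poisson) noise, read noise, photobleaching,
vignetting, chromatic offsets. Noise in synthetic samples is additive
Gaussian and seeded, so every image in the system is reproducible.

## Synthetic samples

`generate_synthetic_sample` builds the multi-channel sample the simulated
microscope navigates: channel 0 carries anti-aliased filled disks
("nuclei") at caller-chosen positions over a low background (default 100
counts) with seeded additive Gaussian noise (default σ = 20 counts);
other channels carry background + noise only. Disk edges are anti-aliased
with a 1 px linear ramp. Ground truth (pixel and stage coordinates per
nucleus) is returned alongside. Typical peak intensities used in tests
and the acceptance study are 800–1500 counts, i.e. peak-to-noise ratios
of roughly 40–75 — representative of well-stained DAPI nuclei rather
than a detection-limit regime.

`place_separated_nuclei` rejection-samples placements subject to a
minimum separation, a margin from the image border, and optional
avoidance of given x/y lines. The avoidance lines exist because the
detector deliberately drops circles touching tile edges (below), so a
planted-recovery study of *interior* nuclei must not plant them on tile
boundaries; edge-straddling nuclei are a known, documented miss class,
not a failure mode.

What passing planted-recovery tests shows: the geometry chain (stage →
crop → detection → stage) is consistent to sub-pixel accuracy and the
detector finds isolated disk-like objects at realistic contrast. What it
does not show: performance on textured nuclei, clumped cells, uneven
illumination or debris — real-sample behaviour is out of scope for a
simulation-first package.

## Nested stages

Axes are grouped by dimension and ordered by `rank` (0 = coarse, higher =
finer/faster). The macro position is the per-dimension sum. The split
policy prefers the fine axis (it is the fast one): the finest axis
absorbs the whole delta when the result stays inside its travel;
otherwise it is re-centred mid-range — maximising future fine travel —
clamped so the coarser axes can absorb the remainder, which recurses down
the stack. Plans are computed and validated for all dimensions before any
axis moves, so a rejected move (outside the *combined* soft limits,
reported with the offending dimension) leaves every axis untouched. A
1e-6 µm tolerance absorbs float rounding at exact limit boundaries;
conservation (move then read back) holds to 1e-9 µm. Moves are
instantaneous in simulation; settle time enters only in experiment
compilation.

## Experiment timing

Times are integer microseconds (durations rounded half-up). The loop
nesting is timepoint → Z-slice → channel, channel innermost, the common
convention that minimises stage motion. Per slice: an analogue event
drives the focus line to `z_start + k·z_step` (the commanded macro-Z in
µm), followed by a settle wait (default 1 ms). Per channel: the
filter-wheel and light-power analogue lines are updated when their value
changes (1 ms wheel settle), then light and camera digital lines rise
together, fall together after the exposure, and a readout wait follows
(default 10 ms). The light window exactly bracketing the camera exposure
is the simplest contract consistent with hardware triggering. Defaults
are keyword-overridable on `compile_experiment`.

Interval semantics: `interval_ms` is timepoint start-to-start. Interval 0
requests back-to-back volumes; a positive interval shorter than one
volume produces a warning and a best-effort (immediate) schedule.

The compiled table is the hardware payload; alongside it the table object
carries a `shots` bookkeeping list mapping each camera trigger to its
(t, z, c) indices, which is how the executor labels images without
re-deriving the experiment structure from waveforms. `validate_table`
checks monotone times, known lines, digital/analogue type correctness and
paired rising/falling edges (every line ends low); compiled tables
validate clean by construction. Execution replays events on a virtual
clock — results depend only on the table, never on wall-clock.

## The `.dv` dialect

Written files are MRC2014-conformant: 1024-byte header, mode 6 (uint16),
`nz = Z·C·T`, little-endian with matching machine stamp, `MAP ` magic,
voxel spacing in the cell dimensions, stage origin in the origin words.
Dialect specifics, all marked by `DVSM` in EXTTYP:

* extra words 25/26 hold the wavelength and timepoint counts; word 29
  holds the image-sequence code, always 0 = "ZWT" (Z fastest, then
  wavelength, then time), enforced on read;
* the extended header is one 32-byte record per plane — 8 float32: stage
  x/y/z (µm), timestamp (s), plane min/max/mean, reserved;
* per-channel wavelengths and exposures are serialized as text labels
  (`WAVES=…`, `EXPOSURES=…`) because the fixed per-plane record has no
  per-channel slot.

Plain mode-6 MRC2014 files with a zero extended header read back as
single-channel, single-timepoint stacks with empty optical metadata.
Foreign extended headers of a different record size keep their voxels and
drop the records. Unknown header bytes are preserved verbatim on
read-modify-write. The writer contains no wall-clock content, so
identical datasets produce byte-identical files; timestamps come from the
virtual clock. Interoperability is tested against gemmi as an independent
MRC2014 reader (header words and voxel values).

## Mosaics

The spiral starts at (0, 0), steps east first, then walks
counter-clockwise rings with segment lengths 1, 1, 2, 2, 3, 3, …
Handedness is a fixed decision (tested against an independent
turn-when-free turtle enumerator); the useful properties are
deterministic order, unit-step adjacency, the prefix property, and exact
coverage of {−k..k}² by the first (2k+1)² offsets. Tile pitch is the
sensor extent scaled by (1 − overlap); overlap defaults to 0 (abutting
tiles placed purely by stage coordinates — no image registration). Z is
held at the start value throughout a mosaic. A soft-limit rejection stops
the scan cleanly, keeping the partial mosaic, and the stage returns to
the start either way.

`render_region` is a deliberate CPU stand-in for GPU texture rendering:
nearest-neighbour resampling, tiles painted in acquisition order so later
(e.g. higher-magnification) tiles overpaint earlier ones, zeros where
nothing was imaged. It is idempotent for a frozen store.

## Nuclei detection

Pipeline order is fixed: Gaussian blur (default σ = 2 px) → binarise →
circular Hough over the configured radius range (default 10–30 px).
Binarisation defaults to Otsu with one guard: if the resulting foreground
exceeds 25 % of the tile, the threshold almost certainly split the noise
floor of an empty tile, and the tile is treated as containing nothing. A
fixed threshold is available where the guard is inappropriate.

The accumulator is the scikit-image normalised circular Hough transform
on the one-pixel boundary of the binary mask. Peaks are kept above an
accumulator threshold of 0.4 — measured on clean planted disks, a
blur+Otsu boundary ring supports 0.45–0.7 of the ideal circle, so the
conventional 0.5 cut rejects genuine nuclei — followed by greedy
non-maximum suppression at `radius_min`. Precision is then held by three
filters: radius inside the configured range, circularity
4π·area/perimeter² of the supporting connected component ≥ 0.8 (a digital
disk measures ≈ 0.92–0.95), and the full circle inside the tile — the
edge policy that makes boundary-straddling nuclei an acknowledged miss
class rather than a source of bad marks. Detections are reported in
accumulator-score order and are fully deterministic.

`image_to_stage` applies the module-wide convention (sensor centre =
stage position, +x = columns, +y = rows); `scan_and_mark` merges a new
detection into an existing mark when it lands within one nucleus radius —
the duplicate case that arises from overlapping tiles.

## Problem sizes and determinism

The automated acceptance study uses a 2048×2048 px sample, 12 interior
nuclei (radii 15–25 px), a 3×3 mosaic of a 512×512 px sensor at
1 µm/px, 1000 random stage moves, 200+50 random experiment
specifications, and spiral lengths to 101² — sizes chosen so the entire
study runs in seconds on one CPU while every subsystem is exercised at
scale. All randomness flows from explicit seeds; identical seeds yield
byte-identical `.dv` and points files across runs.

## Known limitations

* The defocus model is a Gaussian blur, not a diffraction PSF; blur
  monotonicity is the only optical property relied upon.
* Detection is tuned for isolated, roughly circular, bright-on-dark
  objects; touching nuclei merge into one component and may fail the
  circularity filter.
* The `.dv` dialect documents its own extended-header layout; it is
  MRC2014-compatible but does not reproduce the legacy DeltaVision field
  catalogue, and only mode 6 is supported.
* Stage motion has no velocity profile or positioning error; settle times
  are fixed constants in the action table.
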