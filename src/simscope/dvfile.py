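"""Reading and writing the '.dv' dialect of the MRC2014 image format.

A .dv file is an MRC2014 volume whose planes are the Z-slices, wavelengths
(channels) and timepoints of a 5D acquisition, plus optical metadata.  The
layout written here:

* 1024-byte MRC2014 main header, little-endian, mode 6 (unsigned 16-bit),
  ``nz`` = Z x C x T, 'MAP ' magic and matching machine stamp.  Voxel
  spacing is carried in the cell dimensions (cella / m{x,y,z}); the stage
  origin in the MRC origin words.
* The dialect marker ``DVSM`` in EXTTYP; extra words 25/26 hold the
  wavelength and timepoint counts and word 29 the image-sequence code
  (0 = "ZWT": Z fastest, then wavelength, then time — the only sequence
  this dialect writes, enforced on read).
* An extended header of one 32-byte record per plane, 8 float32 values:
  stage x/y/z (um), timestamp (s), plane min/max/mean, reserved.
* Per-channel wavelengths and exposures serialized as text labels
  (``WAVES=...`` / ``EXPOSURES=...``) in the standard label block.
* Plane data in ZWT order.

Files with a zero-length extended header and zeroed dialect words are
accepted as plain single-channel, single-timepoint MRC2014 stacks.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DVFormatError, ValidationError
from .stage import MacroPosition

__all__ = ["DVDataset", "DVReport", "write_dv", "read_dv", "validate_dv"]

HEADER_BYTES = 1024
PLANE_RECORD_FLOATS = 8
PLANE_RECORD_BYTES = 4 * PLANE_RECORD_FLOATS
MODE_UINT16 = 6
EXTTYP = b"DVSM"
NVERSION = 20140
SEQ_ZWT = 0  # Z fastest, then wavelength (channel), then time
_STAMP_LE = bytes((0x44, 0x44, 0, 0))
_STAMP_BE = bytes((0x11, 0x11, 0, 0))


@dataclass
class DVDataset:
    """A 5D acquisition: (T, C, Z, Y, X) uint16 voxels plus metadata.

    ``plane_metadata`` holds one 8-float record per plane in ZWT order
    (stage x/y/z um, timestamp s, min, max, mean, reserved); it is
    regenerated on write if absent.
    """

    data: np.ndarray
    pixel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (x, y, z)
    wavelengths_nm: list[float] = field(default_factory=list)
    exposures_ms: list[float] = field(default_factory=list)
    stage_origin_um: MacroPosition = field(default_factory=MacroPosition)
    plane_metadata: np.ndarray | None = None
    raw_header: bytes | None = None  # preserved verbatim on read-modify-write

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValidationError("dataset must be 5D (T, C, Z, Y, X)")
        if self.data.dtype != np.uint16:
            raise ValidationError("dataset voxels must be unsigned 16-bit")
        if 0 in self.data.shape:
            raise ValidationError("dataset dimensions must be positive")
        t, c, z, _, _ = self.data.shape
        if not self.wavelengths_nm:
            self.wavelengths_nm = [0.0] * c
        if not self.exposures_ms:
            self.exposures_ms = [0.0] * c
        if len(self.wavelengths_nm) != c:
            raise ValidationError("wavelengths_nm length must equal C")
        if len(self.exposures_ms) != c:
            raise ValidationError("exposures_ms length must equal C")
        if self.plane_metadata is not None:
            self.plane_metadata = np.asarray(self.plane_metadata, dtype="<f4")
            if self.plane_metadata.shape != (t * c * z, PLANE_RECORD_FLOATS):
                raise ValidationError(
                    "plane_metadata must be (T*C*T planes, 8) float records"
                )

    @property
    def shape(self) -> tuple[int, int, int, int, int]:
        return self.data.shape

    def planes_zwt(self) -> np.ndarray:
        """Planes in file order: Z fastest, then channel, then time."""
        t, c, z, h, w = self.data.shape
        return self.data.reshape(t * c * z, h, w)


def _default_plane_metadata(ds: DVDataset) -> np.ndarray:
    n = ds.planes_zwt().shape[0]
    rec = np.zeros((n, PLANE_RECORD_FLOATS), dtype="<f4")
    rec[:, 0] = ds.stage_origin_um.x_um
    rec[:, 1] = ds.stage_origin_um.y_um
    rec[:, 2] = ds.stage_origin_um.z_um
    planes = ds.planes_zwt()
    rec[:, 4] = planes.min(axis=(1, 2))
    rec[:, 5] = planes.max(axis=(1, 2))
    rec[:, 6] = planes.mean(axis=(1, 2))
    return rec


def _format_label(text: str) -> bytes:
    raw = text.encode("ascii", "replace")[:80]
    return raw + b" " * (80 - len(raw))


def write_dv(dataset: DVDataset, path: str | Path) -> Path:
    """Serialize ``dataset`` to ``path``; returns the path written.

    Byte-deterministic for a given dataset (no wall-clock content): the
    per-plane timestamps come from ``plane_metadata``.
    """
    path = Path(path)
    t, c, z, h, w = dataset.data.shape
    nplanes = t * c * z
    meta = dataset.plane_metadata
    if meta is None:
        meta = _default_plane_metadata(dataset)
    hdr = bytearray(dataset.raw_header or bytes(HEADER_BYTES))
    if len(hdr) != HEADER_BYTES:
        raise ValidationError("raw_header must be exactly 1024 bytes")
    px, py, pz = dataset.pixel_size_um
    struct.pack_into("<3i", hdr, 0, w, h, nplanes)
    struct.pack_into("<i", hdr, 12, MODE_UINT16)
    struct.pack_into("<3i", hdr, 16, 0, 0, 0)
    struct.pack_into("<3i", hdr, 28, w, h, nplanes)
    struct.pack_into("<3f", hdr, 40, w * px, h * py, nplanes * pz)
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)
    struct.pack_into(
        "<3f", hdr, 76,
        float(dataset.data.min()), float(dataset.data.max()),
        float(dataset.data.mean()),
    )
    struct.pack_into("<i", hdr, 88, 0)  # ispg: image stack
    struct.pack_into("<i", hdr, 92, nplanes * PLANE_RECORD_BYTES)
    struct.pack_into("<2i", hdr, 96, c, t)  # dialect: n wavelengths, n times
    hdr[104:108] = EXTTYP
    struct.pack_into("<i", hdr, 108, NVERSION)
    struct.pack_into("<i", hdr, 112, SEQ_ZWT)
    struct.pack_into(
        "<3f", hdr, 196,
        dataset.stage_origin_um.x_um,
        dataset.stage_origin_um.y_um,
        dataset.stage_origin_um.z_um,
    )
    hdr[208:212] = b"MAP "
    hdr[212:216] = _STAMP_LE
    struct.pack_into("<f", hdr, 216, float(dataset.data.std()))
    labels = [
        "simscope .dv dialect (MRC2014, mode 6, seq ZWT)",
        "WAVES=" + ",".join(f"{v:g}" for v in dataset.wavelengths_nm),
        "EXPOSURES=" + ",".join(f"{v:g}" for v in dataset.exposures_ms),
    ]
    struct.pack_into("<i", hdr, 220, len(labels))
    for i, text in enumerate(labels):
        hdr[224 + 80 * i : 224 + 80 * (i + 1)] = _format_label(text)
    body = dataset.planes_zwt().astype("<u2").tobytes()
    tmp = path.with_name(path.name + ".part")
    try:
        with open(tmp, "wb") as fh:
            fh.write(bytes(hdr))
            fh.write(np.ascontiguousarray(meta, dtype="<f4").tobytes())
            fh.write(body)
        os.replace(tmp, path)
    except BaseException:
        tmp.unlink(missing_ok=True)
        raise
    return path


def _parse_labels(hdr: bytes, nlabl: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for i in range(max(0, min(nlabl, 10))):
        text = hdr[224 + 80 * i : 224 + 80 * (i + 1)].decode("ascii", "replace").strip()
        if "=" in text:
            key, _, val = text.partition("=")
            out[key.strip()] = val.strip()
    return out


def read_dv(path: str | Path) -> DVDataset:
    """Parse a .dv (or plain mode-6 MRC2014) file back into a dataset."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < HEADER_BYTES:
        raise DVFormatError(
            f"truncated header: {len(raw)} < {HEADER_BYTES} bytes",
            offset=len(raw),
        )
    hdr = raw[:HEADER_BYTES]
    if hdr[208:212] != b"MAP ":
        raise DVFormatError("missing 'MAP ' magic", offset=208)
    stamp = hdr[212:216]
    if stamp[:1] == _STAMP_LE[:1]:
        bo = "<"
    elif stamp[:1] == _STAMP_BE[:1]:
        bo = ">"
    else:
        raise DVFormatError(f"unrecognised machine stamp {stamp!r}", offset=212)
    nx, ny, nz = struct.unpack_from(f"{bo}3i", hdr, 0)
    (mode,) = struct.unpack_from(f"{bo}i", hdr, 12)
    if mode != MODE_UINT16:
        raise DVFormatError(f"unsupported mode {mode} (only mode 6)", offset=12)
    if nx <= 0 or ny <= 0 or nz <= 0:
        raise DVFormatError("non-positive dimensions in header", offset=0)
    (nsymbt,) = struct.unpack_from(f"{bo}i", hdr, 92)
    n_waves, n_times = struct.unpack_from(f"{bo}2i", hdr, 96)
    dialect = hdr[104:108] == EXTTYP
    if dialect:
        (seq,) = struct.unpack_from(f"{bo}i", hdr, 112)
        if seq != SEQ_ZWT:
            raise DVFormatError(
                f"unsupported image-sequence code {seq}", offset=112
            )
    c = n_waves if dialect and n_waves > 0 else 1
    t = n_times if dialect and n_times > 0 else 1
    if nz % (c * t):
        raise DVFormatError(
            f"nz={nz} not divisible by wavelengths*timepoints={c * t}",
            offset=8,
        )
    z = nz // (c * t)
    mx, my, mz = struct.unpack_from(f"{bo}3i", hdr, 28)
    cx, cy, cz = struct.unpack_from(f"{bo}3f", hdr, 40)
    pixel = (
        cx / mx if mx > 0 else 1.0,
        cy / my if my > 0 else 1.0,
        cz / mz if mz > 0 else 1.0,
    )
    ox, oy, oz = struct.unpack_from(f"{bo}3f", hdr, 196)
    (nlabl,) = struct.unpack_from(f"{bo}i", hdr, 220)
    labels = _parse_labels(hdr, nlabl)

    data_start = HEADER_BYTES + nsymbt
    if len(raw) < data_start:
        raise DVFormatError(
            f"truncated extended header: file ends at {len(raw)}, "
            f"data expected at {data_start}",
            offset=len(raw),
        )
    meta = None
    if nsymbt:
        if nsymbt % PLANE_RECORD_BYTES:
            raise DVFormatError(
                f"extended header length {nsymbt} not a multiple of "
                f"{PLANE_RECORD_BYTES}",
                offset=92,
            )
        n_rec = nsymbt // PLANE_RECORD_BYTES
        meta = np.frombuffer(
            raw, dtype=f"{bo}f4", count=n_rec * PLANE_RECORD_FLOATS,
            offset=HEADER_BYTES,
        ).reshape(n_rec, PLANE_RECORD_FLOATS).astype("<f4")
        if n_rec != nz:
            meta = None  # foreign extended header: keep voxels, drop records
    need = nx * ny * nz * 2
    if len(raw) < data_start + need:
        raise DVFormatError(
            f"truncated data: have {len(raw) - data_start} of {need} bytes",
            offset=len(raw),
        )
    voxels = np.frombuffer(
        raw, dtype=f"{bo}u2", count=nx * ny * nz, offset=data_start
    ).reshape(t, c, z, ny, nx).astype(np.uint16)

    def _floats(key: str, n: int) -> list[float]:
        text = labels.get(key, "")
        try:
            vals = [float(v) for v in text.split(",")] if text else []
        except ValueError:
            vals = []
        return vals if len(vals) == n else [0.0] * n

    return DVDataset(
        data=voxels,
        pixel_size_um=pixel,
        wavelengths_nm=_floats("WAVES", c),
        exposures_ms=_floats("EXPOSURES", c),
        stage_origin_um=MacroPosition(ox, oy, oz),
        plane_metadata=meta,
        raw_header=bytes(hdr),
    )


@dataclass
class DVReport:
    """Result of structural validation; ``ok`` iff no violations."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_dv(path: str | Path) -> DVReport:
    """Structural checks on a .dv file; never raises for content problems."""
    report = DVReport()
    try:
        raw = Path(path).read_bytes()
    except OSError as exc:
        report.violations.append(f"unreadable: {exc}")
        return report
    if len(raw) < HEADER_BYTES:
        report.violations.append("file shorter than the 1024-byte header")
        return report
    hdr = raw[:HEADER_BYTES]
    if hdr[208:212] != b"MAP ":
        report.violations.append("missing 'MAP ' magic at byte 208")
    stamp = hdr[212:216]
    if stamp[:1] == _STAMP_LE[:1]:
        bo = "<"
    elif stamp[:1] == _STAMP_BE[:1]:
        bo = ">"
    else:
        report.violations.append(f"unrecognised machine stamp {stamp!r}")
        return report
    nx, ny, nz = struct.unpack_from(f"{bo}3i", hdr, 0)
    (mode,) = struct.unpack_from(f"{bo}i", hdr, 12)
    if mode != MODE_UINT16:
        report.violations.append(f"mode is {mode}, expected {MODE_UINT16}")
    if min(nx, ny, nz) <= 0:
        report.violations.append(f"non-positive dimensions ({nx}, {ny}, {nz})")
        return report
    (nsymbt,) = struct.unpack_from(f"{bo}i", hdr, 92)
    if nsymbt < 0:
        report.violations.append(f"negative extended header length {nsymbt}")
        return report
    if nsymbt % PLANE_RECORD_BYTES:
        report.violations.append(
            f"extended header length {nsymbt} not a multiple of the "
            f"{PLANE_RECORD_BYTES}-byte plane record"
        )
    n_waves, n_times = struct.unpack_from(f"{bo}2i", hdr, 96)
    if hdr[104:108] == EXTTYP:
        if n_waves <= 0 or n_times <= 0:
            report.violations.append(
                "dialect file with non-positive wavelength/timepoint counts"
            )
        elif nz % (n_waves * n_times):
            report.violations.append(
                f"nz={nz} inconsistent with wavelengths={n_waves} x "
                f"timepoints={n_times}"
            )
        if nsymbt and nsymbt != nz * PLANE_RECORD_BYTES:
            report.violations.append(
                f"extended header holds {nsymbt // PLANE_RECORD_BYTES} "
                f"records for {nz} planes"
            )
    expected = HEADER_BYTES + nsymbt + nx * ny * nz * 2
    if len(raw) != expected:
        report.violations.append(
            f"file size {len(raw)} != expected {expected}"
        )
    return report
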