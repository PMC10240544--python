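"""Simulated devices.

In simulation mode a camera image is a sensor-shaped subregion of a large
multi-channel source image, selected by the current stage position and the
filter-wheel channel, and blurred according to how far the stage Z sits
from the plane of best focus.  This lets every workflow in the package run
with zero hardware.

Coordinate convention (used consistently by the mosaic and detection
modules): stage +x runs along increasing image columns, stage +y along
increasing rows; pixel (0, 0) is the top-left of the source; the stage
position addresses the CENTRE of the camera sensor.  Defocus is modelled
as an isotropic Gaussian blur with sigma = blur_coeff * |z - focus_z|
(pixels), zero sigma meaning a bit-exact crop.  Regions outside the source
are filled with background value 0 so mosaics may overrun the sample edge.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage

from .devices import Handler, HandlerKind, register_device_type
from .errors import AcquisitionError, ConfigurationError, ValidationError
from .stage import AxisState

__all__ = [
    "SourceSample",
    "CameraState",
    "FilterWheelState",
    "PlantedNucleus",
    "acquire",
    "set_filter",
    "generate_synthetic_sample",
    "place_separated_nuclei",
    "default_synthetic_scene",
    "snap",
]

DEFAULT_BLUR_COEFF = 0.5  # Gaussian sigma in pixels per um of defocus
U16_MAX = 65535


@dataclass
class SourceSample:
    """The stored multi-channel sample image the simulated camera looks at."""

    data: np.ndarray  # (channel, Y, X), uint16
    pixel_size_um: float = 1.0
    focus_z_um: float = 0.0
    origin_um: tuple[float, float] = (0.0, 0.0)  # sample x, y of pixel (0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("source sample must be (channel, Y, X)")
        if self.data.dtype != np.uint16:
            raise ValidationError("source sample must be unsigned 16-bit")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class CameraState:
    sensor_shape: tuple[int, int] = (512, 512)  # (height, width) pixels
    pixel_size_um: float = 1.0  # sample-plane scale of one sensor pixel
    enabled: bool = True

    def __post_init__(self) -> None:
        h, w = self.sensor_shape
        if h <= 0 or w <= 0:
            raise ValidationError("sensor dimensions must be positive")


@dataclass(frozen=True)
class FilterWheelState:
    position: int = 0
    channel_map: Mapping[int, int] = field(default_factory=lambda: {0: 0})
    n_positions: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.position < self.n_positions:
            raise ValidationError("filter position out of range")

    @property
    def channel(self) -> int:
        return self.channel_map[self.position]


def set_filter(wheel: FilterWheelState, position: int) -> FilterWheelState:
    """Rotate the wheel; positions wrap modulo the number of slots."""
    return replace(wheel, position=int(position) % wheel.n_positions)


def _crop_zero_fill(plane: np.ndarray, row0: int, col0: int, h: int, w: int) -> np.ndarray:
    """``plane[row0:row0+h, col0:col0+w]`` with out-of-bounds zero fill."""
    out = np.zeros((h, w), dtype=plane.dtype)
    r_lo, r_hi = max(row0, 0), min(row0 + h, plane.shape[0])
    c_lo, c_hi = max(col0, 0), min(col0 + w, plane.shape[1])
    if r_lo < r_hi and c_lo < c_hi:
        out[r_lo - row0 : r_hi - row0, c_lo - col0 : c_hi - col0] = plane[
            r_lo:r_hi, c_lo:c_hi
        ]
    return out


def acquire(
    sample: SourceSample,
    camera: CameraState,
    stage_xyz_um: tuple[float, float, float],
    wheel: FilterWheelState,
    exposure_ms: float,
    *,
    light_power: float = 1.0,
    blur_coeff: float = DEFAULT_BLUR_COEFF,
    reference_exposure_ms: float | None = None,
) -> np.ndarray:
    """Simulate one camera exposure at the given stage position.

    Returns the sensor-shaped crop of the wheel-selected channel centred
    at stage (x, y), Gaussian-blurred with sigma = ``blur_coeff`` *
    |z - focus_z|.  Intensity scales linearly with ``light_power`` and,
    when ``reference_exposure_ms`` is given, with ``exposure_ms`` relative
    to that reference; the result is clipped to the 16-bit ceiling.
    """
    if not camera.enabled:
        raise AcquisitionError("camera is disabled")
    if not exposure_ms > 0:
        raise ValidationError("exposure_ms must be positive")
    channel = wheel.channel
    if not 0 <= channel < sample.n_channels:
        raise ValidationError(
            f"filter maps to channel {channel} but sample has "
            f"{sample.n_channels} channels"
        )
    x_um, y_um, z_um = stage_xyz_um
    h, w = camera.sensor_shape
    px = sample.pixel_size_um
    row0 = round((y_um - sample.origin_um[1]) / px - h / 2)
    col0 = round((x_um - sample.origin_um[0]) / px - w / 2)
    plane = sample.data[channel]
    sigma = blur_coeff * abs(z_um - sample.focus_z_um)
    scale = light_power
    if reference_exposure_ms is not None:
        scale *= exposure_ms / reference_exposure_ms
    if sigma > 0:
        margin = int(np.ceil(4 * sigma))
        padded = _crop_zero_fill(plane, row0 - margin, col0 - margin,
                                 h + 2 * margin, w + 2 * margin)
        blurred = ndimage.gaussian_filter(padded.astype(np.float64), sigma)
        img = blurred[margin : margin + h, margin : margin + w] * scale
        return np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)
    img = _crop_zero_fill(plane, row0, col0, h, w)
    if scale != 1.0:
        img = np.clip(np.rint(img.astype(np.float64) * scale), 0, U16_MAX)
    return img.astype(np.uint16)


@dataclass(frozen=True)
class PlantedNucleus:
    """Ground truth for one synthetic nucleus: pixel and stage coordinates."""

    x_px: float
    y_px: float
    radius_px: float
    peak: float
    x_um: float
    y_um: float


def generate_synthetic_sample(
    width: int,
    height: int,
    n_channels: int,
    nuclei: Sequence[tuple[float, float, float, float]],
    seed: int,
    *,
    background: float = 100.0,
    noise_sigma: float = 20.0,
    pixel_size_um: float = 1.0,
    focus_z_um: float = 0.0,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> tuple[SourceSample, list[PlantedNucleus]]:
    """Build a deterministic multi-channel sample with planted nuclei.

    ``nuclei`` is a list of (x_px, y_px, radius_px, peak) tuples; channel 0
    receives anti-aliased filled disks at those centres on a low-intensity
    background with additive Gaussian noise (other channels carry
    background + noise only).  Ground-truth centres, in both pixel and
    stage coordinates, are returned alongside the sample.
    """
    if width <= 0 or height <= 0 or n_channels <= 0:
        raise ValidationError("sample dimensions must be positive")
    rng = np.random.default_rng(seed)
    data = np.empty((n_channels, height, width), dtype=np.uint16)
    truth: list[PlantedNucleus] = []
    disks = np.zeros((height, width), dtype=np.float64)
    for x, y, r, peak in nuclei:
        if r <= 0:
            raise ValidationError("nucleus radius must be positive")
        if not (r <= x <= width - 1 - r and r <= y <= height - 1 - r):
            raise ValidationError(
                f"nucleus at ({x:g}, {y:g}) r={r:g} extends outside the sample"
            )
        x0, x1 = int(np.floor(x - r - 1)), int(np.ceil(x + r + 2))
        y0, y1 = int(np.floor(y - r - 1)), int(np.ceil(y + r + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - x, yy - y)
        disk = peak * np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
        np.maximum(disks[y0:y1, x0:x1], disk, out=disks[y0:y1, x0:x1])
        truth.append(
            PlantedNucleus(
                x_px=x, y_px=y, radius_px=r, peak=peak,
                x_um=origin_um[0] + x * pixel_size_um,
                y_um=origin_um[1] + y * pixel_size_um,
            )
        )
    for c in range(n_channels):
        plane = background + rng.normal(0.0, noise_sigma, size=(height, width))
        if c == 0:
            plane = plane + disks
        data[c] = np.clip(np.rint(plane), 0, U16_MAX).astype(np.uint16)
    sample = SourceSample(
        data, pixel_size_um=pixel_size_um, focus_z_um=focus_z_um,
        origin_um=origin_um,
    )
    return sample, truth


def place_separated_nuclei(
    width: int,
    height: int,
    n: int,
    seed: int,
    *,
    radius_range: tuple[float, float] = (15.0, 25.0),
    peak_range: tuple[float, float] = (800.0, 1500.0),
    min_separation_px: float = 120.0,
    margin_px: float = 40.0,
    region: tuple[float, float, float, float] | None = None,
    avoid_x: Sequence[float] = (),
    avoid_y: Sequence[float] = (),
) -> list[tuple[float, float, float, float]]:
    """Rejection-sample ``n`` well-separated nucleus placements.

    Candidates stay inside ``region`` = (x_lo, x_hi, y_lo, y_hi) (the whole
    image by default), at least ``min_separation_px`` apart, and at least
    ``radius + margin_px`` away from any line in ``avoid_x`` / ``avoid_y``
    (e.g. mosaic tile boundaries, where detection is unreliable by design).
    Returns (x_px, y_px, radius_px, peak) tuples for
    :func:`generate_synthetic_sample`.
    """
    rng = np.random.default_rng(seed)
    x_lo, x_hi, y_lo, y_hi = region or (0.0, float(width), 0.0, float(height))
    placed: list[tuple[float, float, float, float]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 20000:
            raise ValidationError(
                "could not place the requested nuclei: constraints too tight"
            )
        r = rng.uniform(*radius_range)
        pad = r + margin_px
        x = rng.uniform(x_lo + pad, x_hi - pad)
        y = rng.uniform(y_lo + pad, y_hi - pad)
        if not (pad <= x <= width - 1 - pad and pad <= y <= height - 1 - pad):
            continue
        if any(abs(x - line) < pad for line in avoid_x):
            continue
        if any(abs(y - line) < pad for line in avoid_y):
            continue
        if any(np.hypot(x - px_, y - py_) < min_separation_px for px_, py_, *_ in placed):
            continue
        placed.append((x, y, r, float(rng.uniform(*peak_range))))
    return placed


def default_synthetic_scene(seed: int = 0) -> tuple[SourceSample, list[PlantedNucleus]]:
    """The stock demo sample: 1024x1024, 3 channels, a loose grid of nuclei."""
    rng = np.random.default_rng(seed)
    nuclei = []
    for gy in range(4):
        for gx in range(4):
            nuclei.append(
                (
                    150.0 + gx * 240 + rng.uniform(-40, 40),
                    150.0 + gy * 240 + rng.uniform(-40, 40),
                    float(rng.uniform(15, 25)),
                    float(rng.uniform(1200, 2000)),
                )
            )
    return generate_synthetic_sample(1024, 1024, 3, nuclei, seed=seed + 1)


# ---------------------------------------------------------------------------
# Simulated device classes (registered with the depot's device registry)
# ---------------------------------------------------------------------------


def _require(settings: Mapping[str, str], key: str, device: str) -> str:
    try:
        return settings[key]
    except KeyError:
        raise ConfigurationError(
            f"device {device!r}: missing required setting {key!r}"
        ) from None


def _parse_limits(text: str, device: str) -> tuple[float, float]:
    try:
        lo, hi = (float(t) for t in text.split(":"))
    except ValueError:
        raise ConfigurationError(
            f"device {device!r}: limits must be 'low:high', got {text!r}"
        ) from None
    return lo, hi


@register_device_type("sim_stage")
class SimStage:
    """Simulated translation stage; one STAGE_AXIS handler per axis.

    Settings: ``axes`` (comma list of axis names), per-axis
    ``<name>_limits`` ('low:high' um), ``<name>_rank`` (0 = coarse),
    ``<name>_dimension`` (defaults to the axis name) and
    ``<name>_analogue_line``.
    """

    def __init__(self, name: str, settings: Mapping[str, str]):
        self.name = name
        axis_names = [a.strip() for a in _require(settings, "axes", name).split(",")]
        self.axes: list[AxisState] = []
        for ax in axis_names:
            dim = settings.get(f"{ax}_dimension", ax)
            limits = _parse_limits(
                settings.get(f"{ax}_limits", "-25000:25000"), name
            )
            line = settings.get(f"{ax}_analogue_line")
            handler = Handler(
                name=f"{name}:{ax}",
                kind=HandlerKind.STAGE_AXIS,
                device_name=name,
                analogue_line=int(line) if line is not None else None,
            )
            self.axes.append(
                AxisState(
                    handler=handler,
                    dimension=dim,
                    position_um=float(settings.get(f"{ax}_start", "0")),
                    limits_um=limits,
                    rank=int(settings.get(f"{ax}_rank", "0")),
                )
            )

    def handlers(self) -> list[Handler]:
        return [ax.handler for ax in self.axes]


@register_device_type("sim_camera")
class SimCamera:
    """Simulated camera holding the source sample it images.

    Settings: required ``sensor_shape`` ('HxW'); optional ``pixel_size_um``,
    ``digital_line``, ``blur_coeff``, and either ``source`` (multi-page
    TIFF, one page per channel) or ``synthetic_seed`` for the stock scene.
    """

    def __init__(self, name: str, settings: Mapping[str, str]):
        self.name = name
        shape_text = _require(settings, "sensor_shape", name)
        try:
            h, w = (int(t) for t in shape_text.lower().split("x"))
        except ValueError:
            raise ConfigurationError(
                f"device {name!r}: sensor_shape must be 'HxW', got {shape_text!r}"
            ) from None
        self.state = CameraState(
            sensor_shape=(h, w),
            pixel_size_um=float(settings.get("pixel_size_um", "1.0")),
        )
        self.blur_coeff = float(settings.get("blur_coeff", DEFAULT_BLUR_COEFF))
        line = settings.get("digital_line")
        self._handler = Handler(
            name=f"{name}:camera",
            kind=HandlerKind.CAMERA,
            device_name=name,
            digital_line=int(line) if line is not None else None,
        )
        self.planted: list[PlantedNucleus] = []
        if "source" in settings:
            pages = tifffile.imread(settings["source"])
            if pages.ndim == 2:
                pages = pages[None]
            self.sample = SourceSample(
                np.ascontiguousarray(pages).astype(np.uint16),
                pixel_size_um=float(settings.get("sample_pixel_size_um", "1.0")),
                focus_z_um=float(settings.get("focus_z_um", "0.0")),
            )
        else:
            seed = int(settings.get("synthetic_seed", "0"))
            self.sample, self.planted = default_synthetic_scene(seed)

    def handlers(self) -> list[Handler]:
        return [self._handler]


@register_device_type("sim_filterwheel")
class SimFilterWheel:
    """Simulated filter wheel mapping wheel positions to sample channels.

    Settings: required ``positions``; optional ``channel_map``
    ('pos:channel,...', identity by default) and ``analogue_line``.
    """

    def __init__(self, name: str, settings: Mapping[str, str]):
        self.name = name
        n = int(_require(settings, "positions", name))
        mapping = {i: i for i in range(n)}
        if "channel_map" in settings:
            mapping = {}
            for pair in settings["channel_map"].split(","):
                pos, chan = pair.split(":")
                mapping[int(pos)] = int(chan)
        self.state = FilterWheelState(position=0, channel_map=mapping, n_positions=n)
        line = settings.get("analogue_line")
        self._handler = Handler(
            name=f"{name}:wheel",
            kind=HandlerKind.FILTER_WHEEL,
            device_name=name,
            analogue_line=int(line) if line is not None else None,
        )

    def set_position(self, position: int) -> None:
        self.state = set_filter(self.state, position)

    def handlers(self) -> list[Handler]:
        return [self._handler]


@register_device_type("sim_laser")
class SimLaser:
    """Simulated light source: an on/off handler plus a power handler."""

    def __init__(self, name: str, settings: Mapping[str, str]):
        self.name = name
        self.wavelength_nm = float(settings.get("wavelength_nm", "488"))
        self.on = False
        self.power = 1.0
        dline = settings.get("digital_line")
        aline = settings.get("power_analogue_line")
        self._handlers = [
            Handler(
                name=f"{name}:source",
                kind=HandlerKind.LIGHT_SOURCE,
                device_name=name,
                digital_line=int(dline) if dline is not None else None,
            ),
            Handler(
                name=f"{name}:power",
                kind=HandlerKind.LIGHT_POWER,
                device_name=name,
                analogue_line=int(aline) if aline is not None else None,
            ),
        ]

    def handlers(self) -> list[Handler]:
        return list(self._handlers)


@register_device_type("sim_executor")
class SimExecutor:
    """Software stand-in for the hardware timing device."""

    def __init__(self, name: str, settings: Mapping[str, str]):
        self.name = name
        self._handler = Handler(
            name=f"{name}:executor",
            kind=HandlerKind.EXECUTOR,
            device_name=name,
        )

    def handlers(self) -> list[Handler]:
        return [self._handler]


def snap(depot, exposure_ms: float = 100.0, *, light_power: float = 1.0) -> np.ndarray:
    """One software-triggered exposure using the depot's current state."""
    from .stage import axes_from_depot, current_position

    cameras = depot.of_kind(HandlerKind.CAMERA)
    if not cameras:
        raise AcquisitionError("depot has no camera")
    cam_dev = depot.device_for(cameras[0])
    wheels = depot.of_kind(HandlerKind.FILTER_WHEEL)
    wheel = (
        depot.device_for(wheels[0]).state
        if wheels
        else FilterWheelState(0, {0: 0}, 1)
    )
    pos = current_position(axes_from_depot(depot))
    return acquire(
        cam_dev.sample,
        cam_dev.state,
        pos.as_tuple(),
        wheel,
        exposure_ms,
        light_power=light_power,
        blur_coeff=cam_dev.blur_coeff,
    )
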