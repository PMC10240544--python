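"""Experiment compilation and execution.

An acquisition experiment — channels x Z-stack x time-lapse — is compiled
into an *action table*: a time-ordered list of digital levels and analogue
values on named trigger lines, the same payload a hardware timing device
would replay.  Here a software executor replays the table on a virtual
clock, so experiment timing depends only on the table and is bit-for-bit
reproducible regardless of host performance.

Timing model (integer microseconds throughout):

* loop nesting is timepoint -> Z-slice -> channel (channel innermost);
* per Z-slice: an analogue event drives the focus line to
  ``z_start + k * z_step`` (the commanded macro Z in um), followed by a
  settle wait;
* per channel: the filter-wheel and light-power analogue lines are updated
  when they change, then the light and camera digital lines rise together,
  fall together ``exposure_ms`` later, and a readout wait follows;
* timepoint starts are ``interval_ms`` apart (start-to-start); if a volume
  takes longer than the interval the next timepoint starts immediately and
  a warning is issued.

Digital line ids are ``"D<n>"``, analogue ids ``"A<n>"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .devices import Depot, Handler, HandlerKind
from .dvfile import DVDataset, write_dv
from .errors import CompileError, ExecutionError, ValidationError
from .simulated import acquire
from .stage import axes_from_depot, current_position

__all__ = [
    "ChannelSpec",
    "ExperimentSpec",
    "ActionEvent",
    "ActionTable",
    "TableReport",
    "Shot",
    "compile_experiment",
    "validate_table",
    "execute_table",
    "run_experiment",
]

DEFAULT_SETTLE_US = 1_000       # wait after an analogue focus move
DEFAULT_READOUT_US = 10_000     # camera readout dead-time after exposure
DEFAULT_FILTER_SETTLE_US = 1_000


def _us(ms: float) -> int:
    """Milliseconds to integer microseconds, rounded half-up."""
    return int(np.floor(ms * 1000.0 + 0.5))


@dataclass(frozen=True)
class ChannelSpec:
    """One imaging channel: which light, camera and filter slot to use."""

    name: str
    light_handler: str
    camera_handler: str
    filter_position: int = 0
    exposure_ms: float = 100.0
    light_power_fraction: float = 1.0
    wavelength_nm: float = 0.0

    def __post_init__(self) -> None:
        if not self.exposure_ms > 0:
            raise ValidationError(f"channel {self.name!r}: exposure must be > 0")
        if not 0.0 <= self.light_power_fraction <= 1.0:
            raise ValidationError(
                f"channel {self.name!r}: light power fraction must be in [0, 1]"
            )


@dataclass(frozen=True)
class ExperimentSpec:
    """A channels x Z x time acquisition request."""

    channels: tuple[ChannelSpec, ...]
    z_start_um: float = 0.0
    z_step_um: float = 0.0
    n_slices: int = 1
    n_timepoints: int = 1
    interval_ms: float = 0.0
    save_path: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        if not self.channels:
            raise ValidationError("experiment needs at least one channel")
        if self.n_slices < 1 or self.n_timepoints < 1:
            raise ValidationError("n_slices and n_timepoints must be >= 1")
        if self.interval_ms < 0:
            raise ValidationError("interval_ms must be non-negative")

    def z_levels(self) -> list[float]:
        return [self.z_start_um + k * self.z_step_um for k in range(self.n_slices)]


@dataclass(frozen=True)
class ActionEvent:
    time_us: int
    line: str  # "D<n>" digital, "A<n>" analogue
    value: bool | float

    def __post_init__(self) -> None:
        if self.time_us < 0:
            raise ValidationError("event time must be non-negative")
        if self.line.startswith("D") and not isinstance(self.value, bool):
            raise ValidationError(f"digital line {self.line} needs a boolean")
        if self.line.startswith("A") and isinstance(self.value, bool):
            raise ValidationError(f"analogue line {self.line} needs a real")


@dataclass(frozen=True)
class Shot:
    """Bookkeeping for one camera exposure the table will trigger."""

    time_us: int
    t_index: int
    z_index: int
    c_index: int
    camera_line: str
    exposure_ms: float


@dataclass
class ActionTable:
    """Events sorted by time (stable by line id within equal times).

    ``lines`` maps each referenced line id to the owning handler name;
    ``shots`` is auxiliary bookkeeping (not part of the hardware payload)
    recording the (t, z, c) indices of each camera trigger.
    """

    events: list[ActionEvent] = field(default_factory=list)
    lines: dict[str, str] = field(default_factory=dict)
    shots: list[Shot] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.time_us, e.line))

    @property
    def duration_us(self) -> int:
        return self.events[-1].time_us if self.events else 0

    def rising_edges(self, line: str) -> list[int]:
        level = False
        out = []
        for ev in self.events:
            if ev.line == line:
                if ev.value and not level:
                    out.append(ev.time_us)
                level = bool(ev.value)
        return out

    def to_tsv(self, path: str | Path) -> Path:
        """Export the table for inspection: time_us, line, value."""
        path = Path(path)
        rows = ["time_us\tline\tvalue"]
        for ev in self.events:
            val = ("1" if ev.value else "0") if isinstance(ev.value, bool) else f"{ev.value:g}"
            rows.append(f"{ev.time_us}\t{ev.line}\t{val}")
        path.write_text("\n".join(rows) + "\n")
        return path


def _line_id(handler: Handler, analogue: bool) -> str:
    if analogue:
        if handler.analogue_line is None:
            raise CompileError(f"handler {handler.name!r} has no analogue line")
        return f"A{handler.analogue_line}"
    if handler.digital_line is None:
        raise CompileError(f"handler {handler.name!r} has no digital line")
    return f"D{handler.digital_line}"


def _focus_handler(depot: Depot) -> Handler:
    """The analogue-driven Z axis (finest rank among those with a line)."""
    best: tuple[int, Handler] | None = None
    for ax in axes_from_depot(depot):
        if ax.dimension == "z" and ax.handler.analogue_line is not None:
            if best is None or ax.rank > best[0]:
                best = (ax.rank, ax.handler)
    if best is None:
        raise CompileError("no Z stage axis exposes an analogue focus line")
    return best[1]


def compile_experiment(
    spec: ExperimentSpec,
    depot: Depot,
    *,
    settle_us: int = DEFAULT_SETTLE_US,
    readout_us: int = DEFAULT_READOUT_US,
    filter_settle_us: int = DEFAULT_FILTER_SETTLE_US,
) -> ActionTable:
    """Convert an experiment spec into a validated action table."""
    if not depot.of_kind(HandlerKind.EXECUTOR):
        raise CompileError("depot has no executor handler")
    for ch in spec.channels:
        for hname in (ch.light_handler, ch.camera_handler):
            if not depot.has_handler(hname):
                raise CompileError(
                    f"channel {ch.name!r}: unresolvable handler {hname!r}"
                )
    focus = _focus_handler(depot)
    z_line = _line_id(focus, analogue=True)
    wheels = depot.of_kind(HandlerKind.FILTER_WHEEL)
    wheel_line = None
    if wheels and wheels[0].analogue_line is not None:
        wheel_line = _line_id(wheels[0], analogue=True)

    events: list[ActionEvent] = []
    shots: list[Shot] = []
    lines: dict[str, str] = {z_line: focus.name}
    if wheel_line:
        lines[wheel_line] = wheels[0].name

    interval_us = _us(spec.interval_ms)
    wheel_pos: int | None = None
    power_state: dict[str, float] = {}
    cursor = 0
    prev_start = 0
    for t in range(spec.n_timepoints):
        start = 0 if t == 0 else prev_start + interval_us
        if start < cursor:
            # interval 0 requests back-to-back volumes; only a positive
            # interval that cannot be honoured is a scheduling overrun
            if t > 0 and interval_us > 0:
                warnings.warn(
                    f"interval {spec.interval_ms:g} ms shorter than one volume; "
                    f"timepoint {t} starts late",
                    stacklevel=2,
                )
            start = cursor
        prev_start = start
        cursor = start
        for z_index, z_um in enumerate(spec.z_levels()):
            events.append(ActionEvent(cursor, z_line, float(z_um)))
            cursor += settle_us
            for c_index, ch in enumerate(spec.channels):
                light = depot.handler(ch.light_handler)
                camera = depot.handler(ch.camera_handler)
                light_line = _line_id(light, analogue=False)
                cam_line = _line_id(camera, analogue=False)
                lines[light_line] = light.name
                lines[cam_line] = camera.name
                if wheel_line is not None and ch.filter_position != wheel_pos:
                    events.append(
                        ActionEvent(cursor, wheel_line, float(ch.filter_position))
                    )
                    cursor += filter_settle_us
                    wheel_pos = ch.filter_position
                power_dev = depot.device_for(light)
                power_handlers = [
                    h for h in power_dev.handlers()
                    if h.kind is HandlerKind.LIGHT_POWER
                    and h.analogue_line is not None
                ]
                if power_handlers:
                    p_line = _line_id(power_handlers[0], analogue=True)
                    lines[p_line] = power_handlers[0].name
                    if power_state.get(p_line) != ch.light_power_fraction:
                        events.append(
                            ActionEvent(cursor, p_line, float(ch.light_power_fraction))
                        )
                        power_state[p_line] = ch.light_power_fraction
                events.append(ActionEvent(cursor, light_line, True))
                events.append(ActionEvent(cursor, cam_line, True))
                shots.append(
                    Shot(cursor, t, z_index, c_index, cam_line, ch.exposure_ms)
                )
                cursor += _us(ch.exposure_ms)
                events.append(ActionEvent(cursor, light_line, False))
                events.append(ActionEvent(cursor, cam_line, False))
                cursor += readout_us
    table = ActionTable(events=events, lines=lines, shots=shots)
    report = validate_table(table)
    if not report.ok:  # pragma: no cover - compile output is valid by design
        raise CompileError("compiled table failed validation: "
                           + "; ".join(report.violations))
    return table


@dataclass
class TableReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_table(table: ActionTable, executor: Handler | None = None) -> TableReport:
    """Structural checks: monotone time, known lines, type-correct values,
    paired rising/falling digital edges (every line ends low)."""
    report = TableReport()
    prev = -1
    levels: dict[str, bool] = {}
    for ev in table.events:
        if ev.time_us < prev:
            report.violations.append(
                f"non-monotonic time at {ev.time_us} us on {ev.line}"
            )
        prev = max(prev, ev.time_us)
        if table.lines and ev.line not in table.lines:
            report.violations.append(f"unknown line {ev.line}")
        if ev.line.startswith("D"):
            if not isinstance(ev.value, bool):
                report.violations.append(
                    f"digital line {ev.line} carries non-boolean {ev.value!r}"
                )
                continue
            last = levels.get(ev.line, False)
            if ev.value == last:
                report.violations.append(
                    f"unpaired edge on {ev.line} at {ev.time_us} us "
                    f"(already {'high' if last else 'low'})"
                )
            levels[ev.line] = ev.value
        elif ev.line.startswith("A"):
            if isinstance(ev.value, bool) or not isinstance(ev.value, (int, float)):
                report.violations.append(
                    f"analogue line {ev.line} carries non-real {ev.value!r}"
                )
        else:
            report.violations.append(f"malformed line id {ev.line!r}")
    for line, level in sorted(levels.items()):
        if level:
            report.violations.append(f"digital line {line} left high at table end")
    return report


@dataclass(frozen=True)
class ShotResult:
    image: np.ndarray
    c_index: int
    z_index: int
    t_index: int
    timestamp_us: int


def execute_table(table: ActionTable, depot: Depot) -> list[ShotResult]:
    """Replay the table on a virtual clock against the simulated devices.

    Every camera rising edge produces one image acquired with the stage,
    filter and light-power state prevailing at that clock time; timestamps
    equal the triggering event times.
    """
    known = set(table.lines)
    cameras = {
        f"D{h.digital_line}": h
        for h in depot.of_kind(HandlerKind.CAMERA)
        if h.digital_line is not None
    }
    focus_line = None
    for ax in axes_from_depot(depot):
        if ax.dimension == "z" and ax.handler.analogue_line is not None:
            focus_line = f"A{ax.handler.analogue_line}"
    wheels = depot.of_kind(HandlerKind.FILTER_WHEEL)
    wheel_line = (
        f"A{wheels[0].analogue_line}"
        if wheels and wheels[0].analogue_line is not None
        else None
    )
    power_lines = {
        f"A{h.analogue_line}"
        for h in depot.of_kind(HandlerKind.LIGHT_POWER)
        if h.analogue_line is not None
    }
    shots_by_time = {(s.time_us, s.camera_line): s for s in table.shots}
    pos = current_position(axes_from_depot(depot))
    analogue: dict[str, float] = {}
    levels: dict[str, bool] = {}
    light_power = 1.0
    results: list[ShotResult] = []
    for ev in table.events:
        if known and ev.line not in known:
            raise ExecutionError(f"event on unregistered line {ev.line}")
        if ev.line.startswith("A"):
            analogue[ev.line] = float(ev.value)
            if ev.line in power_lines:
                light_power = float(ev.value)
            continue
        was_high = levels.get(ev.line, False)
        levels[ev.line] = bool(ev.value)
        if ev.value and not was_high and ev.line in cameras:
            cam_handler = cameras[ev.line]
            cam_dev = depot.device_for(cam_handler)
            shot = shots_by_time.get((ev.time_us, ev.line))
            if shot is None:
                raise ExecutionError(
                    f"camera edge at {ev.time_us} us has no shot annotation"
                )
            z_um = analogue.get(focus_line, pos.z_um) if focus_line else pos.z_um
            wheel_state = None
            if wheels:
                wheel_dev = depot.device_for(wheels[0])
                wheel_state = wheel_dev.state
                if wheel_line and wheel_line in analogue:
                    from .simulated import set_filter

                    wheel_state = set_filter(
                        wheel_state, int(analogue[wheel_line])
                    )
            else:
                from .simulated import FilterWheelState

                wheel_state = FilterWheelState(0, {0: 0}, 1)
            image = acquire(
                cam_dev.sample,
                cam_dev.state,
                (pos.x_um, pos.y_um, z_um),
                wheel_state,
                shot.exposure_ms,
                light_power=light_power,
                blur_coeff=cam_dev.blur_coeff,
            )
            results.append(
                ShotResult(image, shot.c_index, shot.z_index, shot.t_index, ev.time_us)
            )
    return results


def run_experiment(spec: ExperimentSpec, depot: Depot, **compile_kwargs) -> DVDataset:
    """Compile, execute and assemble a (T, C, Z, Y, X) dataset; writes the
    .dv file to ``spec.save_path`` when set.  A partially written file is
    removed on failure."""
    table = compile_experiment(spec, depot, **compile_kwargs)
    results = execute_table(table, depot)
    t_n, c_n, z_n = spec.n_timepoints, len(spec.channels), spec.n_slices
    if not results:
        raise ExecutionError("experiment produced no images")
    h, w = results[0].image.shape
    data = np.zeros((t_n, c_n, z_n, h, w), dtype=np.uint16)
    meta = np.zeros((t_n * c_n * z_n, 8), dtype="<f4")
    pos = current_position(axes_from_depot(depot))
    for r in results:
        data[r.t_index, r.c_index, r.z_index] = r.image
        plane = r.t_index * c_n * z_n + r.c_index * z_n + r.z_index
        z_um = spec.z_start_um + r.z_index * spec.z_step_um
        meta[plane] = (
            pos.x_um, pos.y_um, z_um, r.timestamp_us * 1e-6,
            float(r.image.min()), float(r.image.max()),
            float(r.image.mean()), 0.0,
        )
    z_px = abs(spec.z_step_um) if spec.z_step_um else 1.0
    cam = depot.device_for(spec.channels[0].camera_handler)
    dataset = DVDataset(
        data=data,
        pixel_size_um=(cam.state.pixel_size_um, cam.state.pixel_size_um, z_px),
        wavelengths_nm=[ch.wavelength_nm for ch in spec.channels],
        exposures_ms=[ch.exposure_ms for ch in spec.channels],
        stage_origin_um=pos,
        plane_metadata=meta,
    )
    if spec.save_path:
        write_dv(dataset, spec.save_path)
    return dataset
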