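"""Devices, handlers and the depot.

A *device* models one physical unit (a stage, a camera, a laser).  Each
device exposes one or more *handlers*: independently addressable control
facets (one axis of a stage, the on/off state of a light source, its power).
The *depot* aggregates the handlers of every configured device; the rest of
the package talks to handlers through the depot and never to devices
directly.

Device types are looked up in an in-process registry keyed by a ``type``
string.  The registry is populated when :mod:`simscope.simulated` is
imported; any class with a ``handlers()`` method can be registered.
"""

from __future__ import annotations

import configparser
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Protocol
import warnings

from .errors import ConfigurationError

__all__ = [
    "HandlerKind",
    "Handler",
    "DeviceConfig",
    "Device",
    "Depot",
    "register_device_type",
    "registered_device_types",
    "build_depot",
    "handlers_of_kind",
    "load_depot_config",
    "default_sim_config",
]


class HandlerKind(Enum):
    """The control facets a device may expose."""

    CAMERA = "camera"
    STAGE_AXIS = "stage_axis"
    LIGHT_SOURCE = "light_source"
    LIGHT_POWER = "light_power"
    FILTER_WHEEL = "filter_wheel"
    EXECUTOR = "executor"


@dataclass(frozen=True)
class Handler:
    """An addressable control facet of a device.

    Names follow the ``<device>:<facet>`` convention, which makes them
    unique by construction.  ``digital_line`` / ``analogue_line`` are the
    trigger-line indices the executor drives for this handler, if any.
    """

    name: str
    kind: HandlerKind
    device_name: str
    digital_line: int | None = None
    analogue_line: int | None = None

    def __post_init__(self) -> None:
        if self.digital_line is not None and self.digital_line < 0:
            raise ConfigurationError(
                f"handler {self.name!r}: digital_line must be non-negative"
            )
        if self.analogue_line is not None and self.analogue_line < 0:
            raise ConfigurationError(
                f"handler {self.name!r}: analogue_line must be non-negative"
            )


@dataclass(frozen=True)
class DeviceConfig:
    """One configured device: a registry key plus its settings map."""

    device_name: str
    device_type: str
    settings: Mapping[str, str] = field(default_factory=dict)


class Device(Protocol):
    """Anything exposing a name and a set of handlers can be a device."""

    name: str

    def handlers(self) -> Sequence[Handler]: ...


_REGISTRY: dict[str, Callable[[str, Mapping[str, str]], Device]] = {}


def register_device_type(
    type_name: str,
) -> Callable[[Callable[[str, Mapping[str, str]], Device]], Callable]:
    """Class decorator registering a device factory under ``type_name``."""

    def deco(factory: Callable[[str, Mapping[str, str]], Device]):
        _REGISTRY[type_name] = factory
        return factory

    return deco


def registered_device_types() -> list[str]:
    return sorted(_REGISTRY)


class Depot:
    """Registry of all handlers (and their devices) on the system."""

    def __init__(self, devices: Sequence[Device]):
        self._devices: dict[str, Device] = {}
        self._handlers: dict[str, Handler] = {}
        digital_owners: dict[int, str] = {}
        analogue_owners: dict[int, str] = {}
        for dev in devices:
            if dev.name in self._devices:
                raise ConfigurationError(f"duplicate device name {dev.name!r}")
            self._devices[dev.name] = dev
            hs = list(dev.handlers())
            if not hs:
                warnings.warn(
                    f"device {dev.name!r} exposes no handlers", stacklevel=2
                )
            for h in hs:
                if h.name in self._handlers:
                    raise ConfigurationError(
                        f"duplicate handler name {h.name!r}"
                    )
                if h.device_name != dev.name:
                    raise ConfigurationError(
                        f"handler {h.name!r} claims device "
                        f"{h.device_name!r} but was provided by {dev.name!r}"
                    )
                if h.digital_line is not None:
                    owner = digital_owners.setdefault(h.digital_line, h.name)
                    if owner != h.name:
                        raise ConfigurationError(
                            f"digital line {h.digital_line} claimed by both "
                            f"{owner!r} and {h.name!r}"
                        )
                if h.analogue_line is not None:
                    owner = analogue_owners.setdefault(h.analogue_line, h.name)
                    if owner != h.name:
                        raise ConfigurationError(
                            f"analogue line {h.analogue_line} claimed by both "
                            f"{owner!r} and {h.name!r}"
                        )
                self._handlers[h.name] = h

    @property
    def handlers(self) -> list[Handler]:
        return [self._handlers[n] for n in sorted(self._handlers)]

    @property
    def devices(self) -> list[Device]:
        return [self._devices[n] for n in sorted(self._devices)]

    def handler(self, name: str) -> Handler:
        try:
            return self._handlers[name]
        except KeyError:
            raise ConfigurationError(f"no handler named {name!r}") from None

    def has_handler(self, name: str) -> bool:
        return name in self._handlers

    def device(self, name: str) -> Device:
        try:
            return self._devices[name]
        except KeyError:
            raise ConfigurationError(f"no device named {name!r}") from None

    def device_for(self, handler: Handler | str) -> Device:
        h = handler if isinstance(handler, Handler) else self.handler(handler)
        return self.device(h.device_name)

    def of_kind(self, kind: HandlerKind) -> list[Handler]:
        return [h for h in self.handlers if h.kind is kind]


def build_depot(config: Iterable[DeviceConfig]) -> Depot:
    """Construct every configured device and aggregate their handlers.

    Raises :class:`ConfigurationError` for an unknown device type, a
    duplicate handler name, or a missing required setting (the device
    factory reports the missing key).
    """
    devices: list[Device] = []
    for dc in config:
        factory = _REGISTRY.get(dc.device_type)
        if factory is None:
            raise ConfigurationError(
                f"device {dc.device_name!r}: unknown device type "
                f"{dc.device_type!r} (known: {', '.join(registered_device_types())})"
            )
        devices.append(factory(dc.device_name, dict(dc.settings)))
    return Depot(devices)


def handlers_of_kind(depot: Depot, kind: HandlerKind) -> list[Handler]:
    """All handlers of ``kind``, name-sorted for determinism."""
    return depot.of_kind(kind)


def load_depot_config(path: str | Path) -> list[DeviceConfig]:
    """Read an INI depot description: one section per device, ``type`` key
    selecting the registry entry, remaining keys passed as settings."""
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise ConfigurationError(f"cannot read depot config {path!s}")
    configs = []
    for section in parser.sections():
        items = dict(parser.items(section))
        if "type" not in items:
            raise ConfigurationError(
                f"device section [{section}] is missing the 'type' key"
            )
        dtype = items.pop("type")
        configs.append(DeviceConfig(section, dtype, items))
    return configs


def default_sim_config(
    sample_path: str | None = None, seed: int = 0
) -> list[DeviceConfig]:
    """The hardware-free default: a simulated XYZ stage, camera, filter
    wheel, one laser and a software executor.  Used whenever no depot
    configuration is given, so the whole system runs with zero hardware.
    """
    cam_settings: dict[str, str] = {
        "sensor_shape": "512x512",
        "pixel_size_um": "1.0",
        "digital_line": "0",
    }
    if sample_path is not None:
        cam_settings["source"] = sample_path
    else:
        cam_settings["synthetic_seed"] = str(seed)
    return [
        DeviceConfig(
            "stage",
            "sim_stage",
            {
                "axes": "x,y,z",
                "x_limits": "-25000:25000",
                "y_limits": "-25000:25000",
                "z_limits": "-100:100",
                "z_analogue_line": "1",
            },
        ),
        DeviceConfig("camera", "sim_camera", cam_settings),
        DeviceConfig(
            "wheel",
            "sim_filterwheel",
            {"positions": "3", "channel_map": "0:0,1:1,2:2", "analogue_line": "2"},
        ),
        DeviceConfig(
            "laser",
            "sim_laser",
            {
                "wavelength_nm": "488",
                "digital_line": "3",
                "power_analogue_line": "4",
            },
        ),
        DeviceConfig("executor", "sim_executor", {}),
    ]
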