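"""Unified translation manager.

Real microscopes often stack several translation stages on one axis — a
coarse motorised Z stage carrying a fast high-precision piezo, say.  This
module aggregates any number of axis handlers per dimension into a single
*macro position* (the per-dimension sum of member axis positions) and
routes moves between nested axes.

Split policy for nested axes: the finest-rank (fastest) axis absorbs the
whole delta when it fits inside its remaining travel; otherwise the coarse
axis moves so the fine axis can sit mid-range (maximising future fine
travel) and the fine axis takes the remainder.  Moves are all-or-nothing:
a target outside the combined soft limits raises and leaves every axis
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections.abc import Iterable, Sequence

from .devices import Depot, Handler, HandlerKind
from .errors import ConfigurationError, SoftLimitError

__all__ = [
    "MacroPosition",
    "AxisState",
    "current_position",
    "move_to",
    "axes_from_depot",
]

DIMENSIONS = ("x", "y", "z")


@dataclass(frozen=True)
class MacroPosition:
    """An aggregate XYZ sample position in micrometres."""

    x_um: float = 0.0
    y_um: float = 0.0
    z_um: float = 0.0

    def shifted(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "MacroPosition":
        return MacroPosition(self.x_um + dx, self.y_um + dy, self.z_um + dz)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x_um, self.y_um, self.z_um)


@dataclass
class AxisState:
    """One physical translation axis.

    ``rank`` orders nested axes on the same dimension: 0 is the coarse
    stage, higher ranks are successively finer/faster (piezo) stages.
    """

    handler: Handler
    dimension: str
    position_um: float = 0.0
    limits_um: tuple[float, float] = (-25000.0, 25000.0)
    rank: int = 0

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ConfigurationError(
                f"axis {self.handler.name!r}: dimension must be one of "
                f"{DIMENSIONS}, got {self.dimension!r}"
            )
        lo, hi = self.limits_um
        if not lo < hi:
            raise ConfigurationError(
                f"axis {self.handler.name!r}: limits low must be < high"
            )
        if not lo <= self.position_um <= hi:
            raise ConfigurationError(
                f"axis {self.handler.name!r}: position outside limits"
            )

    @property
    def mid_um(self) -> float:
        lo, hi = self.limits_um
        return 0.5 * (lo + hi)


def _by_dimension(axes: Iterable[AxisState]) -> dict[str, list[AxisState]]:
    groups: dict[str, list[AxisState]] = {d: [] for d in DIMENSIONS}
    for ax in axes:
        groups[ax.dimension].append(ax)
    for d, group in groups.items():
        if not group:
            raise ConfigurationError(f"no axis assigned to dimension {d!r}")
        group.sort(key=lambda a: (a.rank, a.handler.name))
    return groups


def current_position(axes: Sequence[AxisState]) -> MacroPosition:
    """Macro position: per-dimension sum of member axis positions."""
    groups = _by_dimension(axes)
    sums = {d: sum(a.position_um for a in groups[d]) for d in DIMENSIONS}
    return MacroPosition(sums["x"], sums["y"], sums["z"])


_LIMIT_EPS_UM = 1e-6  # slack against float rounding at the exact limit


def _plan_dimension(group: Sequence[AxisState], target: float, dim: str) -> list[float]:
    """New positions for one dimension's axes (coarse-to-fine order)."""
    lows = [a.limits_um[0] for a in group]
    highs = [a.limits_um[1] for a in group]
    if not (sum(lows) - _LIMIT_EPS_UM <= target <= sum(highs) + _LIMIT_EPS_UM):
        raise SoftLimitError(
            f"target {target:g} um on {dim!r} outside combined limits "
            f"[{sum(lows):g}, {sum(highs):g}]",
            dimension=dim,
        )
    if len(group) == 1:
        return [min(max(target, lows[0]), highs[0])]
    delta = target - sum(a.position_um for a in group)
    fine = group[-1]
    fine_new = fine.position_um + delta
    if lows[-1] <= fine_new <= highs[-1]:
        # Delta fits in the fine axis's remaining travel: move it alone.
        return [a.position_um for a in group[:-1]] + [fine_new]
    # Re-centre the fine axis (clamped so the coarser axes can absorb the
    # rest) and push the remainder down the coarse side.
    rest_low = sum(lows[:-1])
    rest_high = sum(highs[:-1])
    fine_pos = min(max(fine.mid_um, target - rest_high), target - rest_low)
    fine_pos = min(max(fine_pos, lows[-1]), highs[-1])
    rest = _plan_dimension(group[:-1], target - fine_pos, dim)
    return rest + [fine_pos]


def move_to(axes: Sequence[AxisState], target: MacroPosition) -> None:
    """Move the macro position to ``target``, splitting between nested axes.

    All-or-nothing: the full plan for every dimension is computed and
    validated before any axis position changes, so a rejected move leaves
    all axes untouched.
    """
    groups = _by_dimension(axes)
    wanted = {"x": target.x_um, "y": target.y_um, "z": target.z_um}
    plan: list[tuple[AxisState, float]] = []
    for dim in DIMENSIONS:
        group = groups[dim]
        new_positions = _plan_dimension(group, wanted[dim], dim)
        plan.extend(zip(group, new_positions))
    for ax, pos in plan:
        ax.position_um = pos


def axes_from_depot(depot: Depot) -> list[AxisState]:
    """Collect the axis states owned by every stage device in the depot."""
    axes: list[AxisState] = []
    for handler in depot.of_kind(HandlerKind.STAGE_AXIS):
        dev = depot.device_for(handler)
        for ax in getattr(dev, "axes", []):
            if ax.handler.name == handler.name:
                axes.append(ax)
    return axes
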