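"""Camera viewshed geometry.

Each camera monitors a roughly trapezoidal patch of ground in front of it
(a narrow edge near the lens widening to a far edge at the effective
detection distance).  A station carries two cameras facing each other
across a trail; the station-level area used by the event models is the
larger of the two camera areas, optionally inflated by a scenario
multiplier to probe sensitivity of the estimators to viewshed size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["ViewshedScenario", "SCENARIO_MULTIPLIERS", "trapezoid_area", "station_area"]

#: The three station-area scenarios: the larger of the two camera viewsheds,
#: and that area inflated by 10% and 20%.
SCENARIO_MULTIPLIERS = {
    "largest": 1.0,
    "largest+10%": 1.1,
    "largest+20%": 1.2,
}


@dataclass(frozen=True)
class ViewshedScenario:
    """A named station-area scenario with its multiplier."""

    name: str
    multiplier: float

    def __post_init__(self) -> None:
        expected = SCENARIO_MULTIPLIERS.get(self.name)
        if expected is None:
            raise ValueError(
                f"unknown scenario {self.name!r}; choose from {sorted(SCENARIO_MULTIPLIERS)}"
            )
        if abs(self.multiplier - expected) > 1e-12:
            raise ValueError(
                f"scenario {self.name!r} requires multiplier {expected}, got {self.multiplier}"
            )

    @classmethod
    def from_name(cls, name: str) -> "ViewshedScenario":
        # accept CLI-style shorthand without the % sign
        aliases = {"largest+10": "largest+10%", "largest+20": "largest+20%"}
        name = aliases.get(name, name)
        if name not in SCENARIO_MULTIPLIERS:
            raise ValueError(
                f"unknown scenario {name!r}; choose from {sorted(SCENARIO_MULTIPLIERS)}"
            )
        return cls(name, SCENARIO_MULTIPLIERS[name])


LARGEST = ViewshedScenario.from_name("largest")


def trapezoid_area(near_width_m: float, far_width_m: float, depth_m: float) -> float:
    """Area of a trapezoidal camera viewshed in square meters.

    Parameters are the width of the monitored patch nearest the camera,
    the width at the far (detection-limit) edge, and the depth between
    the two edges.  All must be non-negative.
    """
    if near_width_m < 0 or far_width_m < 0 or depth_m < 0:
        raise ValueError("viewshed dimensions must be non-negative")
    return 0.5 * (near_width_m + far_width_m) * depth_m


def station_area(cam_areas: Iterable[float], scenario: ViewshedScenario = LARGEST) -> float:
    """Station viewshed area: the largest camera area times the scenario multiplier."""
    areas = list(cam_areas)
    if not areas:
        raise ValueError("station has no cameras")
    if any(a < 0 for a in areas):
        raise ValueError("camera areas must be non-negative")
    return max(areas) * scenario.multiplier
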