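"""Model parameters as year-anchored trajectories with scenario overlays.

Every quantity in the projection model — session counts, session lengths,
proportions of the pregnant population, lengths of stay, day weights — is a
:class:`ParameterTrajectory`: a small set of anchor-year values plus a rule
saying how to evaluate the quantity at any year of the 2011–2041 window.
The dominant rule ("linear until the last anchor, then constant") mirrors how
the underlying administrative series were projected; purely elicited constants
use the ``constant`` rule.

A :class:`ParameterSet` is the full collection of trajectories shared by all
scenarios; a :class:`ScenarioSpec` is a named overlay of replacement
trajectories. Applying an overlay never mutates its inputs.

Percent-valued inputs are converted to proportions at load time and converted
back on output, so that all internal arithmetic works on the [0, 1] scale.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

YEAR_MIN = 2011
YEAR_MAX = 2041
BASE_YEAR = 2016

RULES = ("piecewise_linear_then_constant", "constant", "step_at_anchor")

#: units accepted in fixture files; "percent" is normalised to "proportion"
UNITS = ("minutes", "sessions", "services", "days", "proportion", "count", "percent")

PARITIES = ("primiparous", "multiparous")
SOI_LEVELS = ("1", "2", "3_4")
DRGS = ("540", "560")  # caesarean, vaginal

#: ids the pillar computations require from any parameter set
REQUIRED_IDS = tuple(
    [
        "stays_childbirth",
        "p_modhigh_risk",
        "p_poverty",
        "p_multiparous",
        "len_first_session",
        "len_follow_low",
        "len_follow_modhigh",
        "len_extra_ses",
        "n_prenatal_modhigh",
        "n_birthprep_extra_ses",
        "len_birthprep_ind",
        "len_birthprep_group",
        "group_session_size",
        "n_postnatal_d1_5",
        "n_postnatal_complication",
        "n_breastfeeding",
        "coordination_uplift",
        "other_activity_rate",
    ]
    + [f"n_prenatal_low[{p}]" for p in PARITIES]
    + [f"n_birthprep_ind[{p}]" for p in PARITIES]
    + [f"n_birthprep_group[{p}]" for p in PARITIES]
    + [f"n_postnatal_d6plus[{p}]" for p in PARITIES]
    + [f"day_weights[{s}][{d}]" for s in SOI_LEVELS for d in range(1, 6)]
)


class ValidationError(ValueError):
    """Raised when a trajectory, parameter set, or overlay violates its contract."""


@dataclass(frozen=True)
class ParameterTrajectory:
    """A named quantity with anchor-year values and an evaluation rule.

    ``anchors`` maps year -> value, with strictly increasing years and finite
    values. ``proportion`` trajectories must stay within [0, 1].
    """

    id: str
    unit: str
    anchors: Mapping[int, float]
    rule: str = "piecewise_linear_then_constant"

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValidationError(f"{self.id}: anchors must be non-empty")
        if any(not math.isfinite(v) for v in self.anchors.values()):
            raise ValidationError(f"{self.id}: anchor values must be finite")
        if self.rule not in RULES:
            raise ValidationError(f"{self.id}: unknown rule {self.rule!r}")
        if self.rule == "constant" and len(self.anchors) != 1:
            raise ValidationError(f"{self.id}: 'constant' rule takes exactly one anchor")
        # anchors are keyed by year, so years are unique; store them sorted
        object.__setattr__(self, "anchors", dict(sorted(self.anchors.items())))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.anchors)

    def value(self, year: int) -> float:
        return interpolate(self, year)

    def scaled(self, factors: Mapping[int, float]) -> "ParameterTrajectory":
        """Return a copy with each anchor multiplied by its factor (default 1)."""
        anchors = {y: v * factors.get(y, 1.0) for y, v in self.anchors.items()}
        return dataclasses.replace(self, anchors=anchors)


def interpolate(traj: ParameterTrajectory, year: int) -> float:
    """Evaluate ``traj`` at ``year`` under its rule.

    ``piecewise_linear_then_constant``: linear between bracketing anchors,
    flat before the first and after the last anchor. ``constant``: the single
    anchor value everywhere. ``step_at_anchor``: value of the latest anchor
    at or before ``year`` (the first anchor before the series starts).
    """
    if not YEAR_MIN <= year <= YEAR_MAX:
        raise ValidationError(
            f"{traj.id}: year {year} outside the model window {YEAR_MIN}-{YEAR_MAX}"
        )
    years = np.fromiter(traj.anchors, dtype=float)
    values = np.fromiter(traj.anchors.values(), dtype=float)
    if traj.rule == "constant":
        return float(values[0])
    if traj.rule == "step_at_anchor":
        idx = int(np.searchsorted(years, year, side="right")) - 1
        return float(values[max(idx, 0)])
    if year in traj.anchors:  # exact pass-through, no float round trip
        return float(traj.anchors[year])
    return float(np.interp(year, years, values))


@dataclass
class ParameterSet:
    """All trajectories of the model plus the reference frame (base year, horizon)."""

    trajectories: dict[str, ParameterTrajectory]
    base_year: int = BASE_YEAR
    horizon: tuple[int, int] = (BASE_YEAR, YEAR_MAX)

    def value(self, trajectory_id: str, year: int) -> float:
        try:
            traj = self.trajectories[trajectory_id]
        except KeyError:
            raise ValidationError(f"unknown trajectory id {trajectory_id!r}") from None
        return interpolate(traj, year)

    def ids(self) -> frozenset[str]:
        return frozenset(self.trajectories)

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.trajectories), self.base_year, self.horizon)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named overlay of trajectory overrides on the common parameter set."""

    name: str
    overrides: Mapping[str, ParameterTrajectory] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "overrides", dict(self.overrides))


def apply_overlay(common: ParameterSet, scenario: ScenarioSpec) -> ParameterSet:
    """Return a new set with the scenario's overrides in place of the common ones.

    Overrides must reference ids that exist in the common set; inputs are not
    modified.
    """
    unknown = sorted(set(scenario.overrides) - set(common.trajectories))
    if unknown:
        raise ValidationError(
            f"scenario {scenario.name!r} overrides unknown trajectory ids: "
            + ", ".join(unknown)
        )
    merged = dict(common.trajectories)
    merged.update(scenario.overrides)
    return ParameterSet(merged, common.base_year, common.horizon)


def validate(params: ParameterSet, required_ids: Iterable[str] = REQUIRED_IDS) -> list[str]:
    """Return a list of violations (empty list iff the set is valid)."""
    report: list[str] = []
    for rid in required_ids:
        if rid not in params.trajectories:
            report.append(f"missing required trajectory: {rid}")
    for tid, traj in params.trajectories.items():
        for year, value in traj.anchors.items():
            if not math.isfinite(value):
                report.append(f"{tid}: non-finite value at {year}")
            elif traj.unit == "proportion" and not 0.0 <= value <= 1.0:
                report.append(f"{tid}: proportion {value} at {year} outside [0, 1]")
            elif tid.startswith("day_weights") and value <= 0:
                report.append(f"{tid}: day weight must be positive, got {value}")
        if traj.id != tid:
            report.append(f"key {tid!r} does not match trajectory id {traj.id!r}")
    gs = params.trajectories.get("group_session_size")
    if gs is not None and next(iter(gs.anchors.values())) <= 0:
        report.append("group_session_size: must be positive")
    return report


# ---------------------------------------------------------------------------
# CSV interchange: one row per (trajectory id, anchor year, value, unit, rule)

def trajectories_from_frame(frame: pd.DataFrame) -> dict[str, ParameterTrajectory]:
    """Build trajectories from a long-format table (percent -> proportion)."""
    needed = {"trajectory_id", "unit", "rule", "year", "value"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValidationError(f"parameter table missing columns: {sorted(missing)}")
    out: dict[str, ParameterTrajectory] = {}
    for tid, rows in frame.groupby("trajectory_id", sort=False):
        units = rows["unit"].unique()
        rules = rows["rule"].unique()
        if len(units) != 1 or len(rules) != 1:
            raise ValidationError(f"{tid}: inconsistent unit/rule across rows")
        unit, rule = units[0], rules[0]
        if unit not in UNITS:
            raise ValidationError(f"{tid}: unknown unit {unit!r}")
        scale = 0.01 if unit == "percent" else 1.0
        anchors = {
            int(y): round(float(v) * scale, 12)
            for y, v in sorted(zip(rows["year"], rows["value"]))
        }
        out[tid] = ParameterTrajectory(
            id=tid,
            unit="proportion" if unit == "percent" else unit,
            anchors=anchors,
            rule=rule,
        )
    return out


def trajectories_to_frame(trajectories: Mapping[str, ParameterTrajectory]) -> pd.DataFrame:
    """Inverse of :func:`trajectories_from_frame` (proportions written as percent)."""
    records = []
    for traj in trajectories.values():
        percent = traj.unit == "proportion"
        for year, value in traj.anchors.items():
            records.append(
                {
                    "trajectory_id": traj.id,
                    "unit": "percent" if percent else traj.unit,
                    "rule": traj.rule,
                    "year": year,
                    "value": round(value * 100, 10) if percent else value,
                }
            )
    return pd.DataFrame.from_records(records)


def load_parameter_csv(path) -> dict[str, ParameterTrajectory]:
    return trajectories_from_frame(pd.read_csv(path))
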