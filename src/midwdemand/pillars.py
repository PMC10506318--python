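"""Per-year consumption of the five midwifery activity pillars.

Four pillars respond to the scenarios:

* ``prenatal`` — individual obstetric sessions, in minutes. Per pregnancy the
  expected time is ``min(n,1)·len_first + max(n−1,0)·len_follow(risk)``, plus
  ``n·len_extra`` for vulnerable households, all inflated by the coordination
  uplift. Session counts are expected values per pregnancy, so the first
  session is a fraction whenever n < 1.
* ``birth_prep`` — birth-preparation and parenting education, in minutes:
  individual sessions at full length, group sessions at length divided by the
  group size, plus extra individual sessions for vulnerable households.
* ``inpatient_postnatal`` — delivery and early postnatal hospital workload in
  weighted day-units: each case-mix cell contributes its stay workload (day
  weights summed over the length of stay, fractional last day pro-rata).
* ``outpatient_postnatal`` — home/ambulatory postnatal care in
  service-equivalents: early services before day 6 (observed per-stay averages
  up to 2016, one service per home day — 5 minus mean length of stay — from
  2021), services from day 6 by parity, complication services, breastfeeding
  consultations; all inflated by the coordination uplift.

The fifth pillar (``other``: fertility, neonatology, research, ...) is not
scenario-sensitive. By default it is held constant *per pregnancy*, so its
total scales with the projected number of stays; ``other="frozen"`` holds the
total absolutely constant instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .caseload import CaseloadTable, CasemixCell
from .params import ParameterSet, SOI_LEVELS, ValidationError

PILLARS = ("prenatal", "birth_prep", "inpatient_postnatal", "outpatient_postnatal", "other")

PILLAR_UNITS = {
    "prenatal": "minutes",
    "birth_prep": "minutes",
    "inpatient_postnatal": "weighted_day_units",
    "outpatient_postnatal": "service_equivalents",
    "other": "service_equivalents",
}

#: year from which the early-postnatal row switches to the one-per-home-day rule
EARLY_RULE_YEAR = 2021


@dataclass
class PillarConsumption:
    """Per-year consumption of one pillar, in pillar-specific units."""

    pillar: str
    unit: str
    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pillar not in PILLARS:
            raise ValidationError(f"unknown pillar {self.pillar!r}")
        for year, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{self.pillar}: invalid value {v} at {year}")


class DayWeightTable:
    """Hospital-day weights per severity level, day 5 reused beyond day 5."""

    def __init__(self, weights: Mapping[str, tuple[float, ...]]):
        if set(weights) != set(SOI_LEVELS):
            raise ValidationError(f"day weights must cover SOI levels {SOI_LEVELS}")
        for soi, row in weights.items():
            if len(row) != 5 or any(w <= 0 for w in row):
                raise ValidationError(f"SOI {soi}: need 5 positive day weights")
        self._weights = {soi: tuple(row) for soi, row in weights.items()}

    @classmethod
    def from_params(cls, params: ParameterSet) -> "DayWeightTable":
        return cls(
            {
                soi: tuple(
                    params.value(f"day_weights[{soi}][{d}]", params.base_year)
                    for d in range(1, 6)
                )
                for soi in SOI_LEVELS
            }
        )

    def weight(self, soi: str, day: int) -> float:
        if soi not in self._weights:
            raise ValidationError(f"unknown SOI level {soi!r}")
        return self._weights[soi][min(day, 5) - 1]


def stay_workload(weights: DayWeightTable, soi: str, alos: float) -> float:
    """Weighted day-units of one stay of mean length ``alos`` at severity ``soi``.

    Whole days contribute their full weight; the fractional last day
    contributes pro-rata; days beyond the fifth reuse the day-5 weight.
    """
    if alos < 0:
        raise ValidationError(f"negative length of stay {alos}")
    whole = int(math.floor(alos))
    total = sum(weights.weight(soi, d) for d in range(1, whole + 1))
    frac = alos - whole
    if frac > 0:
        total += frac * weights.weight(soi, whole + 1)
    return total


# ---------------------------------------------------------------------------
# per-pregnancy expected values (shared with the microsimulation oracle)

def _uplift(params: ParameterSet, year: int) -> float:
    return 1.0 + params.value("coordination_uplift", year)


def prenatal_minutes_per_pregnancy(
    params: ParameterSet, year: int, risk: str, parity: str, vulnerable: bool
) -> float:
    if risk == "low":
        n = params.value(f"n_prenatal_low[{parity}]", year)
        len_follow = params.value("len_follow_low", year)
    else:
        n = params.value("n_prenatal_modhigh", year)
        len_follow = params.value("len_follow_modhigh", year)
    if n < 0:
        raise ValidationError(f"negative session count {n}")
    minutes = (
        min(n, 1.0) * params.value("len_first_session", year)
        + max(n - 1.0, 0.0) * len_follow
    )
    if vulnerable:
        minutes += n * params.value("len_extra_ses", year)
    return minutes * _uplift(params, year)


def birthprep_minutes_per_pregnancy(
    params: ParameterSet, year: int, parity: str, vulnerable: bool
) -> float:
    group_size = params.value("group_session_size", year)
    if group_size <= 0:
        raise ValidationError(f"group session size must be positive, got {group_size}")
    minutes = (
        params.value(f"n_birthprep_ind[{parity}]", year)
        * params.value("len_birthprep_ind", year)
        + params.value(f"n_birthprep_group[{parity}]", year)
        * params.value("len_birthprep_group", year)
        / group_size
    )
    if vulnerable:
        # extra sessions for vulnerable households are individual sessions
        minutes += (
            params.value("n_birthprep_extra_ses", year)
            * params.value("len_birthprep_ind", year)
        )
    return minutes


def mean_alos(params: ParameterSet, casemix: Mapping[CasemixCell, float], year: int) -> float:
    """Case-mix weighted mean length of stay, in days."""
    if not casemix:
        raise ValidationError("case-mix shares required to compute mean length of stay")
    return sum(
        share * params.value(f"alos[{drg}][{soi}][{age}]", year)
        for (drg, soi, age), share in casemix.items()
    )


def early_postnatal_services(
    params: ParameterSet,
    casemix: Mapping[CasemixCell, float],
    year: int,
    convention: str = "home_days",
) -> float:
    """Postnatal services up to day 5 postpartum, per stay.

    Observed per-stay averages apply through 2016. From ``EARLY_RULE_YEAR`` on,
    the elicited rule is one service per home day before day 6, i.e.
    ``max(0, 5 − mean ALOS)`` (``convention="home_days"``), or a flat one
    service per stay (``convention="per_stay"``). Years in between blend the
    two linearly.
    """
    def rule_value(y: int) -> float:
        if convention == "per_stay":
            return 1.0
        alos = mean_alos(params, casemix, y)
        if alos < 0:
            raise ValidationError(f"negative mean length of stay {alos}")
        return max(0.0, 5.0 - alos)

    if year >= EARLY_RULE_YEAR:
        return rule_value(year)
    observed = params.trajectories["n_postnatal_d1_5"]
    last_obs = max(observed.anchors)
    if year <= last_obs:
        return observed.value(year)
    w = (year - last_obs) / (EARLY_RULE_YEAR - last_obs)
    return (1 - w) * observed.value(last_obs) + w * rule_value(EARLY_RULE_YEAR)


def outpatient_services_per_pregnancy(
    params: ParameterSet, year: int, parity: str, early: float
) -> float:
    services = (
        early
        + params.value(f"n_postnatal_d6plus[{parity}]", year)
        + params.value("n_postnatal_complication", year)
        + params.value("n_breastfeeding", year)
    )
    return services * _uplift(params, year)


# ---------------------------------------------------------------------------
# aggregate pillar consumption

def prenatal_consumption(caseload: CaseloadTable, params: ParameterSet, year: int) -> float:
    """Total prenatal obstetric-session minutes in ``year``."""
    return sum(
        count * prenatal_minutes_per_pregnancy(params, year, risk, parity, vulnerable)
        for (risk, parity, vulnerable), count in caseload.strata.items()
    )


def birth_prep_consumption(caseload: CaseloadTable, params: ParameterSet, year: int) -> float:
    """Total birth-preparation minutes in ``year``."""
    return sum(
        count * birthprep_minutes_per_pregnancy(params, year, parity, vulnerable)
        for (_risk, parity, vulnerable), count in caseload.strata.items()
    )


def inpatient_consumption(caseload: CaseloadTable, params: ParameterSet, year: int) -> float:
    """Total weighted day-units of delivery/postnatal hospital stays in ``year``."""
    if not caseload.casemix:
        raise ValidationError("caseload has no case-mix shares")
    weights = DayWeightTable.from_params(params)
    per_stay = sum(
        share * stay_workload(weights, soi, params.value(f"alos[{drg}][{soi}][{age}]", year))
        for (drg, soi, age), share in caseload.casemix.items()
    )
    return caseload.total_stays * per_stay


def outpatient_postnatal_consumption(
    caseload: CaseloadTable,
    params: ParameterSet,
    year: int,
    early_convention: str = "home_days",
) -> float:
    """Total outpatient postnatal service-equivalents in ``year``."""
    early = early_postnatal_services(params, caseload.casemix, year, early_convention)
    return sum(
        count * outpatient_services_per_pregnancy(params, year, parity, early)
        for (_risk, parity, _vuln), count in caseload.strata.items()
    )


def other_consumption(
    caseload: CaseloadTable,
    params: ParameterSet,
    year: int,
    convention: str = "stays_proportional",
) -> float:
    """Scenario-insensitive activities (fertility, neonatology, research, ...).

    ``stays_proportional`` (default): constant per pregnancy, so the total
    follows the demographic stays series. ``frozen``: constant total.
    """
    rate = params.value("other_activity_rate", year)
    if convention == "frozen":
        return params.value("stays_childbirth", params.base_year) * rate
    return caseload.total_stays * rate
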