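"""End-to-end projection: parameters + scenario -> pillar series -> index."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import caseload as cl
from . import pillars as pl
from .aggregate import AllocationKey, DemandIndexSeries, demand_index
from .params import ParameterSet, ScenarioSpec, ValidationError, apply_overlay


@dataclass(frozen=True)
class RunOptions:
    """Modelling conventions that are selectable but have documented defaults."""

    early_postnatal: str = "home_days"  # or "per_stay"
    other_pillar: str = "stays_proportional"  # or "frozen"

    def __post_init__(self) -> None:
        if self.early_postnatal not in ("home_days", "per_stay"):
            raise ValidationError(f"unknown early-postnatal convention {self.early_postnatal!r}")
        if self.other_pillar not in ("stays_proportional", "frozen"):
            raise ValidationError(f"unknown other-pillar convention {self.other_pillar!r}")


def pillar_series(
    params: ParameterSet,
    casemix: Mapping[cl.CasemixCell, float],
    years: Iterable[int],
    options: RunOptions = RunOptions(),
) -> list[pl.PillarConsumption]:
    """Compute all five pillar consumption series over ``years``.

    The base year is always included so the series can be indexed.
    """
    years = sorted(set(years) | {params.base_year})
    values: dict[str, dict[int, float]] = {p: {} for p in pl.PILLARS}
    for year in years:
        table = cl.stratify(params, year, casemix=casemix)
        values["prenatal"][year] = pl.prenatal_consumption(table, params, year)
        values["birth_prep"][year] = pl.birth_prep_consumption(table, params, year)
        values["inpatient_postnatal"][year] = pl.inpatient_consumption(table, params, year)
        values["outpatient_postnatal"][year] = pl.outpatient_postnatal_consumption(
            table, params, year, early_convention=options.early_postnatal
        )
        values["other"][year] = pl.other_consumption(
            table, params, year, convention=options.other_pillar
        )
    return [
        pl.PillarConsumption(pillar=p, unit=pl.PILLAR_UNITS[p], values=values[p])
        for p in pl.PILLARS
    ]


def run_scenario(
    common: ParameterSet,
    scenario: ScenarioSpec,
    casemix: Mapping[cl.CasemixCell, float],
    key: AllocationKey,
    years: Sequence[int],
    options: RunOptions = RunOptions(),
) -> DemandIndexSeries:
    """Apply the scenario overlay, compute pillar series, and index them."""
    params = apply_overlay(common, scenario)
    pillars = pillar_series(params, casemix, years, options)
    return demand_index(pillars, key, base_year=common.base_year, scenario=scenario.name)


def run_all(
    common: ParameterSet,
    scenarios: Mapping[str, ScenarioSpec],
    casemix: Mapping[cl.CasemixCell, float],
    key: AllocationKey,
    years: Sequence[int],
    options: RunOptions = RunOptions(),
) -> dict[str, DemandIndexSeries]:
    return {
        name: run_scenario(common, spec, casemix, key, years, options)
        for name, spec in scenarios.items()
    }
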