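"""Allocation-key aggregation of pillar consumption into demand indices.

Pillars are measured in incompatible units (minutes, weighted day-units,
service-equivalents), so levels cannot be summed. Instead each pillar's
*relative* change since the base year is weighted by its share of total
midwifery activity in that base year (the allocation key):

    contribution_p(t) = 100 · w_p · (C_p(t) / C_p(base) − 1)
    total(t)          = Σ_p contribution_p(t)

The total is the percent change in overall demand vs the base year; the
per-pillar terms are its exact percentage-point decomposition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .params import ValidationError
from .pillars import PILLARS, PillarConsumption

logger = logging.getLogger(__name__)

DEFAULT_TABLE_YEARS = (2021, 2026, 2031, 2036, 2041)


@dataclass(frozen=True)
class AllocationKey:
    """Base-year share of total midwifery activity per pillar (sums to 1)."""

    shares: Mapping[str, float]
    reference_year: int = 2016

    def __post_init__(self) -> None:
        if set(self.shares) != set(PILLARS):
            raise ValidationError(
                f"allocation key must cover exactly the pillars {PILLARS}"
            )
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"allocation-key shares sum to {total}, expected 1")
        object.__setattr__(self, "shares", dict(self.shares))


def normalize_allocation_key(
    raw_shares: Mapping[str, float], reference_year: int = 2016
) -> AllocationKey:
    """Normalise raw (percent-scale) shares to proportions summing to 1.

    A deviation of the raw sum from 100 by more than 0.1 is logged as a
    warning before renormalising.
    """
    if any(v < 0 for v in raw_shares.values()):
        raise ValidationError("allocation-key shares must be nonnegative")
    total = sum(raw_shares.values())
    if total == 0:
        raise ValidationError("allocation-key shares are all zero")
    if abs(total - 100.0) > 0.1:
        logger.warning(
            "allocation key sums to %.3f (expected 100); renormalising", total
        )
    return AllocationKey(
        {pillar: value / total for pillar, value in raw_shares.items()},
        reference_year=reference_year,
    )


def allocation_key_from_frame(frame: pd.DataFrame, reference_year: int = 2016) -> AllocationKey:
    return normalize_allocation_key(
        dict(zip(frame["pillar"], frame["share_percent"])), reference_year
    )


@dataclass
class DemandIndexSeries:
    """Total percent change vs the base year and its pillar decomposition."""

    scenario: str
    base_year: int
    totals: dict[int, float] = field(default_factory=dict)
    contributions: dict[tuple[int, str], float] = field(default_factory=dict)
    #: within-pillar percent change (the alternative, unweighted reading)
    pillar_changes: dict[tuple[int, str], float] = field(default_factory=dict)

    def contribution(self, year: int, pillar: str) -> float:
        return self.contributions[(year, pillar)]


def demand_index(
    pillars: Sequence[PillarConsumption],
    key: AllocationKey,
    base_year: int = 2016,
    scenario: str = "",
) -> DemandIndexSeries:
    """Weight pillar changes vs ``base_year`` by the allocation key.

    Every pillar must have a positive base-year value; the index is invariant
    to rescaling any single pillar's unit.
    """
    series = DemandIndexSeries(scenario=scenario, base_year=base_year)
    years = sorted({y for p in pillars for y in p.values})
    for pillar in pillars:
        base = pillar.values.get(base_year)
        if base is None or base <= 0 or not math.isfinite(base):
            raise ValidationError(
                f"pillar {pillar.pillar!r}: base-year ({base_year}) value must be "
                f"positive, got {base}"
            )
    for year in years:
        total = 0.0
        for pillar in pillars:
            change = pillar.values[year] / pillar.values[base_year] - 1.0
            contribution = 100.0 * key.shares[pillar.pillar] * change
            series.contributions[(year, pillar.pillar)] = contribution
            series.pillar_changes[(year, pillar.pillar)] = 100.0 * change
            total += contribution
        series.totals[year] = total
    return series


def scenario_table(
    indices: Mapping[str, DemandIndexSeries],
    years: Iterable[int] = DEFAULT_TABLE_YEARS,
) -> pd.DataFrame:
    """One row per scenario, one column per year, totals in percent vs base."""
    years = list(years)
    rows = {}
    for name, series in indices.items():
        missing = [y for y in years if y not in series.totals]
        if missing:
            raise ValidationError(f"scenario {name!r}: no totals for years {missing}")
        rows[name] = [series.totals[y] for y in years]
    return pd.DataFrame.from_dict(rows, orient="index", columns=years).rename_axis("scenario")


def decomposition_table(indices: Mapping[str, DemandIndexSeries]) -> pd.DataFrame:
    """Long-format per-pillar decomposition across scenarios and years.

    ``contribution_pp`` are allocation-key-weighted percentage points (they sum
    to the total); ``within_pillar_pct`` is each pillar's own percent change.
    """
    records = []
    for name, series in indices.items():
        for (year, pillar), contribution in sorted(series.contributions.items()):
            records.append(
                {
                    "scenario": name,
                    "year": year,
                    "pillar": pillar,
                    "contribution_pp": contribution,
                    "within_pillar_pct": series.pillar_changes[(year, pillar)],
                }
            )
    return pd.DataFrame.from_records(records)
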