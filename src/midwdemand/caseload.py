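"""Annual caseload: total childbirth stays, pregnancy strata, hospital case mix.

The projection distinguishes pregnancies along three binary axes — risk level
(low vs moderate/high), parity (primiparous vs multiparous) and socioeconomic
vulnerability (household below the poverty threshold) — and, for inpatient
workload, hospital case-mix cells (APR-DRG 540 caesarean / 560 vaginal ×
severity-of-illness level × maternal age band). Only the marginal shares of
the three axes are observed, so the eight strata are completed under
independence; a joint distribution can be supplied instead via CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .params import ParameterSet, SOI_LEVELS, DRGS, ValidationError

RISKS = ("low", "modhigh")
PARITIES = ("primiparous", "multiparous")
VULNERABILITY = (False, True)

#: (risk, parity, vulnerable) triples in a fixed order
STRATA = tuple(
    (risk, parity, vulnerable)
    for risk in RISKS
    for parity in PARITIES
    for vulnerable in VULNERABILITY
)

Stratum = tuple[str, str, bool]
CasemixCell = tuple[str, str, str]  # (drg, soi, age_band)


@dataclass
class StratumShares:
    year: int
    p_modhigh: float
    p_multiparous: float
    p_vulnerable: float

    def __post_init__(self) -> None:
        for name in ("p_modhigh", "p_multiparous", "p_vulnerable"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")


@dataclass
class CaseloadTable:
    """Stays in one year, split into strata counts and case-mix shares."""

    year: int
    total_stays: float
    strata: dict[Stratum, float]
    casemix: dict[CasemixCell, float] = field(default_factory=dict)

    def parity_share(self, parity: str) -> float:
        total = sum(self.strata.values())
        return sum(v for (r, p, s), v in self.strata.items() if p == parity) / total


def project_stays(params: ParameterSet, year: int) -> float:
    """Number of hospital stays involving childbirth (anchor years exact)."""
    return params.value("stays_childbirth", year)


def shares_for_year(params: ParameterSet, year: int) -> StratumShares:
    return StratumShares(
        year=year,
        p_modhigh=params.value("p_modhigh_risk", year),
        p_multiparous=params.value("p_multiparous", year),
        p_vulnerable=params.value("p_poverty", year),
    )


def stratify(
    params: ParameterSet,
    year: int,
    casemix: Mapping[CasemixCell, float] | None = None,
    joint: Mapping[Stratum, float] | None = None,
) -> CaseloadTable:
    """Split the projected stays of ``year`` into the eight strata.

    By default stratum shares are products of the marginals (independence);
    ``joint`` may supply an explicit stratum -> share mapping instead.
    """
    total = project_stays(params, year)
    if joint is not None:
        s = sum(joint.values())
        if abs(s - 1.0) > 1e-6:
            raise ValidationError(f"joint stratum shares sum to {s}, expected 1")
        strata = {stratum: total * joint.get(stratum, 0.0) for stratum in STRATA}
    else:
        sh = shares_for_year(params, year)
        strata = {}
        for risk, parity, vulnerable in STRATA:
            share = (
                (sh.p_modhigh if risk == "modhigh" else 1.0 - sh.p_modhigh)
                * (sh.p_multiparous if parity == "multiparous" else 1.0 - sh.p_multiparous)
                * (sh.p_vulnerable if vulnerable else 1.0 - sh.p_vulnerable)
            )
            strata[(risk, parity, vulnerable)] = total * share
    cm = dict(casemix) if casemix is not None else {}
    if cm:
        validate_casemix(cm)
    return CaseloadTable(year=year, total_stays=total, strata=strata, casemix=cm)


def validate_casemix(casemix: Mapping[CasemixCell, float]) -> None:
    s = sum(casemix.values())
    if abs(s - 1.0) > 1e-6:
        raise ValidationError(f"case-mix shares sum to {s}, expected 1")
    for (drg, soi, _age), share in casemix.items():
        if drg not in DRGS:
            raise ValidationError(f"unknown APR-DRG {drg!r}")
        if soi not in SOI_LEVELS:
            raise ValidationError(f"unknown SOI level {soi!r}")
        if share < 0:
            raise ValidationError("case-mix shares must be nonnegative")


def casemix_from_frame(frame: pd.DataFrame) -> dict[CasemixCell, float]:
    cells = {
        (str(r.drg), str(r.soi), str(r.age_band)): float(r.share)
        for r in frame.itertuples()
    }
    validate_casemix(cells)
    return cells


def load_casemix_csv(path) -> dict[CasemixCell, float]:
    return casemix_from_frame(pd.read_csv(path, dtype={"drg": str, "soi": str, "age_band": str}))
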