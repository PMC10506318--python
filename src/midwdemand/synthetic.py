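"""Packaged parameter fixtures, perturbed variants, and a microsimulation oracle.

``packaged_parameters`` loads the transcribed assumption tables shipped with
the package (common trajectories, scenario overlays A/B/C, the base-year
allocation key) and ``packaged_casemix`` the editable case-mix defaults.

``perturb`` emulates elicitation uncertainty: every targeted anchor value is
multiplied by an independent uniform factor in [1−spread, 1+spread]
(multiplicative noise keeps counts and lengths positive). ``sensitivity_run``
propagates those draws through the full pipeline to percentile bands of the
demand index. ``microsim_oracle`` is a brute-force per-pregnancy simulation
used to cross-check the aggregate arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import caseload as cl
from . import pillars as pl
from .aggregate import AllocationKey, allocation_key_from_frame
from .params import (
    ParameterSet,
    ScenarioSpec,
    ValidationError,
    trajectories_from_frame,
    validate,
)
from .pipeline import RunOptions, pillar_series
from .aggregate import demand_index

SCENARIO_NAMES = ("baseline", "A", "B", "C")

#: trajectory ids whose projected values come from the expert elicitation
ELICITED_IDS = frozenset(
    [
        "len_first_session",
        "len_follow_low",
        "len_follow_modhigh",
        "len_extra_ses",
        "n_birthprep_extra_ses",
        "len_birthprep_ind",
        "len_birthprep_group",
        "group_session_size",
        "coordination_uplift",
        "n_prenatal_modhigh",
    ]
    + [f"n_prenatal_low[{p}]" for p in ("primiparous", "multiparous")]
    + [f"n_birthprep_ind[{p}]" for p in ("primiparous", "multiparous")]
    + [f"n_birthprep_group[{p}]" for p in ("primiparous", "multiparous")]
    + [f"n_postnatal_d6plus[{p}]" for p in ("primiparous", "multiparous")]
)

_SCENARIO_DESCRIPTIONS = {
    "baseline": "Current organisation; shortening stays and demographic trends only.",
    "A": "Gynaecologist-led care with greater midwife involvement in low-risk antenatal care.",
    "B": "Midwife-led care in a hospital-centred network.",
    "C": "Midwife-led care in an outpatient-centred network; short stays, more home care.",
}


def _fixture_frame(name: str) -> pd.DataFrame:
    ref = resources.files("midwdemand.fixtures").joinpath(name)
    with ref.open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle, dtype={"drg": str, "soi": str, "age_band": str})


def fixture_paths() -> dict[str, str]:
    root = resources.files("midwdemand.fixtures")
    return {
        name: str(root.joinpath(name))
        for name in (
            "common_parameters.csv",
            "scenario_A.csv",
            "scenario_B.csv",
            "scenario_C.csv",
            "allocation_key.csv",
            "casemix.csv",
        )
    }


def packaged_parameters() -> tuple[ParameterSet, dict[str, ScenarioSpec], AllocationKey]:
    """The transcribed assumption tables: common set, scenario overlays, key."""
    common = ParameterSet(trajectories_from_frame(_fixture_frame("common_parameters.csv")))
    report = validate(common)
    if report:
        raise ValidationError("packaged fixtures are corrupted: " + "; ".join(report))
    scenarios: dict[str, ScenarioSpec] = {
        "baseline": ScenarioSpec("baseline", {}, _SCENARIO_DESCRIPTIONS["baseline"])
    }
    for name in ("A", "B", "C"):
        overrides = trajectories_from_frame(_fixture_frame(f"scenario_{name}.csv"))
        scenarios[name] = ScenarioSpec(name, overrides, _SCENARIO_DESCRIPTIONS[name])
    key = allocation_key_from_frame(_fixture_frame("allocation_key.csv"))
    return common, scenarios, key


def packaged_casemix() -> dict[cl.CasemixCell, float]:
    return cl.casemix_from_frame(_fixture_frame("casemix.csv"))


# ---------------------------------------------------------------------------
# perturbation

@dataclass(frozen=True)
class PerturbationSpec:
    """Multiplicative uniform noise around the elicited point values."""

    spread: float = 0.1
    targeted_ids: frozenset[str] = field(default_factory=lambda: ELICITED_IDS)
    draws: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spread < 1.0:
            raise ValidationError(f"spread must be in [0, 1), got {self.spread}")
        if self.draws < 1:
            raise ValidationError("at least one draw is required")
        object.__setattr__(self, "targeted_ids", frozenset(self.targeted_ids))


def perturb(params: ParameterSet, spec: PerturbationSpec) -> list[ParameterSet]:
    """Independent perturbed copies of ``params`` (deterministic per seed).

    Each draw multiplies every anchor of every targeted trajectory by an
    independent factor ~ U[1−spread, 1+spread]; other trajectories are
    untouched. Draws use per-draw substreams of the global seed, so draw ``i``
    is reproducible regardless of how many draws are requested.
    """
    targeted = sorted(spec.targeted_ids & set(params.trajectories))
    streams = np.random.SeedSequence(spec.seed).spawn(spec.draws)
    out = []
    for stream in streams:
        rng = np.random.default_rng(stream)
        new = dict(params.trajectories)
        for tid in targeted:
            traj = params.trajectories[tid]
            factors = {
                year: float(f)
                for year, f in zip(
                    traj.anchors,
                    rng.uniform(1.0 - spec.spread, 1.0 + spec.spread, len(traj.anchors)),
                )
            }
            new[tid] = traj.scaled(factors)
        out.append(ParameterSet(new, params.base_year, params.horizon))
    return out


# ---------------------------------------------------------------------------
# microsimulation oracle

@dataclass
class MicrosimResult:
    n_pregnancies: int
    seed: int
    totals: dict[str, float]  # pillar -> summed value over simulated pregnancies

    def per_pregnancy(self, pillar: str) -> float:
        return self.totals[pillar] / self.n_pregnancies


def microsim_oracle(
    params: ParameterSet,
    casemix: Mapping[cl.CasemixCell, float],
    year: int,
    n: int,
    seed: int = 0,
    options: RunOptions = RunOptions(),
) -> MicrosimResult:
    """Simulate ``n`` pregnancies and sum their expected pillar workloads.

    Each pregnancy draws a stratum (risk, parity, vulnerability) from the
    marginal shares and a hospital case-mix cell from the case-mix shares, and
    is assigned the *expected* sessions/minutes/stay workload of that stratum
    or cell. Per-pregnancy means therefore converge to the aggregate module's
    per-stay values by the law of large numbers.
    """
    if n < 1:
        raise ValidationError("need at least one simulated pregnancy")
    rng = np.random.default_rng(seed)
    shares = cl.shares_for_year(params, year)
    risk = np.where(rng.random(n) < shares.p_modhigh, "modhigh", "low")
    parity = np.where(rng.random(n) < shares.p_multiparous, "multiparous", "primiparous")
    vulnerable = rng.random(n) < shares.p_vulnerable

    early = pl.early_postnatal_services(params, casemix, year, options.early_postnatal)
    prenatal = np.empty(n)
    birthprep = np.empty(n)
    outpatient = np.empty(n)
    for r in ("low", "modhigh"):
        for p in ("primiparous", "multiparous"):
            for v in (False, True):
                mask = (risk == r) & (parity == p) & (vulnerable == v)
                if not mask.any():
                    continue
                prenatal[mask] = pl.prenatal_minutes_per_pregnancy(params, year, r, p, v)
                birthprep[mask] = pl.birthprep_minutes_per_pregnancy(params, year, p, v)
                outpatient[mask] = pl.outpatient_services_per_pregnancy(params, year, p, early)

    cells = list(casemix)
    cell_shares = np.array([casemix[c] for c in cells])
    weights = pl.DayWeightTable.from_params(params)
    cell_workload = np.array(
        [
            pl.stay_workload(weights, soi, params.value(f"alos[{drg}][{soi}][{age}]", year))
            for (drg, soi, age) in cells
        ]
    )
    drawn = rng.choice(len(cells), size=n, p=cell_shares / cell_shares.sum())
    inpatient = cell_workload[drawn]

    other = np.full(n, params.value("other_activity_rate", year))
    totals = {
        "prenatal": float(prenatal.sum()),
        "birth_prep": float(birthprep.sum()),
        "inpatient_postnatal": float(inpatient.sum()),
        "outpatient_postnatal": float(outpatient.sum()),
        "other": float(other.sum()),
    }
    return MicrosimResult(n_pregnancies=n, seed=seed, totals=totals)


# ---------------------------------------------------------------------------
# sensitivity propagation

def sensitivity_run(
    spec: PerturbationSpec,
    scenario: ScenarioSpec,
    years: Sequence[int],
    common: ParameterSet | None = None,
    casemix: Mapping[cl.CasemixCell, float] | None = None,
    key: AllocationKey | None = None,
    options: RunOptions = RunOptions(),
    percentiles: Iterable[float] = (2.5, 50.0, 97.5),
) -> pd.DataFrame:
    """Propagate elicitation uncertainty to the demand index.

    The scenario overlay is composed first, then every draw perturbs the
    targeted trajectories of the composed set and reruns the pipeline. Returns
    one row per year with the requested percentiles of the total index.
    """
    from .params import apply_overlay

    if common is None or key is None:
        packaged_common, _scen, packaged_key = packaged_parameters()
        common = common or packaged_common
        key = key or packaged_key
    if casemix is None:
        casemix = packaged_casemix()
    composed = apply_overlay(common, scenario)
    draws = perturb(composed, spec)
    totals = np.empty((len(draws), len(years)))
    for i, draw in enumerate(draws):
        pillars = pillar_series(draw, casemix, years, options)
        series = demand_index(pillars, key, base_year=common.base_year, scenario=scenario.name)
        totals[i] = [series.totals[y] for y in years]
    pct = list(percentiles)
    bands = np.percentile(totals, pct, axis=0)
    frame = pd.DataFrame(
        {"year": list(years), "scenario": scenario.name}
        | {f"p{p:g}": bands[j] for j, p in enumerate(pct)}
    )
    return frame
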