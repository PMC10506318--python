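"""Expert-elicitation utilities: response aggregation and consensus voting.

Parameters without an administrative data source were assigned values in two
steps: an online survey of experts produced candidate values, and a workshop
voted on the plausibility of each proposed value. A value is accepted when at
least 75% of the voters consider it plausible; otherwise discussion and a new
vote follow.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Sequence

from .params import ValidationError

CONSENSUS_THRESHOLD = 0.75


@dataclass(frozen=True)
class VoteTally:
    parameter_id: str
    n_voters: int
    n_plausible: int
    round: int = 1

    def __post_init__(self) -> None:
        if self.n_voters <= 0:
            raise ValidationError("a vote needs at least one voter")
        if not 0 <= self.n_plausible <= self.n_voters:
            raise ValidationError(
                f"n_plausible={self.n_plausible} outside [0, {self.n_voters}]"
            )
        if self.round < 1:
            raise ValidationError("voting rounds are numbered from 1")


@dataclass
class ElicitedParameter:
    parameter_id: str
    responses: list[float]
    point_estimate: float
    consensus: bool = False
    rounds: list[VoteTally] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValidationError(f"{self.parameter_id}: no responses")
        lo, hi = min(self.responses), max(self.responses)
        if not lo <= self.point_estimate <= hi:
            raise ValidationError(
                f"{self.parameter_id}: point estimate {self.point_estimate} outside "
                f"the response range [{lo}, {hi}]"
            )


def consensus_reached(tally: VoteTally, threshold: float = CONSENSUS_THRESHOLD) -> bool:
    """True iff at least ``threshold`` of the voters found the value plausible.

    Reaching the threshold exactly counts as consensus (failure is defined as
    *less than* 75% of the voters).
    """
    return tally.n_plausible / tally.n_voters >= threshold


def aggregate_responses(responses: Sequence[float], method: str = "median") -> float:
    """Collapse survey responses into the value proposed for the vote.

    ``median`` (default), ``mean``, or ``mode`` (modal ties broken toward the
    median). The result always lies within the response range.
    """
    if len(responses) == 0:
        raise ValidationError("cannot aggregate an empty response list")
    if method == "median":
        return float(statistics.median(responses))
    if method == "mean":
        return float(statistics.fmean(responses))
    if method == "mode":
        med = statistics.median(responses)
        counts: dict[float, int] = {}
        for r in responses:
            counts[r] = counts.get(r, 0) + 1
        best = max(counts.values())
        modes = [v for v, c in counts.items() if c == best]
        return float(min(modes, key=lambda v: (abs(v - med), v)))
    raise ValidationError(f"unknown aggregation method {method!r}")


def agreement_share(responses: Sequence[float], value: float, tol: float = 0.0) -> float:
    """Fraction of responses within ``tol`` of ``value``."""
    if len(responses) == 0:
        raise ValidationError("cannot compute agreement on an empty response list")
    if tol < 0:
        raise ValidationError("tolerance must be nonnegative")
    hits = sum(1 for r in responses if abs(r - value) <= tol)
    return hits / len(responses)
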