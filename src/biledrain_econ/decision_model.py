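"""Base-case cost-minimization over a 30-day episode of care.

The decision problem: a patient with malignant distal biliary obstruction has
failed ERCP and needs salvage drainage, either EUS-guided (EUS-BD) or
percutaneous transhepatic (PTBD).  Each strategy incurs its bundled initial
episode cost with certainty and, with a strategy-specific probability, one
bundled unscheduled re-intervention.  The expected 30-day cost is therefore
the affine form

    E[C_s] = C_init,s + p_s * C_reint,s

and the preferred strategy is the strict cost minimizer.  With no discounting
over a 30-day horizon the model collapses to this single decision episode;
horizon length and discount rate are carried for reporting but do not enter
the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Real
from typing import Sequence

from .cost_inputs import (
    ReinterventionEvidence,
    StrategyCostProfile,
    build_strategy_inputs,
    us_fee_schedule,
)

#: Monetary resolution: cost differences below one cent are ties.
TIE_TOLERANCE = 0.01

StrategyPair = tuple[StrategyCostProfile, ReinterventionEvidence]


@dataclass(frozen=True)
class DecisionModel:
    """Two competing drainage strategies with their binomial evidence."""

    strategies: tuple[StrategyPair, StrategyPair]
    horizon_days: int = 30
    discount_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.strategies) != 2:
            raise ValueError("exactly two strategies are compared")
        names = [profile.strategy for profile, _ in self.strategies]
        if names[0] == names[1]:
            raise ValueError("strategy names must be distinct")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be positive")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")

    @property
    def names(self) -> tuple[str, str]:
        return tuple(profile.strategy for profile, _ in self.strategies)

    def pair(self, strategy: str) -> StrategyPair:
        for item in self.strategies:
            if item[0].strategy == strategy:
                return item
        raise KeyError(f"unknown strategy {strategy!r}; model has {self.names}")


@dataclass(frozen=True)
class BaseCaseResult:
    """Expected cost per strategy, savings of the first versus the second."""

    expected_costs: dict[str, float]
    savings: float          # cost(second strategy) - cost(first strategy)
    preferred: str | None   # None flags a tie at money resolution
    reference: str          # the strategy savings are quoted for (the first)

    @property
    def tie(self) -> bool:
        return self.preferred is None


def expected_cost(profile: StrategyCostProfile, p: Real | Fraction) -> float:
    """Expected episode cost C_init + p * C_reint at full float precision."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"re-intervention probability must be in [0, 1], got {p}")
    return float(profile.initial_cost) + p * float(profile.reintervention_cost)


def run_base_case(model: DecisionModel) -> BaseCaseResult:
    """Evaluate both strategies at their full-precision point estimates."""
    costs = {
        profile.strategy: expected_cost(profile, evidence.point_estimate)
        for profile, evidence in model.strategies
    }
    first, second = model.names
    savings = costs[second] - costs[first]
    if abs(savings) < TIE_TOLERANCE:
        preferred = None
    else:
        preferred = first if savings > 0 else second
    return BaseCaseResult(
        expected_costs=costs, savings=savings, preferred=preferred, reference=first
    )


def cost_savings(result: BaseCaseResult, reference: str) -> float:
    """Savings from choosing ``reference`` over the other strategy.

    Antisymmetric: savings w.r.t. one strategy is minus the savings w.r.t.
    the other.
    """
    names = list(result.expected_costs)
    if reference not in names:
        raise KeyError(f"unknown strategy {reference!r}; result has {names}")
    other = names[0] if reference == names[1] else names[1]
    return result.expected_costs[other] - result.expected_costs[reference]


def default_us_model(
    evidence: dict[str, ReinterventionEvidence] | None = None,
) -> DecisionModel:
    """The US Medicare model with packaged Table-style strategy bundles.

    EUS-BD ($8,002.48 initial / $6,351.83 re-intervention, p = 8/34) versus
    PTBD ($13,369.98 initial / $957.11 re-intervention, p = 17/32).
    """
    pairs = build_strategy_inputs(us_fee_schedule(), evidence=evidence)
    return DecisionModel(strategies=(pairs[0], pairs[1]))
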