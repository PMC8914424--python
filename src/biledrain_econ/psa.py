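"""Probabilistic sensitivity analysis by Monte Carlo over beta-distributed rates.

Uncertainty in each strategy's re-intervention probability is represented by a
beta distribution derived from the binomial trial counts; costs are treated as
fixed reimbursements.  Each Monte-Carlo trial draws one probability per
strategy (independently), maps it through the affine episode cost, and the
resulting cost samples are summarised by their mean and an empirical
percentile interval.

Because the episode cost is a monotone affine function of the probability,
the percentile interval of the cost sample is computed exactly as the affine
image of the probability-sample percentiles; this keeps interval endpoints
consistent with the sampled probabilities to the last bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .cost_inputs import ReinterventionEvidence
from .decision_model import DecisionModel

BetaRule = Literal["counts", "jeffreys"]


@dataclass(frozen=True)
class PsaSettings:
    """Monte-Carlo settings: trial count, seed, interval level, beta rule."""

    n_trials: int = 10_000
    seed: int = 20220225
    ci_level: float = 0.95
    beta_rule: BetaRule = "counts"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.beta_rule not in ("counts", "jeffreys"):
            raise ValueError(f"unknown beta rule {self.beta_rule!r}")


@dataclass(frozen=True)
class SampleSummary:
    mean: float
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class PsaResult:
    """Per-strategy cost summaries, savings summary, probability of saving."""

    strategy_costs: dict[str, SampleSummary]
    savings: SampleSummary
    prob_cost_saving: float
    reference: str            # the strategy whose savings are summarised
    settings: PsaSettings
    cost_samples: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def beta_params(
    evidence: ReinterventionEvidence, rule: BetaRule = "counts"
) -> tuple[float, float]:
    """Beta shape parameters for a binomial re-intervention rate.

    ``counts`` uses (alpha=k, beta=n-k), whose mean k/n equals the base-case
    point estimate; ``jeffreys`` uses (k+1/2, n-k+1/2), which stays proper
    when k = 0 or k = n.
    """
    k, n = evidence.events, evidence.trials
    if rule == "counts":
        if k == 0 or k == n:
            raise ValueError(
                f"counts rule needs 0 < events < trials (got {k}/{n}); "
                "use rule='jeffreys' for zero-event or all-event evidence"
            )
        return float(k), float(n - k)
    if rule == "jeffreys":
        return k + 0.5, n - k + 0.5
    raise ValueError(f"unknown beta rule {rule!r}")


def sample_reintervention_prob(
    alpha: float,
    beta: float,
    n_trials: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Draw ``n_trials`` i.i.d. Beta(alpha, beta) probabilities, reproducibly."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta shape parameters must be positive")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    return rng.beta(alpha, beta, size=n_trials)


def percentile_interval(samples, level: float) -> tuple[float, float]:
    """Central empirical interval via linear-interpolation quantiles."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot take percentiles of an empty sample")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [tail, 1.0 - tail], method="linear")
    return float(lo), float(hi)


def _strategy_seeds(settings: PsaSettings, n: int) -> list[np.random.SeedSequence]:
    """One child seed per strategy, in model order, derived from the run seed."""
    return np.random.SeedSequence(settings.seed).spawn(n)


def run_psa(model: DecisionModel, settings: PsaSettings = PsaSettings()) -> PsaResult:
    """Propagate beta-distributed re-intervention rates through the cost model.

    Per strategy ``s`` and trial ``t`` an independent probability ``p_{s,t}``
    is drawn and mapped to ``cost = C_init,s + p_{s,t} * C_reint,s``.  The
    savings sample is cost(second strategy) minus cost(first strategy), and
    ``prob_cost_saving`` is the fraction of trials in which the first-listed
    strategy is strictly cheaper.
    """
    seeds = _strategy_seeds(settings, len(model.strategies))
    cost_samples: dict[str, np.ndarray] = {}
    summaries: dict[str, SampleSummary] = {}
    for (profile, evidence), seed in zip(model.strategies, seeds):
        alpha, beta = beta_params(evidence, settings.beta_rule)
        p = sample_reintervention_prob(alpha, beta, settings.n_trials, seed)
        c_init = float(profile.initial_cost)
        c_reint = float(profile.reintervention_cost)
        costs = c_init + p * c_reint
        # monotone affine map: cost percentiles are the image of p percentiles
        p_lo, p_hi = percentile_interval(p, settings.ci_level)
        summaries[profile.strategy] = SampleSummary(
            mean=float(np.mean(costs)),
            ci_lower=c_init + p_lo * c_reint,
            ci_upper=c_init + p_hi * c_reint,
        )
        cost_samples[profile.strategy] = costs

    first, second = model.names
    savings_samples = cost_samples[second] - cost_samples[first]
    sv_lo, sv_hi = percentile_interval(savings_samples, settings.ci_level)
    savings = SampleSummary(float(np.mean(savings_samples)), sv_lo, sv_hi)
    return PsaResult(
        strategy_costs=summaries,
        savings=savings,
        prob_cost_saving=float(np.mean(savings_samples > 0.0)),
        reference=first,
        settings=settings,
        cost_samples=cost_samples,
    )
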