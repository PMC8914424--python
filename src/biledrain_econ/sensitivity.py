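"""Deterministic sensitivity analysis over re-intervention rates.

Two-way analysis evaluates the closed-form expected costs on a grid of
(p_EUS, p_PTBD) pairs and records the preferred (strictly cheaper) strategy at
every node — the preference surface.  One-way analysis is the two axis-aligned
slices of that surface, holding the other strategy at its base-case rate.
Because both expected costs are affine in their probabilities, the preference
boundary is the straight line

    p_first = (C_init,second - C_init,first + p_second * C_reint,second) / C_reint,first

and cost-equivalence thresholds have a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision_model import TIE_TOLERANCE, DecisionModel, expected_cost


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned grid over the two re-intervention probabilities."""

    p_range_first: tuple[float, float] = (0.0, 0.5)
    p_range_second: tuple[float, float] = (0.0, 0.5)
    step: float = 0.01

    def __post_init__(self) -> None:
        for lo, hi in (self.p_range_first, self.p_range_second):
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError(f"probability range ({lo}, {hi}) not within [0, 1]")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def axis(self, which: int) -> np.ndarray:
        lo, hi = (self.p_range_first, self.p_range_second)[which]
        n = int(round((hi - lo) / self.step))
        pts = lo + self.step * np.arange(n + 1)
        if pts[-1] < hi - 1e-12:  # ensure both endpoints present
            pts = np.append(pts, hi)
        pts[-1] = hi
        return np.clip(pts, 0.0, 1.0)


@dataclass(frozen=True)
class PreferenceSurface:
    """Grid of savings and preferred strategy over (p_first, p_second)."""

    nodes: pd.DataFrame = field(repr=False)
    names: tuple[str, str]

    @property
    def fraction_first_preferred(self) -> float:
        return float((self.nodes["preferred"] == self.names[0]).mean())


def preference_surface(model: DecisionModel, grid: GridSpec = GridSpec()) -> PreferenceSurface:
    """Evaluate the base-case closed form at every grid node (no sampling).

    Columns of the result: probabilities and costs per strategy, savings of
    the first strategy (cost_second − cost_first), and the strictly preferred
    strategy ("tie" below one cent).
    """
    (prof_a, _), (prof_b, _) = model.strategies
    axis_a, axis_b = grid.axis(0), grid.axis(1)
    if axis_a.size == 0 or axis_b.size == 0:
        raise ValueError("degenerate (empty) grid")
    pa, pb = np.meshgrid(axis_a, axis_b, indexing="ij")
    pa, pb = pa.ravel(), pb.ravel()
    cost_a = float(prof_a.initial_cost) + pa * float(prof_a.reintervention_cost)
    cost_b = float(prof_b.initial_cost) + pb * float(prof_b.reintervention_cost)
    savings = cost_b - cost_a
    preferred = np.where(
        savings > TIE_TOLERANCE,
        prof_a.strategy,
        np.where(savings < -TIE_TOLERANCE, prof_b.strategy, "tie"),
    )
    name_a, name_b = model.names
    nodes = pd.DataFrame(
        {
            f"p_{name_a}": pa,
            f"p_{name_b}": pb,
            f"cost_{name_a}": cost_a,
            f"cost_{name_b}": cost_b,
            "savings": savings,
            "preferred": preferred,
        }
    )
    return PreferenceSurface(nodes=nodes, names=(name_a, name_b))


def one_way_slices(
    model: DecisionModel, grid: GridSpec = GridSpec()
) -> dict[str, pd.DataFrame]:
    """One-way analysis: vary one strategy's rate, hold the other at base case."""
    out: dict[str, pd.DataFrame] = {}
    for vary_idx, fixed_idx in ((0, 1), (1, 0)):
        vary_prof, _ = model.strategies[vary_idx]
        fixed_prof, fixed_ev = model.strategies[fixed_idx]
        fixed_cost = expected_cost(fixed_prof, fixed_ev.point_estimate)
        axis = grid.axis(vary_idx)
        cost = float(vary_prof.initial_cost) + axis * float(
            vary_prof.reintervention_cost
        )
        savings = fixed_cost - cost
        preferred = np.where(
            savings > TIE_TOLERANCE,
            vary_prof.strategy,
            np.where(savings < -TIE_TOLERANCE, fixed_prof.strategy, "tie"),
        )
        out[vary_prof.strategy] = pd.DataFrame(
            {
                "p": axis,
                f"cost_{vary_prof.strategy}": cost,
                f"cost_{fixed_prof.strategy}": fixed_cost,
                "savings": savings,
                "preferred": preferred,
            }
        )
    return out


def equal_cost_threshold(
    model: DecisionModel, vary: str, fixed_p: float
) -> float | None:
    """Rate p* at which the varied strategy's cost equals the other's.

    Solves ``C_init,v + p* C_reint,v = C_init,o + fixed_p * C_reint,o``.
    Returns ``None`` when no crossing exists within [0, 1] (including the
    degenerate case of zero re-intervention cost with unequal fixed costs).
    """
    if not 0.0 <= fixed_p <= 1.0:
        raise ValueError("fixed_p must lie in [0, 1]")
    vary_prof, _ = model.pair(vary)
    other_name = model.names[0] if vary == model.names[1] else model.names[1]
    other_prof, _ = model.pair(other_name)
    target = expected_cost(other_prof, fixed_p)
    c_reint = float(vary_prof.reintervention_cost)
    gap = target - float(vary_prof.initial_cost)
    if c_reint == 0.0:
        return None if abs(gap) > TIE_TOLERANCE else fixed_p
    p_star = gap / c_reint
    return p_star if 0.0 <= p_star <= 1.0 else None


def favored_region_bound(model: DecisionModel, step: float = 0.01, exact: bool = False) -> float:
    """Largest b such that the first strategy is strictly preferred on [0, b]^2.

    The expected costs are non-decreasing in their probabilities, so the worst
    node for the first strategy on the square is (p_first=b, p_second=0); the
    exact bound is the crossing point of ``C_first(b) = C_second(0)``, clipped
    to [0, 1].  With ``exact=False`` the bound is resolved on the step grid.
    """
    (prof_a, _), (prof_b, _) = model.strategies
    c_init_a, c_reint_a = float(prof_a.initial_cost), float(prof_a.reintervention_cost)
    cost_b_at_0 = float(prof_b.initial_cost)
    if c_init_a + TIE_TOLERANCE >= cost_b_at_0:
        return 0.0  # not strictly preferred even at the origin
    if c_reint_a == 0.0:
        return 1.0
    bound = (cost_b_at_0 - c_init_a) / c_reint_a
    bound = min(bound, 1.0)
    if exact:
        return bound
    # largest grid multiple of `step` at which preference is still strict
    b = np.floor(bound / step) * step
    while b > 0 and (c_init_a + b * c_reint_a) >= cost_b_at_0 - TIE_TOLERANCE:
        b -= step
    return float(max(b, 0.0))
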