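"""Per-patient cost comparison between two drainage arms of a clinical trial.

Each patient record carries the hospital charges other than biliary drainage,
the cost of the primary drainage intervention, and the cost of any unscheduled
re-intervention, from which the total drainage cost and grand total are
derived.  Arms are summarised as median (range) per cost category, compared
with two-sided Mann-Whitney tests, and the between-arm difference in mean
costs is interval-estimated with a bias-corrected (BC) stratified bootstrap.

The Mann-Whitney test takes the exact-enumeration path for small untied
samples (min arm size <= 8) and the tie-corrected, continuity-corrected
normal approximation otherwise; the result records which path was used.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Cost categories, in report order.  The first three are recorded per
#: patient; the last two are per-patient derived sums.
CATEGORIES = (
    "hospital_other_cost",
    "primary_bd_cost",
    "reintervention_cost",
    "total_bd_cost",
    "total_cost",
)

RECORD_COLUMNS = (
    "patient_id",
    "arm",
    "hospital_other_cost",
    "primary_bd_cost",
    "reintervention_cost",
    "n_reinterventions",
    "n_primary_sessions",
)


@dataclass(frozen=True)
class PatientCostRecord:
    """One trial patient's per-category costs and re-intervention history.

    A positive re-intervention cost requires at least one recorded
    re-intervention; conversely a recorded re-intervention with zero cost is
    rejected unless ``allow_zero_cost_reintervention`` is set (e.g. a repeat
    procedure fully absorbed into bundled charges).
    """

    patient_id: str
    arm: str
    hospital_other_cost: float
    primary_bd_cost: float
    reintervention_cost: float = 0.0
    n_reinterventions: int = 0
    n_primary_sessions: int = 1
    allow_zero_cost_reintervention: bool = False

    def __post_init__(self) -> None:
        for name in ("hospital_other_cost", "primary_bd_cost", "reintervention_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 for patient {self.patient_id}")
        if self.n_reinterventions < 0:
            raise ValueError("n_reinterventions must be >= 0")
        if self.n_primary_sessions < 1:
            raise ValueError("n_primary_sessions must be >= 1")
        if self.reintervention_cost > 0 and self.n_reinterventions == 0:
            raise ValueError(
                f"patient {self.patient_id}: re-intervention cost recorded "
                "without any re-intervention"
            )
        if (
            self.n_reinterventions > 0
            and self.reintervention_cost == 0
            and not self.allow_zero_cost_reintervention
        ):
            raise ValueError(
                f"patient {self.patient_id}: re-intervention recorded with zero "
                "cost (set allow_zero_cost_reintervention to accept)"
            )

    @property
    def total_bd_cost(self) -> float:
        return self.primary_bd_cost + self.reintervention_cost

    @property
    def total_cost(self) -> float:
        return self.hospital_other_cost + self.total_bd_cost


@dataclass(frozen=True)
class MannWhitneyResult:
    p_value: float
    u_statistic: float
    method: Literal["exact", "asymptotic"]


@dataclass(frozen=True)
class ArmComparison:
    """Median (min, max) per category per arm, tests, re-intervention summary."""

    summary: pd.DataFrame = field(repr=False)  # rows: categories x arms
    p_values: dict[str, float]
    test_methods: dict[str, str]
    reintervention_rate: dict[str, float]      # patients with >=1 event / n
    mean_reintervention_frequency: dict[str, float]  # total events / n
    arm_sizes: dict[str, int]


@dataclass(frozen=True)
class BootstrapCI:
    """Bias-corrected bootstrap interval for a between-arm cost difference."""

    category: str
    point_difference: float        # first arm minus second arm
    lower: float
    upper: float
    n_boot: int
    method: str
    z0: float
    arms: tuple[str, str]
    degenerate: bool = False       # all resampled statistics identical
    bootstrap_statistics: np.ndarray = field(
        repr=False, default_factory=lambda: np.empty(0)
    )


def aggregate_costs(records: Sequence[PatientCostRecord]) -> pd.DataFrame:
    """Per-patient table with the derived drainage and grand totals."""
    if not records:
        raise ValueError("no patient records")
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "arm": r.arm,
                "hospital_other_cost": r.hospital_other_cost,
                "primary_bd_cost": r.primary_bd_cost,
                "reintervention_cost": r.reintervention_cost,
                "n_reinterventions": r.n_reinterventions,
                "n_primary_sessions": r.n_primary_sessions,
                "total_bd_cost": r.total_bd_cost,
                "total_cost": r.total_cost,
            }
        )
    return pd.DataFrame(rows)


def mann_whitney_p(sample_a, sample_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney test.

    Exact enumeration when the smaller sample has at most 8 observations and
    the pooled data are tie-free; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = min(a.size, b.size) <= 8 and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(
        p_value=float(res.pvalue), u_statistic=float(res.statistic), method=method
    )


def _arm_values(frame: pd.DataFrame, arm: str, category: str) -> np.ndarray:
    return frame.loc[frame["arm"] == arm, category].to_numpy(dtype=float)


def summarize_arms(
    records: Sequence[PatientCostRecord], arms: tuple[str, str] | None = None
) -> ArmComparison:
    """Median/range per category per arm, Mann-Whitney p-values, event rates."""
    frame = aggregate_costs(records)
    if arms is None:
        found = tuple(pd.unique(frame["arm"]))
        if len(found) != 2:
            raise ValueError(f"expected exactly two arms, found {found}")
        arms = found  # type: ignore[assignment]
    for arm in arms:
        if (frame["arm"] == arm).sum() == 0:
            raise ValueError(f"arm {arm!r} has zero patients")

    rows = []
    p_values: dict[str, float] = {}
    methods: dict[str, str] = {}
    for category in CATEGORIES:
        vals = {arm: _arm_values(frame, arm, category) for arm in arms}
        for arm in arms:
            v = vals[arm]
            rows.append(
                {
                    "category": category,
                    "arm": arm,
                    "median": float(np.median(v)),
                    "min": float(np.min(v)),
                    "max": float(np.max(v)),
                }
            )
        test = mann_whitney_p(vals[arms[0]], vals[arms[1]])
        p_values[category] = test.p_value
        methods[category] = test.method

    rate: dict[str, float] = {}
    freq: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for arm in arms:
        sub = frame[frame["arm"] == arm]
        n = len(sub)
        sizes[arm] = n
        rate[arm] = float((sub["n_reinterventions"] > 0).sum() / n)
        freq[arm] = float(sub["n_reinterventions"].sum() / n)

    return ArmComparison(
        summary=pd.DataFrame(rows),
        p_values=p_values,
        test_methods=methods,
        reintervention_rate=rate,
        mean_reintervention_frequency=freq,
        arm_sizes=sizes,
    )


def bc_bootstrap_diff(
    records: Sequence[PatientCostRecord],
    category: str,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
    arms: tuple[str, str] | None = None,
    statistic: Literal["mean", "median"] = "mean",
    method: Literal["bc", "bca"] = "bc",
    ci_level: float = 0.95,
) -> BootstrapCI:
    """Bias-corrected bootstrap CI for the between-arm difference in a category.

    The statistic is the difference of arm summaries (first arm minus second;
    arm means by default).  Resampling is stratified within arm with
    replacement, preserving arm sizes.  The bias correction shifts the
    percentile levels by ``z0 = Phi^{-1}(fraction of bootstrap statistics
    below the observed statistic)``; with ``method="bca"`` a jackknife
    acceleration term is added.
    """
    if category not in CATEGORIES:
        raise KeyError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    frame = aggregate_costs(records)
    if arms is None:
        found = tuple(pd.unique(frame["arm"]))
        if len(found) != 2:
            raise ValueError(f"expected exactly two arms, found {found}")
        arms = found  # type: ignore[assignment]
    a = _arm_values(frame, arms[0], category)
    b = _arm_values(frame, arms[1], category)
    if a.size < 2 or b.size < 2:
        raise ValueError("both arms need at least 2 patients to bootstrap")
    stat = np.mean if statistic == "mean" else np.median
    observed = float(stat(a) - stat(b))

    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    boot = stat(a[idx_a], axis=1) - stat(b[idx_b], axis=1)

    if np.ptp(boot) == 0.0:
        v = float(boot[0])
        return BootstrapCI(
            category=category,
            point_difference=observed,
            lower=v,
            upper=v,
            n_boot=n_boot,
            method=method,
            z0=0.0,
            arms=arms,
            degenerate=True,
            bootstrap_statistics=boot,
        )

    z0 = float(stats.norm.ppf(np.mean(boot < observed)))
    accel = 0.0
    if method == "bca":
        pooled_theta = _jackknife_diff(a, b, stat)
        dev = pooled_theta.mean() - pooled_theta
        denom = 6.0 * (dev**2).sum() ** 1.5
        accel = float((dev**3).sum() / denom) if denom > 0 else 0.0
    lo_level, hi_level = bc_levels(z0, ci_level, accel)
    lower, upper = np.quantile(boot, [lo_level, hi_level], method="linear")
    return BootstrapCI(
        category=category,
        point_difference=observed,
        lower=float(lower),
        upper=float(upper),
        n_boot=n_boot,
        method=method,
        z0=z0,
        arms=arms,
        bootstrap_statistics=boot,
    )


def bc_levels(z0: float, ci_level: float, accel: float = 0.0) -> tuple[float, float]:
    """Adjusted percentile levels of the bias-corrected bootstrap interval.

    ``Phi(z0 + (z0 + z_a) / (1 - accel*(z0 + z_a)))`` for the two tail
    z-scores; with z0 = 0 and accel = 0 this reduces to the plain percentile
    levels (alpha/2, 1 - alpha/2).
    """
    alpha = (1.0 - ci_level) / 2.0
    z_lo, z_hi = stats.norm.ppf([alpha, 1.0 - alpha])
    lo = stats.norm.cdf(z0 + (z0 + z_lo) / (1.0 - accel * (z0 + z_lo)))
    hi = stats.norm.cdf(z0 + (z0 + z_hi) / (1.0 - accel * (z0 + z_hi)))
    return float(lo), float(hi)


def _jackknife_diff(a: np.ndarray, b: np.ndarray, stat) -> np.ndarray:
    """Delete-one jackknife of the two-sample difference over both arms."""
    thetas = []
    for i in range(a.size):
        thetas.append(stat(np.delete(a, i)) - stat(b))
    for j in range(b.size):
        thetas.append(stat(a) - stat(np.delete(b, j)))
    return np.asarray(thetas)


def bootstrap_report(
    records: Sequence[PatientCostRecord],
    n_boot: int = 1000,
    seed: int | None = 0,
    arms: tuple[str, str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """BC bootstrap intervals for every cost category (report-table layout)."""
    seeds = np.random.SeedSequence(seed).spawn(len(CATEGORIES))
    rows = []
    for category, s in zip(CATEGORIES, seeds):
        ci = bc_bootstrap_diff(
            records, category, n_boot=n_boot, seed=s, arms=arms, **kwargs
        )
        rows.append(
            {
                "category": category,
                "cost_difference": ci.point_difference,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
                "n_boot": ci.n_boot,
                "method": ci.method,
            }
        )
    return pd.DataFrame(rows)


def read_records_csv(path: str | Path) -> list[PatientCostRecord]:
    """Load patient records from the documented CSV dialect."""
    frame = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            PatientCostRecord(
                patient_id=str(row["patient_id"]),
                arm=str(row["arm"]),
                hospital_other_cost=float(row["hospital_other_cost"]),
                primary_bd_cost=float(row["primary_bd_cost"]),
                reintervention_cost=float(row["reintervention_cost"]),
                n_reinterventions=int(row["n_reinterventions"]),
                n_primary_sessions=int(row["n_primary_sessions"]),
            )
        )
    return records


def write_records_csv(records: Iterable[PatientCostRecord], path: str | Path) -> None:
    """Write patient records in the documented CSV dialect (deterministic)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.arm,
                    f"{r.hospital_other_cost:.2f}",
                    f"{r.primary_bd_cost:.2f}",
                    f"{r.reintervention_cost:.2f}",
                    r.n_reinterventions,
                    r.n_primary_sessions,
                ]
            )
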