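"""Monetary model inputs: fee schedules, strategy cost profiles, re-intervention evidence.

Money is carried as :class:`decimal.Decimal` (cent-exact) through loading and
validation; downstream numerics convert to ``float`` only inside the model
evaluation, and rounding to two decimals happens only at presentation time via
:func:`round_money`.

Re-intervention rates are stored as binomial counts ``(events k, trials n)``
rather than percentages: the displayed "23.6%" / "53.1%" are rounded values,
and only the full-precision fractions 8/34 and 17/32 reproduce the published
base-case strategy costs to the cent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

Money = Union[Decimal, int, float]

#: Recognised cost-item categories.
CATEGORIES = frozenset(
    {
        "primary-intervention",
        "secondary-intervention",
        "hospital-day",
        "bundled-strategy-initial",
        "bundled-strategy-reintervention",
    }
)

#: Default fee-schedule labels of the four US strategy bundles, keyed by
#: strategy name as ``(initial episode, re-intervention episode)``.
US_BUNDLE_LABELS: Mapping[str, tuple[str, str]] = {
    "EUS-BD": ("EUS-BD", "Re-intervention with PTBD after failed EUS-BD"),
    "PTBD": ("PTBD", "Re-intervention after failed PTBD"),
}


class FeeScheduleError(ValueError):
    """Raised for malformed fee-schedule files or failed lookups."""


def round_money(amount: Money) -> Decimal:
    """Round a monetary amount to cents, half-up (presentation only)."""
    return Decimal(str(amount)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def convert_currency(amount: Money, factor: Money) -> Decimal:
    """Convert ``amount`` by a positive conversion ``factor`` at full precision.

    No rounding is applied here; round-tripping with ``1/factor`` recovers the
    input to well under a cent.  Use :func:`round_money` for display.
    """
    factor = Decimal(str(factor))
    if factor <= 0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    return Decimal(str(amount)) * factor


@dataclass(frozen=True)
class CostItem:
    """One line of a fee schedule: a labelled, categorised monetary amount."""

    label: str
    category: str
    amount: Decimal
    country: str

    def __post_init__(self) -> None:
        if not self.label:
            raise FeeScheduleError("cost item label must be non-empty")
        if self.category not in CATEGORIES:
            raise FeeScheduleError(
                f"unknown category {self.category!r} for item {self.label!r}; "
                f"expected one of {sorted(CATEGORIES)}"
            )
        object.__setattr__(self, "amount", Decimal(str(self.amount)))
        if self.amount < 0:
            raise FeeScheduleError(
                f"negative amount {self.amount} for item {self.label!r}"
            )


@dataclass
class FeeSchedule:
    """A set of cost items keyed by unique label, with one conversion factor."""

    items: dict[str, CostItem] = field(default_factory=dict)
    currency: str = "USD"
    conversion_factor: Decimal = Decimal("1")

    def __post_init__(self) -> None:
        self.conversion_factor = Decimal(str(self.conversion_factor))
        if self.conversion_factor <= 0:
            raise FeeScheduleError(
                f"conversion_factor must be positive, got {self.conversion_factor}"
            )

    def add(self, item: CostItem) -> None:
        if item.label in self.items:
            raise FeeScheduleError(f"duplicate label {item.label!r}")
        self.items[item.label] = item

    def lookup(self, label: str) -> Decimal:
        """Amount for ``label``; an unknown label is an error, never 0."""
        try:
            return self.items[label].amount
        except KeyError:
            raise FeeScheduleError(
                f"unknown fee-schedule label {label!r}; "
                f"known labels: {sorted(self.items)}"
            ) from None

    def __getitem__(self, label: str) -> Decimal:
        return self.lookup(label)

    def __len__(self) -> int:
        return len(self.items)

    def in_usd(self, label: str) -> Decimal:
        """Amount for ``label`` converted to USD via ``conversion_factor``."""
        return convert_currency(self.lookup(label), self.conversion_factor)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "category", "amount", "country"])
            for item in self.items.values():
                writer.writerow([item.label, item.category, item.amount, item.country])


@dataclass(frozen=True)
class StrategyCostProfile:
    """Initial-episode and re-intervention bundle costs of one drainage strategy."""

    strategy: str
    initial_cost: Decimal
    reintervention_cost: Decimal

    def __post_init__(self) -> None:
        object.__setattr__(self, "initial_cost", Decimal(str(self.initial_cost)))
        object.__setattr__(
            self, "reintervention_cost", Decimal(str(self.reintervention_cost))
        )
        if self.initial_cost < 0 or self.reintervention_cost < 0:
            raise ValueError(f"negative cost in profile for {self.strategy!r}")


@dataclass(frozen=True)
class ReinterventionEvidence:
    """Binomial evidence (k events out of n) behind a re-intervention rate.

    ``point_estimate`` is the exact fraction k/n; the rounded percentage is a
    display value only.
    """

    events: int
    trials: int

    def __post_init__(self) -> None:
        if self.trials <= 0:
            raise ValueError("trials must be positive")
        if not 0 <= self.events <= self.trials:
            raise ValueError(
                f"events must lie in [0, trials], got {self.events}/{self.trials}"
            )

    @property
    def point_estimate(self) -> Fraction:
        return Fraction(self.events, self.trials)


def load_fee_schedule(
    path: str | Path,
    country: str | None = None,
    currency: str = "USD",
    conversion_factor: Money = 1,
) -> FeeSchedule:
    """Read a fee-schedule CSV (``label,category,amount,country``) into a schedule.

    Rows are validated as they are read; a missing column, negative amount or
    duplicate label raises :class:`FeeScheduleError` naming the offending row.
    If ``country`` is given, rows tagged with other countries are rejected.
    """
    schedule = FeeSchedule(currency=currency, conversion_factor=conversion_factor)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"label", "category", "amount", "country"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise FeeScheduleError(
                f"{path}: missing column(s) {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                item = CostItem(
                    label=(row["label"] or "").strip(),
                    category=(row["category"] or "").strip(),
                    amount=Decimal((row["amount"] or "").strip()),
                    country=(row["country"] or "").strip(),
                )
                if country is not None and item.country != country:
                    raise FeeScheduleError(
                        f"row tagged {item.country!r}, expected {country!r}"
                    )
                schedule.add(item)
            except (FeeScheduleError, ArithmeticError) as exc:
                raise FeeScheduleError(f"{path}, line {lineno}: {exc}") from exc
    return schedule


def _packaged(name: str) -> Path:
    return Path(str(resources.files("biledrain_econ").joinpath("data", name)))


def us_fee_schedule() -> FeeSchedule:
    """The packaged US Medicare strategy-bundle fee schedule."""
    return load_fee_schedule(_packaged("fee_schedule_us.csv"), country="US")


def korea_fee_schedule() -> FeeSchedule:
    """The packaged Korean per-procedure fee schedule (already in USD)."""
    return load_fee_schedule(_packaged("fee_schedule_korea.csv"), country="KR")


#: Default binomial counts behind the US model's re-intervention rates.
DEFAULT_US_EVIDENCE: Mapping[str, ReinterventionEvidence] = {
    "EUS-BD": ReinterventionEvidence(events=8, trials=34),
    "PTBD": ReinterventionEvidence(events=17, trials=32),
}


def build_strategy_inputs(
    schedule: FeeSchedule,
    evidence: Mapping[str, ReinterventionEvidence] | None = None,
    bundle_labels: Mapping[str, tuple[str, str]] = US_BUNDLE_LABELS,
) -> list[tuple[StrategyCostProfile, ReinterventionEvidence]]:
    """Assemble per-strategy (cost profile, evidence) pairs from a fee schedule.

    Costs are taken from the schedule's bundled-strategy items exactly as
    listed; evidence carries the full-precision binomial counts.
    """
    if evidence is None:
        evidence = DEFAULT_US_EVIDENCE
    pairs = []
    for strategy, (initial_label, reint_label) in bundle_labels.items():
        profile = StrategyCostProfile(
            strategy=strategy,
            initial_cost=schedule.lookup(initial_label),
            reintervention_cost=schedule.lookup(reint_label),
        )
        try:
            ev = evidence[strategy]
        except KeyError:
            raise KeyError(f"no re-intervention evidence for strategy {strategy!r}")
        pairs.append((profile, ev))
    return pairs
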