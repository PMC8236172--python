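"""Voucher scheme rules over time and dated scenario events.

The Elderly Health Care Voucher scheme is encoded as an ordered list of
policy epochs, each fixing the annual amount (HKD/person/year), the
eligibility age and the carry-forward cap from its start year until the
next epoch.  Scenarios are named lists of dated attribute overrides
applied on top of the baseline schedule.

The packaged baseline reproduces the historical schedule: $250/yr for
ages 70+ in 2009-2011, $500 in 2012, $1000 in 2013, $2000 from 2014 with
a $4000 carry-forward cap, and eligibility lowered to 65+ from 2017.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .errors import ValidationError

SCHEME_START_YEAR = 2009

_SCENARIO_ATTRIBUTES = ("annual_amount", "eligibility_age", "chronic_amount")


@dataclass(frozen=True)
class PolicyEpoch:
    """Scheme rules in force from ``start_year`` onward."""

    start_year: int
    annual_amount: float
    eligibility_age: int
    carry_cap: float = 0.0

    def __post_init__(self) -> None:
        if self.annual_amount < 0:
            raise ValidationError(f"annual_amount must be >= 0, got {self.annual_amount}")
        if self.eligibility_age not in (60, 65, 70):
            raise ValidationError(f"eligibility_age must be one of 60/65/70, got {self.eligibility_age}")
        if self.carry_cap != 0 and self.carry_cap < self.annual_amount:
            raise ValidationError(
                f"carry_cap must be 0 (no carry-forward) or >= annual_amount, got {self.carry_cap}"
            )


_NULL_EPOCH = object()  # sentinel for pre-scheme years


@dataclass
class VoucherPolicy:
    """A full scheme: ordered epochs plus an optional chronic add-on."""

    epochs: list[PolicyEpoch]
    chronic_amount: float = 0.0
    chronic_start_year: int | None = None

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValidationError("a policy needs at least one epoch")
        starts = [e.start_year for e in self.epochs]
        if sorted(set(starts)) != starts:
            raise ValidationError(f"epochs must be sorted by start_year without duplicates, got {starts}")
        if self.chronic_amount < 0:
            raise ValidationError("chronic_amount must be >= 0")


def policy_at(policy: VoucherPolicy, year: int) -> PolicyEpoch:
    """The epoch in force in ``year`` (latest epoch with start <= year).

    Years before the scheme start return a null epoch with amount 0.
    """
    current = None
    for epoch in policy.epochs:
        if epoch.start_year <= year:
            current = epoch
        else:
            break
    if current is None:
        # scheme not yet started: no entitlement, age gate of the first epoch
        return PolicyEpoch(
            start_year=year,
            annual_amount=0.0,
            eligibility_age=policy.epochs[0].eligibility_age,
            carry_cap=0.0,
        )
    return current


def chronic_amount_at(policy: VoucherPolicy, year: int) -> float:
    """Chronic add-on entitlement in force in ``year`` (0 when inactive)."""
    if policy.chronic_start_year is None or year < policy.chronic_start_year:
        return 0.0
    return policy.chronic_amount


def carry_forward(unspent: float, new_allocation: float, cap: float) -> float:
    """Balance available after adding this year's allocation.

    With a positive cap the accumulated balance is truncated at the cap
    (the scheme's $4000 rule); with cap 0 there is no carry-forward and
    only the new allocation is available.
    """
    if unspent < 0 or new_allocation < 0 or cap < 0:
        raise ValidationError("carry_forward arguments must be non-negative")
    if cap > 0:
        return min(unspent + new_allocation, cap)
    return new_allocation


@dataclass(frozen=True)
class ScenarioSpec:
    """A named list of dated (year, attribute, value) policy overrides."""

    name: str
    events: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        events = tuple((int(y), str(a), float(v)) for y, a, v in self.events)
        for year, attr, value in events:
            if attr not in _SCENARIO_ATTRIBUTES:
                raise ValidationError(
                    f"unknown scenario attribute {attr!r}; expected one of {_SCENARIO_ATTRIBUTES}"
                )
            if year < SCHEME_START_YEAR:
                raise ValidationError(f"scenario event year {year} predates the scheme ({SCHEME_START_YEAR})")
            if value < 0:
                raise ValidationError(f"scenario value must be >= 0, got {value} for {attr}")
        object.__setattr__(self, "events", events)


def apply_scenario(baseline: VoucherPolicy, scenario: ScenarioSpec) -> VoucherPolicy:
    """Return a new policy with all scenario events applied.

    Each event inserts (or replaces) an epoch at its year, inheriting the
    unchanged attributes from the epoch previously in force.  The baseline
    object is not modified; an empty scenario returns an equal policy.
    """
    policy = copy.deepcopy(baseline)
    for year, attr, value in scenario.events:
        if attr == "chronic_amount":
            policy.chronic_amount = value
            policy.chronic_start_year = year
            continue
        current = policy_at(policy, year)
        fields = {
            "annual_amount": current.annual_amount,
            "eligibility_age": current.eligibility_age,
            "carry_cap": current.carry_cap,
        }
        if attr == "eligibility_age":
            fields[attr] = int(value)
        else:
            fields[attr] = value
            # a raised amount keeps the cap meaningful: never below the amount
            if 0 < fields["carry_cap"] < fields["annual_amount"]:
                fields["carry_cap"] = fields["annual_amount"]
        new_epoch = PolicyEpoch(start_year=year, **fields)
        epochs = [e for e in policy.epochs if e.start_year != year]
        epochs.append(new_epoch)
        policy.epochs = sorted(epochs, key=lambda e: e.start_year)
    return policy


def baseline_policy() -> VoucherPolicy:
    """The historical EHCV schedule, 2009 onward."""
    return VoucherPolicy(
        epochs=[
            PolicyEpoch(2009, 250.0, 70, 0.0),
            PolicyEpoch(2012, 500.0, 70, 0.0),
            PolicyEpoch(2013, 1000.0, 70, 0.0),
            PolicyEpoch(2014, 2000.0, 70, 4000.0),
            PolicyEpoch(2017, 2000.0, 65, 4000.0),
        ]
    )


#: Scenario definitions tested in the study, applied to the baseline policy.
BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    "baseline": ScenarioSpec("baseline", ()),
    "amount_escalation": ScenarioSpec(
        "amount_escalation",
        ((2021, "annual_amount", 3000.0), (2025, "annual_amount", 4000.0), (2029, "annual_amount", 5000.0)),
    ),
    "age_lowering": ScenarioSpec("age_lowering", ((2021, "eligibility_age", 60.0),)),
    "chronic_voucher": ScenarioSpec("chronic_voucher", ((2021, "chronic_amount", 2000.0),)),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise ValidationError(
            f"unknown scenario {name!r}; packaged scenarios: {sorted(BUILTIN_SCENARIOS)}"
        ) from None
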