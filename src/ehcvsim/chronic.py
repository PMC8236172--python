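"""Designated chronic-conditions voucher demand.

The chronic add-on targets the elderly population living with chronic
disease.  Band-level eligibility is the population at or above the
eligibility age times a chronic prevalence; per-person utilization is a
monotone piecewise-linear function of the annual add-on amount
(saturating beyond the last knot), reflecting survey-derived behaviour.
Total chronic visits are capped so spending never exceeds the eligible
dollars, and all chronic-voucher visits occur in the private sector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import N_BANDS, eligible_mask
from .demography import PopulationState
from .errors import ValidationError


@dataclass(frozen=True)
class ChronicParams:
    """Prevalence, utilization curve and claim price of the chronic voucher.

    utilization_knots maps annual amount (HKD) to visits/person/year; it
    must start at (0, 0) and be non-decreasing.  The claim price inflates
    geometrically from ``reference_year`` like the general service prices.
    """

    prevalence: np.ndarray
    utilization_knots: tuple[tuple[float, float], ...]
    chronic_price: float
    reference_year: int = 2009
    inflation_rate: float = 0.0

    def __post_init__(self) -> None:
        prev = np.asarray(self.prevalence, dtype=float)
        if prev.shape != (N_BANDS,) or np.any(prev < 0) or np.any(prev > 1):
            raise ValidationError(f"prevalence must be {N_BANDS} fractions in [0, 1], got {prev}")
        object.__setattr__(self, "prevalence", prev)
        knots = tuple((float(a), float(v)) for a, v in self.utilization_knots)
        if not knots or knots[0] != (0.0, 0.0):
            raise ValidationError("utilization curve must start at the knot (0, 0)")
        amounts = [a for a, _ in knots]
        values = [v for _, v in knots]
        if any(a2 <= a1 for a1, a2 in zip(amounts, amounts[1:])):
            raise ValidationError(f"utilization knot amounts must be strictly increasing, got {amounts}")
        if any(v2 < v1 for v1, v2 in zip(values, values[1:])):
            raise ValidationError(f"utilization curve must be non-decreasing, got {values}")
        object.__setattr__(self, "utilization_knots", knots)
        if self.chronic_price <= 0:
            raise ValidationError(f"chronic_price must be positive, got {self.chronic_price}")
        if self.inflation_rate < 0:
            raise ValidationError("inflation_rate must be >= 0")

    def price_at(self, year: int) -> float:
        if year < self.reference_year:
            raise ValidationError(f"year {year} precedes price reference year {self.reference_year}")
        return self.chronic_price * (1.0 + self.inflation_rate) ** (year - self.reference_year)


def chronic_eligible(
    state: PopulationState, params: ChronicParams, eligibility_age: int
) -> np.ndarray:
    """Persons per band eligible for the chronic voucher.

    Bands entirely at or above the eligibility age contribute their count
    times the band's chronic prevalence; younger bands contribute zero.
    """
    mask = np.array(eligible_mask(eligibility_age), dtype=float)
    return state.counts * params.prevalence * mask


def chronic_utilization(amount: float, knots: tuple[tuple[float, float], ...]) -> float:
    """Visits/person/year at a given annual amount.

    Piecewise-linear interpolation between knots with flat extrapolation
    beyond the last knot (utilization saturates).
    """
    if amount < 0:
        raise ValidationError(f"amount must be >= 0, got {amount}")
    xs = np.array([a for a, _ in knots])
    ys = np.array([v for _, v in knots])
    if np.any(np.diff(ys) < 0):
        raise ValidationError("utilization knot table must be non-decreasing")
    return float(np.interp(amount, xs, ys))


def chronic_voucher_visits(
    eligible: np.ndarray,
    amount: float,
    params: ChronicParams,
    year: int | None = None,
) -> float:
    """Total chronic-voucher visits per year across bands.

    Per-person utilization is read off the curve, then capped at
    amount/price so spending cannot exceed the eligible dollars.  The
    price used is the reference price unless a year is given.
    """
    eligible = np.asarray(eligible, dtype=float)
    if np.any(eligible < 0):
        raise ValidationError("eligible counts must be non-negative")
    if amount == 0:
        return 0.0
    price = params.chronic_price if year is None else params.price_at(year)
    per_person = min(chronic_utilization(amount, params.utilization_knots), amount / price)
    return float(eligible.sum() * per_person)
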