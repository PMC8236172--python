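"""Voucher demand: entitlement dollars to expected visits by service.

Voucher dollars are allocated across the five claimable service
categories (non-preventive consultations, chronic-conditions follow-up,
dentistry, vaccination, other) by fixed budget shares and divided by the
category's claim price in the given year — a constant-budget-share demand
form under which dollars are conserved exactly.  Claim prices inflate
geometrically from a reference year, representing supplier-induced
demand; with a constant entitlement this erodes the visits a voucher
buys year over year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import N_BANDS
from .errors import ValidationError

CATEGORY_LABELS: tuple[str, ...] = (
    "non_preventive",
    "chronic_follow_up",
    "dentistry",
    "vaccination",
    "other",
)
N_CATEGORIES = len(CATEGORY_LABELS)


def _as_cat_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_CATEGORIES,):
        raise ValidationError(f"{name} must have {N_CATEGORIES} entries (one per service category)")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ServiceMix:
    """Budget shares, reference-year prices and inflation per category."""

    weight: np.ndarray
    base_price: np.ndarray
    inflation_rate: np.ndarray
    reference_year: int = 2009

    def __post_init__(self) -> None:
        weight = _as_cat_array(self.weight, "weight")
        base_price = _as_cat_array(self.base_price, "base_price")
        inflation = _as_cat_array(self.inflation_rate, "inflation_rate")
        if np.any(weight < 0) or abs(weight.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights must be >= 0 and sum to 1, got {weight} (sum {weight.sum()})")
        if np.any(base_price <= 0):
            raise ValidationError(f"base prices must be positive, got {base_price}")
        if np.any(inflation < 0):
            raise ValidationError(f"inflation rates must be >= 0, got {inflation}")
        object.__setattr__(self, "weight", weight)
        object.__setattr__(self, "base_price", base_price)
        object.__setattr__(self, "inflation_rate", inflation)

    def prices_at(self, year: int) -> np.ndarray:
        """All category claim prices inflated to ``year``."""
        return np.array(
            [
                inflate_price(p, self.reference_year, year, r)
                for p, r in zip(self.base_price, self.inflation_rate)
            ]
        )


@dataclass
class ExpectedVoucherVisits:
    """Expected voucher visits per eligible band and category, per year."""

    visits: np.ndarray  # shape (N_BANDS, N_CATEGORIES)

    def __post_init__(self) -> None:
        visits = np.asarray(self.visits, dtype=float)
        if visits.shape != (N_BANDS, N_CATEGORIES):
            raise ValidationError(f"visits must have shape ({N_BANDS}, {N_CATEGORIES})")
        if np.any(visits < 0) or not np.all(np.isfinite(visits)):
            raise ValidationError("expected visits must be finite and non-negative")
        self.visits = visits

    @property
    def by_category(self) -> np.ndarray:
        return self.visits.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.visits.sum())


def inflate_price(base_price: float, reference_year: int, target_year: int, rate: float) -> float:
    """Geometric price inflation: base * (1+rate)^(target-reference)."""
    if target_year < reference_year:
        raise ValidationError(f"target year {target_year} precedes reference year {reference_year}")
    if rate < 0:
        raise ValidationError(f"inflation rate must be >= 0, got {rate}")
    return base_price * (1.0 + rate) ** (target_year - reference_year)


def expected_voucher_visits(
    eligible_counts: np.ndarray,
    entitlement: float,
    mix: ServiceMix,
    year: int,
) -> ExpectedVoucherVisits:
    """Expected voucher visits if every eligible person spent the full
    entitlement at this year's prices.

    visits[band, cat] = eligible[band] * entitlement * weight[cat] / price[cat, year]
    """
    if entitlement < 0:
        raise ValidationError(f"entitlement must be >= 0, got {entitlement}")
    eligible = np.asarray(eligible_counts, dtype=float)
    if eligible.shape != (N_BANDS,) or np.any(eligible < 0):
        raise ValidationError("eligible_counts must be a non-negative per-band vector")
    prices = mix.prices_at(year)
    if np.any(prices <= 0):
        raise ValidationError(f"inflated prices must be positive, got {prices}")
    visits = eligible[:, None] * entitlement * (mix.weight / prices)[None, :]
    return ExpectedVoucherVisits(visits=visits)


def expected_visits_matrix(
    eligible_counts: np.ndarray,
    entitlement_per_band: np.ndarray,
    mix: ServiceMix,
    year: int,
) -> np.ndarray:
    """Band-by-category expected visits with per-band entitlements.

    Same demand form as :func:`expected_voucher_visits` but allowing the
    entitlement to differ across bands (carry-forward balances diverge
    once eligibility ages change).
    """
    eligible = np.asarray(eligible_counts, dtype=float)
    entitlement = np.asarray(entitlement_per_band, dtype=float)
    if np.any(entitlement < 0):
        raise ValidationError("entitlements must be >= 0")
    prices = mix.prices_at(year)
    if np.any(prices <= 0):
        raise ValidationError(f"inflated prices must be positive, got {prices}")
    return (eligible * entitlement)[:, None] * (mix.weight / prices)[None, :]
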