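"""Willingness-to-join and annual claim expenditure.

Not every eligible person uses vouchers.  Participation is modelled as a
logistic function of calendar time — low in the pilot years, rising as
the scheme matured — that scales expected voucher visits into actual
visits.  Actual visits priced at the year's claim prices give the annual
expenditure series used for calibration against published claim totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demand import ExpectedVoucherVisits, ServiceMix
from .errors import ValidationError


@dataclass(frozen=True)
class UptakeParams:
    """Logistic willingness curve: w(t) = w_max / (1 + exp(-k (t - t0)))."""

    w_max: float
    growth_rate: float
    midpoint_year: float
    band_multiplier: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_max <= 1.0:
            raise ValidationError(f"w_max must lie in [0, 1], got {self.w_max}")
        if self.growth_rate < 0:
            raise ValidationError(f"growth_rate must be >= 0, got {self.growth_rate}")
        if any(m < 0 for m in self.band_multiplier):
            raise ValidationError("band multipliers must be >= 0")


@dataclass
class ExpenditureSeries:
    """Annual voucher-claim expenditure, HKD per calendar year."""

    years: np.ndarray
    amounts: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        amounts = np.asarray(self.amounts, dtype=float)
        if years.shape != amounts.shape or years.ndim != 1:
            raise ValidationError("years and amounts must be 1-D arrays of equal length")
        if np.any(np.diff(years) <= 0):
            raise ValidationError(f"years must be strictly increasing, got {years}")
        if np.any(amounts < 0):
            raise ValidationError("expenditure amounts must be >= 0")
        self.years, self.amounts = years, amounts

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"year": self.years, "amount_hkd": self.amounts}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpenditureSeries":
        df = pd.read_csv(path)
        missing = {"year", "amount_hkd"} - set(df.columns)
        if missing:
            raise ValidationError(f"expenditure CSV missing columns {sorted(missing)}")
        return cls(years=df["year"].to_numpy(), amounts=df["amount_hkd"].to_numpy())


def willingness_at(year: float, params: UptakeParams) -> float:
    """Participation fraction in a calendar year (logistic in time)."""
    z = -params.growth_rate * (year - params.midpoint_year)
    return params.w_max / (1.0 + np.exp(z))


def actual_voucher_visits(expected: ExpectedVoucherVisits, willingness: float) -> np.ndarray:
    """Scale expected visits (band x category) by the participation fraction."""
    if not 0.0 <= willingness <= 1.0:
        raise ValidationError(f"willingness must lie in [0, 1], got {willingness}")
    return expected.visits * willingness


def annual_expenditure(actual_by_category: np.ndarray, mix: ServiceMix, year: int) -> float:
    """Claim expenditure: actual visits per category times that year's prices."""
    visits = np.asarray(actual_by_category, dtype=float)
    if np.any(visits < 0):
        raise ValidationError("visit counts must be non-negative")
    return float(visits @ mix.prices_at(year))
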