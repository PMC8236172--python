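"""Age-structured population model and baseline visit generation.

The demographic core is a four-compartment stock-and-flow system: births
enter the under-60 band, deaths remove a band-specific fraction each week,
and aging moves people from each band to the next as a first-order outflow
(rate 1/(width*52) per week for the five-year bands, so that the mean
residence time equals the band width).  Each band generates primary-care
visits in proportion to its size, and those visits are split into the
baseline public and private streams with band-specific shares.  The split
is independent of voucher use; vouchers act later, by shifting visits
between the two streams.

All rates are per week.  Euler integration is explicit; a step that would
drive a stock negative raises instead of clamping so that instability is
visible rather than silently absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BAND_LABELS, N_BANDS
from .errors import IntegrationInstabilityError, ValidationError


def _as_band_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_BANDS,):
        raise ValidationError(f"{name} must have {N_BANDS} entries (one per age band), got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values: {arr}")
    return arr


@dataclass(frozen=True)
class PopulationState:
    """Persons per age band at a given week index."""

    week_index: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = _as_band_array(self.counts, "counts")
        if np.any(counts < 0):
            raise ValidationError(f"population counts must be non-negative, got {counts}")
        if self.week_index < 0:
            raise ValidationError(f"week_index must be >= 0, got {self.week_index}")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class DemographyRates:
    """Weekly vital rates, visit rates and baseline sector shares per band.

    birth_inflow
        Persons per week entering the under-60 band.
    death_rate, aging_rate
        Fraction per week leaving each band; the terminal band has no
        aging outflow.
    visit_rate
        Primary-care visits per person per week.
    public_share
        Fraction of each band's visits that go to the public sector in
        the absence of vouchers.
    """

    birth_inflow: float
    death_rate: np.ndarray
    aging_rate: np.ndarray
    visit_rate: np.ndarray
    public_share: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.birth_inflow) or self.birth_inflow < 0:
            raise ValidationError(f"birth_inflow must be finite and >= 0, got {self.birth_inflow}")
        for name in ("death_rate", "aging_rate", "visit_rate", "public_share"):
            arr = _as_band_array(getattr(self, name), name)
            if np.any(arr < 0):
                raise ValidationError(f"{name} must be non-negative, got {arr}")
            object.__setattr__(self, name, arr)
        if np.any(self.public_share > 1):
            raise ValidationError(f"public_share must lie in [0, 1], got {self.public_share}")
        if self.aging_rate[-1] != 0:
            raise ValidationError("the terminal age band cannot have an aging outflow")


@dataclass
class VisitFlows:
    """Visits per week per band, total and split into sector streams."""

    total: np.ndarray
    public_base: np.ndarray = field(default=None)  # type: ignore[assignment]
    private_base: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.total = _as_band_array(self.total, "total visits")
        if np.any(self.total < 0):
            raise ValidationError("visit flows must be non-negative")


def step_population(state: PopulationState, rates: DemographyRates, dt: float) -> PopulationState:
    """Advance the population one explicit Euler step of ``dt`` weeks.

    Per band: d(count)/dt = inflow_from_younger (+ births for under-60)
    - death_rate*count - aging_rate*count.  Raises
    :class:`IntegrationInstabilityError` naming the band if a count would
    go negative.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    counts = state.counts
    aging_out = rates.aging_rate * counts
    inflow = np.zeros(N_BANDS)
    inflow[0] = rates.birth_inflow
    inflow[1:] += aging_out[:-1]
    new_counts = counts + dt * (inflow - rates.death_rate * counts - aging_out)
    if np.any(new_counts < 0):
        band = BAND_LABELS[int(np.argmin(new_counts))]
        raise IntegrationInstabilityError(
            f"Euler step of dt={dt} weeks drove band {band!r} negative "
            f"({new_counts.min():.3g}); reduce dt or the outflow rates"
        )
    return PopulationState(week_index=state.week_index + dt, counts=new_counts)


def generate_visits(state: PopulationState, rates: DemographyRates) -> VisitFlows:
    """Visits per week per band: count times the band's visit rate."""
    return VisitFlows(total=state.counts * rates.visit_rate)


def split_public_private(flows: VisitFlows, rates: DemographyRates) -> VisitFlows:
    """Split each band's visits into baseline public and private streams."""
    flows.public_base = rates.public_share * flows.total
    flows.private_base = flows.total - flows.public_base
    return flows
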