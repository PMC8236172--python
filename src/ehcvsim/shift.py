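"""Public/private utilization shift accounting.

Each voucher-funded visit either replaces a visit that would have gone to
the public sector (a true shift), replaces one that was already private
(no net change), or is newly induced demand.  The three fractions sum to
one.  The headline reliance metric is the ratio of annual public to
private visits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import UndefinedRatioError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstitutionParams:
    """Where voucher visits come from: public, private, or new demand."""

    from_public: float
    from_private: float
    induced: float

    def __post_init__(self) -> None:
        parts = (self.from_public, self.from_private, self.induced)
        if any(not 0.0 <= p <= 1.0 for p in parts):
            raise ValidationError(f"substitution fractions must lie in [0, 1], got {parts}")
        if abs(sum(parts) - 1.0) > 1e-9:
            raise ValidationError(f"substitution fractions must sum to 1, got {sum(parts)}")


def net_shift(
    public_base: float,
    private_base: float,
    voucher_visits: float,
    sub: SubstitutionParams,
) -> tuple[float, float]:
    """Sector totals after accounting for voucher visits.

    public loses from_public * V; private gains the shifted visits plus
    the induced ones; the from_private share is already inside
    private_base and moves nothing.  A shift exceeding the public stock
    is truncated (with a warning) rather than raising: aggregate flows
    can transiently overshoot in extreme scenarios.
    """
    if public_base < 0 or private_base < 0 or voucher_visits < 0:
        raise ValidationError("visit counts must be non-negative")
    shifted = sub.from_public * voucher_visits
    if shifted > public_base:
        logger.warning(
            "voucher shift %.3g exceeds public baseline %.3g; truncating", shifted, public_base
        )
        shifted = public_base
    induced = sub.induced * voucher_visits
    return public_base - shifted, private_base + shifted + induced


def public_private_ratio(public: float, private: float) -> float:
    """Annual public visits divided by private visits."""
    if private <= 0:
        raise UndefinedRatioError(f"ratio undefined for private visits = {private}")
    return public / private
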