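"""Age-band definitions shared across the model.

The population is partitioned into four bands: everyone under 60, two
five-year elderly bands (60-64, 65-69), and an open-ended 70+ band.
Voucher eligibility rules are expressed against the lower edge of a band.
"""

from __future__ import annotations

BAND_LABELS: tuple[str, ...] = ("under60", "b60_64", "b65_69", "b70plus")
N_BANDS: int = len(BAND_LABELS)

#: Lower age edge of each band in years.
BAND_LOWER_AGE: tuple[int, ...] = (0, 60, 65, 70)

#: Band width in years; the first and last bands are open-ended (None).
BAND_WIDTH_YEARS: tuple[int | None, ...] = (None, 5, 5, None)

WEEKS_PER_YEAR: int = 52


def band_index(label: str) -> int:
    """Return the positional index of a band label."""
    try:
        return BAND_LABELS.index(label)
    except ValueError:
        raise KeyError(f"unknown age band {label!r}; expected one of {BAND_LABELS}") from None


def eligible_mask(eligibility_age: int) -> tuple[bool, ...]:
    """Bands whose members are all at least ``eligibility_age`` years old."""
    return tuple(lower >= eligibility_age and lower > 0 for lower in BAND_LOWER_AGE)
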