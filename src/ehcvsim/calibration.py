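"""Parameter fitting against annual expenditure and trajectory anchors.

The free parameters (uptake curve, substitution fractions, price
inflation, chronic utilization scale, carry-forward release) are
identified by dotted names and applied to a copy of a fixture bundle.
The objective is the mean absolute percentage error (MAPE) of simulated
versus observed annual claim expenditure, optionally plus weighted
squared errors on named trajectory anchors (e.g. a published
public-to-private ratio in a given year).  Minimization is multi-start
bounded Nelder-Mead with a fixed seed; a fit is accepted when its MAPE
stays below 40%.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .demand import CATEGORY_LABELS
from .errors import CalibrationFailureError, ValidationError
from .fixtures import FixtureBundle
from .uptake import ExpenditureSeries

MAPE_ACCEPTANCE_THRESHOLD = 40.0  # percent


# -- fitness metrics ----------------------------------------------------


def _align(simulated: ExpenditureSeries, observed: ExpenditureSeries) -> tuple[np.ndarray, np.ndarray]:
    if len(observed.years) == 0:
        raise ValidationError("observed series is empty")
    if not set(observed.years).issubset(set(simulated.years)):
        raise ValidationError(
            f"simulated years {simulated.years.tolist()} do not cover observed years {observed.years.tolist()}"
        )
    sim_map = dict(zip(simulated.years.tolist(), simulated.amounts.tolist()))
    sim = np.array([sim_map[y] for y in observed.years.tolist()])
    return sim, observed.amounts


def mape(simulated: ExpenditureSeries, observed: ExpenditureSeries) -> float:
    """Mean absolute percentage error over the observed years, in percent."""
    sim, obs = _align(simulated, observed)
    if np.any(obs <= 0):
        raise ValidationError("MAPE undefined: observed series contains non-positive values")
    return float(np.mean(np.abs(sim - obs) / obs) * 100.0)


def r_squared(simulated: ExpenditureSeries, observed: ExpenditureSeries) -> float:
    """Coefficient of determination about the observed mean (can be < 0)."""
    sim, obs = _align(simulated, observed)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("R-squared undefined: observed series has zero variance")
    ss_res = float(np.sum((obs - sim) ** 2))
    return 1.0 - ss_res / ss_tot


# -- parameter plumbing -------------------------------------------------


def _set_uptake(bundle: FixtureBundle, attr: str, value: float) -> None:
    from .uptake import UptakeParams

    kwargs = {
        "w_max": bundle.uptake.w_max,
        "growth_rate": bundle.uptake.growth_rate,
        "midpoint_year": bundle.uptake.midpoint_year,
        "band_multiplier": bundle.uptake.band_multiplier,
    }
    if attr not in ("w_max", "growth_rate", "midpoint_year"):
        raise ValidationError(f"unknown uptake parameter {attr!r}")
    kwargs[attr] = value
    bundle.uptake = UptakeParams(**kwargs)


def _set_substitution(bundle: FixtureBundle, which: str, attr: str, value: float) -> None:
    from .shift import SubstitutionParams

    current = getattr(bundle, which)
    fp, ind = current.from_public, current.induced
    if attr == "from_public":
        fp = value
    elif attr == "induced":
        ind = value
    else:
        raise ValidationError(f"substitution parameter must be from_public or induced, got {attr!r}")
    if fp + ind > 1.0:
        raise ValidationError(f"from_public + induced must be <= 1, got {fp + ind}")
    setattr(bundle, which, SubstitutionParams(from_public=fp, from_private=1.0 - fp - ind, induced=ind))


def _set_mix(bundle: FixtureBundle, attr: str, value: float) -> None:
    from .demand import ServiceMix

    mix = bundle.service_mix
    kwargs = {
        "weight": mix.weight.copy(),
        "base_price": mix.base_price.copy(),
        "inflation_rate": mix.inflation_rate.copy(),
        "reference_year": mix.reference_year,
    }
    if attr == "price_scale":
        kwargs["base_price"] = kwargs["base_price"] * value
    elif attr.startswith("inflation."):
        cat = attr.split(".", 1)[1]
        if cat == "all":
            kwargs["inflation_rate"] = np.full_like(kwargs["inflation_rate"], value)
        else:
            kwargs["inflation_rate"][CATEGORY_LABELS.index(cat)] = value
    else:
        raise ValidationError(f"unknown service-mix parameter {attr!r}")
    bundle.service_mix = ServiceMix(**kwargs)


def _set_chronic(bundle: FixtureBundle, attr: str, value: float) -> None:
    from .chronic import ChronicParams

    c = bundle.chronic
    kwargs = {
        "prevalence": c.prevalence.copy(),
        "utilization_knots": c.utilization_knots,
        "chronic_price": c.chronic_price,
        "reference_year": c.reference_year,
        "inflation_rate": c.inflation_rate,
    }
    if attr == "price":
        kwargs["chronic_price"] = value
    elif attr == "utilization_scale":
        kwargs["utilization_knots"] = tuple((a, v * value) for a, v in c.utilization_knots)
    elif attr == "inflation_rate":
        kwargs["inflation_rate"] = value
    else:
        raise ValidationError(f"unknown chronic parameter {attr!r}")
    bundle.chronic = ChronicParams(**kwargs)


def apply_parameters(fixture: FixtureBundle, params: dict[str, float]) -> FixtureBundle:
    """Return a copy of ``fixture`` with dotted parameters applied.

    Supported names: ``uptake.w_max``, ``uptake.growth_rate``,
    ``uptake.midpoint_year``; ``substitution.from_public``,
    ``substitution.induced`` (from_private is the remainder), same under
    ``substitution_chronic.*``; ``mix.price_scale``,
    ``mix.inflation.<category|all>``; ``chronic.price``,
    ``chronic.utilization_scale``, ``chronic.inflation_rate``;
    ``carry_release_fraction``.
    """
    bundle = copy.deepcopy(fixture)
    for name, value in params.items():
        head, _, rest = name.partition(".")
        if head == "uptake":
            _set_uptake(bundle, rest, value)
        elif head in ("substitution", "substitution_chronic"):
            _set_substitution(bundle, head, rest, value)
        elif head == "mix":
            _set_mix(bundle, rest, value)
        elif head == "chronic":
            _set_chronic(bundle, rest, value)
        elif name == "carry_release_fraction":
            if not 0.0 <= value <= 1.0:
                raise ValidationError("carry_release_fraction must lie in [0, 1]")
            bundle.carry_release_fraction = value
        else:
            raise ValidationError(f"unknown calibration parameter {name!r}")
    return bundle


# -- fitting ------------------------------------------------------------


@dataclass
class CalibrationSpec:
    """Free parameters with bounds and the optimizer budget."""

    free_parameters: list[tuple[str, float, float]]
    max_evaluations: int = 400
    n_starts: int = 3
    seed: int = 0
    anchor_weight: float = 100.0

    def __post_init__(self) -> None:
        if not self.free_parameters:
            raise ValidationError("at least one free parameter is required")
        for name, lo, hi in self.free_parameters:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValidationError(f"bounds for {name!r} must be finite and ordered, got ({lo}, {hi})")


@dataclass
class CalibrationResult:
    """Fitted values plus the fitness metrics of the calibrated run."""

    parameters: dict[str, float]
    mape: float
    r_squared: float
    accepted: bool
    objective: float
    n_evaluations: int
    start_objectives: list[float] = field(default_factory=list)


def _simulated_expenditure(fixture: FixtureBundle, scenario, start_year: int, end_year: int) -> tuple[ExpenditureSeries, pd.DataFrame]:
    from .engine import SimulationConfig, run_scenario

    out = run_scenario(
        SimulationConfig(fixture=fixture, scenario=scenario, start_year=start_year, end_year=end_year)
    )
    rec = out.records
    series = ExpenditureSeries(
        years=rec["year"].to_numpy(dtype=int), amounts=rec["expenditure_hkd"].to_numpy(dtype=float)
    )
    return series, rec


def fit_parameters(
    spec: CalibrationSpec,
    observed: ExpenditureSeries,
    fixture: FixtureBundle,
    anchors: dict[str, tuple[int, str, float]] | None = None,
    scenario=None,
    end_year: int | None = None,
) -> CalibrationResult:
    """Fit the free parameters to the observed expenditure series.

    ``anchors`` maps a label to (year, output column, target value); each
    contributes ``anchor_weight * ((sim - target)/target)**2`` to the
    objective.  Multi-start Nelder-Mead within bounds, reproducible for a
    fixed seed.  The returned point never lies outside the bounds and its
    objective is no worse than at any start point.
    """
    from .policy import get_scenario

    if scenario is None:
        scenario = get_scenario("baseline")
    anchors = anchors or {}
    start_year = int(min(observed.years.min(), 2009))
    horizon_end = int(end_year if end_year is not None else max(observed.years.max(), *(a[0] for a in anchors.values()), start_year + 1))

    names = [p[0] for p in spec.free_parameters]
    lo = np.array([p[1] for p in spec.free_parameters])
    hi = np.array([p[2] for p in spec.free_parameters])
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        x = np.clip(x, lo, hi)
        try:
            bundle = apply_parameters(fixture, dict(zip(names, x)))
            series, rec = _simulated_expenditure(bundle, scenario, start_year, horizon_end)
            value = mape(series, observed)
            if anchors:
                indexed = rec.set_index("year")
                for year, column, target in anchors.values():
                    sim_val = float(indexed.loc[year, column])
                    value += spec.anchor_weight * ((sim_val - target) / target) ** 2
        except (ValidationError, KeyError):
            return np.inf
        return value

    rng = np.random.default_rng(spec.seed)
    starts = [0.5 * (lo + hi)]
    starts += [lo + (hi - lo) * rng.random(len(names)) for _ in range(max(0, spec.n_starts - 1))]

    best = None
    start_objs = []
    per_start_budget = max(spec.max_evaluations // max(len(starts), 1), 20)
    for x0 in starts:
        f0 = objective(x0)
        start_objs.append(f0)
        if not np.isfinite(f0):
            continue
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxfev": per_start_budget, "xatol": 1e-4, "fatol": 1e-6},
        )
        candidate = (min(res.fun, f0), np.clip(res.x, lo, hi) if res.fun <= f0 else x0)
        if best is None or candidate[0] < best[0]:
            best = candidate
    if best is None:
        raise CalibrationFailureError("objective non-finite at every start point")

    fitted = dict(zip(names, (float(v) for v in best[1])))
    bundle = apply_parameters(fixture, fitted)
    series, _ = _simulated_expenditure(bundle, scenario, start_year, horizon_end)
    final_mape = mape(series, observed)
    final_r2 = r_squared(series, observed)
    return CalibrationResult(
        parameters=fitted,
        mape=final_mape,
        r_squared=final_r2,
        accepted=final_mape < MAPE_ACCEPTANCE_THRESHOLD,
        objective=float(best[0]),
        n_evaluations=n_eval,
        start_objectives=start_objs,
    )
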