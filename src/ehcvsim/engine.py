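"""Weekly Euler simulation loop over the 2009-2032 horizon.

The engine wires the submodels together.  Each simulated year is 52
weeks; annual inputs (policy epoch, willingness, claim prices, voucher
demand) are computed once per year from the start-of-year state and held
constant within it, while demography advances every week.  Annual
outputs are exact sums of the weekly flows (visits, expenditure) or
end-of-year snapshots (population).

Two sector series are emitted: the population-model baseline
(``visits_public_base`` / ``visits_private_base``), which is what the
demography alone generates, and the post-shift series
(``visits_public`` / ``visits_private``) after voucher-funded visits
have displaced public ones and induced new private demand.  The headline
``ratio_public_private`` is the annual post-shift public total divided
by the private total.

Carry-forward is tracked as a mean balance per person per band: each
year the effective entitlement is the new allocation plus a fixed
fraction of the accumulated balance, and the unspent remainder is capped
at the scheme's carry-forward limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BAND_LABELS, N_BANDS, WEEKS_PER_YEAR, eligible_mask
from .chronic import chronic_eligible, chronic_voucher_visits
from .demand import CATEGORY_LABELS, expected_visits_matrix
from .demography import PopulationState, generate_visits, split_public_private, step_population
from .errors import ValidationError
from .fixtures import FixtureBundle
from .policy import (
    ScenarioSpec,
    apply_scenario,
    baseline_policy,
    chronic_amount_at,
    policy_at,
)
from .shift import net_shift, public_private_ratio
from .uptake import annual_expenditure, willingness_at

OUTPUT_COLUMNS = (
    ["year"]
    + [f"pop_{b}" for b in BAND_LABELS]
    + [f"visits_{b}" for b in BAND_LABELS]
    + [
        "visits_total",
        "visits_public_base",
        "visits_private_base",
        "visits_public",
        "visits_private",
        "ratio_public_private",
        "ratio_defined",
    ]
    + [f"voucher_visits_{c}" for c in CATEGORY_LABELS]
    + ["chronic_voucher_visits", "expenditure_hkd", "willingness"]
)


@dataclass
class SimulationConfig:
    """A full run description: fixture, scenario, horizon and step size."""

    fixture: FixtureBundle
    scenario: ScenarioSpec
    start_year: int = 2009
    end_year: int = 2032
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValidationError(f"start_year {self.start_year} must precede end_year {self.end_year}")
        steps = WEEKS_PER_YEAR / self.dt
        if self.dt <= 0 or abs(steps - round(steps)) > 1e-9:
            raise ValidationError(f"dt must be a positive divisor of {WEEKS_PER_YEAR} weeks, got {self.dt}")

    @property
    def steps_per_year(self) -> int:
        return int(round(WEEKS_PER_YEAR / self.dt))


@dataclass
class SimulationOutput:
    """Annual records of a scenario run (one row per simulated year)."""

    scenario: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(OUTPUT_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValidationError(f"output records missing columns {sorted(missing)}")


@dataclass
class YearContext:
    """Inputs held constant across the weeks of one calendar year."""

    year: int
    rates: object  # DemographyRates
    weekly_voucher_visits: float
    weekly_chronic_visits: float
    substitution: object
    substitution_chronic: object


def integrate_week(state: PopulationState, ctx: YearContext, dt: float):
    """One Euler step: demography, visit generation, split, and shift.

    Returns the advanced state and a dict of this step's visit flows.
    """
    flows = split_public_private(generate_visits(state, ctx.rates), ctx.rates)
    week_factor = dt  # flows are per week; a step covers dt weeks
    total_by_band = flows.total * week_factor
    pub_base = float(flows.public_base.sum()) * week_factor
    priv_base = float(flows.private_base.sum()) * week_factor
    v_general = ctx.weekly_voucher_visits * dt
    v_chronic = ctx.weekly_chronic_visits * dt
    pub, priv = net_shift(pub_base, priv_base, v_general, ctx.substitution)
    pub, priv = net_shift(pub, priv, v_chronic, ctx.substitution_chronic)
    new_state = step_population(state, ctx.rates, dt)
    record = {
        "total_by_band": total_by_band,
        "public_base": pub_base,
        "private_base": priv_base,
        "public": pub,
        "private": priv,
    }
    return new_state, record


def run_scenario(config: SimulationConfig) -> SimulationOutput:
    """Run one scenario end to end and return annual records.

    Deterministic: identical configs produce bit-identical outputs.
    """
    fixture = config.fixture
    policy = apply_scenario(baseline_policy(), config.scenario)
    state = PopulationState(week_index=0.0, counts=fixture.initial_counts.copy())
    balance = np.zeros(N_BANDS)  # mean carry-forward balance per person, HKD
    release = fixture.carry_release_fraction
    band_mult = np.asarray(fixture.uptake.band_multiplier, dtype=float)

    rows = []
    for year in range(config.start_year, config.end_year + 1):
        rates = fixture.demography.rates_for(year)
        epoch = policy_at(policy, year)
        elig = np.array(eligible_mask(epoch.eligibility_age), dtype=float)

        # effective entitlement: allocation plus released carry-forward
        available = (epoch.annual_amount + release * balance) * elig
        eligible_counts = state.counts * elig
        w_year = willingness_at(year, fixture.uptake)
        w_band = np.clip(w_year * band_mult, 0.0, 1.0)

        if epoch.annual_amount > 0:
            expected_bc = expected_visits_matrix(eligible_counts, available, fixture.service_mix, year)
        else:
            expected_bc = np.zeros((N_BANDS, len(CATEGORY_LABELS)))
        actual_bc = expected_bc * w_band[:, None]
        actual_by_cat = actual_bc.sum(axis=0)
        annual_voucher_visits = float(actual_bc.sum())

        c_amount = chronic_amount_at(policy, year)
        if c_amount > 0:
            elig_chronic = chronic_eligible(state, fixture.chronic, epoch.eligibility_age)
            annual_chronic_visits = chronic_voucher_visits(elig_chronic, c_amount, fixture.chronic, year=year)
        else:
            elig_chronic = np.zeros(N_BANDS)
            annual_chronic_visits = 0.0

        ctx = YearContext(
            year=year,
            rates=rates,
            weekly_voucher_visits=annual_voucher_visits / WEEKS_PER_YEAR,
            weekly_chronic_visits=annual_chronic_visits / WEEKS_PER_YEAR,
            substitution=fixture.substitution,
            substitution_chronic=fixture.substitution_chronic,
        )

        band_visits = np.zeros(N_BANDS)
        sums = {"public_base": 0.0, "private_base": 0.0, "public": 0.0, "private": 0.0}
        for _ in range(config.steps_per_year):
            try:
                state, rec = integrate_week(state, ctx, config.dt)
            except Exception as exc:  # attach time context, re-raise
                raise type(exc)(f"year {year}, week {state.week_index:.1f}: {exc}") from exc
            band_visits += rec["total_by_band"]
            for key in sums:
                sums[key] += rec[key]

        expenditure = 0.0
        if epoch.annual_amount > 0:
            expenditure += annual_expenditure(actual_by_cat, fixture.service_mix, year)
        if annual_chronic_visits > 0:
            expenditure += annual_chronic_visits * fixture.chronic.price_at(year)

        ratio_defined = sums["private"] > 0
        ratio = public_private_ratio(sums["public"], sums["private"]) if ratio_defined else np.nan

        # end-of-year carry-forward update per eligible band
        spent_pp = w_band * available
        new_balance = balance + epoch.annual_amount * elig - spent_pp
        if epoch.carry_cap > 0:
            balance = np.clip(new_balance, 0.0, epoch.carry_cap) * elig
        else:
            balance = np.zeros(N_BANDS)

        row = {"year": year}
        row.update({f"pop_{b}": state.counts[i] for i, b in enumerate(BAND_LABELS)})
        row.update({f"visits_{b}": band_visits[i] for i, b in enumerate(BAND_LABELS)})
        row.update(
            {
                "visits_total": float(band_visits.sum()),
                "visits_public_base": sums["public_base"],
                "visits_private_base": sums["private_base"],
                "visits_public": sums["public"],
                "visits_private": sums["private"],
                "ratio_public_private": ratio,
                "ratio_defined": bool(ratio_defined),
            }
        )
        row.update({f"voucher_visits_{c}": actual_by_cat[i] for i, c in enumerate(CATEGORY_LABELS)})
        row.update(
            {
                "chronic_voucher_visits": annual_chronic_visits,
                "expenditure_hkd": expenditure,
                "willingness": w_year,
            }
        )
        rows.append(row)

    return SimulationOutput(scenario=config.scenario.name, records=pd.DataFrame(rows, columns=OUTPUT_COLUMNS))


def compare_scenarios(configs: list[SimulationConfig]) -> pd.DataFrame:
    """Per-year deltas of each scenario against the first config.

    Returns a long DataFrame with columns year, scenario,
    d_public_visits, d_private_visits, d_ratio.  The first (reference)
    config compared with itself yields zeros.
    """
    if not configs:
        raise ValidationError("compare_scenarios needs at least one config")
    ref = configs[0]
    for cfg in configs[1:]:
        if (cfg.start_year, cfg.end_year, cfg.dt) != (ref.start_year, ref.end_year, ref.dt):
            raise ValidationError("all configs must share the same horizon and dt")
    outputs = [run_scenario(cfg) for cfg in configs]
    base = outputs[0].records.set_index("year")
    frames = []
    for out in outputs:
        rec = out.records.set_index("year")
        frames.append(
            pd.DataFrame(
                {
                    "year": rec.index,
                    "scenario": out.scenario,
                    "d_public_visits": (rec["visits_public"] - base["visits_public"]).to_numpy(),
                    "d_private_visits": (rec["visits_private"] - base["visits_private"]).to_numpy(),
                    "d_ratio": (rec["ratio_public_private"] - base["ratio_public_private"]).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
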