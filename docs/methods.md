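# Methods

## Model

`ehcvsim` is a deterministic system-dynamics model of primary-care
utilization under Hong Kong's Elderly Health Care Voucher (EHCV)
scheme. Stocks are the population of four age bands (<60, 60–64,
65–69, 70+) and the mean per-person carry-forward voucher balance per
band; flows are births, deaths, band-to-band aging, visits, voucher
claims and the resulting shifts between the public and private sectors.
Time advances in weekly explicit-Euler steps; a simulated year is
exactly 52 weeks (no calendar alignment), so the 2009–2032 horizon is
24 × 52 steps. Annual inputs — the policy epoch in force, willingness
to join, claim prices, and the year's voucher demand — are computed
from the start-of-year state and held constant within the year; annual
outputs are exact sums of weekly flows (visits, expenditure) or
end-of-year snapshots (population).

### Demography and visit generation

Per band *b*, with weekly rates,

```
dN_b/dt = inflow_b − μ_b N_b − a_b N_b,      inflow_0 = births,
inflow_b = a_{b−1} N_{b−1}  (b > 0)
```

Aging is a first-order outflow with `a = 1/(width·52)` per week for the
five-year bands, the standard stock-and-flow approximation of cohort
progression (mean residence time equals the band width). The under-60
band's aging rate (the fraction turning 60 each year) and the 70+ death
rate are year-varying lookup tables, emulating census projections; all
other rates are constant. An Euler step that would drive a stock
negative raises an error rather than clamping, so instability is
visible. Visits are generated as `N_b × v_b` (visits/person/week) and
split into public/private baseline streams by a band-specific public
share that is independent of voucher use.

### Voucher demand

Voucher dollars follow a constant-budget-share demand: a per-person
entitlement `E` allocates across five service categories by fixed
weights `w_c` and buys `E·w_c/p_c(t)` visits at the category's claim
price. This form makes dollar conservation exact
(`Σ_c visits_c · p_c = eligible × E`) and hence testable. Prices
inflate geometrically (`p_c(t) = p_c(2009)(1+g)^(t−2009)`),
representing supplier-induced demand; with a fixed-dollar voucher this
erodes purchased visits year over year, which is the model's main
long-run fade mechanism.

The effective entitlement is the year's allocation plus a fixed
released fraction of the band's carry-forward balance; the unspent
remainder accumulates subject to the scheme's $4000 cap (no
carry-forward before the cap's 2014 introduction). Balances are
aggregate per-band means, not individual accounts — consistent with
the aggregate character of the model, at the cost of ignoring
within-band heterogeneity in balances.

### Uptake

Participation is a logistic in calendar time,
`w(t) = w_max / (1 + exp(−k(t − t₀)))`, capturing the documented low
pilot-phase uptake rising as the scheme matured. Willingness scales
the general-voucher visits only; the chronic add-on's utilization curve
is survey-derived behaviour and is not additionally scaled (that would
double-count uptake). A per-band multiplier exists but defaults to 1.

### Chronic-conditions add-on

Eligible persons are the population at or above the scheme age gate
times a band-specific chronic prevalence. Per-person utilization is a
monotone piecewise-linear function of the annual add-on amount,
saturating beyond its last knot, and is capped at `amount/price(t)` so
spending cannot exceed the entitlement. In the packaged fixture the cap
binds at the $2000 amount, so chronic visits behave as
`eligible × amount / price(t)` — and claim-price inflation drives the
scenario's fade. All chronic-voucher visits occur in the private
sector.

### Utilization shift and the reliance metric

Each voucher-funded visit either replaces a public visit
(`from_public`), replaces an already-private visit (`from_private`,
no net change), or is newly induced demand (`induced`); the three
fractions sum to 1. Weekly sector totals are

```
public  = public_base − from_public·V
private = private_base + (from_public + induced)·V
```

with the shift truncated (and logged) if it would exceed the public
stock. The headline metric is the annual ratio
`R = Σ public / Σ private` of post-shift sums, never an average of
weekly ratios. The engine also emits the pre-shift ("population
model") sector series, because the two series answer different
questions: what demography alone generates versus what remains after
voucher-induced shifting.

Two substitution triples are used: general vouchers
(0.35/0.18/0.47) and the chronic add-on (0.55/0.10/0.35). The large
induced share for general vouchers reflects cohort evidence that
voucher use was largely additional demand rather than substitution;
the higher `from_public` for chronic patients reflects their documented
concentration in public services. Setting `induced = 0` recovers a
pure-substitution variant.

## Parameters of the packaged Hong-Kong-anchored fixture

The study's true inputs (census tables, household-survey utilization,
Department of Health claims) are not public. The packaged bundle
(`src/ehcvsim/data/hk_fixture.json`) is reconstructed by the committed
script `fixtures/build_hk_fixture.py`: bounded least squares over ~19
structural parameters against the published trajectory anchors (age-band
visit shares 2009/2032, sector visit volumes 2018/2019/2032, the
public-to-private ratio 2018/2032, and the first-year shifts of the
amount-escalation and chronic scenarios). Anchors hold within 10%
relative tolerance and are re-verified by a self-check every time the
bundle is first loaded.

Fixed assumptions (not fitted):

- 2009 population split 6.30/0.33/0.29/0.58 million across the four
  bands (Hong-Kong-scale totals).
- Chronic prevalence 0.15/0.45/0.55/0.70 by ascending band — exposed
  in the fixture, tagged `assumed`, and exercised in sensitivity tests.
- Claim-price inflation 7.5%/yr for the general categories — near the
  maximum consistent with holding the GP claim price inside the
  published 260–330 HKD window across 2016–2019 (GP base price
  158 HKD in 2009); the optometry-like "other" category (base 950 HKD)
  tracks its 1600–1951 window approximately. The chronic follow-up
  claim price inflates at 5%/yr: routine consultations sit at the
  cheap, less discretionary end of the mix, where supplier-induced
  escalation is weakest.
- Carry-forward release fraction ≈ 0.1/yr (fitted near its bound): a
  small steady draw-down keeps balances at the $4000 cap in both the
  baseline and escalation scenarios, so a scenario's first-year
  entitlement difference equals its nominal amount difference.

Notable fitted values: uptake `w_max ≈ 0.82`, growth 0.57/yr, midpoint
≈ 2013; per-capita visit rates 2.5/4.7/5.6/16.5 per year by ascending
band; public shares 0.41–0.57 rising with age; chronic utilization
saturating at 7 visits/person/yr at the $2000 add-on (the dollar cap
binds just below this). The printed 2018/2019/2032 trajectory numbers
are not all simultaneously satisfiable from one pair of sector series
under any fixed substitution split; reading the "population model"
figures as pre-shift series and the scenario-comparison figures as
post-shift series resolves most of the tension, and the residual
targets are a consistency-adjusted compromise (every anchor within 10%,
most within ~5%).

The fixture's observed 2009–2016 expenditure series is a synthetic
stand-in for the non-public claims data: model output at the packaged
parameters times seeded mean-one lognormal noise whose level declines
from the pilot years (CV 0.60) to 2016 (CV 0.08). Against it the
packaged model scores MAPE ≈ 26% and R² ≈ 0.95, inside the model's
acceptance bound (MAPE < 40%).

## Calibration machinery

`calibration.fit_parameters` minimizes expenditure MAPE plus optional
weighted squared anchor errors over dotted-named free parameters with
bounds, using multi-start Nelder–Mead (deterministic for a fixed seed;
start points are the bound midpoint plus seeded uniform draws). The
returned point is clipped to bounds and never worse than any start
point. Parameter recovery is verified on synthetic data: fitting
`w_max` to expenditure generated at a known value with 5% multiplicative
noise recovers it within ±0.1; the noiseless self-fit attains MAPE < 1%.

## Synthetic data generator

`generate_synthetic_fixture(seed, scale)` draws structurally valid
random bundles: an aging population (death rates declining over
calendar time, positive aging flows), public reliance rising with age,
a monotone saturating chronic curve, and plausible price/weight ranges.
It emulates the *shape* of the real inputs, not their values: passing
property tests on these bundles demonstrates structural correctness
(conservation, monotonicity, determinism), not empirical fidelity to
Hong Kong. Features of real data it does not emulate include
within-band heterogeneity, migration, sex/income stratification and
calendar seasonality.

## Numerical choices and degenerate inputs

- Explicit Euler only, dt = 1 week by default; dt must divide 52. A
  first-order Richardson check (halving dt halves the single-band decay
  error) is a test utility, not a second integrator. Halving dt moves
  2032 band populations by < 1% on the packaged fixture.
- Annual-to-weekly rate conversion is simple division by 52, consistent
  with linear Euler flows.
- Zero private visits flag the ratio as undefined (NaN) in that record;
  direct ratio calls raise.
- A shift exceeding the public baseline truncates with a warning
  (aggregate flows can transiently overshoot in extreme scenarios);
  population stocks, by contrast, raise on negativity.
- Policy changes take effect in the first week of their calendar year;
  the 2009 pilot's five $50 vouchers are modelled as a $250 annual
  amount.
- Years before 2009 run pure demography: no entitlement, no
  expenditure.

## Known limitations

- No queueing or unmet-need model of the public sector; no provider
  enrollment dynamics; no disease-specific chronic compartments.
- Aggregate carry-forward balances ignore the within-band distribution
  of unspent amounts.
- The anchored fixture is a reconstruction: it reproduces the published
  trajectories within tolerance but is not the study's actual input
  set, and quantities tagged `assumed` in its provenance map carry no
  empirical warrant beyond plausibility.
- The budget-share demand form has no saturation in the entitlement, so
  very large voucher amounts buy proportionally many visits; scenario
  effects at high amounts are upper bounds.
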