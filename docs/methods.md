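# Methods

## The costing model

`spmcost` computes the annual budget a district needs in order to deliver a
mandated minimum package of health services (maternal and neonatal care,
family planning, child health, priority communicable diseases) at
politically set coverage targets. It is a *normative*, bottom-up model: it
costs what best-practice care should consume, not what facilities happen to
spend, and it is sensitive to the three local features that actually move
cost — demography, epidemiology and geography.

For each service *j* in district *i* the expected annual episode count is

    episodes_ij = N_i · t_ij · d_ij · n_j · cov_j

where `N` is the district population, `t` the target-group proportion
(births, infants under one, children 1–5, eligible couples, an age band, or
everyone), `d` the fraction of the target group presenting with the
condition, `n` the fraction of cases needing care at a medical facility
(some conditions resolve at home), and `cov` the coverage target. The
district budget is

    TotalCost_i = Σ_j episodes_ij · c_ij  +  programme overheads + DHO administration

with the blended unit cost per episode

    c_ij = c^p_j + π_j·[(1 − m_j)·c^H_ij + m_j·c^HA_ij] + π_j·r_i

`c^p`, `c^H`, `c^HA` are the unit costs of primary care, hospital care
without admission and hospital care with admission; `π` is the referral
fraction, `m` the admission fraction among referrals, and `r_i` the
district's mean referral-transport cost. Each level cost decomposes as
`c = v + s + f`: variable inputs (drugs, tests, supplies, each priced as
`unit_price × quantity × use_probability`), direct staffing (contact
minutes priced at `daily_salary / (effective_hours × 60)` per cadre) and
apportioned fixed overhead.

Two deliberate choices in the blend:

- **Transport under π.** `r_i` is a cost per *referred* patient, so it is
  weighted by π rather than charged to every episode. The configuration
  switch `referral_cost_mode: per_episode` preserves the alternative
  unconditional reading.
- **Self-referral.** A fraction σ of facility-seeking cases bypasses
  primary care (emergencies; urban populations using hospitals as first
  contact). Their path omits the primary component and the system transport
  cost: `c = (1 − σ)·standard + σ·hospital-only`.

## Overhead apportionment

Three fixed pools are costed per district:

1. **Facility pools** — each facility's operating cost, annualised capital
   and indirect staffing. Capital is annualised with the annuity factor
   `cost · r / (1 − (1+r)^−n)` (defaults: 3% discount, 20-year buildings,
   5-year equipment — conventional costing practice).
2. **Programme pools** — service-attributable public-health overheads
   (vector spraying, surveillance, case finding) that scale with population,
   entered as money per capita on the service definition.
3. **DHO administration** — the annual running cost of the District Health
   Office, allocated per capita.

Facility pools are spread over *total* projected workload — package
episodes plus non-package activity (beds filled, outpatients treated for
conditions outside the package) — so package episodes carry only their
share of fixed costs (economies of scope). A hospital pool is split between
the inpatient and outpatient streams by a cost weight (default 0.7/0.3; no
empirical split rule is available, so it is configurable) and divided by
total bed-days and visits. Health-centre pools (which fold in subordinate
sub-centres, village posts and village midwives) are divided by total
primary visit-equivalents; bedded centres' non-package bed-days enter that
stream at a configurable equivalence of 2 visits per bed-day, chosen so
that every pool is exactly recovered by its stream (`rate × total units =
pool`, verified to 1e-6 relative in the tests).

This construction is what makes sparsity expensive: holding population
fixed, a district that needs more facilities has larger pools over the same
workload, so every per-unit overhead rate — and hence every episode cost —
rises.

## Geography

Referral transport is imputed from a simple map: Euclidean distance between
every health centre and every hospital (haversine when coordinates are
lat/lon), each centre assigned to its nearest hospital with lexicographic
tie-breaking for deterministic reruns. The district rate `r_i` is the
catchment-population-weighted mean of per-centre costs
(`distance × cost_per_km × 2` for the default round trip; tariff
multipliers per centre allow costlier edges such as water crossings).
Straight lines understate real travel, so `r_i` is a floor, not an
estimate, of true transport cost.

## Sensitivity analysis

`sweep_driver` re-costs a deep copy of the district at each level of one
epidemiology/demography driver, everything else fixed. The elasticity is

    e = 100 · [(c_hi − c_lo) / (L_hi − L_lo)] / c_lo

with levels in percentage points. No closed definition of this statistic is
standard; this form was chosen because it reproduces the published
provincial sensitivity rows it can be checked against (birth rate 11.65,
infants 3.51, children 2.65, eligible couples 0.72, malnutrition 1.59,
malaria 2.00 — all to the tables' own 2-decimal rounding). The published
population-density elasticity does not follow from any per-percentage-point
formula at its printed levels (density is not a percentage), so density is
excluded as a check; in the generator, density acts on cost through the
facility-count heuristic instead.

Note that per-capita cost is *not* exactly affine in a prevalence driver:
overhead rates share fixed pools over workload, and workload moves with the
driver. With facility pools fixed at zero the response is exactly affine
and the slope equals the analytic direct cost per case — asserted to 1e-6
in the tests.

## The synthetic-district generator

Since real provincial input sets are not publicly printed, all pipelines
are exercised on synthetic districts designed to span observed
inter-provincial variation:

- **Pyramids.** `bottom_heavy` is a geometric decay (ratio 0.92 per 5-year
  band, under-5 share ≈ 11%), `balanced` a mild decay (0.97), `aging` an
  explicit shape with 15–29 and 60+ bulges (university towns and retirement
  destinations). Jitter is bounded (±3% multiplicative) so bottom-heavy
  monotonicity is preserved.
- **Demographic drivers are derived from the pyramid** — infants under one
  ≈ 21% of the 0–4 band, births ≈ 1.55 × infants, children 1–5 from the
  0–4 and 5–9 bands, eligible couples ≈ 65% of women 15–49 — then clipped
  into the configured ranges. This coupling is the point: pyramid shape
  propagates into need, so a bottom-heavy district costs strictly more per
  head than an aging one with identical facilities, the dominant observed
  mechanism of inter-district variation.
- **Disease drivers** (malnutrition 9–22.1%, TB 0.1–1.1%, malaria
  0.3–26.1%, dengue 0.2–2.5%, plus pneumonia 2–8% and diarrhoea 10–30%
  chosen as plausible under-five/all-age incidence ranges) are drawn
  uniformly from their ranges.
- **Facilities.** One health centre per ~30,000 people (the Indonesian
  puskesmas norm), scaled up at low density by `clip((109/density)^0.3, 1, 3)`;
  sites from a Matérn-style thinned point process; catchments partition the
  population exactly (largest-remainder rounding). Cost pools and
  non-package workloads are drawn at district-hospital/health-centre
  magnitudes that put overhead rates near published per-episode overheads
  (≈ USD 30–40 per bed-day, ≈ USD 10–17 per hospital visit, ≈ USD 3–5 per
  primary visit).
- **Catalogue.** The `spm_like` template defines all 32 package conditions
  with care paths, referral/admission fractions, coverage targets
  (0.75–0.95) and per-level cost targets at published magnitudes; per-seed
  jitter (±15% on variable costs, ±10% on staff minutes) varies the
  catalogue without moving its centre. For obstetric-complication services
  the target selector `births` collapses `t·d` into the per-capita birth
  rate and `facility_need` carries the complication incidence among births
  (every complication needs facility care), keeping complication rates as
  universal clinical constants rather than district inputs. Observed
  utilisation is drawn as 55–90% of each coverage target, reflecting the
  persistent shortfall of demand below normative need.

One integer seed drives a named `numpy` stream per sub-generator
(`pyramid`, `epi_disease`, `geography`, `finance`, `catchment`,
`catalogue:<service>`), so adding a generator never perturbs existing
outputs and identical seeds give byte-identical files.

What the generator does **not** emulate: real facility rosters or budgets
of any actual district, within-district heterogeneity of prices, seasonal
epidemics, road networks or travel times, and demand-side household costs.
Passing tests therefore demonstrate internal correctness and the right
directional mechanisms, not calibration to any particular province.

## Numerical and design notes

- All money is `float64` USD; file loaders apply an optional `fx_to_usd`
  rate once at load. CSV loaders parse floats in round-trip mode so
  save→load is an exact identity.
- Default problem sizes (district of 300,000 people, ~10 centres, 32
  services) make a full district costing run in milliseconds; property
  sweeps in the tests use hundreds of seeds.
- Display rounding (whole USD per episode, 2 d.p. per capita) is applied
  only in report writers; all arithmetic is full precision. Published
  episode tables rounded components independently, so some printed rows are
  off-by-one against their own components; only internally consistent rows
  are used as checks.
- Degenerate inputs: a positive pool with zero total workload in its stream
  is an error (the rate would be undefined); zero pools give zero rates; an
  empty catalogue costs only population-based overheads; a district must
  contain a hospital and centre catchments must partition its population to
  0.1%.
- Utilisation mode swaps each service's coverage target for its observed
  utilisation fraction (falling back to the target when absent), through
  the same code path.
- The CLI is one `spmcost` entry point with `cost-district`, `elasticity`,
  `synth` and `validate` subcommands.

## Known limitations

Straight-line transport is a lower bound; staffing availability (4 h/day
doctors, 6 h/day nurses/midwives, reflecting dual practice) is an
assumption, not a measurement; services for the poor and non-communicable
diseases are out of scope; overhead apportionment is single-pass (no
step-down allocation between support departments); and the model provides
no demand-side (household travel) costs.
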