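# spmcost

Bottom-up, needs-based costing of a mandated minimum health-service package
(SPM — *Standar Pelayanan Minimal*) across heterogeneous districts.

Many health systems allocate budgets to regions with proxy-based formulae.
Where public funding targets a limited package of priority services —
maternal and neonatal care, family planning, child health, tuberculosis,
malaria, dengue — an alternative is to build the budget up from local need:
cost each service's best-practice care path, multiply by the episodes the
district's own demography and epidemiology imply, and add the fixed costs
of the facility network geography requires. `spmcost` implements that
model for analysts in health-financing units who need per-district
capitation amounts, episode unit-cost tables, and sensitivity analyses of
the drivers behind them.

## The model

Annual district budget:

```
TotalCost_i = N_i · Σ_j  t_ij · d_ij · n_j · cov_j · c_ij   +  population overheads

c_ij  = c_p + π_j · [(1 − m_j) · c_H + m_j · c_HA]  +  π_j · r_i
c     = v + s + f        (at each care level)
```

- `t` target-group proportion, `d` presentation rate, `n` facility-need
  fraction, `cov` coverage target (or observed utilisation),
- `π` referral fraction, `m` admission fraction, `r_i` the district's
  catchment-weighted straight-line referral-transport cost,
- `v` drugs/supplies (`price × quantity × use-probability`), `s` direct
  staff minutes priced per cadre at realistic availability (4 h/day
  doctors, 6 h/day nurses/midwives), `f` fixed overhead apportioned from
  facility, programme and district-administration pools over total
  (package + non-package) workload.

A synthetic-district generator produces seeded, fully valid inputs —
population pyramids (bottom-heavy / balanced / aging), epidemiology within
observed inter-provincial ranges, density-driven facility rosters — so
every pipeline runs without confidential district data. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```
$ spmcost synth --seed 42 --pyramid bottom_heavy --out demo/
wrote demo/district.yaml and demo/catalogue.yaml

$ spmcost cost-district --district demo/district.yaml \
      --catalogue demo/catalogue.yaml --out demo/report.csv
synthetic-42-bottom_heavy: per-capita USD 24.23 (need)
```

The run writes three files: `report.csv` (full-precision per-service
table), `report.episodes.csv` (display-rounded episode costs), and
`report.summary.json` (totals, age/sex benefit shares, configuration and
input digests). The episode table begins:

```
                     service  direct_supplies  direct_staff  overhead  total  overhead_pct  per_capita
        Basic Antenatal Care                6             7         3     16            21        0.53
          Post-abortion Care               15            16        27     68            40        0.08
      Antepartum Haemorrhage               60            27       108    211            51        0.09
            Premature Labour              127            24        82    249            33        0.37
```

Reading the first row: an antenatal-care episode costs USD 16 — 6 in
supplies, 7 in staff time, 3 in apportioned facility overhead (21% of the
total) — and providing it to 95% of expected pregnancies costs USD 0.53
per district resident per year. Overhead shares rise steeply for
hospital-heavy conditions (it is 51% for antepartum haemorrhage), which is
why a uniform overhead mark-up misprices a mixed package. The headline
number, USD 24.23 per capita, is the annual budget this bottom-heavy
district needs to meet every coverage target; rerunning with
`--mode utilisation` prices observed demand instead and is always ≤ the
need-based figure.

Driver sensitivity, holding everything else fixed:

```
$ spmcost elasticity --district demo/district.yaml --catalogue demo/catalogue.yaml \
      --driver malnutrition --levels 9.0,13.0,22.1 --out demo/elasticity.csv
malnutrition: elasticity 0.14
```

i.e. each percentage-point rise in child malnutrition raises this
district's per-capita cost by 0.14%.

The same operations are available as library functions
(`spmcost.generate_district`, `spmcost.cost_district`,
`spmcost.sweep_driver`, …) returning pydantic models and pandas frames.

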