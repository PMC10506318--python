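# midwdemand

Scenario-based projection of the demand for midwifery care.

Health-workforce planners need to know how the consumption of midwifery
services will evolve before they can set training quotas. Historical-trend
models miss organisational change: a shift of antenatal follow-up from
gynaecologists to midwives, shorter maternity stays, or a move of postnatal
care out of the hospital all reshape demand without any demographic signal.
`midwdemand` implements the quantitative half of that problem for the Belgian
midwifery system: a transparent consumption model driven by year-anchored
parameter trajectories, with named scenarios expressed as overlays on a common
assumption set, and expert-elicitation utilities for the parameters no
administrative database records.

## The model

Midwifery activity is split into five pillars: antenatal obstetric sessions,
birth-preparation/parenting education, inpatient delivery and postnatal care,
outpatient postnatal care, and other (scenario-insensitive) activities.
Pregnancies in year *t* (`N(t)`, the projected number of hospital stays
involving childbirth) are stratified by risk level, parity, and socioeconomic
vulnerability using marginal shares combined under independence. Each stratum
receives expected per-pregnancy workloads, e.g. for antenatal sessions

    minutes = [ min(n,1)·L_first + max(n−1,0)·L_follow(risk) + 1_vuln·n·L_extra ] · (1 + u)

where `n` is the scenario's expected session count and `u` the coordination
uplift. Inpatient workload weights each hospital day of a case-mix cell
(APR-DRG × severity × age band) by day-specific intensity coefficients, with
the fractional last day pro-rata. Because pillars live in different units,
totals are aggregated as an allocation-key-weighted index: with base-year
activity shares `w_p` (prenatal 5.4%, birth preparation 2.7%, outpatient
postnatal 11.9%, hospital postpartum 48%, other 32%),

    Δ(t) = Σ_p 100 · w_p · ( C_p(t) / C_p(2016) − 1 )

is the percent change in total demand vs 2016, and each term is its exact
percentage-point decomposition. All parameter values are anchored at the
printed 5-year grid (2011–2041) and interpolated "linear until the last
anchor, then constant". Elicitation uncertainty is propagated by multiplying
every elicited anchor with independent uniform factors and rerunning the
pipeline; a per-pregnancy microsimulation provides an independent check of the
aggregation arithmetic.

## Worked example

```python
import midwdemand as md

common, scenarios, key = md.packaged_parameters()
casemix = md.packaged_casemix()
years = [2021, 2026, 2031, 2036, 2041]
indices = md.run_all(common, scenarios, casemix, key, years)
print(md.scenario_table(indices, years).round(1))
```

prints

```
          2021  2026  2031  2036  2041
scenario
baseline   5.8   6.2   5.7   7.5   8.8
A          6.6   7.9   8.9  12.3  16.2
B          7.0   8.5  10.3  15.0  20.4
C         15.6  12.8  14.6  19.6  25.1
```

Each cell is the percent change in total midwifery-care demand vs 2016.
Under current organisation (baseline), demand rises ~6% by 2026: outpatient
postnatal care grows strongly (+9.0 points at 2026, driven by ever-shorter
maternity stays pushing care home) while inpatient workload falls (−5.1
points). Scenario A adds midwife-led antenatal follow-up of low-risk
pregnancies; B shifts to midwife-led care in hospital; C moves care into the
community — fewer hospital days, many more home visits — and dominates at
every horizon. The same objects expose the full decomposition
(`indices["C"].contribution(2026, "outpatient_postnatal")` → `+23.5`).

The same run is available from the shell:

```sh
midwdemand project -o results/           # scenario table + decomposition + manifest
midwdemand sensitivity --draws 500 -o results/
midwdemand validate                      # fixture / allocation-key checks
midwdemand fixtures -o my_fixtures/      # dump editable parameter tables
```

The numbered scripts under `analysis/` run the same steps as a narrated
sequence (`01_project_demand.py`, `02_sensitivity.py`, `03_microsim_check.py`)
and write their tables under `results/`.

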