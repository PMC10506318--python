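# Methods

## Model structure

The unit of projection is a pregnancy ending in a hospital stay involving
childbirth. The annual caseload `N(t)` is an exogenous trajectory (population
forecast already embedded in its anchors); outpatient deliveries (~1% of
births) are ignored, so "pregnancies" and "stays" coincide. Every other model
quantity is a `ParameterTrajectory`: anchor values on the printed 5-year grid
2011–2041 plus an evaluation rule.

* `piecewise_linear_then_constant` — linear between *all* printed anchors,
  flat outside the anchor span. Multi-anchor encoding is deliberate: several
  observed series (e.g. the poverty share 15.3/15.9/16.0/16.4) are not
  collinear, so a two-point line would misstate intermediate years.
* `constant` — single elicited value everywhere (session lengths, group size,
  day weights).
* `step_at_anchor` — retained for regime-switch parameters; unused by the
  shipped fixtures.

Percent-valued inputs are stored as proportions internally; fixture files and
outputs use the percent scale. Years are integers; requests between grid
points use the same linear rule.

Scenarios (baseline, A, B, C) are overlays: replacement trajectories for the
parameters they change, everything else inherited from the common set.
Overlay trajectories keep the observed 2011/2016 anchors of the row they
replace, so every scenario shares the observed base year; elicited values
start at 2021. Where a projection row is parity-specific from 2021 onward but
the observed 2016 value is a single number (antenatal session counts, day-6+
postnatal services), both parity variants are anchored at that observed 2016
value — the base-year consumption must be the observed one, not a
backcast of the elicited split.

## Stratification

Risk (low vs moderate/high), parity, and vulnerability (household below the
poverty threshold) enter as marginal shares combined under independence: the
only closed completion given that no joint distribution is published. An
explicit joint distribution can be supplied per run. The poverty share is
treated as a pregnancy-level marginal — an assumption, since its source
measures the general population.

## Pillar conventions

* **Antenatal sessions.** Expected counts per pregnancy are fractional; the
  first (longer, 52 min) session is therefore entered as `min(n, 1)` and
  follow-ups as `max(n−1, 0)` at 30 min (low risk) or 35 min (moderate/high).
  Vulnerable households add 15 min to every session. The coordination uplift
  (20%, rising to 25% by 2041 in scenarios B/C) multiplies antenatal minutes
  and outpatient postnatal services only — it is defined for pre/postnatal
  consultations, not for group education or hospital wards.
* **Birth preparation.** Individual sessions at 60 min; group sessions cost
  120 min shared by 7 participants (midwife time per pregnancy = 120/7).
  The extra sessions granted to vulnerable households (1.0 from 2021, 2.0
  from 2026) are treated as individual 60-min sessions.
* **Inpatient workload.** A stay in case-mix cell (DRG, severity, age) of
  mean length L contributes `Σ_{d=1..⌊L⌋} w(d) + (L−⌊L⌋)·w(⌈L⌉)` weighted
  day-units, days past the fifth reusing the day-5 weight. Note the severity-2
  weights are non-monotone in day (day 2 > day 1), so workload increments are
  bounded by the *largest* day weight, not the first.
* **Outpatient postnatal.** Early services (before day 6): observed per-stay
  averages through 2016; from 2021 the elicited rule is one service per home
  day, `max(0, 5 − mean ALOS)` — these are claims-based home visits whose
  growth is tied to shorter stays. 2017–2020 blend the two linearly. A flat
  per-stay alternative (`early_postnatal="per_stay"`) is selectable. Day-6+
  services are parity-specific; complication (0.1) and breastfeeding (0.4)
  services are constant.
* **Other activities** (fertility, neonatology, research…) are
  scenario-insensitive. Default convention: constant *per pregnancy*, so the
  pillar follows the demographic caseload; this choice reproduces the
  reference baseline totals markedly better than freezing the pillar
  absolutely (which is available as `other_pillar="frozen"`) and is the
  natural reading of "unaffected by the organisational models". With 32% of
  base-year activity, this pillar contributes `32·(N(t)/N(2016) − 1)` points.

## Aggregation

Pillars are indexed to 2016 and weighted by the base-year allocation key
(5.4 / 2.7 / 11.9 / 48.0 / 32.0 percent). The decomposition is exact by
construction: the total is literally the sum of the per-pillar contributions.
The alternative reading — each pillar's own percent change — is emitted
alongside (`within_pillar_pct`) for comparison. Keys not summing to 100 are
renormalised with a warning.

## Case-mix defaults

The source tables print mean-length-of-stay trajectories only for four
example cells (vaginal and caesarean delivery, severity 1, ages 25–34 and
35–39). The shipped default case mix therefore puts all weight on those
printed cells — vaginal 80% / caesarean 20%, ages 75% / 25% — treating
severity 1 as representative of its delivery group. Severity 2 and 3–4
trajectories are included in the fixtures as clearly flagged synthetic
defaults (levels extrapolated from the scenario-C severity-2 values with the
severity-1 time profile) so that users can edit severity weight back into
`casemix.csv`; they carry no weight by default because invented levels would
otherwise drive the headline numbers.

## Elicitation utilities

Consensus voting uses the ≥75% plausibility threshold (reaching exactly 75%
counts as consensus, since failure is defined as *less than* 75%). Survey
responses are collapsed to a point value by the median by default — the
central-tendency rule of the original exercise is not documented, so this is
the package's choice; mean and mode (ties toward the median) are selectable.

## Uncertainty propagation

`perturb` multiplies every anchor of every elicited trajectory by independent
uniform factors in [1−s, 1+s]. Multiplicative uniform noise keeps counts and
lengths positive without truncation artefacts and is mean-preserving. Draws
use per-draw substreams spawned from one global seed, so draw *i* is
reproducible independently of the number of draws. `sensitivity_run` reruns
the full pipeline per draw and reports 2.5/50/97.5 percentiles of the total
index. The default spread (±10%) is the package's own: the source exercise
published no uncertainty ranges for elicited values.

## Microsimulation oracle

`microsim_oracle` samples stratum attributes and a case-mix cell per
pregnancy and assigns the *expected* workloads of that stratum/cell; it
checks the stratification and weighting arithmetic (law-of-large-numbers
convergence to the aggregate per-pregnancy values), not within-stratum
behavioural variation. At n = 100,000 it reproduces the aggregate index to
well under half a percentage point in seconds.

## Problem sizes and numerical choices

All headline computations are closed-form sums over 8 strata × ≤12 case-mix
cells × years; a full 4-scenario table takes well under a second. Analysis
defaults (500 sensitivity draws, 50,000–100,000 simulated pregnancies) keep
every driver in the seconds range while leaving Monte-Carlo error far below
the effects of interest. Interpolation at anchor years bypasses floating
arithmetic and returns the anchor exactly. Validation is report-based
(list of violations) rather than exception-based wherever a user can act on
the full list.

## Known limitations

* The published totals for the reference exercise embed decomposition
  conventions that cannot be fully recovered: its printed baseline-2026
  contributions do not sum to its printed total, and the birth-preparation
  contribution reported for scenario A (+5.1 points) is unreachable under the
  published 2.7% allocation weight (the pillar would have to nearly triple;
  the computable factor from the printed session counts is ≈1.5×). This
  package reproduces the baseline row and the baseline decomposition within
  ±1 point; alternative-scenario totals computed from the printed parameters
  are 3–5 points below the published ones, with the gap concentrated in
  exactly those antenatal/birth-preparation terms. The full decomposition is
  emitted so the residual is visible rather than absorbed.
* Supply-side modelling (headcounts, FTEs, densities, quotas) is out of
  scope; the output is a demand index, not a workforce gap.
* Stratum axes are combined under independence; correlations between poverty,
  parity, and risk are not represented unless a joint distribution is given.
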