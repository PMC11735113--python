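# Methods

## Scope and shape

`appcap` is a deterministic scenario calculator: no stochastic demand, no
queueing, no cost conversion. Every output is a closed-form function of the
scenario configuration and two input tables (a practice register and an
area appointment volume). The only randomness in the package lives in the
synthetic-data generator, which exists so the pipeline is testable without
any download.

## Parameters, units, defaults

| Parameter | Default | Unit | Why |
|---|---|---|---|
| `cascade.min_age` | 15 | years | the register extracts are banded at 15+, although the role targets 16+; configurable rather than guessing intent |
| `cascade.mh_prevalence` | 0.40 | fraction | share of adults with a mental-health need |
| `cascade.severity_share` | 0.70 | fraction | mild cases as a share of all cases; whether "moderate" cases should add to it is an open choice left to the config |
| `apportionment.mh_share_of_gp_appts` | 0.33 | fraction | one-in-three GP appointments involve mental health; 0.33 exactly, not 1/3, matching the stated parameter |
| `apportionment.staff_type_in_scope` | `gp_only` | — | nurses and other practice staff are out of scope as referrers |
| `annualization.weeks_per_year` | 45 | weeks | working year after leave |
| `annualization.hours_per_week` / `hours_per_day` | 37.5 / 7.5 | hours | full-time contract; a mismatch with a 5-day week warns but does not error |
| `group_cycle` | 8 + 4 weeks, 12 participants | — | group-work weeks then well-being weeks, one half-day session per week |
| `diversion.baseline_gp_visits_per_patient` | 3 | visits | the freed range is reported for {baseline, baseline+1}, i.e. {3, 4} |
| `diversion.app_sessions_per_patient` | 4 | sessions | brief intervention course length; affects patient counts, not appointment counts |
| `diversion.self_referral_fraction` | 0.10 | fraction | share of the MH appointment pool rerouted to 30-min triage |
| `n_pcns` | 41 | — | networks in the modelled area |
| `reduction_band` | (0.25, 1/3) | fractions | aggregate demand-reduction band, anchored on the 28% observed for social prescribing |

## Week templates and calibration

The exact published compositions of the three working weeks are not
available, so the shipped templates are **calibrations**:

* `standard` — 0.5 d community engagement + 0.25 d other/supervision +
  0.5 d group work, remainder as 45-min brief interventions. This is the
  unique reading that reproduces the published per-APP figure exactly:
  floor(28.125 h / 0.75 h) = 37 slots/week, × 45 weeks = 1,665. The
  published description mentions only three main activities for the
  standard week, yet 1,665 requires the half-day of group work; the
  three-activity variant is shipped as `standard_no_group` (1,890/yr)
  rather than silently resolving the discrepancy.
* `alternative_1` — adds a fixed 0.875 d triage stream (13 × 30-min slots
  /week, 585/yr) ahead of the brief remainder (28 slots, 1,260/yr).
* `alternative_2` — 0.8 d triage (12 slots, 540/yr), brief remainder 29
  slots (1,305/yr). Calibrated so that the 41-PCN aggregate, 41 × 1,305 =
  53,505, falls in the band [51,000, 55,000] around the published 53,000;
  the exact arithmetic behind 53,000 (≈ 1,293/APP) cannot be reconstructed
  and is not claimed.

## Numerical choices

* **Rounding point for slots.** Appointments are floored *weekly*, then
  multiplied by weeks (37.5 → 37 → 1,665). Flooring annually would give
  1,687 and contradict the published figure.
* **Report-time rounding.** Person and appointment counts are carried as
  reals through the cascade and rounded half-up only on report, so
  per-practice fractions never compound. WTEs round half-up to one decimal
  (8.198 → 8.2); multi-PCN headline figures get a separate two-significant-
  figure *display* value, never replacing the raw number.
* **Cycle packing.** Full (8+4-week) cycles are packed greedily, then at
  most one trailing group-only cycle; a truncated trailing cycle is never
  well-being-only. The greedy packing is provably optimal under the
  lexicographic preference (more full cycles first) and is tested against
  brute-force enumeration for 0–60-week years.
* **Participant-sessions** count attendances at group-work sessions only
  (4 cycles × 8 × 12 = 384); counting well-being weeks would give 528 and
  contradict the published count.
* **Pathway arithmetic.** "Reducing by three and four appointments" is
  operationalized as baseline k ∈ {3, 4} visits collapsing to 1, i.e.
  freed = M(k−1)/k — the only reading that yields the published 9/8 ratio
  between the low and high freed figures from a single pool M. The
  published pair (13,650, 15,280) is ~0.5% inconsistent under any single
  M; with M inferred from the self-referral figure (10 × 2,038 = 20,380)
  the suite asserts agreement at 1% and documents the drift rather than
  hiding it.
* **Apportionment period.** Appointment inputs spanning any period are
  scaled to a 365.25-day year before apportionment. The population share is
  computed on all-ages populations (the appointment data cannot be split by
  age); an area population may be supplied in the config, otherwise the
  summed register population stands in for the area.
* **Degenerate inputs.** Zero area population, zero per-APP capacity and a
  zero visit baseline raise domain errors; an over-committed week raises an
  infeasibility error listing the block hours; a `min_age` inside an age
  band raises a boundary error naming the band (banded counts cannot be
  split).

## Synthetic data: what it does and does not emulate

`synth` draws practice list sizes from a log-normal (median 7,600, log-sd
0.5; 5 practices per PCN × 41 PCNs ≈ 1.77 M people, matching the modelled
area's ~1.78 M over ~200 practices), splits them 0–14 / 15+ with an 82%
adult fraction, and draws appointment totals as Poisson counts at 5
appointments/person-year with a 50% GP share. Registers carry no event
noise (they are administrative counts); appointments do (they are events).
Seeds make every artifact byte-reproducible.

It does **not** emulate realistic age pyramids, deprivation or morbidity
gradients, seasonality, or appointment-mode mix. A green pipeline test
therefore establishes that the arithmetic is correct and stable under
sampling noise — not that the parameter defaults are right for any
particular real area.

## Determinism and provenance

Reports embed the SHA-256 of both input files and the config, the package
version and the seed, but no timestamp, so identical inputs give
byte-identical outputs. Presentation-rounded values live in clearly
separated display fields.

## Known limitations

* Freed-appointment accounting assumes one APP brief appointment replaces
  exactly one GP appointment and ignores caseload carry-over between weeks.
* The cascade is computed at PCN level (practices pooled), matching the
  source method; per-practice cascades would differ only by rounding.
* Cost-effectiveness, waiting-time dynamics and non-GP referral routes are
  out of scope by design.
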