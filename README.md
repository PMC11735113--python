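# appcap

A deterministic demand-and-capacity model for introducing **Associate
Psychological Practitioners (APPs)** — a new NHS psychological-care role —
into **Primary Care Networks (PCNs)**. Given practice list sizes and
commissioning-area appointment volumes, it computes the in-scope
mental-health population, the annual clinical capacity of one
whole-time-equivalent (WTE) APP under configurable working-week templates,
the GP appointments diverted or freed under referral-pathway scenarios, and
the WTE staffing those scenarios require, scaled across PCNs.

It is aimed at health-workforce planners and health-services researchers
who need transparent, reproducible what-if arithmetic rather than a
black-box simulation.

## The model

Everything is a small deterministic cascade:

1. **In-scope population.** Registered adults (aged ≥ `min_age`, default 15)
   per PCN, of whom a fraction *p* = 0.40 have a mental-health need, of whom
   a fraction *s* = 0.70 are in the mild-to-moderate band:
   `in_scope = adults × p × s`. A 10,000-patient adult list gives 4,000
   MH-prevalent and 2,800 in-scope patients.

2. **Appointment apportionment.** Commissioning-area GP appointment totals
   are sliced by the PCN's population share and multiplied by the fraction
   of GP appointments involving mental health (0.33):
   `M = area_GP_appts × (pcn_pop / area_pop) × 0.33`.

3. **APP capacity.** A working week (37.5 h, 7.5 h/day) is a set of activity
   blocks. The standard week fixes half a day of community engagement, a
   quarter-day of other/supervision and half a day of group work; the
   remaining 28.125 h become 45-minute brief-intervention appointments:
   `floor(28.125 / 0.75) = 37` per week, × 45 working weeks = **1,665 per
   year**. Group work runs in cycles of 8 weekly half-day sessions plus 4
   well-being weeks with 12 participants: a 45-week year packs 3 full
   cycles + 1 group-only cycle → **48 people**, 4 × 8 × 12 = **384
   participant-sessions**. Triage appointments (30 min) are a separate
   stream in the alternative week templates.

4. **Diversion.** Each brief APP appointment diverts one GP appointment.
   Patients in scope currently average *k* ∈ {3, 4} GP visits and in the
   future state see the GP once, freeing `M (k−1)/k` appointments per year;
   dividing by the 1,665 per-APP capacity gives the WTE requirement
   (half-up to one decimal: 13,650 / 1,665 → 8.2). A self-referral route
   sends 10% of *M* straight to APP triage, absorbed up to triage capacity.

## Worked example

No data files are needed — the synthetic generator emulates the register
and appointment extracts the model consumes:

```bash
appcap synth --seed 42 --n-pcns 41 --out demo
appcap run --register demo/register.csv --appointments demo/appointments.csv --out demo/out
```

`demo/out/report.csv` holds one row per PCN plus an aggregate row. For
seed 42 the first PCN and the aggregate read (rounded):

```
 pcn_id  total_population  in_scope_population  mh_appointments_year  diverted_per_app  freed_low  freed_high  wte_low  wte_high
PCN-001            39,457                9,059                32,575             1,665     21,716      24,431     13.0      15.0
    ALL         1,700,755              390,495             1,404,096            68,265    936,064   1,053,071    562.0     632.0
```

Reading PCN-001: of ~39k registered patients, ~9k are adults with
mild-to-moderate mental-health need; their GPs deliver ~32.6k
mental-health appointments a year, of which 21.7k–24.4k could be freed by
the pathway change, needing 13–15 WTE APPs; one APP diverts 1,665 of them.
The JSON report also carries the single-APP-per-PCN headline:
`diverted_appointments_all_pcns = 68,265` (display-rounded 68,000).

`appcap templates list` prints the effective hours of every week template
after remainder resolution; `appcap sweep --param cascade.mh_prevalence
--values 0.3,0.4,0.5 ...` produces a long-format sensitivity table. All
parameters live in a strict YAML scenario file (`--config`); unset fields
take the defaults above.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the default scenario, the per-APP annual
brief-intervention capacity of the standard week, the people reached by
group/well-being cycles in a 45-week year, and the participant-sessions
those cycles deliver, and writes them as JSON. It also executes a seeded
synthetic end-to-end run as a pipeline sanity check.

See `docs/methods.md` for assumptions, calibrations and limitations.
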