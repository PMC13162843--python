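# clonotrack

Longitudinal analysis of bulk TCRβ CDR3 repertoire sequencing: Simpson
clonality, negative-control-calibrated clonal expansion calling, and
per-patient clonotype trajectory tracking.

## The problem

Locoregional cancer therapies (hepatic arterial embolization, Y90
radioembolization, thermal ablation) may release tumour antigens and prime a
systemic T-cell response. Bulk sequencing of the TCRβ CDR3 region in
peripheral blood, before and after a procedure, measures this at the level
of individual T-cell clonotypes: each unique nucleotide rearrangement is a
clonotype whose clonal frequency is

```
p_i = templates_i / Σ_j templates_j      (productive rearrangements only)
```

Repertoire-wide diversity is summarised by **Simpson clonality**,

```
clonality = sqrt( Σ_i p_i² )
```

ranging from ~0 (polyclonal) to 1 (monoclonal).

Calling a clonotype "expanded" between two blood draws is the hard part:
the repertoire fluctuates biologically between draws, so per-clone
significance tests (Fisher exact, or a beta-binomial differential-abundance
model) call many false positives even on no-treatment control pairs.
`clonotrack` implements threshold criteria calibrated against such negative
controls:

* **new** — clonotype undetected at baseline with follow-up frequency
  strictly above **0.025%**;
* **increased** — clonotype detected at baseline with a strictly
  greater-than **tenfold** frequency increase and follow-up frequency
  strictly above **0.01%**.

Both comparators (Fisher exact; a beta-binomial model with overdispersion ρ
estimated from control pairs, BH-corrected) are included so the calibration
argument can be reproduced, and a `calibrate_criteria` routine re-derives
thresholds from any set of control pairs. Clonotypes found in a
pre-procedure tumour biopsy are labelled TILs (tumour-infiltrating
lymphocytes); patients without a biopsy get *unknown*, never *false*.

Intended users: computational immunologists and translational researchers
tracking repertoire dynamics around interventions, with immunoSEQ-style or
AIRR-style clonotype tables as input.

## Worked example

The synthetic-data generator emulates deep blood repertoires (heavy-tailed
clone sizes, multinomial sampling at 2×10⁵ templates) and plants known
expansion events, so the whole pipeline runs without patient data:

```python
import clonotrack as ct
from clonotrack.simulate import SimulationConfig, generate_longitudinal_cohort

cfg = SimulationConfig(n_new_events=4, n_increase_events=3, seed=7)
cohort = generate_longitudinal_cohort(cfg, n_patients=3, followup_days=(30, 90))

for tl, truth in cohort:
    clon = ct.simpson_clonality(tl.baseline)
    res = ct.call_expansions(tl.baseline, tl.followup_at(30))
    print(f"{tl.subject_id}: baseline clonality {clon.simpson_clonality:.4f}  "
          f"new={res.n_new} increased={res.n_increased} "
          f"(planted: {len(truth.planted_new)} new, {len(truth.planted_increased)} increased)")

per, stats_ = ct.summarize_expansion_by_patient([tl for tl, _ in cohort], at=30)
print(f"cohort median expanded clonotypes at 1 month: {stats_.median} "
      f"(range {stats_.minimum}-{stats_.maximum}, IQR {stats_.iqr})")

trajs = ct.build_trajectories(cohort[0][0])
persistent = ct.persistent_expansions(trajs, 30, 90)
print(f"{cohort[0][0].subject_id}: {len(persistent)} clonotypes remain expanded at 3 months,",
      f"{sum(bool(t.is_til) for t in persistent)} of them TILs")
```

Output:

```
SYN01: baseline clonality 0.1107  new=4 increased=3 (planted: 4 new, 3 increased)
SYN02: baseline clonality 0.1030  new=4 increased=3 (planted: 4 new, 3 increased)
SYN03: baseline clonality 0.1123  new=4 increased=3 (planted: 4 new, 3 increased)
cohort median expanded clonotypes at 1 month: 7.0 (range 7-7, IQR 0.0)
SYN01: 7 clonotypes remain expanded at 3 months, 1 of them TILs
```

Every planted event is recovered (new=4, increased=3 per patient) with no
false positives: at deep sequencing, multinomial noise alone never crosses
the calibrated thresholds. The baseline clonality values (~0.10–0.11) are
typical of a polyclonal blood repertoire. All seven expanded clonotypes of
patient SYN01 still meet the criteria versus baseline at day 90 because the
generator keeps planted events in place across follow-ups; the TIL count
reflects the 30% biopsy/blood overlap default.

A CLI mirrors the library (`clonotrack filter | clonality |
clonality-compare | call-expansion | calibrate | track | cohort-summary |
simulate`); see `clonotrack --help`.

## Layout

```
src/clonotrack/
  repertoire.py   clonotype tables, dialects (immunoseq/airr), filtering, frequencies
  diversity.py    Simpson dominance/clonality, Wilcoxon group comparison
  expansion.py    threshold classifier, beta-binomial + Fisher comparators, calibration
  tracking.py     timelines, trajectories, TIL labels, persistence, cohort summaries
  cohort.py       cohort metadata model + packaged fixture
  simulate.py     synthetic repertoire generator with planted ground truth
  cli.py          click CLI
docs/methods.md   model, assumptions, numerical choices, limitations
```
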