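# Methods

## Data model and conventions

A *clonotype* is an exact TCRβ nucleotide rearrangement string; this is the
identity key throughout. An amino-acid-level aggregation
(`amino_acid_view`) exists as a convenience but is never the default,
because distinct rearrangements converging on one CDR3 peptide are distinct
T-cell lineages. Abundance is the *template count* (estimated input DNA
molecules), not read count. Timepoints are integer days relative to the
procedure (day 0); negative days are pre-procedure, and the cohort module
maps the labels "1 month" and "3 months" to +30 and +90.

Non-productive rearrangements (premature stop, frameshift) are excluded
before any analysis, and the clonal-frequency denominator is the
*post-filter* total of productive templates. Whether the denominator should
be pre- or post-filter is genuinely ambiguous in common usage; post-filter
matches the immunoSEQ productive-frequency convention and is enforced
(`compute_frequencies` rejects unfiltered samples rather than silently
including non-productive templates in the denominator).

Frequencies are stored as fractions in [0, 1]. Thresholds quoted in percent
exist only at the JSON boundary (`criteria.json` uses
`new_min_freq_pct: 0.025` etc.) and are converted exactly once on parse.

## Simpson clonality

Dominance is the plain `Σ p_i²` with no unseen-species (−1) small-sample
correction, and clonality is its square root, so values are directly
comparable to immunoSEQ "Simpson clonality" outputs. For a uniform
repertoire of N clones the clonality is exactly 1/√N; the monoclonal limit
is 1.

Group comparisons use the two-tailed Wilcoxon rank-sum test: exact
enumeration when both groups have ≤ 12 observations and no ties, otherwise
the tie-corrected normal approximation (scipy's `mannwhitneyu` under the
hood). A Shapiro–Wilk p-value on the pooled values is reported alongside
for context but never selects the test — the analysis design fixes the
nonparametric test regardless of what normality testing would say on any
particular dataset. A paired (signed-rank) mode exists for
patient-matched comparisons; the independent mode is the default since
blood/biopsy comparisons across partially overlapping patient subsets are
not cleanly pairable.

## Expansion calling

For a baseline → follow-up pair of blood samples, every clonotype in the
union is classified:

* **new**: zero baseline templates AND follow-up frequency > `new_min_freq`
  (default 0.025%);
* **increased**: detected at baseline AND frequency fold change >
  `increased_min_fold` (default 10) AND follow-up frequency >
  `increased_min_freq` (default 0.01%);
* **none** otherwise.

Decisions are deliberately strict at the boundary ("above", "over"):
exactly 0.025%, exactly tenfold, exactly 0.01% do not qualify. "Undetected
at baseline" means zero sampled templates — a sequencing-depth-relative
notion, which is all the data can support. Fold changes are computed on
frequencies so unequal sequencing depths cancel; a clone absent at baseline
has an undefined fold change and is only eligible for "new". Contraction
calls are out of scope — only expansion is defined.

### Why thresholds rather than per-clone tests

Two blood draws from the same person a month apart differ by more than
multinomial sampling noise: the repertoire drifts biologically. Per-clone
significance tests treat that drift as signal. The package ships two such
comparators to make the argument quantitative:

* `fisher_exact_pair` — two-sided Fisher exact test on
  `[[x1, n1−x1], [x2, n2−x2]]`;
* `betabinom_differential_abundance` — for each clone, the two-sided
  minimum-likelihood tail probability of the follow-up count under a
  beta-binomial null centred on the pooled frequency `(x1+x2)/(n1+n2)` with
  overdispersion ρ, then Benjamini–Hochberg FDR (default q < 0.01) across
  clones.

On simulated no-treatment pairs with log-normal drift (σ = 0.5), naive
Fisher at p < 0.05 calls hundreds of "expansions" where the threshold
criteria call ~0–5; the ρ-calibrated beta-binomial sits near the threshold
criteria (both orders of magnitude below Fisher, their exact order varying
seed to seed). This ordering is asserted in the acceptance tests and is the
rationale for the threshold-based design.

`calibrate_criteria` re-derives thresholds from control pairs: candidates
are ordered from least to most stringent (lexicographically by
`new_min_freq`, then `increased_min_freq`, then fold) and the first whose
total control calls fit the false-positive budget wins, so the procedure
returns the loosest criteria the controls can support. The default grid is
new ∈ {0.005, 0.01, 0.025, 0.05}%, increased-freq ∈ {0.005, 0.01, 0.025}%,
fold ∈ {5, 10, 20}.

### Beta-binomial numerics

The pmf is computed in log space via `gammaln`/`betaln`, which is accurate
for shape parameters up to ~1e8. The two-sided tail test instead uses the
pmf *ratio* recurrence

```
pmf(j+1)/pmf(j) = (n−j)(α+j) / ((j+1)(β+n−j−1))
```

accumulated over an evaluation window of ±40 standard deviations around the
null mean and normalised within the window. Only ratios enter, so the
computation stays stable in the near-binomial regime (ρ → 0 makes α, β ~
1/ρ enormous, where direct `betaln` differences lose several digits); the
test reproduces the exact two-sided binomial test to < 1e-6 at ρ = 1e-12.
The minimum-likelihood ("minlike") two-sided definition was chosen over
tail-doubling for consistency with scipy's exact binomial and Fisher tests;
for strongly skewed nulls (large ρ with small pooled frequency) the two
definitions diverge, which is inherent, not a bug.

`estimate_dispersion` maximises the joint beta-binomial likelihood of
follow-up counts over ρ ∈ (0, 0.5) by bounded 1-D optimisation, with each
clone's mean fixed at its *baseline* frequency `x1/n1`. Using the pooled
mean here would centre each clone's null partly on the very count being
modelled and attenuates the recovered ρ by roughly half (measured on
beta-binomially simulated controls); the baseline-mean plug-in inflates ρ
only by ~1/n1, negligible at sequencing depth. Parameter recovery: true
ρ = 0.01 is recovered within a factor of 2 from ≥ 500 informative control
clones, and pure multinomial controls drive the estimate to the lower
bound (< 1e-5).

## Trajectories and TIL labelling

Expansion at every follow-up is judged against the same pre-procedure
baseline, never the previous follow-up, so "remains expanded at day 90"
means "still meets the criteria versus baseline", and a clone first
qualifying only at the later timepoint is expanded there but not
*persistent*. A TIL is any clonotype with ≥ 1 productive template in the
pre-procedure biopsy; biopsy clonotypes never join the blood union — they
only label it. Patients without a biopsy have TIL status `None` (unknown),
which downstream summaries propagate as nulls rather than zeros. Cohort
summaries at a timepoint cover only patients who have that timepoint
(skipped patients warn), and the spread statistics are median, min–max
range, and IQR (Q3 − Q1, linear interpolation).

## Synthetic data generator

The generator's role is to emulate the features of deep bulk TCRseq that
the pipeline's behaviour depends on, with exact ground truth:

* **Clone-size law** — default `power_law` with clone-size exponent
  α = 2.0, realised as Zipf rank-frequency weights `f_i ∝ i^(−1/(α−1))`
  (α = 2 → f_i ∝ 1/i) with mild log-normal rank jitter (σ = 0.1) so seeds
  differ. At the default 5×10⁴ clones this gives baseline blood Simpson
  clonality ≈ 0.10–0.12, inside the 0.004–0.22 range typical of deep blood
  surveys (asserted by a calibration test). A `log_normal` weight law is
  available as an alternative.
* **Sequencing noise** — multinomial at fixed depth (default 2×10⁵
  templates, "deep level"), so totals are exact and frequencies comparable;
  Poisson thinking is used only in analytic detection-rate arguments.
* **Biological drift** — i.i.d. log-normal(0, σ) multipliers on true
  frequencies, renormalised; the mechanism that generates false positives
  in naive per-clone testing. σ = 0.5 makes a realistic-looking
  "no treatment" pair for the calibration study.
* **Planted events** — "new" clones are truly absent from the baseline
  repertoire (not merely unsampled) with follow-up frequency drawn from
  0.05–0.2%; "increased" clones are drawn from those with baseline
  frequency in 0.005–0.05% (comfortably detectable at default depth) and
  multiplied by a fold from U(10, 100). The follow-up weight vector is
  rescaled analytically so planted frequencies and folds are *exact* after
  renormalisation. Planted sets are disjoint by construction.
* **Biopsy** — shares a configurable fraction (default 0.3) of baseline
  blood clones plus the same fraction of planted-new clones
  (tumour-resident clones may predate blood detectability), sampled at its
  own depth (default 5×10⁴).

Per-patient randomness is spawned from one `SeedSequence`, so identical
config + seed reproduces output files bit-exactly.

What the generator does **not** model: V(D)J sequence realism
(rearrangement strings are synthetic identifiers), antigen specificity or
HLA, clone-clone covariance in drift, PCR/amplification bias, or
depth variation between samples. Passing recovery tests therefore shows the
pipeline is correct under idealised sampling plus drift — not that real
repertoires satisfy these criteria with the same sensitivity.

## Problem sizes in the test suite

Recovery and negative-control tests run at the generator defaults
(5×10⁴ clones, depth 2×10⁵; 100 seeded replicates for the
sensitivity/false-positive batch). Auxiliary property tests (drift
monotonicity of naive Fisher calls) use smaller repertoires
(500–5,000 clones) since the property is scale-free; the chosen sizes keep
the full suite around a minute.

## Known limitations

* The beta-binomial comparator is this package's own parameterisation of a
  differential-abundance null (pooled-mean centre, control-estimated ρ,
  BH at q < 0.01); published beta-binomial repertoire tools differ in
  fitting details, and equivalence with any specific one is not claimed —
  its role here is the calibration argument, not clone-level inference.
* Thresholds calibrated on two control pairs (as in small prospective
  designs) carry the controls' sampling variability; `calibrate_criteria`
  makes the dependence explicit but cannot remove it.
* The cohort summary encodes deliberately asymmetric conventions (median
  age over all rows including controls; percent male over treated rows
  only) to reproduce its source table's printed statistics exactly; see
  `clonotrack/cohort.py`.
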