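# Methods

This note documents the models, the numerical choices, the synthetic-data
generator and the known limitations of `mirhars`.

## Model and procedure

The pipeline treats each blood sample as one observation of 667 miRNA
threshold-cycle (CT) values, split over two 384-well low-density-array
card types (A, B); one (sample, card type) pair is one *card run*, the
normalization unit.  The outcome of interest is the HARS severity grade
(H0 unexposed reference, H1-2 mild, H2-3 severe) that develops weeks
after exposure; the predictors are normalized miRNA expression values
measured on days 1–2.

**Detection.**  A well is detected iff its CT is present and CT ≤ `ct_max`
(default 30, inclusive) — the upper limit of the assay's linear-dynamic
range.  `Undetermined` reactions and censored wells are missing data, not
measurements.

**Normalization.**  Per card run, the median CT of the *detected* wells is
subtracted from every well (ΔCT with the card median as reference).
Median centering is exactly invariant to per-card level shifts and does
not depend on any single housekeeping species.  Whether the original
protocol's median covered all wells or detected wells only is not
knowable from its description; detected-only is used here because
censored values are not measurements, and the choice only matters for
heavily censored cards.  Even-count medians are the mean of the two
central values.  A card run with zero detected wells is an error, not a
silent skip.

**Fold change.**  `log2 FC = mean ΔCT(reference) − mean ΔCT(case)` over
detected values (complete case), `FC = 2^log2FC`; lower CT means more
transcript, so case ΔCT above the reference reads as down-regulation
(FC < 1).  `FC ≥ 2` or `≤ 0.5` counts as differential (`fc_min = 2`).
An optional censor-at-limit imputation (`median_normalize(...,
impute_at=30)`) exists for sensitivity analyses and is off by default; no
imputation rule is part of the core method.

**Screen (Stage I).**  Per contrast, a miRNA must be detected in ≥
`det_frac` (default 0.75, inclusive) of the samples of *every* group×day
cell entering the contrast.  The protocol states the detection rule two
slightly different ways (per HARS group; per day and per group); the
cell-wise reading used here is the stricter, internally consistent one
and is enforced uniformly.  Candidates then need the fold-change gate
AND (t-test p < α OR concordance ≥ `conc_min`) — the disjunction is
deliberate and is encoded exactly; validation later uses the
conjunction of all criteria.  Day-1 and day-2 case groups are pooled
into a `merged` day set when their fold changes share a non-flat
direction ("analyzed together", read literally as pooling samples, not
averaging per-day statistics).

**Statistics.**  The t-test is the classical pooled-variance (Student)
two-sample test, two-sided, df = n₁+n₂−2; Welch is available through
scipy for sensitivity analyses but is not the default, matching the
protocol's wording.  Degenerate inputs (all values identical) return
p = 1 by convention, flagged.

The logistic model is univariate and unconditional: class (case = 1 vs
H0 = 0) on normalized CT.  The fit is Newton/IRLS with step-halving,
converging when the log-likelihood changes by < 1e-8, at most 100
iterations; OR = exp(β₁), 95 % CI = exp(β₁ ± 1.959964·SE), Wald p from
β₁²/SE² against χ²(1).  A constant predictor short-circuits to
β₁ = 0, OR = 1, concordance 0.5, p = 1.

**Concordance** is implemented as the c-statistic (Mann–Whitney midranks:
pair counting with half-credit ties), invariant under strictly monotone
transforms of the score.  The protocol's prose gloss ("% of samples
correctly assigned") sounds like classification accuracy, but
"concordance" is the standard name of the c-statistic in
logistic-regression output of the statistical package used there, so the
c-statistic is the implementation; accuracy-at-a-cut can be computed from
the same scores if wanted.

**Complete separation.**  Declared either by the exact ordering test
(max of one class strictly below the min of the other — a cross-class tie
breaks it) or, during IRLS, by |β₁| escaping past 15 (quasi-separation;
the MLE does not exist).  Separated fits report no Wald quantities; the
p-value comes from a frequency-distribution comparison.  The exact
construction of that comparison is not described in the protocol; this
package dichotomizes the predictor at the pooled median (> median vs ≤)
and applies a Pearson χ² (1 df, no continuity correction) to the 2×2
class×side table, with p = 1 for degenerate tables.  The split rule is an
explicit argument so alternatives can be swapped in.  For ordering-test
separation the concordance is exactly 1; for the rare quasi-separated
case with a boundary tie the honest pair-counting value (just below 1)
is reported rather than forcing 1.

**Validation (Stage II)** re-tests every screen-passing candidate on a
disjoint sample set (disjointness is asserted): same direction as Stage
I AND t-test p < α AND |log2FC| ≥ 1 AND concordance ≥ 0.75.  Contrasts
with no Stage-II case samples are *not validatable*; those candidates
keep Stage-I-only status and never enter a validation Bonferroni family.

**Multiple testing.**  Bonferroni with strict `p < α/m`.  The family size
m counts distinct miRNAs in the set a stage's summary figure would show:
the validated set per contrast for validated stages (e.g. 15 validated
candidates → 0.05/15 ≈ 0.0033), the screen-passing set for a contrast
that has no validation arm (e.g. 20 → 0.0025), and the validated set for
the combined Stage I+II analysis.  No correction at the screen itself.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `ct_max` | 30 | cycles | linear-dynamic-range limit (inclusive) |
| `det_frac` | 0.75 | fraction | per-cell detection requirement (inclusive) |
| `fc_min` | 2.0 | ratio | differential-expression bound (≥2 / ≤0.5) |
| `alpha` | 0.05 | — | nominal significance level |
| `conc_min` | 0.75 | — | concordance gate |
| `min_rin` | 7.3 | RIN | sample QC (qRT-PCR bound; 7.5 is the microarray bound) |
| `min_a260_280` | 2.0 | ratio | sample QC |

## Synthetic-data generator

The generator emulates the reference study conditions: the 49-sample
two-stage grid (Stage I: H0 n=5, H1-2 n=4+4, H2-3 n=5+5; Stage II: H0
n=11, H1-2 n=0, H2-3 n=7+8) over 17 animals (51 draws would be complete;
two are missing, matching the design), 667 miRNAs split over cards A/B,
per-miRNA baselines uniform on 18–29 cycles, per-card-run shifts
N(0, 1.0 cycles), well noise N(0, 0.5 cycles), and deterministic
right-censoring at CT 30 (an optional stochastic mode censors with
probability rising smoothly over the last ~3 cycles).  QC metrics are
drawn to match the reported distribution (RIN mean 8.6, sd 0.6, range
7.3–9.5).

Planted effects are additive on the CT scale (−log2fc cycles on case
samples of the matching grade and day pattern), which makes the
ΔΔCT→FC mapping exact in the noise-free limit.  Planted markers draw
their baselines from 19–24 cycles unless pinned explicitly: a marker that
is to be quantifiable in ≥75 % of samples cannot, physically, live at the
censoring boundary, and the study's validated markers were by
construction quantifiable.  Null miRNAs span the full range and are
censored realistically.

The default planted panel mirrors the published candidate composition:
for the mild contrast nine day-1-only, two day-2-only and nine sustained
effects (mostly 2–4-fold up, one down); for the severe contrast thirteen
day-2-only 2–5-fold down effects and two sustained ones including a
single 10-fold down marker.  On miniature panels the effect list is
subsampled evenly.

What the generator does **not** emulate: amplification-efficiency
differences between assays, within-animal correlation across days
(samples from the same animal on days 1 and 2 are independent draws, as
the analysis itself assumes — a documented limitation of both), miRNA
co-expression structure, and grade-correlated global shifts.  Passing
recovery tests therefore demonstrate that the funnel recovers marginal
planted effects at the design's sample sizes and noise level — not that
real blood miRNAs meet the model's assumptions.

**Miniature-panel caveat.**  When a large fraction of a small panel
carries planted effects (e.g. the 33-effect default panel on a 100-miRNA
panel: ~35 % of species), the planted shifts contaminate the per-card
median and attenuate every estimated fold change.  At the full 667-miRNA
panel contamination is ~5 % and negligible.  Monte-Carlo experiments
plant a single marker per replicate for this reason.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on panels of 20–60 miRNAs; one I/O round-trip
uses the full 667.  The Monte-Carlo experiments use 100-miRNA panels
(scaled down from 667, which leaves the per-card median well estimated)
with 100 replicates for the 10-fold-marker power estimate, 30 for the
sub-threshold effect and 20 under the global null.  These sizes were
chosen so the estimates are stable at the granularity of the claims made
about them (power near 1, rates near 0).

## Other design choices

* Long ("tidy") TSV is the canonical CT format; vendor plate exports are
  out of scope.  `Undetermined` (case-insensitive) and empty cells both
  mean missing, since both occur in qPCR exports.
* Missing QC metrics exclude a sample by default (conservative for a
  screening design); configurable.
* Interaction-table columns are mapped by name through a small config
  rather than hard-coding one database dialect; species filtering is by
  taxon id (default human, 9606).  Duplicate (miRNA, gene) pairs keep the
  most negative cumulative context++ score — the conservative
  "strongest predicted repression" reading, since no dedup rule is part
  of the protocol.  Mapping family-level database identifiers onto
  individual miRNA names is left to the column-mapping layer.
* The eligibility-funnel report counts, in order: measured → detected in
  ≥1 screening sample → per-cell ≥75 % for ≥1 contrast → screen-passing →
  validated → Bonferroni survivors; each step filters the previous one's
  survivors, so the counts are monotone by construction.
* Candidate tables render fold changes at one decimal and other floats at
  four, matching the field's summary-table style; `NA` marks undefined
  quantities (e.g. Wald fields of separated fits).

## Limitations

* Firth-penalized and exact logistic regression are out of scope; the
  separation fallback is the method's own answer to divergent MLEs.
* No mixed-effects handling of repeated measures per animal.
* The funnel's absolute counts on synthetic data depend on the generator's
  noise model and are not comparable to any particular real dataset.
* Recovery of effects placed exactly at the 2-fold gate is ~50 % by
  construction (the estimate straddles the threshold); only effects
  clearly beyond the gate are reliably recovered, and the two-stage
  conjunction roughly squares any single-stage miss rate.
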