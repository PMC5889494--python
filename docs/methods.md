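# Methods

## The screening model

`sage-screen` implements a two-stage computerized adaptive diagnostic
screener of the kind used for broad-based behavioral-health intake. An
*instrument* is a declarative JSON document; the engine interprets it and
contains no clinical logic of its own.

1. **Screener stage.** Every respondent answers a fixed screener block
   (65 items over 13 diagnostic categories in the packaged fixture). Most
   screener items are 5-level frequency ratings (never / rarely / sometimes /
   often / always); a few categories use yes/no screeners (lifetime panic
   attack, past-30-day substance use, four trauma-exposure questions) or a
   day count (days drinking alcohol in the last 30 days). The screener
   itself contains one branching mechanism: the four PTSD symptom screeners
   are gated behind the trauma-exposure questions and are skipped when all
   four are "no".
2. **Screen-in.** When the screener completes, each module's threshold rule
   (a monotone any-of / all-of / at-least-k combination of per-item
   comparisons) is evaluated. Screen-in thresholds are deliberately
   *sensitive* — the fixture default is "at least sometimes" (mirrored to
   "at most sometimes" for reverse-scored items), with "I felt sad" raised
   to "at least often" because at "sometimes" that single item dominated
   inconsistent screen-ins.
3. **Follow-up stage.** Screened-in modules present their follow-up
   sections in instrument order, each anchored by a lead prompt ("During the
   time(s) when I felt anxious…") that ties follow-up symptoms to the
   screener episode. Concurrency windows (e.g. the 2-week window for a major
   depressive episode) are therefore carried as metadata
   (`window_days`), not enforced by date arithmetic — the anchoring *is* the
   instrument's concurrency mechanism.
4. **Scoring.** Responses map to binary criterion endorsements: forward
   Likert items endorse at often/always, reverse-scored items at
   never/rarely, yes/no items on yes, day counts at a documented per-item
   cut (alcohol: ≥ 5 days of 30). A criterion is endorsed when any mapped
   item endorses. A diagnosis rule fires when at least `m` of its `n`
   criteria are endorsed and, where a cardinal subset is declared, at least
   one cardinal criterion is endorsed (e.g. 5 of 9 depression criteria, one
   of which must be depressed mood or anhedonia). Because endorsement
   requires "often" while screen-in requires only "sometimes", diagnosis is
   strictly more specific than screening.
5. **Report.** The differential report lists every rule satisfied (episodes
   flagged as such), per-module screen status, incomplete modules (partial
   data is reported, never silently scored), and the full per-item frequency
   inventory as a severity signal. A rescreen form — the deduplicated Likert
   items behind the included diagnoses — supports focused interval
   monitoring.

## The packaged fixture

The fixture reproduces the published *structure* of the instrument it
models: 65 screener items, 13 categories, a 28-disorder catalog, the six
published depression screener items verbatim (two reverse-coded), four
yes/no trauma screeners, and the categorical/count screeners noted above.
The remaining item texts are authored from DSM-5 symptom labels in the same
style rules (single concept, no idioms, ≤ grade-5 reading level) and are
**non-normative**: the original item pool is not published. Likewise the
non-depression screen-in thresholds and the `at-least-k` parameters of the
diagnosis rules beyond depression are declared fixture assumptions, chosen
to respect two structural constraints:

* *sensitive screen, specific diagnosis* — screen-in cuts sit one frequency
  level below endorsement cuts;
* *screen/diagnose coherence* — every diagnosis rule's cardinal criteria map
  only to screener items, so any respondent who meets a diagnosis from
  follow-ups would necessarily have screened in. For rules without a natural
  DSM cardinal symptom (ADHD, the substance-use rules) this adds a fixture
  cardinal (attention/hyperactivity core symptoms; a recurrent-use criterion
  mapped to the use screener). This is an instrument-design choice, not a
  DSM requirement.

The three current-episode rules (major depressive, manic, hypomanic) are
evaluable and reported in the differential but are not catalog entries; the
catalog lists the 28 *disorders* the instrument covers. Diagnoses requiring
information the instrument does not collect (bipolar composition from
episode history, schizophrenia duration criteria, exclusion clauses such as
"not better explained by…") carry that caveat in their rule `notes` and are
never machine-evaluated beyond their symptom counts.

## Reliability statistics

* **ICC(A,1)** — single-measure, two-way mixed model, absolute agreement:
  `ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` with k = 2
  occasions. Absolute agreement is the right target because the "rater" is
  the same respondent at test and retest. The 95% CI is the McGraw & Wong
  F-based interval with Satterthwaite degrees of freedom (cross-checked
  against `pingouin`); the p-value is the standard upper-tail F test of
  H0: ICC = 0 (`F = MSR/MSE`). The estimate is reported unclipped — the raw
  ratio can undershoot −1 in tiny samples; banding clips to [−1, 1].
  Constant data, or zero error *and* occasion variance with zero subject
  variance, yields a `not_analyzable` row rather than an exception. Zero
  error variance with a nonzero occasion shift is handled exactly (perfect
  consistency is *not* perfect absolute agreement).
* **Cohen's kappa** — `κ = (p_o − p_e)/(1 − p_e)` for the yes/no screeners,
  with a two-sided large-sample normal p-value using the Fleiss null
  standard error. A table is `not_analyzable` when an occasion column is
  constant **or** when at most one respondent ever gives a non-modal
  response. The second clause encodes the low-base-rate degeneracy observed
  in practice: with a single stable endorser the 2×2 table has empty cells
  and near-constant margins, and although the kappa formula technically
  returns 1 there, the coefficient is meaningless and is reported as not
  analyzable.
* **Bootstrap CIs** — percentile method, respondent-level resampling,
  B = 2000 by default, seeded. Resamples degenerate under the same rule as
  the headline kappa are skipped and counted; if more than half are
  degenerate the interval is reported unavailable (the behaviour seen for a
  very-low-prevalence trauma screener).
* **Transforms** — a log transform `x ↦ ln(x − min_possible + 1)` is applied
  before the ICC where a module declares it (the agoraphobia summary is
  strongly floor-heavy/right-skewed); `min_possible` is the scale floor so
  floor scores map to 0.
* **Bands** — fair below .60, good from .60 up to the high cut, excellent at
  or above it; the high cut defaults to .75 with .80 selectable, reflecting
  the two conventions in the reliability-interpretation literature.
* **Reliability table** — 18 rows in presentation order: summary-score ICCs
  for the eight pure-Likert modules (hallucination and delusion sub-scales
  for the psychotic module), an ICC for the alcohol day count, and kappas
  for panic, each of the four trauma-exposure items, cannabis, and other
  substances. Only always-administered (ungated) categorical screeners get
  kappa rows.
* **Diagnostics** — `screening_consistency` counts screen-ins at
  both/one/neither occasion per module and identifies items solely
  responsible for single-occasion screen-ins (the analysis that motivated
  raising the "I felt sad" cut); `flag_overendorsed` flags items whose
  endorsement rate strictly exceeds 15% in a sample, the expert-review
  trigger used during threshold calibration.

## The simulator

Two layers, both seeded and reproducible:

* **Session level.** A respondent profile holds a latent severity
  θ ∈ [0, 1] per module (population priors: Beta(1, 4) nonclinical,
  Beta(2, 2) clinical — a declared modeling convenience, not a fitted
  model). Likert levels are drawn by fixed cut-points (0.2, 0.4, 0.6, 0.8)
  on θ plus Normal noise with SD 0.35·√(θ(1−θ)); the vanishing noise at the
  extremes makes θ = 0 exactly an all-never respondent and θ = 1 a ceiling
  respondent. Yes/no items are Bernoulli in the latent, day counts Binomial.
  No claim is made that this matches real response distributions; it exists
  so administration and scoring are testable end-to-end with known truth.
* **Study level.** Paired scores with an exact absolute-agreement ICC come
  from `y_ij = b_i + e_ij`, `b ~ N(0, ρ)`, `e ~ N(0, 1−ρ)` (an optional
  occasion shift stresses the absolute-agreement/consistency distinction).
  Paired binary screeners come from the exchangeable 2×2 joint with marginal
  prevalence p and agreement κ, with feasibility checked.
  `simulate_study` builds a full paired study: module summary scores are
  generated from the exact-ICC latent model, pushed through a monotone map
  to the integer summary range (a floor-heavy log-normal-style map for the
  skewed agoraphobia module, a probability-integral transform elsewhere,
  a Binomial quantile map for drinking days), and distributed
  deterministically across items so the item-level sum reproduces the
  target summary exactly. Item-level response patterns are therefore
  synthetic and carry no signal — only summaries do — and discretization
  attenuates the realized ICC slightly below its generating value. Every
  simulated study carries its generating parameters in a `truth` ledger.

Default study conditions are n = 42 paired respondents (the size of the
validation retest sample this package models), with per-module generating
values set to the published coefficients.

## Problem sizes and numerical choices

Test-suite simulations use 300–500 replicates for parameter recovery at
n = 42, 150 replicates × B = 1000 for bootstrap-coverage calibration, and
10,000+ random response vectors for the screen/diagnose-coherence property;
the acceptance script uses 300 replicates × B = 2000 for the coverage
target. All diagnosis rules keep n ≤ 12 criteria so exhaustive enumeration
(≤ 4096 vectors) is the standing oracle for the rule engine. Ties and
boundaries: over-endorsement flags use a strict > 15% comparison; banding
boundaries are closed on the left (.60 is good); Likert atoms use ≥/≤
comparisons so screen-in is monotone in item responses by construction.

## Known limitations

* Fixture item texts, non-depression thresholds, and follow-up pool sizes
  are authored assumptions; passing tests demonstrate engine correctness
  and statistical calibration under the declared generators, not clinical
  validity of the fixture content.
* The simulator's item-level patterns are not realistic response data;
  analyses that depend on item covariance within a module (beyond the
  summary) should not be run against it.
* Exclusion criteria, duration requirements, and past-episode composition
  are documentation-only (`notes`), by design.
* Kappa p-values use the large-sample normal approximation, which is rough
  below n ≈ 20; the bootstrap CI is the preferred uncertainty statement at
  small n.
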