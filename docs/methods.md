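# Methods

This note documents the models and procedures implemented in `handscreen`,
the design decisions behind them, and what the synthetic-data experiments
do and do not demonstrate.

## The screening instrument

The International HIV Dementia Scale (IHDS) has three subtests — motor
speed (finger tapping), psychomotor speed (Luria hand sequence) and a
four-word delayed recall — each scored 0–4 in half-point steps; the total
is their sum, 0–12, lower is worse. The package validates every IHDS value
against the half-point grid. Half points are accepted on all three
subtests: clinical datasets contain half-point totals without recording
which subtest produced them, and permissive validation avoids rejecting
real data.

Screening strata split the total at 10 and 11: *poor* (≤ 10), *average*
(10.5–11), *high* (11.5–12). The screening recommendation is a function of
the total and a complaints flag only: ≤ 10 → evaluate without delay;
10.5–11 → evaluate; > 11 with active cognitive complaints → evaluate;
> 11 without complaints → rescreen in six months. The recommendation is
monotone in the score (lowering a score never relaxes the action), which
the test suite checks over the whole grid.

## Operational diagnostic rules

Classification into NCN / ANI / MND / HAD uses per-test Z-scores
(demographically corrected, supplied as inputs) and a 22-item yes/no
questionnaire with a 9-item key subset:

* a test is **failed** at Z ≤ −1 and **severely failed** at Z ≤ −2, both
  thresholds inclusive and configurable;
* **HAND** requires ≥ 2 failed tests assignable to ≥ 2 *distinct*
  cognitive domains. Tests carry one or two domain tags; the requirement
  is a matching (a system of distinct representatives), so two failed
  tests sharing one identical single domain never qualify. With exactly
  two representatives required, an exhaustive pairwise scan is an exact
  matching test, and the implementation is verified against a brute-force
  subset/assignment enumerator on random profiles;
* **HAD** applies the same rule restricted to severely failed tests. No
  symptom criterion is imposed for HAD: the operational severity rule is
  self-contained, and advanced cases may be unaware of their own decline;
* non-HAD HAND splits into **MND** if *any* key item is endorsed
  (any-yes, the minimal reading of "depending on the answers given in the
  key questions"; the key subset is configuration), otherwise **ANI**.

The auxiliary "logical thinking" domain (LPS-UT3) is carried on profiles
for test-interpretation purposes but never counts toward the two-domain
requirement. Because the severe threshold is at or below the failure
threshold, HAD ⇒ HAND structurally; the classifier is also monotone in
severity: lowering any single Z-score never yields a less severe label
(property-tested).

## Prevalence estimation

The design is two-phase verification sampling: screen N participants,
stratify by screen score, fully evaluate m_i of the n_i in stratum i.
With e_i diagnosed cases among the m_i evaluated,

    adjusted prevalence = (1/N) Σ_i e_i n_i / m_i .

Each verified case stands for n_i/m_i screened participants; the estimator
reduces to the crude proportion when every stratum is fully verified and
is validated against a replicate-expansion oracle to 1e-12. It is computed
per subtype and summed for overall HAND; controls never enter it.

The point estimator carries no variance theory in the original analysis; a
percentile bootstrap (resampling the evaluated diagnoses within stratum,
default 2,000 draws, seed-controlled) is provided as a clearly labelled
extension.

Printed percentages use half-up rounding (10.2% of 480 prints as 10%), the
convention of clinical report tables; full precision is retained
internally.

## Screen accuracy

Positivity is *score ≤ cutoff* throughout — forced by the recommendation
that low scorers be evaluated, and by the fact that the maximal cutoff
makes everyone screen-positive (sensitivity 100%, specificity 0%). The ROC
curve sweeps the observed half-point cutoffs; AUC is the trapezoidal area,
which for this construction equals the tie-corrected Mann–Whitney
statistic (asserted to 1e-12 against an independent rank-based oracle and
scikit-learn). The optimal cutoff maximises Youden's
J = sensitivity + specificity − 1, ties breaking toward the lower cutoff
(fewer screen-positives). Undefined metrics (empty margins) are reported
as missing, never as silent zeros.

Screen-vs-assessment agreement on a 2×2 table uses the phi coefficient,
which is invariant under transposition — so the orientation of the two
discordant cells is immaterial.

Evaluation pools the HIV-positive evaluations with the controls, since
controls underwent the identical assessment; the agreement analysis is
restricted to the HIV-positive evaluations.

## Demographically adjusted T-scores

Regression-based norming in the Heaton/Rourke tradition:

1. **Raw → scaled:** each distinct raw total maps through its empirical
   mid-rank quantile to a standard-normal deviate, rescaled to mean 10 /
   SD 3, rounded half-up to an integer and clipped. The default clip range
   is (1, 19) — the standard span for mean-10/SD-3 scaled scores; a
   narrower (1, 12) range is available by configuration. Ties share a
   scaled score, so the mapping is monotone by construction.
2. **Scaled ~ demographics:** OLS of scaled on age, education and their
   interaction. "Residual-weighted prediction" is read as plain OLS fitted
   values (projection residuals are exactly what OLS orthogonalises).
   Predictors are centred at reference means before forming the
   interaction — purely for numerical conditioning; predictions are
   identical either way. Residual SD uses denominator n − 4.
3. **T = 50 + 10 (scaled − predicted) / residual SD**, impairment at
   T ≤ 40 (one residual SD below demographic expectation).

The reference sample in the pipeline is all screened HIV-positive totals
(the largest sample with complete demographics). Exported lookup tables
give, per age × education cell (band midpoints), the highest scaled score
whose T is ≤ 40; by construction the threshold flips to unimpaired one
scaled point higher, and a wider residual SD can only lower thresholds.

On demographically balanced reference data, mean T is 50 by construction
(training residuals have mean zero) and SD ≈ 10; both are simulation-
tested at n = 5,000. On synthetic cohorts, screening at T ≤ 40 operates
between the raw-cutoff-10 and raw-cutoff-11 points on both sensitivity and
specificity.

## The synthetic cohort generator

The generator emulates the structure of the Berlin study so every
downstream stage is testable without the original records. Defaults are
the study conditions: 480 screened HIV-positive participants, strata cut
at 10/11, 30 evaluated per stratum, 30 HIV-negative controls, latent
class mixture 57/20/17/6% over NCN/ANI/MND/HAD, 10% of controls ANI-like.

Per participant:

* **Demographics.** Age ~ discretised normal (median 43, IQR 35–51),
  education ~ discretised normal (median 15, IQR 13–17), clipped to
  [19, 80] and [8, 25] — reproducing the reported location and spread
  without inventing shape claims.
* **IHDS.** total = 12 − effect(class) + N(0, σ_IHDS), snapped to the
  half-point grid and clipped to [0, 12]. Class effects (NCN 0, ANI 0.5,
  MND 1.4, HAD 3.0) and σ_IHDS = 0.5 were calibrated once, by desk
  calculation, to the published stratum shares (≈ 10/18/72%) and group
  mean totals; the coupling between screen score and diagnosis class is a
  modelling choice, not an observed joint distribution. The total's
  decrement from the ceiling is spread over the three subtests by
  largest-remainder apportionment proportional to the observed
  poor-group-vs-control subtest deficits (0.70 : 1.17 : 0.68), capped at
  4 points per subtest.
* **Z-profile.** Impaired classes draw 2 affected domains uniformly from
  the eight Frascati domains (2 is the minimum satisfying the two-domain
  rule — the most conservative case for classifier testing); every
  battery test touching an affected domain has mean shifted by the class
  displacement (ANI/MND −1.3, HAD −2.2 SD), and all tests get N(0, σ_Z)
  jitter. σ_Z defaults to 0.1: the class shifts already encode
  between-subject severity, and the small jitter makes generated profiles
  class-prototypical so that the latent label is recoverable — which is
  what parameter-recovery testing of the pipeline requires. Real
  neuropsychological data have far larger within-class dispersion; see
  the caveats below.
* **Questionnaire.** Each of the nine key items is Bernoulli with a
  class-specific rate (NCN/ANI 0.05, MND 0.6, HAD 0.8); the 13 non-key
  items use a background rate of 0.2 (they never enter classification).
  Note that with nine independent key items at rate 0.05, ≈ 37% of latent
  ANI cases endorse at least one key item and are classified MND by the
  any-yes rule — an intended consequence of the operational definitions,
  not a bug.
* **Clinical covariates** (months since diagnosis, CD4 counts, ART
  status) are stratum-shifted lognormals/Bernoullis matched to the
  reported medians. They are carried for schema realism and consumed by
  no computation.

Generation is deterministic given the seed; the verification subsample
uses an independent derived stream, so the screened population is
unchanged by resampling decisions. The strict sampling contract (error
when a stratum is smaller than the request) is relaxed inside the
pipeline, which takes the whole stratum instead: across many seeds the
poor stratum occasionally (< 1% of seeds) falls just short of 30, and the
weighted estimator handles unequal verification fractions by design.

## What the simulations show — and what they do not

The property suite demonstrates *internal validity*: the classifier
equals an exhaustive oracle; the estimator equals replicate expansion;
the mean pipeline estimate over 200 seeds is within 3 SE of the generated
43% prevalence; AUC equals the rank statistic. Because generated profiles
are class-prototypical (small σ_Z), HAND-status recovery is nearly
perfect, which is precisely what makes unbiasedness of the *estimator*
testable in isolation. None of this demonstrates diagnostic accuracy on
real patients, where within-class variability, practice effects,
depression and education gradients blur every boundary: accuracy numbers
computed on synthetic cohorts (e.g. AUC ≈ 0.94 at the defaults) are
optimistic relative to the ≈ 0.84 observed in the field, exactly because
the generator's class separation is idealised.

## Problem sizes

Default experiments run at the study scale: 480 screened + 30 controls,
120 evaluations, 2,000 bootstrap draws. The recovery study uses 200
seeded replicates; oracle comparisons use 1,000 random instances each.
The full test suite runs in well under a minute on one CPU.

## Known limitations

* The key-item subset of the questionnaire is configuration (default
  items 1–9); the published instrument does not number its key items.
* The raw-task → subtest scoring of the screen (tap counts, word lists)
  is outside scope; subtest scores are the input boundary.
* No design-based variance for the prevalence estimator beyond the
  bootstrap; no multi-phase generalisation beyond two phases.
* The normative model's reference-sample choice (all screened totals) and
  the exact regression-norming recipe are reasonable readings of
  under-specified methodology; alternatives (e.g. controls-only
  reference) would shift T-scores by a location factor.
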