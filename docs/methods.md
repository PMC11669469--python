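# Methods

`equity_audit` implements a statistical framework for monitoring inequalities
in psychotic-symptom outcomes across demographic groups in early-intervention-
in-psychosis (EIP) services, using the kind of patient-level table a national
clinical audit produces: gender, age band, broad ONS ethnicity category,
per-treatment uptake status, and HoNOS item 6 (hallucinations and delusions,
ordinal 0–4) at an initial and a follow-up assessment.  The outcome of
interest is the change Δ = follow-up − initial; negative change is symptom
improvement.  This note documents the models, the estimators, the synthetic
data that validates them, and the numerical choices.

## Data model and exclusions

Patients enter the analysis cohort when they are 18 or over and have both
HoNOS item 6 assessments recorded.  The exclusion pipeline applies those two
rules in that order and logs (stage, n_before, n_excluded, n_after); a record
failing both rules is counted at the age stage only, so the chained counts
always reconcile.  After exclusion, the demographic composition of the
filtered cohort is compared with the pre-exclusion cohort by a plain Pearson
χ² test on the category-by-(before/after) table (no continuity correction;
zero-count categories dropped; df = k − 1), two-sided at α = 0.05 — the check
that filtering introduced no new demographic bias.  For the age-band check
only patients 18+ enter the "before" side, since the bands are undefined
below 18.

Age bands are 18–24, 25–34, 35–44, 45–54 and 55–69, with the top band open
ended (the audited population's maximum observed age is 67, and the few older
patients are grouped with the 55+ band).  Uptake statuses are binarised as
taken-up = 1 against everything else (refused, waiting, not offered, not
eligible, unknown) for adjustment; the observational tables keep the fine
statuses.  Waiting sits in the 0 class: a treatment someone is still waiting
for cannot yet have acted on their symptoms.  Reported cells with fewer than
10 members are suppressed (a common statistical-disclosure floor; the audit
itself reports suppressing its non-binary gender and refused/unknown
ethnicity cells for low counts while keeping the records in the analysis).

Unparseable category labels fall back to the variable's unknown-style level
with a logged warning (ethnicity → Unknown/undocumented, uptake → unknown);
gender, which has no unknown level, falls back to Non-binary/other, a group
that is suppressed from reports in any case.

## Observational summaries

Per category of one grouping variable (gender, age band, ethnicity, or the
fine uptake status of one treatment) the package reports n, mean initial and
follow-up scores, mean Δ, and a percentile-bootstrap 95% CI of the mean Δ
(default 1000 resamples, seeded).  Percentile rather than BCa or normal
intervals: the simplest choice consistent with "bootstrap confidence
intervals", and the one whose behaviour the calibration tests document.
Groups are resampled independently by default; a whole-cohort resampling mode
exists because the two schemes answer slightly different questions (fixed
versus random group sizes) — for the group means they agree closely.

## Moderation effects by nearest-neighbour matching

The central estimator asks: do members of a demographic category improve
less than otherwise-comparable non-members?  Each member of the inspected
category is matched with replacement to its single nearest non-member, and
the moderation effect is

    effect = mean Δ(members) − mean Δ(matched non-members),

in HoNOS-change units; positive = less improvement (worse) for the group.
Because members are the target population this is the average effect of
category membership on the members (an ATT).  An ATE variant matching in
both directions and weighting by group size is available but not default.

Two adjustment modes mirror the two columns an audit report would print:
matching on the initial score alone, and matching on the initial score, all
binary uptake indicators, and all demographic variables other than the one
being inspected (the whole variable is excluded, not just the level — when
age is inspected, no age band enters the distance).  Comparing the two modes
is what separates a *mediated* disparity (a group does worse because it
receives less treatment; present in score-only mode, absent in full mode)
from a *direct* one (present in both).

**Distance.**  Covariates are binary/one-hot plus the integer initial score;
the distance is city-block, i.e. Hamming on the binary block.  The initial
score contributes one unit per point of difference, the same cost as one
binary flip.  This weighting matters: outcome change depends strongly on the
initial score, and if score differences are made cheap (e.g. rescaled to
[0, 1] so the whole 0–4 range costs one flip), one-fifth to one-third of
matches take a score mismatch and the full-mode estimator acquires a
measurable positive bias (~+0.04 change units at n ≈ 6800 on synthetic
cohorts, driven by poorly-matchable low-score patients being matched to
better-improving neighbours).  Per-point weighting removes ~85% of that
bias.  A Euclidean-on-one-hot alternative is available via configuration.

**Ties.**  With coarse discrete covariates many pool units are exactly
equidistant.  The raw matching primitive (`match_nearest`) breaks ties
deterministically to the lowest pool index — the property the brute-force
equivalence tests pin down.  The moderation estimator instead breaks ties
uniformly at random (seeded): a deterministic rule would collapse the
comparison set to a handful of units (score-only matching would reuse at
most five patients), making the estimator degenerate and its bootstrap CI
meaningless.  Random tie-breaking is implemented by adding sub-gap jitter to
the distance matrix (distances on this encoding are integers, so any jitter
below 1 reorders nothing but ties; on the fast path integer distances are
left-shifted 8 bits and a random byte is added).

**Confidence intervals.**  The default bootstrap resamples the whole cohort
with replacement and re-runs the matching inside every resample (1000
resamples by default; the validation studies use 200), so the interval
reflects matching and tie-breaking variability as well as sampling noise; a
cheaper variant that resamples the matched-pair differences of the point
estimate is available.  Every resampled copy of a target receives its own
independent tie draw — collapsing duplicates into one weighted draw
correlates their matches and visibly inflates the bootstrap variance.  Even
so the intervals stay mildly conservative (null exclusion ≈ 3.5–4% at
nominal 5% in the calibration study), the familiar behaviour of
bootstrapping nearest-neighbour matching with replacement: resamples contain
fewer distinct pool units than the original sample.  Percentile intervals at
95%.  Categories below the suppression floor are reported as suppressed
rows.

**Known limitation.**  1-NN matching on many moderately-prevalent binary
covariates is biased when exact matches are scarce (the matched neighbour
regresses toward pool-typical covariate patterns).  With the audited
psychological/pharmacological treatments at realistic prevalences the
residual bias measured on synthetic cohorts is below 0.01 change units at
n ≈ 6800, well inside the bootstrap CI; with many half-prevalent covariates
it can reach several hundredths.  Matching quality (exact-match fraction,
reuse multiplicity) is observable through `MatchResult`.

## Ordinal probit regression with interaction terms

The Δ categories (−4…+4 as observed; unobserved extremes collapse inward)
are modelled by a cumulative probit: P(y = j | x) = Φ(α_j − xβ) − Φ(α_{j−1} − xβ)
with strictly increasing cutpoints and no intercept column (location lives in
the cutpoints).  Features are the initial score, the binary uptake variables,
one-hot demographics with reference levels Female / White / 35–44
(configurable), and optionally interaction columns — exact elementwise
products of a demographic indicator and a treatment indicator.  A positive
coefficient shifts mass toward more positive Δ (worse outcome); negative
coefficients indicate improvement, so a negative demographic-by-treatment
interaction means that combination enjoys extra benefit.

Fitting is maximum likelihood with the exact analytic gradient, under the
standard unconstrained reparameterisation (first cutpoint free, increments
log-parameterised), by L-BFGS with a 1000-iteration cap (the ~160-column
all-pairs interaction design converges at just over 500) and gradient
tolerance 1e−6; starting values are β = 0 with cutpoints at Φ⁻¹ of the
cumulative category frequencies (the closed-form intercept-only MLE).
Columns active in fewer patients than the suppression floor are dropped
from pipeline designs before fitting: an interaction carried by one or two
patients (say, non-binary gender × clozapine) is quasi-separated, stalls
the optimiser, and could not be reported anyway under the low-count rule.  Interval
probabilities are computed in the tail-stable direction and floored at
1e−300.  The covariance is the inverse observed information, obtained by
central finite differences of the analytic gradient in the original
parameterisation; the convergence flag is honest and non-converged fits
refuse to produce Wald tests.  Coefficient inference is two-sided normal on
z = estimate/SE at α = 0.05, matching audit practice; no multiple-testing
correction by default, with Benjamini–Hochberg available for the interaction
screen.  Which interactions enter is configurable (all demographic×treatment
pairs, or a whitelist — e.g. all demographics against one treatment under
scrutiny, the layout the power studies use).

On independent cross-checks the fitter agrees with an established ordinal
probit implementation to better than 1e−4 in coefficients and cutpoints on
random small instances.

## Synthetic cohorts and ground truth

The generator emulates the audit's patient-level table.  Demographic
marginals default to the audited round's published filtered-cohort shares
(38.87% female; 13.15% Asian or Asian British, 13.31% Black or Black
British, 3.85% Mixed, 64.17% White, 3.08% other, with small refused/unknown
shares filled in); age-band shares are chosen to give a mean age near 30
(range 18–69); the initial-score distribution defaults to a configurable
skew toward 2–4 (0.04, 0.10, 0.22, 0.36, 0.28) with no claim of realism, as
no published distribution exists.  Treatment uptake is
Bernoulli(logistic(a_t + Σ b_{t,d} x_d)): the b's are the selection-bias
channel, zero by default.  Non-taken-up statuses are drawn from a configured
mix (not offered 50%, refused 25%, not eligible 15%, waiting 10%).

Outcomes come from the same latent-index family the regression fits:
y* = γ0 + γ_s·s0 + Σγ_t·T_t + Σγ_d·x_d + Σγ_{d,t}·x_d·T_t + ε with ε ∼ N(0,1)
(noise SD fixed at 1 for probit identification; logistic noise available as a
misspecification switch), cut at thresholds (default −3.5, −2.5, …, +3.5)
into an integer candidate change, then clipped so the follow-up stays in
0–4.  Clipping (rather than redrawing) preserves the monotone link between
y* and Δ and reproduces the strong dependence of achievable change on the
initial score that real bounded scores have; it is also the one deliberate
misspecification of the fitted model, concentrated at the score boundaries.
Default outcome coefficients (γ0 = 0.2, γ_s = −0.35, modest negative γ_t for
the core treatments) make every group improve on average, like the audited
cohort.  Under-18 records and missing scores are generated at rates (3%, 5%
initial, 30% follow-up) that exercise the exclusion pipeline and land the
filtered size near the audited ~6800 from ~10500 submitted.

`compute_truth` evaluates ground-truth estimands by brute force: for each
demographic level, the *direct* ATT is the mean over members of Δ with the
level's latent (and interaction) contributions present minus Δ with them
removed, holding all other covariates, the realised uptake and the noise
draw fixed (common random numbers).  Holding uptake fixed is what makes the
mediation scenario's truth exactly zero — the uptake-mediated path is
deliberately not part of the direct estimand, because the full-mode matching
estimator adjusts for uptake.  Levels with no direct or interaction term
have identically zero contrast, reported as exact zeros.

## Validation scenarios and study sizes

The validation suite (tests and `scripts/acceptance.py`) runs named
scenarios defined in `equity_audit.scenarios`:

* **direct_effect** — γ_d = +0.35 on the Black or Black British category at
  n = 6813; the cut-and-clip mapping attenuates this to a true direct ATT of
  ≈ +0.31 (Monte-Carlo at 10⁶).  Full-mode CI coverage is assessed over 50
  cohorts with 200 bootstrap resamples each.
* **uptake_mediation** — the 18–24 band's CBTp uptake drops from ~40% to
  ~8% (log-odds shift −2.0) with γ_CBTp = −0.6 and zero direct effect, at
  n = 6813; physical-health interventions are rare (screened subsets), so
  full-mode matches stay near-exact.  Expected pattern: score-only CI
  excludes zero on the harmful side, full-mode CI covers zero.
* **null_effects** — no effects anywhere, mid-range initial scores (0, .25,
  .5, .25, 0) and wide latent cutpoints (spacing 3) so clipping never binds
  and every fitted coefficient is truly null; used at n = 2000 over 100
  replicates to calibrate the moderation CIs (six audited categories) and
  the Wald tests at their nominal 5% level.
* **regression_recovery** — known coefficients including one −0.4
  gender-by-CBTp interaction at n = 5000, clipping-free by the same device,
  so every estimate can be compared to its generating value in SE units and
  the intercept-only fit to the closed-form cutpoints.
* **interaction_power** — the default (clipped) outcome family plus the
  −0.4 interaction at n = 6813, screening all demographic×CBTp interactions;
  detection power of the injected term is reported over 50 replicates.

Replicate counts (50/100), bootstrap sizes (200 inside the replication
studies, 1000 as the user-facing default) and the calibration cohort size
(2000) were fixed when the scenarios were designed.  What passing shows —
and what it does not: the generator draws demographics independently, makes
uptake depend on demographics only through configured log-odds shifts, and
generates outcomes from the very latent family the regression assumes.
Real audit data have correlated demographics, unmodelled confounders
(socioeconomic status, geography, assessment interval) and no guarantee of
probit-shaped noise, so these results demonstrate internal statistical
correctness of the estimators, not external validity of any particular
finding.

## Pipeline and reproducibility

`run_pipeline` executes ingest → exclusions → balance checks → observational
tables → moderation table → regression → interaction report; one global seed
fans out to per-stage seeds via `SeedSequence.spawn`, and within the
moderation table each (variable, level, mode) cell gets its own child seed,
so any cell can be recomputed in isolation bit-for-bit.  A failed analysis
stage is logged and the rest still run.  Outputs are plain CSVs plus a
Markdown summary with the config hash, seed and package version embedded;
re-running with the same config reproduces the bundle exactly.
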