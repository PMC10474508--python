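# Methods

## Scores

**Brackets.** A milestone's scale row gives five ages in fractional months
(`t0 ≤ t75 ≤ t90 ≤ t95 ≤ t100`): the minimal assessment age, the ages by
which 75/90/95% of the reference population attain the milestone, and the
maximal assessment age. The four severity brackets are
`[t0,t75], (t75,t90], (t90,t95], (t95,t100]`. Two conventions keep the
bracket lookup total:

- Ages outside `[t0, t100]` are clamped to the nearest endpoint before
  lookup. Real visit records routinely fall slightly outside the nominal
  assessment range; clamping assigns them the nearest bracket rather than
  failing.
- Degenerate (zero-width) brackets, which arise from step-like attainment
  curves, are permitted but flagged; an age equal to a stack of identical
  thresholds resolves to the highest-index bracket whose closed upper
  bound equals it.

**LMAS closed form.** The linearized score is defined here as the unique
continuous piecewise-linear function of age that is 0 at `t0`, equals `i`
at the upper end of bracket `i`, and is linear within each bracket:

    LMAS(a) = (i − 1) + (a − a_min) / (a_max − a_min),   a ∈ b_i = (a_min, a_max].

Consequences worth noting: a failure exactly at `t0` scores LMAS 0 even
though its DMAS is 1 (forced by continuity), and within a degenerate
bracket the right-limit value — the bracket index — is returned. `ceil(LMAS)
= DMAS` holds strictly inside non-degenerate brackets. LMAS is the default
score variant; the discrete DMAS is available everywhere the continuous
one is.

**DSS aggregation.** The score of an attempt set is the plain arithmetic
mean of per-attempt scores. Every repeated attempt of a milestone counts
separately, and attainments documented by parent report count the same as
observed ones. An empty selection yields an explicit undefined marker
(`None` in scalar APIs; NaN paired with `n_attempts = 0` in tables) —
never 0, which would assert that everything was attained, and never a
silently propagated NaN. Score windows are half-open `[start, end)`; a
window ending at the last assessment age (36 months) is closed there so
final-visit evaluations are included.

## Trajectories

The seven age steps (1-3, 3-6, 6-9, 9-12, 12-18, 18-24, 24-36 months) tile
`[1, 36]` under a half-open convention with the final step closed at 36;
boundary ages therefore bin deterministically (12.0 months → the 12-18
step). Evaluations before 1 month (the post-discharge contact) fold into
step 1; ages beyond 36 months belong to no step. Attempts are binned by
the age at which they were actually evaluated — not the step their
milestone nominally belongs to — because the score itself is
age-dependent. Children missing any step are excluded from trajectory
analyses (count logged); there is no imputation.

## Clustering

k-means (k=4, k-means++ initialization, `n_init=10` restarts under one
master seed) partitions complete trajectory vectors on 6 of the 7 entries:
each domain group has one step containing a single milestone (12-18 months
for motor, 6-9 months for language-social) whose per-child value is
correspondingly noisy, so it is excluded from the distance computation.
Centroids are nevertheless reported over all 7 entries, as means of the
member vectors. A Gaussian mixture (full covariance, same seed policy) is
provided for sensitivity analysis; the covariance structure was an open
choice and full covariance is the least restrictive. Cluster validity is
the Calinski-Harabasz variance-ratio index, implemented directly from its
definition (between-cluster SS / (k−1) over within-cluster SS / (n−k));
zero within-cluster dispersion returns `inf`.

**Pattern labels.** Centroids are labeled by two thresholds on the 0-4
score scale, `θ_low = 0.15` ("near zero") and `θ_high = 0.5` ("clearly
elevated"): *adequate* if all entries < `θ_low`; *catching up* if the
first entry ≥ `θ_high` and the last two < `θ_low`; *worsening* if the last
entry ≥ `θ_high` and exceeds the first; otherwise *other*. The defaults
quantify the qualitative cluster descriptions (near-zero throughout; high
early, resolved by the last steps; rising toward 36 months) and are
configurable. If permissive thresholds make the catching-up and worsening
criteria fire simultaneously, the label falls back to *other*. Clusters
are index-ordered by size so the adequate majority is cluster 0 in
reports.

## Subgroup statistics

The Mann-Whitney U test is implemented with midranks throughout, because
score samples are heavily tied at 0. For combined n ≤ 20 the two-sided
p-value is exact, by full enumeration of all label arrangements of the
midranked pooled sample; beyond that, a normal approximation with
tie-corrected variance and a 0.5 continuity correction is used. The
reported `u_statistic` is U of the first sample (`U_a + U_b = n_a · n_b`).
Pairwise comparisons in stratified tables are two-sided (the directionality
of the original bar-chart asterisks is unstated; two-sided is the
conservative choice) and are not adjusted for multiple testing.

Derived covariates: the postpartum-depression flag is EPDS total ≥ 10 or a
nonzero self-harm item (missing only when both inputs are missing);
prematurity categories are <27, 27-31, 32-36 (preterm), 37-38 (early
term), ≥39 weeks (full term). Every subgroup analysis excludes children
born before 37 weeks or with unknown gestational age — except the
stratification by gestational age itself, which is the one analysis that
keeps them (`subgroup_analysis` enforces this). A child missing a
covariate is excluded from that stratification only. Empty strata are
reported with n = 0, never dropped.

## Synthetic cohort

The generator provides the study conditions every analysis is tested
under; no real registry data are used anywhere.

**Scale.** 59 milestones split 15/15/17/12 across gross-motor, fine-motor,
language and personal-social. Each milestone has a logistic
attainment-rate curve of age — the minimal monotone sigmoid stand-in for
empirical attainment curves, whose true form is unknown — positioned so
that an undelayed child attains it with probability 0.99 at its nominal
("due") visit, with slope `s = 0.08 + 0.10 · due_age` months (early
reflexive skills emerge over weeks, toddler skills over months; the bound
keeps 50%-attainment ages after birth). Thresholds `t75/t90/t95` are read
off the curve on a 0.01-month grid; `t0` and `t100` are set at the 25% and
99.5% attainment ages (with `t0` clamped at birth) — a package convention,
since only "minimal and maximal assessment ages" is specified for them.
Due steps are scheduled so every age step holds at least two milestones
per domain group except one single-milestone step per group (step 5 for
motor, step 3 for language-social), mirroring the real battery's
structure.

**Visits and attempts.** Visits at 1, 2, 4, 6, 9, 12, 18, 24, 36 months;
each visit is attended independently with probability 0.95 (roughly
two-thirds of children end up with complete 7-step trajectories, emulating
substantial but not extreme attrition). A milestone is evaluated at the
first attended visit at or after its due visit; a failure is re-attempted
once at the following attended visit (re-evaluation occurs in practice but
no protocol is published; one retry is the minimal faithful policy).
Evaluation ages carry one-sided arrival jitter (|N(0, 0.15 mo)|, capped at
3 sd): families arrive at or shortly after the scheduled age, never
before, which keeps an evaluation inside its visit's age step. The final
visit is capped at 36.0 months, the end of the surveillance window —
without the cap, jittered 36-month evaluations would fall outside the
trajectory definition and final-visit failures would silently vanish.

**Latent delays.** Attainment probability for milestone *m* at age *a* is
`curve_m(a − f(a)·a)`: a child with pace deficit `f` behaves like an
undelayed child of age `(1 − f)·a`. Fractional (developmental-quotient
style) deficits keep effects comparable between the steep early-infancy
curves and the shallow toddler curves; an absolute months-scale delay
would swamp the early steps and barely register later. The deficit is the
sum of:

- an archetype term — *adequate*: none; *catching up*: `f0 ~ U(1.2, 1.6)`
  decaying exponentially (time constant 3 months, hard zero at 12 months);
  *worsening*: growing linearly from 0 to `U(0.5, 0.7)` at 36 months;
  *other*: a Gaussian bump of height `U(0.4, 0.6)` centered at `U(6, 9)`
  months (sd 2.5) — a mid-infancy dip that recovers, the non-conforming
  shape surveillance data also shows. Magnitudes were chosen so the
  planted shapes are clinically severe enough to be separable from
  binomial attempt noise at a few milestones per step (≥90% archetype
  recovery at n = 2,000);
- constant per-child noise, N(0, 0.03);
- covariate deficits (fractions): male 0.02, 0.012 per gestational week
  below 40, 0.01·(birth weight − 3.4 kg)², 0.01 per education level below
  academic, 0.012 for mothers ≥ 40, 0.02 for a positive
  postpartum-depression screen, 0.004 per elder sibling. Signs and
  ordering reproduce the known risk-factor directions; magnitudes are a
  few percent so subgroup contrasts are detectable at n ≈ 10⁴ without
  dominating the archetypes.

The archetype mixture defaults to 0.75/0.13/0.04 adequate/catching-up/
worsening with the 0.08 remainder as the bump — approximating the cluster
fractions reported for national surveillance data (an emulation target,
not a reproduction). Worsening odds are sex-linked (×1.55 for boys,
×0.423 for girls; the marginal mixture is preserved) so cluster covariate
tables reproduce the reported male excess in late-rising clusters.
Referral-to-tracking flags are drawn with archetype-dependent rates
(1/5/25/5% for adequate/catching-up/worsening/bump). Covariate marginals
approximate published cohort tables: 48.8% girls, ~7% preterm, birth
weight N(3.25, 0.42) kg clipped to [1, 6], ~14% of mothers ≥ 40,
education 44/15/38/3% academic/tertiary/high-school/elementary, EPDS total
~ round(Gamma(2, 2)) with 15% missing. All randomness flows from a single
seed through named substreams; identical seeds give byte-identical CSVs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: joint covariate distributions (only univariate
marginals), secular and seasonal effects, clinic-level clustering,
informative dropout (attrition is independent of the child's development),
milestone-to-milestone correlation beyond the shared latent deficit, and
real attainment-curve shapes. Archetype recovery rates on this generator
are an upper bound on what identically configured clustering could achieve
on noisier registry data.

## Problem sizes and numerical choices

Tests run the full pipeline at n = 2,000 (pattern recovery), covariate
recovery at n = 10,000, attainment-curve calibration at n = 20,000 null
children, and test calibration at 5,000 null replicates — sizes at which
every planted effect is comfortably detectable on a single CPU. LMAS
continuity is verified to 1e-4 at ε = 1e-6 (away from near-degenerate
brackets, where a finite-difference check is meaningless); score-mean and
index identities to 1e-12 and 1e-9; clustering determinism bitwise.
k-means empty clusters (possible only on degenerate inputs such as
all-identical vectors) fall back to the fitted model center rather than a
NaN centroid.

## Known limitations

The score calibration against formal screening instruments (Bayley,
Denver, ASQ) is out of scope, as is any claim about optimal evaluation
windows; the clustering sensitivity analysis covers k ∈ {4, 5} for both
k-means and GMM (with four planted trajectory shapes, k = 3 merges two of
them by construction); and the q-score alternative formulation is not
implemented.
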