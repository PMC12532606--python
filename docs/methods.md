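# Methods

`mscourse` models the course of multiple sclerosis (MS) as movement through
a small set of latent disease states.  The pipeline has two statistical
layers and a synthetic-cohort generator that carries the same structure, so
that every stage can be exercised and validated without access to
restricted patient-level trial data.

## The model

**Measurements.** Eight routinely collected quantities per patient-visit:
EDSS (0–10, half points), timed 25-foot walk (s), 9-hole peg test (s),
PASAT (0–60 correct), T2 lesion volume (ml), normalized brain volume (l),
Gd-enhancing T1 lesion count, and a physician-confirmed relapse flag.

**Layer 1 — sparse probabilistic factor analysis** (`mscourse.factor`).
After fixed link transforms (log for times and volumes, log1p for lesion
counts, a two-point latent-Gaussian encoding of the relapse flag at its
baseline prevalence) and standardization, the measurements follow a
Gaussian factor model `x = Λη + ε`, `η ~ N(0, I_K)`, `ε ~ N(0, Ψ)` with
diagonal `Ψ`.  Each loading carries a spike-and-slab prior with Laplace
components — slab scale 1.0, spike scale 0.05, both in standardized units —
and each column `k` a slab-inclusion weight `θ_k` with a finite
Beta(α/K_max, 1) prior (α = 1, K_max = 10), a truncated stand-in for the
Indian-buffet-process idea that the number of active columns is itself
inferred.  Fitting is MAP via EM on complete baseline rows only (the first
fully observed visit per patient): the E-step integrates scores and
spike/slab memberships in closed form; the M-step is a weighted lasso per
feature row solved by coordinate descent.  A measurement belongs to a
dimension iff its posterior slab probability exceeds 0.5 (strictly);
columns with no such member are pruned.  Dimensions are auto-labelled from
their members: relapse flag → *relapse*; Gd count without the flag →
*asymptomatic activity*; EDSS/walk/peg → *physical disability*; T2
volume/brain volume → *brain damage*.  When two columns match the same
rule, the label goes to the column with the stronger defining loadings and
the other column falls through to the next rule.

Numerical choices that matter here:

- *Spike scale 0.05, θ clamped to [1e-3, 0.8].*  The slab/spike crossover —
  the loading size at which a feature flips to "included" — is
  `ln(b₁/b₀)/(1/b₀ − 1/b₁)`, about 0.09–0.16 over the allowed θ range.
  A much smaller spike makes inclusion equivalent to "nonzero", and an
  unclamped θ saturates at 1 for any active column, after which the 0.5
  rule stops discriminating between defining and incidental loadings.
- *Initialization.*  Varimax-rotated, eigenvalue-shrunk PCA
  (`λ ∝ v·√max(s²−1, 0)`), jittered before rotation because varimax has a
  saddle at symmetric mixtures of equally strong factors.  The shrinkage
  starts noise directions at zero rather than on the ridge along which a
  single feature's variance can be split arbitrarily between loading and
  uniqueness.
- *Discrete column search.*  After EM, whole-column drop and pairwise-merge
  moves are tried (weakest first) and kept when the penalized posterior
  improves.  Smooth EM cannot make these moves once inclusion
  responsibilities saturate, yet they often carry a higher posterior for
  incidental or split columns.
- Ten seeded restarts by default; the best penalized likelihood wins.
  The EM objective is asserted non-decreasing (tolerance 1e-8).

**Scoring.**  With `Λ, Ψ` fixed, each visit's composite scores are the
Gaussian posterior mean `(I + ΛᵀΨ⁻¹Λ)⁻¹ ΛᵀΨ⁻¹ x` (ridge form); the
posterior covariance is shared across visits.  The loading matrix is held
fixed over time — dimensions do not change meaning across visits.

**Layer 2 — hidden Markov model** (`mscourse.hmm`).  Composite-score
sequences follow an HMM with full multivariate-normal emissions; every
patient is an independent chain sharing one parameter set; the transition
matrix is unconstrained (all transitions a priori possible).  Fitting is
multi-sequence Baum–Welch in log space (k-means means initialization,
0.9-diagonal transition start, pooled covariance, covariance eigenvalues
floored at 1e-6, relative tolerance 1e-6, up to 500 iterations, 10
restarts).  The state count is chosen by BIC with the total visit count as
sample size, `BIC(S) = −2 logL + p log(n_visits)`,
`p = (S−1) + S(S−1) + S(K + K(K+1)/2)`; a patient-based BIC column is
reported alongside, and ties break toward fewer states.  Visit-level state
assignments use the Viterbi algorithm (ties toward the lower state index),
with forward–backward posteriors emitted alongside.

**Meta-states** (`mscourse.states`).  Fitted states are labelled from
their score signatures: the relapse state maximizes the relapse-dimension
mean *and* shows the relapse flag at a majority of its decoded visits; the
activity state maximizes the activity score among the rest; remaining
states are ranked by disability + brain damage.  The advanced block is the
largest severity-contiguous suffix `B` of that ranking whose transitions
back to milder non-activity states, and direct inflows from them, all stay
at or below ε = 0.005 — entry only through the activity/relapse states.
Severity-contiguity matters: the defining "no direct transitions" pattern
is symmetric between the mild and advanced blocks, so an unrestricted
largest-set rule is not unique and estimation noise could flip the blocks.
If no suffix satisfies the conditions the least-violating one is returned
with a warning flag.  Aggregated meta-transition probabilities are
occupancy-weighted (Viterbi visit counts):
`meta[g,h] = Σ_{s∈g} w_s Σ_{t∈h} A[s,t]`, which preserves row sums exactly.

**Downstream** (`mscourse.evolution`).  Time to first confirmed
progression independent of relapse activity (PIRA), stratified by baseline
meta-state, uses the Kaplan–Meier product-limit estimator (Greenwood
variance, log-log 95% bands, via lifelines).  The treatment effect on
transitions into the active states is a panel-observed continuous-time
Markov model: the likelihood of each observed state pair over a gap `dt`
is the corresponding entry of `expm(Q·dt)`; treatment multiplies the
intensities into the activity/relapse states by `exp(β)`; standard errors
come from the finite-difference observed information; `1 − exp(β)` is the
percentage risk reduction.  Prognostication of the first transition to an
advanced state is a discrete-time logistic hazard on person-month records
(piecewise-constant baseline hazard on 6-month bins, L2-regularized),
evaluated by Harrell's concordance and an IPCW Brier score at a 24-month
horizon (integrated version alongside).  This learner deliberately
replaces tree-ensemble alternatives: it is deterministic, dependency-light,
and the evaluation metrics are learner-agnostic.

## The synthetic generator

`mscourse.simulate` draws, per patient, a state path from an 8-state
monthly Markov chain (3 mild-to-evolved "EME" states, 1 asymptomatic
radiological activity state, 1 relapse state, 3 advanced states), then
per-visit scores from state-specific Gaussians, then measurements through
the sparse loading matrix and per-feature links (log-normal times and
volumes, EDSS rounded to the half-point grid, PASAT rounded and clamped,
Poisson Gd counts with a log-linear rate, probit relapse flag).
Missingness is applied per feature at the published rates (walk 32.3%,
peg 43.6%, PASAT 53.9%, T2 volume 72.5%, brain volume 69.9%, Gd 73.1%;
EDSS and relapse complete), except at month 0: trial entry requires the
complete battery, so baselines are fully observed.

The defaults live in `src/mscourse/data/default_generator.yaml` and encode
the study conditions:

- Meta-level one-month transition aggregates equal the published values:
  relapse self-persistence 0.37 (equivalently a geometric episode length
  of ~1.6 months ≈ 47 days), relapse→advanced 0.18, activity→advanced
  0.11, activity→relapse 0.06, EME persistence > 0.90, and no direct
  EME↔advanced moves.  The split of these aggregates across individual
  states is a package default — severity-adjacent movement, activity risk
  graded with EME severity, stable EME block versus a still-progressing
  advanced block (which is what makes the absolute PIRA risk highest for
  patients starting advanced) — declared in the YAML, never hard-coded.
- Disability and brain-damage state means are nearly uncorrelated across
  the baseline mix (the clinico-radiological paradox: disability and
  lesion burden associate only weakly cross-sectionally).  This is also
  the independence the factor model assumes of its scores; a generator
  with strongly collinear severity dimensions is not representable by a
  sparse orthogonal-factor truth.
- The relapse dimension has a non-proportional multi-feature signature
  (flag + transient EDSS elevation + some Gd activity): a dimension whose
  only covariance partner can be absorbed by rotating another column is
  not identifiable for any sparse fit.
- The relapse flag saturates given the state (~99.9% flagged in the
  relapse state, ~0% elsewhere), matching the deterministic published
  characterization of those states.
- The baseline state mix puts ~10% of patients in the asymptomatic
  activity state: trials enrol for recent disease activity, so subclinical
  Gd activity is over-represented at entry relative to its long-run
  occupancy.
- Treatment multiplies all off-diagonal transition probabilities into the
  activity and relapse states (default multiplier 0.5), with the removed
  mass absorbed by the diagonal.

What the generator does **not** emulate: structural (MRI-schedule-driven)
missingness — missingness is independent per visit and feature;
measurement drift, rater effects and practice effects; unscheduled visits
off the monthly grid (the grid-mapping code handles day-offset data, but
the generator emits grid-aligned visits); informative dropout; and any
image-level detail.  Passing tests therefore show that the estimation
machinery recovers the truth *under the model's own assumptions at
realistic noise, missingness and sample sizes* — not that those
assumptions hold in any particular registry.

## Preprocessing

Day-offset visits map to the grid via `round(days / 30.44 / interval) ×
interval` (ties half-up; interval 1 month for trial-like data, 6 for
sparse real-world data); collisions merge with non-missing values winning,
relapse flags OR-ed, and conflicts resolving toward the unscheduled
relapse visit.  Partially observed visits are completed per patient and
feature by a penalized smoothing spline over time (GCV-selected smoothing;
log scale for positive features, log1p for counts), falling back to linear
interpolation below 5 support points and to carry-forward below 2.  Two
safeguards: the spline is trusted only inside the observed time span
(nearest observed value is carried beyond it), and predictions are clipped
to the patient's own observed range — imputation interpolates a
trajectory, it must not invent new extremes.  Unconstrained splines on
sparse log-scale MRI series overshoot badly enough to corrupt the state
model.  Rows with no observed feature are left absent; observed cells are
never altered; `obs_* = 0` doubles as the imputation flag.  Imputation
accuracy is estimated by masking a random fraction of observed cells and
reporting per-feature MAE on the standardized transform scale.

PIRA is a 3-month-confirmed, irreversible EDSS worsening with no
attributable relapse: onset at the first crossing of the band threshold
over baseline (+1.5 from EDSS 0, +1.0 from 0.5–5.0, +0.5 from ≥5.5 — the
standard trial convention, configurable), confirmed if every assessment
through ≥3 months stays at/above threshold, discarded if a relapse occurs
within one month before onset or before confirmation, and void if EDSS
later drops below threshold within follow-up.  A relapse-attributed
crossing is not re-dated to the next visit: a sustained plateau has one
onset.

Discovery/holdout splits cluster patients by k-means on per-patient mean
composite scores (k = 5 by default, with the within-cluster variance curve
reported for elbow inspection) and draw `round(0.2 × cluster size)`
patients per cluster into the holdout, seeded.

## Known limitations

- Estimated activity-state transition rates are attenuated: with Gd
  missing at 73% and episodes lasting ~2 months, only a minority of true
  activity visits are detectable, and spline-imputed Gd bleeds some
  activity signal onto neighbouring visits.  Transitions *out of* the
  activity state toward well-identified states (relapse, advanced) remain
  nearly unbiased because detection is independent of the next move, but
  the activity self-transition is underestimated and the activity→relapse
  rate runs ~1–2 points low at the default missingness.
- The discrete monthly chain is not exactly embeddable in a continuous
  time Markov model: the relapse state turns over at ~1 event/month, so
  `expm(Q)` necessarily reallocates part of its one-month self-transition
  to multi-jump paths (~0.04 absolute).
- The advanced block is near-absorbing (persistence 0.985/month), so the
  state chain's mixing time exceeds a trial-length horizon; long-run
  occupancy statements are checked against the finitely propagated law.
- Single imputation without uncertainty propagation; confirmed-EDSS
  assessments by a single (simulated) rater.

## Problem sizes

Default analyses and checks run at the study scale the estimators are
specified for: 2,000 patients × 24 months for transition-matrix recovery
(~48,000 visits), 2,000 baselines for dimension recovery (modal count over
20 seeded replicates), 1,000 patients × 24 months for BIC state-count
selection over S ∈ 4..10, and 1,000 patients per arm for the
treatment-effect model.  Unit tests use smaller cohorts (≈250 patients)
where only interface behaviour, not recovery power, is at stake.
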