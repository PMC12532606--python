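# Default synthetic-cohort generator for the MS disease-course model.
#
# Eight hidden states grouped 3 (EME) + 1 (asymptomatic activity) +
# 1 (relapse) + 3 (advanced).  The meta-state aggregates of `transition`
# reproduce the published one-month transition probabilities (relapse
# self-persistence 0.37, relapse->advanced 0.18, activity->advanced 0.11,
# activity->relapse 0.06, EME persistence > 0.90, no direct EME->advanced
# moves); the split of those aggregates across the individual states is a
# package default (severity-adjacent movement within EME and advanced
# blocks, activity risk graded with EME severity) and lives only in this
# file.  The relapse-state self-transition doubles as the geometric relapse
# persistence: mean episode length 1/(1-0.37) months, about 47 days.
n_patients: 2000
n_months: 24
seed: 20260922
treated: false
treatment_multiplier: 0.5
relapse_duration_mean_days: 47.0

features: [edss, t25fwt, nhpt, pasat, t2_volume, nbv, gd_count, relapse]
dimensions: [disability, brain_damage, relapse, activity]
state_meta: [eme, eme, eme, activity, relapse, advanced, advanced, advanced]

# Sparse loading matrix (feature x dimension) on the latent-Gaussian scale.
# Cross-loadings: relapses transiently elevate the EDSS (assessed at the
# unscheduled relapse visit) and carry some Gd-enhancing activity; active
# Gd lesions add to the T2 burden; cognition tracks brain damage with a
# smaller disability component.
loading:
  edss:      [ 0.85,  0.00,  0.35,  0.00]
  t25fwt:    [ 0.80,  0.00,  0.00,  0.00]
  nhpt:      [ 0.75,  0.00,  0.00,  0.00]
  pasat:     [-0.25, -0.60,  0.00,  0.00]
  t2_volume: [ 0.00,  0.85,  0.00,  0.25]
  nbv:       [ 0.00, -0.70,  0.00,  0.00]
  gd_count:  [ 0.00,  0.00,  0.25,  0.80]
  relapse:   [ 0.00,  0.00,  0.85,  0.00]

# Residual variance so that each latent feature channel has unit variance
# under unit-variance scores.
uniquenesses:
  edss: 0.155
  t25fwt: 0.36
  nhpt: 0.4375
  pasat: 0.5775
  t2_volume: 0.215
  nbv: 0.51
  gd_count: 0.2975
  relapse: 0.2775

# Observation model per feature: how the latent channel u = loading.scores
# + noise maps to measurement units.
feature_links:
  edss:      {kind: identity, loc: 3.5, scale: 1.3, round: half, clip: [0.0, 10.0]}
  t25fwt:    {kind: log, loc: 1.8718, scale: 0.35}
  nhpt:      {kind: log, loc: 3.0445, scale: 0.25}
  pasat:     {kind: identity, loc: 48.0, scale: 9.0, round: int, clip: [0.0, 60.0]}
  t2_volume: {kind: log, loc: 1.7918, scale: 0.55}
  nbv:       {kind: identity, loc: 1.50, scale: 0.05}
  gd_count:  {kind: count, loc: -0.3, scale: 0.9}
  relapse:   {kind: binary, loc: 1.0, scale: 1.0}

# State emission means on the score scale (disability, brain damage,
# relapse, activity).  Severity rises through the EME block (1-3) and the
# advanced block (6-8) in terms of disability + brain damage, but the two
# severity dimensions are kept nearly uncorrelated across the baseline mix
# (the clinico-radiological paradox: disability and lesion burden associate
# only weakly cross-sectionally), which is also the independence the factor
# model assumes of its scores: lesion-dominant advanced state 6 versus
# disability-dominant (spinal-type) advanced state 7, and an EME block with
# heterogeneous lesion burden.
state_means:
  - [-1.6,  0.8, -1.5, -1.7]   # state 1: mild EME, lesion-loaded (RIS-like)
  - [-0.8, -0.6, -1.5, -1.6]   # state 2: moderate EME, low lesion burden
  - [ 0.0, -0.6, -1.5, -1.5]   # state 3: evolved EME
  - [-0.5,  0.7, -1.4,  2.2]   # state 4: asymptomatic radiological activity
  - [ 0.2,  0.0,  3.4, -1.2]   # state 5: relapse (flag saturates: ~100% in relapse)
  - [ 1.1,  1.5, -1.5, -1.2]   # state 6: advanced, lesion-dominant
  - [ 2.0, -0.3, -1.5, -1.4]   # state 7: advanced, disability-dominant
  - [ 2.6,  0.6, -1.5, -1.6]   # state 8: advanced, severe

# Diagonal within-state score variances; the activity state is more
# heterogeneous in activity, the relapse state in disability and relapse.
state_vars:
  - [0.20, 0.30, 0.12, 0.15]
  - [0.20, 0.30, 0.12, 0.15]
  - [0.20, 0.30, 0.12, 0.15]
  - [0.20, 0.30, 0.12, 0.25]
  - [0.25, 0.30, 0.20, 0.15]
  - [0.20, 0.30, 0.12, 0.15]
  - [0.20, 0.30, 0.12, 0.15]
  - [0.20, 0.30, 0.12, 0.15]

# One-month transition matrix (row-stochastic).
# Within the EME block patients are clinically stable (little upward
# drift); within the advanced block disability keeps accumulating, so the
# absolute risk of confirmed progression is highest for patients starting
# advanced.  Block-level aggregates are unchanged by this split.
transition:
  - [0.930, 0.025, 0.010, 0.020, 0.015, 0.000, 0.000, 0.000]
  - [0.010, 0.900, 0.020, 0.040, 0.030, 0.000, 0.000, 0.000]
  - [0.005, 0.015, 0.875, 0.060, 0.045, 0.000, 0.000, 0.000]
  - [0.180, 0.130, 0.070, 0.450, 0.060, 0.080, 0.020, 0.010]
  - [0.120, 0.150, 0.130, 0.050, 0.370, 0.120, 0.040, 0.020]
  - [0.000, 0.000, 0.000, 0.005, 0.010, 0.875, 0.100, 0.010]
  - [0.000, 0.000, 0.000, 0.005, 0.010, 0.015, 0.900, 0.070]
  - [0.000, 0.000, 0.000, 0.005, 0.010, 0.000, 0.015, 0.970]

# Trial-baseline state mix.  Trials enrol for recent disease activity, so
# subclinical Gd activity is over-represented at entry (about 10%) relative
# to its long-run occupancy.
initial: [0.20, 0.20, 0.15, 0.10, 0.06, 0.11, 0.10, 0.08]

# Per-visit missingness (published rates); EDSS and relapse are complete,
# and every baseline (month 0) visit is fully observed, as trial entry
# requires the complete assessment battery.
missing_rates:
  edss: 0.0
  t25fwt: 0.323
  nhpt: 0.436
  pasat: 0.539
  t2_volume: 0.725
  nbv: 0.699
  gd_count: 0.731
  relapse: 0.0
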