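# mscourse

Probabilistic modelling of the multiple sclerosis (MS) disease course from
longitudinal clinical and MRI measures.

MS has traditionally been described by categorical course labels
(relapsing-remitting, secondary/primary progressive).  `mscourse`
implements an alternative, data-driven description: eight routinely
collected measures per visit — EDSS, timed 25-foot walk, 9-hole peg test,
PASAT, T2 lesion volume, normalized brain volume, Gd-enhancing lesion
count, relapse flag — are compressed by a **sparse probabilistic factor
analysis** (spike-and-slab Laplace prior, nonparametric column-inclusion
prior) into four latent MS dimensions

> physical disability · brain damage · relapse · asymptomatic activity

whose per-visit composite scores evolve through a **hidden Markov model**
with multivariate-normal emissions (state count chosen by BIC, visits
assigned by Viterbi).  The fitted states group into four clinical
meta-states from the transition structure alone — early/mild/evolving
(EME), asymptomatic radiological activity, relapse, advanced — with the
defining pattern that patients essentially never move from EME directly to
advanced MS: worsening runs through the focal-inflammatory states.
Downstream analyses cover time to confirmed progression independent of
relapse activity (PIRA, Kaplan–Meier), treatment effects on transition
intensities (panel continuous-time Markov model, hazard ratios and
1−HR risk reductions), and individual prognosis of conversion to advanced
MS (discrete-time hazard; concordance and IPCW Brier score).

The patient-level datasets behind this style of analysis are
access-restricted, so the package ships a first-class **synthetic-cohort
generator** (`mscourse.simulate` + `src/mscourse/data/default_generator.yaml`)
carrying the same statistical structure: an 8-state monthly chain whose
meta-level transition probabilities equal the published values (relapse
persistence 37%, relapse→advanced 18%, activity→advanced 11%,
activity→relapse 6%, EME persistence >90%, no direct EME→advanced moves),
a sparse 4-factor observation layer with realistic measurement links, and
feature-wise missingness at the published rates (up to 73% for MRI
measures).  Every estimator in the package is validated by recovering
these known quantities end to end.

## Worked example

```python
import mscourse as m
from mscourse.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    output_dir="scratch/readme_run",
    generator=m.default_config().replace(n_patients=1000, n_months=24),
    seed=42, pfa_restarts=5, hmm_restarts=3,
)
bundle = run_pipeline(cfg)
print(bundle.dimension_labels)
print((100 * bundle.transition_summary.meta_transition).round(1))
```

prints (abridged):

```text
dimension labels: ['physical disability', 'brain damage', 'relapse', 'asymptomatic activity']
meta transition matrix (%):
           eme  activity  relapse  advanced
eme       95.0       1.5      2.9       0.5
activity  18.4      68.1      3.7       9.9
relapse   36.8       6.5     36.4      20.3
advanced   0.4       1.0      0.9      97.7
validation criteria: True True
KM time-to-PIRA, eme      : n= 567 events= 97 S(24)=0.829
KM time-to-PIRA, advanced : n= 286 events= 53 S(24)=0.815
```

Reading this: the factor stage re-identified all four MS dimensions from
the simulated baselines; the 8-state HMM, decoded and grouped, reproduces
the generative transition pattern — patients in an EME state stay there
with ~95% monthly probability and essentially never jump straight to
advanced MS (0.5%), relapses persist month-to-month ~36% of the time and
convert to advanced states ~20% of the time, asymptomatic radiological
activity converts directly at ~10%.  Both predefined validation criteria
(four dimensions re-identified; EME→advanced only via activity states)
pass, and patients starting in an advanced state reach a first confirmed
PIRA event sooner than those starting EME.

The same stages are available as a CLI
(`mscourse simulate | preprocess | fit-pfa | score | fit-hmm |
select-states | run-all | validate-criteria`); `run-all` exits 0 on
success, 2 when the validation criteria fail.

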