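# proimpute

Intercurrent-event-aware handling of missing data in longitudinal
patient-reported outcomes (PROs).

## The problem

In oncology trials, quality-of-life scores (e.g. the EORTC QLQ-C30 global
QoL scale, 0–100) are collected on a fixed visit schedule, but the data are
riddled with holes — and the holes are not random.  Patients skip
questionnaires when they are doing badly: close to death, after disease
progression (PD), and almost always after treatment discontinuation (TD).
A naive analysis of the available cases, or a mixed model that ignores
these intercurrent events (ICEs), therefore paints too rosy a picture of
quality of life, and implicitly targets a "hypothetical world without
death" rather than the patients actually alive at each visit.

`proimpute` implements the alternative: treat death structurally (a row of
data exists only while the patient is alive — nothing is ever imputed
after death), encode the occurrence and timing of ICEs as *multi-timescale
covariates*, and use them to multiply-impute the missing scores under a
missing-at-random-given-ICE assumption.  It targets the **while-alive
estimand**: the mean PRO at each scheduled cycle $j$ among patients alive
at $j$, reported alongside the Kaplan–Meier probability of being alive.

## The model

Each visit row for patient $i$ at cycle $j$ carries, besides the score
$Y_{ij}$ and baseline covariates (age, sex, ECOG):

* $s_{ij} = S_i - j \ge 0$ — time until death or censoring;
* $t_{ijk} = T_{ik} - j$ — time-distance to non-terminal ICE $k$
  (PD, TD), held constant at 0 after TD and at $-3$ after PD, where data
  become too sparse to estimate anything;
* $E_{ijk}$ — whether ICE $k$ has been observed by cycle $j$
  (censoring never switches it on);
* event/censoring indicators $D_i$, $E_{ik}$.

The workhorse imputation model (engine `lmm_normal`, spec `model3`) is a
random-patient-intercept linear mixed model fitted by REML to the observed
rows:

$$Y_{ij} \sim (1|i) + \mathrm{rcs}(j) + \mathrm{rcs}(t_{ij1}) +
\mathrm{rcs}(t_{ij2}) + \mathrm{rcs}(s_{ij}) \cdot D_i + E_{ij1} +
E_{ij1}{:}E_{i1} + E_{ij2} + \mathrm{age}_i + \mathrm{sex}_i +
\mathrm{ECOG}_i$$

with restricted cubic splines whose knots sit 1, 4, 9 and 20 cycles before
the event.  Missing cells are drawn from the approximate conditional
predictive distribution (coefficient draw + conditional random-intercept
draw + residual noise).  Alternative engines: two-level predictive mean
matching on a B-spline mixed model (`lmm_pmm`), clustered-bootstrap
additive models with normal or PMM draws (`boot_gam_*`), and an ICE-free
`naive_lmm` benchmark.  An IPW route (stabilised, truncated
inverse-probability-of-observation weights + independence GEE) is provided
for comparison.

Per-cycle means of each completed dataset are the independence-GEE
estimates (identical to per-cycle sample means, with patient-clustered
sandwich SEs) and are pooled over the $M$ imputations with Rubin's rules:
$T = W + (1 + 1/M)\,B$.

## Worked example

The motivating trial data are restricted-access, so the package bundles a
synthetic-trial generator with the same structure (tri-weekly cycles 1–10
then alternate cycles to 40, ~2/3 deaths, QoL decline before death and
after PD, collection stopping almost entirely after TD):

```python
import proimpute as pi
from proimpute.pipeline import estimate_from_imputations

cfg = pi.SimConfig(n_patients=300, seed=7)
complete = pi.simulate_trial(cfg)
observed = pi.apply_missingness(complete, cfg.missingness, seed=8)
print(observed)
# <LongTrialData: 300 patients, 5238 rows, 43.4% missing PRO>

fitted = pi.ImputationModel(observed, spec="model3", engine="lmm_normal").fit()
result = fitted.impute(m=10, seed=9)
est = estimate_from_imputations(result.datasets)
print(est.table()[["cycle", "estimate", "se", "ci_low", "ci_high",
                   "n_alive", "km_surv"]].round(2))
```

```
 cycle  estimate   se  ci_low  ci_high  n_alive  km_surv
     1     64.24 0.75   62.78    65.70      300     1.00
     2     63.40 0.82   61.80    65.00      291     0.97
     3     63.67 0.85   62.00    65.34      285     0.95
 ...
    36     56.04 1.46   53.10    58.97      126     0.42
    38     56.08 1.73   52.54    59.63      119     0.40
    40     53.53 3.83   45.09    61.98      115     0.38
```

Read each row as: among the patients still alive at that cycle (38% of the
cohort by cycle 40), the pooled mean QoL estimate with its Rubin SE and
95% interval.  The decline from ~64 to ~54 points reflects both the
post-progression drop and the pre-death deterioration that the available
cases systematically under-report.

The same pipeline is scriptable:

```bash
proimpute simulate --n 300 --seed 7 --out trial.csv
proimpute impute --in trial.csv --engine lmm_normal --model model3 --m 40 --seed 9 --out imputed/
proimpute estimate --imputed imputed/ --estimand while_alive --out result.json
proimpute run --config run.yaml        # config-driven end-to-end with manifest
```

## Layout

| module | contents |
|---|---|
| `proimpute.encoding` | `Schedule`, `PatientRecord`, `LongTrialData`, timescale derivation, validation |
| `proimpute.splines` | restricted cubic and B-spline bases, ICE-anchored knots |
| `proimpute.design` | `ModelSpec`/`Term`, bundled model variants, design-matrix builder |
| `proimpute.simulate` | synthetic-trial generator, missingness mechanisms, truth curves |
| `proimpute.impute` | `ImputationModel` → `ImputationModelResults` → `ImputationResult` |
| `proimpute.ipw` | missingness model, weight stabilisation/truncation, IPW-GEE |
| `proimpute.estimands` | while-alive means, Rubin pooling, Kaplan–Meier, composite / on-treatment / responder transforms |
| `proimpute.pipeline`, `proimpute.cli`, `proimpute.io` | CSV dialect, run configs, manifest, `proimpute` command |
| `proimpute.study` | replicate validation studies used by tests and the acceptance script |
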