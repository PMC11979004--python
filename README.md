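# tgtacs

Behavioral analysis pipeline for multi-session **theta–gamma tACS**
working-memory trials, built for researchers who analyse longitudinal
n-back performance under concurrent brain stimulation and want every
stage — stimulation waveform, data filtering, signal-detection measures,
regression modeling, session-wise effect sizes — reproducible and tested.

The pipeline covers a 16-session parallel-arm design (active vs. sham
stimulation) in which each session pairs 20 minutes of stimulation with
six 1-back and ten 2-back gameplays (96 and 160 gameplays in total).
Because raw data from such trials are typically not deposited, the
package includes a first-class synthetic-cohort generator with the same
statistical structure, plus the contaminants (dropouts, excess
gameplays, no-response gameplays, a constant-"yes" responder) that the
filtering cascade must handle.

## The model at the core

Per-gameplay performance is summarised by equal-variance Gaussian signal
detection. With hit rate H and false-alarm rate F averaged per group and
gameplay,

    d′ = Z(H) − Z(F)          (sensitivity)
    C  = −½ (Z(H) + Z(F))     (response bias; negative = liberal)

where Z is the probit. Learning trajectories are modelled as

    d′ ~ Gameplay × Group + Gameplay²          (linear model)
    RT ~ Gameplay × Group + Gameplay² + age + MoCA   (gamma GLM, log link)

with mean-centred covariates, candidate formulas ranked by AIC
(likelihood-ratio tests for nested pairs), and conventional reporting:
beta, 95% CI, standardized beta, R²/adjusted R² or Nagelkerke R².
Session-wise between-group effects use estimated marginal means from a
session-factor model, Bonferroni correction over the 16 sessions, and
Cohen's d with 95% CIs classified into the standard size bands.

The stimulation module synthesises the trial's waveforms: a 6 Hz theta
carrier with 80 Hz gamma gated onto its peaks by phase-amplitude
coupling, 2 mA peak-to-peak on the plateau, 15 s linear fades; and a
modified sham with two 90 s active phases bracketing an 85 Hz, 50 µA
impedance-control current — validated by measurement (periodogram peaks,
Tort modulation index) rather than by construction.

## Worked example

```python
from tgtacs.cohort import GeneratorParams, generate_cohort, generate_gameplays
from tgtacs.preprocessing import run_filter_pipeline
from tgtacs.sdt import aggregate_group_rates
from tgtacs.modeling import ModelSpec, fit_lm

params = GeneratorParams(seed=4)
cohort = generate_cohort(params)                  # 38 active / 39 sham
table = generate_gameplays(cohort, params=params)
filtered, report = run_filter_pipeline(table, "sdt")
rates = aggregate_group_rates(filtered)           # one row per group x gameplay

mm = rates[rates["task"] == "mm_2back"]
fit = fit_lm(ModelSpec("d_prime ~ gameplay_index * group + gameplay_index^2"), mm)
print(fit.terms.round(6))
```

prints (seed 4):

```
                                    beta        se       stat         p    ci_low   ci_high
Intercept                       1.244534  0.023512  52.932957  0.000000  1.198273  1.290795
group[T.active]                -0.037449  0.025659  -1.459455  0.145443 -0.087935  0.013038
gameplay_index                  0.004096  0.000578   7.090497  0.000000  0.002959  0.005233
gameplay_index:group[T.active]  0.000663  0.000276   2.407003  0.016663  0.000121  0.001206
I(gameplay_index ** 2)         -0.000012  0.000003  -3.613453  0.000352 -0.000019 -0.000006
```

Read: 2-back sensitivity rises ≈0.004 d′ units per gameplay with a
negative quadratic ceiling, and the active arm improves faster (positive
`gameplay_index:group` interaction, here 6.6e-4 ± 2.8e-4, p = 0.017) —
the generator's built-in group-by-gameplay effect recovered by the fit.
The same chain is scriptable from a shell:

```sh
tgtacs simulate --seed 4 --out-prefix sim
tgtacs preprocess --in sim_gameplays.csv --branch sdt --out filtered.csv
tgtacs sdt --in filtered.csv --out rates.csv
tgtacs fit --in rates.csv --spec "d_prime ~ gameplay_index * group + gameplay_index^2"
tgtacs waveform --mode active --out waveform.csv
```

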