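# shortscale

Ant-colony short-form construction and psychometric evaluation for
hierarchical ordinal scales.

Questionnaire developers routinely need to shrink a long trait inventory
— say, 141 items measuring 17 facets nested in 6 trait domains on a
4-point scale — down to a fixed budget of 2 items per facet, without
wrecking model fit, reliability, or validity. Picking the best such
subset is a combinatorial problem (the 141-item pool admits about
4.02 × 10²⁴ selections), so `shortscale` searches it with a MAX–MIN ant
system whose objective combines DWLS fit indices (CFI, RMSEA, SRMR),
McDonald's ω, minimum factor loadings, and part–whole correlations, and
then evaluates the winner the way a validation study would: scaled-χ²
fit statistics, a four-level ordinal measurement-invariance ladder,
model-based reliability, and criterion-validity contrasts.

The measurement model is a second-order ordinal factor model on the
probit scale — items load on facets (λ), facets on domains (γ), domains
correlate freely (Φ) — estimated by two-step DWLS on polychoric
correlations with influence-function weights. Everything runs on plain
pandas DataFrames; a synthetic-data module generates ordinal responses
with exactly this latent structure so every stage is testable end to
end. See `docs/methods.md` for the model, the estimators and the design
choices.

## Worked example

```python
import numpy as np
from shortscale import (
    make_default_config, generate_responses, OrdinalFactorModel,
    polychoric_matrix, omega_report, ShortFormPipeline, ACOConfig,
)

# 2,000 respondents from the 141-item pool template: two strong items
# (lambda = .8) per facet planted among weaker (lambda = .4) distractors
cfg = make_default_config("pid5pool", n=2000)
resp, truth = generate_responses(cfg, seed=11)

# end-to-end: stratified split, 3 runs x 2 objectives, consensus,
# brute-force completion, test-split ranking
pipe = ShortFormPipeline(resp, cfg.spec, aco_config=ACOConfig().scaled_for(cfg.spec))
result = pipe.run(seed=7)
best = result.best
planted = sum(set(best.selection[f]) == set(cfg.spec.facet_items(f)[:2])
              for f in cfg.spec.facets)
print(f"planted pairs recovered: {planted}/17")
print(f"test-split fit: CFI={best.test_fit.cfi:.3f} "
      f"RMSEA={best.test_fit.rmsea:.3f} SRMR={best.test_fit.srmr:.3f}")
```

```
planted pairs recovered: 17/17
test-split fit: CFI=1.000 RMSEA=0.000 SRMR=0.039
```

The pipeline recovers every planted high-loading pair, and the selected
34-item model fits the held-out split essentially perfectly (the data
were generated from the model, so this is the expected ceiling; CFI
clips at 1 when the scaled statistic falls below its degrees of
freedom). Fitting and inspecting a single model directly:

```python
short = cfg.spec.subset(best.items)
res = OrdinalFactorModel(polychoric_matrix(resp, short), short, mode="congeneric").fit()
print(res.summary())          # loadings per facet, scaled chi2, CFI/RMSEA/SRMR
om = omega_report(res)
print(f"mean facet omega = {om.mean_facet:.2f}")
```

```
mean facet omega = 0.78
```

A thin CLI wraps the same functions:

```bash
shortscale simulate --template pid5pool --n 2000 --seed 7 --out data.csv --spec-out pool.yaml
shortscale pipeline --spec pool.yaml --data data.csv --seed 42 --out run.json
shortscale fit --spec short.yaml --data data.csv --mode congeneric --omega
shortscale invariance --spec short.yaml --data grouped.csv
```

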