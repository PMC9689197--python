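# spinemult

Sitting-height multiplier method for predicting spinal growth at skeletal
maturity — a library and CLI for pediatricians, spinal surgeons, and limb
lengthening planners.

## The problem and the method

Sitting height (vertex-to-seat distance: skull + spine + pelvis) is the
standard clinical proxy for spinal growth. The multiplier method predicts
its value at skeletal maturity from a **single** current measurement,
without determining the child's growth percentile or consulting a chart:

```
Lm = S × M(age, sex)
```

where `S` is the current sitting height and `M` is the age- and
sex-specific **multiplier** — the ratio of sitting height at skeletal
maturity to sitting height at the given age, `M = Lm / L`, derived from
percentile-structured growth references. The method works because `M` is
empirically almost identical across percentile/SD lines ("percentile
invariance"): one table serves all children. `M` decreases monotonically
with age and reaches exactly 1 at skeletal maturity (18 y in boys, 16 y in
girls).

The packaged table covers every month from 0+3 (years+months) to maturity,
for both sexes (404 values). On top of it the package implements the
derived clinical formulas:

| quantity | formula |
|---|---|
| mature sitting height | `Lm = S·M` |
| single mature vertebra height | `Lv = L_segment·M / n` (n = 5 lumbar, 12 thoracic) |
| growth remaining in a spine section | `G = L·(M − 1)` |
| growth lost to arthrodesis of Vf vertebrae | `Ge = L_segment·(M − 1)/n × Vf` |
| limb-lengthening target (achondroplasia) | `47/53` (≈88.6%) of predicted mature sitting height |
| mature standing height | sitting height / 0.53 |

The thoracic and lumbar spine share the sitting-height multiplier (their
segment multipliers are nearly identical to it); the cervical spine does
**not** — cervical predictions require a user-supplied cervical table,
loaded through the same interfaces.

The package also contains the derivation machinery that produces such
tables: `derive_multipliers` (M = Lm/L per sex × percentile × age),
cross-percentile `variability_stats`, polynomial-regression comparison of
multiplier sets from different references, and a synthetic growth-database
generator with exact known ground truth for validating all of it.

## Worked example

A 10-year-old girl with a sitting height of 70 cm:

```bash
$ spinemult predict sitting --sex female --age 10+0 --sitting-height 70
formula          : mature_sitting_height
  sitting_height_cm: 70.0
  sex            : female
  age            : 10+0
multiplier M     : 1.178
predicted        : 82.46 cm
```

The table multiplier for girls at 10+0 is 1.178, so her predicted mature
sitting height is 70 × 1.178 = 82.46 cm. Growth remaining for a 10-year-old
boy whose spine section currently measures 80 cm:

```bash
$ spinemult remaining --sex male --age 10+0 --length 80
...
multiplier M     : 1.263
predicted        : 21.04 cm        # 80 × (1.263 − 1)
```

Limb-lengthening target for the girl above (achondroplasia planning,
restoring the adult 53% sitting / 47% lower-extremity proportion):

```bash
$ spinemult limb-target --predicted-sitting 82.46
...
target fraction  : 88.6% of predicted mature sitting height
predicted        : 73.12 cm        # 82.46 × 47/53
```

Other subcommands: `lookup`, `predict vertebra`, `fusion-loss`,
`standing-height`, `derive`, `compare`, `simulate`, `validate-table`,
`show-table`. All accept `--format json` for machine-readable output;
ages are `Y+M` (e.g. `10+6`) or decimal years. Equivalent library calls:

```python
from spinemult import AgeYM, Sex, predict_mature_sitting_height
r = predict_mature_sitting_height(70, Sex.FEMALE, AgeYM(10, 0))
r.predicted_value   # 82.46
```

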