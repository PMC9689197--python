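# Methods

## The multiplier model

For a growing body dimension `L`, the multiplier at age `a` is
`M(a) = Lm / L(a)`, the ratio of the dimension at skeletal maturity to the
dimension at `a`. Prediction inverts the definition: `Lm = L(a) · M(a)`.
The model's single substantive assumption is **percentile invariance**:
children on different percentile/SD lines of a growth reference share
(very nearly) the same multiplier curve, so a population-level table can
be applied to an individual child from one measurement. If a child's
curves cross percentile lines (pathology, treatment effects), the
prediction inherits that error; the package computes, it does not judge —
the treating physician must decide whether the child is tracking the
reference.

The packaged sitting-height table covers 0+3 (years+months) through 18+0
for boys and 16+0 for girls, one multiplier per month, three decimals,
404 cells. The first two months of life are absent in the source table
and are treated as out of domain (an `UnderAgeError`), not extrapolated:
multipliers there would exceed 2.3 and extrapolation is clinically
unsafe. Within the tabulated range no interpolation is ever needed (the
monthly grid is complete); decimal ages are snapped to the nearest whole
month, with exact half-month ties rounded toward the *younger* month
(larger multiplier, conservative for growth-remaining estimates).

Ages past maturity are clamped to `M = 1` only behind an explicit flag:
default **on** in the CLI (the common clinical query "is growth done?"
must work) and **off** in the library (silent misuse in code should be
impossible). The result record carries a `post_maturity` flag either way.

## Clinical formulas

All formulas are exact arithmetic on top of one table lookup (see README
for the table). Two deliberate interpretations, both algebra-preserving:

* Growth remaining is implemented as `G = L·(M − 1)`, i.e. mature length
  minus current length. This matches the verbal definition and the
  per-vertebra forms, and makes the identities below exact.
* The per-vertebra formulas take the length of the segment *named*
  (lumbar length for lumbar predictions, thoracic for thoracic), with
  equal per-vertebra growth contribution assumed exactly (1/5 and 1/12).

Identities guaranteed (and tested) to float precision:

* `growth_remaining(L) = predict_mature_sitting_height(L) − L`
* fusing an entire segment loses exactly that segment's growth remaining
* `h + limb_target(h) = h·100/53 = estimate_mature_standing_height(h)`

The Vitruvian constants are stored as exact rationals (47/53 and 53/100);
"88.6%" appears only in rendered text. Standing height is computed as
`h·100/53` (identical to `h/0.53`) so the three-way identity above holds
to machine precision.

## Deriving and comparing multiplier sets

`derive_multipliers` applies `M = Lm/L` per (sex, percentile, age) to any
percentile-structured reference supplied as CSV. Requirements: unique
(sex, percentile, age) keys and a maturity record for every curve.
Maturity ages default to 216/192 total months and are configurable for
references with other conventions.

**Variability.** The cross-percentile spread of multipliers is summarized
as, per sex and age, `max_p |M_p − mean_p(M_p)|`, then averaged
(unweighted) and maximized over the age grid; per-sex and pooled values
are both reported, along with the full per-age series so alternative
summaries can be computed. This statistic was chosen because it is
brute-force checkable and reproduces the qualitative behaviour of
SD-structured references: largest spread at the youngest ages, shrinking
toward zero at maturity (where every `M_p = 1` by construction).

**Comparison.** Two multiplier sets are compared on the exact
intersection of their monthly age grids (no interpolation — matching
across grids would invent data). The mean curve of one is regressed on a
polynomial in the mean curve of the other (ordinary least squares,
`numpy.polynomial`); the result reports R², residual RMSE, the raw
pre-fit maximum difference between the mean curves, and the number of
shared ages. Degree 3 is a sensible default for growth-curve shapes but
the CLI makes the degree a required flag so published comparisons always
state it.

## Synthetic growth references

Real sitting-height references are not redistributable, so validation
uses generated databases whose ground truth is known exactly. Curves are
built by *inverting* a seed multiplier table, `L(a) = Lm / M(a)` — the
generator is the algebraic inverse of the derivation, which is precisely
what makes the round-trip test meaningful. A parametric growth model
(infancy–childhood–puberty fits, longitudinal correlation) is a
non-goal: the generator validates the derivation machinery, it does not
emulate cohort biology, so passing tests demonstrate correctness of the
arithmetic and its implementation, not field accuracy on real children.

Modes:

* **proportional** — each percentile is a scalar multiple of the inverted
  seed curve; all percentiles share identical multipliers (exact
  percentile invariance).
* **sd_offset** — percentile curves are the inverted median curve plus
  `k_p · s(a)`, where `k_p` is a signed offset index (evenly spaced
  integers centered at 0 by default; explicit values like −2.5 … +2.5
  may be supplied) and the spread `s(a)` interpolates linearly in total
  months from `spread_at_birth` at age 0 to `spread_at_maturity` at
  maturity. This produces percentile-*dependent* multipliers whose
  variability is maximal at the youngest ages — the qualitative pattern
  of real SD-line references. The median ("base") mature height is the
  statistical median of the configured per-sex mature heights.

Defaults, chosen once as typical adult values: mature sitting height
92 cm (male) / 86 cm (female) for a single P50 curve; yearly age grid
1–15 y (inside both sexes' table domains); spreads 3 cm → 1 cm; noise 0.

Noise is multiplicative relative Gaussian (`height × (1 + ε)`,
`ε ~ N(0, σ)`, σ < 0.2 enforced), because measurement error scales with
size. Maturity records are always emitted and always noise-free: the
derivation numerator is then exact and the error of a derived multiplier
is exactly the ratio noise `M_true/(1+ε)`, which makes recovery bounds
provable (e.g. with σ = 0.01 and multipliers ≤ 1.454, 3σ of the ratio
noise stays within ±0.05). Generation is bit-stable: same config and
seed, same database.

## Numerical choices

* Multipliers are stored as parsed; serialization rounds half-even to 3
  decimals (the table's printed precision). Derived sets may be written
  at higher precision (`decimals=` parameter).
* "Exact" float identities are asserted at relative tolerance 1e-12;
  derivation vs. brute-force-oracle agreement is exact float equality
  (both sides perform the same IEEE division).
* R² is clipped to [0, 1]; a constant response with zero residuals
  reports R² = 1.
* Table validation reports *all* violations (it never raises); loading
  rejects invalid tables by default, with `validate=False` available for
  forensic inspection of a broken file.

## Limitations

* The packaged table applies to sitting height and the thoracic/lumbar
  spine only; cervical and upper-extremity multipliers are materially
  higher and must be supplied by the user as separate tables.
* Growth after spinal pathology or surgery need not follow the reference
  trajectory; disk-height changes after maturity are not modeled.
* Whether to use age at surgery or a later planned age for arthrodesis
  loss is left to the caller — the operation takes exactly one age.
* Synthetic references do not emulate longitudinal (within-child)
  correlation, secular trends, or real percentile spacing.
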