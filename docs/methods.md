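# Methods

## The two indicators

**Simple indicator.** A district's population is weighted by
`1 + stunting_rate`, where the stunting rate is the proportion of under-five
children below −3 SD height-for-age. The `1 + s` multiplier form is the one
consistent with the packaged district table: every ratio of
stunting-weighted population to population there lies in [1.12, 1.30],
i.e. one plus a plausible severe-stunting proportion, and dividing the
weighted column by population recovers rates of 0.118–0.303. The table does
not ship stunting rates directly; `derive_implied_stunting` recovers them by
this inversion and is exact to the integer precision of the printed columns.

**Composite indicator.** The Filmer–Pritchett asset index: PCA on the
*correlation* matrix (equivalently, standardized indicators — the index
formula divides by `s_k`, so the covariance-matrix variant would be
inconsistent with it). The scoring weight `f_k` is defined as the unit-norm
PC1 eigenvector loading; this is the only convention for which the stated
property `Σ f_k² = 1` holds, whereas scoring coefficients rescaled by the
eigenvalue or by `s_k` would not. Means and SDs use the denominator-*n*
convention; at n = 31,200 households the n vs n−1 distinction is far below
every tolerance used, but it is fixed for bit-reproducibility.

**Screening.** A variable is retained iff at least one of its pairwise
Spearman correlations with another candidate is significant at the 1% level
(two-sided, midrank ties, the large-sample t approximation). Constant
columns are always dropped ("zero variance"). The retain-iff-any-pair rule
is the weakest faithful operationalisation of "exclude variables not
significant at 1%": with no stated reference variable, a variable correlated
with *anything* in the set carries shared SES signal.

**Sign and direction.** A principal component's sign is arbitrary. The
component is flipped so a configurable wealth-marker set (car/truck,
refrigerator, flush toilet, electric/gas cooking) loads positively; if no
marker survives screening, the fallback orients the score to correlate
positively with the household's total asset count. District means are then
normalized on this orientation — `shift = 1 − min`, minimum district set to
*exactly* 1.0 (computed as an assignment, not as a float sum, so the
invariant is exact). This reproduces the published convention, in which the
urban districts carry the largest normalized indices and the normalized
index correlates negatively with the stunting rate. Aggregation to district
level is the unweighted household mean (standard practice); a
population-weighted mean is available behind `--aggregation popweighted`.

## Allocation formula

`x_i = B · Σ_n a_n V_ni / Σ_j V_nj` with `a_n ≥ 0`, `Σ a_n = 1`. The
additive weighted-share form is the standard capitation composition and the
only simple one that conserves the budget without an extra normalization;
it is proportional to `V` when a single variable carries all weight,
monotone in each `V_ni`, and scale-free in each column. Currency rounding
uses largest-remainder apportionment, which keeps `Σ x_i = B` exact in
currency units. The production formula's other variables (cost index, bed
capacity, OPD utilization) are supported structurally through the variable
matrix but ship with no data, so no monetary-allocation figures are
reproduced — only the share-level comparison.

## Comparison statistics

Spearman ρ is the Pearson correlation of midrank vectors; significance uses
`t = ρ√((n−2)/(1−ρ²))` against Student-t(n−2), two-sided, reported as a
boolean at the 1% level. pp differences, the winner classification and the
subgroup means are computed on full-precision shares; rounding to 2 dp is
presentation-only (on the packaged table both conventions give the same
classification). Relative allocation differences use the symmetric
`max(x_a, x_b)` denominator by default (bounded by 100%); `a` or `b`
denominators are options since no convention is canonical.

A note on the packaged table: recomputing shares from its
weighted-population columns yields the composite indicator ahead in **six**
districts (Blantyre, Karonga, Lilongwe, Mzimba, Rumphi, Salima), not the
five its accompanying narrative lists — Salima's asset share (2.65%)
exceeds its stunting share (2.46%) under every rounding convention the
table supports. The package reports the table-implied 20/6 classification;
the corresponding acceptance test against the narrative's 21/5 split is
expected to fail and documents the discrepancy. All other narrative
quantities reproduce at printed precision.

## Synthetic survey generator

The generator emulates a MICS-style cluster survey with a single-factor SES
structure — the premise under which a first principal component is a
sensible index:

* district latent SES `z_d ~ N(0, ses_spread²)`; household SES
  `z = z_d + N(0, 1)`;
* free-standing indicator `k`: Bernoulli with log-odds
  `logit(prevalence_k) + loading_k · z`;
* mutually exclusive blocks (water, toilet, floor, roof, fuel): one
  categorical draw with probabilities ∝ `prevalence_c · exp(loading_c · z)`,
  so exactly one dummy per block is set;
* district stunting rate `expit(logit(stunting_base) + stunting_slope · z_d)`.

Defaults are the study conditions: 26 districts × 1,200 households, the
published variable list with baseline prevalences equal to the published
means, loadings equal to the published factor scores × 10 (magnitude ≈ 1 on
the log-odds scale — a strong, realistic single-factor signal),
`ses_spread = 0.5` (district spread half the within-district household SD,
typical of national surveys where most SES variance is within-district),
`stunting_base = 0.20` and `stunting_slope = −0.5` (the packaged table's
implied severe-stunting rates centre near 0.20 and poorer districts stunt
more). District populations default to the published 2008 counts when 26
districts are drawn. Everything is reproducible from one integer seed.

What the generator does **not** emulate: cluster/stratum sampling weights
(samples are self-weighting), item nonresponse, spatial correlation between
districts, and idiosyncratic inter-asset correlation beyond the single
factor. Passing tests therefore demonstrate correctness of the pipeline and
recoverability under a clean one-factor world, not robustness of the asset
index to real-survey violations of that premise.

## Numerical choices and problem sizes

* PC1 via `numpy.linalg.eigh` of the correlation matrix; tests check it
  against an independent power-iteration oracle (1e−6 after sign
  alignment) and scikit-learn's PCA.
* Degenerate inputs fail loudly: constant vectors for ρ, empty retained
  sets, zero-sum variable columns, nonpositive populations. Identical share
  columns are reported as "degenerate: identical" rather than raising.
* Unit tests run small designs (4–12 districts, 100–400 households); the
  full 26 × 1,200 design is exercised once per session in shared fixtures
  and ten times (ten seeds) in the latent-SES recovery check, where the
  median recovery ρ exceeds 0.99 against a ≥ 0.9 requirement.
* Hypothesis property tests are derandomized for reproducibility.

## Limitations

* The published scoring table cannot be reproduced numerically (the survey
  microdata are not deposited); it is used as fixed input and for internal
  consistency checks (binary-variable SD ≈ √(m(1−m)) at printed precision).
* Monetary allocations under the four-variable production formula are not
  reproduced (policy weights and two variables' data are unpublished).
* The printed normalized indices carry 3 dp, so recomputed
  weighted populations agree with the printed ones only to ≈0.02%; share
  computations therefore use the printed weighted-population columns, which
  embed the unrounded indices.
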