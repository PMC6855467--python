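# Methods

## Model and estimation

The hybrid flammability-limit model is linear in its coefficients but
nonlinear in the descriptors: an intercept and linear block (multiple
linear regression), powers of the descriptor sum `ω = Σᵢ Xᵢ` (the
polynomial block), products `ω·Xᵢ` (MLR × polynomial interactions),
logarithms `ln Xᵢ`, and cross products `Xⱼ ln Xᵢ` (MLR × logarithmic
interactions). The polynomial × logarithmic interaction family is omitted
by design: it contributes no predictive value in this model class, and
leaving it out keeps the column-count relation `p = 1 + 2n + m + k + n²`
exact. Column order is fixed (intercept, linear, polynomial, interaction,
log, cross) so coefficient vectors are comparable across fits.

Two readings of the polynomial block are supported. `global_sum` (the
default) uses powers `ω, ω², …, ω^D` of the full descriptor sum — the
literal hybrid layout. `pairwise_sum` uses powers of pairwise descriptor
sums `(Xᵢ + Xⱼ)^d`, the shape visible in the published compact equations
(e.g. `(AAC + PW5)` factors). A `poly_min_degree` knob exists because
degree-1 sums — and `ω` itself — lie in the span of the linear columns:
the literal layout is therefore structurally rank-deficient (harmless for
prediction, see below), while ground-truth specs used for coefficient
recovery start pairwise powers at degree 2 to stay identifiable.

**Estimation.** `Θ̂` minimises `‖Y − ΨΘ‖²`. The textbook normal-equations
form `(Ψ′Ψ)⁻¹Ψ′Y` is not computable whenever `p ≥ N` or the design is
structurally collinear — both routine here (the cross family alone has
`n²` columns) — so the default solver is SVD-based (`numpy.linalg.lstsq`)
and returns the **minimum-norm** minimiser, reporting the effective rank.
Structural collinearity then costs nothing for prediction: any null-space
ambiguity of the training design is a null vector of the design built
from *any* rows, because the dependencies (`ω = Σᵢ Xᵢ`,
`Σᵢ ωXᵢ = ω²`) hold identically in the data. The normal-equations path is
kept behind `method="normal"` for full-rank pedagogical use and raises on
singular designs rather than regularising silently.

**Log eligibility.** `ln Xᵢ` and `Xⱼ ln Xᵢ` columns are generated only
for descriptors strictly positive on the rows used to build the design
(the training rows); the mask travels with the term labels, so the exact
same columns are rebuilt for held-out compounds, and a non-positive value
reaching a stored log term raises an error naming the compound and
descriptor. An optional `ln(x + ε)` shift exists but is off by default:
silently shifting would corrupt the coefficients' meaning.

## Pruning

Backward elimination removes one term per step and refits:

* when residual degrees of freedom exist and the retained design has full
  column rank, the term with the largest OLS p-value (smallest |t|) goes;
* otherwise (the `p ≥ N` regime, or a numerically perfect fit where every
  t-ratio is 0/0) the ranking falls back to the drop-one training-R²
  change, removing the term whose loss hurts the fit least.

Stopping is either "all survivors significant at α" (`alpha_level`) or "a
requested coefficient count" (`target_count`); both are exposed because a
significance threshold and a coefficient budget are equally defensible
simplification policies. Ties are broken toward dropping the later
column, so runs are deterministic. Because successive models are nested
least-squares fits, the training-R² trace is non-increasing — this is
asserted in tests, with each trace entry audited against an independent
refit. Pruning uses training rows only; test rows never influence term
selection.

## Accuracy metrics

ARD, AARD and AAE are implemented exactly as printed in this literature,
all with a leading `100/N`: ARD is the signed mean relative deviation (it
can cancel to zero), AARD the absolute version (AARD ≥ |ARD| always, zero
iff predictions are exact), and AAE carries the literal factor 100 even
though its argument is an absolute error in vol % — `scale=1` recovers
the conventional mean absolute error. The variance statistic is offered
in two variants because the printed formula uses deviations of the
*calculated* values about their own mean, which measures the spread of
predictions rather than their error; the `residual` variant (variance of
`cal − exp`) is the one that shrinks as a model improves, and reports
carry both. R², which this literature reports without defining, is the
coefficient of determination `100·(1 − SS_res/SS_tot)` (negative values
possible on held-out data); a squared-Pearson variant sits behind a flag.

## Train/test splitting

Splits are uniform random without replacement, deterministic given a
seed, with train size `round-half-up(fraction·N)`. Round-half-up is
deliberate: at the published dataset sizes it yields exactly 846/211 of
1057 and 412/103 of 515 at fraction 0.8 (845.6 rounds up). Whether the
original 80/20 split was stratified is unknowable from the reported
material; uniform random is assumed and documented rather than guessed as
intent.

## Synthetic data

The generator emulates the statistical shape of real descriptor–property
tables: strictly positive descriptors (uniform on (0.1, 3) by default,
the order-unity range typical of topological and information indices, so
log terms are numerically tame; a lognormal law is available for
heavier-tailed blocks) and a property built from a known sparse hybrid
model plus Gaussian noise. Defaults are desk-scale — 200 compounds, 10
descriptors, sparsity 0.3, noise 0.05 — with the non-intercept signal
rescaled to unit standard deviation so `noise_sd` reads directly as a
fraction of signal scale, and the intercept shifted so noise-free
property values stay above 0.5 vol % (preserving the positivity invariant
of flammability limits). `s1_like_config`/`s2_like_config` produce tables
at the published supplement dimensions (1057 × 105 and 515 × 82) for
dimension- and split-level checks; their generating spec omits the cross
family, whose 105² columns would add cost without adding information to
those checks.

What the generator does **not** emulate: inter-descriptor correlation of
real descriptor software blocks, heavy-tailed property errors, or any
structure–property relationship. Passing tests therefore demonstrate the
correctness of the machinery (design construction, minimum-norm
estimation, pruning order, metric algebra, determinism) — not predictive
accuracy on real compounds, which depends on descriptor quality and
applicability domain.

## Published compact equations

The 11-term LFL and 10-term UFL estimators are stored as declarative term
tables — coefficient plus a product of (linear-combination, power)
factors — at exactly their printed precision, so each term can be audited
against its source. Two textual wrinkles are handled explicitly: the LFL
equation has no constant term (it vanishes at the descriptor origin,
asserted in tests), and the final UFL term is printed with the symbol
"Jhet" where every other occurrence is "Jhetv"; it is evaluated as Jhetv
by default with a `jhet=` override for the literal reading. The scalar
evaluators route through the same numpy ufunc kernels as the vectorised
batch path (numpy's scalar power can differ from the array kernel by one
ulp), so scalar and batch predictions agree bitwise.

## Numerical choices and edge cases

* Descriptors are never standardised before fitting: the compact
  published equations are in raw descriptor units, and standardisation
  would break coefficient comparability.
* Model files are JSON with shortest-round-trip float reprs; save → load →
  predict is bit-identical. CSV I/O writes reprs and parses with
  round-trip float precision for lossless table round-trips.
* Degenerate inputs fail loudly: non-finite design entries, zero
  experimental values in relative metrics (index named), constant
  experimental vectors in R², fewer than two points in variance, empty
  train or test partitions.
* Datasets are validated strictly by default (missing/non-numeric entries
  reject the file); a lenient mode drops offending rows with a logged
  count. Imputation is out of scope by design.

## Problem sizes

Tests and the acceptance script run on generated tables of 30–2000 rows
and up to 1057 × 105 at reduced term counts; a full literal hybrid design
at 105 descriptors (≈ 11 300 columns) is supported by the same code path
and costs minutes of SVD time. The reported coefficient counts in the
source literature for the full-scale LFL/UFL fits (6421 and 12481) cannot
be reconciled with `p = 1 + 2n + m + k + n²` at n = 105 or n = 82 under
any reading of m and k; this discrepancy is documented rather than
resolved, and both pruning stop rules are exposed so either count could
be targeted.

## Known limitations

Descriptor computation from structures is out of scope — tables must come
from descriptor software. No regularised estimation, prediction
intervals, or applicability-domain analysis is provided; minimum-norm
least squares on a `p > N` design interpolates the training data, so
held-out metrics are the only honest accuracy signal in that regime.
Whole-dataset metrics mix training and test rows and are reported for
comparability with this literature's convention, not as validation.
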