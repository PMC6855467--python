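# flamqspr

Hybrid QSPR models for the flammability limits of pure compounds.

The lower and upper flammability limits (LFL/UFL) — the lowest and highest
fuel concentration in air, in volume percent, that can propagate a flame —
are central hazard properties of volatile chemicals, and measuring them is
slow and expensive. Quantitative structure–property relationship (QSPR)
models estimate them instead from numeric **molecular descriptors**
(topological indices, information contents, autocorrelations, …) computed
from structure by descriptor software such as Dragon. This package is for
process-safety and cheminformatics practitioners who have such descriptor
tables and want calibrated, auditable flammability-limit regressions.

## The model

Given descriptors `X₁ … Xₙ` and property `Y` (vol %), the hybrid model
pools five coefficient families in one linear-in-parameters fit:

```
Y = α₀ + Σᵢ αᵢXᵢ  +  Σ_d γ_d ω^d  +  Σᵢ δᵢ ωXᵢ  +  Σᵢ βᵢ ln Xᵢ  +  Σⱼᵢ λⱼᵢ Xⱼ ln Xᵢ  + ε
```

with `ω = Σᵢ Xᵢ` the descriptor sum. With every family active the design
matrix Ψ has `p = 1 + 2n + m + k + n²` columns (`m` polynomial powers, `k`
interactions, `n²` cross terms). Because `p` routinely exceeds the number
of training compounds `N`, coefficients are estimated as the
**minimum-norm least-squares solution** `Θ̂ = Ψ⁺Y` via SVD rather than the
normal equations, and then simplified by **backward elimination**: the
least significant coefficient (by |t|-statistic, or drop-one-R² change
when no residual degrees of freedom exist) is removed and the model refit,
until all survivors are significant at a chosen level or a target count is
reached. Accuracy is reported with the field's panel — R², ARD, AARD, AAE
and σ², the relative metrics carrying a leading 100/N factor.

Two published compact estimators ship ready to use: an 11-term LFL
equation in SIC0, AAC, PW5 and GATS1v, and a 10-term UFL equation in
MLOGP, Jhetv, PW5, SIC0 and MATS4m, both stored as declarative term tables
at printed coefficient precision.

A synthetic-data module generates descriptor tables from a known sparse
hybrid model, so every stage (design construction, fitting, pruning,
metrics) is testable for exact recovery without any licensed data.

## Worked example

`examples/01_fit_hybrid_model.py` draws a 200-compound table with 10
descriptors whose LFL follows a known 141-term hybrid model plus 5% noise,
then runs the 80/20 training protocol:

```
table: 200 compounds x 10 descriptors (141 generating terms)
fitted 141 terms, effective rank 141
train: R2 =  99.96 %   ARD =  0.000 %   AARD =  0.51 %   AAE =   1.46
 test: R2 =  95.06 %   ARD = -0.182 %   AARD =  4.76 %   AAE =  15.87
whole: R2 =  98.95 %   ARD = -0.036 %   AARD =  1.36 %   AAE =   4.34
```

R² near 100% with AARD ~1% on the whole set means the fit explains nearly
all property variance with average relative errors of about one percent;
the train/test gap is the expected optimism of a 141-term model fit on 160
compounds. The other examples show the published compact equations
(`02`), the backward-elimination trace on a known null coefficient (`03`),
and the anatomy of the design matrix, including the `1 + 2n + m + k + n²`
column count (`04`).

The same workflow is available from the shell:

```bash
flamqspr simulate --out-dir sim --seed 5
flamqspr fit --input sim/synthetic.csv --property LFL --seed 7 \
             --model-out model.json --metrics-out metrics.json
flamqspr published-predict --property ufl --input my_descriptors.csv
```

## Data format

Input tables are CSV/TSV (header row, `.` decimal separator) or XLSX: one
identifier column, one property column (vol %), and numeric descriptor
columns for everything else. Validation is strict by default — missing or
non-numeric entries reject the file (`lenient=True` drops such rows with a
logged count), duplicate compound identifiers are always an error, and
LFL/UFL values must be positive.
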