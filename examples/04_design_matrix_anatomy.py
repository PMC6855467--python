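"""Anatomy of the hybrid design matrix.

Shows how the five term families expand three descriptors into the full
hybrid design, and that the column count obeys p = 1 + 2n + m + k + n²
when every family is on.
"""

import numpy as np

from flamqspr import DescriptorDataset, HybridTermSpec, build_design_matrix, term_count

ds = DescriptorDataset(
    compound_ids=["methanol", "ethanol", "propanol", "butanol"],
    descriptor_names=["SIC0", "AAC", "PW5"],
    X=np.array([
        [0.58, 1.20, 0.31],
        [0.62, 1.10, 0.38],
        [0.66, 1.05, 0.42],
        [0.69, 1.02, 0.45],
    ]),
    Y=np.array([6.0, 3.3, 2.2, 1.7]),  # LFL, vol %
    property_name="LFL",
)

spec = HybridTermSpec(poly_degree_max=2)  # omega and omega^2
design = build_design_matrix(ds, spec)

n = ds.n_descriptors
print(f"n = {n} descriptors -> p = {design.n_columns} columns "
      f"(1 + 2n + m + k + n^2 = {term_count(spec, n)})")
for fam in ("intercept", "linear", "poly", "interaction", "log", "cross"):
    cols = [t for lbl, t in zip(design.column_labels, design.label_texts())
            if lbl[0] == fam]
    print(f"  {fam:<11} {len(cols):2d} column(s): {', '.join(cols[:4])}"
          + (" ..." if len(cols) > 4 else ""))

# Each family maps to one coefficient block of the hybrid model: intercept
# and linear terms to the MLR part, omega powers to the polynomial part,
# omega*X_i to the MLR x polynomial interactions, ln X_i to the logarithmic
# part, and X_j ln X_i to the MLR x logarithmic interactions.
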