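"""Hybrid design-matrix construction.

The hybrid QSPR model augments ordinary multiple linear regression with
three further term families built from the same descriptors:

* **polynomial** terms in the descriptor sum ``ω = Σ_i X_i`` (powers
  ``ω, ω², …, ω^D``), or — in ``pairwise_sum`` mode — powers of pairwise
  descriptor sums ``(X_i + X_j)^d``, the shape visible in the published
  compact flammability equations;
* **interaction** terms ``ω·X_i`` coupling the polynomial and linear parts;
* **logarithmic** terms ``ln X_i`` and **cross** terms ``X_j ln X_i``
  coupling the linear and logarithmic parts.

With every family enabled, a global-sum polynomial of degree ``m`` and
``k`` interactions, the design holds ``p = 1 + 2n + m + k + n²`` columns
(the intercept plus the count relation ``2n+m+k+n² = p``).  Logarithmic
and cross columns are only generated for descriptors strictly positive on
the rows used to build the matrix (the "log eligibility" mask), so the
column set is learned on training data and re-applied verbatim to new
compounds.

Coefficient families map onto the model's symbols: intercept ``α₀``,
linear ``α_i``, polynomial ``γ_i``, interaction ``δ_i``, logarithmic
``β_i``, cross ``λ_{j,i}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .datasets import DescriptorDataset

__all__ = [
    "HybridTermSpec",
    "DesignMatrix",
    "EligibilityError",
    "LogDomainError",
    "build_design_matrix",
    "apply_terms",
    "term_count",
    "linear_only_spec",
    "term_label_text",
]

FAMILY_SYMBOLS = {
    "intercept": "alpha0",
    "linear": "alpha",
    "poly": "gamma",
    "interaction": "delta",
    "log": "beta",
    "cross": "lambda",
}


class EligibilityError(ValueError):
    """A log/cross term was requested for a non-positive descriptor."""


class LogDomainError(ValueError):
    """A stored log term met a non-positive value at application time."""


@dataclass
class HybridTermSpec:
    """Declarative description of which term families enter the design.

    Parameters
    ----------
    include_intercept, linear, log_terms, cross_terms : bool
        Switch the α₀, α, β and λ families on or off.
    poly_mode : {"global_sum", "pairwise_sum", "none"}
        ``global_sum`` uses powers of ``ω = Σ X_i``; ``pairwise_sum`` uses
        powers of ``X_i + X_j`` over ``poly_pairs``.
    poly_degree_max : int
        Highest power D of the ω features (``m = D`` in global mode).
    poly_min_degree : int
        Lowest ω power generated (default 1, the literal hybrid layout).
        Degree-1 sums are linear combinations of the linear columns, so
        identifiable ground-truth specs start at 2.
    poly_pairs : list of (i, j) or None
        Descriptor index pairs for ``pairwise_sum``; defaults to adjacent
        pairs (0,1), (2,3), …
    interaction_k : int or None
        Number of ω·X_i interaction columns; ``None`` means one per
        descriptor (k = n).
    log_epsilon : float or None
        When set, log terms use ``ln(x + ε)`` and every descriptor is
        eligible; default off (strict positivity).
    """

    include_intercept: bool = True
    linear: bool = True
    poly_mode: str = "global_sum"
    poly_degree_max: int = 2
    poly_min_degree: int = 1
    poly_pairs: list[tuple[int, int]] | None = None
    interaction: bool = True
    interaction_k: int | None = None
    log_terms: bool = True
    cross_terms: bool = True
    log_epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.poly_mode not in ("global_sum", "pairwise_sum", "none"):
            raise ValueError(f"unknown poly_mode {self.poly_mode!r}")
        if self.poly_mode != "none":
            if self.poly_degree_max < 1:
                raise ValueError("poly_degree_max must be >= 1")
            if not 1 <= self.poly_min_degree <= self.poly_degree_max:
                raise ValueError("need 1 <= poly_min_degree <= poly_degree_max")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if d["poly_pairs"] is not None:
            d["poly_pairs"] = [list(p) for p in d["poly_pairs"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HybridTermSpec":
        d = dict(d)
        if d.get("poly_pairs") is not None:
            d["poly_pairs"] = [tuple(p) for p in d["poly_pairs"]]
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HybridTermSpec":
        return cls.from_dict(json.loads(text))

    # -- helpers -------------------------------------------------------
    def resolved_pairs(self, n: int) -> list[tuple[int, int]]:
        if self.poly_pairs is not None:
            return [tuple(p) for p in self.poly_pairs]
        return [(i, i + 1) for i in range(0, n - 1, 2)]

    def resolved_k(self, n: int) -> int:
        if not self.interaction:
            return 0
        k = n if self.interaction_k is None else self.interaction_k
        if k < 0 or k > n:
            raise ValueError(f"interaction_k must be in [0, n={n}], got {k}")
        return k

    def poly_degrees(self) -> range:
        return range(self.poly_min_degree, self.poly_degree_max + 1)

    def poly_m(self, n: int) -> int:
        if self.poly_mode == "none":
            return 0
        n_deg = len(self.poly_degrees())
        if self.poly_mode == "global_sum":
            return n_deg
        return n_deg * len(self.resolved_pairs(n))


def linear_only_spec() -> HybridTermSpec:
    """Spec reducing the design to plain MLR: ``Ψ = [1 | X]``."""
    return HybridTermSpec(
        include_intercept=True,
        linear=True,
        poly_mode="none",
        interaction=False,
        log_terms=False,
        cross_terms=False,
    )


@dataclass
class DesignMatrix:
    """Realized design Ψ plus the per-column term labels that rebuild it.

    Labels are small JSON-friendly tuples:

    =============  =========================  ==========
    label          column value               family
    =============  =========================  ==========
    (intercept,)   1                          α₀
    (linear, i)    X_i                        α
    (poly, d)      ω^d, ω = Σ X_i             γ
    (poly_pair,    (X_i + X_j)^d              γ
     i, j, d)
    (interaction,  ω·X_i                      δ
     i)
    (log, i)       ln X_i                     β
    (cross, j, i)  X_j · ln X_i               λ
    =============  =========================  ==========
    """

    values: np.ndarray
    column_labels: list[tuple]
    descriptor_names: list[str]
    log_eligibility: np.ndarray
    log_epsilon: float | None = None
    spec: HybridTermSpec | None = None

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def label_texts(self) -> list[str]:
        return [term_label_text(lbl, self.descriptor_names) for lbl in self.column_labels]


def term_label_text(label: tuple, names: list[str]) -> str:
    """Human-readable form of a term label, e.g. ``SIC0*ln(PW5)``."""
    kind = label[0]
    if kind == "intercept":
        return "1"
    if kind == "linear":
        return names[label[1]]
    if kind == "poly":
        return "omega" if label[1] == 1 else f"omega^{label[1]}"
    if kind == "poly_pair":
        i, j, d = label[1], label[2], label[3]
        base = f"({names[i]}+{names[j]})"
        return base if d == 1 else f"{base}^{d}"
    if kind == "interaction":
        return f"omega*{names[label[1]]}"
    if kind == "log":
        return f"ln({names[label[1]]})"
    if kind == "cross":
        return f"{names[label[1]]}*ln({names[label[2]]})"
    raise ValueError(f"unknown term label {label!r}")


def term_family(label: tuple) -> str:
    kind = label[0]
    return "poly" if kind == "poly_pair" else kind


def _make_labels(spec: HybridTermSpec, n: int, eligible: np.ndarray) -> list[tuple]:
    labels: list[tuple] = []
    if spec.include_intercept:
        labels.append(("intercept",))
    if spec.linear:
        labels.extend(("linear", i) for i in range(n))
    if spec.poly_mode == "global_sum":
        labels.extend(("poly", d) for d in spec.poly_degrees())
    elif spec.poly_mode == "pairwise_sum":
        for (i, j) in spec.resolved_pairs(n):
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"poly pair ({i},{j}) out of range for n={n}")
            labels.extend(("poly_pair", i, j, d) for d in spec.poly_degrees())
    labels.extend(("interaction", i) for i in range(spec.resolved_k(n)))
    if spec.log_terms:
        labels.extend(("log", i) for i in range(n) if eligible[i])
    if spec.cross_terms:
        labels.extend(
            ("cross", j, i) for j in range(n) for i in range(n) if eligible[i]
        )
    return labels


def _safe_log(
    x: np.ndarray, name: str, epsilon: float | None, row_ids=None
) -> np.ndarray:
    if epsilon is not None:
        return np.log(x + epsilon)
    if np.any(x <= 0):
        row = int(np.nonzero(x <= 0)[0][0])
        who = f"compound {row_ids[row]!r}" if row_ids is not None else f"row {row}"
        raise LogDomainError(
            f"descriptor {name!r} is non-positive at {who}; "
            "cannot evaluate its log term"
        )
    return np.log(x)


def apply_terms(
    labels: list[tuple],
    X: np.ndarray,
    descriptor_names: list[str],
    log_epsilon: float | None = None,
    row_ids=None,
) -> np.ndarray:
    """Evaluate stored term labels on a descriptor matrix.

    This is the re-application contract: the same labels evaluated on the
    training rows regenerate Ψ exactly, and on held-out rows produce the
    prediction design.  Raises :class:`LogDomainError` when a log term
    meets a non-positive value (unless an ε-shift is configured).
    """
    X = np.asarray(X, dtype=float)
    N, n = X.shape
    omega = X.sum(axis=1)
    logs: dict[int, np.ndarray] = {}

    def log_col(i: int) -> np.ndarray:
        if i not in logs:
            logs[i] = _safe_log(X[:, i], descriptor_names[i], log_epsilon, row_ids)
        return logs[i]

    cols = np.empty((N, len(labels)), dtype=float)
    for c, lbl in enumerate(labels):
        kind = lbl[0]
        if kind == "intercept":
            cols[:, c] = 1.0
        elif kind == "linear":
            cols[:, c] = X[:, lbl[1]]
        elif kind == "poly":
            cols[:, c] = omega ** lbl[1]
        elif kind == "poly_pair":
            cols[:, c] = (X[:, lbl[1]] + X[:, lbl[2]]) ** lbl[3]
        elif kind == "interaction":
            cols[:, c] = omega * X[:, lbl[1]]
        elif kind == "log":
            cols[:, c] = log_col(lbl[1])
        elif kind == "cross":
            cols[:, c] = X[:, lbl[1]] * log_col(lbl[2])
        else:
            raise ValueError(f"unknown term label {lbl!r}")
    return cols


def build_design_matrix(
    ds: DescriptorDataset,
    spec: HybridTermSpec,
    log_eligibility: np.ndarray | None = None,
) -> DesignMatrix:
    """Build Ψ from a dataset's descriptors under a term spec.

    Log eligibility is computed from the rows being transformed (strict
    minimum > 0) unless an explicit mask is supplied — supply the training
    mask when transforming held-out rows.  Forcing eligibility on a
    descriptor with non-positive values raises :class:`EligibilityError`.
    """
    X = ds.X
    n = ds.n_descriptors
    if spec.log_epsilon is not None:
        eligible = np.ones(n, dtype=bool)
    elif log_eligibility is not None:
        eligible = np.asarray(log_eligibility, dtype=bool)
        if eligible.shape != (n,):
            raise ValueError("log_eligibility must have one flag per descriptor")
        needs_log = spec.log_terms or spec.cross_terms
        if needs_log:
            mins = X.min(axis=0)
            bad = [ds.descriptor_names[i] for i in range(n) if eligible[i] and mins[i] <= 0]
            if bad:
                raise EligibilityError(
                    f"descriptors {bad} have non-positive values; cannot take ln "
                    "(enable log_epsilon to shift)"
                )
    else:
        eligible = X.min(axis=0) > 0

    labels = _make_labels(spec, n, eligible)
    values = apply_terms(labels, X, ds.descriptor_names, spec.log_epsilon)
    return DesignMatrix(
        values=values,
        column_labels=labels,
        descriptor_names=list(ds.descriptor_names),
        log_eligibility=eligible,
        log_epsilon=spec.log_epsilon,
        spec=spec,
    )


def term_count(spec: HybridTermSpec, n: int) -> int:
    """Column count p for the fully log-eligible case.

    With every family on, global-sum polynomials and intercept included,
    this is ``1 + 2n + m + k + n²``.
    """
    p = 0
    if spec.include_intercept:
        p += 1
    if spec.linear:
        p += n
    p += spec.poly_m(n)
    p += spec.resolved_k(n)
    if spec.log_terms:
        p += n
    if spec.cross_terms:
        p += n * n
    return p
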