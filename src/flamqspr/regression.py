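"""Least-squares estimation, significance pruning and prediction.

The hybrid model is linear in its coefficients, so estimation is ordinary
least squares on the expanded design: ``Θ̂ = argmin ‖Y − ΨΘ‖²``.  Because
the expansion can produce more columns than training compounds (the cross
family alone contributes n² terms), Ψ′Ψ is routinely singular and the
textbook normal-equations solution ``(Ψ′Ψ)⁻¹Ψ′Y`` is not computable; the
default solver therefore returns the **minimum-norm** least-squares
solution via a singular-value decomposition and reports the effective
rank.  The normal-equations path is kept behind ``method="normal"`` for
full-rank pedagogical use.

Model simplification follows backward elimination: repeatedly remove the
coefficient whose loss hurts training fit least — ranked by |t|-statistic
when residual degrees of freedom exist, by drop-one R² change otherwise —
refitting after every removal, until either all survivors are significant
at a chosen level or a requested coefficient count is reached.  Each
removal is recorded in a pruning trace; because the models are nested the
training-R² trace is non-increasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .datasets import DescriptorDataset, split_dataset
from .features import (
    DesignMatrix,
    HybridTermSpec,
    apply_terms,
    build_design_matrix,
    term_label_text,
)
from .metrics import MetricsReport, r2 as r2_metric

__all__ = [
    "FittedHybridModel",
    "FitReport",
    "fit_least_squares",
    "predict",
    "prune_coefficients",
    "run_training_protocol",
    "save_model",
    "load_model",
]


@dataclass
class FittedHybridModel:
    """Coefficient vector Θ̂ aligned with its term labels.

    ``term_labels`` fully determine how to rebuild design columns on new
    data, so a saved model predicts without refitting.  ``meta`` carries
    training provenance: dataset fingerprint, split seed, solver rank and
    the pruning trace.
    """

    coefficients: np.ndarray
    term_labels: list[tuple]
    descriptor_names: list[str]
    log_epsilon: float | None = None
    spec: HybridTermSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.term_labels),):
            raise ValueError("coefficient count must equal term-label count")

    @property
    def n_terms(self) -> int:
        return len(self.term_labels)

    def term_texts(self) -> list[str]:
        return [term_label_text(lbl, self.descriptor_names) for lbl in self.term_labels]


@dataclass
class FitReport:
    """Residuals and the train/test/whole accuracy panels of one run."""

    residuals: np.ndarray
    reports: dict[str, MetricsReport]
    rank: int
    pruning_trace: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "reports": {k: v.to_dict() for k, v in self.reports.items()},
            "pruning_trace": self.pruning_trace,
        }


def _check_finite(A: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{what} contains non-finite entries")


def _solve(values: np.ndarray, y: np.ndarray, method: str) -> tuple[np.ndarray, int]:
    if method == "svd":
        coef, _, rank, _ = np.linalg.lstsq(values, y, rcond=None)
        return coef, int(rank)
    if method == "normal":
        # Literal (Ψ'Ψ)⁻¹Ψ'Y; only valid at full column rank.
        gram = values.T @ values
        coef = np.linalg.solve(gram, values.T @ y)
        return coef, values.shape[1]
    raise ValueError(f"unknown solver method {method!r}")


def fit_least_squares(
    design: DesignMatrix, Y, method: str = "svd"
) -> FittedHybridModel:
    """Fit Θ̂ by (minimum-norm) least squares.

    Among all coefficient vectors minimising ``‖Y − ΨΘ‖²`` the SVD path
    returns the one of smallest Euclidean norm; no explicit inverse of
    Ψ′Ψ is ever formed.
    """
    y = np.asarray(Y, dtype=float).ravel()
    if design.values.shape[0] != y.shape[0]:
        raise ValueError(
            f"design has {design.values.shape[0]} rows but Y has {y.shape[0]}"
        )
    _check_finite(design.values, "design matrix")
    _check_finite(y, "Y")
    coef, rank = _solve(design.values, y, method)
    return FittedHybridModel(
        coefficients=coef,
        term_labels=list(design.column_labels),
        descriptor_names=list(design.descriptor_names),
        log_epsilon=design.log_epsilon,
        spec=design.spec,
        meta={"rank": rank, "n_train_rows": int(y.shape[0]), "solver": method},
    )


def _model_design(model: FittedHybridModel, ds: DescriptorDataset) -> np.ndarray:
    col_idx = [ds.descriptor_index(name) for name in model.descriptor_names]
    X = ds.X[:, col_idx]
    return apply_terms(
        model.term_labels,
        X,
        model.descriptor_names,
        model.log_epsilon,
        row_ids=ds.compound_ids,
    )


def predict(model: FittedHybridModel, ds: DescriptorDataset) -> np.ndarray:
    """Calculated property values ``FL_cal = Ψ(new rows)·Θ̂``.

    Raises a schema error when a required descriptor column is absent and
    a domain error (naming compound and descriptor) when a stored log
    term meets a non-positive value.
    """
    return _model_design(model, ds) @ model.coefficients


# ---------------------------------------------------------------------------
# backward elimination


def _train_r2(values: np.ndarray, y: np.ndarray) -> float:
    coef, _ = _solve(values, y, "svd")
    return r2_metric(values @ coef, y)


def _drop_one_choice(values: np.ndarray, y: np.ndarray) -> tuple[int, float]:
    """Index whose removal least reduces training R² (ties drop the later column)."""
    best_c, best_r2 = 0, -np.inf
    for c in range(values.shape[1]):
        r = _train_r2(np.delete(values, c, axis=1), y)
        if r >= best_r2:
            best_c, best_r2 = c, r
    return best_c, best_r2


def _t_test_choice(values: np.ndarray, y: np.ndarray) -> tuple[int, float] | None:
    """Least-significant column by OLS p-value, or None when t-tests are undefined.

    Undefined when there are no residual degrees of freedom, the design is
    column-rank-deficient, or the fit is numerically perfect (zero residual
    variance makes every t-ratio 0/0).
    """
    N, p = values.shape
    if N - p < 1:
        return None
    if np.linalg.matrix_rank(values) < p:
        return None
    res = sm.OLS(y, values).fit()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0 or float(res.ssr) <= 1e-12 * ss_tot:
        return None
    pvals = np.nan_to_num(np.asarray(res.pvalues), nan=1.0)
    # ties broken toward dropping the later column (earlier retained)
    worst = int(np.flatnonzero(pvals == pvals.max())[-1])
    return worst, float(pvals[worst])


def prune_coefficients(
    model: FittedHybridModel,
    train_ds: DescriptorDataset,
    mode: str,
    value: float,
) -> FittedHybridModel:
    """Backward elimination of insignificant coefficients, refitting each step.

    ``mode="alpha_level"`` removes terms until every survivor has OLS
    p-value ≤ ``value`` (falling back to drop-one-R² ranking while t-tests
    are undefined, e.g. when p ≥ N); ``mode="target_count"`` removes terms
    until ``value`` coefficients remain.  Returns a new model whose meta
    records the pruning trace ``[{dropped, train_r2, n_terms}, …]``.
    """
    if mode not in ("alpha_level", "target_count"):
        raise ValueError(f"unknown pruning mode {mode!r}")
    labels = list(model.term_labels)
    if mode == "target_count":
        target = int(value)
        if target < 1 or target > len(labels):
            raise ValueError(
                f"target_count must be in [1, {len(labels)}], got {target}"
            )

    values = apply_terms(
        labels,
        train_ds.X[:, [train_ds.descriptor_index(n) for n in model.descriptor_names]],
        model.descriptor_names,
        model.log_epsilon,
    )
    y = train_ds.Y
    trace: list[dict] = []

    while len(labels) > 1:
        if mode == "target_count" and len(labels) <= target:
            break
        choice = _t_test_choice(values, y)
        if mode == "alpha_level":
            if choice is not None:
                c, pval = choice
                if pval <= value:
                    break
            else:
                # no residual df / perfect fit: shed the cheapest term
                c, _ = _drop_one_choice(values, y)
        else:
            c = choice[0] if choice is not None else _drop_one_choice(values, y)[0]
        dropped = labels.pop(c)
        values = np.delete(values, c, axis=1)
        trace.append(
            {
                "dropped": term_label_text(dropped, model.descriptor_names),
                "train_r2": _train_r2(values, y),
                "n_terms": len(labels),
            }
        )

    coef, rank = _solve(values, y, "svd")
    meta = dict(model.meta)
    meta.update({"rank": rank, "pruning_trace": trace, "pruning_mode": mode})
    return FittedHybridModel(
        coefficients=coef,
        term_labels=labels,
        descriptor_names=list(model.descriptor_names),
        log_epsilon=model.log_epsilon,
        spec=model.spec,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# end-to-end protocol


def run_training_protocol(
    ds: DescriptorDataset,
    spec: HybridTermSpec,
    fraction: float = 0.8,
    seed: int = 0,
    prune_mode: str | None = None,
    prune_value: float | None = None,
    method: str = "svd",
) -> tuple[FittedHybridModel, FitReport]:
    """Split → build Ψ on training rows → fit → (prune) → evaluate.

    Accuracy panels are computed on the training set, the held-out test
    set, and the whole dataset, mirroring how flammability QSPR models
    are reported.  Deterministic given ``seed``.
    """
    split = split_dataset(ds, fraction=fraction, seed=seed)
    train = ds.subset(split.train_idx)
    test = ds.subset(split.test_idx)

    design = build_design_matrix(train, spec)
    model = fit_least_squares(design, train.Y, method=method)
    fingerprint = f"{ds.n_compounds}x{ds.n_descriptors}:{float(ds.X.sum()):.6g}"
    model.meta.update(
        {
            "dataset_fingerprint": fingerprint,
            "split_seed": seed,
            "split_fraction": fraction,
            "n_train": train.n_compounds,
            "n_test": test.n_compounds,
        }
    )
    if prune_mode is not None:
        if prune_value is None:
            raise ValueError("prune_value required when prune_mode is set")
        model = prune_coefficients(model, train, prune_mode, prune_value)

    cal_train = predict(model, train)
    cal_test = predict(model, test)
    cal_whole = predict(model, ds)
    report = FitReport(
        residuals=train.Y - cal_train,
        reports={
            "train": MetricsReport.from_pair(cal_train, train.Y),
            "test": MetricsReport.from_pair(cal_test, test.Y),
            "whole": MetricsReport.from_pair(cal_whole, ds.Y),
        },
        rank=int(model.meta.get("rank", -1)),
        pruning_trace=list(model.meta.get("pruning_trace", [])),
    )
    return model, report


# ---------------------------------------------------------------------------
# serialization (JSON keeps shortest round-trip float repr, lossless)


def save_model(model: FittedHybridModel, path) -> None:
    doc = {
        "format": "flamqspr-model",
        "version": 1,
        "descriptor_names": model.descriptor_names,
        "term_labels": [list(lbl) for lbl in model.term_labels],
        "coefficients": [float(c) for c in model.coefficients],
        "log_epsilon": model.log_epsilon,
        "spec": model.spec.to_dict() if model.spec is not None else None,
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> FittedHybridModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "flamqspr-model":
        raise ValueError(f"{path} is not a flamqspr model file")
    return FittedHybridModel(
        coefficients=np.array(doc["coefficients"], dtype=float),
        term_labels=[tuple(lbl) for lbl in doc["term_labels"]],
        descriptor_names=list(doc["descriptor_names"]),
        log_epsilon=doc.get("log_epsilon"),
        spec=HybridTermSpec.from_dict(doc["spec"]) if doc.get("spec") else None,
        meta=doc.get("meta", {}),
    )
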