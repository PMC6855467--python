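"""The two published compact flammability-limit predictors.

These are the pruned closed-form equations distilled from the hybrid
modelling pipeline: an 11-term LFL estimator in four topological /
information descriptors (SIC0, AAC, PW5, GATS1v) and a 10-term UFL
estimator in five descriptors (MLOGP, Jhetv, PW5, SIC0, MATS4m).  All
descriptor values must be supplied (e.g. from Dragon); computing them
from structures is out of scope.

The coefficients live in declarative term tables at exactly their printed
precision so each term is auditable against the source equation, rather
than being buried in inlined arithmetic.  Note one typographical wrinkle:
the final UFL term is printed with the symbol "Jhet" where every other
occurrence of that descriptor is "Jhetv"; by default it is evaluated as
Jhetv, and a ``jhet=`` override is available for anyone wanting the
literal reading with a separate value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .datasets import DatasetFormatError, DescriptorDataset

__all__ = [
    "LflDescriptorVector",
    "UflDescriptorVector",
    "LFL_TERMS",
    "UFL_TERMS",
    "lfl_eq12",
    "ufl_eq13",
    "batch_predict_published",
    "LFL_DESCRIPTORS",
    "UFL_DESCRIPTORS",
]

LFL_DESCRIPTORS = ("SIC0", "AAC", "PW5", "GATS1v")
UFL_DESCRIPTORS = ("MLOGP", "Jhetv", "PW5", "SIC0", "MATS4m")


@dataclass(frozen=True)
class Term:
    """One additive term: coefficient × Π (linear combo of descriptors)^power.

    ``factors`` is a tuple of ``(combo, power)`` where ``combo`` is a
    tuple of ``(sign, descriptor)`` entries summed before exponentiation.
    An empty ``factors`` tuple is a constant term.
    """

    coefficient: float
    factors: tuple = ()

    def evaluate(self, values: dict):
        out = self.coefficient
        for combo, power in self.factors:
            base = sum(sign * values[name] for sign, name in combo)
            out = out * base**power
        return out

    def text(self) -> str:
        if not self.factors:
            return f"{self.coefficient}"
        parts = []
        for combo, power in self.factors:
            if len(combo) == 1 and combo[0][0] == 1:
                base = combo[0][1]
            else:
                base = "(" + "".join(
                    (("+" if s > 0 else "-") if (i or s < 0) else "") + n
                    for i, (s, n) in enumerate(combo)
                ) + ")"
            parts.append(base if power == 1 else f"{base}^{power}")
        return f"{self.coefficient}*" + "*".join(parts)


def _v(name: str):  # single positive symbol
    return ((1, name),)


def _s(a: str, b: str):  # a + b
    return ((1, a), (1, b))


def _d(a: str, b: str):  # a - b
    return ((1, a), (-1, b))


# LFL estimator, 11 terms, no constant: zero descriptors give zero.
LFL_TERMS: tuple[Term, ...] = (
    Term(17.1352, ((_v("SIC0"), 1),)),
    Term(-1.8536, ((_s("AAC", "PW5"), 1),)),
    Term(1.044, ((_v("AAC"), 1), (_s("AAC", "PW5"), 1))),
    Term(-11.266, ((_v("SIC0"), 1), (_s("AAC", "PW5"), 1))),
    Term(-76.4768, ((_v("PW5"), 2), (_s("AAC", "PW5"), 1))),
    Term(13.4096, ((_v("SIC0"), 2), (_s("AAC", "PW5"), 1))),
    Term(28.0829, ((_v("SIC0"), 2), (_s("SIC0", "GATS1v"), 1))),
    Term(0.032, ((_v("SIC0"), 3), (_s("SIC0", "GATS1v"), 1))),
    Term(518.4484, ((_s("AAC", "PW5"), 1), (_v("PW5"), 3))),
    Term(-9.1264, ((_s("AAC", "PW5"), 1), (_v("SIC0"), 3))),
    Term(-165.743, ((_s("PW5", "SIC0"), 1), (_v("PW5"), 2))),
)

# UFL estimator, 10 terms including the 14.011 intercept.  The last term is
# printed "(Jhet+PW5)PW5"; "Jhet" is mapped to Jhetv (see module docstring).
UFL_TERMS: tuple[Term, ...] = (
    Term(14.011),
    Term(-0.765, ((_v("MLOGP"), 1),)),
    Term(-33.853, ((_s("Jhetv", "PW5"), 1),)),
    Term(0.834, ((_s("SIC0", "MATS4m"), 1),)),
    Term(32.167, ((_d("Jhetv", "PW5"), 1),)),
    Term(-281.86, ((_v("PW5"), 2),)),
    Term(35.904, ((_v("SIC0"), 2),)),
    Term(2622.185, ((_v("PW5"), 3),)),
    Term(-23.301, ((_v("SIC0"), 3),)),
    Term(11.134, ((_s("Jhet", "PW5"), 1), (_v("PW5"), 1))),
)


@dataclass(frozen=True)
class LflDescriptorVector:
    SIC0: float
    AAC: float
    PW5: float
    GATS1v: float


@dataclass(frozen=True)
class UflDescriptorVector:
    MLOGP: float
    Jhetv: float
    PW5: float
    SIC0: float
    MATS4m: float


def _as_values(d) -> dict:
    # length-1 arrays keep the scalar path on the exact ufunc kernels the
    # vectorised path uses (numpy's scalar power can differ by 1 ulp), so
    # batch and scalar agree bitwise
    vals = {}
    for f in fields(d):
        v = float(getattr(d, f.name))
        if not math.isfinite(v):
            raise ValueError(f"descriptor {f.name} is not finite: {v}")
        vals[f.name] = np.array([v])
    return vals


def _eval_terms(terms, values: dict):
    return sum(t.evaluate(values) for t in terms)


def _scalar(value) -> float:
    return float(np.asarray(value).reshape(-1)[0])


def lfl_eq12(d: LflDescriptorVector) -> float:
    """Lower flammability limit estimate (vol %) from the compact LFL equation."""
    return _scalar(_eval_terms(LFL_TERMS, _as_values(d)))


def ufl_eq13(d: UflDescriptorVector, jhet: float | None = None) -> float:
    """Upper flammability limit estimate (vol %) from the compact UFL equation.

    ``jhet`` overrides the value used for the literal "Jhet" symbol in the
    final term; by default it is the Jhetv descriptor.
    """
    values = _as_values(d)
    values["Jhet"] = values["Jhetv"] if jhet is None else np.array([float(jhet)])
    return _scalar(_eval_terms(UFL_TERMS, values))


def batch_predict_published(
    ds: DescriptorDataset, which: str = "LFL", case_insensitive: bool = False
) -> np.ndarray:
    """Vectorised per-row evaluation of the chosen compact equation.

    The dataset must carry the equation's descriptor columns under their
    canonical names (``case_insensitive=True`` relaxes the matching).
    """
    which = which.upper()
    if which == "LFL":
        needed, terms = LFL_DESCRIPTORS, LFL_TERMS
    elif which == "UFL":
        needed, terms = UFL_DESCRIPTORS, UFL_TERMS
    else:
        raise ValueError(f"which must be 'LFL' or 'UFL', got {which!r}")

    lookup = {name: i for i, name in enumerate(ds.descriptor_names)}
    if case_insensitive:
        lookup.update({name.lower(): i for i, name in enumerate(ds.descriptor_names)})

    values: dict[str, np.ndarray] = {}
    missing = []
    for name in needed:
        key = name if name in lookup else (name.lower() if case_insensitive else None)
        if key is None or key not in lookup:
            missing.append(name)
        else:
            values[name] = ds.X[:, lookup[key]]
    if missing:
        raise DatasetFormatError(
            f"dataset lacks descriptor column(s) {missing} required for the {which} equation"
        )
    if which == "UFL":
        values["Jhet"] = values["Jhetv"]
    return np.asarray(_eval_terms(terms, values), dtype=float) + np.zeros(ds.n_compounds)
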