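"""Accuracy statistics for flammability-limit models.

All four headline statistics are implemented literally as printed in the
source model papers of this field, with a leading ``100/N`` factor on the
deviations:

.. math::

    ARD  &= \\frac{100}{N} \\sum_i \\frac{FL^{cal}_i - FL^{exp}_i}{FL^{exp}_i} \\\\
    AARD &= \\frac{100}{N} \\sum_i \\left| \\frac{FL^{cal}_i - FL^{exp}_i}{FL^{exp}_i} \\right| \\\\
    AAE  &= \\frac{100}{N} \\sum_i |FL^{cal}_i - FL^{exp}_i|

Note the AAE therefore carries the literal factor of 100 even though its
argument is an absolute (not relative) error; a ``scale=1`` call gives the
plain mean absolute error.  The variance statistic ``σ²`` is likewise
offered in two variants: the ``printed`` form, the sample variance of the
*calculated* values, and a ``residual`` form, the sample variance of the
calculated-minus-experimental differences — the latter is what actually
shrinks as a model improves.  R² is the coefficient of determination
``100·(1 − SS_res/SS_tot)`` (reported in percent); a squared-Pearson
variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "MetricsReport",
    "ard",
    "aard",
    "aae",
    "sigma2",
    "r2",
    "error_histogram",
]


class MetricsDomainError(ValueError):
    """Raised for zero experimental values or degenerate denominators."""


def _pair(cal, exp) -> tuple[np.ndarray, np.ndarray]:
    cal = np.asarray(cal, dtype=float).ravel()
    exp = np.asarray(exp, dtype=float).ravel()
    if cal.shape != exp.shape:
        raise ValueError(f"length mismatch: {cal.shape} vs {exp.shape}")
    if cal.size < 1:
        raise ValueError("need at least one point")
    return cal, exp


def _check_nonzero_exp(exp: np.ndarray) -> None:
    zeros = np.nonzero(exp == 0)[0]
    if zeros.size:
        raise MetricsDomainError(
            f"experimental value is zero at index {int(zeros[0])}; relative deviation undefined"
        )


def ard(cal, exp) -> float:
    """Average (signed) relative deviation in percent; errors may cancel."""
    cal, exp = _pair(cal, exp)
    _check_nonzero_exp(exp)
    return float(100.0 * np.mean((cal - exp) / exp))


def aard(cal, exp) -> float:
    """Average absolute relative deviation in percent; 0 iff cal == exp."""
    cal, exp = _pair(cal, exp)
    _check_nonzero_exp(exp)
    return float(100.0 * np.mean(np.abs(cal - exp) / np.abs(exp)))


def aae(cal, exp, scale: float = 100.0) -> float:
    """Average absolute error with the literal leading 100/N factor.

    ``scale=1`` gives the conventional mean absolute error in the data's
    own units (volume percent).
    """
    cal, exp = _pair(cal, exp)
    return float(scale * np.mean(np.abs(cal - exp)))


def sigma2(cal, exp=None, variant: str = "printed") -> float:
    """Sample variance statistic (divisor N−1).

    ``printed``: variance of the calculated values about their own mean.
    ``residual``: variance of (cal − exp) about its mean — requires exp.
    """
    cal = np.asarray(cal, dtype=float).ravel()
    if cal.size < 2:
        raise MetricsDomainError("sigma2 needs at least 2 points (N-1 degrees of freedom)")
    if variant == "printed":
        return float(np.var(cal, ddof=1))
    if variant == "residual":
        if exp is None:
            raise ValueError("residual variant requires experimental values")
        cal, exp = _pair(cal, exp)
        return float(np.var(cal - exp, ddof=1))
    raise ValueError(f"unknown sigma2 variant {variant!r}")


def r2(cal, exp, variant: str = "determination") -> float:
    """R² in percent.

    ``determination``: ``100·(1 − Σ(exp−cal)²/Σ(exp−mean(exp))²)``; can be
    negative on held-out data.  ``pearson``: squared Pearson correlation,
    always in [0, 100].
    """
    cal, exp = _pair(cal, exp)
    if cal.size < 2:
        raise MetricsDomainError("r2 needs at least 2 points")
    ss_tot = float(np.sum((exp - exp.mean()) ** 2))
    if ss_tot == 0.0:
        raise MetricsDomainError("experimental values are constant; R2 undefined")
    if variant == "determination":
        ss_res = float(np.sum((exp - cal) ** 2))
        return 100.0 * (1.0 - ss_res / ss_tot)
    if variant == "pearson":
        if np.std(cal) == 0.0:
            return 0.0
        return 100.0 * float(np.corrcoef(cal, exp)[0, 1] ** 2)
    raise ValueError(f"unknown r2 variant {variant!r}")


@dataclass
class MetricsReport:
    """The full accuracy panel for one (calculated, experimental) pairing."""

    r2: float
    ard: float
    aard: float
    aae: float
    sigma2_printed: float
    sigma2_residual: float
    n_points: int

    @classmethod
    def from_pair(cls, cal, exp) -> "MetricsReport":
        cal_a, exp_a = _pair(cal, exp)
        return cls(
            r2=r2(cal_a, exp_a),
            ard=ard(cal_a, exp_a),
            aard=aard(cal_a, exp_a),
            aae=aae(cal_a, exp_a),
            sigma2_printed=sigma2(cal_a, variant="printed"),
            sigma2_residual=sigma2(cal_a, exp_a, variant="residual"),
            n_points=int(cal_a.size),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def error_histogram(errors, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Bin per-compound errors for reporting plots; counts always sum to N."""
    errors = np.asarray(errors, dtype=float).ravel()
    counts, edges = np.histogram(errors, bins=bins)
    return counts, edges
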