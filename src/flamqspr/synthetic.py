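"""Synthetic descriptor tables with known hybrid-model ground truth.

Real flammability QSPR tables pair a property column of positive volume
percentages with dozens of heterogeneous, strictly positive molecular
descriptors.  This generator emulates that statistical shape without any
external data: descriptors are drawn i.i.d. from a strictly positive law
(uniform on (0.1, 3) by default, the magnitude range of order-unity
topological indices), and the property is a known sparse hybrid model of
those descriptors plus Gaussian noise.  Because the generating
coefficients are returned alongside the data, every downstream stage —
design construction, least squares, pruning, metrics — can be tested for
exact recovery, consistency and monotonicity.

The generator does not attempt to mimic inter-descriptor correlation of
real descriptor blocks; see the methods note for what that implies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import DescriptorDataset, PropertyKind, write_dataset
from .features import HybridTermSpec, build_design_matrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_true_spec",
    "generate_dataset",
    "make_fixture_suite",
    "s1_like_config",
    "s2_like_config",
]


def default_true_spec() -> HybridTermSpec:
    """Identifiable ground-truth spec: pairwise sums starting at degree 2.

    Degree-1 pairwise sums duplicate the span of the linear columns, which
    would make the generating coefficients unrecoverable even from
    noiseless data; starting at 2 keeps the design full column rank.
    """
    return HybridTermSpec(
        poly_mode="pairwise_sum",
        poly_degree_max=3,
        poly_min_degree=2,
        log_terms=True,
        cross_terms=True,
    )


@dataclass
class SyntheticConfig:
    """Recipe for one synthetic compound table.

    ``descriptor_law`` is ``("uniform_positive", lo, hi)`` with lo > 0 or
    ``("lognormal", mu, sigma)``; both guarantee strictly positive
    descriptors so log terms are always defined.  ``sparsity`` is the
    fraction of generating coefficients drawn nonzero.  The intercept is
    adjusted so noise-free property values sit above ``y_floor`` (keeping
    the LFL/UFL positivity invariant); the adjusted value is what the
    ground truth records.
    """

    N: int = 200
    n: int = 10
    descriptor_law: tuple = ("uniform_positive", 0.1, 3.0)
    true_spec: HybridTermSpec = field(default_factory=default_true_spec)
    true_coefficients: np.ndarray | None = None
    sparsity: float = 0.3
    coef_scale: float = 1.0
    signal_sd: float = 1.0
    y_floor: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0
    property_kind: PropertyKind = PropertyKind.LFL
    ensure_positive: bool = True

    def __post_init__(self) -> None:
        if self.N < 1 or self.n < 1:
            raise ValueError("N and n must be positive")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        law = self.descriptor_law[0]
        if law == "uniform_positive":
            if self.descriptor_law[1] <= 0:
                raise ValueError("uniform_positive lower bound must be > 0")
        elif law != "lognormal":
            raise ValueError(f"unknown descriptor law {law!r}")
        if self.ensure_positive and not self.true_spec.include_intercept:
            raise ValueError(
                "ensure_positive requires an intercept term in true_spec "
                "(nothing to shift otherwise)"
            )


@dataclass
class GroundTruth:
    """The generating model, for recovery tests and fixture sidecars."""

    term_labels: list[tuple]
    coefficients: np.ndarray
    descriptor_names: list[str]
    spec: HybridTermSpec
    noise_sd: float
    seed: int
    noise_free_Y: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "term_labels": [list(l) for l in self.term_labels],
                "coefficients": [float(c) for c in self.coefficients],
                "descriptor_names": self.descriptor_names,
                "spec": self.spec.to_dict(),
                "noise_sd": self.noise_sd,
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            term_labels=[tuple(l) for l in d["term_labels"]],
            coefficients=np.array(d["coefficients"], dtype=float),
            descriptor_names=list(d["descriptor_names"]),
            spec=HybridTermSpec.from_dict(d["spec"]),
            noise_sd=float(d["noise_sd"]),
            seed=int(d["seed"]),
            noise_free_Y=np.array([]),
        )


def _draw_descriptors(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    law = cfg.descriptor_law
    if law[0] == "uniform_positive":
        return rng.uniform(law[1], law[2], size=(cfg.N, cfg.n))
    return rng.lognormal(mean=law[1], sigma=law[2], size=(cfg.N, cfg.n))


def generate_dataset(cfg: SyntheticConfig) -> tuple[DescriptorDataset, GroundTruth]:
    """Draw one table: ``Y = Ψ(X; true_spec)·θ + N(0, noise_sd²)``.

    Deterministic given ``cfg.seed``.  When ``true_coefficients`` is not
    supplied a sparse vector is drawn: each coefficient is nonzero with
    probability ``sparsity``, nonzero ones uniform on ±``coef_scale``, the
    non-intercept block rescaled so the noise-free signal has standard
    deviation ``signal_sd`` (so ``noise_sd`` reads as a fraction of the
    signal scale).
    """
    rng = np.random.default_rng(cfg.seed)
    X = _draw_descriptors(cfg, rng)
    names = [f"D{i + 1:03d}" for i in range(cfg.n)]
    ids = [f"cmpd-{i + 1:04d}" for i in range(cfg.N)]

    shell = DescriptorDataset(
        compound_ids=ids,
        descriptor_names=names,
        X=X,
        Y=np.ones(cfg.N),
        property_kind=PropertyKind.OTHER,
    )
    design = build_design_matrix(shell, cfg.true_spec)
    p = design.n_columns
    labels = design.column_labels
    intercept_pos = next(
        (i for i, l in enumerate(labels) if l[0] == "intercept"), None
    )

    if cfg.true_coefficients is not None:
        coef = np.asarray(cfg.true_coefficients, dtype=float).copy()
        if coef.shape != (p,):
            raise ValueError(
                f"true_coefficients must align with the {p} generated terms, got {coef.shape}"
            )
    else:
        mask = rng.random(p) < cfg.sparsity
        if not mask.any():
            mask[rng.integers(p)] = True
        coef = np.where(mask, rng.uniform(-cfg.coef_scale, cfg.coef_scale, p), 0.0)
        rest = np.arange(p) != intercept_pos
        base = design.values[:, rest] @ coef[rest]
        sd = float(np.std(base))
        if sd > 0:
            coef[rest] *= cfg.signal_sd / sd

    if cfg.ensure_positive and intercept_pos is not None:
        rest = np.arange(p) != intercept_pos
        base = design.values[:, rest] @ coef[rest]
        coef[intercept_pos] = cfg.y_floor - float(base.min())

    noise_free = design.values @ coef
    Y = noise_free + rng.normal(0.0, cfg.noise_sd, cfg.N)
    kind = cfg.property_kind
    if kind in (PropertyKind.LFL, PropertyKind.UFL) and np.any(Y <= 0):
        raise ValueError(
            "noise pushed the property non-positive; lower noise_sd or raise y_floor"
        )
    ds = DescriptorDataset(
        compound_ids=ids,
        descriptor_names=names,
        X=X,
        Y=Y,
        property_kind=kind,
        property_name=kind.value if kind != PropertyKind.OTHER else "Y",
    )
    truth = GroundTruth(
        term_labels=list(labels),
        coefficients=coef,
        descriptor_names=names,
        spec=cfg.true_spec,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
        noise_free_Y=noise_free,
    )
    return ds, truth


def s1_like_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A table shaped like the published LFL supplement: 1057 × 105.

    The generating spec drops the cross family (105² columns would serve
    no testing purpose at this size) but keeps the other four.
    """
    kw = dict(
        N=1057,
        n=105,
        true_spec=HybridTermSpec(
            poly_mode="pairwise_sum", poly_degree_max=3, poly_min_degree=2,
            cross_terms=False,
        ),
        sparsity=0.15,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


def s2_like_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A table shaped like the published UFL supplement: 515 × 82."""
    return s1_like_config(seed, N=515, n=82, **overrides)


def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the canonical small fixtures used by the tests and docs.

    ``noise_free``   60 × 4, exact hybrid data, full column rank;
    ``noisy``        same shape with noise_sd = 0.1;
    ``rank_deficient``  30 rows whose literal hybrid design has 43 columns
                        (the p > N regime);
    ``zero_coeff``   80 × 3 linear+log model with one generating
                     coefficient exactly zero, for pruning tests.

    Each CSV gets a ``<name>.truth.json`` ground-truth sidecar.  Returns
    ``{name: csv_path}``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    small_spec = HybridTermSpec(
        poly_mode="pairwise_sum", poly_degree_max=2, poly_min_degree=2
    )
    configs = {
        "noise_free": SyntheticConfig(
            N=60, n=4, true_spec=small_spec, noise_sd=0.0, seed=seed
        ),
        "noisy": SyntheticConfig(
            N=60, n=4, true_spec=small_spec, noise_sd=0.1, seed=seed + 1
        ),
        "rank_deficient": SyntheticConfig(
            N=30,
            n=5,
            true_spec=HybridTermSpec(poly_mode="global_sum", poly_degree_max=2),
            noise_sd=0.0,
            seed=seed + 2,
        ),
        "zero_coeff": None,  # built explicitly below
    }
    paths: dict[str, Path] = {}
    for name, cfg in configs.items():
        if name == "zero_coeff":
            cfg = SyntheticConfig(
                N=80,
                n=3,
                true_spec=HybridTermSpec(
                    poly_mode="none", interaction=False, cross_terms=False
                ),
                noise_sd=0.0,
                seed=seed + 3,
            )
            # terms: intercept, 3 linear, 3 log -> zero the second linear coef
            coef = np.array([1.5, 0.8, 0.0, -0.6, 0.4, -0.3, 0.2])
            cfg.true_coefficients = coef
        ds, truth = generate_dataset(cfg)
        csv_path = out / f"{name}.csv"
        write_dataset(ds, csv_path)
        (out / f"{name}.truth.json").write_text(truth.to_json())
        paths[name] = csv_path
    return paths
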