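"""Least-squares fitting, pruning, prediction and the training protocol."""

import numpy as np
import pytest

from flamqspr import (
    DescriptorDataset,
    HybridTermSpec,
    SyntheticConfig,
    build_design_matrix,
    fit_least_squares,
    generate_dataset,
    linear_only_spec,
    load_model,
    predict,
    prune_coefficients,
    run_training_protocol,
    save_model,
)
from flamqspr.features import DesignMatrix
from flamqspr.metrics import r2
from flamqspr.regression import FittedHybridModel
from tests.conftest import load_fixture


def raw_design(values, labels=None, names=None):
    values = np.asarray(values, dtype=float)
    p = values.shape[1]
    names = names or [f"D{i}" for i in range(p)]
    labels = labels or [("linear", i) for i in range(p)]
    return DesignMatrix(
        values=values,
        column_labels=labels,
        descriptor_names=names,
        log_eligibility=np.ones(len(names), dtype=bool),
    )


class TestFit:
    def test_identity_system(self):
        model = fit_least_squares(raw_design(np.eye(2)), [3.0, 5.0])
        np.testing.assert_allclose(model.coefficients, [3.0, 5.0])

    def test_noiseless_full_rank_recovery(self, rng):
        Psi = rng.normal(size=(50, 8))
        theta = rng.normal(size=8)
        model = fit_least_squares(raw_design(Psi), Psi @ theta)
        np.testing.assert_allclose(model.coefficients, theta, atol=1e-8)
        assert model.meta["rank"] == 8

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("shape", [(5, 8), (20, 6), (12, 12)])
    def test_minimum_norm_matches_svd_pseudoinverse_oracle(self, seed, shape):
        rng = np.random.default_rng(seed)
        N, p = shape
        Psi = rng.normal(size=(N, p))
        if p > 3:
            Psi[:, -1] = Psi[:, 0] + Psi[:, 1]  # force rank deficiency
        y = rng.normal(size=N)
        model = fit_least_squares(raw_design(Psi), y)
        # independent oracle: SVD pseudo-inverse, U Σ⁺ Vᵀ applied to y
        U, s, Vt = np.linalg.svd(Psi, full_matrices=False)
        s_inv = np.where(s > s.max() * max(N, p) * np.finfo(float).eps, 1.0 / s, 0.0)
        oracle = Vt.T @ (s_inv * (U.T @ y))
        np.testing.assert_allclose(model.coefficients, oracle, atol=1e-8)

    def test_normal_equations_match_svd_at_full_rank(self, rng):
        Psi = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        a = fit_least_squares(raw_design(Psi), y, method="svd")
        b = fit_least_squares(raw_design(Psi), y, method="normal")
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-8)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_least_squares(raw_design([[np.nan, 1.0]]), [1.0])
        with pytest.raises(ValueError, match="non-finite"):
            fit_least_squares(raw_design([[1.0, 1.0]]), [np.inf])


class TestPredict:
    def test_constant_model(self, rng):
        ds, _ = generate_dataset(SyntheticConfig(N=5, n=2, seed=0))
        model = FittedHybridModel(
            coefficients=np.array([4.2]),
            term_labels=[("intercept",)],
            descriptor_names=ds.descriptor_names,
        )
        np.testing.assert_allclose(predict(model, ds), 4.2)

    def test_noiseless_interpolation(self, noiseless_pair):
        ds, truth = noiseless_pair
        design = build_design_matrix(ds, truth.spec)
        model = fit_least_squares(design, ds.Y)
        np.testing.assert_allclose(predict(model, ds), ds.Y, atol=1e-8)

    def test_row_order_invariance(self, noiseless_pair):
        ds, truth = noiseless_pair
        design = build_design_matrix(ds, truth.spec)
        model = fit_least_squares(design, ds.Y)
        perm = np.random.default_rng(0).permutation(ds.n_compounds)
        shuffled = ds.subset(perm)
        np.testing.assert_allclose(predict(model, shuffled), predict(model, ds)[perm])

    def test_save_load_round_trip_bitwise(self, tmp_path, noiseless_pair):
        ds, truth = noiseless_pair
        design = build_design_matrix(ds, truth.spec)
        model = fit_least_squares(design, ds.Y)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        np.testing.assert_array_equal(predict(back, ds), predict(model, ds))

    def test_missing_descriptor_is_schema_error(self, noiseless_pair):
        ds, truth = noiseless_pair
        model = fit_least_squares(build_design_matrix(ds, truth.spec), ds.Y)
        narrower = DescriptorDataset(
            compound_ids=ds.compound_ids,
            descriptor_names=ds.descriptor_names[:-1],
            X=ds.X[:, :-1],
            Y=ds.Y,
        )
        with pytest.raises(Exception, match=ds.descriptor_names[-1]):
            predict(model, narrower)


class TestPrune:
    def test_true_zero_coefficient_dropped_first(self, fixture_suite):
        ds, truth = load_fixture(fixture_suite, "zero_coeff")
        design = build_design_matrix(ds, truth.spec)
        model = fit_least_squares(design, ds.Y)
        r2_before = r2(predict(model, ds), ds.Y)
        pruned = prune_coefficients(model, ds, "target_count", model.n_terms - 1)
        zero_term = [
            t for t, c in zip(model.term_texts(), truth.coefficients) if c == 0.0
        ][0]
        assert pruned.meta["pruning_trace"][0]["dropped"] == zero_term
        assert abs(pruned.meta["pruning_trace"][0]["train_r2"] - r2_before) < 1e-10

    def test_target_count_noop(self, fixture_suite):
        ds, truth = load_fixture(fixture_suite, "zero_coeff")
        model = fit_least_squares(build_design_matrix(ds, truth.spec), ds.Y)
        same = prune_coefficients(model, ds, "target_count", model.n_terms)
        np.testing.assert_array_equal(same.coefficients, model.coefficients)

    def test_trace_non_increasing_and_matches_refit(self, rng):
        # prune a 20-term model down to 5 and audit every step by exhaustive refit
        ds, truth = generate_dataset(
            SyntheticConfig(
                N=120, n=6, noise_sd=0.05, seed=21,
                true_spec=HybridTermSpec(poly_mode="none", cross_terms=False),
            )
        )
        design = build_design_matrix(ds, truth.spec)
        model = fit_least_squares(design, ds.Y)
        pruned = prune_coefficients(model, ds, "target_count", 5)
        trace = pruned.meta["pruning_trace"]
        assert len(trace) == model.n_terms - 5
        r2s = [t["train_r2"] for t in trace]
        assert all(a >= b - 1e-9 for a, b in zip(r2s, r2s[1:]))
        # final trace entry must equal an independent refit on surviving terms
        from flamqspr.features import apply_terms

        surv = apply_terms(pruned.term_labels, ds.X, ds.descriptor_names)
        coef, *_ = np.linalg.lstsq(surv, ds.Y, rcond=None)
        assert abs(r2(surv @ coef, ds.Y) - r2s[-1]) < 1e-9

    def test_alpha_level_keeps_only_significant_terms(self):
        ds, truth = generate_dataset(
            SyntheticConfig(
                N=150, n=4, noise_sd=0.1, seed=33,
                true_spec=HybridTermSpec(poly_mode="none", cross_terms=False),
            )
        )
        model = fit_least_squares(build_design_matrix(ds, truth.spec), ds.Y)
        pruned = prune_coefficients(model, ds, "alpha_level", 0.05)
        import statsmodels.api as sm
        from flamqspr.features import apply_terms

        surv = apply_terms(pruned.term_labels, ds.X, ds.descriptor_names)
        pvals = sm.OLS(ds.Y, surv).fit().pvalues
        assert np.all(np.nan_to_num(pvals, nan=1.0) <= 0.05)

    def test_bad_target_count_rejected(self, fixture_suite):
        ds, truth = load_fixture(fixture_suite, "zero_coeff")
        model = fit_least_squares(build_design_matrix(ds, truth.spec), ds.Y)
        for bad in (0, model.n_terms + 1):
            with pytest.raises(ValueError):
                prune_coefficients(model, ds, "target_count", bad)


class TestProtocol:
    def test_noiseless_protocol_reaches_r2_100(self, noiseless_pair):
        ds, truth = noiseless_pair
        _, report = run_training_protocol(ds, truth.spec, seed=7)
        for part in ("train", "test", "whole"):
            assert report.reports[part].r2 == pytest.approx(100.0, abs=1e-6)
        assert report.reports["whole"].aard == pytest.approx(0.0, abs=1e-6)

    def test_determinism(self, fixture_suite):
        ds, truth = load_fixture(fixture_suite, "noisy")
        _, a = run_training_protocol(ds, truth.spec, seed=5)
        _, b = run_training_protocol(ds, truth.spec, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_training_r2_usually_exceeds_test_r2(self):
        wins = 0
        for seed in range(20):
            ds, truth = generate_dataset(
                SyntheticConfig(N=80, n=4, noise_sd=0.3, y_floor=3.0, seed=100 + seed,
                                true_spec=HybridTermSpec(poly_mode="none", cross_terms=False))
            )
            _, report = run_training_protocol(ds, truth.spec, seed=seed)
            wins += report.reports["train"].r2 >= report.reports["test"].r2
        assert wins > 10

    def test_nesting_dominance_hybrid_vs_linear(self, fixture_suite):
        for name in ("noise_free", "noisy", "zero_coeff"):
            ds, _ = load_fixture(fixture_suite, name)
            _, hybrid = run_training_protocol(ds, HybridTermSpec(poly_degree_max=2), seed=3)
            _, linear = run_training_protocol(ds, linear_only_spec(), seed=3)
            assert hybrid.reports["train"].r2 >= linear.reports["train"].r2 - 1e-9

    def test_scale_equivariance(self, fixture_suite):
        ds, truth = load_fixture(fixture_suite, "noisy")
        model, report = run_training_protocol(ds, truth.spec, seed=2)
        scaled = DescriptorDataset(
            compound_ids=ds.compound_ids,
            descriptor_names=ds.descriptor_names,
            X=ds.X,
            Y=3.0 * ds.Y,
            property_kind=ds.property_kind,
            property_name=ds.property_name,
        )
        model_s, report_s = run_training_protocol(scaled, truth.spec, seed=2)
        np.testing.assert_allclose(model_s.coefficients, 3.0 * model.coefficients, rtol=1e-7)
        assert report_s.reports["whole"].aard == pytest.approx(
            report.reports["whole"].aard, rel=1e-6
        )
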