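"""OLS engine, moderated-mediation algebra, and bootstrap inference."""

import numpy as np
import pandas as pd
import pytest

from smglyc.errors import (
    InsufficientDataError,
    ModerationUndefinedError,
    SingularDesignError,
    ValidationError,
)
from smglyc.mediation import (
    ModelSpec,
    bootstrap_cis,
    conditional_indirect_effect,
    fit_moderated_mediation,
    fit_ols,
    index_of_moderated_mediation,
    run_moderated_mediation,
)

SMALL_SPEC = ModelSpec(covariate_names=(), n_boot=500, seed=4)


def toy_table(n=60, seed=0, a1=0.5, a3=-0.3, b=2.0, sd_m=0.5, sd_y=1.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 13, size=n).astype(float)
    w = rng.integers(0, 2, size=n).astype(float)
    m = 1.0 + a1 * x + 0.4 * w + a3 * x * w + rng.normal(0, sd_m, n)
    y = 2.0 + 0.1 * x + b * m + rng.normal(0, sd_y, n)
    return pd.DataFrame(
        dict(sm_months=x, dsmq_composite=m, a1c_tic_percent=y, rurality_code=w)
    )


class TestFitOls:
    def test_perfect_linear_fit(self):
        x = np.arange(10, dtype=float)
        X = pd.DataFrame({"const": 1.0, "x": x})
        table = fit_ols(2 * x, X)
        assert table.loc["x", "coef"] == pytest.approx(2.0, abs=1e-12)
        assert table.loc["const", "coef"] == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_gives_sample_mean(self):
        y = np.array([1.0, 4.0, 7.0, 8.0])
        table = fit_ols(y, pd.DataFrame({"const": np.ones(4)}))
        assert table.loc["const", "coef"] == pytest.approx(y.mean())

    def test_matches_pseudoinverse_oracle_on_random_designs(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n, p = 20, 3
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            table = fit_ols(y, pd.DataFrame(X, columns=["c0", "c1", "c2"]))
            oracle = np.linalg.pinv(X) @ y
            assert np.allclose(table["coef"].to_numpy(), oracle, atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        coefs = fit_ols(y, pd.DataFrame(X, columns=list("abcd")))["coef"].to_numpy()
        resid = y - X @ coefs
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_singular_design_names_collinear_columns(self):
        x = np.arange(8, dtype=float)
        X = pd.DataFrame({"const": 1.0, "x": x, "x2": 2 * x})
        with pytest.raises(SingularDesignError) as exc:
            fit_ols(np.ones(8), X)
        assert {"x", "x2"} & set(exc.value.columns)

    def test_too_few_rows_raises(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(InsufficientDataError):
            fit_ols(np.ones(3), X)


class TestAlgebraicIdentities:
    def test_conditional_indirect_formula(self):
        assert conditional_indirect_effect(0.12, -0.08, 10.38, 0) == pytest.approx(1.2456)
        assert conditional_indirect_effect(0.0, 0.5, 0.0, 1) == 0.0

    def test_printed_coefficient_products(self):
        """Products of the published conditional a-paths and b-path."""
        assert round(conditional_indirect_effect(0.04, 0.0, 10.38, 0), 2) == 0.42
        assert round(conditional_indirect_effect(-0.04, 0.0, 10.38, 0), 2) == -0.42

    def test_index_equals_difference_of_conditional_effects(self):
        fit = fit_moderated_mediation(toy_table(), SMALL_SPEC)
        rural, urban = (fit.conditional_indirect[k] for k in ("rural", "urban"))
        assert fit.index_mm == pytest.approx(urban - rural, abs=1e-12)
        assert fit.index_mm == pytest.approx(fit.a3 * fit.b, abs=1e-12)
        for w, key in zip(SMALL_SPEC.w_coding, ("rural", "urban")):
            assert fit.conditional_indirect[key] == pytest.approx(
                (fit.a1 + fit.a3 * w) * fit.b, abs=1e-12
            )

    def test_alternative_moderator_coding_keeps_unit_spacing_index(self):
        """Recoding W from 0/1 to 1/2 changes the conditional levels but not
        the interaction-times-b index (unit spacing either way)."""
        data01 = toy_table(seed=5)
        data12 = data01.assign(rurality_code=data01["rurality_code"] + 1)
        f01 = fit_moderated_mediation(data01, SMALL_SPEC)
        f12 = fit_moderated_mediation(
            data12, ModelSpec(covariate_names=(), w_coding=(1, 2), n_boot=500, seed=4)
        )
        assert f12.index_mm == pytest.approx(f01.index_mm, abs=1e-9)
        assert index_of_moderated_mediation(f01.a3, f01.b, (0, 1)) == pytest.approx(
            f01.index_mm
        )


class TestModeratedMediationFit:
    def test_null_b_path_gives_near_zero_indirect_effects(self):
        data = toy_table(n=400, b=0.0, seed=2)
        fit = fit_moderated_mediation(data, SMALL_SPEC)
        se_b = fit.outcome_model.loc["dsmq_composite", "se"]
        assert abs(fit.b) < 3 * se_b
        for v in fit.conditional_indirect.values():
            assert abs(v) < 3 * se_b * 13  # |a1 + a3 w| <= ~1 here

    def test_missing_column_raises(self):
        with pytest.raises(ValidationError, match="missing columns"):
            fit_moderated_mediation(toy_table().drop(columns=["dsmq_composite"]), SMALL_SPEC)

    def test_single_moderator_level_raises(self):
        data = toy_table()
        data["rurality_code"] = 0
        with pytest.raises(ModerationUndefinedError):
            fit_moderated_mediation(data, SMALL_SPEC)

    def test_unexpected_moderator_codes_raise(self):
        data = toy_table()
        data.loc[0, "rurality_code"] = 2
        with pytest.raises(ValidationError, match="w_coding"):
            fit_moderated_mediation(data, SMALL_SPEC)

    def test_listwise_deletion_counts(self):
        data = toy_table(n=80)
        data.loc[:4, "dsmq_composite"] = np.nan
        fit = fit_moderated_mediation(data, SMALL_SPEC)
        assert fit.n_used == 75

    def test_outcome_model_excludes_moderator_by_default(self):
        fit = fit_moderated_mediation(toy_table(), SMALL_SPEC)
        assert "rurality_code" not in fit.outcome_model.index
        spec = ModelSpec(covariate_names=(), include_w_in_outcome=True, n_boot=10, seed=0)
        fit_w = fit_moderated_mediation(toy_table(), spec)
        assert "rurality_code" in fit_w.outcome_model.index


class TestBootstrap:
    def test_seeded_determinism(self):
        data = toy_table(n=80)
        r1 = bootstrap_cis(data, SMALL_SPEC)
        r2 = bootstrap_cis(data, SMALL_SPEC)
        assert r1.index_ci == r2.index_ci
        assert r1.conditional_ci == r2.conditional_ci

    def test_different_seed_changes_cis(self):
        data = toy_table(n=80)
        r1 = bootstrap_cis(data, SMALL_SPEC)
        r2 = bootstrap_cis(data, ModelSpec(covariate_names=(), n_boot=500, seed=5))
        assert r1.index_ci != r2.index_ci

    def test_degenerate_noiseless_data_gives_zero_width_ci(self):
        """Exact linear M and Y: every resample refits the same coefficients."""
        rng = np.random.default_rng(0)
        x = rng.integers(0, 13, size=40).astype(float)
        w = rng.integers(0, 2, size=40).astype(float)
        m = 1.0 + 0.5 * x + 0.4 * w - 0.3 * x * w
        y = 2.0 + 0.1 * x + 2.0 * m
        data = pd.DataFrame(
            dict(sm_months=x, dsmq_composite=m, a1c_tic_percent=y, rurality_code=w)
        )
        r = bootstrap_cis(data, ModelSpec(covariate_names=(), n_boot=300, seed=1))
        lo, hi = r.index_ci
        assert hi - lo == pytest.approx(0.0, abs=1e-7)

    def test_significance_flag_follows_ci(self):
        data = toy_table(n=400, a3=-0.5, b=3.0, sd_m=0.3, sd_y=0.5, seed=7)
        report = run_moderated_mediation(data, SMALL_SPEC)
        lo, hi = report.boot.index_ci
        assert report.boot.significant["index_mm"] == (not (lo <= 0 <= hi))
        assert report.boot.n_boot_completed + report.boot.n_boot_skipped == SMALL_SPEC.n_boot

    def test_report_round_trip_serializable(self):
        import json

        report = run_moderated_mediation(toy_table(), SMALL_SPEC)
        payload = json.dumps(report.to_dict())
        assert "index_of_moderated_mediation" in payload
        text = report.to_text()
        assert "Conditional indirect effects" in text
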