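"""Linear / logistic fits and the per-stratum SNP association wrapper."""

import numpy as np
import pandas as pd
import pytest

from transmeta.assoc import ModelSpec, fit_linear, fit_logistic, snp_assoc
from transmeta.exceptions import (
    MonomorphicSNPError,
    SeparationError,
    SingularDesignError,
    ZeroVarianceError,
)
from transmeta.synth import gen_stratum
from tests.conftest import sem_spec


class TestLinear:
    def test_exact_fit_recovers_weights(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        w = np.array([1.0, -2.0, 0.5])
        fit = fit_linear(X @ w, X, names=["const", "x1", "x2"])
        assert np.allclose(fit.params, w, atol=1e-10)

    def test_six_point_line(self):
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([1, 1, 2, 2, 3, 3], dtype=float)
        fit = fit_linear(y, np.column_stack([np.ones(6), x]), names=["const", "x"])
        assert fit.params == pytest.approx([1.0, 1.0], abs=1e-12)
        resid = y - np.column_stack([np.ones(6), x]) @ fit.params
        assert resid @ resid == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 2))])
        y = rng.normal(size=50)
        fit = fit_linear(y, X)
        # explicit matrix-inversion oracle with unbiased residual variance
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        s2 = resid @ resid / (50 - 3)
        se = np.sqrt(np.diag(s2 * xtx_inv))
        assert np.allclose(fit.params, beta, atol=1e-8)
        assert np.allclose(fit.se, se, atol=1e-8)

    def test_singular_design_names_columns(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"const": 1.0, "x": x, "x_copy": x})
        with pytest.raises(SingularDesignError) as err:
            fit_linear(rng.normal(size=30), X)
        assert "x_copy" in err.value.columns or "x" in err.value.columns


class TestLogistic:
    def test_contingency_table_closed_form(self):
        # 2x2 counts (20,30;40,10): slope = log OR = log((20*10)/(30*40))
        x = np.repeat([1, 1, 0, 0], [20, 30, 40, 10]).astype(float)
        y = np.repeat([1, 0, 1, 0], [20, 30, 40, 10]).astype(float)
        fit = fit_logistic(y, np.column_stack([np.ones_like(x), x]), names=["const", "x"])
        assert fit.coef("x")[0] == pytest.approx(np.log(1 / 6), abs=1e-8)

    def test_null_and_nonnull_recovery(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        for true in (0.0, 0.5):
            p = 1 / (1 + np.exp(-(-0.5 + true * x)))
            y = rng.binomial(1, p)
            fit = fit_logistic(y, np.column_stack([np.ones(n), x]), names=["const", "x"])
            b, se, _ = fit.coef("x")
            assert abs(b - true) < 3 * se

    def test_matches_brute_force_ml_oracle(self):
        # direct Nelder-Mead minimisation of the negative log-likelihood,
        # refined from a coarse grid start, independent of the Newton path
        from scipy.optimize import minimize

        x = np.array([-2, -1, -0.5, 0.5, 1, 2.0])
        y = np.array([0, 0, 1, 0, 1, 1.0])
        X = np.column_stack([np.ones(6), x])
        fit = fit_logistic(y, X)

        def nll(b):
            eta = X @ b
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        grid = np.linspace(-3, 3, 61)
        starts = min(
            ((g0, g1) for g0 in grid for g1 in grid), key=lambda b: nll(np.array(b))
        )
        opt = minimize(nll, np.array(starts), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12})
        assert np.allclose(fit.params, opt.x, atol=1e-4)

    def test_perfect_separation_raises(self):
        x = np.array([-2, -1, -0.5, 0.5, 1, 2.0])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(y, np.column_stack([np.ones(6), x]))


class TestSnpAssoc:
    def test_recovers_mediator_effect(self):
        df = gen_stratum(sem_spec(n=5000, a=3.5), seed=21)
        est = snp_assoc(df, "S", ModelSpec(trait="m", covariates=("age",)))
        assert abs(est.beta - 3.5) < 3 * est.se
        assert est.n == 5000

    def test_constant_trait_raises(self):
        df = gen_stratum(sem_spec(n=100), seed=1)
        df["flat"] = 1.0
        with pytest.raises(ZeroVarianceError):
            snp_assoc(df, "S", ModelSpec(trait="flat"))

    def test_monomorphic_snp_raises(self):
        df = gen_stratum(sem_spec(n=100), seed=1)
        df["dosage"] = 1
        with pytest.raises(MonomorphicSNPError):
            snp_assoc(df, "S", ModelSpec(trait="m"))

    def test_scaling_equivariance(self):
        df = gen_stratum(sem_spec(n=2000, a=2.0), seed=13)
        base = snp_assoc(df, "S", ModelSpec(trait="m", covariates=("age",)))
        df2 = df.assign(m=df["m"] * 3.0)
        scaled = snp_assoc(df2, "S", ModelSpec(trait="m", covariates=("age",)))
        assert scaled.beta == pytest.approx(3.0 * base.beta, rel=1e-9)
        assert scaled.se == pytest.approx(3.0 * base.se, rel=1e-9)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)

    def test_allele_flip_antisymmetry(self):
        df = gen_stratum(sem_spec(n=2000, a=2.0), seed=14)
        base = snp_assoc(df, "S", ModelSpec(trait="m", covariates=("age",)))
        flipped = snp_assoc(
            df.assign(dosage=2 - df["dosage"]), "S",
            ModelSpec(trait="m", covariates=("age",)),
        )
        assert flipped.beta == pytest.approx(-base.beta, rel=1e-9)
        assert flipped.se == pytest.approx(base.se, rel=1e-9)
        assert flipped.p == pytest.approx(base.p, rel=1e-9)

    def test_categorical_covariates_expand_to_indicators(self, rng):
        df = gen_stratum(sem_spec(n=600), seed=15)
        df["site"] = rng.choice(["u1", "u2", "u3"], size=len(df))
        est = snp_assoc(df, "S", ModelSpec(trait="m", covariates=("age", "site")))
        assert est.n == 600  # fit succeeded with 2 indicator columns

    def test_sqrt_transform_applied(self):
        df = gen_stratum(sem_spec(n=800), seed=16)
        df["ratio"] = (df["m"] - df["m"].min() + 1.0) ** 2
        raw = snp_assoc(df, "S", ModelSpec(trait="ratio"))
        tr = snp_assoc(df, "S", ModelSpec(trait="ratio", transform="sqrt"))
        assert tr.beta != pytest.approx(raw.beta)

    def test_permutation_null_type_i_error(self, rng):
        """Permuting dosage against the trait gives nominal type-I error."""
        df = gen_stratum(sem_spec(n=600, a=3.0), seed=17)
        n_reps, hits = 600, 0
        dosage = df["dosage"].to_numpy().copy()
        for _ in range(n_reps):
            df["dosage"] = rng.permutation(dosage)
            est = snp_assoc(df, "S", ModelSpec(trait="m", covariates=("age",)))
            hits += est.p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(hits / n_reps - 0.05) < 3 * se

    def test_complete_case_subset_reported(self):
        df = gen_stratum(sem_spec(n=1000), seed=18)
        df.loc[df.index[:100], "m"] = np.nan
        est = snp_assoc(df, "S", ModelSpec(trait="m", covariates=("age",)))
        assert est.n == 900
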