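"""REML engine against closed-form, grid-search and mixed-model-equation
oracles; stage-1 adjusted means."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from diallelgp import lmm
from diallelgp.lmm import (
    AdjustedMeans,
    LMMSpec,
    RandomTerm,
    TrialData,
    blup_predict,
    reml_fit,
    stage1_blues,
)
from diallelgp.synthetic_data import SimConfig, simulate_trial_data


def reml_loglik(theta_g, theta_e, y, X, G):
    """Independent restricted log-likelihood evaluation (direct formula,
    no EM machinery)."""
    n = len(y)
    V = theta_g * G + theta_e * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + float(r @ Vi @ y)
    )


def grid_search_oracle(y, X, G, grid=None):
    """Profile the variance ratio lambda = s2_g/s2_e on a dense grid with a
    bounded refinement; returns (s2_g, s2_e, loglik)."""
    n, p = X.shape

    def profiled(lam):
        V = lam * G + np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        Py = Vi @ (y - X @ beta)
        s2e = float(y @ Py) / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(s2e)
            + np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtViX)[1]
            + (n - p)
        )
        return s2e, ll

    grid = np.logspace(-4, 4, 400) if grid is None else grid
    lls = [profiled(l)[1] for l in grid]
    best = int(np.argmax(lls))
    lo, hi = grid[max(best - 1, 0)], grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda l: -profiled(l)[1], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    lam = float(res.x)
    s2e, ll = profiled(lam)
    return lam * s2e, s2e, ll


class TestREML:
    def test_intercept_only_residual_is_sample_variance(self, rng):
        y = rng.normal(2.0, 1.5, size=25)
        spec = LMMSpec(y=y, X=np.ones((25, 1)), fixed_names=["mu"], random=[])
        fit = reml_fit(spec)
        assert fit.varcomps["residual"] == pytest.approx(np.var(y, ddof=1), rel=1e-6)
        assert fit.beta["mu"] == pytest.approx(y.mean(), rel=1e-6)

    def test_balanced_oneway_anova_closed_form(self, rng):
        """Identity-kernel random groups in a balanced design: REML equals
        the ANOVA estimators s2_e = MSE, s2_g = (MSA - MSE)/r."""
        q, r = 8, 6
        groups = np.repeat(np.arange(q), r)
        effects = rng.normal(0, 2.0, size=q)
        y = 5.0 + effects[groups] + rng.normal(0, 1.0, size=q * r)
        Z = np.eye(q)[groups]
        spec = LMMSpec(
            y=y, X=np.ones((q * r, 1)), fixed_names=["mu"],
            random=[RandomTerm("group", Z=Z)],
        )
        fit = reml_fit(spec, tol=1e-12)
        gm = y.reshape(q, r).mean(axis=1)
        msa = r * np.sum((gm - y.mean()) ** 2) / (q - 1)
        mse = np.sum((y - gm[groups]) ** 2) / (q * (r - 1))
        assert fit.varcomps["residual"] == pytest.approx(mse, rel=1e-5)
        assert fit.varcomps["group"] == pytest.approx((msa - mse) / r, rel=1e-4)

    @pytest.mark.parametrize("method", ["em", "ai"])
    def test_grid_search_oracle_12obs(self, rng, method):
        """Single-kernel 12-observation instance: the REML maximum matches a
        dense grid search over the variance ratio."""
        n = 12
        L = rng.normal(size=(n, n))
        G = L @ L.T / n
        y = rng.multivariate_normal(np.zeros(n), 1.2 * G + 0.8 * np.eye(n))
        X = np.ones((n, 1))
        spec = LMMSpec(y=y, X=X, fixed_names=["mu"], random=[RandomTerm("g", Z=np.eye(n), K=G)])
        fit = reml_fit(spec, tol=1e-12, max_iter=2000, method=method)
        s2g, s2e, ll = grid_search_oracle(y, X, G)
        assert fit.loglik == pytest.approx(ll, abs=1e-4)
        assert fit.varcomps["g"] == pytest.approx(s2g, abs=1e-3)
        assert fit.varcomps["residual"] == pytest.approx(s2e, abs=1e-3)

    def test_em_loglik_monotone(self, rng):
        n = 40
        L = rng.normal(size=(n, n))
        G = L @ L.T / n
        y = rng.multivariate_normal(np.zeros(n), G + np.eye(n))
        spec = LMMSpec(
            y=y, X=np.ones((n, 1)), fixed_names=["mu"],
            random=[RandomTerm("g", Z=np.eye(n), K=G)],
        )
        fit = reml_fit(spec, method="em", max_iter=500)
        assert (np.diff(fit.history) >= -1e-6).all()

    def test_heterogeneous_residuals_recovered(self, rng):
        """Per-group residual variances separate clearly different groups."""
        n = 400
        groups = np.repeat(["a", "b"], n // 2)
        y = np.where(groups == "a", rng.normal(0, 0.5, n), rng.normal(0, 2.0, n))
        spec = LMMSpec(
            y=y, X=np.ones((n, 1)), fixed_names=["mu"], random=[],
            residual_groups=groups,
        )
        fit = reml_fit(spec)
        assert fit.varcomps["residual[a]"] == pytest.approx(0.25, rel=0.35)
        assert fit.varcomps["residual[b]"] == pytest.approx(4.0, rel=0.35)

    def test_residual_to_zero_fits_observations(self, rng):
        """Noiseless kernel-generated data: fitted values approach y."""
        n = 20
        L = rng.normal(size=(n, n))
        G = L @ L.T / n
        u = rng.multivariate_normal(np.zeros(n), G)
        y = 1.0 + u
        spec = LMMSpec(
            y=y, X=np.ones((n, 1)), fixed_names=["mu"],
            random=[RandomTerm("g", Z=np.eye(n), K=G)],
        )
        fit = reml_fit(spec)
        fitted = fit.beta["mu"] + fit.blups["g"].to_numpy()
        np.testing.assert_allclose(fitted, y, atol=1e-2)

    def test_rank_deficient_X_rejected(self, rng):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            reml_fit(LMMSpec(y=rng.normal(size=10), X=X, fixed_names=["a", "b"], random=[]))


class TestBlupPredict:
    def _fit(self, rng, n=10):
        L = rng.normal(size=(n, n))
        G = L @ L.T / n + 0.5 * np.eye(n)
        y = rng.multivariate_normal(np.zeros(n), G + np.eye(n))
        spec = LMMSpec(
            y=y, X=np.ones((n, 1)), fixed_names=["mu"],
            random=[RandomTerm("g", Z=np.eye(n), K=G)],
        )
        return reml_fit(spec), G, y

    def test_duplicate_level_reproduces_blup(self, rng):
        fit, G, _ = self._fit(rng)
        pred = blup_predict(fit, "g", G[[3], :])
        assert pred[0] == pytest.approx(fit.blups["g"].iloc[3], abs=1e-4)

    def test_zero_kernel_gives_prior_mean(self, rng):
        fit, G, _ = self._fit(rng)
        assert blup_predict(fit, "g", np.zeros((1, G.shape[0])))[0] == 0.0

    def test_matches_augmented_mme(self, rng):
        """8 training levels + 2 new: prediction equals the direct joint-BLUP
        formula s2_u K_new,train Z' V^-1 (y - X beta)."""
        n, m = 8, 2
        L = rng.normal(size=(n + m, n + m))
        Kfull = L @ L.T / (n + m) + 0.3 * np.eye(n + m)
        Ktr = Kfull[:n, :n]
        y = rng.multivariate_normal(np.zeros(n), Ktr + np.eye(n))
        spec = LMMSpec(
            y=y, X=np.ones((n, 1)), fixed_names=["mu"],
            random=[RandomTerm("g", Z=np.eye(n), K=Ktr)],
        )
        fit = reml_fit(spec, tol=1e-12)
        s2u = fit.varcomps["g"]
        s2e = fit.varcomps["residual"]
        V = s2u * Ktr + s2e * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        direct = s2u * Kfull[n:, :n] @ Vi @ (y - X @ beta)
        pred = blup_predict(fit, "g", Kfull[n:, :n])
        np.testing.assert_allclose(pred, direct, atol=1e-5)

    def test_shape_mismatch(self, rng):
        fit, G, _ = self._fit(rng)
        with pytest.raises(ValueError):
            blup_predict(fit, "g", np.zeros((1, 3)))


class TestStage1:
    def _noiseless_trial(self, n_entries=24):
        cfg = SimConfig(
            n_lines=10, n_markers=50, n_pools=1, n_diallel_parents=8,
            var_env=0.0, var_block=0.0, var_residual=0.0,
            n_envs=3, block_size=8, n_checks=2, seed=3,
        )
        values = pd.Series(
            np.linspace(-2, 2, n_entries), index=[f"H{i}" for i in range(n_entries)]
        )
        return values, simulate_trial_data(values, cfg, rng=np.random.default_rng(0))

    def test_noiseless_blues_equal_truth(self):
        values, trial = self._noiseless_trial()
        means, _ = stage1_blues(trial)
        np.testing.assert_allclose(means.values.loc[values.index], values, atol=1e-5)

    def test_checks_excluded(self):
        _, trial = self._noiseless_trial()
        means, _ = stage1_blues(trial)
        assert not any(str(e).startswith("CHECK") for e in means.values.index)

    def test_balanced_design_matches_least_squares(self, rng):
        """Complete balanced layout, homogeneous residual: BLUEs equal the
        ordinary-least-squares entry means adjusted for environments."""
        entries = [f"H{i}" for i in range(6)]
        envs = ["E1", "E2", "E3"]
        env_eff = {"E1": 1.0, "E2": -0.5, "E3": -0.5}
        rows = []
        truth = dict(zip(entries, rng.normal(size=6)))
        for e in envs:
            for g in entries:
                rows.append(
                    {"env": e, "block": "B1", "entry": g, "is_check": False,
                     "y": truth[g] + env_eff[e] + rng.normal(0, 0.3)}
                )
            rows.append(
                {"env": e, "block": "B1", "entry": "CK", "is_check": True,
                 "y": env_eff[e] + rng.normal(0, 0.3)}
            )
        trial = TrialData(pd.DataFrame(rows))
        means, _ = stage1_blues(trial, residual_mode="homogeneous")
        df = trial.records
        ls_means = {}
        for g in entries:
            sub = df[(df["entry"] == g)]
            # balanced complete design: LS mean = raw mean minus mean env effect,
            # and env effects are estimated from all rows; use two-way OLS fit
            ls_means[g] = sub["y"].mean() - df.groupby("env")["y"].mean().mean() + df["y"].mean()
        # the model-based check: entry differences match raw-mean differences
        raw = df[~df["is_check"].astype(bool)].groupby("entry")["y"].mean()
        d_model = means.values.loc[entries].to_numpy() - means.values.loc[entries[0]]
        d_raw = raw.loc[entries].to_numpy() - raw.loc[entries[0]]
        np.testing.assert_allclose(d_model, d_raw, atol=1e-8)

    def test_per_env_residual_mode_runs(self, two_pool_study):
        means, fit = stage1_blues(two_pool_study.trial)
        assert fit.converged
        res_keys = [k for k in fit.varcomps if k.startswith("residual[")]
        assert len(res_keys) == two_pool_study.config.n_envs

    def test_unknown_trait(self, two_pool_study):
        with pytest.raises(KeyError):
            stage1_blues(two_pool_study.trial, trait="nope")


def test_adjusted_means_roundtrip(tmp_path):
    m = AdjustedMeans(trait="gy", values=pd.Series({"AxB": 1.0, "CxD": -1.0}))
    m.write(tmp_path / "m.tsv")
    df = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col=0)
    assert df.loc["AxB", "blue"] == 1.0
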