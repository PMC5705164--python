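import shutil
import subprocess

import numpy as np
import pytest
from scipy.special import expit

from hiermove.glmm import (
    fit_laplace,
    fit_pql,
    laplace_loglik_and_grad,
    marginal_loglik_quadrature,
)
from hiermove.hierbayes import HierLogitModel
from hiermove.preprocess import TrackIndex
from hiermove.simulate import SimConfig, simulate_dataset


def _sim_model(seed=0, n_groups=5, rows=20, beta=(0.2, 1.0, -0.7), sigma_u=1.0):
    rng = np.random.default_rng(seed)
    n = n_groups * rows
    X = np.column_stack([np.ones(n), rng.normal(size=(n, len(beta) - 1))])
    idx = TrackIndex(np.arange(0, n + 1, rows) + 1)
    u = sigma_u * rng.standard_normal(n_groups)
    eta = X @ np.asarray(beta) + np.repeat(u, rows)
    z = (rng.uniform(size=n) < expit(eta)).astype(int)
    return HierLogitModel(X, z, idx, tuple(f"B{i}" for i in range(len(beta))))


class TestLaplaceGradient:
    def test_analytic_matches_numerical(self):
        """Implicit-differentiation gradient of the Laplace objective agrees
        with central differences at random points."""
        m = _sim_model(seed=1)
        rng = np.random.default_rng(2)
        for _ in range(3):
            theta = np.append(rng.normal(0, 0.5, 3), rng.normal(0, 0.3))
            _, g, _ = laplace_loglik_and_grad(m, theta[:3], theta[3])
            gn = np.empty(4)
            for k in range(4):
                tp, tm = theta.copy(), theta.copy()
                tp[k] += 1e-6
                tm[k] -= 1e-6
                lp, _, _ = laplace_loglik_and_grad(m, tp[:3], tp[3])
                lm, _, _ = laplace_loglik_and_grad(m, tm[:3], tm[3])
                gn[k] = (lp - lm) / 2e-6
            np.testing.assert_allclose(g, gn, rtol=1e-5, atol=1e-7)


class TestLaplaceFit:
    def test_matches_glmer_oracle(self, tiny_dataset):
        """Independent oracle: lme4::glmer (Laplace) on the same data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        import os
        import tempfile

        tab = tiny_dataset.table.drop(columns=["date"])
        with tempfile.TemporaryDirectory() as d:
            p = os.path.join(d, "t.csv")
            tab.to_csv(p, index=False)
            script = (
                'suppressMessages(library(lme4));'
                f'd <- read.csv("{p}"); d$sex <- factor(d$sex);'
                "f <- glmer(z ~ Spring + Summer + Winter + L + sex + MEI_Index"
                " + (1|ptt), family=binomial, data=d);"
                'cat(fixef(f), sqrt(unlist(VarCorr(f))), sep="\\n")'
            )
            res = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True,
                timeout=300,
            )
            if res.returncode != 0:
                pytest.skip(f"glmer oracle failed: {res.stderr[-200:]}")
            vals = np.array([float(v) for v in res.stdout.split()])
        fit = fit_laplace(tiny_dataset.model())
        np.testing.assert_allclose(fit.beta, vals[:7], rtol=5e-3, atol=5e-3)
        assert fit.sigma_u == pytest.approx(vals[7], rel=0.02, abs=0.02)

    def test_sigma_zero_limit_is_pooled_logistic(self):
        """With the random effect pinned at zero the MLE is the ordinary
        pooled logistic regression."""
        import statsmodels.api as sm

        m = _sim_model(seed=3, sigma_u=0.0)
        ll0 = marginal_loglik_quadrature(m, np.zeros(3), 0.0, 1)
        res = sm.GLM(m.z, m.X, family=sm.families.Binomial()).fit()
        beta_hat = np.asarray(res.params)
        # quadrature at sigma=0 equals the plain logistic log-likelihood
        assert marginal_loglik_quadrature(m, beta_hat, 0.0, 7) == pytest.approx(
            float(res.llf), rel=1e-10
        )
        assert ll0 == pytest.approx(m.n_rows * np.log(0.5), rel=1e-12)

    def test_recovery_within_wald_intervals(self):
        """Known-truth simulation: the Wald 95% interval covers the truth at
        roughly the nominal rate across seeded replicates."""
        beta_true = (0.2, 1.0, -0.7)
        hits = np.zeros(3)
        n_rep = 40
        for r in range(n_rep):
            m = _sim_model(seed=100 + r, n_groups=12, rows=40, beta=beta_true)
            fit = fit_laplace(m)
            ci = fit.wald_intervals()
            hits += (ci[:, 0] <= beta_true) & (beta_true <= ci[:, 1])
        cover = hits / n_rep
        tol = 3 * np.sqrt(0.95 * 0.05 / n_rep)
        assert (cover >= 0.95 - tol - 0.02).all()

    def test_degenerate_inputs_rejected(self):
        m = _sim_model(seed=4)
        single = HierLogitModel(
            m.X[:20], m.z[:20], TrackIndex(np.array([1, 21])), m.coef_names
        )
        with pytest.raises(ValueError, match="2 groups"):
            fit_laplace(single)
        const = HierLogitModel(
            m.X, np.zeros(m.n_rows, dtype=int), m.track_index, m.coef_names
        )
        with pytest.raises(ValueError, match="constant"):
            fit_pql(const)

    def test_row_order_within_groups_irrelevant(self):
        m = _sim_model(seed=5)
        rng = np.random.default_rng(0)
        perm = np.concatenate(
            [rng.permutation(np.arange(s, s + c)) for s, c in
             zip(m.track_index.starts0, m.track_index.counts)]
        )
        m2 = HierLogitModel(m.X[perm], m.z[perm], m.track_index, m.coef_names)
        f1, f2 = fit_laplace(m), fit_laplace(m2)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-6)
        assert f1.sigma_u == pytest.approx(f2.sigma_u, abs=1e-6)


class TestQuadrature:
    def test_one_node_equals_laplace_exactly(self):
        m = _sim_model(seed=6)
        fit = fit_laplace(m)
        agh1 = marginal_loglik_quadrature(m, fit.beta, fit.sigma_u, 1)
        assert agh1 == pytest.approx(fit.loglik, rel=1e-12)

    def test_laplace_within_tenth_of_50_node_quadrature(self):
        m = _sim_model(seed=7, n_groups=5, rows=20)
        fit = fit_laplace(m)
        agh50 = marginal_loglik_quadrature(m, fit.beta, fit.sigma_u, 50)
        assert abs(fit.loglik - agh50) < 0.1

    def test_refinement_converges(self):
        """Doubling the node count shrinks successive differences."""
        m = _sim_model(seed=8)
        beta = np.array([0.1, 0.8, -0.5])
        vals = [
            marginal_loglik_quadrature(m, beta, 1.2, k)
            for k in (1, 2, 4, 8, 16, 32, 64)
        ]
        diffs = np.abs(np.diff(vals))
        assert diffs[-1] < 1e-8
        assert diffs[-1] <= diffs[0]
        # monotone shrinkage over the tail of the refinement
        assert np.all(diffs[2:] <= diffs[1:-1] + 1e-12)

    def test_invalid_inputs(self):
        m = _sim_model(seed=9)
        with pytest.raises(ValueError):
            marginal_loglik_quadrature(m, np.zeros(3), 1.0, 0)
        with pytest.raises(ValueError):
            marginal_loglik_quadrature(m, np.zeros(3), -1.0, 5)


class TestPQL:
    def test_attenuation_at_large_sigma(self):
        """For binary data with a large random-effect sd, PQL slope
        estimates are attenuated toward zero relative to Laplace."""
        ratios = []
        for r in range(8):
            m = _sim_model(seed=200 + r, n_groups=20, rows=15,
                           beta=(0.0, 1.5, -1.5), sigma_u=2.5)
            fl, fp = fit_laplace(m), fit_pql(m)
            ratios.append(np.abs(fp.beta[1:]) / np.abs(fl.beta[1:]))
        mean_ratio = float(np.mean(ratios))
        assert mean_ratio < 1.0

    def test_agrees_with_laplace_in_benign_regime(self):
        """Many observations per group and moderate sigma_u: PQL and
        Laplace slopes agree within 5%."""
        m = _sim_model(seed=11, n_groups=10, rows=200, beta=(0.3, 1.0, -0.8),
                       sigma_u=0.8)
        fl, fp = fit_laplace(m), fit_pql(m)
        np.testing.assert_allclose(fp.beta[1:], fl.beta[1:], rtol=0.05)

    def test_quasi_likelihood_flagged(self):
        m = _sim_model(seed=12)
        fit = fit_pql(m)
        assert fit.loglik is None
        assert fit.method == "pql"
        assert fit.converged
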