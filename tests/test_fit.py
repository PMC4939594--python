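import subprocess
import textwrap

import numpy as np
import pytest

from crtimbalance.design import CollinearDesignError, ImbalanceSpec, TrialDesign
from crtimbalance.fit import (
    arm_means,
    fit_adjusted,
    fit_cluster_means,
    fit_unadjusted,
    reml_components,
)
from crtimbalance.simulate import ModelParams, TrialData, generate_trial

from conftest import make_design
from reml_oracle import numeric_reml_fit


def _random_small_trial(i: int):
    """Small random trial over n2 in {8,12}, n1 in {2,5}, varying imbalance."""
    rng = np.random.default_rng(np.random.SeedSequence((321, i)))
    n2 = int(rng.choice([8, 12]))
    n1 = int(rng.choice([2, 5]))
    k = int(rng.integers(1, n2 // 2))
    rho = float(rng.uniform(0.02, 0.3))
    d = make_design(n1, n2, k)
    params = ModelParams.from_icc(rho, 0.5, 0.5)
    return generate_trial(d, params, np.random.SeedSequence((322, i)))


class TestToyTrial:
    """Hand-computed ANOVA on four clusters of two subjects."""

    def test_adjusted_fit(self, toy_trial):
        f = fit_adjusted(toy_trial)
        assert f.beta1_hat == pytest.approx(3.0, abs=1e-10)
        assert f.beta2_hat == pytest.approx(2.0, abs=1e-10)
        assert f.sigma_e2_hat == pytest.approx(2.0, abs=1e-10)
        assert f.sigma_u2_hat == pytest.approx(0.0, abs=1e-10)
        assert f.se_beta1 == pytest.approx(1.0, abs=1e-10)
        assert f.t_stat == pytest.approx(3.0, abs=1e-10)
        assert f.df == 1

    def test_unadjusted_fit(self, toy_trial):
        f = fit_unadjusted(toy_trial)
        assert f.beta1_hat == pytest.approx(3.0, abs=1e-10)
        assert f.sigma_u2_hat == pytest.approx(1.5, abs=1e-10)
        assert f.sigma_e2_hat == pytest.approx(2.0, abs=1e-10)
        assert f.se_beta1 == pytest.approx(np.sqrt(2.5), abs=1e-10)
        assert f.df == 2

    def test_arm_means(self, toy_trial):
        m = arm_means(toy_trial)
        assert m.ybar_I == pytest.approx(5.5)
        assert m.ybar_C == pytest.approx(2.5)
        assert m.zbar_I == m.zbar_C == 0.5

    def test_components_match_hand_anova(self, toy_trial):
        assert reml_components(toy_trial, adjusted=True) == pytest.approx((0.0, 2.0))
        assert reml_components(toy_trial, adjusted=False) == pytest.approx((1.5, 2.0))


class TestExactIdentities:
    def test_noise_free_fit_recovers_coefficients(self):
        d = make_design(3, 12, 5)
        t = generate_trial(
            d, ModelParams(beta1=0.5, beta2=0.8, sigma_u2=0.0, sigma_e2=0.0), 0
        )
        f = fit_adjusted(t)
        assert f.beta1_hat == pytest.approx(0.5, abs=1e-12)
        assert f.beta2_hat == pytest.approx(0.8, abs=1e-12)

    def test_noise_free_arm_means_under_imbalance(self):
        d = make_design(3, 12, 5)
        t = generate_trial(
            d, ModelParams(beta1=0.5, beta2=0.8, sigma_u2=0.0, sigma_e2=0.0), 0
        )
        m = arm_means(t)
        assert m.ybar_I == pytest.approx(0.5 + 0.8 * 5 / 6)
        assert m.ybar_C == pytest.approx(0.8 * 1 / 6)
        assert m.zbar_I - m.zbar_C == pytest.approx((2 * 5 - 6) / 6)

    def test_unadjusted_estimate_is_arm_mean_difference(self):
        for i in range(10):
            t = _random_small_trial(i)
            f = fit_unadjusted(t)
            m = arm_means(t)
            assert f.beta1_hat == pytest.approx(m.ybar_I - m.ybar_C, abs=1e-10)

    def test_unadjusted_absorbs_covariate_effect_without_noise(self):
        d = make_design(3, 12, 5)
        t = generate_trial(
            d, ModelParams(beta1=0.5, beta2=0.8, sigma_u2=0.0, sigma_e2=0.0), 0
        )
        assert fit_unadjusted(t).beta1_hat == pytest.approx(0.5 + 0.8 * 2 / 3)

    def test_adjusted_equals_arm_difference_at_balance(self):
        d = make_design(5, 12, 3)  # k = n2/4: x orthogonal to z
        t = generate_trial(d, ModelParams.from_icc(0.1, 0.5, 0.5), 9)
        f = fit_adjusted(t)
        m = arm_means(t)
        assert f.beta1_hat == pytest.approx(m.ybar_I - m.ybar_C, abs=1e-10)

    def test_gls_equals_cluster_mean_ols(self):
        """Explicit individual-level GLS at the estimated V reproduces the
        cluster-mean OLS estimate and model-based SE."""
        for i in range(5):
            t = _random_small_trial(i)
            f = fit_adjusted(t)
            d = t.design
            X = np.repeat(
                np.column_stack([np.ones(d.n2), d.x, d.z]), d.n1, axis=0
            )
            from scipy.linalg import block_diag

            V = f.sigma_u2_hat * block_diag(
                *[np.ones((d.n1, d.n1))] * d.n2
            ) + f.sigma_e2_hat * np.eye(d.n1 * d.n2)
            Vinv = np.linalg.inv(V)
            cov = np.linalg.inv(X.T @ Vinv @ X)
            beta = cov @ X.T @ Vinv @ t.y.ravel()
            assert beta[1] == pytest.approx(f.beta1_hat, abs=1e-10)
            assert np.sqrt(cov[1, 1]) == pytest.approx(f.se_beta1, abs=1e-10)


class TestRemlOracle:
    def test_matches_numeric_reml_on_random_trials(self):
        """Closed-form fits agree with a brute-force optimizer-based REML.

        Interior solutions must agree to 1e-6 relative tolerance; boundary
        solutions (sigma_u2_hat = 0) are compared more loosely because the
        optimizer only approaches the boundary asymptotically.
        """
        n_interior = 0
        for i in range(200):
            t = _random_small_trial(i)
            f = fit_adjusted(t)
            d = t.design
            oracle = numeric_reml_fit(
                t.y, np.column_stack([np.ones(d.n2), d.x, d.z])
            )
            assert f.beta1_hat == pytest.approx(oracle["beta"][1], rel=1e-6, abs=1e-8)
            if f.sigma_u2_hat > 1e-4:
                n_interior += 1
                # abs floor covers the optimizer's resolution near sigma_u2 = 0
                assert f.sigma_u2_hat == pytest.approx(
                    oracle["sigma_u2"], rel=1e-6, abs=1e-7
                )
                assert f.sigma_e2_hat == pytest.approx(oracle["sigma_e2"], rel=1e-6)
                assert f.se_beta1 == pytest.approx(oracle["se"][1], rel=1e-6)
            else:
                assert oracle["sigma_u2"] < max(2 * f.sigma_u2_hat, 1e-2)
                assert f.se_beta1 == pytest.approx(oracle["se"][1], rel=2e-2)
        assert n_interior >= 50  # both regimes must actually be exercised

    def test_unadjusted_matches_numeric_reml(self):
        for i in range(20):
            t = _random_small_trial(i)
            f = fit_unadjusted(t)
            d = t.design
            oracle = numeric_reml_fit(t.y, np.column_stack([np.ones(d.n2), d.x]))
            assert f.beta1_hat == pytest.approx(oracle["beta"][1], rel=1e-6, abs=1e-8)
            if f.sigma_u2_hat > 1e-4:
                assert f.sigma_u2_hat == pytest.approx(
                    oracle["sigma_u2"], rel=1e-6, abs=1e-7
                )
                assert f.se_beta1 == pytest.approx(oracle["se"][1], rel=1e-6)

    def test_matches_nlme_lme(self, tmp_path):
        """Agreement with nlme::lme, the standard REML tool for these models,
        including a boundary case."""
        rows = []
        for i in (3, 6):  # one interior, one boundary draw
            t = _random_small_trial(i)
            csv = tmp_path / f"trial{i}.csv"
            t.to_frame().to_csv(csv, index=False)
            rows.append((i, t))
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                """
                library(nlme)
                for (path in commandArgs(trailingOnly=TRUE)) {
                  d <- read.csv(path)
                  m <- lme(y ~ x + z, random = ~1|cluster, data=d, method="REML")
                  vc <- VarCorr(m)
                  cat(sprintf("%s %.10f %.10f %.10f %.10f\\n", path,
                      fixef(m)["x"], sqrt(vcov(m)["x","x"]),
                      as.numeric(vc[1,1]), as.numeric(vc[2,1])))
                }
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)] + [str(tmp_path / f"trial{i}.csv") for i, _ in rows],
            capture_output=True,
            text=True,
            check=True,
        )
        lines = {l.split()[0]: list(map(float, l.split()[1:]))
                 for l in out.stdout.strip().splitlines()}
        for i, t in rows:
            beta1, se, su2, se2 = lines[str(tmp_path / f"trial{i}.csv")]
            f = fit_adjusted(t)
            assert f.beta1_hat == pytest.approx(beta1, rel=1e-6)
            assert f.se_beta1 == pytest.approx(se, rel=1e-4)
            assert f.sigma_e2_hat == pytest.approx(se2, rel=1e-4)
            assert f.sigma_u2_hat == pytest.approx(su2, abs=1e-4)


class TestFitExport:
    def test_long_format_fit_table(self, toy_trial):
        from crtimbalance.fit import fits_to_frame

        frame = fits_to_frame(
            [fit_adjusted(toy_trial), fit_unadjusted(toy_trial)],
            condition={"n1": 2, "n2": 4},
        )
        assert list(frame.replicate) == [0, 1]
        assert list(frame.model) == ["adjusted", "unadjusted"]
        assert {"beta1_hat", "se_beta1", "df", "t_stat", "p_value", "reject"} <= set(
            frame.columns
        )


class TestVarianceOrdering:
    def test_unadjusted_cluster_variance_exceeds_adjusted(self):
        """Omitting a real cluster-level covariate inflates the estimated
        cluster-level variance on average."""
        d = make_design(5, 12, 5)
        params = ModelParams.from_icc(0.1, 0.5, 0.8)
        diffs = np.empty(2000)
        for r in range(2000):
            t = generate_trial(d, params, np.random.SeedSequence((9, r)))
            su_adj, _ = reml_components(t, adjusted=True)
            su_un, _ = reml_components(t, adjusted=False)
            diffs[r] = su_un - su_adj
        assert diffs.mean() > 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))


class TestErrors:
    def test_collinear_adjusted_fit_raises(self):
        d = TrialDesign(
            n1=2,
            n2=4,
            x=np.array([1, 1, 0, 0]),
            z=np.array([1, 1, 0, 0]),
            imbalance=ImbalanceSpec(q=0.99, k=2, rho_xz=1.0),
        )
        t = TrialData(design=d, y=np.arange(8.0).reshape(4, 2))
        with pytest.raises(CollinearDesignError):
            fit_adjusted(t)

    def test_single_subject_clusters_raise(self):
        d = make_design(1, 8, 2)
        t = TrialData(design=d, y=np.arange(8.0).reshape(8, 1))
        with pytest.raises(ValueError):
            fit_adjusted(t)
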