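"""Sampler tests: R-hat, summaries, parameter recovery, imputation quality."""

import arviz as az
import numpy as np
import pytest

from bayesmr import (
    CombinedDataset,
    MCMCSettings,
    PriorSpec,
    SimulationConfig,
    fit,
    rhat,
    simulate_combined,
    summarize,
)

FAST = MCMCSettings(iterations=500, warmup=500, chains=2, seed=99)


@pytest.fixture(scope="module")
def fitted():
    """One fit at the standard conditions (beta = 0.3, alpha = 0.3, 20% missing)."""
    cfg = SimulationConfig(
        n_total=400, missing_rate=0.2, alpha_level=0.3, beta_level=0.3, seed=17
    )
    combined, params = simulate_combined(cfg, 0, keep_hidden=True)
    settings = MCMCSettings(iterations=2000, warmup=500, chains=2, seed=99)
    return combined, params, fit(combined, settings=settings)


class TestRhat:
    def test_identical_constant_chains_give_unity(self):
        chains = np.ones((2, 100))
        assert rhat(chains) == 1.0

    def test_iid_standard_normal_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 1000))
        assert 0.99 <= rhat(chains) <= 1.02

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(-5, 1, 500), rng.normal(5, 1, 500)])
        assert rhat(chains) > 2.0

    def test_matches_arviz_split_rhat(self, rng):
        chains = np.cumsum(rng.standard_normal((4, 800)), axis=1) * 0.05
        ours = rhat(chains)
        theirs = float(
            np.asarray(az.rhat(az.convert_to_dataset(chains[:, :, None]), method="split")["x"]).ravel()[0]
        )
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_shape_requirements(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestSummarize:
    def test_constant_draws(self, fitted):
        _, _, draws = fitted
        import copy

        frozen = copy.deepcopy(draws)
        frozen.draws = np.full_like(frozen.draws, 3.25)
        s = summarize(frozen)
        assert np.allclose(s["mean"], 3.25)
        assert np.allclose(s["sd"], 0.0)
        assert np.allclose(s["lower"], 3.25)
        assert np.allclose(s["upper"], 3.25)

    def test_quantiles_match_sorted_oracle(self, fitted):
        _, _, draws = fitted
        pooled = np.sort(draws.pooled("beta1"))
        lo, hi = draws.interval("beta1", 0.95)
        # independent quantile routine: linear interpolation over sorted draws
        def quantile(q):
            h = q * (pooled.size - 1)
            i = int(np.floor(h))
            return pooled[i] + (h - i) * (pooled[min(i + 1, pooled.size - 1)] - pooled[i])

        assert lo == pytest.approx(quantile(0.025))
        assert hi == pytest.approx(quantile(0.975))

    def test_level_out_of_range_rejected(self, fitted):
        _, _, draws = fitted
        with pytest.raises(ValueError, match="level"):
            summarize(draws, level=1.0)
        with pytest.raises(ValueError, match="level"):
            draws.interval("beta1", 0.0)


class TestFit:
    def test_recovers_causal_effects(self, fitted):
        _, params, draws = fitted
        for name, truth in (("beta1", params.beta1), ("beta2", params.beta2)):
            assert abs(draws.mean(name) - truth) < 3 * draws.sd(name) + 0.01

    def test_structural_rhat_below_threshold(self, fitted):
        _, _, draws = fitted
        assert draws.max_rhat() < 1.1

    def test_imputed_exposures_track_hidden_truth(self, fitted):
        combined, _, draws = fitted
        r = np.corrcoef(draws.latent_means["X1_star"], combined.study_b.hidden_X1)[0, 1]
        assert r > 0.9

    def test_confounder_sign_mixture_is_symmetric(self, fitted):
        # the (delta, U) reflection makes the delta posterior a symmetric
        # two-mode mixture; the sampler must visit both modes
        _, _, draws = fitted
        d = draws.pooled("delta_x1")
        assert d.max() > 0.5 and d.min() < -0.5
        assert abs(np.mean(d > 0) - 0.5) < 0.2

    def test_posterior_concentrates_with_sample_size(self):
        sds = {}
        for n in (400, 1600):
            cfg = SimulationConfig(
                n_total=n, missing_rate=0.5, alpha_level=0.3, beta_level=0.3, seed=23
            )
            combined, _ = simulate_combined(cfg, 0)
            draws = fit(combined, settings=FAST)
            sds[n] = draws.sd("beta1")
        assert sds[1600] < sds[400]

    def test_missing_rate_zero_out_of_contract(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_total=400, missing_rate=0.0)

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(n_total=100, missing_rate=0.5, seed=5)
        combined, _ = simulate_combined(cfg, 0)
        s = MCMCSettings(iterations=50, warmup=50, chains=2, seed=7)
        d1 = fit(combined, settings=s)
        d2 = fit(combined, settings=s)
        np.testing.assert_array_equal(d1.draws, d2.draws)

    def test_posterior_matches_independent_mcmc_engine(self, tmp_path):
        # dual-route check: the same model fitted in JAGS (which imputes NA
        # responses natively) must reproduce the posterior of the causal
        # effects and identified residual scales within Monte-Carlo error
        import subprocess

        from bayesmr.mr_model import combined_to_frame

        cfg = SimulationConfig(
            n_total=150, missing_rate=0.5, alpha_level=0.3, beta_level=0.3, seed=77
        )
        combined, _ = simulate_combined(cfg, 0)
        data_csv = tmp_path / "data.csv"
        combined_to_frame(combined).to_csv(data_csv, index=False)
        model = """
        model {
          for (j in 1:L) { a1[j] ~ dnorm(0, 1/0.09) }
          for (j in 1:K) { a2[j] ~ dnorm(0, 1/0.09) }
          for (j in 1:M) { a31[j] ~ dnorm(0, 1/0.09); a32[j] ~ dnorm(0, 1/0.09) }
          beta1 ~ dnorm(0, 0.01); beta2 ~ dnorm(0, 0.01)
          dx1 ~ dnorm(0, 1); dx2 ~ dnorm(0, 1); dy1 ~ dnorm(0, 1); dy2 ~ dnorm(0, 1)
          vx1 ~ dnorm(0, 1); vx2 ~ dnorm(0, 1); vy1 ~ dnorm(0, 1); vy2 ~ dnorm(0, 1)
          for (g in 1:8) { ig[g] ~ dgamma(3, 2); sig[g] <- 1/ig[g]; tau[g] <- 1/(sig[g]*sig[g]) }
          for (i in 1:n) {
            U[i] ~ dnorm(0, 1)
            mx1[i] <- inprod(a1, Z1[i,]) + inprod(a31, Z3[i,]) + dx1*U[i] + vx1*isB[i]
            mx2[i] <- inprod(a2, Z2[i,]) + inprod(a32, Z3[i,]) + dx2*U[i] + vx2*isB[i]
            X1[i] ~ dnorm(mx1[i], isB[i]*tau[5] + (1-isB[i])*tau[1])
            X2[i] ~ dnorm(mx2[i], isB[i]*tau[6] + (1-isB[i])*tau[2])
            Y1[i] ~ dnorm(beta1*X1[i] + dy1*U[i] + vy1*isB[i], isB[i]*tau[7] + (1-isB[i])*tau[3])
            Y2[i] ~ dnorm(beta2*X2[i] + dy2*U[i] + vy2*isB[i], isB[i]*tau[8] + (1-isB[i])*tau[4])
          }
        }"""
        (tmp_path / "model.jags").write_text(model)
        rscript = f"""
        suppressMessages(library(rjags))
        df <- read.csv("{data_csv}")
        L <- 15; K <- 15; M <- 5
        data <- list(n = nrow(df), L = L, K = K, M = M,
                     Z1 = as.matrix(df[, paste0("Z1_", 1:L)]),
                     Z2 = as.matrix(df[, paste0("Z2_", 1:K)]),
                     Z3 = as.matrix(df[, paste0("Z3_", 1:M)]),
                     X1 = df$X1, X2 = df$X2, Y1 = df$Y1, Y2 = df$Y2,
                     isB = as.numeric(df$study == "B"))
        set.seed(1)
        jm <- jags.model("{tmp_path / 'model.jags'}", data = data, n.chains = 2,
                         n.adapt = 500, quiet = TRUE)
        update(jm, 1500)
        samp <- coda.samples(jm, c("beta1", "beta2", "sig"), n.iter = 3000)
        s <- summary(samp)$statistics
        out <- s[c("beta1", "beta2", "sig[3]"), c("Mean", "SD")]
        write.csv(out, "{tmp_path / 'jags.csv'}")
        """
        (tmp_path / "check.R").write_text(rscript)
        subprocess.run(
            ["Rscript", str(tmp_path / "check.R")], check=True, capture_output=True
        )
        import pandas as pd

        jags = pd.read_csv(tmp_path / "jags.csv", index_col=0)
        draws = fit(
            combined, settings=MCMCSettings(iterations=2000, warmup=1000, chains=2, seed=3)
        )
        for ours, theirs in (("beta1", "beta1"), ("beta2", "beta2"), ("sigma_y1a", "sig[3]")):
            mean_tol = 3.0 * max(draws.sd(ours), jags.loc[theirs, "SD"]) / np.sqrt(50)
            assert draws.mean(ours) == pytest.approx(jags.loc[theirs, "Mean"], abs=mean_tol)
            assert draws.sd(ours) == pytest.approx(jags.loc[theirs, "SD"], rel=0.35)

    def test_homogeneous_data_consistent_with_zero_v(self):
        # data generated with V = 0: the V posteriors should cover zero
        cfg = SimulationConfig(
            n_total=400, missing_rate=0.5, alpha_level=0.3, beta_level=0.3,
            V_low=0.0, V_high=0.0, seed=41,
        )
        combined, _ = simulate_combined(cfg, 0)
        draws = fit(combined, settings=FAST)
        for name in ("v_y1", "v_y2"):
            lo, hi = draws.interval(name, 0.99)
            assert lo < 0.0 < hi
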