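"""MCMC inference with simultaneous imputation of the missing exposures.

The posterior targeted is the joint law of the structural parameters, the
per-individual confounders U (both studies) and the imputed Study-B exposures
X1*, X2*, under the likelihood of :mod:`bayesmr.mr_model` summed over both
studies plus the stated priors.

Because every structural equation is linear-Gaussian, the sampler is a Gibbs
scan with exact conditional draws:

1. impute X1*, X2* for Study B from their normal full conditionals (each
   exposure enters its own regression as the response and the matching
   outcome regression as a covariate);
2. draw the coefficient block of each of the four regressions — instrument
   strengths, confounder loading and Study-B intercept together — from the
   conjugate multivariate normal given the residual scales;
3. draw each residual sd sigma by univariate slice sampling (the
   Inv-Gamma(3, 2) prior is placed on the sd itself, which is not conjugate);
4. draw all U from their independent normal full conditionals.

One scan per iteration; imputation and parameter estimation therefore happen
inside a single Markov chain, which is the "impute, complete, estimate,
repeat" scheme with exact conditional steps.

Two exact non-identified directions of the model need dedicated moves,
because coordinate-wise Gibbs mixes arbitrarily slowly along them:

* Because Study B's exposures are entirely latent, shifting every imputed
  X1* by a constant c while moving v_x1 to v_x1 + c and v_y1 to
  v_y1 - beta1 c leaves the likelihood unchanged; only the N(0, V_sd^2)
  priors on the intercepts tie the level down.  The sampler therefore draws
  the shift c from its exact Gaussian full conditional each scan (and the
  analogous move for X2*), and similarly a location shift of all Study-B
  confounders U with the matching intercept adjustments.
* The likelihood is exactly invariant under jointly negating all four
  confounder loadings delta and every U, so the posterior is a symmetric
  two-mode mixture.  A sign-flip move applies this reflection with
  probability 1/2 per scan, letting every chain traverse both modes (the
  causal effects beta are invariant under the reflection).

Convergence is monitored with the plain split-chain potential scale reduction
statistic (R-hat), computed for every structural parameter and — from running
split-half moments, to avoid storing per-individual trajectories — for the
latent U and X* as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mr_model import CombinedDataset, PriorSpec, StructuralParams

__all__ = ["MCMCSettings", "PosteriorDraws", "fit", "rhat", "summarize"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCMCSettings:
    """Chain geometry and initialisation dispersion."""

    iterations: int = 1000  # post-warmup draws kept per chain
    warmup: int = 1000
    chains: int = 4
    seed: int = 0
    init_scale: float = 0.1
    store_latent_draws: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.warmup < 0:
            raise ValueError("warmup must be >= 0")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for R-hat")


def rhat(chains: np.ndarray) -> float:
    """Plain split-chain potential scale reduction for one parameter.

    ``chains`` is a (n_chains, n_iterations) array.  Each chain is split in
    half; R-hat compares the between- and within-half variances.  Chains with
    zero total variance return 1.0 by convention.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need a (chains >= 2, iterations >= 4) array")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    return _rhat_from_moments(
        splits.mean(axis=1), splits.var(axis=1, ddof=1), half
    )


def _rhat_from_moments(means: np.ndarray, variances: np.ndarray, m: int) -> float:
    """Split R-hat from per-split-chain means and variances of length-m halves."""
    W = float(np.mean(variances))
    B = m * float(np.var(means, ddof=1))
    if W <= 0.0:
        if B <= 0.0:
            logger.debug("zero total variance in R-hat; returning 1 by convention")
            return 1.0
        return np.inf
    var_hat = (m - 1) / m * W + B / m
    return float(np.sqrt(var_hat / W))


def summarize(draws: "PosteriorDraws", level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, sd and equal-tailed interval per structural parameter.

    Quantiles are empirical quantiles of the pooled post-warmup draws.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    pooled = draws.draws.reshape(-1, draws.draws.shape[-1])
    lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    q = np.quantile(pooled, [lo, 0.5, hi], axis=0)
    return pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "sd": pooled.std(axis=0, ddof=1),
            "lower": q[0],
            "median": q[1],
            "upper": q[2],
            "rhat": draws.rhats(),
        },
        index=draws.names,
    )


@dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws of the structural parameters plus diagnostics.

    ``draws`` has shape (chains, iterations, n_parameters); ``names`` labels
    the last axis.  Posterior means of the latent per-individual quantities
    (U for all rows, X1*/X2* for Study B) are kept instead of their full
    trajectories, together with split-R-hat values computed from running
    moments; full latent trajectories are stored only on request.
    """

    names: list[str]
    draws: np.ndarray
    latent_means: dict[str, np.ndarray]
    latent_rhat: dict[str, np.ndarray]
    settings: MCMCSettings
    latent_draws: Optional[dict[str, np.ndarray]] = field(default=None, repr=False)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def parameter(self, name: str) -> np.ndarray:
        """(chains, iterations) draws for one named parameter."""
        return self.draws[:, :, self.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.parameter(name).reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.pooled(name).mean())

    def sd(self, name: str) -> float:
        return float(self.pooled(name).std(ddof=1))

    def interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        if not 0.0 < level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {level}")
        lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
        q = np.quantile(self.pooled(name), [lo, hi])
        return float(q[0]), float(q[1])

    def rhats(self) -> np.ndarray:
        return np.array([rhat(self.draws[:, :, j]) for j in range(len(self.names))])

    def rhat(self, name: str) -> float:
        return rhat(self.parameter(name))

    def max_rhat(self, structural_only: bool = True) -> float:
        worst = float(self.rhats().max())
        if not structural_only:
            for arr in self.latent_rhat.values():
                if arr.size:
                    worst = max(worst, float(arr.max()))
        return worst

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return summarize(self, level)


def structural_param_names(L: int, K: int, M: int) -> list[str]:
    names = [f"alpha1[{j + 1}]" for j in range(L)]
    names += [f"alpha2[{j + 1}]" for j in range(K)]
    names += [f"alpha31[{j + 1}]" for j in range(M)]
    names += [f"alpha32[{j + 1}]" for j in range(M)]
    names += ["beta1", "beta2", "delta_x1", "delta_x2", "delta_y1", "delta_y2"]
    names += [
        "sigma_x1a", "sigma_x2a", "sigma_y1a", "sigma_y2a",
        "sigma_x1b", "sigma_x2b", "sigma_y1b", "sigma_y2b",
    ]
    names += ["v_x1", "v_x2", "v_y1", "v_y2"]
    return names


# ---------------------------------------------------------------------------
# Gibbs machinery

def _sample_coef(
    D: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    prior_prec: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw from N(Lam^-1 b, Lam^-1) with Lam = D'WD + P0, b = D'Wy."""
    Dw = D * w[:, None]
    Lam = Dw.T @ D
    Lam[np.diag_indices_from(Lam)] += prior_prec
    b = Dw.T @ y
    L = np.linalg.cholesky(Lam)
    mu = np.linalg.solve(L.T, np.linalg.solve(L, b))
    z = rng.standard_normal(len(b))
    return mu + np.linalg.solve(L.T, z)


def _slice_sample(
    x0: float,
    logf,
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 50,
) -> float:
    """Univariate slice sampler with stepping-out and shrinkage."""
    y = logf(x0) + np.log(rng.uniform())
    lo = x0 - width * rng.uniform()
    hi = lo + width
    for _ in range(max_steps):
        if logf(lo) <= y:
            break
        lo -= width
    for _ in range(max_steps):
        if logf(hi) <= y:
            break
        hi += width
    while True:
        x1 = rng.uniform(lo, hi)
        if logf(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _slice_sample_log_sigma(
    x0: float,
    n_obs: float,
    ss: float,
    shape: float,
    scale: float,
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 50,
) -> float:
    """Slice-sample x = log(sigma) for a normal scale with Inv-Gamma prior on sigma.

    Target (up to a constant): -(n_obs + shape) x - ss/2 * exp(-2x) - scale * exp(-x).
    """

    def logf(x: float) -> float:
        return -(n_obs + shape) * x - 0.5 * ss * np.exp(-2.0 * x) - scale * np.exp(-x)

    return _slice_sample(x0, logf, rng, width=width, max_steps=max_steps)


def _slice_sample_log_sigma_marginal(
    x0: float,
    n_obs: float,
    ss_marg: float,
    beta: float,
    var_y: float,
    shape: float,
    scale: float,
    rng: np.random.Generator,
) -> float:
    """Slice-sample x = log(sigma_xB) with the latent exposures integrated out.

    With X* marginalised, the Study-B outcome residuals have variance
    beta^2 sigma^2 + var_y, which is the only way the data inform sigma_xB;
    conditioning on the imputed X* instead creates a slowly mixing feedback
    loop (degenerating to no mixing at all when beta = 0).
    """

    def logf(x: float) -> float:
        v = beta * beta * np.exp(2.0 * x) + var_y
        return -0.5 * n_obs * np.log(v) - 0.5 * ss_marg / v - shape * x - scale * np.exp(-x)

    return _slice_sample(x0, logf, rng)


class _RunningSplitMoments:
    """Per-chain split-half running moments for latent-vector R-hat."""

    def __init__(self, n_chains: int, size: int, iterations: int) -> None:
        self.half = iterations // 2
        self.count = np.zeros((2 * n_chains, 1))
        self.s1 = np.zeros((2 * n_chains, size))
        self.s2 = np.zeros((2 * n_chains, size))

    def update(self, chain: int, t: int, x: np.ndarray) -> None:
        if t < self.half:
            row = 2 * chain
        elif t < 2 * self.half:
            row = 2 * chain + 1
        else:
            return
        self.count[row] += 1
        self.s1[row] += x
        self.s2[row] += x * x

    def rhat(self) -> np.ndarray:
        n = self.count
        means = self.s1 / n
        variances = (self.s2 - n * means**2) / (n - 1)
        out = np.empty(self.s1.shape[1])
        for j in range(out.size):
            out[j] = _rhat_from_moments(means[:, j], variances[:, j], self.half)
        return out


def _ols_impute_init(combined: CombinedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Initial X* for Study B: least-squares prediction from instruments fit on A."""
    a, b = combined.study_a, combined.study_b
    D_a1 = np.column_stack([a.Z1, a.Z3, np.ones(a.n)])
    D_b1 = np.column_stack([b.Z1, b.Z3, np.ones(b.n)])
    D_a2 = np.column_stack([a.Z2, a.Z3, np.ones(a.n)])
    D_b2 = np.column_stack([b.Z2, b.Z3, np.ones(b.n)])
    c1, *_ = np.linalg.lstsq(D_a1, a.X1, rcond=None)
    c2, *_ = np.linalg.lstsq(D_a2, a.X2, rcond=None)
    return D_b1 @ c1, D_b2 @ c2


def fit(
    dataset: CombinedDataset,
    priors: PriorSpec = PriorSpec(),
    settings: MCMCSettings = MCMCSettings(),

) -> PosteriorDraws:
    """Sample the joint posterior of parameters, confounders U and imputed X*.

    Runs ``settings.chains`` independent chains (seeded from independent
    streams of ``settings.seed``), each ``warmup + iterations`` Gibbs scans;
    warmup draws are discarded.
    """
    a, b = dataset.study_a, dataset.study_b
    lay = dataset.layout
    L, K, M = lay.L, lay.K, lay.M
    nA, nB, n = a.n, b.n, dataset.n
    names = structural_param_names(L, K, M)
    P = len(names)

    # stacked rows: Study A first, then Study B
    is_b = np.zeros(n)
    is_b[nA:] = 1.0
    Z1 = np.vstack([a.Z1, b.Z1])
    Z2 = np.vstack([a.Z2, b.Z2])
    Z3 = np.vstack([a.Z3, b.Z3])
    Y1 = np.concatenate([a.Y1, b.Y1])
    Y2 = np.concatenate([a.Y2, b.Y2])

    # design matrices with mutable columns for U (and X in the outcome ones)
    D1 = np.column_stack([Z1, Z3, np.zeros(n), is_b])  # alpha1, alpha31, delta_x1, v_x1
    D2 = np.column_stack([Z2, Z3, np.zeros(n), is_b])  # alpha2, alpha32, delta_x2, v_x2
    E1 = np.column_stack([np.zeros(n), np.zeros(n), is_b])  # beta1, delta_y1, v_y1
    E2 = np.column_stack([np.zeros(n), np.zeros(n), is_b])  # beta2, delta_y2, v_y2

    prior_prec_x = np.concatenate(
        [
            np.full(L + M, priors.alpha_sd**-2),
            [priors.delta_sd**-2, priors.V_sd**-2],
        ]
    )
    prior_prec_x2 = np.concatenate(
        [
            np.full(K + M, priors.alpha_sd**-2),
            [priors.delta_sd**-2, priors.V_sd**-2],
        ]
    )
    prior_prec_y = np.array([priors.beta_sd**-2, priors.delta_sd**-2, priors.V_sd**-2])

    total = settings.warmup + settings.iterations
    draws = np.empty((settings.chains, settings.iterations, P))
    lat_sum = {"U": np.zeros(n), "X1_star": np.zeros(nB), "X2_star": np.zeros(nB)}
    lat_mom = {k: _RunningSplitMoments(settings.chains, v.size, settings.iterations)
               for k, v in lat_sum.items()}
    lat_draws = (
        {k: np.empty((settings.chains, settings.iterations, v.size)) for k, v in lat_sum.items()}
        if settings.store_latent_draws
        else None
    )
    x1_init, x2_init = _ols_impute_init(dataset)
    ig_mean = priors.sigma_scale / max(priors.sigma_shape - 1.0, 0.5)

    for chain in range(settings.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(settings.seed, spawn_key=(chain,))
        )
        sc = settings.init_scale
        # overdispersed start: prior draws shrunk toward zero (sigmas jittered
        # around the prior mean on the log scale)
        c1 = np.concatenate(
            [
                rng.normal(0.0, sc * priors.alpha_sd, L + M),
                rng.normal(0.0, sc * priors.delta_sd, 1),
                rng.normal(0.0, sc * priors.V_sd, 1),
            ]
        )
        c2 = np.concatenate(
            [
                rng.normal(0.0, sc * priors.alpha_sd, K + M),
                rng.normal(0.0, sc * priors.delta_sd, 1),
                rng.normal(0.0, sc * priors.V_sd, 1),
            ]
        )
        e1 = np.array(
            [
                rng.normal(0.0, sc * priors.beta_sd),
                rng.normal(0.0, sc * priors.delta_sd),
                rng.normal(0.0, sc * priors.V_sd),
            ]
        )
        e2 = np.array(
            [
                rng.normal(0.0, sc * priors.beta_sd),
                rng.normal(0.0, sc * priors.delta_sd),
                rng.normal(0.0, sc * priors.V_sd),
            ]
        )
        log_sig = np.log(ig_mean) + sc * rng.standard_normal(8)
        U = sc * rng.standard_normal(n)
        X1b = x1_init + sc * rng.standard_normal(nB)
        X2b = x2_init + sc * rng.standard_normal(nB)
        X1 = np.concatenate([a.X1, X1b])
        X2 = np.concatenate([a.X2, X2b])

        for t in range(total):
            sig = np.exp(log_sig)
            s_x1a, s_x2a, s_y1a, s_y2a, s_x1b, s_x2b, s_y1b, s_y2b = sig
            w_x1 = np.where(is_b == 1.0, s_x1b**-2, s_x1a**-2)
            w_x2 = np.where(is_b == 1.0, s_x2b**-2, s_x2a**-2)
            w_y1 = np.where(is_b == 1.0, s_y1b**-2, s_y1a**-2)
            w_y2 = np.where(is_b == 1.0, s_y2b**-2, s_y2a**-2)

            # --- Study-B exposure-equation scales (X* marginalised out), then
            #     imputation of X1*, X2* from their full conditionals
            Ub = U[nA:]
            beta1, delta_y1, v_y1 = e1
            beta2, delta_y2, v_y2 = e2
            m1 = b.Z1 @ c1[:L] + b.Z3 @ c1[L : L + M] + c1[L + M] * Ub + c1[L + M + 1]
            resid_marg = b.Y1 - beta1 * m1 - delta_y1 * Ub - v_y1
            log_sig[4] = _slice_sample_log_sigma_marginal(
                log_sig[4], nB, float(resid_marg @ resid_marg), beta1, s_y1b**2,
                priors.sigma_shape, priors.sigma_scale, rng,
            )
            s_x1b = np.exp(log_sig[4])
            prec = s_x1b**-2 + beta1**2 * s_y1b**-2
            mean = (m1 * s_x1b**-2 + beta1 * (b.Y1 - delta_y1 * Ub - v_y1) * s_y1b**-2) / prec
            X1b = mean + rng.standard_normal(nB) / np.sqrt(prec)
            m2 = b.Z2 @ c2[:K] + b.Z3 @ c2[K : K + M] + c2[K + M] * Ub + c2[K + M + 1]
            resid_marg = b.Y2 - beta2 * m2 - delta_y2 * Ub - v_y2
            log_sig[5] = _slice_sample_log_sigma_marginal(
                log_sig[5], nB, float(resid_marg @ resid_marg), beta2, s_y2b**2,
                priors.sigma_shape, priors.sigma_scale, rng,
            )
            s_x2b = np.exp(log_sig[5])
            prec = s_x2b**-2 + beta2**2 * s_y2b**-2
            mean = (m2 * s_x2b**-2 + beta2 * (b.Y2 - delta_y2 * Ub - v_y2) * s_y2b**-2) / prec
            X2b = mean + rng.standard_normal(nB) / np.sqrt(prec)
            X1[nA:] = X1b
            X2[nA:] = X2b
            w_x1 = np.where(is_b == 1.0, s_x1b**-2, s_x1a**-2)
            w_x2 = np.where(is_b == 1.0, s_x2b**-2, s_x2a**-2)

            # --- regression coefficient blocks (conjugate MVN)
            D1[:, L + M] = U
            D2[:, K + M] = U
            c1 = _sample_coef(D1, X1, w_x1, prior_prec_x, rng)
            c2 = _sample_coef(D2, X2, w_x2, prior_prec_x2, rng)
            E1[:, 0] = X1
            E1[:, 1] = U
            E2[:, 0] = X2
            E2[:, 1] = U
            e1 = _sample_coef(E1, Y1, w_y1, prior_prec_y, rng)
            e2 = _sample_coef(E2, Y2, w_y2, prior_prec_y, rng)

            # --- remaining residual scales by slice sampling on log sigma
            #     (sigma_x1b, sigma_x2b were updated marginally above)
            r1 = X1 - D1 @ c1
            r2 = X2 - D2 @ c2
            r3 = Y1 - E1 @ e1
            r4 = Y2 - E2 @ e2
            for gi, resid in enumerate((r1, r2, r3, r4)):
                ss_a = float(np.sum(resid[:nA] ** 2))
                log_sig[gi] = _slice_sample_log_sigma(
                    log_sig[gi], nA, ss_a, priors.sigma_shape, priors.sigma_scale, rng
                )
                if gi >= 2:
                    ss_b = float(np.sum(resid[nA:] ** 2))
                    log_sig[4 + gi] = _slice_sample_log_sigma(
                        log_sig[4 + gi], nB, ss_b, priors.sigma_shape, priors.sigma_scale, rng
                    )
            sig = np.exp(log_sig)
            s_x1a, s_x2a, s_y1a, s_y2a, s_x1b, s_x2b, s_y1b, s_y2b = sig
            w_x1 = np.where(is_b == 1.0, s_x1b**-2, s_x1a**-2)
            w_x2 = np.where(is_b == 1.0, s_x2b**-2, s_x2a**-2)
            w_y1 = np.where(is_b == 1.0, s_y1b**-2, s_y1a**-2)
            w_y2 = np.where(is_b == 1.0, s_y2b**-2, s_y2a**-2)

            # --- latent confounders: independent normal full conditionals
            d_x1, d_x2 = c1[L + M], c2[K + M]
            beta1, d_y1, v_y1 = e1
            beta2, d_y2, v_y2 = e2
            rx1 = X1 - (D1 @ c1 - d_x1 * U)
            rx2 = X2 - (D2 @ c2 - d_x2 * U)
            ry1 = Y1 - (beta1 * X1 + v_y1 * is_b)
            ry2 = Y2 - (beta2 * X2 + v_y2 * is_b)
            prec_u = 1.0 + d_x1**2 * w_x1 + d_x2**2 * w_x2 + d_y1**2 * w_y1 + d_y2**2 * w_y2
            mean_u = (
                d_x1 * rx1 * w_x1 + d_x2 * rx2 * w_x2 + d_y1 * ry1 * w_y1 + d_y2 * ry2 * w_y2
            ) / prec_u
            U = mean_u + rng.standard_normal(n) / np.sqrt(prec_u)

            # --- exact moves along the non-identified directions
            v_prec = priors.V_sd**-2
            # shift of (X1*, v_x1, v_y1): likelihood-invariant, prior-Gaussian
            prec_c = (1.0 + beta1**2) * v_prec
            mu_c = (beta1 * e1[2] - c1[L + M + 1]) * v_prec / prec_c
            shift = mu_c + rng.standard_normal() / np.sqrt(prec_c)
            X1b = X1b + shift
            X1[nA:] = X1b
            c1[L + M + 1] += shift
            e1[2] -= beta1 * shift
            # same for (X2*, v_x2, v_y2)
            prec_c = (1.0 + beta2**2) * v_prec
            mu_c = (beta2 * e2[2] - c2[K + M + 1]) * v_prec / prec_c
            shift = mu_c + rng.standard_normal() / np.sqrt(prec_c)
            X2b = X2b + shift
            X2[nA:] = X2b
            c2[K + M + 1] += shift
            e2[2] -= beta2 * shift
            # location shift of all Study-B confounders with intercept adjustment
            dvec = np.array([d_x1, d_x2, d_y1, d_y2])
            vvec = np.array([c1[L + M + 1], c2[K + M + 1], e1[2], e2[2]])
            prec_d = nB + float(dvec @ dvec) * v_prec
            mu_d = (float(dvec @ vvec) * v_prec - nB * float(U[nA:].mean())) / prec_d
            shift = mu_d + rng.standard_normal() / np.sqrt(prec_d)
            U[nA:] += shift
            c1[L + M + 1] -= d_x1 * shift
            c2[K + M + 1] -= d_x2 * shift
            e1[2] -= d_y1 * shift
            e2[2] -= d_y2 * shift
            # reflection (delta, U) -> (-delta, -U): exact likelihood symmetry
            if rng.uniform() < 0.5:
                U = -U
                c1[L + M] = -c1[L + M]
                c2[K + M] = -c2[K + M]
                e1[1] = -e1[1]
                e2[1] = -e2[1]

            t_keep = t - settings.warmup
            if t_keep >= 0:
                # layout: alpha1, alpha2, alpha31, alpha32, betas, deltas, sigmas, Vs
                row = draws[chain, t_keep]
                row[:L] = c1[:L]
                row[L : L + K] = c2[:K]
                row[L + K : L + K + M] = c1[L : L + M]
                row[L + K + M : L + K + 2 * M] = c2[K : K + M]
                o = L + K + 2 * M
                row[o : o + 6] = (e1[0], e2[0], c1[L + M], c2[K + M], e1[1], e2[1])
                row[o + 6 : o + 14] = (
                    sig[0], sig[1], sig[2], sig[3], sig[4], sig[5], sig[6], sig[7],
                )
                row[o + 14 : o + 18] = (c1[L + M + 1], c2[K + M + 1], e1[2], e2[2])
                lat_sum["U"] += U
                lat_sum["X1_star"] += X1b
                lat_sum["X2_star"] += X2b
                lat_mom["U"].update(chain, t_keep, U)
                lat_mom["X1_star"].update(chain, t_keep, X1b)
                lat_mom["X2_star"].update(chain, t_keep, X2b)
                if lat_draws is not None:
                    lat_draws["U"][chain, t_keep] = U
                    lat_draws["X1_star"][chain, t_keep] = X1b
                    lat_draws["X2_star"][chain, t_keep] = X2b

    n_kept = settings.chains * settings.iterations
    latent_means = {k: v / n_kept for k, v in lat_sum.items()}
    latent_rhat = {k: m.rhat() for k, m in lat_mom.items()}
    return PosteriorDraws(
        names=names,
        draws=draws,
        latent_means=latent_means,
        latent_rhat=latent_rhat,
        settings=settings,
        latent_draws=lat_draws,
    )


def params_from_draw(draws: PosteriorDraws, chain: int, iteration: int) -> StructuralParams:
    """Rehydrate one stored draw into a StructuralParams (round-trip helper)."""
    row = draws.draws[chain, iteration]
    get = lambda name: row[draws.index(name)]
    L = sum(1 for s in draws.names if s.startswith("alpha1["))
    K = sum(1 for s in draws.names if s.startswith("alpha2["))
    M = sum(1 for s in draws.names if s.startswith("alpha31["))
    o = 0
    alpha1 = row[o : o + L]; o += L
    alpha2 = row[o : o + K]; o += K
    alpha31 = row[o : o + M]; o += M
    alpha32 = row[o : o + M]; o += M
    return StructuralParams(
        alpha1=alpha1, alpha2=alpha2, alpha31=alpha31, alpha32=alpha32,
        beta1=get("beta1"), beta2=get("beta2"),
        delta_x1=get("delta_x1"), delta_x2=get("delta_x2"),
        delta_y1=get("delta_y1"), delta_y2=get("delta_y2"),
        sigma_x1a=get("sigma_x1a"), sigma_x2a=get("sigma_x2a"),
        sigma_y1a=get("sigma_y1a"), sigma_y2a=get("sigma_y2a"),
        sigma_x1b=get("sigma_x1b"), sigma_x2b=get("sigma_x2b"),
        sigma_y1b=get("sigma_y1b"), sigma_y2b=get("sigma_y2b"),
        v_x1=get("v_x1"), v_x2=get("v_x2"), v_y1=get("v_y1"), v_y2=get("v_y2"),
    )
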