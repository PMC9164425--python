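"""Simulation experiments evaluating the Bayesian and IVW estimators.

The small-sample study crosses three exposure missing rates (20%, 50%, 80%)
with two instrument strengths (alpha = 0.1, 0.3) and two true causal effects
(beta = 0, 0.3) at a combined sample size of 400, simulating many replicates
per configuration and scoring each estimator by four metrics: mean and sd of
the point estimates, coverage of the 95% intervals at the true effect, and —
when the true effect is non-zero — power (the fraction of intervals excluding
zero).

The large-sample study simulates a single big dataset per configuration,
fits the full data and J-way partitions, aggregates the subset posteriors by
recentring, and returns the joint (beta1, beta2) kernel-density grids for
contour comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .divide_combine import AggregatedPosterior, aggregate, kde2d, partition
from .inference import MCMCSettings, fit
from .ivw import ivw_for_pair
from .mr_model import PriorSpec
from .synthetic_data import SimulationConfig, simulate_combined

__all__ = [
    "MetricsTable",
    "coverage",
    "power",
    "run_small_study",
    "run_large_study",
    "default_grid",
    "LargeStudyResult",
]

logger = logging.getLogger(__name__)

_MASK31 = (1 << 31) - 1


def _derived_seed(base: int, *key: int) -> int:
    return int(np.random.SeedSequence(base, spawn_key=tuple(key)).generate_state(1)[0]) & _MASK31


def coverage(intervals: Sequence[tuple[float, float]], truth: float) -> float:
    """Fraction of closed intervals containing the true value."""
    if len(intervals) == 0:
        raise ValueError("empty interval list")
    return float(np.mean([lo <= truth <= hi for lo, hi in intervals]))


def power(intervals: Sequence[tuple[float, float]]) -> float:
    """Fraction of closed intervals excluding zero."""
    if len(intervals) == 0:
        raise ValueError("empty interval list")
    return float(np.mean([not (lo <= 0.0 <= hi) for lo, hi in intervals]))


@dataclass
class MetricsTable:
    """Four-metric results per (configuration, method, effect) cell."""

    frame: pd.DataFrame

    def cell(
        self,
        missing_rate: float,
        alpha_level: float,
        beta_level: float,
        method: str,
        effect: str,
    ) -> pd.Series:
        f = self.frame
        m = (
            np.isclose(f["missing_rate"], missing_rate)
            & np.isclose(f["alpha_level"], alpha_level)
            & np.isclose(f["beta_level"], beta_level)
            & (f["method"] == method)
            & (f["effect"] == effect)
        )
        if m.sum() != 1:
            raise KeyError("cell not found (or ambiguous)")
        return f[m].iloc[0]

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index=False)


def metrics_row(
    estimates: Sequence[float],
    intervals: Sequence[tuple[float, float]],
    truth: float,
    beta_level: float,
) -> dict:
    """The four metrics for one cell; power only when the true effect is non-zero."""
    est = np.asarray(estimates, dtype=float)
    return {
        "mean": float(est.mean()),
        "sd": float(est.std(ddof=1)) if est.size > 1 else 0.0,
        "coverage": coverage(intervals, truth),
        "power": power(intervals) if beta_level != 0.0 else np.nan,
        "n_replicates": est.size,
    }


def default_grid(
    n_total: int = 400, n_replicates: int = 200, seed: int = 0
) -> list[SimulationConfig]:
    """The 12-configuration evaluation grid (distinct stream per configuration)."""
    grid = []
    ci = 0
    for missing in (0.2, 0.5, 0.8):
        for alpha in (0.3, 0.1):
            for beta in (0.3, 0.0):
                grid.append(
                    SimulationConfig(
                        n_total=n_total,
                        missing_rate=missing,
                        alpha_level=alpha,
                        beta_level=beta,
                        n_replicates=n_replicates,
                        seed=_derived_seed(seed, ci),
                    )
                )
                ci += 1
    return grid


def run_small_study(
    grid: Sequence[SimulationConfig],
    settings: MCMCSettings = MCMCSettings(),
    priors: PriorSpec = PriorSpec(),
    methods: Sequence[str] = ("Bayesian", "IVW"),
    n_replicates: Optional[int] = None,
    rhat_limit: float = 1.1,
) -> MetricsTable:
    """Run the replicate study over a configuration grid.

    Per replicate: simulate a combined dataset, compute the IVW estimate for
    both exposure-outcome pairs, and/or fit the Bayesian model (posterior
    mean point estimate, equal-tailed 95% credible interval).  A Bayesian
    replicate whose structural R-hat exceeds ``rhat_limit`` is refit once
    with doubled iterations, then excluded (with a logged count) if still
    above the limit.
    """
    rows = []
    for config in grid:
        reps = n_replicates if n_replicates is not None else config.n_replicates
        results: dict[tuple[str, str], list] = {
            (m, e): {"est": [], "ci": []} for m in methods for e in ("beta1", "beta2")
        }
        n_excluded = 0
        for r in range(reps):
            combined, _true = simulate_combined(config, r)
            if "IVW" in methods:
                for pair, eff in ((1, "beta1"), (2, "beta2")):
                    est = ivw_for_pair(combined, pair)
                    results[("IVW", eff)]["est"].append(est.beta_hat)
                    results[("IVW", eff)]["ci"].append(est.ci95)
            if "Bayesian" in methods:
                rep_settings = _replicate_settings(settings, config.seed, r)
                draws = fit(combined, priors, rep_settings)
                if draws.max_rhat() > rhat_limit:
                    logger.info(
                        "replicate %d: max R-hat %.3f > %.2f; refitting with doubled iterations",
                        r, draws.max_rhat(), rhat_limit,
                    )
                    rep_settings = _replicate_settings(
                        settings, config.seed, r,
                        iterations=2 * settings.iterations, warmup=2 * settings.warmup,
                    )
                    draws = fit(combined, priors, rep_settings)
                    if draws.max_rhat() > rhat_limit:
                        n_excluded += 1
                        logger.warning("replicate %d excluded (R-hat %.3f)", r, draws.max_rhat())
                        continue
                for eff in ("beta1", "beta2"):
                    results[("Bayesian", eff)]["est"].append(draws.mean(eff))
                    results[("Bayesian", eff)]["ci"].append(draws.interval(eff))
        if n_excluded:
            logger.warning(
                "configuration %s: %d replicate(s) excluded for non-convergence",
                config, n_excluded,
            )
        for (method, eff), acc in results.items():
            if not acc["est"]:
                continue
            row = {
                "missing_rate": config.missing_rate,
                "alpha_level": config.alpha_level,
                "beta_level": config.beta_level,
                "method": method,
                "effect": eff,
                "n_excluded": n_excluded if method == "Bayesian" else 0,
            }
            row.update(metrics_row(acc["est"], acc["ci"], config.beta_level, config.beta_level))
            rows.append(row)
    return MetricsTable(pd.DataFrame(rows))


def _replicate_settings(
    settings: MCMCSettings, config_seed: int, replicate: int, **overrides
) -> MCMCSettings:
    kwargs = dict(
        iterations=settings.iterations,
        warmup=settings.warmup,
        chains=settings.chains,
        init_scale=settings.init_scale,
        seed=_derived_seed(config_seed, replicate, 1),
    )
    kwargs.update(overrides)
    return MCMCSettings(**kwargs)


@dataclass
class LargeStudyResult:
    """Aggregated posterior and (beta1, beta2) KDE grid per subset count J."""

    config: SimulationConfig
    true_beta: float
    posteriors: dict[int, AggregatedPosterior]
    kde_grids: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(repr=False)

    def grand_mean(self, J: int, effect: str = "beta1") -> float:
        return self.posteriors[J].mean(effect)

    def distance_to_truth(self, J: int) -> float:
        p = self.posteriors[J]
        return float(
            np.hypot(p.mean("beta1") - self.true_beta, p.mean("beta2") - self.true_beta)
        )


def run_large_study(
    config: SimulationConfig,
    J_list: Sequence[int] = (1, 5, 50),
    settings: MCMCSettings = MCMCSettings(),
    priors: PriorSpec = PriorSpec(),
    kde_grid: int = 100,
) -> LargeStudyResult:
    """Single-dataset partitioning experiment.

    Simulates one combined dataset from ``config``, then for each J fits the
    model on each of the J subsets (independent seeds per subset, so fits can
    run in any order) and aggregates by recentring.  J=1 is the plain
    full-data fit.
    """
    combined, _true = simulate_combined(config, 0)
    posteriors: dict[int, AggregatedPosterior] = {}
    grids = {}
    for J in J_list:
        subsets, _plan = partition(combined, J, seed=_derived_seed(config.seed, J, 2))
        subset_draws = []
        for j, sub in enumerate(subsets):
            sub_settings = _replicate_settings(settings, config.seed, j, seed=_derived_seed(config.seed, J, 3, j))
            subset_draws.append(fit(sub, priors, sub_settings))
        agg = aggregate(subset_draws)
        posteriors[J] = agg
        grids[J] = kde2d(agg.pooled("beta1"), agg.pooled("beta2"), grid=kde_grid)
    return LargeStudyResult(
        config=config,
        true_beta=config.beta_level,
        posteriors=posteriors,
        kde_grids=grids,
    )
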