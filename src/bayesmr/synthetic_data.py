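"""Simulation of two-study Mendelian-randomization datasets.

The generator mirrors the evaluation design: three instrument blocks of
15, 15 and 5 variants, dosages drawn i.i.d. Binomial(2, 0.3); all instrument
strengths alpha share one magnitude per configuration (0.1 or 0.3); the
causal effects beta1 = beta2 are 0 or 0.3; confounder loadings delta are 1
and residual sds sigma are 0.1 in every equation of both studies.  Study B's
four random intercepts V are drawn fresh per replicate from Uniform(-0.5, 0.5)
and its exposures are masked after generation.  The combined sample size is
split so that n_B = round(n_total * missing_rate).

Seeding is counter-based: replicate ``i`` of base seed ``s`` uses the
independent stream ``SeedSequence(s, spawn_key=(i,))``, so replicates can be
generated in any order or in parallel and still reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .mr_model import (
    CombinedDataset,
    InstrumentLayout,
    StructuralParams,
    StudyDataset,
)

__all__ = [
    "SimulationConfig",
    "draw_genotypes",
    "simulate_study",
    "simulate_combined",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation configuration of the evaluation grid."""

    layout: InstrumentLayout = InstrumentLayout(15, 15, 5)
    n_total: int = 400
    missing_rate: float = 0.5
    alpha_level: float = 0.3
    beta_level: float = 0.3
    delta_level: float = 1.0
    sigma_level: float = 0.1
    genotype_p: float = 0.3
    V_low: float = -0.5
    V_high: float = 0.5
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in (0, 1)")
        if not 0.0 < self.genotype_p < 1.0:
            raise ValueError("genotype_p must be in (0, 1)")
        if self.n_total < 2:
            raise ValueError("n_total must be at least 2")
        if self.V_high < self.V_low:
            raise ValueError("V_high must be >= V_low")
        nb = self.n_b
        if nb == 0 or nb == self.n_total:
            raise ValueError(
                f"missing_rate {self.missing_rate} with n_total {self.n_total} leaves an empty study"
            )
        if abs(nb / self.n_total - self.missing_rate) > 0.01:
            raise ValueError(
                f"rounded n_B={nb} changes the missing rate by more than 1% "
                f"({nb / self.n_total:.4f} vs {self.missing_rate})"
            )

    @property
    def n_b(self) -> int:
        # round half up, so e.g. 0.5 * 25 -> 13
        return int(np.floor(self.n_total * self.missing_rate + 0.5))

    @property
    def n_a(self) -> int:
        return self.n_total - self.n_b

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def draw_genotypes(n: int, m: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """n-by-m dosage matrix with entries i.i.d. Binomial(2, p)."""
    if n < 1 or m < 0:
        raise ValueError("n must be >= 1 and m >= 0")
    if not 0.0 < p < 1.0:
        raise ValueError(f"genotype frequency p must be in (0, 1), got {p}")
    return rng.binomial(2, p, size=(n, m)).astype(float)


def simulate_study(
    params: StructuralParams,
    n: int,
    study: str,
    rng: np.random.Generator,
    genotype_p: float = 0.3,
    keep_hidden: bool = False,
) -> StudyDataset:
    """Simulate one study from the structural equations.

    Draws U ~ N(0,1) per individual, then exposures and outcomes from the
    conditional normals of the given study (Study B means include the V
    intercepts).  For Study B the exposures are masked; ``keep_hidden``
    retains the generated values in ``hidden_X1``/``hidden_X2`` only.
    """
    lay = params.layout
    Z1 = draw_genotypes(n, lay.L, genotype_p, rng)
    Z2 = draw_genotypes(n, lay.K, genotype_p, rng)
    Z3 = draw_genotypes(n, lay.M, genotype_p, rng)
    U = rng.standard_normal(n)
    s_x1, s_x2, s_y1, s_y2 = params.sigmas(study)
    is_b = study == "B"
    m_x1 = Z1 @ params.alpha1 + Z3 @ params.alpha31 + params.delta_x1 * U
    m_x2 = Z2 @ params.alpha2 + Z3 @ params.alpha32 + params.delta_x2 * U
    if is_b:
        m_x1 = m_x1 + params.v_x1
        m_x2 = m_x2 + params.v_x2
    X1 = rng.normal(m_x1, s_x1)
    X2 = rng.normal(m_x2, s_x2)
    m_y1 = params.beta1 * X1 + params.delta_y1 * U + (params.v_y1 if is_b else 0.0)
    m_y2 = params.beta2 * X2 + params.delta_y2 * U + (params.v_y2 if is_b else 0.0)
    Y1 = rng.normal(m_y1, s_y1)
    Y2 = rng.normal(m_y2, s_y2)
    if is_b:
        return StudyDataset(
            study="B",
            Z1=Z1,
            Z2=Z2,
            Z3=Z3,
            Y1=Y1,
            Y2=Y2,
            hidden_X1=X1 if keep_hidden else None,
            hidden_X2=X2 if keep_hidden else None,
        )
    return StudyDataset(study="A", Z1=Z1, Z2=Z2, Z3=Z3, X1=X1, X2=X2, Y1=Y1, Y2=Y2)


def replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    """Independent stream for one replicate of a base seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate_index,)))


def true_params_for(
    config: SimulationConfig, V: tuple[float, float, float, float]
) -> StructuralParams:
    return StructuralParams.homogeneous(
        config.layout,
        alpha=config.alpha_level,
        beta=config.beta_level,
        delta=config.delta_level,
        sigma=config.sigma_level,
        V=V,
    )


def simulate_combined(
    config: SimulationConfig,
    replicate_index: int = 0,
    keep_hidden: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[CombinedDataset, StructuralParams]:
    """Simulate one combined two-study replicate.

    Returns the dataset together with the true parameter values used to
    generate it (the V intercepts differ per replicate).  Deterministic given
    (config.seed, replicate_index).
    """
    if rng is None:
        rng = replicate_rng(config.seed, replicate_index)
    V = tuple(rng.uniform(config.V_low, config.V_high, size=4))
    params = true_params_for(config, V)
    study_a = simulate_study(params, config.n_a, "A", rng, config.genotype_p)
    study_b = simulate_study(
        params, config.n_b, "B", rng, config.genotype_p, keep_hidden=keep_hidden
    )
    return CombinedDataset(study_a=study_a, study_b=study_b), params
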