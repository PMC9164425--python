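"""Two-sample inverse-variance weighted (IVW) estimation.

The benchmark estimator: per-instrument exposure associations (gamma) are
estimated in Study A, per-instrument outcome associations (Gamma) in Study B,
and the causal effect is the fixed-effect IVW combination of the per-variant
Wald ratios with first-order weights,

    beta_hat = sum_i gamma_i Gamma_i / se(Gamma_i)^2
               / sum_i gamma_i^2 / se(Gamma_i)^2 ,
    se(beta_hat) = ( sum_i gamma_i^2 / se(Gamma_i)^2 )^{-1/2},

equivalently weighted least squares of Gamma on gamma through the origin.

By default the instrument set of each pair is its own block only — Z1 for
(X1, Y1) and Z2 for (X2, Y2) — and the stage regressions are marginal, one
simple regression per instrument, exactly as when only per-variant summary
statistics are available.  The shared block Z3 (a valid instrument for both
exposures in this model) can be added with ``include_shared=True``, and
``joint=True`` replaces the marginal regressions by one multivariable
regression per stage, which conditions each instrument on the others and
reduces weak-instrument attenuation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mr_model import CombinedDataset

__all__ = ["IVWEstimate", "per_instrument_assoc", "ivw_estimate", "ivw_for_pair"]

logger = logging.getLogger(__name__)


@dataclass
class IVWEstimate:
    """Fixed-effect IVW causal-effect estimate with normal-theory 95% CI."""

    beta_hat: float
    se: float
    ci95: tuple[float, float]
    n_instruments: int
    gamma: np.ndarray
    gamma_se: np.ndarray
    Gamma: np.ndarray
    Gamma_se: np.ndarray

    def per_instrument_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gamma": self.gamma,
                "gamma_se": self.gamma_se,
                "Gamma": self.Gamma,
                "Gamma_se": self.Gamma_se,
                "wald_ratio": self.Gamma / self.gamma,
            }
        )


def per_instrument_assoc(response: np.ndarray, dosage: np.ndarray) -> tuple[float, float]:
    """Simple-linear-regression slope of response on dosage and its standard error."""
    y = np.asarray(response, dtype=float)
    z = np.asarray(dosage, dtype=float)
    n = y.size
    if n < 3 or z.shape != y.shape:
        raise ValueError("need matching vectors with n >= 3")
    zc = z - z.mean()
    szz = float(zc @ zc)
    if szz == 0.0:
        raise ValueError("constant dosage: slope undefined")
    slope = float(zc @ y) / szz
    resid = y - y.mean() - slope * zc
    s2 = float(resid @ resid) / (n - 2)
    return slope, float(np.sqrt(s2 / szz))


def _assoc_matrix(response: np.ndarray, dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-column slopes/ses; constant columns flagged for dropping."""
    y = np.asarray(response, dtype=float)
    Z = np.asarray(dosages, dtype=float)
    n = y.size
    zc = Z - Z.mean(axis=0)
    szz = np.einsum("ij,ij->j", zc, zc)
    keep = szz > 0.0
    if not keep.all():
        logger.warning("dropping %d constant-dosage instrument(s)", int((~keep).sum()))
    szz_safe = np.where(keep, szz, 1.0)
    slopes = (zc.T @ y) / szz_safe
    yc = y - y.mean()
    resid_ss = float(yc @ yc) - 2.0 * slopes * (zc.T @ y) + slopes**2 * szz
    ses = np.sqrt(np.maximum(resid_ss, 0.0) / (n - 2) / szz_safe)
    return slopes, ses, keep


def joint_instrument_assoc(
    response: np.ndarray, dosages: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Association of each instrument with the response, conditional on the
    others: coefficients and standard errors of one multivariable regression
    with intercept.  Constant columns are dropped (flagged in the mask)."""
    y = np.asarray(response, dtype=float)
    Z = np.asarray(dosages, dtype=float)
    n, m = Z.shape
    keep = Z.std(axis=0) > 0.0
    if not keep.all():
        logger.warning("dropping %d constant-dosage instrument(s)", int((~keep).sum()))
    Zk = Z[:, keep]
    k = Zk.shape[1]
    if n < k + 2:
        raise ValueError(f"need n > #instruments + 1 for joint associations (n={n}, k={k})")
    D = np.column_stack([Zk, np.ones(n)])
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    s2 = float(resid @ resid) / (n - k - 1)
    cov_diag = np.diag(np.linalg.inv(D.T @ D))[:k]
    slopes = np.full(m, np.nan)
    ses = np.full(m, np.nan)
    slopes[keep] = coef[:k]
    ses[keep] = np.sqrt(s2 * cov_diag)
    return slopes, ses, keep


def ivw_estimate(
    gamma: np.ndarray,
    Gamma: np.ndarray,
    Gamma_se: np.ndarray,
    gamma_se: np.ndarray | None = None,
) -> IVWEstimate:
    """Fixed-effect IVW combination with first-order weights 1/se(Gamma)^2."""
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    Gamma_se = np.asarray(Gamma_se, dtype=float)
    if not (gamma.shape == Gamma.shape == Gamma_se.shape) or gamma.size < 1:
        raise ValueError("gamma, Gamma and Gamma_se must be equal-length, nonempty")
    w = Gamma_se**-2.0
    denom = float(np.sum(gamma**2 * w))
    if denom <= 0.0 or not np.isfinite(denom):
        raise ValueError("all IVW weights vanish: cannot estimate")
    beta = float(np.sum(gamma * Gamma * w)) / denom
    se = denom**-0.5
    return IVWEstimate(
        beta_hat=beta,
        se=se,
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        n_instruments=gamma.size,
        gamma=gamma,
        gamma_se=np.full_like(gamma, np.nan) if gamma_se is None else np.asarray(gamma_se, float),
        Gamma=Gamma,
        Gamma_se=Gamma_se,
    )


def ivw_for_pair(
    combined: CombinedDataset,
    pair: int,
    include_shared: bool = False,
    joint: bool = False,
) -> IVWEstimate:
    """IVW estimate for exposure-outcome pair 1 (X1, Y1) or 2 (X2, Y2).

    Stage-1 (instrument-exposure) regressions use Study A only; stage-2
    (instrument-outcome) regressions use Study B only — an exact two-sample
    split.  By default each stage runs one simple regression per instrument
    of the pair's own block; ``include_shared`` adds the Z3 block and
    ``joint`` switches to one multivariable regression per stage.
    Instruments constant in either study are dropped.
    """
    if pair not in (1, 2):
        raise ValueError("pair must be 1 (X1,Y1) or 2 (X2,Y2)")
    a, b = combined.study_a, combined.study_b
    if pair == 1:
        Z_a, Z_b, x, y = a.Z1, b.Z1, a.X1, b.Y1
    else:
        Z_a, Z_b, x, y = a.Z2, b.Z2, a.X2, b.Y2
    if include_shared:
        Z_a = np.hstack([Z_a, a.Z3])
        Z_b = np.hstack([Z_b, b.Z3])
    assoc = joint_instrument_assoc if joint else _assoc_matrix
    g, g_se, keep_a = assoc(x, Z_a)
    G, G_se, keep_b = assoc(y, Z_b)
    keep = keep_a & keep_b
    if not keep.any():
        raise ValueError("no usable instruments after dropping constant dosages")
    return ivw_estimate(g[keep], G[keep], G_se[keep], gamma_se=g_se[keep])
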