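"""Linear structural model for two-study Mendelian randomization.

The model has two exposures and two outcomes.  Instruments come in three
mutually independent blocks: Z1 (length L) instruments X1 only, Z2 (length K)
instruments X2 only, and Z3 (length M) is shared by both exposures.  A scalar
standard-normal latent U per individual summarises the unobserved confounders.

Study A (exposures observed):

    U           ~ N(0, 1)
    X1 | Z1,Z3,U ~ N(alpha1·Z1 + alpha31·Z3 + delta_x1 U,  sigma_x1a^2)
    X2 | Z2,Z3,U ~ N(alpha2·Z2 + alpha32·Z3 + delta_x2 U,  sigma_x2a^2)
    Y1 | X1,U    ~ N(beta1 X1 + delta_y1 U,               sigma_y1a^2)
    Y2 | X2,U    ~ N(beta2 X2 + delta_y2 U,               sigma_y2a^2)

Study B (exposures entirely missing) adds a study-level random intercept V to
each regression mean and uses its own residual scales sigma_*b.  Genotypes are
treated as fixed covariates: no likelihood term is placed on Z.

This module is the single source of truth for the model: the synthetic-data
generator simulates from these equations and the sampler targets the posterior
defined by :func:`log_joint`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace
from typing import Optional, TextIO, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InstrumentLayout",
    "StructuralParams",
    "StudyDataset",
    "CombinedDataset",
    "PriorSpec",
    "conditional_means",
    "log_joint",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class InstrumentLayout:
    """Counts of instruments in the three blocks.

    L instruments act on X1 only, K on X2 only, and M (the shared block Z3)
    on both exposures.
    """

    L: int = 15
    K: int = 15
    M: int = 5

    def __post_init__(self) -> None:
        for name in ("L", "K", "M"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.L + self.K + self.M < 1:
            raise ValueError("at least one instrument is required (L + K + M >= 1)")

    @property
    def total(self) -> int:
        return self.L + self.K + self.M


# residual-scale field names, grouped by study
SIGMA_FIELDS_A = ("sigma_x1a", "sigma_x2a", "sigma_y1a", "sigma_y2a")
SIGMA_FIELDS_B = ("sigma_x1b", "sigma_x2b", "sigma_y1b", "sigma_y2b")
V_FIELDS = ("v_x1", "v_x2", "v_y1", "v_y2")


@dataclass
class StructuralParams:
    """All generative-model coefficients.

    ``alpha*`` are instrument strengths, ``beta*`` the causal effects,
    ``delta_*`` the confounder loadings, ``sigma_*`` positive residual
    standard deviations (per equation and study) and ``v_*`` the Study-B
    random intercepts.
    """

    alpha1: np.ndarray
    alpha2: np.ndarray
    alpha31: np.ndarray
    alpha32: np.ndarray
    beta1: float = 0.0
    beta2: float = 0.0
    delta_x1: float = 0.0
    delta_x2: float = 0.0
    delta_y1: float = 0.0
    delta_y2: float = 0.0
    sigma_x1a: float = 1.0
    sigma_x2a: float = 1.0
    sigma_y1a: float = 1.0
    sigma_y2a: float = 1.0
    sigma_x1b: float = 1.0
    sigma_x2b: float = 1.0
    sigma_y1b: float = 1.0
    sigma_y2b: float = 1.0
    v_x1: float = 0.0
    v_x2: float = 0.0
    v_y1: float = 0.0
    v_y2: float = 0.0

    def __post_init__(self) -> None:
        self.alpha1 = np.atleast_1d(np.asarray(self.alpha1, dtype=float))
        self.alpha2 = np.atleast_1d(np.asarray(self.alpha2, dtype=float))
        self.alpha31 = np.atleast_1d(np.asarray(self.alpha31, dtype=float))
        self.alpha32 = np.atleast_1d(np.asarray(self.alpha32, dtype=float))
        if self.alpha31.shape != self.alpha32.shape:
            raise ValueError(
                "alpha31 and alpha32 must have the same length (shared block Z3); "
                f"got {self.alpha31.shape} vs {self.alpha32.shape}"
            )
        for name in SIGMA_FIELDS_A + SIGMA_FIELDS_B:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def layout(self) -> InstrumentLayout:
        return InstrumentLayout(len(self.alpha1), len(self.alpha2), len(self.alpha31))

    def sigmas(self, study: str) -> tuple[float, float, float, float]:
        """Residual sds (X1, X2, Y1, Y2) for one study label."""
        names = SIGMA_FIELDS_A if study == "A" else SIGMA_FIELDS_B
        return tuple(getattr(self, n) for n in names)

    def with_(self, **kwargs) -> "StructuralParams":
        return replace(self, **kwargs)

    @classmethod
    def homogeneous(
        cls,
        layout: InstrumentLayout,
        alpha: float = 0.3,
        beta: float = 0.3,
        delta: float = 1.0,
        sigma: float = 0.1,
        V: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
    ) -> "StructuralParams":
        """Parameters with one common magnitude per parameter class."""
        return cls(
            alpha1=np.full(layout.L, alpha),
            alpha2=np.full(layout.K, alpha),
            alpha31=np.full(layout.M, alpha),
            alpha32=np.full(layout.M, alpha),
            beta1=beta,
            beta2=beta,
            delta_x1=delta,
            delta_x2=delta,
            delta_y1=delta,
            delta_y2=delta,
            sigma_x1a=sigma,
            sigma_x2a=sigma,
            sigma_y1a=sigma,
            sigma_y2a=sigma,
            sigma_x1b=sigma,
            sigma_x2b=sigma,
            sigma_y1b=sigma,
            sigma_y2b=sigma,
            v_x1=V[0],
            v_x2=V[1],
            v_y1=V[2],
            v_y2=V[3],
        )


@dataclass
class StudyDataset:
    """Individual-level data for one study.

    Dosage matrices hold values in {0, 1, 2}.  For Study B the exposures are
    absent (``X1 is None and X2 is None``); a simulator may stash the
    generated-but-masked values in ``hidden_X1``/``hidden_X2`` for debugging.
    """

    study: str
    Z1: np.ndarray
    Z2: np.ndarray
    Z3: np.ndarray
    Y1: np.ndarray
    Y2: np.ndarray
    X1: Optional[np.ndarray] = None
    X2: Optional[np.ndarray] = None
    hidden_X1: Optional[np.ndarray] = field(default=None, repr=False)
    hidden_X2: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.study not in ("A", "B"):
            raise ValueError(f"study must be 'A' or 'B', got {self.study!r}")
        self.Z1 = np.atleast_2d(np.asarray(self.Z1, dtype=float))
        self.Z2 = np.atleast_2d(np.asarray(self.Z2, dtype=float))
        self.Z3 = np.atleast_2d(np.asarray(self.Z3, dtype=float))
        n = self.Z1.shape[0]
        for name in ("Z2", "Z3"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} has {getattr(self, name).shape[0]} rows, expected {n}")
        for name in ("Y1", "Y2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
            setattr(self, name, arr)
        if (self.X1 is None) != (self.X2 is None):
            raise ValueError("X1 and X2 must be both present or both absent")
        for name in ("X1", "X2", "hidden_X1", "hidden_X2"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
                setattr(self, name, arr)
        for name in ("Z1", "Z2", "Z3"):
            Z = getattr(self, name)
            if Z.size and not np.isin(Z, (0.0, 1.0, 2.0)).all():
                raise ValueError(f"{name} contains dosages outside {{0, 1, 2}}")

    @property
    def n(self) -> int:
        return self.Z1.shape[0]

    @property
    def layout(self) -> InstrumentLayout:
        return InstrumentLayout(self.Z1.shape[1], self.Z2.shape[1], self.Z3.shape[1])

    @property
    def has_exposures(self) -> bool:
        return self.X1 is not None

    def take(self, idx: np.ndarray) -> "StudyDataset":
        """Row subset (used by the partitioner)."""
        pick = lambda a: None if a is None else a[idx]
        return StudyDataset(
            study=self.study,
            Z1=self.Z1[idx],
            Z2=self.Z2[idx],
            Z3=self.Z3[idx],
            Y1=self.Y1[idx],
            Y2=self.Y2[idx],
            X1=pick(self.X1),
            X2=pick(self.X2),
            hidden_X1=pick(self.hidden_X1),
            hidden_X2=pick(self.hidden_X2),
        )


@dataclass
class CombinedDataset:
    """Study A (exposures present) plus Study B (exposures absent)."""

    study_a: StudyDataset
    study_b: StudyDataset

    def __post_init__(self) -> None:
        if not self.study_a.has_exposures:
            raise ValueError("study_a must have observed exposures")
        if self.study_b.has_exposures:
            raise ValueError("study_b must have exposures absent")
        if self.study_a.layout != self.study_b.layout:
            raise ValueError("instrument layouts differ between studies")
        if self.study_a.n == 0 or self.study_b.n == 0:
            raise ValueError("both studies must contain at least one individual")

    @property
    def n(self) -> int:
        return self.study_a.n + self.study_b.n

    @property
    def missing_rate(self) -> float:
        return self.study_b.n / self.n

    @property
    def layout(self) -> InstrumentLayout:
        return self.study_a.layout


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    Every alpha component is N(0, alpha_sd^2) with alpha_sd = 0.3 (individual
    variants explain little exposure variance); beta1, beta2 are N(0, beta_sd^2)
    with beta_sd = 10; each residual sd sigma has an Inv-Gamma(sigma_shape,
    sigma_scale) prior on the sd itself; Study-B intercepts V are N(0, V_sd^2);
    the confounder loadings delta are N(0, delta_sd^2).
    """

    alpha_sd: float = 0.3
    beta_sd: float = 10.0
    sigma_shape: float = 3.0
    sigma_scale: float = 2.0
    V_sd: float = 1.0
    delta_sd: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    def to_yaml(self, stream: Union[str, TextIO, None] = None):
        d = {f.name: float(getattr(self, f.name)) for f in fields(self)}
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                yaml.safe_dump(d, fh)
        elif stream is not None:
            yaml.safe_dump(d, stream)
        else:
            return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, stream: Union[str, TextIO]) -> "PriorSpec":
        if isinstance(stream, str):
            with open(stream) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(stream)
        return cls(**(d or {}))


def _check_consistent(params: StructuralParams, dataset: StudyDataset) -> None:
    if params.layout != dataset.layout:
        raise ValueError(
            f"parameter layout {params.layout} does not match data layout {dataset.layout}"
        )


def _resolve_exposures(dataset: StudyDataset, X1, X2) -> tuple[np.ndarray, np.ndarray]:
    X1 = dataset.X1 if X1 is None else np.asarray(X1, dtype=float)
    X2 = dataset.X2 if X2 is None else np.asarray(X2, dtype=float)
    if X1 is None or X2 is None:
        raise ValueError(
            "exposures absent: supply observed or imputed X1, X2 explicitly"
        )
    if X1.shape != (dataset.n,) or X2.shape != (dataset.n,):
        raise ValueError(f"X1, X2 must have shape ({dataset.n},)")
    return X1, X2


def conditional_means(
    params: StructuralParams,
    dataset: StudyDataset,
    U: np.ndarray,
    X1: Optional[np.ndarray] = None,
    X2: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Conditional means of (X1, X2, Y1, Y2) given instruments, U and exposures.

    For Study B each mean gains the corresponding random intercept V.  The
    outcome means require exposure values: the dataset's own (Study A) or
    imputed ones passed as ``X1``/``X2``.
    """
    _check_consistent(params, dataset)
    U = np.asarray(U, dtype=float)
    if U.shape != (dataset.n,):
        raise ValueError(f"U must have shape ({dataset.n},), got {U.shape}")
    X1v, X2v = _resolve_exposures(dataset, X1, X2)

    m_x1 = dataset.Z1 @ params.alpha1 + dataset.Z3 @ params.alpha31 + params.delta_x1 * U
    m_x2 = dataset.Z2 @ params.alpha2 + dataset.Z3 @ params.alpha32 + params.delta_x2 * U
    m_y1 = params.beta1 * X1v + params.delta_y1 * U
    m_y2 = params.beta2 * X2v + params.delta_y2 * U
    if dataset.study == "B":
        m_x1 = m_x1 + params.v_x1
        m_x2 = m_x2 + params.v_x2
        m_y1 = m_y1 + params.v_y1
        m_y2 = m_y2 + params.v_y2
    return m_x1, m_x2, m_y1, m_y2


def _normal_logpdf_sum(x: np.ndarray, mean: np.ndarray, sd: float) -> float:
    z = (x - mean) / sd
    return float(-0.5 * np.sum(z * z) - x.size * (np.log(sd) + 0.5 * _LOG_2PI))


def log_prior(params: StructuralParams, priors: PriorSpec) -> float:
    """Log prior density of all structural parameters."""
    lp = 0.0
    for a in (params.alpha1, params.alpha2, params.alpha31, params.alpha32):
        lp += _normal_logpdf_sum(a, 0.0, priors.alpha_sd)
    lp += _normal_logpdf_sum(np.array([params.beta1, params.beta2]), 0.0, priors.beta_sd)
    deltas = np.array([params.delta_x1, params.delta_x2, params.delta_y1, params.delta_y2])
    lp += _normal_logpdf_sum(deltas, 0.0, priors.delta_sd)
    Vs = np.array([getattr(params, n) for n in V_FIELDS])
    lp += _normal_logpdf_sum(Vs, 0.0, priors.V_sd)
    a, b = priors.sigma_shape, priors.sigma_scale
    from scipy.special import gammaln

    for name in SIGMA_FIELDS_A + SIGMA_FIELDS_B:
        s = getattr(params, name)
        lp += a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(s) - b / s
    return float(lp)


def log_joint(
    params: StructuralParams,
    dataset: StudyDataset,
    U: np.ndarray,
    priors: PriorSpec,
    X1: Optional[np.ndarray] = None,
    X2: Optional[np.ndarray] = None,
    include_priors: bool = True,
) -> float:
    """Log joint density: latent-U prior + four conditional normals (+ priors).

    The data part is the sum over individuals of the standard-normal log
    density of U and the four regression log densities at the study-specific
    means and residual scales.
    """
    m_x1, m_x2, m_y1, m_y2 = conditional_means(params, dataset, U, X1, X2)
    X1v, X2v = _resolve_exposures(dataset, X1, X2)
    s_x1, s_x2, s_y1, s_y2 = params.sigmas(dataset.study)
    U = np.asarray(U, dtype=float)
    ll = _normal_logpdf_sum(U, 0.0, 1.0)
    ll += _normal_logpdf_sum(X1v, m_x1, s_x1)
    ll += _normal_logpdf_sum(X2v, m_x2, s_x2)
    ll += _normal_logpdf_sum(dataset.Y1, m_y1, s_y1)
    ll += _normal_logpdf_sum(dataset.Y2, m_y2, s_y2)
    if include_priors:
        ll += log_prior(params, priors)
    return float(ll)


# ---------------------------------------------------------------------------
# serialisation: delimited text tables with Z1_1..Z1_L, ..., X1, X2, Y1, Y2

def dataset_to_frame(ds: StudyDataset) -> pd.DataFrame:
    lay = ds.layout
    cols: dict[str, np.ndarray] = {"study": np.repeat(ds.study, ds.n)}
    for block, Z, count in (("Z1", ds.Z1, lay.L), ("Z2", ds.Z2, lay.K), ("Z3", ds.Z3, lay.M)):
        for j in range(count):
            cols[f"{block}_{j + 1}"] = Z[:, j].astype(int)
    cols["X1"] = ds.X1 if ds.X1 is not None else np.full(ds.n, np.nan)
    cols["X2"] = ds.X2 if ds.X2 is not None else np.full(ds.n, np.nan)
    cols["Y1"] = ds.Y1
    cols["Y2"] = ds.Y2
    return pd.DataFrame(cols)


def combined_to_frame(combined: CombinedDataset) -> pd.DataFrame:
    return pd.concat(
        [dataset_to_frame(combined.study_a), dataset_to_frame(combined.study_b)],
        ignore_index=True,
    )


def _frame_to_study(df: pd.DataFrame, study: str) -> StudyDataset:
    def block(prefix: str) -> np.ndarray:
        names = sorted(
            (c for c in df.columns if c.startswith(prefix + "_")),
            key=lambda c: int(c.split("_")[1]),
        )
        return df[names].to_numpy(dtype=float)

    X1 = df["X1"].to_numpy(dtype=float)
    X2 = df["X2"].to_numpy(dtype=float)
    missing = np.isnan(X1)
    if missing.any() and not (missing.all() and np.isnan(X2).all()):
        raise ValueError("exposures must be entirely present or entirely absent per study")
    return StudyDataset(
        study=study,
        Z1=block("Z1"),
        Z2=block("Z2"),
        Z3=block("Z3"),
        X1=None if missing.all() else X1,
        X2=None if missing.all() else X2,
        Y1=df["Y1"].to_numpy(dtype=float),
        Y2=df["Y2"].to_numpy(dtype=float),
    )


def frame_to_combined(df: pd.DataFrame) -> CombinedDataset:
    return CombinedDataset(
        study_a=_frame_to_study(df[df["study"] == "A"].reset_index(drop=True), "A"),
        study_b=_frame_to_study(df[df["study"] == "B"].reset_index(drop=True), "B"),
    )


def write_combined(combined: CombinedDataset, path: str) -> None:
    combined_to_frame(combined).to_csv(path, index=False)


def read_combined(path: Union[str, io.TextIOBase]) -> CombinedDataset:
    return frame_to_combined(pd.read_csv(path))
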