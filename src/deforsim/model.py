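"""The deforestation hazard model.

Each forest cell x in year t has a probability of being cleared during the
year,

    P_defor(x, t) = 1 / (1 + exp(-k_{x,t})),      k_{x,t} = theta . c_{x,t},

where c_{x,t} is the cell's covariate row (intercept first) and theta the
coefficient vector. Observed one-year outcomes Z_{x,t} in {0, 1} over forest
cells are treated as independent Bernoulli trials, giving the standard
logistic-regression log-likelihood

    L(theta) = sum_x [ Z_x ln P_x + (1 - Z_x) ln(1 - P_x) ].

Probabilities are clipped to [1e-12, 1 - 1e-12] before the logs so the
likelihood stays finite under extreme parameter draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "INTERCEPT",
    "ModelSpec",
    "ParameterSet",
    "ParameterPosterior",
    "linear_predictor",
    "defor_probability",
    "log_likelihood",
    "PROB_EPS",
]

#: Column name of the implicit intercept (always first in any design).
INTERCEPT = "intercept"

#: Probability clipping bound applied before taking logs in the likelihood.
PROB_EPS = 1e-12


class ModelSpecError(ValueError):
    """Mismatched or unresolvable model specification."""


@dataclass(frozen=True)
class ModelSpec:
    """An identified combination of covariates; the intercept is implicit.

    ``variables`` excludes the intercept, which is always present and always
    the first column of any design assembled for this spec.
    """

    id: str
    variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ModelSpecError(f"duplicate variable in spec {self.id!r}")
        if INTERCEPT in self.variables:
            raise ModelSpecError("intercept is implicit; do not list it")

    @property
    def columns(self) -> tuple[str, ...]:
        return (INTERCEPT,) + self.variables

    @property
    def n_params(self) -> int:
        return 1 + len(self.variables)


@dataclass
class ParameterSet:
    """Coefficient vector theta aligned with a ModelSpec's columns."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficients must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ParameterPosterior:
    """Per-coefficient posterior summaries (and optionally raw samples).

    ``lower``/``upper`` are the 2.5% / 97.5% sample percentiles — the 95%
    credible interval the significance rule inspects.
    """

    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    samples: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        self.lower = np.asarray(self.lower, dtype=np.float64)
        self.upper = np.asarray(self.upper, dtype=np.float64)
        n = len(self.names)
        for arr, what in ((self.mean, "mean"), (self.sd, "sd"),
                          (self.lower, "lower"), (self.upper, "upper")):
            if arr.shape != (n,):
                raise ValueError(f"{what} must have one entry per coefficient")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")

    @property
    def n_params(self) -> int:
        return len(self.names)

    def mean_parameters(self) -> ParameterSet:
        return ParameterSet(self.mean.copy())

    def significant(self) -> np.ndarray:
        """Per-coefficient flag: 95% credible interval excludes zero."""
        return (self.lower > 0) | (self.upper < 0)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table (parameter, mean, lower, upper, sd)."""
        return pd.DataFrame({
            "parameter": list(self.names),
            "mean": self.mean,
            "lower": self.lower,
            "upper": self.upper,
            "sd": self.sd,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterPosterior":
        names = tuple(df["parameter"].astype(str))
        if "sd" in df.columns:
            sd = df["sd"].to_numpy(dtype=float)
        else:
            # Gaussian approximation: 95% interval spans ~2*1.96 sd.
            sd = (df["upper"].to_numpy(float) - df["lower"].to_numpy(float)) / 3.92
        return cls(names=names,
                   mean=df["mean"].to_numpy(dtype=float),
                   sd=sd,
                   lower=df["lower"].to_numpy(dtype=float),
                   upper=df["upper"].to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path) -> "ParameterPosterior":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def point(cls, names, values) -> "ParameterPosterior":
        """Degenerate posterior (sd 0) around a known coefficient vector."""
        v = np.asarray(values, dtype=float)
        return cls(names=tuple(names), mean=v, sd=np.zeros_like(v),
                   lower=v.copy(), upper=v.copy())


def linear_predictor(design: np.ndarray, params: ParameterSet) -> np.ndarray | float:
    """k = theta . row for one design row or a whole design matrix."""
    design = np.asarray(design, dtype=np.float64)
    if design.shape[-1] != len(params):
        raise ModelSpecError(
            f"design has {design.shape[-1]} columns, parameters {len(params)}")
    return design @ params.values


def defor_probability(k) -> np.ndarray | float:
    """Annual clearing probability: the standard logistic of k.

    Strictly increasing in k, saturating to 0/1 without overflow at
    arbitrarily large |k|.
    """
    return expit(k)


def log_likelihood(params: ParameterSet, design: np.ndarray,
                   z: np.ndarray) -> float:
    """Bernoulli log-likelihood of outcomes z under the logistic hazard."""
    z = np.asarray(z, dtype=np.float64).ravel()
    design = np.atleast_2d(np.asarray(design, dtype=np.float64))
    if design.shape[0] != z.size:
        raise ModelSpecError(
            f"design has {design.shape[0]} rows but z has {z.size} outcomes")
    p = np.clip(expit(design @ params.values), PROB_EPS, 1.0 - PROB_EPS)
    return float(np.sum(z * np.log(p) + (1.0 - z) * np.log1p(-p)))
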