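"""Joint probability model for one species' monthly count series.

Latent relative abundance N_{t,s} follows a Markovian random walk on the log
scale, log N_{t+1,s} = log N_{t,s} + r_{t,s}, where the monthly log-growth
deviations r_{t,s} ~ Normal(mu_r, sigma_proc^2) carry the process error.
Observed counts are Poisson with an effort-adjusted, overdispersed mean:

    y_{t,s} ~ Poisson(lambda_{t,s}),
    log lambda_{t,s} = log N_{t,s} + B * x_{t,s} + eta_{t,s},

with x the scaled-and-centered survey-duration covariate, B its shared
coefficient, and eta_{t,s} ~ Normal(0, sigma_obs^2) the log-scale
observation noise.  The ratio sigma_obs/sigma_proc is the model-adequacy
"error ratio".  Priors are deliberately vague: normal(0, 10^2) on mu_r, B
and each initial log-abundance, uniform(0, 10) on both SDs; all
user-overridable.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import yaml
from scipy.special import gammaln

from .data_io import SurveyDataset
from .exceptions import ValidationError

_LOG_2PI = math.log(2.0 * math.pi)


@dataclasses.dataclass
class SSMParams:
    """Full parameter state for one species.

    Shapes: ``logN1`` (S,), ``r`` (T-1, S), ``eta`` (T, S); ``mu_r``, ``B``
    and the two SDs are scalars shared across sites and months.
    """

    logN1: np.ndarray
    r: np.ndarray
    mu_r: float
    sigma_proc: float
    sigma_obs: float
    B: float
    eta: np.ndarray

    def __post_init__(self) -> None:
        self.logN1 = np.atleast_1d(np.asarray(self.logN1, dtype=float))
        self.r = np.asarray(self.r, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        S = self.logN1.shape[0]
        if self.r.ndim != 2 or self.r.shape[1] != S:
            raise ValidationError(f"r must have shape (T-1, {S}), got {self.r.shape}")
        T = self.r.shape[0] + 1
        if self.eta.shape != (T, S):
            raise ValidationError(f"eta must have shape ({T}, {S}), got {self.eta.shape}")
        if not (self.sigma_proc > 0 and self.sigma_obs > 0):
            raise ValidationError("both SDs must be strictly positive")

    @property
    def n_sites(self) -> int:
        return self.logN1.shape[0]

    @property
    def n_months(self) -> int:
        return self.r.shape[0] + 1


@dataclasses.dataclass
class NormalPrior:
    loc: float = 0.0
    scale: float = 10.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValidationError("prior scale must be positive")

    def logpdf(self, x) -> float:
        z = (np.asarray(x, dtype=float) - self.loc) / self.scale
        return float(np.sum(-0.5 * (_LOG_2PI + z * z) - math.log(self.scale)))


@dataclasses.dataclass
class UniformPrior:
    lower: float = 0.0
    upper: float = 10.0

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValidationError("uniform prior bounds must be ordered")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    def logpdf(self, x: float) -> float:
        if not self.contains(x):
            return -math.inf
        return -math.log(self.upper - self.lower)


@dataclasses.dataclass
class PriorSpec:
    """Vague prior defaults; every block user-overridable and YAML-round-trippable."""

    mu_r: NormalPrior = dataclasses.field(default_factory=NormalPrior)
    B: NormalPrior = dataclasses.field(default_factory=NormalPrior)
    logN1: NormalPrior = dataclasses.field(default_factory=NormalPrior)
    sigma_proc: UniformPrior = dataclasses.field(default_factory=UniformPrior)
    sigma_obs: UniformPrior = dataclasses.field(default_factory=UniformPrior)

    def to_dict(self) -> dict:
        return {
            "mu_r": {"loc": self.mu_r.loc, "scale": self.mu_r.scale},
            "B": {"loc": self.B.loc, "scale": self.B.scale},
            "logN1": {"loc": self.logN1.loc, "scale": self.logN1.scale},
            "sigma_proc": {"lower": self.sigma_proc.lower, "upper": self.sigma_proc.upper},
            "sigma_obs": {"lower": self.sigma_obs.lower, "upper": self.sigma_obs.upper},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        kwargs = {}
        for key in ("mu_r", "B", "logN1"):
            if key in d:
                kwargs[key] = NormalPrior(**d[key])
        for key in ("sigma_proc", "sigma_obs"):
            if key in d:
                kwargs[key] = UniformPrior(**d[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "PriorSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def latent_states(params: SSMParams) -> np.ndarray:
    """Latent abundance N_{t,s} = exp(logN1_s + cumulative sum of r), shape (T, S)."""
    logN = np.vstack([params.logN1[None, :],
                      params.logN1[None, :] + np.cumsum(params.r, axis=0)])
    return np.exp(logN)


def _observation_arrays(params: SSMParams, data: SurveyDataset, species=None):
    k = data.species_index(species)
    y = data.counts[:, :, k].T  # (T, S)
    x = data.effort_std.T
    if y.shape != (params.n_months, params.n_sites):
        raise ValidationError(
            f"data shape {y.shape} does not match params ({params.n_months}, {params.n_sites})"
        )
    return y, x


def log_likelihood(params: SSMParams, data: SurveyDataset, species=None) -> float:
    """Poisson log-likelihood of the observed counts; missing cells contribute 0."""
    y, x = _observation_arrays(params, data, species)
    mask = ~np.isnan(y)
    logN = np.log(latent_states(params))
    loglam = logN + params.B * np.nan_to_num(x) + params.eta
    ll = y * loglam - np.exp(loglam) - gammaln(y + 1.0)
    return float(np.sum(ll[mask]))


def log_prior(params: SSMParams, priors: PriorSpec) -> float:
    """Joint log prior density, including the hierarchical r and eta layers."""
    if not (priors.sigma_proc.contains(params.sigma_proc)
            and priors.sigma_obs.contains(params.sigma_obs)):
        return -math.inf
    total = priors.sigma_proc.logpdf(params.sigma_proc)
    total += priors.sigma_obs.logpdf(params.sigma_obs)
    total += priors.mu_r.logpdf(params.mu_r)
    total += priors.B.logpdf(params.B)
    total += priors.logN1.logpdf(params.logN1)
    z = (params.r - params.mu_r) / params.sigma_proc
    total += float(np.sum(-0.5 * (_LOG_2PI + z * z) - math.log(params.sigma_proc)))
    z = params.eta / params.sigma_obs
    total += float(np.sum(-0.5 * (_LOG_2PI + z * z) - math.log(params.sigma_obs)))
    return total


def log_posterior_unnormalized(
    params: SSMParams, data: SurveyDataset, priors: PriorSpec, species=None
) -> float:
    lp = log_prior(params, priors)
    if lp == -math.inf:
        return -math.inf
    return lp + log_likelihood(params, data, species)
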