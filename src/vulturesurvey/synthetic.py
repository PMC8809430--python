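"""Synthetic survey and questionnaire data under the model's own generative laws.

The count simulator draws from exactly the state-space model the inference
stage fits: a log-scale random walk with drift per site, Poisson counts with
log-normal observation noise, and an effort covariate scaled to mean 0 / SD 1.
The default scenario mirrors the study design: 11 sites surveyed monthly for
a year, survey sessions lasting 2-4 hours, seven analyzable species whose
initial abundances follow the observed ranking (a few tens of birds at the
richest sites down to the occasional single bird).

The questionnaire simulator produces a 300-respondent table whose demographic
structure matches the study population: roughly 70% formally educated,
formally educated respondents younger (median age ~31 vs ~44), and binary
responses drawn per education group.  Ages come from a discretized log-normal
truncated at 17 (adults only).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_io import RespondentTable, SurveyDataset, standardize_effort
from .exceptions import DegenerateCovariateError, ValidationError

DEFAULT_SPECIES = (
    "White-rumped Vulture",
    "Egyptian Vulture",
    "Himalayan Vulture",
    "Red-headed Vulture",
    "Slender-billed Vulture",
    "Griffon Vulture",
    "Cinereous Vulture",
)

# typical per-survey abundance level of each default species (ranking as observed)
_SPECIES_LEVELS = {
    "White-rumped Vulture": 8.0,
    "Egyptian Vulture": 6.0,
    "Himalayan Vulture": 3.5,
    "Red-headed Vulture": 2.0,
    "Slender-billed Vulture": 0.8,
    "Griffon Vulture": 0.5,
    "Cinereous Vulture": 0.3,
}


@dataclasses.dataclass
class SpeciesSimParams:
    """Ground-truth dynamics for one simulated species."""

    mu_r: float = 0.02
    sigma_proc: float = 0.2
    sigma_obs: float = 0.3
    B: float = 0.3
    initial_logN: np.ndarray | None = None  # per-site; filled from n_sites if None

    def __post_init__(self) -> None:
        if self.sigma_proc < 0 or self.sigma_obs < 0:
            raise ValidationError("process and observation SDs must be non-negative")
        if self.initial_logN is not None:
            self.initial_logN = np.atleast_1d(np.asarray(self.initial_logN, dtype=float))


@dataclasses.dataclass
class SimParams:
    """Full scenario: sites x months layout, per-species dynamics, effort rule."""

    n_sites: int = 11
    n_months: int = 12
    species: dict[str, SpeciesSimParams] = dataclasses.field(default_factory=dict)
    effort_hours: np.ndarray | None = None  # (S, T); None draws uniform on [2, 4] h
    effort_range: tuple[float, float] = (2.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_months < 2:
            raise ValidationError("need at least 1 site and 2 months")
        if not self.species:
            self.species = {"White-rumped Vulture": SpeciesSimParams()}
        for name, sp in self.species.items():
            if sp.initial_logN is None:
                sp.initial_logN = default_initial_logN(self.n_sites)
            elif sp.initial_logN.shape[0] != self.n_sites:
                raise ValidationError(
                    f"species {name!r}: initial_logN length {sp.initial_logN.shape[0]} "
                    f"!= n_sites {self.n_sites}"
                )
        if self.effort_hours is not None:
            self.effort_hours = np.asarray(self.effort_hours, dtype=float)
            if self.effort_hours.shape != (self.n_sites, self.n_months):
                raise ValidationError("effort_hours must have shape (n_sites, n_months)")
            if np.any(self.effort_hours <= 0):
                raise ValidationError("effort_hours must be positive")


def default_initial_logN(n_sites: int, level: float = 1.0) -> np.ndarray:
    """Per-site initial log-abundance: log-spaced 5-40 birds, scaled by ``level``."""
    base = np.geomspace(5.0, 40.0, n_sites)
    return np.log(level * base)


def default_sim_params(seed: int = 0) -> SimParams:
    """The study-design default: 11 sites, 12 months, 7 species, 2-4 h surveys."""
    species = {
        name: SpeciesSimParams(
            initial_logN=default_initial_logN(11, level=_SPECIES_LEVELS[name] / 8.0)
        )
        for name in DEFAULT_SPECIES
    }
    return SimParams(n_sites=11, n_months=12, species=species, seed=seed)


def recovery_sim_params(seed: int = 0) -> SimParams:
    """Single-species default scenario used for parameter-recovery experiments."""
    return SimParams(
        n_sites=11,
        n_months=12,
        species={"White-rumped Vulture": SpeciesSimParams()},
        seed=seed,
    )


def simulate_counts(params: SimParams) -> tuple[SurveyDataset, dict]:
    """Forward-simulate the state-space model.

    Returns the observable SurveyDataset and a ground-truth dict holding, per
    species, the latent abundance array (T, S) and every generating parameter.
    The truth is never written into the observable table.  Identical seeds
    give bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    S, T = params.n_sites, params.n_months

    if params.effort_hours is not None:
        effort = params.effort_hours.copy()
    else:
        lo, hi = params.effort_range
        effort = rng.uniform(lo, hi, size=(S, T))
    try:
        effort_std = standardize_effort(effort)
        degenerate = False
    except DegenerateCovariateError:
        effort_std = np.zeros_like(effort)
        degenerate = True

    species_names = list(params.species)
    counts = np.zeros((S, T, len(species_names)))
    truth: dict = {"species": {}, "effort_hours": effort.copy(), "seed": params.seed}

    x = effort_std.T  # (T, S)
    for k, name in enumerate(species_names):
        sp = params.species[name]
        r = rng.normal(sp.mu_r, sp.sigma_proc, size=(T - 1, S))
        logN = np.vstack([sp.initial_logN[None, :],
                          sp.initial_logN[None, :] + np.cumsum(r, axis=0)])
        eta = rng.normal(0.0, sp.sigma_obs, size=(T, S)) if sp.sigma_obs > 0 else np.zeros((T, S))
        lam = np.exp(logN + sp.B * x + eta)
        y = rng.poisson(lam)  # (T, S)
        counts[:, :, k] = y.T
        truth["species"][name] = {
            "mu_r": sp.mu_r,
            "sigma_proc": sp.sigma_proc,
            "sigma_obs": sp.sigma_obs,
            "B": sp.B,
            "initial_logN": sp.initial_logN.copy(),
            "r": r,
            "eta": eta,
            "latent_N": np.exp(logN),
        }

    sites = [f"site_{i + 1:02d}" for i in range(S)]
    dataset = SurveyDataset(
        sites=sites,
        months=list(range(1, T + 1)),
        species=species_names,
        counts=counts,
        effort_raw=effort,
        effort_std=effort_std,
        effort_degenerate=degenerate,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# questionnaire simulation
# ---------------------------------------------------------------------------

DEFAULT_RESPONSE_PROBS: dict[str, dict[str, float]] = {
    "seen_vulture": {"formal": 0.99, "nonformal": 0.96},
    "seen_nest": {"formal": 0.09, "nonformal": 0.02},
    "vultures_useful": {"formal": 0.98, "nonformal": 0.98},
    "aware_diclofenac": {"formal": 0.04, "nonformal": 0.01},
    "believes_declining": {"formal": 0.96, "nonformal": 0.96},
    "buries_carcass": {"formal": 0.85, "nonformal": 0.84},
}


@dataclasses.dataclass
class RespondentSimParams:
    """Scenario for the questionnaire table: demography plus response rates."""

    n_respondents: int = 300
    p_formal_education: float = 0.7
    p_male: float = 0.5
    age_median: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"formal": 31.0, "nonformal": 44.0}
    )
    age_log_sd: float = 0.35
    min_age: int = 17
    response_probs: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {q: dict(p) for q, p in DEFAULT_RESPONSE_PROBS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValidationError("n_respondents must be positive")
        for p in (self.p_formal_education, self.p_male):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        for question, probs in self.response_probs.items():
            for group, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(
                        f"response probability {p} for {question}/{group} outside [0, 1]"
                    )
        if not self.age_log_sd > 0:
            raise ValidationError("age_log_sd must be positive")


def _truncated_lognormal_ages(
    rng: np.random.Generator, n: int, median: float, log_sd: float, min_age: int
) -> np.ndarray:
    """Discretized log-normal ages, truncated below at ``min_age`` via inverse CDF."""
    mu = np.log(median)
    lo = norm.cdf((np.log(min_age - 0.5) - mu) / log_sd)
    u = lo + rng.uniform(size=n) * (1.0 - lo)
    ages = np.round(np.exp(mu + log_sd * norm.ppf(u))).astype(int)
    return np.maximum(ages, min_age)


def simulate_respondents(params: RespondentSimParams) -> RespondentTable:
    """Draw a questionnaire table; every field independent per respondent, seeded."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_respondents
    education = np.where(
        rng.uniform(size=n) < params.p_formal_education, "formal", "nonformal"
    )
    gender = np.where(rng.uniform(size=n) < params.p_male, "male", "female")
    ages = np.empty(n, dtype=int)
    for group in ("formal", "nonformal"):
        idx = np.flatnonzero(education == group)
        if idx.size:
            ages[idx] = _truncated_lognormal_ages(
                rng, idx.size, float(params.age_median[group]),
                params.age_log_sd, params.min_age,
            )
    data = {
        "respondent_id": [f"R{i + 1:04d}" for i in range(n)],
        "age": ages,
        "gender": gender,
        "education": education,
    }
    for question, probs in params.response_probs.items():
        p = np.where(
            education == "formal", float(probs["formal"]), float(probs["nonformal"])
        )
        data[question] = rng.uniform(size=n) < p
    return RespondentTable(pd.DataFrame(data))
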