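"""Posterior sampling and the two model-checking diagnostics.

The sampler is a Metropolis-within-Gibbs scheme on the latent log-abundance
path.  Rather than updating growth deviations r directly, it updates the
path logN_{t,s} element-wise (a checkerboard over time keeps the updates
conditionally independent and fully vectorized across sites), adds a
per-site path-shift move to decorrelate the level from the observation
noise, and updates eta element-wise.  The hierarchical scalars use exact
conditional draws where conjugacy allows: mu_r is normal-normal, and under
the uniform-on-SD prior each variance has a truncated inverse-gamma
conditional.  Only the effort coefficient B needs an adaptive random-walk
step.  Proposal scales adapt (Robbins-Monro toward ~35% acceptance) during
the first ``n_adapt`` iterations only, so the retained chain targets the
exact posterior.

The default schedule is three chains of 300,000 iterations, 150,000 burn-in,
20,000 adaptation and thinning of 50, retaining 3,000 draws per chain; a
desk-scale schedule (20,000 / 10,000 / thin 10) is one call away for tests
and simulation studies.

Diagnostics: the classical Gelman-Rubin statistic on retained draws (no
chain splitting; convergence declared when every R-hat < 1.1), and the
error ratio sigma_obs/sigma_proc per pooled draw, with the probability that
the ratio exceeds 10 reported against the 0.90 adequacy rule.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaincc, gammainccinv

from .data_io import SurveyDataset
from .exceptions import ConfigurationError, UndefinedStatisticError, ValidationError
from .ssm import NormalPrior, PriorSpec, UniformPrior

_ADAPT_TARGET = 0.35  # middle of the 20-50% acceptance band
_SCALE_BOUNDS = (1e-3, 50.0)


@dataclasses.dataclass
class MCMCConfig:
    """Chain schedule.  Retained draws per chain = (n_iterations - n_burnin) // thin."""

    n_chains: int = 3
    n_iterations: int = 300_000
    n_burnin: int = 150_000
    n_adapt: int = 20_000
    thin: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ConfigurationError("need at least one chain")
        if not (0 <= self.n_burnin < self.n_iterations):
            raise ConfigurationError("require 0 <= n_burnin < n_iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.n_adapt < 0:
            raise ConfigurationError("n_adapt must be non-negative")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin

    @classmethod
    def desk_scale(cls, seed: int = 0, n_chains: int = 3) -> "MCMCConfig":
        """Reduced schedule for tests and simulation studies."""
        return cls(
            n_chains=n_chains,
            n_iterations=20_000,
            n_burnin=10_000,
            n_adapt=5_000,
            thin=10,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PosteriorDraws:
    """Retained draws for one species, organized (chain, draw, ...)."""

    species: str
    sites: list[str]
    months: list[int]
    mu_r: np.ndarray  # (C, D)
    B: np.ndarray  # (C, D)
    sigma_proc: np.ndarray  # (C, D)
    sigma_obs: np.ndarray  # (C, D)
    logN1: np.ndarray  # (C, D, S)
    r: np.ndarray  # (C, D, T-1, S)
    eta: np.ndarray  # (C, D, T, S)
    latent_N: np.ndarray  # (C, D, T, S)
    data: SurveyDataset | None = None
    config: MCMCConfig | None = None
    acceptance_rates: dict = dataclasses.field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.mu_r.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu_r.shape[1]

    @property
    def parameter_names(self) -> list[str]:
        """Scalar parameters monitored by default for R-hat and traces."""
        names = ["mu_r", "B", "sigma_proc", "sigma_obs"]
        names += [f"logN1[{s}]" for s in self.sites]
        return names

    def get(self, name: str) -> np.ndarray:
        """(C, D) array of one scalar parameter by flattened name."""
        if name in ("mu_r", "B", "sigma_proc", "sigma_obs"):
            return getattr(self, name)
        if name.startswith("logN1[") and name.endswith("]"):
            label = name[len("logN1["):-1]
            return self.logN1[:, :, self.sites.index(label)]
        raise KeyError(f"unknown parameter name {name!r}")

    def save(self, path) -> None:
        meta = {
            "species": self.species,
            "sites": self.sites,
            "months": self.months,
            "config": self.config.to_dict() if self.config else None,
            "acceptance_rates": self.acceptance_rates,
        }
        arrays = {
            k: getattr(self, k)
            for k in ("mu_r", "B", "sigma_proc", "sigma_obs", "logN1", "r", "eta", "latent_N")
        }
        if self.data is not None:
            arrays["data_counts"] = self.data.counts
            arrays["data_effort_raw"] = self.data.effort_raw
            arrays["data_effort_std"] = self.data.effort_std
            meta["data_species"] = self.data.species
        np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["_meta"]))
            arrays = {k: npz[k] for k in npz.files if k != "_meta"}
        data = None
        if "data_counts" in arrays:
            data = SurveyDataset(
                sites=meta["sites"],
                months=meta["months"],
                species=meta["data_species"],
                counts=arrays.pop("data_counts"),
                effort_raw=arrays.pop("data_effort_raw"),
                effort_std=arrays.pop("data_effort_std"),
            )
        config = MCMCConfig(**meta["config"]) if meta.get("config") else None
        return cls(
            species=meta["species"],
            sites=meta["sites"],
            months=meta["months"],
            data=data,
            config=config,
            acceptance_rates=meta.get("acceptance_rates", {}),
            **arrays,
        )


@dataclasses.dataclass
class DiagnosticsReport:
    """Convergence and adequacy summary for one fitted species."""

    rhat: dict[str, float]
    converged: bool
    error_ratio_draws: np.ndarray
    p_error_ratio_gt_threshold: float
    threshold: float
    adequate: bool
    large_observation_error: bool
    acceptance_rates: dict[str, float]

    def to_dict(self) -> dict:
        ratios = np.asarray(self.error_ratio_draws, dtype=float)
        return {
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "converged": bool(self.converged),
            "error_ratio": {
                "threshold": float(self.threshold),
                "p_gt_threshold": float(self.p_error_ratio_gt_threshold),
                "median": float(np.median(ratios)),
                "pct_2_5": float(np.percentile(ratios, 2.5)),
                "pct_97_5": float(np.percentile(ratios, 97.5)),
            },
            "adequate": bool(self.adequate),
            "large_observation_error": bool(self.large_observation_error),
            "acceptance_rates": {k: float(v) for k, v in self.acceptance_rates.items()},
        }


# ---------------------------------------------------------------------------
# conditional distributions used by the Gibbs steps
# ---------------------------------------------------------------------------


def mu_r_conditional(
    r: np.ndarray, sigma_proc: float, prior: NormalPrior
) -> tuple[float, float]:
    """Closed-form normal conditional for mu_r given the growth deviations."""
    r = np.asarray(r, dtype=float)
    n = r.size
    prec = n / sigma_proc**2 + 1.0 / prior.scale**2
    mean = (r.sum() / sigma_proc**2 + prior.loc / prior.scale**2) / prec
    return float(mean), float(1.0 / math.sqrt(prec))


def _sample_sd(rng: np.random.Generator, half_sq_sum: float, n: int,
               prior: UniformPrior) -> float:
    """Draw an SD whose variance has a truncated inverse-gamma conditional.

    For n normal deviates with known mean and a flat prior on the SD over
    (lower, upper), the variance v has density v^{-(n+1)/2} exp(-A/v) with
    A = half the sum of squared deviations, i.e. InvGamma((n-1)/2, A)
    truncated to (lower^2, upper^2).  The inverse CDF goes through the
    regularized upper incomplete gamma: P(V <= v) = Q(a, A/v).
    """
    a = (n - 1) / 2.0
    A = max(half_sq_sum, 1e-300)
    lo2 = prior.lower**2
    hi2 = prior.upper**2
    c_lo = float(gammaincc(a, A / lo2)) if lo2 > 0 else 0.0
    c_hi = float(gammaincc(a, A / hi2))
    u = rng.uniform()
    if c_hi - c_lo < 1e-14:  # numerically all mass outside: clamp to nearest edge
        v = min(max(A / (a + 1.0), lo2 + 1e-12), hi2)
    else:
        v = A / float(gammainccinv(a, c_lo + u * (c_hi - c_lo)))
        v = min(max(v, lo2 + 1e-300), hi2)
    return math.sqrt(v)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class _ChainState:
    """Mutable state of one chain; all arrays are (T, S) oriented."""

    __slots__ = ("logN", "eta", "mu_r", "B", "sigma_proc", "sigma_obs")

    def __init__(self, logN, eta, mu_r, B, sigma_proc, sigma_obs):
        self.logN = logN
        self.eta = eta
        self.mu_r = mu_r
        self.B = B
        self.sigma_proc = sigma_proc
        self.sigma_obs = sigma_obs


def _init_chain(rng, y, mask, x, priors: PriorSpec) -> _ChainState:
    T, S = y.shape
    filled = np.where(mask, np.log(np.maximum(y, 0.0) + 0.5), np.nan)
    col_mean = np.nanmean(np.where(mask, filled, np.nan), axis=0)
    col_mean = np.where(np.isnan(col_mean), np.nanmean(filled), col_mean)
    filled = np.where(mask, filled, col_mean[None, :])
    logN = filled + rng.normal(0.0, 0.2, size=(T, S))
    eta = rng.normal(0.0, 0.05, size=(T, S))
    mu_r = float(np.mean(np.diff(logN, axis=0))) + rng.normal(0.0, 0.05)
    B = rng.normal(0.0, 0.2)
    def init_sd(prior: UniformPrior) -> float:
        lo = max(prior.lower, prior.upper / 1000.0)
        hi = min(prior.upper, max(1.0, 10.0 * lo))
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return _ChainState(logN, eta, mu_r, B,
                       init_sd(priors.sigma_proc), init_sd(priors.sigma_obs))


def _obs_term(y, mask, loglam):
    """Cell-wise Poisson log-density up to the y! constant; 0 off-survey."""
    return np.where(mask, y * loglam - np.exp(loglam), 0.0)


def _run_single_chain(rng, y, mask, x, priors: PriorSpec, config: MCMCConfig):
    T, S = y.shape
    st = _init_chain(rng, y, mask, x, priors)

    scale_logN = np.full((T, S), 0.3)
    scale_eta = np.full((T, S), 0.3)
    scale_shift = np.full(S, 0.2)
    scale_B = 0.1
    scale_proc_rescale = 0.3
    scale_obs_rescale = 0.3

    parity_sets = [np.arange(0, T, 2), np.arange(1, T, 2)]
    inv2_prior_logN1 = 1.0 / (2.0 * priors.logN1.scale**2)
    loc_logN1 = priors.logN1.loc
    n_r = (T - 1) * S
    n_eta = T * S

    n_keep = config.retained_per_chain
    out = {
        "mu_r": np.empty(n_keep),
        "B": np.empty(n_keep),
        "sigma_proc": np.empty(n_keep),
        "sigma_obs": np.empty(n_keep),
        "logN1": np.empty((n_keep, S)),
        "r": np.empty((n_keep, T - 1, S)),
        "eta": np.empty((n_keep, T, S)),
        "latent_N": np.empty((n_keep, T, S)),
    }
    blocks = ("latent", "shift", "eta", "B", "proc_rescale", "obs_rescale")
    acc_counts = {k: 0.0 for k in blocks}
    acc_possible = {k: 0.0 for k in blocks}
    kept = 0

    for it in range(1, config.n_iterations + 1):
        adapting = it <= config.n_adapt
        gamma = min(0.25, 2.0 / math.sqrt(it)) if adapting else 0.0
        inv2sp2 = 1.0 / (2.0 * st.sigma_proc**2)

        # --- latent path: element-wise Metropolis, checkerboard over time ---
        for idx in parity_sets:
            m = idx.shape[0]
            cur = st.logN[idx]
            prop = cur + scale_logN[idx] * rng.standard_normal((m, S))
            base = st.B * x[idx] + st.eta[idx]
            d_obs = (_obs_term(y[idx], mask[idx], prop + base)
                     - _obs_term(y[idx], mask[idx], cur + base))

            first = (idx == 0)[:, None]
            prev_idx = np.maximum(idx - 1, 0)
            next_idx = np.minimum(idx + 1, T - 1)
            notlast = (idx < T - 1)[:, None]
            prev_vals = st.logN[prev_idx]
            next_vals = st.logN[next_idx]

            def proc(vals):
                back = -((vals - prev_vals - st.mu_r) ** 2) * inv2sp2
                pri = -((vals - loc_logN1) ** 2) * inv2_prior_logN1
                fwd = -((next_vals - vals - st.mu_r) ** 2) * inv2sp2
                return np.where(first, pri, back) + np.where(notlast, fwd, 0.0)

            logalpha = d_obs + proc(prop) - proc(cur)
            accept = np.log(rng.uniform(size=(m, S))) < logalpha
            st.logN[idx] = np.where(accept, prop, cur)
            acc_counts["latent"] += accept.sum()
            acc_possible["latent"] += accept.size
            if adapting:
                scale_logN[idx] = np.clip(
                    scale_logN[idx] * np.exp(gamma * (accept - _ADAPT_TARGET)),
                    *_SCALE_BOUNDS,
                )

        # --- per-site path shift (level move; increments unchanged) ---
        delta = scale_shift * rng.standard_normal(S)
        loglam = st.logN + st.B * x + st.eta
        d_obs_col = (_obs_term(y, mask, loglam + delta[None, :]).sum(axis=0)
                     - _obs_term(y, mask, loglam).sum(axis=0))
        d_pri = (-((st.logN[0] + delta - loc_logN1) ** 2)
                 + (st.logN[0] - loc_logN1) ** 2) * inv2_prior_logN1
        accept_s = np.log(rng.uniform(size=S)) < (d_obs_col + d_pri)
        st.logN[:, accept_s] += delta[accept_s][None, :]
        acc_counts["shift"] += accept_s.sum()
        acc_possible["shift"] += S
        if adapting:
            scale_shift = np.clip(
                scale_shift * np.exp(gamma * (accept_s - _ADAPT_TARGET)), *_SCALE_BOUNDS
            )

        # --- eta: element-wise Metropolis (independent cells given the path) ---
        prop_eta = st.eta + scale_eta * rng.standard_normal((T, S))
        base = st.logN + st.B * x
        inv2so2 = 1.0 / (2.0 * st.sigma_obs**2)
        logalpha = (
            _obs_term(y, mask, base + prop_eta) - _obs_term(y, mask, base + st.eta)
            - (prop_eta**2 - st.eta**2) * inv2so2
        )
        accept_e = np.log(rng.uniform(size=(T, S))) < logalpha
        st.eta = np.where(accept_e, prop_eta, st.eta)
        acc_counts["eta"] += accept_e.sum()
        acc_possible["eta"] += accept_e.size
        if adapting:
            scale_eta = np.clip(
                scale_eta * np.exp(gamma * (accept_e - _ADAPT_TARGET)), *_SCALE_BOUNDS
            )

        # --- B: adaptive random-walk Metropolis ---
        Bp = st.B + scale_B * rng.standard_normal()
        loglam = st.logN + st.B * x + st.eta
        loglam_p = st.logN + Bp * x + st.eta
        d_obs = float(
            (_obs_term(y, mask, loglam_p) - _obs_term(y, mask, loglam)).sum()
        )
        d_pri = (-((Bp - priors.B.loc) ** 2) + (st.B - priors.B.loc) ** 2) / (
            2.0 * priors.B.scale**2
        )
        accept_b = math.log(rng.uniform()) < d_obs + d_pri
        if accept_b:
            st.B = float(Bp)
        acc_counts["B"] += accept_b
        acc_possible["B"] += 1
        if adapting:
            scale_B = float(np.clip(
                scale_B * math.exp(gamma * (accept_b - _ADAPT_TARGET)), *_SCALE_BOUNDS
            ))

        # --- mu_r: exact normal-normal conditional ---
        r = np.diff(st.logN, axis=0)
        mean, sd = mu_r_conditional(r, st.sigma_proc, priors.mu_r)
        st.mu_r = mean + sd * rng.standard_normal()

        # --- SDs: truncated inverse-gamma conditionals ---
        st.sigma_proc = _sample_sd(
            rng, 0.5 * float(((r - st.mu_r) ** 2).sum()), n_r, priors.sigma_proc
        )
        st.sigma_obs = _sample_sd(
            rng, 0.5 * float((st.eta**2).sum()), n_eta, priors.sigma_obs
        )

        # --- non-centered interweaving: rescale increments with sigma_proc ---
        # Holding z = (r - mu_r)/sigma_proc fixed, a multiplicative move on the
        # SD rescales the whole path's roughness in one step, breaking the
        # funnel between the SD and the latent increments.
        z_step = rng.standard_normal()
        log_u = math.log(rng.uniform())
        s_new = st.sigma_proc * math.exp(scale_proc_rescale * z_step)
        accept_p = False
        if priors.sigma_proc.contains(s_new):
            r = np.diff(st.logN, axis=0)
            r_new = st.mu_r + (r - st.mu_r) * (s_new / st.sigma_proc)
            logN_new = np.vstack([st.logN[0][None, :],
                                  st.logN[0][None, :] + np.cumsum(r_new, axis=0)])
            d_obs = float(
                (_obs_term(y, mask, logN_new + st.B * x + st.eta)
                 - _obs_term(y, mask, st.logN + st.B * x + st.eta)).sum()
            )
            accept_p = log_u < d_obs + math.log(s_new / st.sigma_proc)
            if accept_p:
                st.logN = logN_new
                st.sigma_proc = float(s_new)
        acc_counts["proc_rescale"] += accept_p
        acc_possible["proc_rescale"] += 1
        if adapting:
            scale_proc_rescale = float(np.clip(
                scale_proc_rescale * math.exp(gamma * (accept_p - _ADAPT_TARGET)),
                *_SCALE_BOUNDS,
            ))

        # --- non-centered interweaving: rescale eta with sigma_obs ---
        z_step = rng.standard_normal()
        log_u = math.log(rng.uniform())
        s_new = st.sigma_obs * math.exp(scale_obs_rescale * z_step)
        accept_o = False
        if priors.sigma_obs.contains(s_new):
            eta_new = st.eta * (s_new / st.sigma_obs)
            base = st.logN + st.B * x
            d_obs = float(
                (_obs_term(y, mask, base + eta_new)
                 - _obs_term(y, mask, base + st.eta)).sum()
            )
            accept_o = log_u < d_obs + math.log(s_new / st.sigma_obs)
            if accept_o:
                st.eta = eta_new
                st.sigma_obs = float(s_new)
        acc_counts["obs_rescale"] += accept_o
        acc_possible["obs_rescale"] += 1
        if adapting:
            scale_obs_rescale = float(np.clip(
                scale_obs_rescale * math.exp(gamma * (accept_o - _ADAPT_TARGET)),
                *_SCALE_BOUNDS,
            ))

        if it > config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            out["mu_r"][kept] = st.mu_r
            out["B"][kept] = st.B
            out["sigma_proc"][kept] = st.sigma_proc
            out["sigma_obs"][kept] = st.sigma_obs
            out["logN1"][kept] = st.logN[0]
            out["r"][kept] = np.diff(st.logN, axis=0)
            out["eta"][kept] = st.eta
            out["latent_N"][kept] = np.exp(st.logN)
            kept += 1

    rates = {k: acc_counts[k] / max(acc_possible[k], 1.0) for k in acc_counts}
    return out, rates


def run_mcmc(
    data: SurveyDataset,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    species: str | int | None = None,
) -> PosteriorDraws:
    """Sample the posterior for one species; fully reproducible given the seed."""
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    k = data.species_index(species)
    y = data.counts[:, :, k].T  # (T, S)
    x = np.nan_to_num(data.effort_std.T)
    mask = ~np.isnan(y)
    if data.n_months < 2 or data.n_sites < 1:
        raise ValidationError("need at least 2 months and 1 site")
    if not mask.any():
        raise ValidationError("all counts missing; nothing to fit")
    y = np.nan_to_num(y)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    rates_all = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        out, rates = _run_single_chain(rng, y, mask, x, priors, config)
        chains.append(out)
        rates_all.append(rates)

    stack = {key: np.stack([c[key] for c in chains]) for key in chains[0]}
    mean_rates = {
        key: float(np.mean([r[key] for r in rates_all])) for key in rates_all[0]
    }
    return PosteriorDraws(
        species=data.species[k],
        sites=list(data.sites),
        months=list(data.months),
        data=data,
        config=config,
        acceptance_rates=mean_rates,
        **stack,
    )


def fit_all_species(
    data: SurveyDataset,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> dict[str, PosteriorDraws]:
    """Fit each species independently with deterministically derived child seeds."""
    config = config or MCMCConfig()
    result = {}
    for i, name in enumerate(data.species):
        child_seed = int(
            np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31)
        )
        cfg = dataclasses.replace(config, seed=child_seed)
        result[name] = run_mcmc(data, priors, cfg, species=name)
    return result


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(chains: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Classical potential scale reduction factor on retained draws.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain sample
    variance and B = n * the sample variance of the chain means.  No chain
    splitting.  Raises when every chain is constant (W = 0).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("chains must be a 2-D (chain, draw) structure")
    m, n = arr.shape
    if m < 2:
        raise ValidationError("need at least 2 chains")
    if n < 2:
        raise ValidationError("need at least 2 draws per chain")
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    if W == 0.0:
        raise UndefinedStatisticError("all chains constant; R-hat undefined")
    B = n * float(np.var(np.mean(arr, axis=1), ddof=1))
    return math.sqrt(((n - 1) / n * W + B / n) / W)


def error_ratio_probability(
    draws: PosteriorDraws, threshold: float = 10.0
) -> tuple[np.ndarray, float]:
    """Per-draw sigma_obs/sigma_proc pooled across chains, and P(ratio > threshold)."""
    ratios = (draws.sigma_obs / draws.sigma_proc).reshape(-1)
    p = float(np.count_nonzero(ratios > threshold) / ratios.size)
    return ratios, p


def compute_diagnostics(
    draws: PosteriorDraws,
    threshold: float = 10.0,
    rhat_limit: float = 1.1,
    adequacy_prob: float = 0.90,
    parameters: Sequence[str] | None = None,
) -> DiagnosticsReport:
    names = list(parameters) if parameters is not None else draws.parameter_names
    rhat = {name: gelman_rubin(draws.get(name)) for name in names}
    converged = all(v < rhat_limit for v in rhat.values())
    ratios, p = error_ratio_probability(draws, threshold)
    return DiagnosticsReport(
        rhat=rhat,
        converged=converged,
        error_ratio_draws=ratios,
        p_error_ratio_gt_threshold=p,
        threshold=threshold,
        adequate=p > adequacy_prob,
        large_observation_error=p > adequacy_prob,
        acceptance_rates=draws.acceptance_rates,
    )


def export_traces(
    draws: PosteriorDraws,
    path,
    parameters: Sequence[str] | None = None,
    plot: bool = False,
    plot_path=None,
) -> pd.DataFrame:
    """Write a long-format trace table (parameter, chain, iteration, value) as CSV."""
    if draws.n_draws == 0:
        raise ValidationError("no retained draws to export")
    names = list(parameters) if parameters is not None else draws.parameter_names
    rows = []
    for name in names:
        arr = draws.get(name)
        for chain in range(draws.n_chains):
            for i in range(draws.n_draws):
                rows.append((name, chain, i, arr[chain, i]))
    frame = pd.DataFrame(rows, columns=["parameter", "chain", "iteration", "value"])
    frame.to_csv(path, index=False, float_format="%.10g")
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(len(names), 1, figsize=(8, 2 * len(names)), squeeze=False)
        for ax, name in zip(axes[:, 0], names):
            arr = draws.get(name)
            for chain in range(draws.n_chains):
                ax.plot(arr[chain], lw=0.5)
            ax.set_ylabel(name)
        fig.tight_layout()
        fig.savefig(plot_path or str(path) + ".png", dpi=100)
        plt.close(fig)
    return frame
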