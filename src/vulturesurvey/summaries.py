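"""Posterior relative-abundance summaries and effort-coefficient reports.

All percentiles use linear interpolation between order statistics (numpy's
default), pinned by tests.  Cross-species site totals are formed per draw --
summation precedes summarization -- because the median of sums is not the
sum of medians for skewed posteriors.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .mcmc import PosteriorDraws

_COLUMNS = ["species", "site", "n_observations", "pct_2_5", "median", "pct_97_5"]


@dataclasses.dataclass(frozen=True)
class AbundanceRow:
    species: str
    site: str
    n_observations: int
    pct_2_5: float
    median: float
    pct_97_5: float

    def __post_init__(self) -> None:
        if not (self.pct_2_5 <= self.median <= self.pct_97_5):
            raise ValidationError(
                f"percentiles out of order for {self.species}/{self.site}: "
                f"{self.pct_2_5}, {self.median}, {self.pct_97_5}"
            )
        if self.n_observations < 0:
            raise ValidationError("n_observations must be non-negative")


@dataclasses.dataclass
class AbundanceSummary:
    """Report rows of median / 2.5th / 97.5th relative-abundance percentiles."""

    rows: list[AbundanceRow] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(row) for row in self.rows], columns=_COLUMNS
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceSummary":
        rows = [
            AbundanceRow(
                species=str(rec["species"]),
                site=str(rec["site"]),
                n_observations=int(rec["n_observations"]),
                pct_2_5=float(rec["pct_2_5"]),
                median=float(rec["median"]),
                pct_97_5=float(rec["pct_97_5"]),
            )
            for rec in frame.to_dict("records")
        ]
        return cls(rows)

    def extend(self, other: "AbundanceSummary") -> None:
        self.rows.extend(other.rows)


def _percentile_row(values: np.ndarray, species: str, site: str, n_obs: int) -> AbundanceRow:
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5])
    return AbundanceRow(species, site, int(n_obs), float(lo), float(med), float(hi))


def _observed_total(draws: PosteriorDraws, site: str | None = None) -> int:
    if draws.data is None:
        return 0
    counts = draws.data.species_counts(draws.species)  # (S, T)
    if site is not None:
        counts = counts[draws.sites.index(site)]
    return int(np.nansum(counts))


def species_relative_abundance(
    draws: PosteriorDraws, use_expected_counts: bool = False
) -> AbundanceRow:
    """Pool latent N over all sites, months, chains and draws for one species.

    ``use_expected_counts`` pools the effort-adjusted expected count
    N * exp(B x + eta) instead of latent N.
    """
    values = _pooled_values(draws, use_expected_counts)
    if values.size == 0:
        raise ValidationError("no draws to summarize")
    return _percentile_row(values.reshape(-1), draws.species, "ALL", _observed_total(draws))


def _pooled_values(draws: PosteriorDraws, use_expected_counts: bool) -> np.ndarray:
    if not use_expected_counts:
        return draws.latent_N
    if draws.data is None:
        raise ValidationError("expected-count pooling needs the observed dataset")
    x = np.nan_to_num(draws.data.effort_std.T)  # (T, S)
    return draws.latent_N * np.exp(
        draws.B[:, :, None, None] * x[None, None] + draws.eta
    )


def site_relative_abundance(
    draws: PosteriorDraws, sites: list[str] | None = None,
    use_expected_counts: bool = False,
) -> AbundanceSummary:
    """Per-site percentile rows, pooled within site across months/chains/draws."""
    values = _pooled_values(draws, use_expected_counts)
    wanted = sites if sites is not None else draws.sites
    rows = []
    for site in wanted:
        if site not in draws.sites:
            raise ValidationError(f"unknown site label {site!r}")
        j = draws.sites.index(site)
        rows.append(
            _percentile_row(
                values[:, :, :, j].reshape(-1), draws.species, site,
                _observed_total(draws, site),
            )
        )
    return AbundanceSummary(rows)


def cross_species_totals(
    draws_by_species: Mapping[str, PosteriorDraws]
) -> AbundanceSummary:
    """Per-site totals over species, summed draw-by-draw before summarizing.

    Species fitted with different schedules are paired by (chain, retained
    index) after truncation to the shortest draw count.
    """
    if not draws_by_species:
        raise ValidationError("no species draws supplied")
    items = list(draws_by_species.values())
    first = items[0]
    for d in items[1:]:
        if d.sites != first.sites or d.months != first.months:
            raise ValidationError("species draws have misaligned sites or months")
        if d.n_chains != first.n_chains:
            raise ValidationError("species draws have different chain counts")
    n_draws = min(d.n_draws for d in items)
    total = np.zeros_like(items[0].latent_N[:, :n_draws])
    for d in items:
        total = total + d.latent_N[:, :n_draws]
    rows = []
    for j, site in enumerate(first.sites):
        n_obs = sum(_observed_total(d, site) for d in items)
        rows.append(_percentile_row(total[:, :, :, j].reshape(-1), "ALL", site, n_obs))
    return AbundanceSummary(rows)


@dataclasses.dataclass(frozen=True)
class EffortCoefficientSummary:
    """Posterior summary of the shared survey-effort coefficient B."""

    species: str
    pct_2_5: float
    median: float
    pct_97_5: float
    p_positive: float
    p_negative: float
    positive_lower_bound: bool
    negative_upper_bound: bool


def effort_coefficient_summary(draws: PosteriorDraws) -> EffortCoefficientSummary:
    b = draws.B.reshape(-1)
    lo, med, hi = np.percentile(b, [2.5, 50.0, 97.5])
    return EffortCoefficientSummary(
        species=draws.species,
        pct_2_5=float(lo),
        median=float(med),
        pct_97_5=float(hi),
        p_positive=float(np.count_nonzero(b > 0) / b.size),
        p_negative=float(np.count_nonzero(b < 0) / b.size),
        positive_lower_bound=bool(lo > 0),
        negative_upper_bound=bool(hi < 0),
    )
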