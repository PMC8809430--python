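"""From-scratch questionnaire tests: exact Fisher (2x2) and Kruskal-Wallis.

The two-tailed Fisher p-value follows the "sum of small p" convention: all
tables with the observed margins whose hypergeometric probability does not
exceed the observed table's (within a 1e-7 relative tolerance for floating
ties) contribute.  Probabilities are computed on the log scale via
log-gamma, so large-margin tables cannot overflow.  The Kruskal-Wallis
statistic uses mid-ranks for ties, the usual tie-correction divisor, and a
chi-square reference with k-1 degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, rankdata

from .data_io import EDUCATION_LEVELS, GENDER_LEVELS, RespondentTable
from .exceptions import UndefinedStatisticError, ValidationError

_TIE_RTOL = 1e-7


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts (row 1: a b; row 2: c d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(v < 0 or v != int(v) for v in cells):
            raise ValidationError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValidationError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable2x2":
        """Simultaneous row and column swap (d c / b a)."""
        return ContingencyTable2x2(self.d, self.c, self.b, self.a)


@dataclasses.dataclass(frozen=True)
class TestResult:
    p_value: float
    method: str
    statistic: float | None = None
    df: int | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> TestResult:
    """Two-tailed Fisher exact p for a 2x2 table with fixed margins.

    Enumerates the full feasible range of the top-left cell under the
    hypergeometric null; a table with a zero row or column margin is
    degenerate and returns p = 1 by convention.
    """
    r1 = table.a + table.b
    r2 = table.c + table.d
    c1 = table.a + table.c
    c2 = table.b + table.d
    n = table.total
    if 0 in (r1, r2, c1, c2):
        return TestResult(p_value=1.0, method="fisher_exact_two_tailed", degenerate=True)

    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    denom = _log_binom(n, c1)
    xs = np.arange(lo, hi + 1)
    logp = np.array(
        [_log_binom(r1, x) + _log_binom(r2, c1 - x) - denom for x in xs]
    )
    p_obs = math.exp(logp[table.a - lo])
    probs = np.exp(logp)
    p = float(probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return TestResult(p_value=min(p, 1.0), method="fisher_exact_two_tailed")


def kruskal_wallis(samples: Mapping[str, Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square(k-1) p-value.

    H = 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1), divided by the tie correction
    1 - sum(t^3 - t)/(N^3 - N).  All observations identical makes the
    correction divide by zero: an undefined-statistic error.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(g.size == 0 for g in groups.values()):
        raise ValidationError("every group must be nonempty")
    pooled = np.concatenate(list(groups.values()))
    N = pooled.size
    if N < 3:
        raise ValidationError("need at least 3 observations in total")

    ranks = rankdata(pooled)  # mid-ranks
    h = 0.0
    offset = 0
    for g in groups.values():
        rj = ranks[offset:offset + g.size].sum()
        h += rj * rj / g.size
        offset += g.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    correction = 1.0 - tie_term / (N**3 - N)
    if correction == 0.0:
        raise UndefinedStatisticError("all observations identical; H undefined")
    h /= correction

    df = len(groups) - 1
    p = float(chi2.sf(h, df))
    return TestResult(p_value=max(p, np.nextafter(0, 1)), method="kruskal_wallis",
                      statistic=float(h), df=df)


def _binary_levels(series: pd.Series, var: str) -> list:
    values = series.dropna()
    if values.dtype == bool or set(values.unique()) <= {True, False}:
        return [True, False]
    levels = sorted(values.unique())
    for canonical in (GENDER_LEVELS, EDUCATION_LEVELS):
        if set(levels) <= set(canonical):
            return list(canonical)
    if len(levels) > 2:
        raise ValidationError(f"variable {var!r} is not binary; levels: {levels}")
    if len(levels) < 2:
        raise ValidationError(f"variable {var!r} has a single level: {levels}")
    return levels


def respondent_crosstab(
    table: RespondentTable, row_var: str, col_var: str
) -> ContingencyTable2x2:
    """2x2 cross-tabulation of two binary respondent variables.

    Rows/columns are ordered by each variable's canonical level order
    (male/female, formal/nonformal, True/False, else sorted).  Respondents
    missing either field are excluded.
    """
    frame = table.frame
    for var in (row_var, col_var):
        if var not in frame.columns:
            raise ValidationError(f"unknown variable {var!r}")
    sub = frame[[row_var, col_var]].dropna()
    row_levels = _binary_levels(sub[row_var], row_var)
    col_levels = _binary_levels(sub[col_var], col_var)
    cells = [
        int(((sub[row_var] == r) & (sub[col_var] == c)).sum())
        for r in row_levels
        for c in col_levels
    ]
    return ContingencyTable2x2(*cells)


def standard_questionnaire_tests(table: RespondentTable) -> pd.DataFrame:
    """The report battery: age by gender and by education (Kruskal-Wallis),
    then every binary question crossed with education (Fisher exact)."""
    rows = []
    frame = table.frame
    for group_var in ("gender", "education"):
        samples = {
            level: frame.loc[frame[group_var] == level, "age"].to_numpy()
            for level in frame[group_var].unique()
        }
        res = kruskal_wallis(samples)
        rows.append(
            {
                "variable": "age",
                "comparison": group_var,
                "method": res.method,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
        )
    fisher_vars = ["gender"] + table.questions
    for var in fisher_vars:
        ct = respondent_crosstab(table, var, "education")
        res = fisher_exact_two_tailed(ct)
        rows.append(
            {
                "variable": var,
                "comparison": "education",
                "method": res.method,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(
        rows, columns=["variable", "comparison", "method", "statistic", "df", "p_value"]
    )
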