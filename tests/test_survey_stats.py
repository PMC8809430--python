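import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from vulturesurvey.data_io import RespondentTable
from vulturesurvey.exceptions import UndefinedStatisticError, ValidationError
from vulturesurvey.survey_stats import (
    ContingencyTable2x2,
    fisher_exact_two_tailed,
    kruskal_wallis,
    respondent_crosstab,
    standard_questionnaire_tests,
)


def fisher_enumeration_oracle(a, b, c, d, tie_rtol=1e-7):
    """Exact-rational enumeration of the two-tailed Fisher p-value."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    cutoff = p_obs * (1 + Fraction(tie_rtol).limit_denominator(10**12))
    return float(sum(p for p in probs.values() if p <= cutoff))


def kw_permutation_p(groups):
    """Exact permutation p-value: fraction of equal-size group assignments
    with H at least as large as observed."""
    vals = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    sizes = [len(v) for v in groups.values()]
    h_obs = kruskal_wallis(groups).statistic

    def assignments(remaining, sizes):
        if not sizes:
            yield []
            return
        for comb in itertools.combinations(remaining, sizes[0]):
            rest = [i for i in remaining if i not in comb]
            for tail in assignments(rest, sizes[1:]):
                yield [list(comb)] + tail

    count = total = 0
    for assign in assignments(list(range(len(vals))), sizes):
        g = {str(j): vals[ix] for j, ix in enumerate(assign)}
        try:
            h = kruskal_wallis(g).statistic
        except UndefinedStatisticError:
            h = 0.0
        total += 1
        count += h >= h_obs - 1e-12
    return count / total


def random_kw_groups(rng, max_total=8, min_total=5):
    """A random small-sample comparison: 2-3 groups, mixed tied/continuous."""
    while True:
        k = int(rng.integers(2, 4))
        sizes = rng.integers(1, 7, size=k)
        if min_total <= sizes.sum() <= max_total:
            break
    if rng.uniform() < 0.5:
        vals = rng.normal(size=int(sizes.sum()))
    else:
        vals = rng.integers(1, 6, size=int(sizes.sum())).astype(float)
        if len(set(vals)) < 2:
            vals[0] += 1.0
    groups, off = {}, 0
    for j, s in enumerate(sizes):
        groups[f"g{j}"] = vals[off:off + s]
        off += s
    return groups


class TestFisherExact:
    def test_diagonal_2x2(self):
        res = fisher_exact_two_tailed(ContingencyTable2x2(2, 0, 0, 2))
        assert res.p_value == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_three_one_table(self):
        res = fisher_exact_two_tailed(ContingencyTable2x2(3, 1, 1, 3))
        assert res.p_value == pytest.approx(0.4857142857142857, abs=1e-10)

    def test_extreme_antidiagonal(self):
        res = fisher_exact_two_tailed(ContingencyTable2x2(0, 5, 5, 0))
        assert res.p_value == pytest.approx(2.0 / 252.0, abs=1e-12)

    def test_degenerate_margin_p_one(self):
        res = fisher_exact_two_tailed(ContingencyTable2x2(0, 0, 3, 4))
        assert res.p_value == 1.0 and res.degenerate

    def test_matches_rational_enumeration(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 16, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d)).p_value
            assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), abs=1e-12)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 30, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            ours = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d)).p_value
            ref = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_row_and_column_swap_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = ContingencyTable2x2(a, b, c, d)
        assert fisher_exact_two_tailed(t).p_value == pytest.approx(
            fisher_exact_two_tailed(t.swapped()).p_value, rel=1e-10
        )

    def test_large_margins_no_overflow(self):
        res = fisher_exact_two_tailed(ContingencyTable2x2(120, 80, 90, 110))
        ref = scipy.stats.fisher_exact([[120, 80], [90, 110]]).pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-7)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestKruskalWallis:
    def test_hand_derived_two_group_example(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.statistic == pytest.approx(27.0 / 7.0, abs=1e-12)
        assert res.df == 1

    def test_identical_groups_h_zero_p_one(self):
        res = kruskal_wallis({"a": [1, 2], "b": [1, 2]})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=10)
        groups = {"a": vals[:4], "b": vals[4:]}
        cubed = {k: np.asarray(v) ** 3 for k, v in groups.items()}
        assert kruskal_wallis(groups).statistic == pytest.approx(
            kruskal_wallis(cubed).statistic, abs=1e-12
        )

    def test_all_values_identical_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0]})

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            g1 = rng.integers(1, 6, size=int(rng.integers(3, 10))).astype(float)
            g2 = rng.integers(1, 6, size=int(rng.integers(3, 10))).astype(float)
            g3 = rng.integers(1, 6, size=int(rng.integers(3, 10))).astype(float)
            if len(set(np.concatenate([g1, g2, g3]))) < 2:
                continue
            ours = kruskal_wallis({"a": g1, "b": g2, "c": g3})
            ref = scipy.stats.kruskal(g1, g2, g3)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_group_h_is_squared_rank_sum_z(self, rng):
        """Without ties, two-group H equals the squared standardized
        Wilcoxon rank-sum statistic."""
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        h = kruskal_wallis({"x": x, "y": y}).statistic
        n1, n2 = len(x), len(y)
        N = n1 + n2
        ranks = scipy.stats.rankdata(np.concatenate([x, y]))
        w = ranks[:n1].sum()
        z = (w - n1 * (N + 1) / 2.0) / math.sqrt(n1 * n2 * (N + 1) / 12.0)
        assert h == pytest.approx(z * z, abs=1e-10)

    def test_chi2_close_to_permutation_in_rejection_region(self, rng):
        """In the small-p regime (where the test is actually used) the
        chi-square tail tracks the exact permutation tail closely."""
        groups = {"a": [1.0, 2.0, 3.0, 4.0], "b": [6.0, 7.0, 8.0, 9.0]}
        res = kruskal_wallis(groups)
        p_perm = kw_permutation_p(groups)
        assert abs(res.p_value - p_perm) < 0.02


class TestCrosstab:
    def _table(self, rows):
        frame = pd.DataFrame(rows)
        frame["respondent_id"] = [f"R{i}" for i in range(len(frame))]
        return RespondentTable(frame)

    def test_balanced_square(self):
        t = self._table(
            [
                {"age": 30, "gender": "male", "education": "formal"},
                {"age": 40, "gender": "male", "education": "nonformal"},
                {"age": 50, "gender": "female", "education": "formal"},
                {"age": 60, "gender": "female", "education": "nonformal"},
            ]
        )
        ct = respondent_crosstab(t, "gender", "education")
        assert (ct.a, ct.b, ct.c, ct.d) == (1, 1, 1, 1)

    def test_missing_values_excluded(self):
        t = self._table(
            [
                {"age": 30, "gender": "male", "education": "formal", "q": True},
                {"age": 40, "gender": "female", "education": "nonformal", "q": None},
                {"age": 50, "gender": "female", "education": "formal", "q": False},
            ]
        )
        ct = respondent_crosstab(t, "q", "education")
        assert ct.total == 2

    def test_swapping_variables_transposes(self):
        t = self._table(
            [
                {"age": 30, "gender": "male", "education": "formal"},
                {"age": 40, "gender": "male", "education": "formal"},
                {"age": 50, "gender": "female", "education": "nonformal"},
                {"age": 60, "gender": "male", "education": "nonformal"},
            ]
        )
        ct = respondent_crosstab(t, "gender", "education")
        tt = respondent_crosstab(t, "education", "gender")
        assert (ct.a, ct.b, ct.c, ct.d) == (tt.a, tt.c, tt.b, tt.d)

    def test_non_binary_variable_rejected(self):
        t = self._table(
            [
                {"age": 30, "gender": "male", "education": "formal", "color": x}
                for x in ("red", "green", "blue")
            ]
        )
        with pytest.raises(ValidationError, match="color"):
            respondent_crosstab(t, "color", "education")


class TestStandardBattery:
    def test_report_shape_on_simulated_table(self):
        from vulturesurvey.synthetic import RespondentSimParams, simulate_respondents

        table = simulate_respondents(RespondentSimParams(seed=5))
        frame = standard_questionnaire_tests(table)
        assert list(frame.columns) == [
            "variable", "comparison", "method", "statistic", "df", "p_value"
        ]
        kw_rows = frame[frame.method == "kruskal_wallis"]
        assert set(kw_rows.comparison) == {"gender", "education"}
        assert ((frame.p_value > 0) & (frame.p_value <= 1)).all()
        # formally educated respondents are simulated younger: strong age signal
        age_edu = frame[(frame.variable == "age") & (frame.comparison == "education")]
        assert float(age_edu.p_value.iloc[0]) < 0.01
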