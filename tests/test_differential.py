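import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xenopept.differential import (
    CountMatrix,
    ScreenCriteria,
    _exact_permutation_p,
    group_pvalues,
    normalize_counts,
    presence_category,
    screen_differential,
)


def matrix(rows, n_control=4, n_tumor=4):
    cols = [f"C{i}" for i in range(n_control)] + [f"T{i}" for i in range(n_tumor)]
    df = pd.DataFrame(rows).T if isinstance(rows, dict) else pd.DataFrame(rows)
    df.columns = cols
    groups = {c: ("control" if c.startswith("C") else "tumor") for c in cols}
    return CountMatrix(df, groups)


class TestNormalizeCounts:
    def test_equal_depth_is_identity(self):
        m = matrix([[5, 5, 5, 5, 5, 5, 5, 5], [5, 5, 5, 5, 5, 5, 5, 5]])
        out = normalize_counts(m)
        assert np.allclose(out.counts, m.counts)

    def test_scale_factors_from_totals(self):
        cols = ["C0", "C1", "T0"]
        df = pd.DataFrame([[100, 200, 300]], columns=cols, index=["p"])
        groups = {"C0": "control", "C1": "control", "T0": "tumor"}
        out = normalize_counts(CountMatrix(df, groups))
        assert np.allclose(out.counts.loc["p"], [200.0, 200.0, 200.0])
        # factors 2.0, 1.0, 2/3 against the mean total of 200
        assert np.allclose(out.counts.sum() / df.sum(), [2.0, 1.0, 2 / 3])

    def test_zeros_stay_zero(self):
        m = matrix([[0, 2, 4, 2, 3, 1, 2, 2], [4, 2, 0, 2, 1, 3, 2, 2]])
        out = normalize_counts(m)
        assert (out.counts.to_numpy() == 0).sum() == 2

    def test_all_zero_sample_named_in_error(self):
        m = matrix([[1, 1, 0, 1, 1, 1, 1, 1], [2, 1, 0, 1, 1, 1, 1, 1]])
        with pytest.raises(ValueError, match="C2"):
            normalize_counts(m)


class TestPresenceCategory:
    def test_full_presence_both_groups(self):
        m = matrix([[1, 2, 3, 4, 5, 6, 7, 8]])
        assert presence_category(m.counts.iloc[0], m) == "both_groups"

    def test_tumor_only(self):
        m = matrix([[0, 0, 0, 0, 5, 6, 7, 8]])
        assert presence_category(m.counts.iloc[0], m) == "tumor_only"

    def test_control_only(self):
        m = matrix([[5, 6, 7, 8, 0, 0, 0, 0]])
        assert presence_category(m.counts.iloc[0], m) == "control_only"

    def test_partial_presence_not_reportable(self):
        m = matrix([[1, 2, 0, 0, 5, 6, 7, 8]])
        assert presence_category(m.counts.iloc[0], m) is None

    def test_relaxed_presence(self):
        m = matrix([[1, 0, 0, 0, 5, 6, 7, 8]])
        assert (
            presence_category(m.counts.iloc[0], m, require_full_presence=False)
            == "both_groups"
        )


class TestPermutationP:
    def test_matches_scipy_exact_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.poisson(10, size=4).astype(float)
            y = rng.poisson(14, size=4).astype(float)
            ref = stats.permutation_test(
                (x, y),
                lambda a, b, axis=-1: a.mean(axis=axis) - b.mean(axis=axis),
                permutation_type="independent",
                n_resamples=np.inf,
                alternative="two-sided",
            )
            assert _exact_permutation_p(x, y) == pytest.approx(ref.pvalue)


class TestScreenDifferential:
    def quants(self, m, n_unique=9):
        return {acc: n_unique for acc in m.counts.index}

    def test_identical_groups_excluded(self):
        m = matrix([[4, 6, 5, 7, 4, 6, 5, 7]])
        assert screen_differential(m, self.quants(m)) == []

    def test_down_regulated_toy(self):
        m = matrix([[8, 8, 8, 8, 2, 2, 2, 2]], n_control=4, n_tumor=4)
        m = CountMatrix(m.counts.astype(float), m.groups)
        (res,) = screen_differential(m, self.quants(m))
        assert res.raw_fc == pytest.approx(0.25)
        assert res.fold_change_reported == pytest.approx(4.0)
        assert res.trend == "Down"
        # constant within-group counts with unequal means: permutation fallback
        assert res.p_value == pytest.approx(2 / 70)

    def test_min_unique_peptides_dominates_effect_size(self):
        m = matrix([[2, 3, 2, 3, 25, 30, 22, 28]])
        assert screen_differential(m, self.quants(m, n_unique=1)) == []

    def test_exclusive_proteins_reported_without_fc_or_p(self):
        m = matrix(
            [[0, 0, 0, 0, 5, 6, 7, 8], [3, 4, 5, 6, 0, 0, 0, 0]],
        )
        results = screen_differential(m, self.quants(m))
        by_presence = {r.presence: r for r in results}
        assert set(by_presence) == {"tumor_only", "control_only"}
        for r in results:
            assert r.p_value is None and r.fold_change_reported is None
            assert r.trend is None

    def test_fold_gate_blocks_modest_changes(self):
        # significant but below 2-fold: excluded
        m = matrix([[10, 11, 10, 11, 15, 16, 15, 16]])
        assert screen_differential(m, self.quants(m)) == []

    def test_reported_fold_change_at_least_gate(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(
            np.repeat([[6.0], [30.0]], 8, axis=1) * [1, 1, 1, 1, 5, 5, 5, 5],
        )
        m = matrix(counts.astype(float))
        criteria = ScreenCriteria()
        for r in screen_differential(m, self.quants(m), criteria):
            if r.presence == "both_groups":
                assert r.fold_change_reported >= max(
                    criteria.fc_up, 1 / criteria.fc_down
                )

    def test_fdr_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(10.0, size=(300, 8)) + 1
        m = matrix(counts.astype(float))
        raw = screen_differential(m, self.quants(m))
        adj = screen_differential(m, self.quants(m), fdr=True)
        assert len(adj) <= len(raw)

    def test_byte_identical_repeat_runs(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(9.0, size=(50, 8)) + 1
        m = matrix(counts.astype(float))
        a = screen_differential(m, self.quants(m))
        b = screen_differential(m, self.quants(m))
        assert a == b


class TestGroupPvalues:
    def test_zero_variance_equal_means_p_is_one(self):
        m = matrix([[5, 5, 5, 5, 5, 5, 5, 5]])
        assert group_pvalues(m).iloc[0] == 1.0

    def test_only_both_group_rows_tested(self):
        m = matrix([[0, 0, 0, 0, 5, 6, 7, 8], [4, 5, 6, 7, 4, 5, 6, 8]])
        assert len(group_pvalues(m)) == 1
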