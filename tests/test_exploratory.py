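import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seapatch.errors import DomainError, ValidationError
from seapatch.exploratory_stats import (
    StepwiseFit,
    StepwiseStep,
    anova_by_line,
    bonferroni_flag,
    forward_stepwise,
    ks_normality,
)


def oracle_forward_path(y, X: pd.DataFrame, entry_p: float = 0.1):
    """Independent forward-selection oracle via exhaustive submodel enumeration.

    Reconstructs the forward path from raw residual sums of squares and the
    partial-F test, without reusing any package code.
    """
    yz = (y - y.mean()) / y.std(ddof=1)
    cols = list(X.columns)
    z = {c: (X[c] - X[c].mean()) / X[c].std(ddof=1) for c in cols}
    n = len(yz)

    def rss(subset):
        if not subset:
            return float(((yz - yz.mean()) ** 2).sum()), 0
        design = np.column_stack([np.ones(n)] + [z[c] for c in subset])
        beta, *_ = np.linalg.lstsq(design, yz, rcond=None)
        resid = yz - design @ beta
        return float(resid @ resid), len(subset)

    selected = []
    while True:
        remaining = [c for c in cols if c not in selected]
        if not remaining or n <= len(selected) + 2:
            break
        rss_old, _ = rss(selected)
        best = None
        for c in remaining:
            rss_new, k = rss(selected + [c])
            df2 = n - k - 1
            if rss_new <= 0:
                p = 0.0
            else:
                f = (rss_old - rss_new) / (rss_new / df2)
                p = float(stats.f.sf(f, 1, df2))
            if best is None or p < best[0]:
                best = (p, c)
        if best[0] > entry_p:
            break
        selected.append(best[1])
    return selected


class TestForwardStepwise:
    def test_perfect_predictor_enters_first(self, rng):
        n = 41
        x = rng.normal(size=n)
        X = pd.DataFrame(
            {f"noise{i}": rng.normal(size=n) for i in range(5)} | {"signal": x}
        )
        fit = forward_stepwise(x.copy(), X)
        assert fit.selected[0] == "signal"
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_oracle_on_small_pools(self, rng):
        agree = 0
        for _ in range(20):
            n = 30
            X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
            y = 0.7 * X["a"].to_numpy() + rng.normal(size=n)
            fit = forward_stepwise(y, X)
            agree += fit.selected == oracle_forward_path(pd.Series(y), X)
        assert agree == 20

    def test_entry_threshold_zero_selects_nothing_on_noise(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        fit = forward_stepwise(rng.normal(size=40), X, entry_p=0.0)
        assert fit.selected == [] and fit.adjusted_r2 == 0.0

    def test_entry_threshold_one_reproduces_full_model(self, rng):
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = rng.normal(size=n)
        fit = forward_stepwise(y, X, entry_p=1.0)
        assert sorted(fit.selected) == ["a", "b", "c"]
        import statsmodels.api as sm

        z = (X - X.mean()) / X.std()  # pandas default ddof=1
        yz = (y - y.mean()) / y.std(ddof=1)
        full = sm.OLS(yz, sm.add_constant(z[fit.selected].to_numpy())).fit()
        for step, coef in zip(fit.steps, full.params[1:]):
            assert step.coefficient == pytest.approx(coef, abs=1e-8)

    def test_collinear_candidate_skipped_with_warning(self, rng):
        n = 40
        a = rng.normal(size=n)
        X = pd.DataFrame({"a": a, "dup": 2.0 * a + 3.0, "b": rng.normal(size=n)})
        y = a + 0.5 * rng.normal(size=n)
        fit = forward_stepwise(y, X, entry_p=1.0)
        assert "dup" not in fit.selected or "a" not in fit.selected
        assert any("collinear" in w for w in fit.warnings)

    def test_adjusted_r2_never_exceeds_r2(self, rng):
        for _ in range(10):
            X = pd.DataFrame(rng.normal(size=(35, 4)), columns=list("abcd"))
            y = X["a"].to_numpy() + rng.normal(size=35)
            fit = forward_stepwise(y, X)
            assert fit.adjusted_r2 <= fit.r2 + 1e-12

    def test_spurious_entries_common_but_rarely_bonferroni_flagged(self, rng):
        # under a global null, a permissive entry threshold admits noise often,
        # while the corrected flags stay rare
        n, m, reps = 41, 10, 60
        any_entry, any_flag = 0, 0
        for _ in range(reps):
            X = pd.DataFrame(
                rng.normal(size=(n, m)), columns=[f"v{i}" for i in range(m)]
            )
            fit = forward_stepwise(rng.normal(size=n), X, bonferroni_m=18)
            any_entry += bool(fit.selected)
            any_flag += any(s.bonferroni_significant for s in fit.steps)
        assert any_entry / reps > 0.4
        assert any_flag / reps <= 0.1


class TestBonferroni:
    def _fit(self, pvals):
        steps = [
            StepwiseStep(variable=f"v{i}", coefficient=0.3, p_at_entry=p, p_final=p)
            for i, p in enumerate(pvals)
        ]
        return StepwiseFit(
            response="gx", steps=steps, adjusted_r2=0.3, r2=0.4,
            ks_stat=0.1, ks_p=0.5, n=41, entry_p=0.1, bonferroni_m=len(pvals),
        )

    def test_family_of_18(self):
        fit = self._fit([0.001, 0.02, 0.004, 0.04])
        assert bonferroni_flag(fit, 18) == [True, False, False, False]

    def test_family_of_one(self):
        fit = self._fit([0.04, 0.06])
        assert bonferroni_flag(fit, 1) == [True, False]

    def test_invalid_family_size(self):
        with pytest.raises(ValidationError):
            bonferroni_flag(self._fit([0.01]), 0)


class TestAnovaByLine:
    @staticmethod
    def _balanced(rng, sizes, shifts):
        y, g = [], []
        for line, (size, shift) in enumerate(zip(sizes, shifts), start=1):
            y.extend(rng.normal(shift, 1.0, size=size))
            g.extend([str(line)] * size)
        return np.array(y), np.array(g)

    def test_seven_lines_of_41_gives_df_6_34(self, rng):
        y, g = self._balanced(rng, [6, 6, 6, 6, 6, 6, 5], [0] * 7)
        res = anova_by_line(y, g)
        assert (res.df_between, res.df_within) == (6, 34)
        assert len(res.tukey) == 21  # C(7, 2) pairwise comparisons

    def test_centered_groups_give_zero_f(self, rng):
        y, g = self._balanced(rng, [5, 5, 5], [0, 0, 0])
        for line in np.unique(g):
            y[g == line] -= y[g == line].mean()
        res = anova_by_line(y, g)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_strong_effect_detected_with_high_r2(self, rng):
        y, g = self._balanced(rng, [6] * 4, [0, 3, 6, 9])
        res = anova_by_line(y, g)
        assert res.p < 0.001 and res.r2 > 0.7

    def test_singleton_line_dropped_from_tukey_with_warning(self, rng):
        y, g = self._balanced(rng, [5, 5, 1], [0, 1, 2])
        res = anova_by_line(y, g)
        assert len(res.tukey) == 1  # only the two non-singleton lines
        assert any("single observation" in w for w in res.warnings)

    @staticmethod
    def _f_stat(y, g, labels):
        grand = y.mean()
        ssb = sum((g == lab).sum() * (y[g == lab].mean() - grand) ** 2 for lab in labels)
        sst = ((y - grand) ** 2).sum()
        dfb, dfw = len(labels) - 1, y.size - len(labels)
        return (ssb / dfb) / ((sst - ssb) / dfw)

    def test_agrees_with_permutation_anova(self, rng):
        # reject/accept agreement with a brute-force permutation F-test
        agree = 0
        reps = 20
        for _ in range(reps):
            y, g = self._balanced(rng, [8, 8, 8], [0, 0.9, 1.8])
            labels = np.unique(g)
            res = anova_by_line(y, g)
            assert res.F == pytest.approx(self._f_stat(y, g, labels), abs=1e-10)
            perm_f = [
                self._f_stat(rng.permutation(y), g, labels) for _ in range(400)
            ]
            p_perm = (1 + sum(f >= res.F for f in perm_f)) / 401
            agree += (res.p <= 0.05) == (p_perm <= 0.05)
        assert agree >= 0.95 * reps


class TestKSNormality:
    def test_calibrated_under_normal_data(self, rng):
        pvals = [ks_normality(rng.normal(size=80))[1] for _ in range(100)]
        # parameter estimation makes the classical p conservative; it must
        # not cluster near zero under the null
        assert np.quantile(pvals, 0.1) > 0.05

    def test_location_shift_invariance(self, rng):
        r = rng.normal(size=50)
        s1, _ = ks_normality(r)
        s2, _ = ks_normality(r + 100.0)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_tiny_sample_rejected(self):
        with pytest.raises(DomainError):
            ks_normality([0.1, -0.2, 0.05])

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            ks_normality([1.0] * 10)


def test_between_group_pair_counts():
    """Pairs split across a {4}|{3} partition of 7 lines number 4*3 = 12."""
    lines = [str(i) for i in range(1, 8)]
    pairs = list(itertools.combinations(lines, 2))
    assert len(pairs) == 21
    group_a, group_b = {"1", "5", "6", "7"}, {"2", "3", "4"}
    crossing = [p for p in pairs if (p[0] in group_a) != (p[1] in group_a)]
    assert len(crossing) == len(group_a) * len(group_b) == 12
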