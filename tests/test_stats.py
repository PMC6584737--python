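"""Classical inference: paired t, JZS Bayes factor, mixed ANOVA, correlations."""

import math

import numpy as np
import pandas as pd
import pytest

from vwmtradeoff.errors import DesignError, EstimationError
from vwmtradeoff.stats import (
    jzs_bf10,
    mixed_anova,
    paired_t,
    pearson_one_tailed,
)


class TestPairedT:
    def test_identical_samples_give_null_result(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, x.copy())
        assert (res.t, res.cohens_d, res.p) == (0.0, 0.0, 1.0)
        assert res.bf10 < 1.0

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(EstimationError):
            paired_t([1, 2, 3, 4], [0, 1, 2, 3])

    def test_against_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == 14
        assert res.cohens_d == pytest.approx(res.t / math.sqrt(15))

    def test_noncentral_t_calibration(self):
        """With a true standardised effect d injected, mean |t| follows the
        noncentral-t expectation t ~ nct(df, d*sqrt(n))."""
        from scipy.stats import nct

        n, d_true, reps = 13, 0.86, 400
        rng = np.random.default_rng(2)
        ts = []
        for _ in range(reps):
            diff = rng.normal(d_true, 1.0, n)
            ts.append(paired_t(diff, np.zeros(n)).t)
        expected = nct.mean(n - 1, d_true * math.sqrt(n))
        assert np.mean(ts) == pytest.approx(expected, abs=3 * np.std(ts) / math.sqrt(reps))


class TestJzsBayesFactor:
    def test_null_favoring_at_zero_t(self):
        assert jzs_bf10(0.0, 13) < 1.0

    def test_monotone_in_abs_t(self):
        values = [jzs_bf10(t, 13) for t in np.linspace(0, 6, 25)]
        assert np.all(np.diff(values) > 0)

    @pytest.mark.parametrize(
        "t, n, published",
        [
            (4.102, 13, 28.57),
            (2.621, 13, 3.03),
            (0.732, 13, 0.35),
            (1.117, 13, 0.47),
        ],
    )
    def test_reproduces_published_jasp_values(self, t, n, published):
        """Default-prior (r = sqrt(2)/2) BF10 for reported paired contrasts."""
        assert jzs_bf10(t, n) == pytest.approx(published, rel=0.02)

    def test_matches_independent_dense_grid_quadrature(self):
        """Adaptive quadrature agrees with a dense trapezoid integration of
        the same integrand (substituted g = u/(1-u))."""
        from vwmtradeoff.stats import _jzs_integrand

        for t, n in [(0.5, 10), (2.0, 13), (4.102, 13), (7.0, 30)]:
            u = np.linspace(1e-9, 1 - 1e-9, 400_001)
            g = u / (1 - u)
            vals = _jzs_integrand(g, t, n, math.sqrt(2) / 2) / (1 - u) ** 2
            alt = np.trapezoid(vals, u)
            null = (1 + t**2 / (n - 1)) ** (-(n) / 2.0)
            assert jzs_bf10(t, n) == pytest.approx(alt / null, rel=1e-4)

    def test_orders_consistently_with_p(self):
        bf_small, bf_big = jzs_bf10(1.0, 20), jzs_bf10(3.0, 20)
        assert bf_small < bf_big


class TestPearsonOneTailed:
    def test_perfect_correlation(self):
        res = pearson_one_tailed([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_wrong_direction_p_above_half(self):
        res = pearson_one_tailed([1, 2, 3, 4, 5], [5, 4.2, 3.1, 2.4, 1.0], "positive")
        assert res.p > 0.5

    def test_one_tailed_is_half_two_tailed_when_directions_agree(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        x = rng.normal(size=26)
        y = 0.4 * x + rng.normal(size=26)
        res = pearson_one_tailed(x, y, "positive")
        two = sps.pearsonr(x, y)
        assert two.statistic > 0
        assert res.p == pytest.approx(two.pvalue / 2)

    def test_null_calibration_type_i_rate(self):
        """Independent x, y at n = 26: one-tailed false-positive rate ~ 0.05."""
        rng = np.random.default_rng(4)
        reps, n = 10_000, 26
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        from scipy import stats as sps

        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = sps.t.sf(t, n - 2)
        # vectorised replica of pearson_one_tailed's transform; spot-check one
        res = pearson_one_tailed(x[0], y[0], "positive")
        assert res.p == pytest.approx(p[0], rel=1e-10)
        rate = float(np.mean(p < 0.05))
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(EstimationError):
            pearson_one_tailed([1, 1, 1, 1], [1, 2, 3, 4])


@pytest.fixture()
def mixed_table():
    rng = np.random.default_rng(5)
    rows = []
    for i in range(26):
        g = "low" if i < 13 else "high"
        base = rng.normal(30, 5)
        eff = 4.0 if g == "high" else 0.5
        rows.append(dict(subject=f"s{i}", group=g, condition="low_precision",
                         value=base + rng.normal(0, 2)))
        rows.append(dict(subject=f"s{i}", group=g, condition="high_precision",
                         value=base - eff + rng.normal(0, 2)))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_pingouin(self, mixed_table):
        pg = pytest.importorskip("pingouin")
        mine = {e.effect: e for e in mixed_anova(
            mixed_table, dv="value", within="condition", subject="subject", between="group"
        )}
        ref = pg.mixed_anova(data=mixed_table, dv="value", within="condition",
                             subject="subject", between="group")
        ref = ref.set_index("Source")
        assert mine["group"].f == pytest.approx(ref.loc["group", "F"])
        assert mine["condition"].f == pytest.approx(ref.loc["condition", "F"])
        assert mine["condition * group"].f == pytest.approx(ref.loc["Interaction", "F"])
        assert mine["condition"].p == pytest.approx(ref.loc["condition", "p_unc"])
        assert mine["condition"].eta_sq_partial == pytest.approx(ref.loc["condition", "np2"])

    def test_within_f_equals_squared_paired_t(self, mixed_table):
        """On a two-level within design with one homogeneous group, the
        within-factor F equals the squared paired t."""
        effects = mixed_anova(
            mixed_table, dv="value", within="condition", subject="subject", between=[]
        )
        wide = mixed_table.pivot_table(index="subject", columns="condition", values="value")
        t = paired_t(wide["low_precision"].to_numpy(), wide["high_precision"].to_numpy())
        within = [e for e in effects if e.effect == "condition"][0]
        assert within.f == pytest.approx(t.t**2, abs=1e-8)
        assert within.df1 == 1 and within.df2 == 25

    def test_constant_dv_gives_zero_f(self):
        rows = []
        for i in range(8):
            for c in ("low_precision", "high_precision"):
                rows.append(dict(subject=f"s{i}", group="low" if i < 4 else "high",
                                 condition=c, value=5.0 + 0.001 * i))
        df = pd.DataFrame(rows)
        effects = mixed_anova(df, dv="value", within="condition", subject="subject",
                              between="group")
        within = [e for e in effects if e.effect == "condition"][0]
        assert within.f == pytest.approx(0.0, abs=1e-9)

    def test_eta_squared_within_unit_interval(self, mixed_table):
        effects = mixed_anova(mixed_table, dv="value", within="condition",
                              subject="subject", between="group")
        total = 0.0
        for e in effects:
            assert 0.0 <= e.eta_sq <= 1.0
            assert 0.0 <= e.eta_sq_partial <= 1.0
            total += e.eta_sq
        assert total <= 1.0

    def test_unbalanced_design_rejected(self, mixed_table):
        df = mixed_table[mixed_table.subject != "s0"]
        with pytest.raises(DesignError, match="unbalanced"):
            mixed_anova(df, dv="value", within="condition", subject="subject",
                        between="group")

    def test_missing_cell_rejected(self, mixed_table):
        df = mixed_table.drop(index=[0])
        with pytest.raises(DesignError, match="missing cells"):
            mixed_anova(df, dv="value", within="condition", subject="subject",
                        between="group")

    def test_three_way_design_dfs(self):
        rng = np.random.default_rng(6)
        rows = []
        for exp in ("e1", "e2"):
            for i in range(26):
                g = "low" if i < 13 else "high"
                base = rng.normal(30, 5)
                rows.append(dict(subject=f"{exp}s{i}", group=g, experiment=exp,
                                 condition="low", value=base + rng.normal(0, 2)))
                rows.append(dict(subject=f"{exp}s{i}", group=g, experiment=exp,
                                 condition="high", value=base + rng.normal(0, 2)))
        effects = mixed_anova(pd.DataFrame(rows), dv="value", within="condition",
                              subject="subject", between=["group", "experiment"])
        by_name = {e.effect: e for e in effects}
        assert set(by_name) == {
            "group", "experiment", "group * experiment", "condition",
            "condition * group", "condition * experiment",
            "condition * group * experiment",
        }
        assert all(e.df1 == 1 and e.df2 == 48 for e in effects)

    def test_interaction_power_at_injected_effect(self):
        """A group x condition interaction of ~1.2 SD units at n = 13/group is
        detected in most replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        reps = 200
        for _ in range(reps):
            rows = []
            for i in range(26):
                g = "low" if i < 13 else "high"
                base = rng.normal(0, 1)
                eff = 1.2 if g == "high" else 0.0
                rows.append(dict(subject=f"s{i}", group=g, condition="a",
                                 value=base + rng.normal(0, 0.5)))
                rows.append(dict(subject=f"s{i}", group=g, condition="b",
                                 value=base - eff + rng.normal(0, 0.5)))
            effects = mixed_anova(pd.DataFrame(rows), dv="value", within="condition",
                                  subject="subject", between="group")
            inter = [e for e in effects if e.effect == "condition * group"][0]
            hits += inter.p < 0.05
        assert hits / reps > 0.8
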