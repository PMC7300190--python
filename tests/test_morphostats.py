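import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mitomorph.morphostats import (
    density_estimate,
    ks_distance,
    sample_distance_table,
    two_way_anova,
    wilcoxon_rank_sum,
)


def brute_force_ks(x, y):
    """sup |ECDF_x - ECDF_y| evaluated at every pooled point."""
    pts = np.concatenate([x, y])
    d = 0.0
    for p in pts:
        fx = np.mean(x <= p)
        fy = np.mean(y <= p)
        d = max(d, abs(fx - fy))
    return d


class TestDensityEstimate:
    def test_unit_integral(self, rng):
        est = density_estimate(rng.lognormal(0, 0.5, 400))
        assert np.trapezoid(est.density, est.grid) == pytest.approx(1.0, abs=1e-3)
        assert (est.density >= 0).all()

    def test_mode_near_zero_for_standard_normal(self):
        x = np.random.default_rng(7).normal(0, 1, 2000)
        est = density_estimate(x)
        assert abs(est.grid[np.argmax(est.density)]) < 0.1

    def test_silverman_type_bandwidth(self, rng):
        x = rng.normal(0, 2, 500)
        est = density_estimate(x)
        sd = np.std(x, ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        assert est.bandwidth == pytest.approx(0.9 * min(sd, iqr / 1.34) * 500 ** -0.2)

    def test_log_transform(self, rng):
        x = rng.lognormal(0, 0.3, 300)
        est = density_estimate(x, transform="log")
        assert est.transform == "log"
        assert est.grid.min() < 0 < est.grid.max()  # log scale around 0

    def test_errors(self):
        with pytest.raises(ValueError):
            density_estimate([3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            density_estimate([1.0, -1.0, 2.0], transform="log")


class TestKSDistance:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(0, 1, 50)
        assert ks_distance(x, x.copy()) == 0.0

    def test_disjoint_supports_one(self, rng):
        assert ks_distance(rng.uniform(0, 1, 40), rng.uniform(5, 6, 60)) == 1.0

    def test_shifted_uniforms_half(self):
        r = np.random.default_rng(3)
        d = ks_distance(r.uniform(0, 1, 5000), r.uniform(0.5, 1.5, 5000))
        assert d == pytest.approx(0.5, abs=0.03)

    def test_matches_bruteforce_ecdf_sup(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, rng.integers(5, 40))
            y = rng.normal(0.3, 1.2, rng.integers(5, 40))
            assert ks_distance(x, y) == pytest.approx(brute_force_ks(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.lognormal(0, 0.4, 200)
        y = rng.lognormal(0.2, 0.5, 150)
        d = ks_distance(x, y)
        for f in (np.log, np.sqrt, lambda v: 3 * v + 2, lambda v: v ** 3):
            assert ks_distance(f(x), f(y)) == pytest.approx(d, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_distance([], [1.0])


def _particles_df(rng, shift_mut_cccp=0.0):
    rows = []
    for group in ("CTRL", "MUT"):
        for subj in range(2):
            for trt in ("DMSO", "CCCP"):
                for fov in range(3):
                    loc = shift_mut_cccp if (group, trt) == ("MUT", "CCCP") else 0.0
                    for v in rng.normal(loc, 1, 30):
                        rows.append(
                            dict(
                                subject=f"{group}{subj + 1}",
                                group=group,
                                treatment=trt,
                                fov=fov,
                                circularity=v,
                            )
                        )
    return pd.DataFrame(rows)


class TestSampleDistanceTable:
    def test_self_comparison_without_loo_is_zero(self, rng):
        df = _particles_df(rng)
        one = df[(df.group == "CTRL") & (df.treatment == "DMSO")]
        dist = sample_distance_table(one, "circularity", unit="fov", leave_one_out=False)
        # the pool is all CTRL/DMSO particles; a fov vs the pool is not 0,
        # but a *single* fov study vs itself is
        single = one[(one.subject == "CTRL1") & (one.fov == 0)]
        d0 = sample_distance_table(single, "circularity", unit="fov", leave_one_out=False)
        assert d0["D"].iloc[0] == 0.0
        assert (dist["D"] >= 0).all() and (dist["D"] <= 1).all()

    def test_leave_one_out_excludes_own_particles(self, rng):
        df = _particles_df(rng)
        loo = sample_distance_table(df, "circularity", leave_one_out=True)
        ref_n = ((df.group == "CTRL") & (df.treatment == "DMSO")).sum()
        ctrl_rows = loo[(loo.group == "CTRL") & (loo.treatment == "DMSO")]
        other_rows = loo[(loo.group != "CTRL") | (loo.treatment != "DMSO")]
        assert (ctrl_rows["n_reference"] < ref_n).all()
        assert (other_rows["n_reference"] == ref_n).all()

    def test_planted_shift_raises_distance(self, rng):
        df = _particles_df(rng, shift_mut_cccp=2.0)
        dist = sample_distance_table(df, "circularity")
        mean_mut_cccp = dist[(dist.group == "MUT") & (dist.treatment == "CCCP")]["D"].mean()
        mean_ctrl = dist[(dist.group == "CTRL") & (dist.treatment == "DMSO")]["D"].mean()
        assert mean_mut_cccp > mean_ctrl + 0.2

    def test_unknown_parameter_and_empty_reference(self, rng):
        df = _particles_df(rng)
        with pytest.raises(KeyError):
            sample_distance_table(df, "nope")
        with pytest.raises(ValueError):
            sample_distance_table(df[df.group == "MUT"], "circularity")


def _anova_oracle(df, response="y"):
    """Projection-matrix least squares with effect coding (type-II on a
    balanced design equals the closed-form decomposition)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(f"{response} ~ C(group) * C(treatment)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


class TestTwoWayAnova:
    def test_matches_projection_oracle(self, rng):
        rows = []
        for g in ("CTRL", "MUT"):
            for t in ("DMSO", "CCCP"):
                for _ in range(5):
                    rows.append(dict(group=g, treatment=t, y=rng.normal()))
        df = pd.DataFrame(rows)
        res = two_way_anova(df, "y")
        oracle = _anova_oracle(df)
        assert res.table.loc["mutation", "SS"] == pytest.approx(
            oracle.loc["C(group)", "sum_sq"], abs=1e-8
        )
        assert res.table.loc["treatment", "SS"] == pytest.approx(
            oracle.loc["C(treatment)", "sum_sq"], abs=1e-8
        )
        assert res.table.loc["interaction", "SS"] == pytest.approx(
            oracle.loc["C(group):C(treatment)", "sum_sq"], abs=1e-8
        )
        assert res.table.loc["error", "SS"] == pytest.approx(
            oracle.loc["Residual", "sum_sq"], abs=1e-8
        )
        for mine, theirs in (
            ("mutation", "C(group)"),
            ("treatment", "C(treatment)"),
            ("interaction", "C(group):C(treatment)"),
        ):
            assert res.table.loc[mine, "F"] == pytest.approx(oracle.loc[theirs, "F"], abs=1e-8)
            assert res.table.loc[mine, "p"] == pytest.approx(
                oracle.loc[theirs, "PR(>F)"], abs=1e-8
            )

    def test_ss_decomposition(self, rng):
        rows = [
            dict(group=g, treatment=t, y=rng.normal())
            for g in "AB" for t in "CD" for _ in range(4)
        ]
        df = pd.DataFrame(rows)
        res = two_way_anova(df, "y")
        ss = res.table["SS"]
        total = ((df.y - df.y.mean()) ** 2).sum()
        assert ss["mutation"] + ss["treatment"] + ss["interaction"] + ss["error"] == pytest.approx(
            total, rel=1e-9
        )
        assert res.table["df"].sum() == len(df) - 1

    def test_pure_factor_a_effect(self):
        rows = [
            dict(group=g, treatment=t, y=(1.0 if g == "B" else 0.0))
            for g in "AB" for t in "CD" for _ in range(3)
        ]
        res = two_way_anova(pd.DataFrame(rows), "y")
        assert res.table.loc["treatment", "SS"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.loc["interaction", "SS"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_all_equal(self):
        rows = [dict(group=g, treatment=t, y=2.0) for g in "AB" for t in "CD" for _ in range(3)]
        res = two_way_anova(pd.DataFrame(rows), "y")
        assert res.degenerate
        assert math.isnan(res.table.loc["mutation", "F"])

    def test_empty_cell_error_names_cell(self):
        rows = [dict(group="A", treatment="C", y=1.0), dict(group="A", treatment="D", y=1.0),
                dict(group="B", treatment="C", y=1.0)]
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(pd.DataFrame(rows), "y")


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided p by full enumeration of rank assignments."""
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs_x = ranks[:n].sum() - n * (n + 1) / 2
    stats = []
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        stats.append(u)
    stats = np.array(stats)
    # two-sided around the symmetric center nm/2
    dev = abs(u_obs_x - n * m / 2)
    p = np.mean(np.abs(stats - n * m / 2) >= dev - 1e-12)
    return p


class TestWilcoxon:
    def test_fully_separated_small_samples(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_sets_p_near_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 5.0, 9.0], [1.0, 2.0, 5.0, 9.0])
        assert p > 0.8

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(8):
            x = rng.normal(0, 1, int(rng.integers(3, 6)))
            y = rng.normal(0.5, 1, int(rng.integers(3, 6)))
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-10)

    def test_null_pvalues_roughly_uniform(self):
        r = np.random.default_rng(11)
        ps = []
        for _ in range(400):
            _, p = wilcoxon_rank_sum(r.normal(0, 1, 30), r.normal(0, 1, 30))
            ps.append(p)
        d = brute_force_ks(np.array(ps), np.random.default_rng(1).uniform(0, 1, 4000))
        assert d < 0.08

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])
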