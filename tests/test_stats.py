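"""The cohort statistical battery against brute-force and library oracles."""

import numpy as np
import pytest

from myodmi.errors import ValidationError
from myodmi.stats import (
    partial_spearman,
    pearson_r,
    run_cohort_stats,
    shapiro_wilk,
    two_sample_t,
    two_way_anova,
)
from myodmi.synthetic import generate_cohort


class TestTwoSampleT:
    def test_published_bmi_difference(self):
        """Male 23.60 +/- 1.81 vs female 21.60 +/- 1.48 (n = 11 each)
        reproduces the printed p = 0.01."""
        res = two_sample_t(summary_a=(11, 23.60, 1.81), summary_b=(11, 21.60, 1.48))
        assert round(res.p_value, 2) == 0.01
        assert res.df == 20

    def test_published_age_difference(self):
        res = two_sample_t(summary_a=(11, 26.30, 2.76), summary_b=(11, 27.10, 3.45))
        assert round(res.p_value, 2) == 0.55

    def test_identical_groups(self):
        res = two_sample_t(group_a=[1.0, 2.0, 3.0], group_b=[1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_raw_equals_summaries(self, rng):
        a = rng.normal(10, 2, 14)
        b = rng.normal(9, 2, 9)
        raw = two_sample_t(group_a=a, group_b=b)
        summ = two_sample_t(
            summary_a=(len(a), a.mean(), a.std(ddof=1)),
            summary_b=(len(b), b.mean(), b.std(ddof=1)),
        )
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)

    def test_constant_unequal_groups_degenerate(self):
        res = two_sample_t(group_a=[2.0, 2.0], group_b=[1.0, 1.0])
        assert res.p_value == 0.0


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.estimate == pytest.approx(1.0)

    def test_null_large_n(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert abs(pearson_r(x, y).estimate) < 0.1

    def test_matches_brute_force_formula(self, rng):
        x = np.array([1.0, 4.0, 2.0, 7.0, 5.0, 3.0])
        y = np.array([2.0, 3.0, 3.5, 8.0, 4.0, 1.0])
        r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson_r(x, y).estimate == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialSpearman:
    def test_constant_covariate_equals_plain_spearman(self, rng):
        from scipy.stats import spearmanr

        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        res = partial_spearman(x, y, np.ones(20))
        assert "constant_covariate" in res.flags
        assert res.estimate == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_confound_removal(self, rng):
        """x and y driven only by a shared binary covariate: partial rho ~ 0."""
        z = np.repeat([0.0, 1.0], 100)
        x = 3 * z + rng.normal(0, 0.5, 200)
        y = -2 * z + rng.normal(0, 0.5, 200)
        plain = pearson_r(x, y).estimate
        partial = partial_spearman(x, y, z).estimate
        assert abs(plain) > 0.5
        assert abs(partial) < 0.15

    def test_matches_longhand_residualization(self):
        """Oracle: explicit rank + projection computed step by step."""
        from scipy.stats import rankdata, t as tdist

        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5, 6.0])
        z = np.array([1.0, 2.0, 1.0, 3.0, 2.0, 1.0, 3.0])
        rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
        zc = rz - rz.mean()
        ex = (rx - rx.mean()) - zc * np.dot(rx - rx.mean(), zc) / np.dot(zc, zc)
        ey = (ry - ry.mean()) - zc * np.dot(ry - ry.mean(), zc) / np.dot(zc, zc)
        rho = np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey))
        df = len(x) - 3
        p = 2 * tdist.sf(abs(rho) * np.sqrt(df / (1 - rho**2)), df)
        res = partial_spearman(x, y, z)
        assert res.estimate == pytest.approx(rho, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_pingouin(self, rng):
        """Independent library cross-check."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        df = pd.DataFrame(
            {
                "x": rng.normal(size=30),
                "y": rng.normal(size=30),
                "z": rng.integers(0, 2, 30).astype(float),
            }
        )
        df["y"] += 0.8 * df["x"] + df["z"]
        expected = pingouin.partial_corr(
            df, x="x", y="y", covar="z", method="spearman"
        )
        res = partial_spearman(df["x"], df["y"], df["z"])
        assert res.estimate == pytest.approx(expected["r"].iloc[0], abs=1e-9)

    def test_invariance_under_monotone_transform(self, rng):
        x = rng.uniform(1, 2, 50)
        y = x**2 + rng.normal(0, 0.1, 50)
        z = rng.normal(size=50)
        a = partial_spearman(x, y, z).estimate
        b = partial_spearman(np.log(x), y, z).estimate  # strictly monotone map
        assert a == pytest.approx(b, abs=1e-12)


class TestShapiroWilk:
    def test_normal_data_rarely_rejected(self):
        hits = sum(
            shapiro_wilk(np.random.default_rng(s).normal(size=500)).p_value > 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_exponential_data_rejected(self):
        hits = sum(
            shapiro_wilk(
                np.random.default_rng(s).exponential(size=500)
            ).p_value < 0.05
            for s in range(100)
        )
        assert hits >= 95

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk(np.ones(10))

    def test_n_out_of_range(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([1.0, 2.0])


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2))


class TestTwoWayAnova:
    def test_pure_group_effect(self):
        """Additive group effect, balanced 2x2; the within-cell perturbation
        preserves every cell mean, so all interaction SS is exactly zero while
        the residual stays positive (guards the F -> infinity degeneracy)."""
        sex = np.repeat(["M", "F"], 8)
        grp = np.tile(["high", "low"], 8)
        y = (grp == "high").astype(float) * 5.0
        for s in ("M", "F"):
            for g in ("high", "low"):
                idx = np.flatnonzero((sex == s) & (grp == g))
                y[idx] += 1e-3 * np.array([1.0, -1.0, 1.0, -1.0])
        res = two_way_anova(y, sex, grp)
        assert res["group"].p_value < 1e-10
        assert res["sex:group"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_unbalanced_matches_nested_rss_oracle(self, rng):
        """Type II F via explicit nested least-squares model comparison."""
        n = 21
        sex = rng.choice(["M", "F"], n, p=[0.6, 0.4])
        grp = rng.choice(["high", "low"], n, p=[0.3, 0.7])
        y = (
            1.0
            + 0.8 * (sex == "M")
            + 1.5 * (grp == "high")
            + 0.5 * ((sex == "M") & (grp == "high"))
            + rng.normal(0, 1.0, n)
        )
        s = (sex == "M").astype(float)
        g = (grp == "high").astype(float)
        one = np.ones(n)
        X_add = np.column_stack([one, s, g])
        X_full = np.column_stack([one, s, g, s * g])
        rss_add, rss_full = _rss(X_add, y), _rss(X_full, y)
        df_resid = n - 4
        from scipy.stats import f as fdist

        oracle = {
            "sex": _rss(np.column_stack([one, g]), y) - rss_add,
            "group": _rss(np.column_stack([one, s]), y) - rss_add,
            "sex:group": rss_add - rss_full,
        }
        res = two_way_anova(y, sex, grp)
        for term, ss in oracle.items():
            F = (ss / 1) / (rss_full / df_resid)
            assert res[term].statistic == pytest.approx(F, rel=1e-8), term
            assert res[term].p_value == pytest.approx(
                float(fdist.sf(F, 1, df_resid)), rel=1e-8
            )

    def test_empty_cell_drops_interaction(self, rng):
        sex = np.array(["M"] * 6 + ["F"] * 6)
        grp = np.array(["high"] * 6 + ["low"] * 6)  # M-low and F-high empty
        y = rng.normal(size=12)
        res = two_way_anova(y, sex, grp)
        assert "sex:group" not in res
        assert "interaction_dropped" in res["sex"].flags

    def test_null_pvalues_uniform(self):
        """Under a true null, each effect's p-value is U(0,1): KS check."""
        from scipy.stats import kstest

        rng = np.random.default_rng(7)
        sex = np.repeat(["M", "F"], [12, 10])
        grp = np.array((["high"] * 7 + ["low"] * 5) + (["high"] * 4 + ["low"] * 6))
        ps = {"sex": [], "group": [], "sex:group": []}
        for _ in range(300):
            y = rng.normal(size=22)
            res = two_way_anova(y, sex, grp)
            for k in ps:
                ps[k].append(res[k].p_value)
        for k, vals in ps.items():
            assert kstest(vals, "uniform").pvalue > 0.01, k


class TestCohortBattery:
    def test_report_structure_and_detections(self):
        df = generate_cohort(seed=42)
        report = run_cohort_stats(df)
        assert report["n_male"] == 11 and report["n_female"] == 11
        assert report["sex_differences"]["ssc_v_intra"]["p_value"] < 0.05
        key = "ssc_v_intra~internal_rotation_max_kg"
        assert report["strength_correlations"][key]["pearson"]["estimate"] > 0
        iso_key = "ssc_v_iso~internal_rotation_max_kg"
        assert report["strength_correlations"][iso_key]["pearson"]["estimate"] < 0
        import json

        json.dumps(report)  # report must be JSON-serializable
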