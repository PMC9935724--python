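"""Cohort statistics: the study's full testing battery.

Sex differences use the pooled-variance Student's t (Welch behind a flag),
accepting either raw vectors or printed summary statistics so published
tables can be re-tested directly. Associations use Pearson's r and partial
Spearman's rho controlling for sex (rank-transform everything, residualize
the x- and y-ranks on the covariate ranks, correlate the residuals).
Normality is screened with Shapiro-Wilk. Group-by-imbalance analyses use an
unbalanced factorial two-way ANOVA with Type II sums of squares. p-values
are never adjusted for multiple testing, matching the exploratory design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class StatResult:
    name: str
    statistic: float
    df: object
    p_value: float
    estimate: float | None = None
    groups: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": None if self.statistic is None else float(self.statistic),
            "df": self.df,
            "p_value": float(self.p_value),
            "estimate": None if self.estimate is None else float(self.estimate),
            "groups": self.groups,
            "flags": list(self.flags),
        }


def two_sample_t(
    group_a=None,
    group_b=None,
    summary_a=None,
    summary_b=None,
    equal_var: bool = True,
    name: str = "t-test",
) -> StatResult:
    """Two-sided two-sample t-test from raw vectors or (n, mean, sd) summaries.

    Pooled-variance Student's t by default; ``equal_var=False`` gives Welch.
    Raw vectors and their exact summaries produce identical results.
    """
    if summary_a is not None or summary_b is not None:
        if group_a is not None or group_b is not None:
            raise ValidationError("pass either raw groups or summaries, not both")
        (n1, m1, s1), (n2, m2, s2) = summary_a, summary_b
    else:
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValidationError("non-finite values in t-test input")
        n1, m1, s1 = len(a), a.mean(), a.std(ddof=1) if len(a) > 1 else 0.0
        n2, m2, s2 = len(b), b.mean(), b.std(ddof=1) if len(b) > 1 else 0.0
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 per group")
    if s1 == 0 and s2 == 0:
        # degenerate: both groups constant
        if m1 == m2:
            t, p, df = 0.0, 1.0, n1 + n2 - 2
        else:
            t, p, df = np.inf if m1 > m2 else -np.inf, 0.0, n1 + n2 - 2
    else:
        t, p = sps.ttest_ind_from_stats(
            m1, s1, n1, m2, s2, n2, equal_var=equal_var
        )
        if equal_var:
            df = n1 + n2 - 2
        else:
            v1, v2 = s1**2 / n1, s2**2 / n2
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return StatResult(
        name=name,
        statistic=float(t),
        df=df,
        p_value=float(p),
        estimate=float(m1 - m2),
        groups=[
            {"n": int(n1), "mean": float(m1), "sd": float(s1)},
            {"n": int(n2), "mean": float(m2), "sd": float(s2)},
        ],
    )


def pearson_r(x, y, name: str = "pearson") -> StatResult:
    """Sample Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return StatResult(
        name=name,
        statistic=float(res.statistic),
        df=len(x) - 2,
        p_value=float(res.pvalue),
        estimate=float(res.statistic),
    )


def _rank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def partial_spearman(x, y, covariate, name: str = "partial-spearman") -> StatResult:
    """Spearman correlation of x and y partialling out one covariate.

    Ranks (average ranks for ties) of x, y, and the covariate are computed;
    x- and y-ranks are residualized on the covariate ranks by least squares
    (with intercept) and the residuals correlated. p uses the t
    approximation with n - 3 degrees of freedom. A constant covariate cannot
    be partialled out; the result then equals plain Spearman's rho and is
    flagged ``"constant_covariate"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = len(x)
    if not (len(y) == n == len(z)) or n < 4:
        raise ValidationError("need equal-length vectors with n >= 4")
    rx, ry, rz = _rank(x), _rank(y), _rank(z)
    flags = []
    if np.std(rz) == 0:
        rho = float(sps.spearmanr(x, y).statistic)
        flags.append("constant_covariate")
        df = n - 2
    else:
        design = np.column_stack([np.ones(n), rz])
        ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
        denom = np.sqrt((ex**2).sum() * (ey**2).sum())
        if denom == 0:
            raise ValidationError("zero residual variance after partialling")
        rho = float((ex * ey).sum() / denom)
        df = n - 3
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
        tstat = np.inf * np.sign(rho_c)
    else:
        tstat = rho_c * np.sqrt(df / (1.0 - rho_c**2))
        p = float(2.0 * sps.t.sf(abs(tstat), df))
    return StatResult(
        name=name, statistic=float(tstat), df=df, p_value=p, estimate=rho, flags=flags
    )


def shapiro_wilk(x, name: str = "shapiro-wilk") -> StatResult:
    """Shapiro-Wilk normality test (diagnostic, not a gate)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("constant vector: Shapiro-Wilk undefined")
    res = sps.shapiro(x)
    return StatResult(
        name=name,
        statistic=float(res.statistic),
        df=len(x),
        p_value=float(res.pvalue),
        estimate=float(res.statistic),
    )


def two_way_anova(outcome, factor_sex, factor_group, typ: int = 2) -> dict:
    """Unbalanced factorial two-way ANOVA on a continuous outcome.

    Fits ``outcome ~ sex * group`` by ordinary least squares and returns
    Type ``typ`` (default II) F-tests for the two main effects and their
    interaction, as ``{"sex": StatResult, "group": ..., "sex:group": ...}``.
    If an empty design cell makes the interaction inestimable, the additive
    model is fitted instead and the results carry an
    ``"interaction_dropped"`` flag.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    y = np.asarray(outcome, dtype=float)
    sex = np.asarray(factor_sex)
    grp = np.asarray(factor_group)
    if not (len(y) == len(sex) == len(grp)):
        raise ValidationError("outcome and factors must have equal length")
    if len(np.unique(sex)) != 2 or len(np.unique(grp)) != 2:
        raise ValidationError("both factors must be binary")
    df = pd.DataFrame({"y": y, "sex": sex.astype(str), "grp": grp.astype(str)})
    cells = df.groupby(["sex", "grp"], observed=True).size()
    flags = []
    formula = "y ~ C(sex) * C(grp)"
    if len(cells) < 4:
        formula = "y ~ C(sex) + C(grp)"
        flags.append("interaction_dropped")
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=typ)

    def pick(term: str) -> StatResult | None:
        if term not in table.index:
            return None
        row = table.loc[term]
        return StatResult(
            name=term,
            statistic=float(row["F"]),
            df=(int(row["df"]), int(table.loc["Residual", "df"])),
            p_value=float(row["PR(>F)"]),
            estimate=float(row["F"]),
            flags=list(flags),
        )

    out = {
        "sex": pick("C(sex)"),
        "group": pick("C(grp)"),
        "sex:group": pick("C(sex):C(grp)"),
    }
    return {k: v for k, v in out.items() if v is not None}


# ---------------------------------------------------------------------------
# cohort-level battery

SEX_TTEST_VARS = (
    "age", "weight_kg", "height_m", "bmi",
    "ssc_v_intra", "ssc_v_extra", "ssc_v_iso", "ssc_ff",
    "isp_v_intra", "isp_v_extra", "isp_v_iso", "isp_ff",
    "ssp_v_intra", "ssp_v_extra", "ssp_v_iso", "ssp_ff",
    "internal_rotation_mean_kg", "internal_rotation_max_kg",
    "external_rotation_mean_kg", "external_rotation_max_kg",
    "jobe_mean_kg", "jobe_max_kg", "starter_mean_kg", "starter_max_kg",
    "er_ir_ratio_mean", "er_ir_ratio_max",
)

#: strength test whose (mean, max) values are correlated with each muscle's
#: DMI metrics
MUSCLE_TEST = {"ssc": "internal_rotation", "isp": "external_rotation", "ssp": "jobe"}


def run_cohort_stats(cohort: pd.DataFrame) -> dict:
    """The full statistical battery on a cohort table.

    Returns a JSON-serializable report with sex-difference t-tests,
    muscle-specific strength correlations (Pearson, plus partial Spearman
    controlling for sex), Shapiro-Wilk diagnostics, and the two-way
    sex-by-ER/IR-group ANOVAs on the ISP/SSC metric ratios.
    """
    males = cohort[cohort["sex"] == "M"]
    females = cohort[cohort["sex"] == "F"]
    report: dict = {"n_male": len(males), "n_female": len(females)}

    report["sex_differences"] = {
        var: two_sample_t(
            males[var].to_numpy(), females[var].to_numpy(), name=f"sex:{var}"
        ).to_dict()
        for var in SEX_TTEST_VARS
        if var in cohort.columns
    }

    sex_code = (cohort["sex"] == "M").astype(float).to_numpy()
    correlations = {}
    for muscle, test in MUSCLE_TEST.items():
        for metric in ("v_intra", "v_extra", "v_iso", "ff"):
            xcol = f"{muscle}_{metric}"
            for kind in ("mean", "max"):
                ycol = f"{test}_{kind}_kg"
                if xcol not in cohort.columns or ycol not in cohort.columns:
                    continue
                x = cohort[xcol].to_numpy()
                y = cohort[ycol].to_numpy()
                key = f"{xcol}~{ycol}"
                correlations[key] = {
                    "pearson": pearson_r(x, y, name=key).to_dict(),
                    "partial_spearman_sex": partial_spearman(
                        x, y, sex_code, name=key
                    ).to_dict(),
                }
    report["strength_correlations"] = correlations

    report["normality"] = {
        var: shapiro_wilk(cohort[var].to_numpy(), name=f"sw:{var}").to_dict()
        for var in ("ssc_v_intra", "ssc_v_iso", "internal_rotation_mean_kg")
        if var in cohort.columns and np.ptp(cohort[var].to_numpy()) > 0
    }

    if "er_ir_group" in cohort.columns and cohort["er_ir_group"].nunique() == 2:
        anovas = {}
        for metric in ("v_intra", "v_extra", "v_iso", "ff"):
            col = f"isp_ssc_{metric}"
            if col not in cohort.columns:
                continue
            res = two_way_anova(
                cohort[col].to_numpy(),
                cohort["sex"].to_numpy(),
                cohort["er_ir_group"].to_numpy(),
            )
            anovas[col] = {k: v.to_dict() for k, v in res.items()}
        report["er_ir_anova"] = anovas
    else:
        report["er_ir_anova"] = {}
    return report


__all__ = [
    "StatResult",
    "two_sample_t",
    "pearson_r",
    "partial_spearman",
    "shapiro_wilk",
    "two_way_anova",
    "run_cohort_stats",
    "SEX_TTEST_VARS",
    "MUSCLE_TEST",
]
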