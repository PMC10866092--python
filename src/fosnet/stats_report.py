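"""Statistical battery: factorial ANOVA, nonparametric paired tests, and
the small-world-change vs transition-energy regression.

Percent-change FOS values are analyzed per region by three-way ANOVA
(genotype x treatment x sex, type-III sums of squares for unbalanced
designs) with Tukey or Sidak post hocs.  Paired per-region metric
profiles across conditions are compared with a Friedman test plus Dunn's
(Bonferroni-adjusted) pairwise comparisons, or a Wilcoxon matched-pairs
signed-rank test.  The link between network topology and dynamics is
summarized by an OLS regression of z-scored transition energy on the
z-scored change in small-world sigma.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class AnovaTable:
    """Effect-level F tests plus pairwise post hoc comparisons."""

    effects: pd.DataFrame
    posthoc: pd.DataFrame | None = None
    method: str = ""
    flags: list = field(default_factory=list)


def factorial_anova(
    data: pd.DataFrame,
    dv: str = "value",
    factors=("genotype", "treatment", "sex"),
    posthoc: str = "tukey",
) -> AnovaTable:
    """Up-to-three-way crossed ANOVA with type-III sums of squares.

    ``data`` is tidy (one observation per row); ``factors`` are the
    between-subject columns.  Post hoc compares every pair of factor-
    combination cells, Tukey HSD or Sidak-adjusted pairwise t tests.
    """
    factors = [f for f in factors if f in data.columns]
    if not factors:
        raise ValueError("no factor columns present")
    work = data.dropna(subset=[dv] + factors).copy()
    flags = []
    for f in factors:
        if work[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    cells = work.groupby(factors, sort=False)[dv].count()
    if (cells < 2).any():
        flags.append(f"cells with < 2 observations: {list(cells[cells < 2].index)}")

    formula = f"{dv} ~ " + " * ".join(f"C({f}, Sum)" for f in factors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ols(formula, data=work).fit()
        aov = anova_lm(model, typ=3)
    df_resid = float(model.df_resid)
    rows = []
    for name, row in aov.iterrows():
        if name in ("Intercept", "Residual"):
            continue
        clean = name.replace("C(", "").replace(", Sum)", "").replace(":", " x ")
        F, p = row["F"], row["PR(>F)"]
        if row["sum_sq"] <= 1e-12 * max(1.0, abs(float(aov["sum_sq"].sum()))):
            # degenerate effect (e.g. all observations identical): report a
            # null effect rather than the 0/0 indeterminate
            F, p = 0.0, 1.0
        rows.append(
            {
                "effect": clean,
                "F": F,
                "df1": int(row["df"]),
                "df2": int(df_resid),
                "p": p,
            }
        )
    effects = pd.DataFrame(rows)

    groups = work[factors].astype(str).agg("/".join, axis=1)
    ph = _posthoc_table(work[dv].to_numpy(dtype=float), groups.to_numpy(), posthoc)
    return AnovaTable(effects=effects, posthoc=ph, method=posthoc, flags=flags)


def _posthoc_table(values: np.ndarray, groups: np.ndarray, method: str) -> pd.DataFrame:
    levels = pd.unique(groups)
    if len(levels) < 2 or method == "none":
        return pd.DataFrame(columns=["group1", "group2", "estimate", "p_adj", "ci_low", "ci_high"])
    if method == "tukey":
        res = pairwise_tukeyhsd(values, groups)
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        return frame.rename(
            columns={"meandiff": "estimate", "p-adj": "p_adj", "lower": "ci_low", "upper": "ci_high"}
        )[["group1", "group2", "estimate", "p_adj", "ci_low", "ci_high"]]
    if method == "sidak":
        pairs = list(itertools.combinations(levels, 2))
        m = len(pairs)
        rows = []
        for g1, g2 in pairs:
            a, b = values[groups == g1], values[groups == g2]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            p_adj = 1.0 - (1.0 - min(p, 1.0)) ** m
            df = len(a) + len(b) - 2
            se = (b.mean() - a.mean()) / t if t != 0 else np.nan
            crit = stats.t.ppf(1 - 0.05 / (2 * m), df)
            diff = b.mean() - a.mean()
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "estimate": diff,
                    "p_adj": min(p_adj, 1.0),
                    "ci_low": diff - crit * abs(se) if np.isfinite(se) else np.nan,
                    "ci_high": diff + crit * abs(se) if np.isfinite(se) else np.nan,
                }
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown posthoc method {method!r}")


def nonparametric_battery(matrix: pd.DataFrame, test: str = "friedman_dunn") -> AnovaTable:
    """Paired nonparametric comparisons across conditions.

    ``matrix`` is subjects (e.g. regions) x conditions.  ``friedman_dunn``
    runs the Friedman rank test (k >= 3 conditions) with Dunn's pairwise
    z comparisons, Bonferroni-adjusted; ``wilcoxon`` requires exactly two
    columns and runs the matched-pairs signed-rank test (exact null for
    small n without ties).
    """
    X = matrix.dropna()
    n, k = X.shape
    flags = []
    if test == "friedman_dunn":
        if k < 3:
            raise ValueError("Friedman test needs >= 3 paired conditions")
        ranks = X.rank(axis=1)
        mean_ranks = ranks.mean(axis=0)
        if np.allclose(X.to_numpy().std(axis=1), 0):
            flags.append("all-tied data; statistic 0")
            Q, p = 0.0, 1.0
        else:
            Q, p = stats.friedmanchisquare(*[X[c] for c in X.columns])
        effects = pd.DataFrame([{"effect": "condition", "F": Q, "df1": k - 1, "df2": np.nan, "p": p}])
        se = np.sqrt(k * (k + 1) / (6.0 * n))
        pairs = list(itertools.combinations(X.columns, 2))
        m = len(pairs)
        rows = []
        for c1, c2 in pairs:
            z = (mean_ranks[c1] - mean_ranks[c2]) / se
            p_adj = min(2.0 * stats.norm.sf(abs(z)) * m, 1.0)
            rows.append(
                {"group1": c1, "group2": c2, "estimate": z, "p_adj": p_adj, "ci_low": np.nan, "ci_high": np.nan}
            )
        return AnovaTable(effects=effects, posthoc=pd.DataFrame(rows), method="friedman_dunn", flags=flags)
    if test == "wilcoxon":
        if k != 2:
            raise ValueError("Wilcoxon matched pairs needs exactly 2 conditions")
        if n < 5:
            flags.append("fewer than 5 pairs; test underpowered")
        d = X.iloc[:, 0] - X.iloc[:, 1]
        if np.allclose(d, 0):
            flags.append("all paired differences zero")
            W, p = 0.0, 1.0
        else:
            W, p = stats.wilcoxon(X.iloc[:, 0], X.iloc[:, 1], mode="auto")
        effects = pd.DataFrame([{"effect": "condition", "F": W, "df1": np.nan, "df2": np.nan, "p": p}])
        return AnovaTable(effects=effects, posthoc=None, method="wilcoxon", flags=flags)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class RegressionResult:
    """OLS fit of z-scored energy on z-scored change in sigma."""

    slope: float
    intercept: float
    r2: float
    F: float
    p: float
    ci_low: float
    ci_high: float
    n: int


def sigma_energy_correlation(delta_sigma, energy) -> RegressionResult:
    """Regress z-scored transition energy on the z-scored change in sigma.

    Both inputs are standardized over the pooled sample before an
    ordinary least-squares fit; returns the slope with its 95% CI, R^2,
    and the overall F test.
    """
    x = np.asarray(delta_sigma, dtype=float)
    y = np.asarray(energy, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance in an input")
    xz = (x - x.mean()) / x.std(ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    df = pd.DataFrame({"x": xz, "y": yz})
    model = ols("y ~ x", data=df).fit()
    ci = model.conf_int().loc["x"]
    return RegressionResult(
        slope=float(model.params["x"]),
        intercept=float(model.params["Intercept"]),
        r2=float(model.rsquared),
        F=float(model.fvalue),
        p=float(model.f_pvalue),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        n=int(x.size),
    )
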