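"""Statistical comparisons over per-sample proportion tables.

The comparison layer mirrors standard practice for reporter-assay data:
Welch's unequal-variance t test for single two-group contrasts, the
Wilcoxon signed-rank test for paired HR-vs-NHEJ proportions, and factorial
ANOVA (two or three crossed factors) followed by Tukey's HSD with the
Tukey-Kramer adjustment for unbalanced groups.

Proportions are analyzed untransformed.  For the factorial reproduction
design the complementary HR/NHEJ percentages of each sample both enter as
rows with a ``pathway`` factor (see :func:`melt_pathway`); residual degrees
of freedom under that layout match the reported F statistics.

Balanced designs use the sequential sum-of-squares decomposition (all
types coincide there); unbalanced designs use marginal (Type-III-style)
sums of squares with sum-to-zero contrasts, and every result records which
was used.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

P_FLOOR = 1e-15


def format_p(p: float) -> str:
    """Render a p value, flooring vanishing values at < 1e-15."""
    return f"< {P_FLOOR:g}" if p < P_FLOOR else f"{p:.4g}"


@dataclass(frozen=True)
class FactorialDesign:
    """A response column, 1-3 categorical factors, and the long-format data."""

    response: str
    factors: tuple[str, ...]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not 1 <= len(self.factors) <= 3:
            raise ValueError("between 1 and 3 factors are supported")
        missing = {self.response, *self.factors} - set(self.data.columns)
        if missing:
            raise ValueError(f"design columns missing from data: {sorted(missing)}")
        y = self.data[self.response].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        for f in self.factors:
            if self.data[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than 2 levels")
        cells = self.data.groupby(list(self.factors), observed=True).size()
        full = np.prod([self.data[f].nunique() for f in self.factors])
        if len(cells) < full:
            raise ValueError("every factor-level cell needs >= 1 observation")

    @property
    def balanced(self) -> bool:
        counts = self.data.groupby(list(self.factors), observed=True).size()
        return counts.nunique() == 1


@dataclass(frozen=True)
class AnovaResult:
    """Tidy effect table plus the error variance used by post-hoc tests."""

    table: pd.DataFrame  # effect, sum_sq, df1, df2, F, p
    mse: float
    df_resid: float
    ss_type: str  # "sequential" or "marginal"
    interaction_testable: bool = True


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, two-sided p).

    Degenerate zero-variance inputs follow the conventions: equal means
    give t = 0, p = 1; unequal means give p = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    if vx == 0 and vy == 0:
        df = float(nx + ny - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        warnings.warn(
            "zero variance in both groups with unequal means; p degenerates "
            "to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.sign(x.mean() - y.mean()) * np.inf), df, 0.0
    se2 = vx / nx + vy / ny
    t = float((x.mean() - y.mean()) / np.sqrt(se2))
    df = float(se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)))
    p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return t, df, p


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W, two-sided p).

    Zero differences are dropped (Wilcoxon's convention); the p value is
    exact for n <= 25 retained pairs and uses the continuity-corrected
    normal approximation above.  All-zero differences give p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    d = x - y
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        warnings.warn(
            "all paired differences are zero; p = 1", RuntimeWarning, stacklevel=2
        )
        return 0.0, 1.0
    method = "exact" if n_nonzero <= 25 else "approx"
    res = scipy.stats.wilcoxon(
        x,
        y,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


def _clean_effect(term: str) -> str:
    """'C(sex, Sum):C(tissue, Sum)' -> 'sex:tissue'."""
    parts = []
    for piece in term.split(":"):
        piece = piece.strip()
        if piece.startswith("C("):
            piece = piece[2:].split(",")[0].rstrip(") ")
        parts.append(piece)
    return ":".join(parts)


def factorial_anova(design: FactorialDesign) -> AnovaResult:
    """Fit a fully crossed factorial ANOVA with all interactions.

    A saturated model (one observation per cell) leaves no residual
    degrees of freedom; the result is returned with
    ``interaction_testable=False`` and NaN F statistics rather than
    raising.
    """
    formula = f"{design.response} ~ " + "*".join(
        f"C({f}, Sum)" for f in design.factors
    )
    model = ols(formula, data=design.data).fit()
    balanced = design.balanced
    ss_type = "sequential" if balanced else "marginal"
    df_resid = float(model.df_resid)
    if df_resid <= 0:
        warnings.warn(
            "saturated design: interaction untestable (no residual df)",
            RuntimeWarning,
            stacklevel=2,
        )
        rows = [
            {"effect": _clean_effect(t), "sum_sq": np.nan, "df1": np.nan,
             "df2": 0.0, "F": np.nan, "p": np.nan}
            for t in model.model.exog_names
            if t != "Intercept"
        ]
        return AnovaResult(pd.DataFrame(rows), np.nan, 0.0, ss_type, False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        anova = sm.stats.anova_lm(model, typ=(1 if balanced else 3))
    anova = anova.drop(index=[i for i in ("Intercept",) if i in anova.index])
    resid = anova.loc["Residual"]
    rows = []
    for term, r in anova.drop(index="Residual").iterrows():
        rows.append(
            {
                "effect": _clean_effect(str(term)),
                "sum_sq": float(r["sum_sq"]),
                "df1": float(r["df"]),
                "df2": float(resid["df"]),
                "F": float(r["F"]),
                "p": float(r["PR(>F)"]),
            }
        )
    mse = float(resid["sum_sq"] / resid["df"])
    return AnovaResult(pd.DataFrame(rows), mse, float(resid["df"]), ss_type)


def tukey_hsd(
    design: FactorialDesign,
    effect: str | list[str] | None = None,
    anova: AnovaResult | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD over the levels of a factor (or the full cell means).

    Uses the factorial model's error mean square and residual df; unequal
    group sizes use the Tukey-Kramer standard error.  ``effect=None``
    compares all factor-combination cells.  Returns one row per pair with
    the mean difference, studentized-range statistic q, adjusted p, and
    the simultaneous confidence interval.
    """
    if anova is None:
        anova = factorial_anova(design)
    if not np.isfinite(anova.mse):
        raise ValueError("no residual variance available for Tukey HSD")
    if effect is None:
        group_cols = list(design.factors)
    elif isinstance(effect, str):
        group_cols = [effect]
    else:
        group_cols = list(effect)
    grouped = design.data.groupby(group_cols, observed=True)[design.response]
    stats = grouped.agg(["mean", "count"]).sort_index()
    labels = [
        k if isinstance(k, str) else ":".join(map(str, k if isinstance(k, tuple) else (k,)))
        for k in stats.index
    ]
    k_groups = len(labels)
    if k_groups < 2:
        return pd.DataFrame(
            columns=["group1", "group2", "diff", "se", "q", "p_adj",
                     "ci_lower", "ci_upper", "reject"]
        )
    q_crit = float(
        scipy.stats.studentized_range.ppf(1 - alpha, k_groups, anova.df_resid)
    )
    rows = []
    means = stats["mean"].to_numpy(dtype=float)
    counts = stats["count"].to_numpy(dtype=float)
    for i, j in itertools.combinations(range(k_groups), 2):
        diff = means[j] - means[i]
        se = float(np.sqrt(anova.mse / 2.0 * (1.0 / counts[i] + 1.0 / counts[j])))
        q = abs(diff) / se if se > 0 else np.inf
        p_adj = float(
            scipy.stats.studentized_range.sf(q, k_groups, anova.df_resid)
        )
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "diff": float(diff),
                "se": se,
                "q": float(q),
                "p_adj": min(1.0, p_adj),
                "ci_lower": float(diff - q_crit * se),
                "ci_upper": float(diff + q_crit * se),
                "reject": bool(p_adj < alpha),
            }
        )
    return pd.DataFrame(rows)


def melt_pathway(
    calls: pd.DataFrame,
    id_vars: list[str] | None = None,
    stats: tuple[str, ...] = ("rel_HR", "rel_NHEJ"),
) -> pd.DataFrame:
    """Stack per-sample HR/NHEJ percentages into pathway rows.

    Produces the complementary-rows layout used for the factorial
    reproduction analyses: one row per sample per pathway with columns
    ``pathway`` (HR / NHEJ) and ``value``.  Samples with undefined
    relative proportions are dropped.
    """
    id_vars = id_vars or [
        c for c in ("sample_id", "sex", "tissue", "condition") if c in calls.columns
    ]
    usable = calls[calls[list(stats)].notna().all(axis=1)]
    long = usable.melt(
        id_vars=id_vars, value_vars=list(stats),
        var_name="pathway", value_name="value",
    )
    long["pathway"] = long["pathway"].str.replace("rel_", "", regex=False)
    return long
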