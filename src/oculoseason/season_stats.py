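"""Descriptive season statistics and regression diagnostics.

Per-session change tests (one-sample t-tests of baseline-normalized deltas
against zero), Cohen's d effect sizes between cohorts, the Pearson/Spearman
correlation panel of ONSD change against each ImPACT composite change,
linear-vs-quadratic model comparison by adjusted R^2 and Cook's distance
outlier screening (observations with D > 1 are flagged as unduly
influential).  No multiple-testing correction is applied; reports carry the
number of tests performed instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

COHEN_LABELS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))


def session_change_tests(delta_table: pd.DataFrame, outcome_cols=None,
                         subject_col: str = "subject_id",
                         session_col: str = "session") -> pd.DataFrame:
    """One-sample two-sided t-test of each session's deltas against zero.

    Baseline rows (``is_baseline`` True, deltas identically zero) are
    skipped.  Sessions with fewer than two values come back with NaN.
    """
    if outcome_cols is None:
        outcome_cols = [c for c in delta_table.columns
                        if c not in (subject_col, session_col, "is_baseline")
                        and pd.api.types.is_numeric_dtype(delta_table[c])]
    df = delta_table
    if "is_baseline" in df.columns:
        df = df[~df["is_baseline"].astype(bool)]
    rows = []
    for session, grp in df.groupby(session_col):
        for col in outcome_cols:
            v = grp[col].dropna().to_numpy(dtype=float)
            if v.size < 2:
                rows.append(dict(session=session, outcome=col, n=int(v.size),
                                 t=np.nan, p=np.nan))
                continue
            if np.std(v, ddof=1) == 0:
                # degenerate sample: all deltas identical
                t = 0.0 if np.mean(v) == 0 else float(np.sign(np.mean(v)) * np.inf)
                p = 1.0 if np.mean(v) == 0 else 0.0
            else:
                t, p = stats.ttest_1samp(v, 0.0)
            rows.append(dict(session=session, outcome=col, n=int(v.size),
                             t=float(t), p=float(p)))
    return pd.DataFrame(rows)


def cohens_d_label(d: float) -> str:
    a = abs(d)
    for cut, label in COHEN_LABELS:
        if a < cut:
            return label
    return "large"


def cohort_effect_sizes(group_a, group_b) -> tuple[float, str]:
    """Cohen's d between two cohorts with its magnitude label.

    Pooled standard deviation uses (n-1) weights.  Positive d means group A
    has the larger mean.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    pooled = np.sqrt(((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1))
                     / (a.size + b.size - 2))
    if pooled == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, "negligible"
        raise ValueError("zero pooled standard deviation")
    d = float((np.mean(a) - np.mean(b)) / pooled)
    return d, cohens_d_label(d)


def correlation_panel(delta_onsd, delta_composites: pd.DataFrame) -> pd.DataFrame:
    """Pearson and Spearman (r, p) of ONSD change vs each composite change.

    Rows with a missing value in either variable are dropped pairwise.
    Baseline (0, 0) rows must be excluded by the caller before this point.
    """
    x_all = np.asarray(delta_onsd, dtype=float)
    rows = []
    for col in delta_composites.columns:
        y_all = delta_composites[col].to_numpy(dtype=float)
        ok = np.isfinite(x_all) & np.isfinite(y_all)
        x, y = x_all[ok], y_all[ok]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"constant or too-short vector for composite {col!r}")
        pr, pp = stats.pearsonr(x, y)
        sr, sp = stats.spearmanr(x, y)
        rows.append(dict(composite=col, pearson_r=float(pr), pearson_p=float(pp),
                         spearman_r=float(sr), spearman_p=float(sp), n=int(x.size)))
    return pd.DataFrame(rows)


@dataclass
class FitComparison:
    """Linear vs quadratic least-squares fits of y on x."""

    linear_params: np.ndarray
    quadratic_params: np.ndarray
    linear_adj_r2: float
    quadratic_adj_r2: float
    linear_p: float  # F-test p-value of the regression
    quadratic_p: float
    better_model: str  # by adjusted R^2
    linear_cooks_d: np.ndarray
    quadratic_cooks_d: np.ndarray
    linear_flags: np.ndarray  # Cook's D > 1
    quadratic_flags: np.ndarray


def fit_diagnostics(x, y) -> FitComparison:
    """Compare linear and quadratic fits of ``y`` on ``x`` with Cook's D.

    Adjusted R^2 decides the better model; Cook's distances above 1 flag
    observations that unduly drive either fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant (collinear design)")
    X1 = sm.add_constant(x)
    X2 = sm.add_constant(np.column_stack([x, x**2]))
    if np.linalg.matrix_rank(X2) < X2.shape[1]:
        raise ValueError("collinear quadratic design")
    fit1 = sm.OLS(y, X1).fit()
    fit2 = sm.OLS(y, X2).fit()

    def _cooks(fit):
        # an (all but numerically) exact fit moves nothing when a point leaves
        if fit.mse_resid <= 1e-12 * max(np.var(y), 1e-30):
            return np.zeros(y.size)
        return fit.get_influence().cooks_distance[0]

    d1 = _cooks(fit1)
    d2 = _cooks(fit2)
    better = "quadratic" if fit2.rsquared_adj > fit1.rsquared_adj else "linear"
    return FitComparison(
        linear_params=np.asarray(fit1.params), quadratic_params=np.asarray(fit2.params),
        linear_adj_r2=float(fit1.rsquared_adj), quadratic_adj_r2=float(fit2.rsquared_adj),
        linear_p=float(fit1.f_pvalue), quadratic_p=float(fit2.f_pvalue),
        better_model=better, linear_cooks_d=d1, quadratic_cooks_d=d2,
        linear_flags=d1 > 1.0, quadratic_flags=d2 > 1.0,
    )


def diagnostics_report(delta_table: pd.DataFrame, onsd_col: str = "onsd_mm",
                       composite_cols=None) -> dict:
    """Bundle the season diagnostics into one JSON-serializable report."""
    from .outcomes import COMPOSITES

    if composite_cols is None:
        composite_cols = [c for c in COMPOSITES if c in delta_table.columns]
    tests = session_change_tests(delta_table)
    nonbase = delta_table
    if "is_baseline" in delta_table.columns:
        nonbase = delta_table[~delta_table["is_baseline"].astype(bool)]
    panel = correlation_panel(nonbase[onsd_col], nonbase[composite_cols])
    n_tests = len(tests) + 2 * len(panel)
    return {
        "session_tests": tests.to_dict(orient="records"),
        "correlation_panel": panel.to_dict(orient="records"),
        "n_statistical_tests": int(n_tests),
        "note": "no multiple-testing correction applied",
    }
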