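"""Cohort statistics relating eye shape and size to refractive error.

Covers the refraction-side derivations (spherical equivalent, refraction
grouping, cycloplegia / scan-quality exclusions), the hypothesis tests
(Pearson correlation, one-way ANOVA, Pearson chi-square), restricted-cubic-
spline regression, Bland-Altman method comparison, and the report tables:
cohort descriptives, an MRI-vs-biometry correlation matrix, and group means
with between-group differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import EMMETROPIA, HYPEROPIA, MYOPIA

GROUP_ORDER = [HYPEROPIA, EMMETROPIA, MYOPIA]


# ---------------------------------------------------------------------------
# refraction derivations


def spherical_equivalent(sphere: float, cylinder: float) -> float:
    """SE (diopters) = sphere + cylinder / 2."""
    return sphere + cylinder / 2.0


def refraction_group(
    se: float, myopia_cutoff: float = -0.5, hyperopia_cutoff: float = 2.0
) -> str:
    """Myopia at SE <= -0.5 D, hyperopia at SE >= +2.0 D, else emmetropia.

    Both boundary values belong to the outer groups, matching the printed
    inequalities (myopia <= -0.5, hyperopia >= +2.0).
    """
    if not np.isfinite(se):
        raise ValueError(f"SE must be finite, got {se}")
    if se <= myopia_cutoff:
        return MYOPIA
    if se >= hyperopia_cutoff:
        return HYPEROPIA
    return EMMETROPIA


def apply_exclusions(
    cohort: pd.DataFrame,
    pupil_col: str = "pupil_diameter",
    quality_col: str = "scan_quality_pass",
    min_pupil_mm: float = 6.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Apply the scan-quality and cycloplegia exclusion rules.

    Returns ``(mri_cohort, se_cohort, log)``: subjects failing visual scan
    quality are dropped from all analyses; subjects with inadequate
    cycloplegia (pupil < 6.0 mm) are additionally dropped from SE-based
    analyses.  The log counts exclusions per reason.
    """
    n0 = len(cohort)
    if quality_col in cohort.columns:
        mri = cohort[cohort[quality_col].astype(bool)].copy()
    else:
        mri = cohort.copy()
    n_quality = n0 - len(mri)
    if pupil_col in mri.columns:
        se_cohort = mri[mri[pupil_col] >= min_pupil_mm].copy()
    else:
        se_cohort = mri.copy()
    n_cyclo = len(mri) - len(se_cohort)
    log = {
        "n_input": n0,
        "excluded_low_quality_scan": n_quality,
        "excluded_inadequate_cycloplegia": n_cyclo,
        "n_mri_analyses": len(mri),
        "n_se_analyses": len(se_cohort),
    }
    return mri, se_cohort, log


# ---------------------------------------------------------------------------
# tests


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D arrays")
    if len(x) < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Standard one-way ANOVA F and p across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each ANOVA group needs n >= 2")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("contingency table has an empty row or column")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def group_compare(
    cohort: pd.DataFrame, variable: str, group_col: str = "group"
) -> dict[str, float | str]:
    """ANOVA on a continuous variable or chi-square on a categorical one,
    across refraction groups."""
    present = [g for g in GROUP_ORDER if g in set(cohort[group_col])]
    if len(present) < 2:
        raise ValueError("need at least two non-empty refraction groups")
    col = cohort[variable]
    if pd.api.types.is_numeric_dtype(col):
        groups = [
            cohort.loc[cohort[group_col] == g, variable].dropna().to_numpy()
            for g in present
        ]
        if any(len(g) == 0 for g in groups):
            raise ValueError("empty group in ANOVA")
        f, p = anova_oneway(groups)
        return {"test": "anova", "statistic": f, "p": p}
    table = pd.crosstab(cohort[group_col], col).to_numpy()
    chi2, p = chi_square(table)
    return {"test": "chi_square", "statistic": chi2, "p": p}


# ---------------------------------------------------------------------------
# restricted cubic splines


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted-cubic-spline design columns (without intercept).

    Truncated-power natural spline: linear term plus k-2 curvature terms,
    each constrained so the function is linear beyond the boundary knots.
    Terms are scaled by the squared knot span for numerical balance.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("restricted cubic splines need >= 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"knots must be strictly increasing, got {t}")
    span2 = (t[-1] - t[0]) ** 2

    def pos3(v: np.ndarray) -> np.ndarray:
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / span2)
    return np.column_stack(cols)


@dataclass
class RcsFit:
    """OLS fit on a restricted-cubic-spline basis."""

    knots: np.ndarray
    result: sm.regression.linear_model.RegressionResultsWrapper

    def predict(self, x_new: np.ndarray) -> pd.DataFrame:
        """Predictions with pointwise 95% CIs on ``x_new``."""
        X = sm.add_constant(rcs_basis(np.asarray(x_new, float), self.knots),
                            has_constant="add")
        pred = self.result.get_prediction(X)
        frame = pred.summary_frame(alpha=0.05)
        return pd.DataFrame(
            {
                "x": np.asarray(x_new, float),
                "fit": frame["mean"].to_numpy(),
                "ci_low": frame["mean_ci_lower"].to_numpy(),
                "ci_high": frame["mean_ci_upper"].to_numpy(),
            }
        )


def rcs_regression(
    x: np.ndarray,
    y: np.ndarray,
    n_knots: int = 3,
    knot_percentiles: tuple[float, ...] | None = None,
) -> RcsFit:
    """OLS on a restricted-cubic-spline basis with knots at percentiles of x.

    With three knots (the default) the knots sit at the 10th, 50th and 90th
    percentiles.  The fitted curve is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= 10:
        raise ValueError("rcs_regression needs n > 10")
    if knot_percentiles is None:
        if n_knots == 3:
            knot_percentiles = (10.0, 50.0, 90.0)
        else:
            knot_percentiles = tuple(np.linspace(5, 95, n_knots))
    knots = np.percentile(x, knot_percentiles)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate x: duplicate knot locations")
    X = sm.add_constant(rcs_basis(x, knots), has_constant="add")
    result = sm.OLS(y, X).fit()
    return RcsFit(knots=knots, result=result)


# ---------------------------------------------------------------------------
# Bland-Altman


def bland_altman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean ± 1.96 SD) of x − y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("Bland-Altman needs paired arrays with n >= 3")
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def bland_altman_frame(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-pair means and differences for plotting, plus the agreement lines."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mean, lo, hi = bland_altman(x, y)
    out = pd.DataFrame({"mean": (x + y) / 2.0, "diff": x - y})
    out.attrs["mean_diff"] = mean
    out.attrs["loa_low"] = lo
    out.attrs["loa_high"] = hi
    return out


# ---------------------------------------------------------------------------
# report tables


def descriptives_table(
    cohort: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Cohort-level mean (SD) descriptives, overall and by sex."""
    if variables is None:
        variables = [
            c for c in cohort.columns
            if pd.api.types.is_numeric_dtype(cohort[c]) and c != "subject_id"
        ]
    rows = []
    strata: list[tuple[str, pd.DataFrame]] = [("all", cohort)]
    if "sex" in cohort.columns:
        for s, sub in cohort.groupby("sex"):
            strata.append((str(s), sub))
    for var in variables:
        row: dict[str, float | str] = {"variable": var}
        for name, sub in strata:
            vals = sub[var].dropna()
            row[f"{name}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            row[f"{name}_n"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(
    cohort: pd.DataFrame, row_vars: list[str], col_vars: list[str]
) -> pd.DataFrame:
    """Pearson r between each row variable and each column variable,
    starred at p < 0.05 (*) and p < 0.01 (**); complete-case per pair."""
    out = pd.DataFrame(index=row_vars, columns=col_vars, dtype=object)
    for rv in row_vars:
        for cv in col_vars:
            pair = cohort[[rv, cv]].dropna()
            if len(pair) < 3 or pair[rv].std() == 0 or pair[cv].std() == 0:
                out.loc[rv, cv] = ""
                continue
            r, p = pearson(pair[rv].to_numpy(), pair[cv].to_numpy())
            stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            out.loc[rv, cv] = f"{r:.3f}{stars}"
    out.index.name = "variable"
    return out


def group_means_table(
    cohort: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
    shape_col: str | None = None,
) -> pd.DataFrame:
    """Group mean (SD) per refraction group with ANOVA p; optionally a
    shape-class percentage block with a chi-square p."""
    rows = []
    for var in variables:
        row: dict[str, float | str] = {"variable": var}
        for g in GROUP_ORDER:
            vals = cohort.loc[cohort[group_col] == g, var].dropna()
            row[f"{g}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{g}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        try:
            row["p"] = group_compare(cohort, var, group_col)["p"]
        except ValueError:
            row["p"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if shape_col is not None and shape_col in cohort.columns:
        shape_rows = []
        for shape in ("oblate", "spherical", "prolate"):
            row = {"variable": f"{shape_col}:{shape}"}
            for g in GROUP_ORDER:
                sub = cohort[cohort[group_col] == g]
                row[f"{g}_mean"] = (
                    100.0 * float((sub[shape_col] == shape).mean())
                    if len(sub) else np.nan
                )
                row[f"{g}_sd"] = np.nan
            row["p"] = np.nan
            shape_rows.append(row)
        try:
            chi_p = group_compare(cohort, shape_col, group_col)["p"]
            shape_rows[0]["p"] = chi_p
        except ValueError:
            pass
        out = pd.concat([out, pd.DataFrame(shape_rows)], ignore_index=True)
    return out


def group_differences(group_means: pd.DataFrame) -> pd.DataFrame:
    """Between-group deltas (myopia − emmetropia, myopia − hyperopia) from a
    table of group means as produced by :func:`group_means_table`."""
    rows = []
    for _, r in group_means.iterrows():
        if not np.isfinite(r.get(f"{MYOPIA}_mean", np.nan)):
            continue
        rows.append(
            {
                "variable": r["variable"],
                "myopia_minus_emmetropia":
                    r[f"{MYOPIA}_mean"] - r[f"{EMMETROPIA}_mean"],
                "myopia_minus_hyperopia":
                    r[f"{MYOPIA}_mean"] - r[f"{HYPEROPIA}_mean"],
            }
        )
    return pd.DataFrame(rows)


def total_eye_volume(ps: float, lens: float, ac: float,
                     round_to: float = 10.0) -> float:
    """Whole-eye volume as the sum of the compartments, rounded to the
    reporting precision (nearest 10 mm^3 by default)."""
    return float(np.round((ps + lens + ac) / round_to) * round_to)


def build_report(
    cohort: pd.DataFrame,
    mri_vars: list[str] | None = None,
    biometry_vars: list[str] | None = None,
    group_col: str = "group",
) -> dict[str, pd.DataFrame]:
    """Assemble the descriptive, correlation, group-mean and group-difference
    tables for a measured cohort.  Empty cohorts yield headers-only tables.

    No multiple-testing correction is applied; each table uses complete
    cases for its own variables.
    """
    mri_vars = mri_vars or [
        c for c in ("height", "width", "ps_length", "ps_volume",
                    "lens_volume", "ac_volume", "hs", "vs")
        if c in cohort.columns
    ]
    biometry_vars = biometry_vars or [
        c for c in ("se", "al_cr_ratio", "al_biometry", "cr", "acd_biometry",
                    "al_growth", "body_height", "birth_weight",
                    "gestational_age")
        if c in cohort.columns
    ]
    if cohort.empty:
        empty = pd.DataFrame()
        return {"descriptives": empty, "correlations": empty,
                "group_means": empty, "group_differences": empty}
    tables: dict[str, pd.DataFrame] = {}
    tables["descriptives"] = descriptives_table(cohort)
    tables["correlations"] = correlation_table(cohort, biometry_vars, mri_vars)
    has_groups = group_col in cohort.columns and (
        cohort[group_col].nunique() >= 2
    )
    if has_groups:
        shape_col = "shape_h" if "shape_h" in cohort.columns else None
        gm = group_means_table(cohort, mri_vars, group_col, shape_col=shape_col)
        tables["group_means"] = gm
        tables["group_differences"] = group_differences(gm)
    else:
        tables["group_means"] = pd.DataFrame()
        tables["group_differences"] = pd.DataFrame()
    return tables
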