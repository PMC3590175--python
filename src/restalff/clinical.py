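"""Clinical associations and demographic group tests.

Regional standardized ALFF is related to drug-use history (duration in
months, daily dose in g/day) by partial correlation controlling for age,
education and nicotine use.  The partial correlation is computed by
residualization: both variables are regressed on [intercept, covariates]
and the Pearson correlation of the residuals is tested on
``df = n - 2 - k`` (k covariates).

Demographic group differences reproduce the classic summary-statistics
two-sample t-test: pooled variance, two-tailed p.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "partial_correlation",
    "alff_use_association",
    "demographic_tests",
    "demographic_tests_from_summary",
]


def _drop_collinear(design: np.ndarray) -> np.ndarray:
    keep = [0]
    for j in range(1, design.shape[1]):
        if np.linalg.matrix_rank(design[:, keep + [j]]) == len(keep) + 1:
            keep.append(j)
    if len(keep) < design.shape[1]:
        warnings.warn(
            f"dropped {design.shape[1] - len(keep)} collinear covariates",
            stacklevel=3,
        )
        design = design[:, keep]
    return design


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y controlling covariates.

    Returns ``(r_partial, p_two_tailed)``.  With no covariates this
    reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if covariates is None or (np.size(covariates) == 0):
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = _drop_collinear(np.column_stack([np.ones(n), cov]))
    k = design.shape[1] - 1
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def alff_use_association(
    regional_alff,
    manifest: pd.DataFrame,
    use_variables: tuple[str, ...] = ("duration", "dose"),
    covariate_names: tuple[str, ...] = ("age", "education", "nicotine"),
    group: str = "B",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Partial correlation of regional standardized ALFF with each
    drug-use variable, controlling the demographic covariates, within the
    dependent group.

    ``regional_alff`` is a mapping subject_id -> regional mean mALFF (or a
    Series indexed by subject_id).  Subjects with missing covariates are
    dropped with a warning.
    """
    alff = pd.Series(regional_alff, dtype=float)
    sub = manifest[manifest["group"] == group].set_index("subject_id")
    sub = sub.loc[[s for s in sub.index if s in alff.index]]
    rows = []
    n_tests = len(use_variables)
    for var in use_variables:
        cols = [var, *covariate_names]
        complete = sub[cols].notna().all(axis=1)
        if (~complete).any():
            warnings.warn(
                f"dropped {int((~complete).sum())} subjects with missing "
                f"{var}/covariates",
                stacklevel=2,
            )
        d = sub.loc[complete]
        r, p = partial_correlation(
            alff.loc[d.index].to_numpy(),
            d[var].to_numpy(),
            d[list(covariate_names)].to_numpy(),
        )
        p_eff = min(1.0, p * n_tests) if bonferroni else p
        rows.append(
            {
                "variable": var,
                "n": int(len(d)),
                "r_partial": r,
                "p": p_eff,
                "significant": p_eff < alpha,
            }
        )
    return pd.DataFrame(rows)


def demographic_tests_from_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Pooled two-sample t from per-group summary statistics.

    ``rows`` needs columns: variable, mean_a, sd_a, n_a, mean_b, sd_b, n_b.
    Sign convention: group B minus group A.
    """
    out = []
    for _, row in rows.iterrows():
        n_a, n_b = int(row["n_a"]), int(row["n_b"])
        if n_a < 2 or n_b < 2:
            raise ValueError("need n >= 2 in each group")
        res = stats.ttest_ind_from_stats(
            row["mean_b"], row["sd_b"], n_b,
            row["mean_a"], row["sd_a"], n_a,
            equal_var=True,
        )
        out.append(
            {
                "variable": row["variable"],
                "t": float(res.statistic),
                "df": n_a + n_b - 2,
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(out)


def demographic_tests(
    manifest: pd.DataFrame,
    variables: tuple[str, ...] = ("age", "education", "nicotine"),
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample t-tests (pooled by default; Welch behind a flag) on raw
    per-subject demographics, group B minus group A."""
    out = []
    for var in variables:
        a = manifest.loc[manifest["group"] == "A", var].dropna().to_numpy(dtype=float)
        b = manifest.loc[manifest["group"] == "B", var].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need n >= 2 in each group for {var}")
        res = stats.ttest_ind(b, a, equal_var=not welch)
        df = len(a) + len(b) - 2 if not welch else float(res.df)
        out.append(
            {"variable": var, "t": float(res.statistic), "df": df, "p": float(res.pvalue)}
        )
    return pd.DataFrame(out)
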