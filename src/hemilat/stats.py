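"""Group-level inference on hemispheric asymmetry.

Two analyses:

* **Hemisphere effect** — a univariate ANCOVA on hemisphere-stacked
  metric values (2n observations per metric) with gender as covariate;
  the F statistic for the hemisphere factor comes from the
  full-versus-reduced linear-model comparison with df (1, 2n - 3).
  p values are corrected across metrics within a family (global
  metrics; regional efficiencies) by Benjamini-Hochberg FDR.
* **Asymmetry-behavior association** — partial Pearson correlations
  between per-subject asymmetry scores and behavioral measures,
  adjusting for age, gender, handedness and education by residualizing
  both variables on the covariates.  Constant covariate columns (e.g.
  handedness in an all-right-handed cohort) are dropped with a logged
  warning.  Association p values are reported uncorrected by default,
  flagged as exploratory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    target: str
    effect: str  # "hemisphere" or "association"
    stat: float  # F (ANCOVA) or r (partial correlation)
    df: tuple[int, int]
    p: float
    q: float | None = None
    direction: str = "none"  # "leftward", "rightward" or "none"


def _as_numeric_covariates(covariates) -> np.ndarray:
    """Binary-code string columns, pass numeric ones through."""
    if covariates is None:
        return np.empty((0, 0))
    if isinstance(covariates, pd.DataFrame):
        cols = []
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                levels = sorted(col.astype(str).unique())
                if len(levels) > 2:
                    raise ValueError(f"covariate {name!r} has more than two levels")
                cols.append((col.astype(str) == levels[-1]).to_numpy(float))
            else:
                cols.append(col.to_numpy(float))
        return np.column_stack(cols) if cols else np.empty((len(covariates), 0))
    arr = np.asarray(covariates, dtype=float)
    return arr.reshape(len(arr), -1)


def _drop_constant_columns(z: np.ndarray) -> np.ndarray:
    if z.size == 0:
        return z
    keep = z.std(axis=0) > 0
    if not keep.all():
        logger.warning(
            "dropping %d constant covariate column(s) (e.g. handedness in an "
            "all-right-handed cohort)",
            int((~keep).sum()),
        )
    return z[:, keep]


def ancova_hemisphere(
    left_values: np.ndarray,
    right_values: np.ndarray,
    gender: np.ndarray,
    target: str = "",
) -> StatResult:
    """ANCOVA for the hemisphere effect with gender covariate.

    Values are stacked as 2n observations; the F for the hemisphere
    factor compares ``intercept + hemisphere + gender`` against
    ``intercept + gender`` on residual sums of squares, with
    df (1, 2n - 3).
    """
    left_values = np.asarray(left_values, dtype=float)
    right_values = np.asarray(right_values, dtype=float)
    n = len(left_values)
    if len(right_values) != n or len(gender) != n:
        raise ValueError("left, right and gender must have one entry per subject")
    if n < 2:
        raise ValueError("need at least 2 subjects per hemisphere")
    g = _as_numeric_covariates(pd.DataFrame({"gender": list(gender)})).ravel()

    y = np.concatenate([left_values, right_values])
    hemi = np.concatenate([np.zeros(n), np.ones(n)])  # 0 = L, 1 = R
    gg = np.concatenate([g, g])
    x_full = np.column_stack([np.ones(2 * n), hemi, gg])
    x_red = np.column_stack([np.ones(2 * n), gg])

    def rss(x: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return float(resid @ resid)

    df = (1, 2 * n - 3)
    if np.ptp(y) == 0:  # constant response: F undefined
        return StatResult(target, "hemisphere", math.nan, df, math.nan, direction="none")
    rss_full, rss_red = rss(x_full), rss(x_red)
    mean_diff = left_values.mean() - right_values.mean()
    direction = "leftward" if mean_diff > 0 else ("rightward" if mean_diff < 0 else "none")
    if rss_full <= 1e-300:
        f = math.inf
    else:
        f = max(0.0, (rss_red - rss_full)) / (rss_full / df[1])
    p = float(sps.f.sf(f, *df)) if math.isfinite(f) else 0.0
    return StatResult(target, "hemisphere", float(f), df, p, direction=direction)


def fdr_bh(p_values, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p values, rejection mask)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p_values, alpha=q_level, method="fdr_bh")
    return adjusted, reject


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates=None,
    target: str = "",
) -> StatResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on ``[intercept, covariates]`` by
    least squares; the correlation of the residuals is tested with the
    t transform on df = n - n_covariates - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    z_raw = _as_numeric_covariates(covariates)
    n_cov_raw = z_raw.shape[1] if z_raw.size else 0
    if n <= n_cov_raw + 2:
        raise ValueError(
            f"need more than {n_cov_raw + 2} observations for {n_cov_raw} covariates"
        )
    z = _drop_constant_columns(z_raw)
    if z.size == 0:
        z = np.empty((n, 0))
    n_cov = z.shape[1]
    design = np.column_stack([np.ones(n), z])

    def residualize(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx, ry = residualize(x), residualize(y)
    sx, sy = rx.std(), ry.std()
    df = (1, n - n_cov - 2)
    if sx == 0 or sy == 0:
        return StatResult(target, "association", math.nan, df, math.nan)
    r = float(np.clip((rx @ ry) / (n * sx * sy), -1.0, 1.0))
    dof = n - n_cov - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(dof / (1 - r * r))
        p = float(2 * sps.t.sf(abs(t), dof))
    direction = "rightward" if r > 0 else ("leftward" if r < 0 else "none")
    return StatResult(target, "association", r, df, p, direction=direction)


def hemisphere_effect_scan(
    metrics_table: pd.DataFrame,
    covariates: pd.DataFrame,
    value_columns: list[str],
    q_level: float = 0.05,
) -> pd.DataFrame:
    """ANCOVA per metric column with BH correction within the family.

    ``metrics_table`` must be long over hemispheres with columns
    ``subject_id``, ``hemisphere`` and the metric value columns;
    ``covariates`` must carry ``subject_id`` and ``gender``.
    """
    merged = metrics_table.merge(covariates[["subject_id", "gender"]], on="subject_id")
    left = merged[merged["hemisphere"] == "L"].sort_values("subject_id")
    right = merged[merged["hemisphere"] == "R"].sort_values("subject_id")
    if not (left["subject_id"].values == right["subject_id"].values).all():
        raise ValueError("left/right subject sets differ")
    gender = left["gender"].to_numpy()
    rows = []
    for col in value_columns:
        res = ancova_hemisphere(
            left[col].to_numpy(), right[col].to_numpy(), gender, target=col
        )
        rows.append(
            {
                "target": col,
                "F": res.stat,
                "df1": res.df[0],
                "df2": res.df[1],
                "p": res.p,
                "direction": res.direction,
            }
        )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    out["significant"] = False
    if ok.any():
        adjusted, reject = fdr_bh(out.loc[ok, "p"].to_numpy(), q_level)
        out.loc[ok, "q"] = adjusted
        out.loc[ok, "significant"] = reject
    return out


def association_scan(
    as_table: pd.DataFrame,
    behavior: pd.DataFrame,
    covariates: pd.DataFrame,
    selection: list[str],
    apply_fdr: bool = False,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Partial correlations of selected asymmetry scores with behavior.

    ``as_table`` is long with columns ``subject_id``, ``metric``,
    ``AS``; only metrics in ``selection`` (those with a significant
    hemisphere effect) are scanned against every behavioral column.
    p values are uncorrected unless ``apply_fdr`` — the scan is
    exploratory by design.
    """
    if not selection:
        return pd.DataFrame(
            columns=["metric", "score", "r", "df", "p", "q", "significant", "exploratory"]
        )
    score_cols = [c for c in behavior.columns if c != "subject_id"]
    cov_cols = [c for c in ("age", "gender", "handedness", "education") if c in covariates]
    rows = []
    for metric in selection:
        sub = as_table[as_table["metric"] == metric][["subject_id", "AS"]]
        merged = sub.merge(behavior, on="subject_id").merge(covariates, on="subject_id")
        missing = set(sub["subject_id"]) - set(merged["subject_id"])
        if missing or len(merged) != len(sub):
            raise ValueError(f"behavior/covariate join failed for subjects: {sorted(missing)}")
        z = merged[cov_cols]
        for score in score_cols:
            res = partial_correlation(
                merged["AS"].to_numpy(), merged[score].to_numpy(), z, target=f"{metric}~{score}"
            )
            rows.append(
                {
                    "metric": metric,
                    "score": score,
                    "r": res.stat,
                    "df": res.df[1],
                    "p": res.p,
                }
            )
    out = pd.DataFrame(rows)
    if apply_fdr and len(out):
        adjusted, reject = fdr_bh(out["p"].to_numpy(), q_level)
        out["q"] = adjusted
        out["significant"] = reject
    else:
        out["q"] = np.nan
        out["significant"] = out["p"] < 0.05
    out["exploratory"] = not apply_fdr
    return out
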