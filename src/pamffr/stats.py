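"""Inferential pipeline: transforms, gaze contrasts, correlation structure,
regression with collinearity diagnostics, and bootstrap Sobel mediation.

Observations for the correlation/regression/mediation analyses are
subject x gaze-position rows (amplitudes aggregated over the five gaze
positions).  The rows of one subject are not independent; reported
degrees of freedom follow the naive row count, which matches common
practice for these analyses and is documented as such.

The repeated-measures gaze effect is tested with orthogonal polynomial
contrasts computed for the actual, unequally spaced azimuths
(-70, -35, 0, +35, +70 degrees): per-subject contrast scores are reduced
to a one-sample t statistic across subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ContrastResult",
    "RegressionFit",
    "MediationResult",
    "sqrt_transform",
    "polynomial_contrast_weights",
    "gaze_contrasts",
    "correlate",
    "partial_correlation",
    "fit_regression",
    "mediate",
]

#: Amplitude columns eligible for the square-root variance-stabilizing
#: transform; latency columns are never transformed.
AMPLITUDE_COLUMNS = ("pam_p2p", "ffr_rms", "ffr_rms_c7", "f0_amp")


@dataclass(frozen=True)
class ContrastResult:
    contrast: str          # "linear" or "quadratic"
    estimate: float        # mean per-subject contrast score
    t_statistic: float
    df: int
    p_value: float
    channel: str = ""


@dataclass
class RegressionFit:
    """OLS fit of amplitude ~ music * PAM with collinearity diagnostics."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    vif: Dict[str, float]
    partial_r: Dict[str, float]
    f_interaction: float           # nested-model F: full vs music-only
    f_df: Tuple[int, int]
    f_pvalue: float
    n_obs: int
    r_squared: float


@dataclass
class MediationResult:
    """Paths and inference for the mediation X -> M -> Y."""

    a: float                  # X -> M
    b: float                  # M -> Y | X
    c: float                  # total X -> Y
    c_prime: float            # direct X -> Y | M
    se_a: float
    se_b: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    sobel_z: float
    sobel_p: float
    indirect: float           # a*b
    ci: Tuple[float, float]   # percentile bootstrap CI of a*b
    n_boot: int
    criteria: Dict[str, bool] = field(default_factory=dict)
    label: str = ""           # "full", "partial", or "none"


def sqrt_transform(table: pd.DataFrame,
                   columns: Sequence[str] = AMPLITUDE_COLUMNS) -> pd.DataFrame:
    """Element-wise square root of the amplitude columns (latencies untouched)."""
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise ValueError(f"column {col!r} contains negative amplitudes")
        out[col] = np.sqrt(vals)
    return out


def polynomial_contrast_weights(angles: Sequence[float]) -> Dict[str, np.ndarray]:
    """Orthogonal linear/quadratic contrast weights for arbitrary spacing.

    Gram–Schmidt on {1, θ, θ²}: each returned weight vector sums to zero,
    is orthogonal to the other, and is normalized to unit length.
    """
    th = np.asarray(angles, dtype=float)
    ones = np.ones_like(th)
    lin = th - th.mean()
    quad = th**2
    quad = quad - quad.mean()
    quad = quad - (quad @ lin) / (lin @ lin) * lin
    return {
        "linear": lin / np.linalg.norm(lin),
        "quadratic": quad / np.linalg.norm(quad),
    }


def gaze_contrasts(table: pd.DataFrame, channel: str,
                   value: str = "ffr_rms",
                   angle_col: str = "angle") -> Tuple[ContrastResult, ContrastResult]:
    """Linear and quadratic gaze contrasts on per-subject response profiles.

    Each subject contributes one score per contrast (the weighted sum of
    their responses over the five gaze angles); the scores are tested
    against zero with a one-sample t (df = n_subjects - 1).  Subjects
    with missing cells are dropped with a warning.
    """
    import warnings

    sub = table[table["channel"] == channel] if "channel" in table.columns else table
    wide = sub.pivot_table(index="subject_id", columns=angle_col, values=value)
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        warnings.warn(f"{n_dropped} subject(s) dropped from gaze contrasts (missing cells)")
    angles = complete.columns.to_numpy(dtype=float)
    if angles.size < 3:
        raise ValueError("gaze contrasts need at least three gaze positions")
    weights = polynomial_contrast_weights(angles)
    results = []
    for name in ("linear", "quadratic"):
        scores = complete.to_numpy() @ weights[name]
        t, p = scipy.stats.ttest_1samp(scores, 0.0)
        results.append(ContrastResult(
            contrast=name, estimate=float(scores.mean()),
            t_statistic=float(t), df=len(scores) - 1,
            p_value=float(p), channel=channel,
        ))
    return results[0], results[1]


def _complete(table: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    return table[list(cols)].dropna()


def correlate(table: pd.DataFrame, x_col: str, y_col: str) -> Tuple[float, float]:
    """Pearson correlation with two-sided t-based p-value."""
    d = _complete(table, [x_col, y_col])
    if len(d) < 3:
        raise ValueError("correlation needs at least 3 complete pairs")
    x, y = d[x_col].to_numpy(float), d[y_col].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance column: correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def partial_correlation(table: pd.DataFrame, x_col: str, y_col: str,
                        control: str) -> Tuple[float, float]:
    """Correlation of x and y after removing the control variable.

    Both variables are residualized on the control by least squares (with
    intercept); the residual correlation is tested with df = n - 3.  If a
    variable is (numerically) collinear with the control its residual
    carries no information and the partial correlation is 0 by convention.
    """
    d = _complete(table, [x_col, y_col, control])
    n = len(d)
    if n < 4:
        raise ValueError("partial correlation needs at least 4 complete triples")
    c = d[control].to_numpy(float)
    design = np.column_stack([np.ones(n), c])

    def resid(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    xv = d[x_col].to_numpy(float)
    yv = d[y_col].to_numpy(float)
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero-variance column: partial correlation undefined")
    rx, ry = resid(xv), resid(yv)
    if rx.std() <= 1e-12 * xv.std() or ry.std() <= 1e-12 * yv.std():
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = r * math.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2 * scipy.stats.t.sf(abs(t), df))
    return r, p


def fit_regression(table: pd.DataFrame, y_col: str = "ffr_rms",
                   x_col: str = "music_years",
                   m_col: str = "pam_p2p") -> RegressionFit:
    """OLS of ``y ~ x * m`` with VIFs, partial correlations and a nested F.

    VIFs are computed on the main-effect design (intercept + the two
    predictors); the nested F compares the interaction model against the
    x-only model.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    d = _complete(table, [y_col, x_col, m_col])
    n = len(d)
    if n < 5:
        raise ValueError("regression needs at least p + 2 observations")
    x = d[x_col].to_numpy(float)
    m = d[m_col].to_numpy(float)
    y = d[y_col].to_numpy(float)
    X_full = pd.DataFrame({
        "const": 1.0, x_col: x, m_col: m, f"{x_col}:{m_col}": x * m,
    })
    rank = np.linalg.matrix_rank(X_full.to_numpy())
    if rank < X_full.shape[1]:
        raise ValueError(
            f"rank-deficient design: columns {list(X_full.columns)} are collinear"
        )
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, sm.add_constant(x)).fit()
    df1 = int(full.df_model - reduced.df_model)
    df2 = int(full.df_resid)
    f = ((reduced.ssr - full.ssr) / df1) / (full.ssr / df2)
    f_p = float(scipy.stats.f.sf(f, df1, df2))
    X_main = np.column_stack([np.ones(n), x, m])
    vif = {
        x_col: float(variance_inflation_factor(X_main, 1)),
        m_col: float(variance_inflation_factor(X_main, 2)),
    }
    partial = {
        x_col: partial_correlation(d, x_col, y_col, m_col)[0],
        m_col: partial_correlation(d, m_col, y_col, x_col)[0],
    }
    return RegressionFit(
        params=pd.Series(full.params.values, index=X_full.columns),
        bse=pd.Series(full.bse.values, index=X_full.columns),
        pvalues=pd.Series(full.pvalues.values, index=X_full.columns),
        vif=vif, partial_r=partial,
        f_interaction=float(f), f_df=(df1, df2), f_pvalue=f_p,
        n_obs=n, r_squared=float(full.rsquared),
    )


def _ols_2pred(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Coefficients and SEs for y ~ 1 + x + m, closed form."""
    n = x.size
    X = np.column_stack([np.ones(n), x, m])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - 3
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * scipy.stats.t.sf(np.abs(t), df)
    return beta, se, p


def _ols_1pred(x: np.ndarray, y: np.ndarray):
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * scipy.stats.t.sf(np.abs(t), df)
    return beta, se, p


def _boot_indirect(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                   n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized case-resampling bootstrap of the indirect effect a*b."""
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    xm, mm, ym = xb.mean(1, keepdims=True), mb.mean(1, keepdims=True), yb.mean(1, keepdims=True)
    xc, mc, yc = xb - xm, mb - mm, yb - ym
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
        det = sxx * smm - sxm**2
        b = (sxx * smy - sxm * sxy) / det
    ab = a * b
    return ab[np.isfinite(ab)]


def mediate(table: pd.DataFrame, x_col: str = "music_years",
            m_col: str = "pam_p2p", y_col: str = "ffr_rms",
            n_boot: int = 1000, seed: int = 0,
            alpha: float = 0.05) -> MediationResult:
    """Sobel mediation of X -> M -> Y with a percentile bootstrap CI.

    Paths by ordinary least squares: ``a`` from M ~ X, ``b`` and ``c'``
    from Y ~ X + M, and the total effect ``c`` from Y ~ X.  The OLS
    identity c = c' + a*b holds exactly and is verified internally.
    The Sobel statistic z = a*b / sqrt(b² SE_a² + a² SE_b²) is referred to
    the normal distribution; the indirect effect additionally gets a
    case-resampling percentile bootstrap CI (``n_boot`` resamples).

    Mediation criteria: (i) X predicts Y on its own, (ii) X predicts M,
    (iii) the direct X -> Y path is rendered non-significant once M is
    controlled (full mediation); if (i) and (ii) hold, the indirect
    effect is significant, but the direct path survives, the pattern is
    labelled partial mediation.
    """
    d = _complete(table, [x_col, m_col, y_col])
    n = len(d)
    if n < 10:
        raise ValueError("mediation needs at least 10 complete triples")
    x = d[x_col].to_numpy(float)
    m = d[m_col].to_numpy(float)
    y = d[y_col].to_numpy(float)
    if m.std() == 0:
        raise ValueError("zero-variance mediator")
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    beta_a, se_a_v, p_a_v = _ols_1pred(x, m)
    a, se_a, p_a = float(beta_a[1]), float(se_a_v[1]), float(p_a_v[1])
    beta_c, se_c_v, p_c_v = _ols_1pred(x, y)
    c, p_c = float(beta_c[1]), float(p_c_v[1])
    beta_f, se_f, p_f = _ols_2pred(x, m, y)
    c_prime, b = float(beta_f[1]), float(beta_f[2])
    se_b, p_b = float(se_f[2]), float(p_f[2])
    p_c_prime = float(p_f[1])
    indirect = a * b
    assert abs(c - (c_prime + indirect)) <= 1e-8 * max(1.0, abs(c)), \
        "OLS identity c = c' + a*b violated"
    denom = math.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    z = indirect / denom if denom > 0 else 0.0
    sobel_p = float(2 * scipy.stats.norm.sf(abs(z)))
    rng = np.random.default_rng(seed)
    ab = _boot_indirect(x, m, y, n_boot, rng)
    lo, hi = np.percentile(ab, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    criteria = {
        "i_x_predicts_y": p_c < alpha,
        "ii_x_predicts_m": p_a < alpha,
        "iii_direct_nonsig_given_m": p_c_prime >= alpha,
    }
    indirect_sig = sobel_p < alpha
    if criteria["i_x_predicts_y"] and criteria["ii_x_predicts_m"] and indirect_sig:
        label = "full" if criteria["iii_direct_nonsig_given_m"] else "partial"
    else:
        label = "none"
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, se_a=se_a, se_b=se_b,
        p_a=p_a, p_b=p_b, p_c=p_c, p_c_prime=p_c_prime,
        sobel_z=float(z), sobel_p=sobel_p, indirect=float(indirect),
        ci=(float(lo), float(hi)), n_boot=n_boot,
        criteria=criteria, label=label,
    )
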