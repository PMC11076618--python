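"""Cohort statistics: mixed models, FDR control and effect sizes.

Per-image metrics from multiple images per animal are compared across
experimental conditions with a linear mixed model,
``metric ~ condition + (1 | animal)``, so the animal random intercept
absorbs the pseudo-replication of repeated images.  Degrees of freedom
for fixed-effect contrasts use the Satterthwaite approximation; p-values
across the contrast family are Benjamini–Hochberg adjusted, with
significance declared at q < 0.1.  Pairwise effect sizes are unsigned
Cohen's d with bins at 0.2 / 0.5 / 0.8.  Nerve morphometrics are
compared with a two-sided t-test at p < 0.05.

The REML fit comes from :mod:`statsmodels`; the Satterthwaite layer is
computed here from the closed-form block structure of the
random-intercept covariance (see ``docs/methods.md``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Significance level on BH-adjusted q-values.
DEFAULT_ALPHA = 0.1


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1, mapped back to
    the input order.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Unsigned Cohen's d with the pooled standard deviation.

    d = |mean_a − mean_b| / s_p,
    s_p = sqrt(((n_a−1)s_a² + (n_b−1)s_b²) / (n_a+n_b−2)).
    Undefined (NaN, with a warning) when the pooled sd is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        warnings.warn("zero pooled sd: Cohen's d undefined", stacklevel=2)
        return float("nan")
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled_var))


def effect_category(d: float) -> str:
    """Bin an unsigned effect size: d >= 0.2 small, >= 0.5 medium,
    >= 0.8 large, below 0.2 none."""
    if not np.isfinite(d):
        return "undefined"
    if d < 0:
        raise ValueError("effect_category expects an unsigned d")
    if d >= 0.8:
        return "large"
    if d >= 0.5:
        return "medium"
    if d >= 0.2:
        return "small"
    return "none"


def significance_stars(q: float, alpha: float = DEFAULT_ALPHA) -> str:
    """Annotation string: * q <= alpha, ** q < 0.01, *** q < 0.001,
    **** q < 0.0001, else 'ns'."""
    if q < 1e-4:
        return "****"
    if q < 1e-3:
        return "***"
    if q < 1e-2:
        return "**"
    if q <= alpha:
        return "*"
    return "ns"


def nerve_ttest(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sided two-sample (Welch) t-test p-value for nerve metrics."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups: p undefined", stacklevel=2)
            return float("nan")
        return 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


@dataclass
class BoxplotSummary:
    """Boxplot convention: box from Q1 to Q3, whiskers at Q1/Q3 ∓/± 1.5·IQR,
    points beyond the whiskers are outliers; mean and median both reported."""

    q1: float
    median: float
    mean: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


def boxplot_summary(values: np.ndarray) -> BoxplotSummary:
    """Summarise a sample by the boxplot convention above.

    Quartiles use linear interpolation.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = v[(v < lo) | (v > hi)]
    return BoxplotSummary(q1=float(q1), median=float(med), mean=float(v.mean()),
                          q3=float(q3), whisker_lo=float(lo), whisker_hi=float(hi),
                          outliers=outliers)


# ---------------------------------------------------------------------------
# Linear mixed model with Satterthwaite degrees of freedom
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    """One pairwise fixed-effect contrast from the mixed model."""

    contrast: str
    estimate: float
    se: float
    df: float
    p: float
    q: float = float("nan")
    d: float = float("nan")
    d_category: str = "undefined"
    significant: bool = False
    boundary_fit: bool = False
    n_a: int = 0
    n_b: int = 0

    @property
    def stars(self) -> str:
        return significance_stars(self.q)


class _BlockGLS:
    """Closed-form GLS and REML information for a random-intercept model.

    With V_i = σe² I + σa² 11' per animal block, V_i⁻ᵏ has the spectral
    form σe⁻ᵏ (I − J/nᵢ) + λᵢ⁻ᵏ J/nᵢ with λᵢ = σe² + nᵢ σa², which makes
    every trace and quadratic form needed for the Satterthwaite
    approximation a cheap per-block accumulation.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, blocks: list[np.ndarray],
                 sigma_a2: float, sigma_e2: float):
        p = X.shape[1]
        se2 = max(sigma_e2, 1e-12)
        sa2 = max(sigma_a2, 0.0)

        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        M1 = np.zeros((p, p))
        M2 = np.zeros((p, p))
        N11 = np.zeros((p, p))
        N12 = np.zeros((p, p))
        N22 = np.zeros((p, p))
        T1 = np.zeros((2, 2))

        for idx in blocks:
            Xi = X[idx]
            yi = y[idx]
            ni = len(idx)
            lam = se2 + ni * sa2
            gi = Xi.sum(axis=0)               # X_i' 1
            G = np.outer(gi, gi)
            XtXi = Xi.T @ Xi
            within = XtXi - G / ni            # deviation part
            ysum = yi.sum()

            XtVX += within / se2 + G / (ni * lam)
            XtVy += (Xi.T @ yi - gi * ysum / ni) / se2 + gi * ysum / (ni * lam)
            M1 += G / lam ** 2
            M2 += within / se2 ** 2 + G / (ni * lam ** 2)
            N11 += ni * G / lam ** 3
            N12 += G / lam ** 3
            N22 += within / se2 ** 3 + G / (ni * lam ** 3)
            T1[0, 0] += ni ** 2 / lam ** 2
            T1[0, 1] += ni / lam ** 2
            T1[1, 1] += 1 / lam ** 2 + (ni - 1) / se2 ** 2
        T1[1, 0] = T1[0, 1]

        self.C = np.linalg.inv(XtVX)
        self.beta = self.C @ XtVy
        self.M = (M1, M2)
        N = {(0, 0): N11, (0, 1): N12, (1, 0): N12, (1, 1): N22}

        # REML expected information for theta = (sigma_a2, sigma_e2):
        # I_jk = 0.5 * tr(P V_j P V_k)
        info = np.zeros((2, 2))
        for j in range(2):
            for k in range(2):
                info[j, k] = 0.5 * (
                    T1[j, k]
                    - np.trace(self.C @ N[(j, k)]) - np.trace(self.C @ N[(k, j)])
                    + np.trace(self.C @ self.M[j] @ self.C @ self.M[k])
                )
        self.info = info
        try:
            self.info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            self.info_inv = np.linalg.pinv(info)

    def contrast(self, c: np.ndarray) -> tuple[float, float, float]:
        """(estimate, se, satterthwaite_df) for the contrast c'beta."""
        phi = float(c @ self.C @ c)
        grad = np.array([float(c @ self.C @ self.M[j] @ self.C @ c) for j in range(2)])
        var_phi = float(grad @ self.info_inv @ grad)
        df = 2.0 * phi ** 2 / var_phi if var_phi > 0 else np.inf
        return float(c @ self.beta), float(np.sqrt(phi)), df


def fit_metric_lmm(
    table: pd.DataFrame,
    metric: str,
    condition_col: str = "condition",
    animal_col: str = "animal",
    contrasts: list[tuple[str, str]] | None = None,
    log_transform: bool = False,
    alpha: float = DEFAULT_ALPHA,
) -> list[StatResult]:
    """Fit ``metric ~ condition + (1 | animal)`` and test pairwise contrasts.

    One model is fitted per metric across all conditions (cell-means
    coding) with a random intercept per animal, estimated by REML.
    Each requested contrast (default: all pairwise) is tested with a
    t-statistic on Satterthwaite degrees of freedom; the resulting
    p-values are BH-adjusted within the contrast family and flagged
    significant at q < ``alpha``.  Cohen's d is computed from the raw
    per-image values of the two conditions (on the model scale).

    Ratio-valued metrics (e.g. FTR) should be fitted with
    ``log_transform=True``; non-finite or non-positive values are
    dropped with a log entry.  A fit with zero animal variance sits on
    the boundary of the parameter space: it is reported with
    fixed-effects residual degrees of freedom and ``boundary_fit=True``,
    never silently.
    """
    import statsmodels.api as sm

    data = table[[animal_col, condition_col, metric]].copy()
    n_before = len(data)
    values = pd.to_numeric(data[metric], errors="coerce")
    keep = np.isfinite(values)
    if log_transform:
        keep &= values > 0
    if keep.sum() < n_before:
        logger.info("dropped %d rows with undefined %s values", n_before - keep.sum(), metric)
    data = data[keep]
    y = values[keep].to_numpy(dtype=float)
    if log_transform:
        y = np.log(y)

    conditions = sorted(data[condition_col].unique())
    if len(conditions) < 2:
        raise ValueError("need at least two conditions to form contrasts")
    cond_idx = {c: i for i, c in enumerate(conditions)}
    X = np.zeros((len(data), len(conditions)))
    for row, cond in enumerate(data[condition_col]):
        X[row, cond_idx[cond]] = 1.0

    animals = data[animal_col].to_numpy()
    blocks = [np.flatnonzero(animals == a) for a in pd.unique(animals)]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=animals)
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except Exception:
            fit = model.fit(reml=True)
    sigma_a2 = float(np.asarray(fit.cov_re)[0, 0])
    sigma_e2 = float(fit.scale)
    boundary = sigma_a2 <= 1e-8 * sigma_e2
    if boundary:
        logger.warning("animal variance estimated at zero: boundary fit, "
                       "falling back to fixed-effects residual df")

    gls = _BlockGLS(X, y, blocks, sigma_a2, sigma_e2)
    resid_df = len(data) - len(conditions)

    if contrasts is None:
        contrasts = [(conditions[i], conditions[j])
                     for i in range(len(conditions)) for j in range(i + 1, len(conditions))]

    results: list[StatResult] = []
    for cond_a, cond_b in contrasts:
        c = np.zeros(len(conditions))
        c[cond_idx[cond_a]] = 1.0
        c[cond_idx[cond_b]] = -1.0
        estimate, se, df = gls.contrast(c)
        if boundary or not np.isfinite(df):
            df = float(resid_df)
        df = float(np.clip(df, 1.0, resid_df))
        t_stat = estimate / se if se > 0 else np.inf
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
        vals_a = y[X[:, cond_idx[cond_a]] == 1]
        vals_b = y[X[:, cond_idx[cond_b]] == 1]
        d = cohens_d(vals_a, vals_b) if min(len(vals_a), len(vals_b)) >= 2 else float("nan")
        results.append(StatResult(
            contrast=f"{cond_a} vs {cond_b}", estimate=estimate, se=se, df=df,
            p=p, d=d, d_category=effect_category(d) if np.isfinite(d) else "undefined",
            boundary_fit=boundary, n_a=len(vals_a), n_b=len(vals_b),
        ))

    qs = bh_adjust(np.array([r.p for r in results]))
    for r, q in zip(results, qs):
        r.q = float(q)
        r.significant = bool(q < alpha)
    return results


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    """Tidy results table (contrast, estimate, se, df, p, q, d, ...)."""
    return pd.DataFrame([
        {"contrast": r.contrast, "estimate": r.estimate, "se": r.se, "df": r.df,
         "p": r.p, "q": r.q, "d": r.d, "d_category": r.d_category,
         "significant": r.significant, "stars": r.stars,
         "boundary_fit": r.boundary_fit, "n_a": r.n_a, "n_b": r.n_b}
        for r in results
    ])
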