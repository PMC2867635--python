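"""Expression analysis: normalization, empirical-Bayes moderated t, FDR calls.

The two-color mRNA design reduces to a one-sample test on per-replicate
M-values (tumor vs normal within array, technical triplicates); single-color
microRNA arrays are quantile-normalized and paired into M-values across the
tumor/normal duplicates.  Per-feature variances are shrunk toward a prior
estimated by closed-form moment matching on log-variances, the moderated t
is referred to a t-distribution with augmented degrees of freedom, and
Benjamini-Hochberg q-values with absolute log2-fold-change cutoffs define
up/down calls (mRNA defaults: |logFC| > 1, q < 0.05; microRNA: 0.5, 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DECutoffs",
    "EBayesFit",
    "QuantileNormalizer",
    "ModeratedTTest",
    "lowess_normalize",
    "quantile_normalize",
    "paired_mvalues",
    "moderated_t",
    "bh_fdr",
    "call_de",
    "trend_test",
    "direction_frequency_test",
    "summarize_de",
]

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass(frozen=True)
class DECutoffs:
    """Absolute log2 fold-change and FDR cutoffs for calling a feature DE."""

    fc: float = 1.0
    fdr: float = 0.05

    @classmethod
    def mrna(cls) -> "DECutoffs":
        return cls(fc=1.0, fdr=0.05)

    @classmethod
    def mirna(cls) -> "DECutoffs":
        return cls(fc=0.5, fdr=0.05)


@dataclass(frozen=True)
class EBayesFit:
    """Empirical-Bayes variance prior: df d0 (may be inf) and variance s0^2."""

    prior_df: float
    prior_var: float


# ---------------------------------------------------------------------------
# Normalization


def lowess_normalize(M: np.ndarray, A: np.ndarray, span: float = 0.3,
                     iterations: int = 3) -> np.ndarray:
    """Remove the intensity-dependent trend: M' = M - lowess(M ~ A)."""
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.shape != A.shape:
        raise ValueError("M and A must have the same shape")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if M.ndim == 2:
        return np.vstack([
            lowess_normalize(m, a, span=span, iterations=iterations)
            for m, a in zip(M, A)
        ])
    if M.size < 10:
        raise ValueError("too few features for a stable lowess fit (need >= 10)")
    fitted = _sm_lowess(M, A, frac=span, it=iterations, return_sorted=False)
    return M - fitted


def _quantile_map(row: np.ndarray, reference: np.ndarray) -> np.ndarray:
    order = np.argsort(row, kind="mergesort")
    mapped = np.empty_like(reference)
    mapped[order] = reference
    # average reference values over tied input values
    out = pd.Series(mapped).groupby(pd.Series(row)).transform("mean").to_numpy()
    return out


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every replicate (row) onto the mean of the sorted distributions.

    Ties within a replicate receive the average of their reference values.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two replicates")
    reference = np.sort(matrix, axis=1).mean(axis=0)
    return np.vstack([_quantile_map(row, reference) for row in matrix])


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization as a transformer (rows = arrays/replicates).

    ``fit`` learns the reference distribution (mean of sorted rows);
    ``transform`` maps each row onto it, averaging ties.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least two replicates")
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.vstack([_quantile_map(row, self.reference_) for row in X])


def paired_mvalues(tumor: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Replicate-paired M-values for a single-channel design: tumor - normal."""
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise ValueError("tumor and normal matrices must have the same shape")
    return tumor - normal


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> EBayesFit:
    """Moment-matching fit of (d0, s0^2) on log sample variances."""
    ok = (df > 0) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("too few positive-variance features to fit the prior")
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond chi-square sampling noise: variances are
        # exchangeable and the prior is their mean with infinite df
        d0 = np.inf
        s0 = float(np.mean(s2[ok]))
    return EBayesFit(prior_df=d0, prior_var=s0)


def _posterior_var(s2: np.ndarray, df: np.ndarray, fit: EBayesFit) -> np.ndarray:
    if np.isinf(fit.prior_df):
        post = np.full_like(s2, fit.prior_var)
    else:
        post = (fit.prior_df * fit.prior_var + df * s2) / (fit.prior_df + df)
    post = np.where(s2 == 0, fit.prior_var, post)  # zero-variance features
    return post


def _t_pvalue(t: np.ndarray, df) -> np.ndarray:
    df = np.asarray(df, dtype=float)
    p = np.where(
        np.isinf(df),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df), 1.0, df)),
    )
    return np.clip(p, 0.0, 1.0)


class ModeratedTTest(BaseEstimator):
    """One-sample empirical-Bayes moderated t over a replicate-by-feature matrix.

    Parameters
    ----------
    prior_df, prior_var : optional overrides of the estimated prior; pass
        ``prior_df=np.inf`` with a fixed ``prior_var`` for a z-like statistic,
        or ``prior_df=0`` for the ordinary t.

    Attributes (all per feature unless noted)
    ----------
    logfc_, s2_, df_, t_, p_, q_ : arrays; ebayes_ : the fitted prior.
    """

    def __init__(self, prior_df: float | None = None, prior_var: float | None = None):
        self.prior_df = prior_df
        self.prior_var = prior_var

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a replicate-by-feature matrix")
        n = (~np.isnan(X)).sum(axis=0).astype(float)
        usable = n >= 2
        if not usable.all():
            warnings.warn(
                f"{int((~usable).sum())} features with < 2 replicates excluded"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            logfc = np.nanmean(X, axis=0)
            s2 = np.nanvar(X, axis=0, ddof=1)
        df = n - 1.0
        if self.prior_df is not None:
            if self.prior_var is None:
                raise ValueError("prior_var required when prior_df is fixed")
            fit = EBayesFit(prior_df=float(self.prior_df), prior_var=float(self.prior_var))
        else:
            fit = _fit_variance_prior(s2[usable], df[usable])
        post = _posterior_var(np.where(usable, s2, np.nan), df, fit)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = logfc / np.sqrt(post / n)
        # total df capped at the pooled residual df: the prior is estimated
        # from the data and cannot carry more information than that
        total_df = np.minimum(fit.prior_df + df, np.sum(df[usable]))
        p = _t_pvalue(t, total_df)
        p = np.where(usable, p, np.nan)
        q = np.full_like(p, np.nan)
        q[usable] = bh_fdr(p[usable])
        self.n_ = n
        self.usable_ = usable
        self.logfc_ = logfc
        self.s2_ = s2
        self.df_ = df
        self.t_ = np.where(usable, t, np.nan)
        self.p_ = p
        self.q_ = q
        self.ebayes_ = fit
        return self


def moderated_t(
    matrix: np.ndarray,
    feature_ids=None,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> tuple[pd.DataFrame, EBayesFit]:
    """Moderated one-sample t per feature (columns) over replicates (rows).

    Returns a result frame (feature, logfc, s2, df, t, p, q, direction="none")
    and the fitted variance prior.  Features with fewer than two replicates
    are excluded (NaN statistics) with a warning.
    """
    est = ModeratedTTest(prior_df=prior_df, prior_var=prior_var).fit(matrix)
    m = est.logfc_.size
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(m)]
    res = pd.DataFrame(
        {
            "feature": list(feature_ids),
            "logfc": est.logfc_,
            "s2": est.s2_,
            "df": est.df_,
            "t": est.t_,
            "p": est.p_,
            "q": est.q_,
            "direction": NONE,
        }
    )
    return res, est.ebayes_


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order restored to the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, cutoffs: DECutoffs) -> pd.DataFrame:
    """Set the direction column: up/down require both FC and FDR cutoffs."""
    out = results.copy()
    up = (out["logfc"] > cutoffs.fc) & (out["q"] < cutoffs.fdr)
    down = (out["logfc"] < -cutoffs.fc) & (out["q"] < cutoffs.fdr)
    out["direction"] = np.where(up, UP, np.where(down, DOWN, NONE))
    return out


# ---------------------------------------------------------------------------
# Stage-trend and direction-frequency tests


def trend_test(
    stage_matrices: dict[str, np.ndarray],
    stage_codes: dict[str, float] | None = None,
    feature_ids=None,
) -> pd.DataFrame:
    """Per-feature linear trend of stage-mean M-values on stage codes.

    Stages are coded 1..S in dict order unless ``stage_codes`` is given;
    residual variances (df = S - 2) are moderated with the same
    empirical-Bayes machinery as the moderated t.
    """
    stages = list(stage_matrices)
    if len(stages) < 3:
        raise ValueError("trend test needs at least three stages")
    if stage_codes is None:
        stage_codes = {s: float(i + 1) for i, s in enumerate(stages)}
    x = np.array([stage_codes[s] for s in stages], dtype=float)
    means = np.vstack([
        np.nanmean(np.atleast_2d(np.asarray(stage_matrices[s], dtype=float)), axis=0)
        for s in stages
    ])  # stages x features
    S = len(stages)
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    slope = (xc @ means) / sxx
    intercept = means.mean(axis=0)
    resid = means - (intercept[None, :] + np.outer(xc, slope))
    rss = np.sum(resid**2, axis=0)
    df = float(S - 2)
    s2 = rss / df
    fit = _fit_variance_prior(s2, np.full_like(s2, df))
    post = _posterior_var(s2, np.full_like(s2, df), fit)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = slope / np.sqrt(post / sxx)
    t = np.where((slope == 0) & (s2 == 0), 0.0, t)
    p = _t_pvalue(t, min(fit.prior_df + df, df * slope.size))
    m = slope.size
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(m)]
    return pd.DataFrame(
        {"feature": list(feature_ids), "slope": slope, "t": t, "p": p}
    )


def direction_frequency_test(n_up: int, n_down: int) -> tuple[float, float]:
    """1-df chi-square of the up/down split against a 50:50 expectation."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    total = n_up + n_down
    if total == 0:
        raise ValueError("no directional calls to test")
    stat = (n_up - n_down) ** 2 / total
    return float(stat), float(stats.chi2.sf(stat, df=1))


def summarize_de(
    results_by_stage: dict[str, pd.DataFrame],
    annotations,
) -> pd.DataFrame:
    """Per-stage, per-chromosome up/down counts plus stage percent-DE rows.

    Returns a tidy frame (stage, chrom, up, down) with one "TOT" row per
    stage carrying totals and the integer percent of features called DE.
    Features without an annotation still count toward totals (flagged).
    """
    from .cgh import round_half_away

    ann = annotations.table.set_index("id")
    rows = []
    for stage, res in results_by_stage.items():
        n_total = len(res)
        missing = (~res["feature"].isin(ann.index)).sum()
        if missing:
            warnings.warn(f"stage {stage}: {missing} features lack annotations")
        merged = res.merge(
            ann[["chrom"]], left_on="feature", right_index=True, how="left"
        )
        for chrom, grp in merged.groupby("chrom", sort=True):
            rows.append(
                {
                    "stage": stage,
                    "chrom": chrom,
                    "up": int((grp["direction"] == UP).sum()),
                    "down": int((grp["direction"] == DOWN).sum()),
                }
            )
        n_up = int((res["direction"] == UP).sum())
        n_down = int((res["direction"] == DOWN).sum())
        rows.append(
            {
                "stage": stage,
                "chrom": "TOT",
                "up": n_up,
                "down": n_down,
                "percent_de": round_half_away(100.0 * (n_up + n_down) / n_total)
                if n_total
                else 0,
            }
        )
    return pd.DataFrame(rows)
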