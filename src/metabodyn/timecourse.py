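"""Ordination and time-trend statistics for the activation time course.

PCA on square-root-scaled intensities gives an unsupervised overview;
PLS regression of sampling time on log-scaled intensities (PLS1, NIPALS)
identifies time-associated features via loadings; a likelihood ratio test of
a natural-cubic-spline model of time against an intercept-only null flags
features with a significant time trend, Bonferroni-corrected across features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats

from .containers import FeatureTable

__all__ = [
    "OrdinationResult",
    "TimeTrendResult",
    "pca",
    "pls_time",
    "rank_features_by_loading",
    "time_trend_lrt",
]


@dataclass
class OrdinationResult:
    """Scores, loadings and explained variance of a PCA or PLS fit.

    ``explained_variance`` is the fraction of total intensity variance per
    component for PCA, and the fraction of variance of the predicted variable
    (sampling time) per component for PLS.
    """

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance: np.ndarray
    scaling: str
    method: str
    weights: pd.DataFrame | None = None  # PLS x-weights

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _orient_by_time(scores: np.ndarray, loadings: np.ndarray,
                    time: np.ndarray, weights: np.ndarray | None = None) -> None:
    """Flip component signs in place so the mean score at the latest time
    point is >= the mean score at the first; ties left unflipped."""
    t_last, t_first = np.nanmax(time), np.nanmin(time)
    for k in range(scores.shape[1]):
        late = scores[time == t_last, k].mean()
        early = scores[time == t_first, k].mean()
        if late < early:
            scores[:, k] *= -1
            loadings[:, k] *= -1
            if weights is not None:
                weights[:, k] *= -1


def pca(table: FeatureTable, n_components: int | None = None,
        scale: str = "sqrt") -> OrdinationResult:
    """Principal component analysis of a (blank-free, normalized) table.

    Intensities are square-root scaled to limit the leverage of high-intensity
    features, feature-centered over samples, and decomposed by SVD of the
    sample covariance. Explained-variance fractions sum to 1 over all
    components.
    """
    x = table.values.to_numpy(dtype=float).T  # samples x features
    if scale == "sqrt":
        if (x < 0).any():
            raise ValueError("square-root scaling requires non-negative intensities")
        x = np.sqrt(x)
    elif scale != "none":
        raise ValueError("scale must be 'sqrt' or 'none'")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    evr = s**2 / max((s**2).sum(), np.finfo(float).tiny)
    k = min(len(s), n_components) if n_components else len(s)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    time = table.sample_meta["time_h"].to_numpy(dtype=float)
    _orient_by_time(scores, loadings, time)
    comp = [f"PC{i + 1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=table.values.columns, columns=comp),
        loadings=pd.DataFrame(loadings, index=table.values.index, columns=comp),
        explained_variance=evr[:k],
        scaling=scale,
        method="pca",
    )


def pls_time(table: FeatureTable, n_components: int = 2,
             scale: str = "log", log_offset: float | None = None) -> OrdinationResult:
    """PLS1 regression of sampling time on log-scaled intensities (NIPALS).

    Time in hours is the predicted variable; components maximize covariance
    between the log-intensity matrix and time. The algorithm is deterministic:
    each weight vector starts from the X-y covariance, so no random
    initialization enters. Components are oriented so scores increase from the
    first to the last time point. ``explained_variance`` is the fraction of
    time variance captured per component.

    Intensities must be strictly positive for the log transform; with zeros
    present a +1 offset is applied (set ``log_offset`` explicitly to control
    this), and negative intensities are an error.
    """
    time = table.sample_meta["time_h"].to_numpy(dtype=float)
    if np.isnan(time).any():
        raise ValueError("table contains blank samples; drop them before PLS")
    if np.ptp(time) == 0:
        raise ValueError("sampling time is constant; PLS needs a varying predicted variable")
    x = table.values.to_numpy(dtype=float).T
    if scale == "log":
        if (x < 0).any():
            raise ValueError("negative intensities cannot be log scaled")
        offset = log_offset if log_offset is not None else (1.0 if (x == 0).any() else 0.0)
        if (x + offset <= 0).any():
            raise ValueError(
                "zero intensities present; pass log_offset=1 (or gap-fill) "
                "before log scaling"
            )
        x = np.log(x + offset)
    elif scale != "none":
        raise ValueError("scale must be 'log' or 'none'")

    n, m = x.shape
    n_components = min(n_components, n - 1, m)
    xc = x - x.mean(axis=0, keepdims=True)
    y = time - time.mean()
    ss_y = float(y @ y)

    T = np.zeros((n, n_components))
    P = np.zeros((m, n_components))
    W = np.zeros((m, n_components))
    evr = np.zeros(n_components)
    xk, yk = xc.copy(), y.copy()
    for a in range(n_components):
        w = xk.T @ yk
        nw = np.linalg.norm(w)
        if nw == 0:
            n_components = a
            break
        w /= nw
        t = xk @ w
        tt = float(t @ t)
        if tt == 0:
            n_components = a
            break
        p = xk.T @ t / tt
        q = float(yk @ t) / tt
        xk = xk - np.outer(t, p)
        yk = yk - q * t
        T[:, a], P[:, a], W[:, a] = t, p, w
        evr[a] = (q * q * tt) / ss_y if ss_y > 0 else 0.0
    T, P, W, evr = T[:, :n_components], P[:, :n_components], W[:, :n_components], evr[:n_components]
    _orient_by_time(T, P, time, W)
    comp = [f"PLS{i + 1}" for i in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(T, index=table.values.columns, columns=comp),
        loadings=pd.DataFrame(P, index=table.values.index, columns=comp),
        explained_variance=evr,
        scaling=scale,
        method="pls",
        weights=pd.DataFrame(W, index=table.values.index, columns=comp),
    )


def rank_features_by_loading(pls: OrdinationResult) -> pd.DataFrame:
    """Rank features by the sum of absolute PLS loadings over components.

    With time as the predicted variable, |loading| measures how much a
    feature contributes to the time-dependent structure. Ties are broken by
    feature id. Returns a DataFrame (feature_id index, ``importance`` column)
    sorted in descending importance.
    """
    if pls.loadings.shape[1] < 1:
        raise ValueError("ordination has no components")
    imp = pls.loadings.abs().sum(axis=1)
    out = pd.DataFrame({"importance": imp})
    out["_id"] = out.index.astype(str)
    out = out.sort_values(["importance", "_id"], ascending=[False, True])
    return out.drop(columns="_id").rename_axis("feature_id")


@dataclass
class TimeTrendResult:
    """Per-feature spline-vs-intercept likelihood ratio test results.

    ``per_feature`` columns: loglik_null, loglik_spline, lrt_stat (2*Delta
    logL), df, p, significant (Bonferroni at alpha / n_tested).
    """

    per_feature: pd.DataFrame
    alpha: float
    spline_df: int
    n_tested: int
    reference: str

    @property
    def significant(self) -> pd.Series:
        return self.per_feature["significant"]

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_tested


def _spline_basis(time: np.ndarray, spline_df: int) -> np.ndarray:
    """Design matrix (intercept + natural cubic spline of time, spline_df
    basis columns) evaluated at the sample times."""
    dm = dmatrix(f"cr(x, df={spline_df})", {"x": time}, return_type="matrix")
    return np.asarray(dm)


def time_trend_lrt(
    table: FeatureTable,
    spline_df: int = 5,
    alpha: float = 0.05,
    reference: str = "f",
) -> TimeTrendResult:
    """Likelihood ratio test for a time trend in every feature.

    Each feature's intensity is fit by a Gaussian model with a natural cubic
    spline of time (``spline_df`` unpenalized basis functions) against an
    intercept-only null; the statistic is 2*Delta logL. Because the models are
    nested least-squares fits, the statistic is a monotone function of the
    exact F statistic, and p-values use the finite-sample
    F(spline_df, n - spline_df - 1) reference by default (``reference="f"``),
    which is exactly calibrated under the Gaussian model at the small sample
    sizes of a 9-time-point design; ``reference="chisq"`` gives the asymptotic
    chi-square(spline_df) p-values instead. Significance applies a Bonferroni
    threshold of alpha / n_tested.

    The table should be quantile normalized, restricted to above-blank
    features, and blank-free (blank columns are ignored if present).
    """
    if reference not in ("f", "chisq"):
        raise ValueError("reference must be 'f' or 'chisq'")
    cells = table.drop_blanks() if table.blank_ids else table
    time = cells.sample_meta["time_h"].to_numpy(dtype=float)
    n_distinct = len(set(time))
    if spline_df >= n_distinct:
        raise ValueError(
            f"spline_df={spline_df} must be smaller than the number of distinct "
            f"time points ({n_distinct})"
        )
    for t in sorted(set(time)):
        if int((time == t).sum()) < 2:
            raise ValueError(f"time point {t} h has fewer than 2 replicates")

    y = cells.values.to_numpy(dtype=float).T  # samples x features
    n, n_feat = y.shape
    X = _spline_basis(time, spline_df)
    df_model = X.shape[1] - 1  # spline columns beyond the intercept
    q, _ = np.linalg.qr(X)
    resid = y - q @ (q.T @ y)
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((y - y.mean(axis=0, keepdims=True)) ** 2).sum(axis=0)

    tiny = np.finfo(float).tiny
    # degenerate features (constant, or perfectly fit): statistic 0 / inf
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(np.maximum(rss0, tiny) / np.maximum(rss1, tiny))
    stat = np.where(rss0 <= tiny * n, 0.0, stat)
    stat = np.maximum(stat, 0.0)

    df_resid = n - df_model - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df_model) / np.maximum(rss1 / df_resid, tiny)
    f = np.where(rss0 <= tiny * n, 0.0, np.maximum(f, 0.0))
    if reference == "f":
        p = stats.f.sf(f, df_model, df_resid)
    else:
        p = stats.chi2.sf(stat, df_model)

    def _loglik(rss: np.ndarray) -> np.ndarray:
        return -0.5 * n * (np.log(2 * np.pi) + np.log(np.maximum(rss, tiny) / n) + 1.0)

    per_feature = pd.DataFrame(
        {
            "loglik_null": _loglik(rss0),
            "loglik_spline": _loglik(rss1),
            "lrt_stat": stat,
            "df": df_model,
            "p": p,
            "significant": p < alpha / n_feat,
        },
        index=cells.values.index,
    )
    return TimeTrendResult(
        per_feature=per_feature,
        alpha=alpha,
        spline_df=df_model,
        n_tested=n_feat,
        reference=reference,
    )
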