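"""Differential expression engines for the within-sex stage contrast.

Two engines share one result contract:

* ``moderated_t_test`` — for log2-intensity matrices: per-gene group-mean
  linear model, empirical-Bayes variance shrinkage (prior fitted by matching
  the moments of the log residual variances across genes), moderated t.
* ``nb_wald_test`` — for count matrices: per-gene negative-binomial GLM with
  log link and size-factor offsets, Wald test on the group coefficient,
  Cook's-distance outlier flagging and independent filtering before the
  Benjamini-Hochberg adjustment.

Both engines operate on explicit reference/alternative column groups via the
``*_core`` functions, so the same machinery serves the T1->T2 within-sex
contrast and the M-vs-F contrast at T2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from gonodyn.exceptions import ValidationError
from gonodyn.io import ExpressionDataset

LOG2 = math.log(2.0)

STATUS_TESTED = "tested"
STATUS_UNTESTED = "untested"
STATUS_COOKS = "cooks_outlier"
STATUS_LOW_EXPR = "filtered_low_expression"

DEFAULT_FC_THRESHOLD = 1.5  # log2 units
DEFAULT_ALPHA = 0.05
DEFAULT_COOKS_CUTOFF = 19.17
DEFAULT_IF_ALPHA = 0.1
DEFAULT_MIN_TOTAL_COUNT = 10
_DISP_FLOOR = 1e-8
_DISP_CEIL = 20.0


@dataclass
class DEResult:
    """Per-gene test results for one two-group contrast.

    ``table`` is indexed by gene id with columns ``log2fc``, ``pvalue``,
    ``padj``, ``base_mean``, ``status`` and ``is_deg``.  ``log2fc`` is the
    alternative group relative to the reference group (T2 vs T1, or M vs F).
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    sex: str | None = None
    platform: str = ""
    params: dict = field(default_factory=dict)

    @property
    def tested(self) -> pd.Series:
        return self.table["status"] == STATUS_TESTED

    @property
    def n_deg(self) -> int:
        return int(self.table["is_deg"].sum())

    def write(self, path) -> None:
        out = self.table.copy()
        out["is_deg"] = out["is_deg"].astype(bool)
        out.rename_axis("gene_id").to_csv(path, sep="\t")


def read_de_result(path) -> DEResult:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    table.index = table.index.astype(str)
    table["is_deg"] = table["is_deg"].astype(bool)
    return DEResult(table=table, contrast=("?", "?"))


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def estimate_size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors.

    The reference per gene is the geometric mean across samples, computed on
    zero-free rows only; each sample's factor is the median ratio of its
    counts to that reference.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValidationError("counts must be a 2-D matrix")
    if mat.shape[1] == 1:
        return np.ones(1)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValidationError("no zero-free gene rows; cannot estimate size factors")
    ref_rows = mat[positive]
    log_geomean = np.log(ref_rows).mean(axis=1)
    log_ratios = np.log(ref_rows) - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return factors


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjustment; NaN entries pass through and do not count in m."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[mask] = result
    return out


# ---------------------------------------------------------------------------
# moderated t (intensity platform)
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on y -> trigamma(y) = x
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the scaled inverse-chi-square prior (d0, s0^2) for gene variances.

    Matches the mean and variance of log(s2) against the theoretical moments
    of a scaled F distribution; returns (inf, geometric-style mean) when the
    excess spread is non-positive.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        warnings.warn("too few positive variances; using d0=inf", stacklevel=2)
        s0sq = float(np.mean(s2[ok])) if ok.any() else 0.0
        return math.inf, s0sq
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0sq = math.exp(emean)
    if math.isnan(d0) or d0 <= 0:  # d0 = inf is a valid homogeneous-variance fit
        warnings.warn("non-finite prior df; falling back to d0=inf", stacklevel=2)
        d0, s0sq = math.inf, math.exp(emean)
    return d0, s0sq


def moderated_t_core(
    matrix: pd.DataFrame,
    cols_ref: Sequence[str],
    cols_alt: Sequence[str],
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group t-test on log2 values, alt relative to ref.

    ``prior_df`` overrides the fitted prior degrees of freedom: 0 recovers
    the ordinary pooled t, inf fully shrinks to the common variance.
    """
    n1, n2 = len(cols_ref), len(cols_alt)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >=2 samples")
    x1 = matrix[list(cols_ref)].to_numpy(dtype=float)
    x2 = matrix[list(cols_alt)].to_numpy(dtype=float)
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    log2fc = mean2 - mean1
    df_resid = n1 + n2 - 2
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(
        axis=1
    )
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0sq = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        if d0 > 0 and (s2 > 0).any():
            # bias-corrected location of log s2 (chi-square log-moment offset)
            s0sq = float(
                np.exp(
                    np.log(s2[s2 > 0]).mean()
                    - special.digamma(df_resid / 2.0)
                    + math.log(df_resid / 2.0)
                )
            )
        else:
            s0sq = 0.0

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    tstat = np.full(len(matrix), np.nan)
    pval = np.full(len(matrix), np.nan)
    status = np.full(len(matrix), STATUS_TESTED, dtype=object)

    degenerate = se == 0
    usable = ~degenerate
    tstat[usable] = log2fc[usable] / se[usable]
    pval[usable] = 2.0 * stats.t.sf(np.abs(tstat[usable]), df=df_total)
    # zero posterior variance: t undefined unless the difference is also zero
    zero_diff = degenerate & (log2fc == 0)
    tstat[zero_diff] = 0.0
    pval[zero_diff] = 1.0
    status[degenerate & ~zero_diff] = STATUS_UNTESTED

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "tstat": tstat,
            "pvalue": pval,
            "padj": benjamini_hochberg(np.where(status == STATUS_TESTED, pval, np.nan)),
            "base_mean": np.concatenate([x1, x2], axis=1).mean(axis=1),
            "status": status,
            "is_deg": False,
        },
        index=matrix.index,
    )
    table.attrs["prior_df"] = d0
    table.attrs["prior_var"] = s0sq
    return table


def moderated_t_test(
    dataset: ExpressionDataset,
    sex: str,
    contrast: tuple[str, str] = ("T1", "T2"),
    prior_df: float | None = None,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    fc_scale: str = "log2",
) -> DEResult:
    """Within-sex stage contrast on an intensity dataset."""
    if dataset.platform != "intensity":
        raise ValidationError("moderated_t_test requires platform=intensity")
    cols_ref = dataset.sample_ids(sex=sex, stage=contrast[0])
    cols_alt = dataset.sample_ids(sex=sex, stage=contrast[1])
    table = moderated_t_core(dataset.values, cols_ref, cols_alt, prior_df=prior_df)
    result = DEResult(
        table=table,
        contrast=contrast,
        sex=sex,
        platform="intensity",
        params={"prior_df": table.attrs["prior_df"], "prior_var": table.attrs["prior_var"]},
    )
    return apply_deg_filter(result, fc_threshold=fc_threshold, alpha=alpha, fc_scale=fc_scale)


# ---------------------------------------------------------------------------
# negative-binomial Wald (counts platform)
# ---------------------------------------------------------------------------


def _fit_group_log_mean(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene MLE of eta where mu_j = s_j * exp(eta), NB dispersion alpha.

    Vectorized Newton iteration over genes; returns (eta, fisher_info).
    Genes with zero total count get eta = -inf and info 0.
    """
    y = np.asarray(y, dtype=float)
    total = y.sum(axis=1)
    eta = np.full(y.shape[0], -np.inf)
    pos = total > 0
    eta[pos] = np.log(total[pos] / s.sum())
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(eta[:, None])
        denom = 1.0 + a * mu
        score = ((y - mu) / denom).sum(axis=1)
        fisher = (mu * (1.0 + a * y) / denom**2).sum(axis=1)
        step = np.zeros_like(eta)
        np.divide(score, fisher, out=step, where=(fisher > 0) & pos)
        step = np.clip(step, -5.0, 5.0)
        eta = np.where(pos, eta + step, eta)
        if np.max(np.abs(step), initial=0.0) < 1e-12:
            break
    mu = s[None, :] * np.exp(eta[:, None])
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    info = np.where(pos, info, 0.0)
    return eta, info


def _moment_dispersion(
    q: np.ndarray, groups: list[np.ndarray], xi: float
) -> np.ndarray:
    """Method-of-moments dispersion from normalized counts, pooled over groups.

    For each group: alpha ~ (var(q) - mean(q)*xi) / mean(q)^2, where xi is the
    mean reciprocal size factor (the Poisson part on the normalized scale).
    Group estimates are df-weighted; output floored at ``_DISP_FLOOR``.
    """
    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    for idx in groups:
        sub = q[:, idx]
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        est = np.zeros(q.shape[0])
        ok = m > 0
        est[ok] = (v[ok] - m[ok] * xi) / m[ok] ** 2
        num += (n - 1) * est
        den += n - 1
    alpha = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return np.clip(alpha, _DISP_FLOOR, _DISP_CEIL)


def _fit_dispersion_trend(base_mean: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Robust fit of alpha(mu) = a1 + a0/mu on genes with informative estimates.

    Iteratively reweighted least squares on 1/mu with trimming of extreme
    ratios, in the spirit of parametric mean-dispersion trend fits.
    """
    use = (base_mean > 0) & (alpha_mom > _DISP_FLOOR * 10)
    if use.sum() < 10:
        return 0.0, float(np.median(alpha_mom[alpha_mom > 0]) if (alpha_mom > 0).any() else _DISP_FLOOR)
    x = 1.0 / base_mean[use]
    y = alpha_mom[use]
    # trim against the current fit BEFORE each refit so a single extreme
    # high-leverage gene cannot capture the intercept
    a0, a1 = 0.0, float(np.median(y))
    for _ in range(8):
        fitted = np.maximum(a0 * x + a1, _DISP_FLOOR)
        ratio = y / fitted
        keep = (ratio > 1e-4) & (ratio < 15.0)
        if keep.sum() < 10:
            break
        X = np.column_stack([x[keep], np.ones(keep.sum())])
        coef, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
        a0, a1 = max(float(coef[0]), 0.0), max(float(coef[1]), _DISP_FLOOR)
    return a0, a1


def _shrink_dispersion(
    alpha_mom: np.ndarray,
    base_mean: np.ndarray,
    df_resid: float,
    mode: str,
) -> np.ndarray:
    """Combine per-gene moment estimates with a fitted mean-dispersion trend.

    mode='gene' returns the raw per-gene estimates; 'trend' the fitted curve;
    'shrunk' an empirical-Bayes compromise in log space with weights set by
    the sampling variance of a log variance estimate at the residual df.
    """
    if mode == "gene":
        return alpha_mom
    a0, a1 = _fit_dispersion_trend(base_mean, alpha_mom)
    trend = np.clip(a0 / np.maximum(base_mean, 1e-8) + a1, _DISP_FLOOR, _DISP_CEIL)
    if mode == "trend":
        return trend
    if mode != "shrunk":
        raise ValidationError(f"unknown dispersion mode: {mode!r}")
    log_gene = np.log(np.maximum(alpha_mom, _DISP_FLOOR))
    log_trend = np.log(trend)
    samp_var = float(special.polygamma(1, max(df_resid, 1) / 2.0))
    resid = log_gene - log_trend
    prior_var = max(float(np.var(resid, ddof=1)) - samp_var, 0.0)
    w = prior_var / (prior_var + samp_var)  # weight on the per-gene estimate
    log_post = w * log_gene + (1.0 - w) * log_trend
    return np.clip(np.exp(log_post), _DISP_FLOOR, _DISP_CEIL)


def cooks_distances(
    counts: np.ndarray,
    groups: list[np.ndarray],
    size_factors: np.ndarray,
    group_log_means: list[np.ndarray],
    alpha: np.ndarray,
    n_coef: int = 2,
) -> np.ndarray:
    """Cook's distance per observation from the fitted group-mean NB GLM.

    D = r^2 * h / (p * (1-h)^2) with Pearson residual r, leverage h from the
    working weights within the observation's group, and p coefficients.
    """
    D = np.zeros_like(counts, dtype=float)
    for idx, eta in zip(groups, group_log_means):
        mu = size_factors[None, idx] * np.exp(eta[:, None])
        var = mu * (1.0 + alpha[:, None] * mu)
        w = mu / (1.0 + alpha[:, None] * mu)
        wsum = w.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            h = np.where(wsum > 0, w / wsum, 0.0)
            r = np.where(var > 0, (counts[:, idx] - mu) / np.sqrt(var), 0.0)
            D[:, idx] = r**2 * h / (n_coef * (1.0 - h) ** 2)
    return np.nan_to_num(D, nan=0.0, posinf=np.inf)


def cooks_outlier_flags(
    counts,
    groups: Sequence[Sequence[int]] | Sequence[str],
    cutoff: float = DEFAULT_COOKS_CUTOFF,
    size_factors: np.ndarray | None = None,
    dispersion: np.ndarray | None = None,
) -> np.ndarray:
    """Flag genes with any Cook's distance above ``cutoff``.

    Only samples in groups with >=3 replicates can trigger a flag (with two
    replicates an outlier cannot be told apart from its partner).  When the
    fit is not supplied, group means and moment dispersions are estimated
    from the normalized counts.
    """
    mat = np.asarray(counts, dtype=float)
    if len(groups) and isinstance(groups[0], str):
        labels = np.asarray(groups)
        idx_groups = [np.flatnonzero(labels == g) for g in pd.unique(labels)]
    else:
        idx_groups = [np.asarray(g, dtype=int) for g in groups]
    if size_factors is None:
        size_factors = estimate_size_factors(mat)
    q = mat / size_factors[None, :]
    if dispersion is None:
        xi = float(np.mean(1.0 / size_factors))
        dispersion = _moment_dispersion(q, idx_groups, xi)
    etas = []
    for idx in idx_groups:
        eta, _ = _fit_group_log_mean(mat[:, idx], size_factors[idx], dispersion)
        etas.append(eta)
    D = cooks_distances(mat, idx_groups, size_factors, etas, dispersion)
    flags = np.zeros(mat.shape[0], dtype=bool)
    for idx in idx_groups:
        if len(idx) >= 3:
            flags |= (D[:, idx] > cutoff).any(axis=1)
    return flags


def nb_wald_core(
    matrix: pd.DataFrame,
    cols_ref: Sequence[str],
    cols_alt: Sequence[str],
    cooks_cutoff: float | None = DEFAULT_COOKS_CUTOFF,
    if_alpha: float | None = DEFAULT_IF_ALPHA,
    min_total_count: int = DEFAULT_MIN_TOTAL_COUNT,
    dispersion_mode: str = "trend",
    size_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """NB Wald test of alt vs ref columns of a counts matrix.

    Returns the full result table (one row per input gene) with raw and
    BH-adjusted p-values, base means on the normalized scale, and status
    flags for untested, Cook's-outlier and low-expression-filtered genes.
    """
    cols_ref = list(cols_ref)
    cols_alt = list(cols_alt)
    cols = cols_ref + cols_alt
    counts = matrix[cols].to_numpy(dtype=float)
    n_genes = counts.shape[0]
    idx_ref = np.arange(len(cols_ref))
    idx_alt = np.arange(len(cols_ref), len(cols))
    groups = [idx_ref, idx_alt]

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    size_factors = np.asarray(size_factors, dtype=float)
    q = counts / size_factors[None, :]
    base_mean = q.mean(axis=1)

    status = np.full(n_genes, STATUS_TESTED, dtype=object)
    total = counts.sum(axis=1)
    zero_group = (counts[:, idx_ref].sum(axis=1) == 0) | (
        counts[:, idx_alt].sum(axis=1) == 0
    )
    status[zero_group] = STATUS_UNTESTED
    low = (total < min_total_count) & (status == STATUS_TESTED)
    status[low] = STATUS_LOW_EXPR

    testable = status == STATUS_TESTED

    xi = float(np.mean(1.0 / size_factors))
    alpha_mom = _moment_dispersion(q, groups, xi)
    df_resid = len(cols) - 2
    if testable.any():
        alpha_hat = alpha_mom.copy()
        alpha_hat[testable] = _shrink_dispersion(
            alpha_mom[testable], base_mean[testable], df_resid, dispersion_mode
        )
    else:
        alpha_hat = alpha_mom

    eta_ref, info_ref = _fit_group_log_mean(
        counts[:, idx_ref], size_factors[idx_ref], alpha_hat
    )
    eta_alt, info_alt = _fit_group_log_mean(
        counts[:, idx_alt], size_factors[idx_alt], alpha_hat
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(testable, eta_alt - eta_ref, np.nan)
        se = np.sqrt(1.0 / info_ref + 1.0 / info_alt)
        z = beta / se
    log2fc = np.where(testable, beta / LOG2, np.nan)
    pval = np.where(testable, 2.0 * stats.norm.sf(np.abs(z)), np.nan)

    if cooks_cutoff is not None:
        D = cooks_distances(
            counts, groups, size_factors, [eta_ref, eta_alt], alpha_hat
        )
        cooks_flag = np.zeros(n_genes, dtype=bool)
        for idx in groups:
            if len(idx) >= 3:
                cooks_flag |= (D[:, idx] > cooks_cutoff).any(axis=1)
        cooks_flag &= testable
        status[cooks_flag] = STATUS_COOKS
        pval[cooks_flag] = np.nan

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pval,
            "padj": np.nan,
            "base_mean": base_mean,
            "status": status,
            "is_deg": False,
        },
        index=matrix.index,
    )
    if if_alpha is not None:
        table = independent_filtering(table, if_alpha=if_alpha)
    else:
        tested = table["status"] == STATUS_TESTED
        table.loc[tested, "padj"] = benjamini_hochberg(
            table.loc[tested, "pvalue"].to_numpy()
        )
    return table


def nb_wald_test(
    dataset: ExpressionDataset,
    sex: str,
    contrast: tuple[str, str] = ("T1", "T2"),
    cooks_cutoff: float | None = DEFAULT_COOKS_CUTOFF,
    if_alpha: float | None = DEFAULT_IF_ALPHA,
    min_total_count: int = DEFAULT_MIN_TOTAL_COUNT,
    dispersion_mode: str = "trend",
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    fc_scale: str = "log2",
) -> DEResult:
    """Within-sex stage contrast on a counts dataset."""
    if dataset.platform != "counts":
        raise ValidationError("nb_wald_test requires platform=counts")
    cols_ref = dataset.sample_ids(sex=sex, stage=contrast[0])
    cols_alt = dataset.sample_ids(sex=sex, stage=contrast[1])
    table = nb_wald_core(
        dataset.values,
        cols_ref,
        cols_alt,
        cooks_cutoff=cooks_cutoff,
        if_alpha=if_alpha,
        min_total_count=min_total_count,
        dispersion_mode=dispersion_mode,
    )
    result = DEResult(
        table=table,
        contrast=contrast,
        sex=sex,
        platform="counts",
        params={
            "cooks_cutoff": cooks_cutoff,
            "if_alpha": if_alpha,
            "min_total_count": min_total_count,
            "dispersion_mode": dispersion_mode,
        },
    )
    return apply_deg_filter(result, fc_threshold=fc_threshold, alpha=alpha, fc_scale=fc_scale)


# ---------------------------------------------------------------------------
# independent filtering and DEG flagging
# ---------------------------------------------------------------------------


def independent_filtering(
    table: pd.DataFrame, if_alpha: float = DEFAULT_IF_ALPHA
) -> pd.DataFrame:
    """Choose the base-mean filter threshold maximizing BH rejections.

    Scans base-mean quantiles 0%, 1%, ..., 95% over the tested genes, picks
    the smallest threshold attaining the maximal number of BH rejections at
    ``if_alpha``, flags genes below it and computes final padj on the rest.
    """
    table = table.copy()
    tested = table["status"] == STATUS_TESTED
    if not tested.any():
        raise ValidationError("no tested genes for independent filtering")
    base = table.loc[tested, "base_mean"].to_numpy()
    pvals = table.loc[tested, "pvalue"].to_numpy()
    quantiles = np.arange(0.0, 0.96, 0.01)
    thresholds = np.quantile(base, quantiles)
    best_q, best_thr, best_rej = 0.0, thresholds[0], -1
    for qt, thr in zip(quantiles, thresholds):
        mask = base >= thr
        if not mask.any():
            continue
        padj = benjamini_hochberg(pvals[mask])
        rej = int((padj < if_alpha).sum())
        if rej > best_rej:
            best_q, best_thr, best_rej = qt, thr, rej
    keep = base >= best_thr
    tested_idx = table.index[tested]
    dropped = tested_idx[~keep]
    table.loc[dropped, "status"] = STATUS_LOW_EXPR
    table.loc[dropped, "padj"] = np.nan
    kept_idx = tested_idx[keep]
    table.loc[kept_idx, "padj"] = benjamini_hochberg(
        table.loc[kept_idx, "pvalue"].to_numpy()
    )
    table.attrs["if_theta_quantile"] = float(best_q)
    table.attrs["if_threshold"] = float(best_thr)
    table.attrs["if_rejections"] = int(best_rej)
    return table


def apply_deg_filter(
    result: DEResult,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    fc_scale: str = "log2",
) -> DEResult:
    """Set the DEG flag: tested, |log2FC| >= threshold and padj < alpha.

    ``fc_scale='linear'`` reinterprets the threshold as a linear fold change
    (log2 threshold = log2(fc_threshold)).
    """
    if fc_scale == "log2":
        thr = fc_threshold
    elif fc_scale == "linear":
        thr = math.log2(fc_threshold)
    else:
        raise ValidationError(f"fc_scale must be 'log2' or 'linear', got {fc_scale!r}")
    table = result.table
    tested = table["status"] == STATUS_TESTED
    with np.errstate(invalid="ignore"):
        is_deg = (
            tested
            & (table["log2fc"].abs() >= thr)
            & (table["padj"] < alpha)
            & table["padj"].notna()
        )
    table["is_deg"] = is_deg.fillna(False).astype(bool)
    result.params.update({"fc_threshold": fc_threshold, "alpha": alpha, "fc_scale": fc_scale})
    return result


def run_stage_contrast(
    dataset: ExpressionDataset,
    sex: str,
    contrast: tuple[str, str] = ("T1", "T2"),
    **options,
) -> DEResult:
    """Platform dispatch: moderated t for intensities, NB Wald for counts."""
    if dataset.platform == "intensity":
        allowed = {"prior_df", "fc_threshold", "alpha", "fc_scale"}
        opts = {k: v for k, v in options.items() if k in allowed}
        return moderated_t_test(dataset, sex, contrast=contrast, **opts)
    return nb_wald_test(dataset, sex, contrast=contrast, **options)
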