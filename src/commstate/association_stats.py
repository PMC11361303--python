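"""Log-ratio summaries and covariate-adjusted association testing.

Covers the composition-summary log ratios (Prevotella/Bacteroides and
Blautia/Bacteroides), per-metabolite multiple regression with Bonferroni
control and double-residualized ("covariate-adjusted") Spearman correlations,
sequential explained-variance decomposition, per-subject dissimilarity
regressions, and the shared nonparametric rank tests (Mann-Whitney,
Kruskal-Wallis, Dunn).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_tables import FeatureTable, FeatureTableError

logger = logging.getLogger("commstate")


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Log ratios
# ---------------------------------------------------------------------------

@dataclass
class RatioSeries:
    values: pd.Series  # sample_id -> log10((num + c)/(den + c))
    numerator: str
    denominator: str
    pseudocount: float


def log_ratio(
    t: FeatureTable, numerator: str, denominator: str, c: float = 1.0
) -> RatioSeries:
    """Per-sample log10((numerator + c) / (denominator + c)) from raw counts."""
    for g in (numerator, denominator):
        if g not in t.data.index:
            raise AssociationError(f"genus {g!r} not present in table")
    if c <= 0:
        raise AssociationError("pseudocount must be positive")
    num = t.data.loc[numerator].astype(float) + c
    den = t.data.loc[denominator].astype(float) + c
    vals = np.log10(num / den)
    return RatioSeries(values=vals.rename(f"log10_{numerator}_{denominator}"),
                       numerator=numerator, denominator=denominator, pseudocount=c)


# ---------------------------------------------------------------------------
# Covariate designs
# ---------------------------------------------------------------------------

DEFAULT_COVARIATES = ("sex", "race_ethnicity", "bmi", "timepoint")


def build_covariate_design(
    meta: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> pd.DataFrame:
    """One-hot covariate design (reference level dropped), indexed by sample_id.

    ``timepoint`` is treated as a 3-level categorical; numeric covariates pass
    through.  Rows with missing covariate values are dropped (complete case)
    and the count is logged.
    """
    meta = meta.loc[~meta.get("is_qc_pool", pd.Series(False, index=meta.index))]
    cols = {}
    for cov in covariates:
        if cov not in meta.columns:
            raise AssociationError(f"covariate {cov!r} missing from metadata")
        col = meta[cov]
        if cov == "timepoint" or not pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.astype("category")
        else:
            cols[cov] = col.astype(float)
    df = pd.DataFrame(cols)
    df.index = meta["sample_id"].to_numpy()
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("complete-case: dropped %d rows with missing covariates",
                    n0 - len(df))
    design = pd.get_dummies(df, drop_first=True, dtype=float)
    constant = design.columns[design.nunique() <= 1]
    if len(constant):
        logger.info("dropping constant covariate column(s): %s", list(constant))
        design = design.drop(columns=constant)
    return design


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        cur = np.empty((X.shape[0], 0))
        for j, name in enumerate(names):
            cand = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                aliased.append(name)
            else:
                cur = cand
        raise AssociationError(f"rank-deficient design; aliased columns: {aliased}")


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with coefficient SEs and two-sided t-test p-values."""
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    if dof <= 0:
        raise AssociationError("not enough observations for the design")
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    return beta, se, pvals, resid


# ---------------------------------------------------------------------------
# Per-feature adjusted associations
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    feature_id: str
    beta: float
    p: float
    p_adj: float
    rho: float
    n: int


def adjusted_feature_associations(
    y: RatioSeries, feats: FeatureTable, covariate_design: pd.DataFrame
) -> pd.DataFrame:
    """OLS of the ratio on [feature + covariates], per feature, with Bonferroni.

    Also reports a covariate-adjusted Spearman correlation: the Spearman
    correlation between the residuals of (ratio ~ covariates) and
    (feature ~ covariates).  Repeated subjects are treated as independent
    observations (the regression runs per sample).
    """
    common = y.values.index.intersection(feats.data.columns).intersection(
        covariate_design.index
    )
    if len(common) < covariate_design.shape[1] + 3:
        raise AssociationError("too few complete-case samples")
    yv = y.values.loc[common].to_numpy(dtype=float)
    C = covariate_design.loc[common].to_numpy(dtype=float)
    Xc = np.column_stack([np.ones(len(common)), C])
    names = ["intercept"] + list(covariate_design.columns)
    _check_full_rank(Xc, names)
    # residualize the ratio once
    _, _, _, y_resid = _ols(yv, Xc)

    F = feats.data[common].to_numpy(dtype=float)  # features x samples
    m = F.shape[0]
    rows = []
    for i, fid in enumerate(feats.feature_ids):
        f = F[i]
        X = np.column_stack([np.ones(len(common)), f, C])
        if np.std(f) == 0:
            rows.append(dict(feature_id=fid, beta=0.0, p=1.0, p_adj=1.0,
                             rho=0.0, n=len(common)))
            continue
        beta, _, pvals, _ = _ols(yv, X)
        _, _, _, f_resid = _ols(f, Xc)
        if np.std(f_resid) == 0 or np.std(y_resid) == 0:
            rho = 0.0
        else:
            rho = float(stats.spearmanr(y_resid, f_resid).statistic)
        rows.append(
            dict(
                feature_id=fid,
                beta=float(beta[1]),
                p=float(pvals[1]),
                p_adj=float(min(1.0, pvals[1] * m)),
                rho=rho,
                n=len(common),
            )
        )
    return pd.DataFrame(rows).set_index("feature_id")


def explained_variance(
    y: pd.Series, design_blocks: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Sequential (type-I) percent of total sum of squares per predictor block.

    Blocks enter in the given order; each block's share is the drop in
    residual SS when it is added, as a percent of the total SS.  The result is
    order-dependent, so the order is recorded in the output.
    """
    idx = y.index
    for blk in design_blocks.values():
        idx = idx.intersection(blk.index)
    yv = y.loc[idx].to_numpy(dtype=float)
    total_ss = float(((yv - yv.mean()) ** 2).sum())
    if total_ss == 0:
        raise AssociationError("outcome has zero variance")
    X = np.ones((len(idx), 1))
    prev_rss = total_ss
    rows = []
    for order, (name, blk) in enumerate(design_blocks.items(), start=1):
        X = np.column_stack([X, blk.loc[idx].to_numpy(dtype=float)])
        beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
        rss = float(((yv - X @ beta) ** 2).sum())
        rows.append(dict(predictor=name, order=order,
                         pct_variance=100.0 * (prev_rss - rss) / total_ss))
        prev_rss = rss
    rows.append(dict(predictor="residual", order=len(rows) + 1,
                     pct_variance=100.0 * prev_rss / total_ss))
    return pd.DataFrame(rows)


def dissimilarity_regressions(
    outcome: pd.Series, predictors: pd.DataFrame, bonferroni: bool = False
) -> pd.DataFrame:
    """Univariable OLS of a per-subject outcome on each predictor separately.

    The outcome is typically the sqrt-transformed median intra-individual
    Bray-Curtis dissimilarity; predictors are per-subject mean Shannon index
    and mean CLR core-genus values.  Betas are the per-predictor effect sizes.
    """
    common = outcome.index.intersection(predictors.index)
    if len(common) < 5:
        raise AssociationError("need at least 5 subjects")
    yv = outcome.loc[common].to_numpy(dtype=float)
    rows = []
    m = predictors.shape[1]
    for col in predictors.columns:
        x = predictors.loc[common, col].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(common)), x])
        beta, _, pvals, _ = _ols(yv, X)
        p = float(pvals[1])
        rows.append(dict(predictor=col, beta=float(beta[1]), p=p,
                         p_adj=float(min(1.0, p * m)) if bonferroni else p,
                         n=len(common)))
    return pd.DataFrame(rows).set_index("predictor")


# ---------------------------------------------------------------------------
# Rank tests (shared with the variance-layer comparisons)
# ---------------------------------------------------------------------------

def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided tie-corrected Mann-Whitney U; all-tied input gives p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise AssociationError("empty group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return len(a) * len(b) / 2.0, 1.0
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H across labeled groups."""
    vals = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(vals) < 2 or any(len(v) == 0 for v in vals):
        raise AssociationError("need >=2 non-empty groups")
    pooled = np.concatenate(vals)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*vals)
    return float(h), float(p)


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc pairwise z-tests on pooled ranks, Bonferroni adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),
    with tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(groups)
    if len(names) < 3:
        raise AssociationError("Dunn's test needs >=3 groups")
    vals = [np.asarray(groups[k], dtype=float) for k in names]
    if any(len(v) == 0 for v in vals):
        raise AssociationError("empty group")
    pooled = np.concatenate(vals)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(v) for v in vals]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - T
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            denom = var_base * (1.0 / sizes[i] + 1.0 / sizes[j])
            if denom <= 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom)
                p = 2 * stats.norm.sf(abs(z))
            rows.append(dict(group_a=names[i], group_b=names[j], z=float(z),
                             p=float(p), p_adj=float(min(1.0, p * n_pairs))))
    return pd.DataFrame(rows)


def rank_tests(groups: dict[str, np.ndarray], test: str):
    """Dispatch to mann_whitney, kruskal_wallis, or dunn."""
    if test == "mann_whitney":
        if len(groups) != 2:
            raise AssociationError("mann_whitney needs exactly 2 groups")
        a, b = groups.values()
        return mann_whitney(a, b)
    if test == "kruskal_wallis":
        return kruskal_wallis(groups)
    if test == "dunn":
        return dunn_test(groups)
    raise AssociationError(f"unknown test {test!r}")
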