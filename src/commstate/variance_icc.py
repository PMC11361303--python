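"""Per-feature variance decomposition, ICC, and cross-layer comparisons.

Each feature is decomposed with a one-way random-effects (repeated-measures)
ANOVA treating subjects as random: the intraclass correlation coefficient is

    ICC = inter-individual variance / (inter- + intra-individual variance)

estimated by method of moments.  With a balanced design (every subject
contributing the same number of samples) this coincides with the closed-form
balanced ANOVA solution and, asymptotically, with a mixed-model fit.
Layer-level comparisons of total variance, intra-individual variance, and ICC
use Kruskal-Wallis with Dunn's Bonferroni-adjusted post-hoc pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import dunn_test, kruskal_wallis
from .feature_tables import FeatureTable, FeatureTableError

logger = logging.getLogger("commstate")


class VarianceError(ValueError):
    pass


def variance_components(
    t: FeatureTable, meta: pd.DataFrame, estimator: str = "moments"
) -> pd.DataFrame:
    """One-way random-effects decomposition per feature.

    Expects values already on the layer's analysis scale (CLR for taxa and
    function, log10 for metabolites).  Subjects with a single sample are
    excluded (warned); fewer than 3 usable subjects is an error.  Negative
    moment estimates of the between-subject variance are truncated to zero
    (truncations are logged).

    Returns a DataFrame indexed by feature with columns ``layer``,
    ``inter_var``, ``intra_var``, ``total_var``, ``icc``, ``mean_abundance``.
    """
    if estimator != "moments":
        raise VarianceError(f"unknown estimator {estimator!r}")
    subj = meta.set_index("sample_id")["subject_id"]
    cols = [c for c in t.data.columns if c in subj.index]
    groups = subj.loc[cols]
    sizes = groups.value_counts()
    usable_subjects = sizes.index[sizes >= 2]
    dropped = sizes.index[sizes < 2]
    if len(dropped):
        logger.warning("variance_components: excluding %d single-sample subject(s)",
                       len(dropped))
    if len(usable_subjects) < 3:
        raise VarianceError("need at least 3 subjects with >=2 samples")
    keep_cols = [c for c in cols if groups.loc[c] in set(usable_subjects)]
    X = t.data[keep_cols].to_numpy(dtype=float)  # features x samples
    g = groups.loc[keep_cols].to_numpy()
    subjects, subj_idx = np.unique(g, return_inverse=True)
    I = len(subjects)
    N = X.shape[1]
    n_i = np.bincount(subj_idx)  # per-subject replicate counts

    # subject means per feature: features x subjects
    sums = np.zeros((X.shape[0], I))
    np.add.at(sums.T, subj_idx, X.T)
    means_i = sums / n_i[None, :]
    grand = X.mean(axis=1, keepdims=True)

    msb = ((n_i[None, :] * (means_i - grand) ** 2).sum(axis=1)) / (I - 1)
    ssw = ((X - means_i[:, subj_idx]) ** 2).sum(axis=1)
    msw = ssw / (N - I)
    n0 = (N - (n_i**2).sum() / N) / (I - 1)

    sigma_w = msw
    sigma_b = (msb - msw) / n0
    truncated = sigma_b < 0
    if truncated.any():
        logger.info("variance_components: truncated %d negative between-subject "
                    "variance estimate(s) to 0", int(truncated.sum()))
    sigma_b = np.maximum(sigma_b, 0.0)
    total = sigma_b + sigma_w
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(total > 0, sigma_b / total, 0.0)

    return pd.DataFrame(
        dict(
            layer=t.layer,
            inter_var=sigma_b,
            intra_var=sigma_w,
            total_var=total,
            icc=icc,
            mean_abundance=X.mean(axis=1),
        ),
        index=t.data.index,
    )


@dataclass
class LayerComparison:
    metric_tests: pd.DataFrame  # metric -> H, p
    dunn: pd.DataFrame  # metric, pair, z, p, p_adj
    medians: pd.DataFrame  # layer x metric medians


def compare_layers(vcs: pd.DataFrame) -> LayerComparison:
    """Kruskal-Wallis + Dunn comparisons of variance metrics across layers.

    ``vcs`` is the concatenation of per-layer ``variance_components`` outputs;
    all three layers (taxa, function, metabolome) must be present.
    """
    layers = sorted(vcs["layer"].unique())
    for required in ("taxa", "function", "metabolome"):
        if required not in layers:
            raise VarianceError(f"layer {required!r} missing")
    metrics = ("total_var", "intra_var", "icc")
    test_rows = []
    dunn_rows = []
    for metric in metrics:
        groups = {
            layer: vcs.loc[vcs["layer"] == layer, metric].to_numpy()
            for layer in ("taxa", "function", "metabolome")
        }
        if any(len(v) < 2 for v in groups.values()):
            raise VarianceError("need >=2 features per layer")
        h, p = kruskal_wallis(groups)
        test_rows.append(dict(metric=metric, H=h, p=p))
        d = dunn_test(groups)
        d.insert(0, "metric", metric)
        dunn_rows.append(d)
    medians = vcs.groupby("layer")[list(metrics)].median()
    return LayerComparison(
        metric_tests=pd.DataFrame(test_rows).set_index("metric"),
        dunn=pd.concat(dunn_rows, ignore_index=True),
        medians=medians,
    )


def abundance_variance_correlation(vcs: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of per-feature mean abundance vs intra-individual
    variance (on the layer's analysis scale).

    When the intra-individual variances are all tied the correlation is
    undefined; by convention (0.0, 1.0) is returned and the tie is logged.
    """
    if len(vcs) < 4:
        raise VarianceError("need at least 4 features")
    x = vcs["mean_abundance"].to_numpy(dtype=float)
    y = vcs["intra_var"].to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        logger.warning("abundance_variance_correlation: all-tied input; rho set to 0")
        return 0.0, 1.0
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
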