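"""Alpha diversity, pairwise dissimilarity, and intra-/inter-individual
partitioning of dissimilarities for longitudinal cohorts."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, spearmanr

from .feature_tables import FeatureTable, FeatureTableError

logger = logging.getLogger("commstate")

METRICS = ("bray_curtis", "canberra")


class DiversityError(ValueError):
    pass


def shannon_index(t: FeatureTable, log_base: float = np.e) -> pd.Series:
    """Shannon diversity H = -sum p_i log(p_i) per sample.

    Zero-count features contribute nothing.  Natural log by default; pass
    ``log_base=2`` for bits.  Rarefied input is recommended so depths are equal.
    """
    values = t.values()
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        sid = np.asarray(t.sample_ids)[totals <= 0][0]
        raise DiversityError(f"zero-total sample {sid!r}")
    p = values / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=0) / np.log(log_base)
    return pd.Series(h, index=t.sample_ids, name="shannon")


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.sample_ids):
            raise DiversityError("matrix shape does not match sample ids")
        if np.abs(m - m.T).max(initial=0.0) > 1e-12:
            raise DiversityError("matrix must be symmetric")
        if np.abs(np.diag(m)).max(initial=0.0) > 0:
            raise DiversityError("diagonal must be zero")
        if (m < 0).any():
            raise DiversityError("distances must be nonnegative")
        if self.metric == "bray_curtis" and m.max(initial=0.0) > 1 + 1e-12:
            raise DiversityError("Bray-Curtis values must lie in [0, 1]")

    def get(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)


def distance_matrix(t: FeatureTable, metric: str) -> DistanceMatrix:
    """Pairwise dissimilarities between samples.

    bray_curtis: sum|x-y| / sum(x+y); canberra: sum over features with
    x+y > 0 of |x-y|/(x+y).  Both delegate to scipy's pairwise kernels.
    """
    if metric not in METRICS:
        raise DiversityError(f"unknown metric {metric!r}")
    values = t.values().T  # samples x features
    totals = values.sum(axis=1)
    if (totals <= 0).sum() >= 1 and metric == "bray_curtis":
        sid = np.asarray(t.sample_ids)[totals <= 0][0]
        raise DiversityError(f"all-zero sample {sid!r}")
    scipy_metric = "braycurtis" if metric == "bray_curtis" else "canberra"
    condensed = pdist(values, metric=scipy_metric)
    mat = squareform(condensed)
    mat = np.nan_to_num(mat, nan=0.0)  # identical all-zero pairs (canberra)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(sample_ids=t.sample_ids, matrix=mat, metric=metric)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_distance_matrix(path: str | Path, metric: str) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(sample_ids=list(df.index.astype(str)),
                          matrix=df.to_numpy(dtype=float), metric=metric)


@dataclass
class DissimilarityPartition:
    """Off-diagonal pairs split into same-subject and cross-subject sets."""

    intra: np.ndarray
    inter: np.ndarray
    per_subject_median: pd.Series  # subject_id -> median intra dissimilarity
    per_subject_sqrt_median: pd.Series
    mannwhitney_u: float
    p_value: float


def partition_dissimilarity(dm: DistanceMatrix, meta: pd.DataFrame) -> DissimilarityPartition:
    """Split pairwise dissimilarities by shared subject and compare the sets.

    Returns the intra-individual (same subject) and inter-individual value
    sets — together exhaustive over the n(n-1)/2 off-diagonal pairs — the
    per-subject median intra value and its square root, and a two-sided
    Mann-Whitney U comparing intra vs inter.
    """
    subj = meta.set_index("sample_id")["subject_id"]
    missing = [s for s in dm.sample_ids if s not in subj.index]
    if missing:
        raise DiversityError(f"samples missing from metadata: {missing[:5]}")
    subjects = subj.loc[dm.sample_ids].to_numpy()
    n = len(dm.sample_ids)
    iu = np.triu_indices(n, k=1)
    vals = dm.matrix[iu]
    same = subjects[iu[0]] == subjects[iu[1]]
    intra = vals[same]
    inter = vals[~same]
    if len(intra) == 0:
        raise DiversityError("no intra-individual pairs (need repeated subjects)")

    med_rows = {}
    for s in np.unique(subjects):
        mask = same & (subjects[iu[0]] == s)
        if mask.any():
            med_rows[s] = float(np.median(vals[mask]))
    med = pd.Series(med_rows, name="median_intra")

    if np.ptp(np.concatenate([intra, inter])) == 0:
        u, p = len(intra) * len(inter) / 2.0, 1.0  # all ties: no evidence either way
    else:
        u, p = mannwhitneyu(intra, inter, alternative="two-sided")
    return DissimilarityPartition(
        intra=intra,
        inter=inter,
        per_subject_median=med,
        per_subject_sqrt_median=np.sqrt(med).rename("sqrt_median_intra"),
        mannwhitney_u=float(u),
        p_value=float(p),
    )


def delta_correlation(subject_deltas_a: pd.Series, subject_deltas_b: pd.Series):
    """Spearman rank correlation of paired per-subject change values.

    Used e.g. for correlating a subject's range of CLR genus abundance across
    timepoints against the matching range of a pathway's abundance.  Requires
    at least 4 paired subjects; ties get average ranks.
    """
    common = subject_deltas_a.index.intersection(subject_deltas_b.index)
    if len(common) < 4:
        raise DiversityError("need at least 4 paired subjects")
    rho, p = spearmanr(subject_deltas_a.loc[common], subject_deltas_b.loc[common])
    return float(rho), float(p)
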