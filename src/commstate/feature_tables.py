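"""Feature tables: the shared data model plus table-level filters and transforms.

A :class:`FeatureTable` wraps a feature-by-sample :class:`pandas.DataFrame` for
one omics layer (genus counts, inferred pathway abundances, or metabolite
intensities) together with a layer tag and a transform tag.  All downstream
stages (community typing, diversity, variance decomposition, associations)
consume these tables, so validation lives here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("commstate")

LAYERS = ("taxa", "function", "metabolome")
TRANSFORMS = ("raw", "rarefied", "clr", "relabund", "pareto_log")

#: Default thresholds used across the pipeline.
CORE_PREVALENCE_FRAC = 0.30
CORE_MIN_COUNT = 10
VARIANCE_PREVALENCE_FRAC = 0.10
RAREFACTION_DEPTH = 7600
QC_CV_MAX = 0.20
QC_PRESENCE_MIN = 0.80
CLR_PSEUDOCOUNT = 1.0

REQUIRED_META_COLUMNS = ("sample_id", "subject_id", "timepoint")


class FeatureTableError(ValueError):
    """Raised for invalid tables, metadata, or filter outcomes."""


@dataclass(frozen=True)
class FeatureTable:
    """One omics layer's features x samples matrix.

    Parameters
    ----------
    data:
        DataFrame with feature ids as the index and sample ids as columns.
    layer:
        One of ``taxa``, ``function``, ``metabolome``.
    transform_tag:
        One of ``raw``, ``rarefied``, ``clr``, ``relabund``, ``pareto_log``.
    """

    data: pd.DataFrame
    layer: str
    transform_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise FeatureTableError(f"unknown layer {self.layer!r}")
        if self.transform_tag not in TRANSFORMS:
            raise FeatureTableError(f"unknown transform {self.transform_tag!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FeatureTableError("non-numeric values in table")
        if not np.all(np.isfinite(values)):
            raise FeatureTableError("non-finite values in table")
        if self.transform_tag in ("raw", "rarefied", "relabund") and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FeatureTableError(
                f"negative value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.transform_tag == "clr":
            sums = values.sum(axis=0)
            if np.abs(sums).max(initial=0.0) > 1e-9:
                raise FeatureTableError("clr table does not sum to 0 per sample")

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        """Feature-major matrix (features x samples)."""
        return self.data.to_numpy(dtype=float)

    def counts(self) -> np.ndarray:
        """Integer count matrix; errors if the table is not integral."""
        values = self.data.to_numpy(dtype=float)
        rounded = np.rint(values)
        if not np.allclose(values, rounded):
            raise FeatureTableError("table does not hold integer counts")
        return rounded.astype(np.int64)

    def with_data(self, data: pd.DataFrame, transform_tag: str | None = None) -> "FeatureTable":
        return FeatureTable(
            data=data,
            layer=self.layer,
            transform_tag=self.transform_tag if transform_tag is None else transform_tag,
        )


def read_feature_table(
    path: str | Path, layer: str, samples_as_rows: bool = False
) -> FeatureTable:
    """Read a TSV feature table (feature ids in first column, sample ids in header).

    ``samples_as_rows=True`` accepts the transposed orientation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise FeatureTableError(
                f"non-numeric cell at feature {row!r}, sample {col!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy()][0]
            raise FeatureTableError(f"missing value at feature {row!r}, sample {col!r}")
        out[col] = converted
    out.index.name = None
    out.columns.name = None
    return FeatureTable(data=out, layer=layer)


def write_feature_table(t: FeatureTable, path: str | Path) -> None:
    """Write a TSV table; integer counts are written without decimal points."""
    df = t.data
    values = df.to_numpy(dtype=float)
    if t.transform_tag in ("raw", "rarefied") and np.allclose(values, np.rint(values)):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV and validate required columns and uniqueness."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise FeatureTableError(f"metadata missing required columns: {missing}")
    if "is_qc_pool" not in meta.columns:
        meta = meta.assign(is_qc_pool=False)
    meta = meta.copy()
    meta["is_qc_pool"] = meta["is_qc_pool"].astype(bool)
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FeatureTableError(f"duplicate sample_id in metadata: {dup!r}")
    non_qc = meta.loc[~meta["is_qc_pool"]]
    pair_dup = non_qc.duplicated(subset=["subject_id", "timepoint"])
    if pair_dup.any():
        row = non_qc.loc[pair_dup].iloc[0]
        raise FeatureTableError(
            "duplicate (subject_id, timepoint) pair: "
            f"({row['subject_id']!r}, {row['timepoint']!r})"
        )
    return meta


# ---------------------------------------------------------------------------
# Filters and transforms
# ---------------------------------------------------------------------------

def filter_core_features(
    t: FeatureTable,
    prevalence_frac: float = CORE_PREVALENCE_FRAC,
    min_count: float = CORE_MIN_COUNT,
) -> FeatureTable:
    """Keep features observed at >= ``min_count`` in at least
    ``ceil(prevalence_frac * n_samples)`` samples (boundary inclusive).

    Mirrors the core-taxa rule used before community typing: prevalent in at
    least 30% of samples with a minimum count of 10.
    """
    values = t.values()
    needed = math.ceil(prevalence_frac * t.n_samples)
    prevalent = (values >= min_count).sum(axis=1)
    keep = prevalent >= needed
    if not keep.any():
        raise FeatureTableError(
            "no features pass the core filter; lower prevalence_frac or min_count"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("core filter dropped %d/%d features", n_dropped, t.n_features)
    return t.with_data(t.data.loc[keep])


def rarefy(t: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (and logged).
    Uses multivariate hypergeometric draws, deterministic for a fixed seed.
    """
    if depth <= 0:
        raise FeatureTableError("rarefaction depth must be positive")
    if t.layer != "taxa":
        raise FeatureTableError("rarefaction applies to taxa count tables")
    counts = t.counts()
    totals = counts.sum(axis=0)
    rng = np.random.default_rng(seed)
    kept_cols: list[str] = []
    out_cols: list[np.ndarray] = []
    dropped: list[str] = []
    for j, sid in enumerate(t.sample_ids):
        if totals[j] < depth:
            dropped.append(sid)
            continue
        if totals[j] == depth:
            sub = counts[:, j]
        else:
            sub = rng.multivariate_hypergeometric(counts[:, j], depth)
        kept_cols.append(sid)
        out_cols.append(sub)
    if dropped:
        logger.info("rarefy dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    if not kept_cols:
        raise FeatureTableError("all samples below rarefaction depth")
    data = pd.DataFrame(
        np.column_stack(out_cols), index=t.data.index, columns=kept_cols
    )
    return t.with_data(data, transform_tag="rarefied")


def relative_abundance(t: FeatureTable) -> FeatureTable:
    """Per-sample proportions; errors on zero-total samples."""
    values = t.values()
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        sid = np.asarray(t.sample_ids)[totals <= 0][0]
        raise FeatureTableError(f"zero-total sample {sid!r}")
    return t.with_data(t.data / totals, transform_tag="relabund")


def clr_transform(t: FeatureTable, pseudocount: float = CLR_PSEUDOCOUNT) -> FeatureTable:
    """Centered log-ratio transform: log(x + c) centered per sample.

    The per-sample mean of log(x + c) is subtracted, so every output column
    sums to zero (to within 1e-9).
    """
    values = t.values()
    if pseudocount <= 0 and (values == 0).any():
        raise FeatureTableError("pseudocount must be > 0 when zeros are present")
    logged = np.log(values + pseudocount)
    centered = logged - logged.mean(axis=0, keepdims=True)
    data = pd.DataFrame(centered, index=t.data.index, columns=t.data.columns)
    return t.with_data(data, transform_tag="clr")


def qc_filter_metabolome(
    t: FeatureTable,
    qc_ids: Iterable[str],
    cv_max: float = QC_CV_MAX,
    presence_min: float = QC_PRESENCE_MIN,
) -> FeatureTable:
    """Keep metabolite features with CV < ``cv_max`` across QC pools and with
    nonzero intensity in strictly more than ``presence_min`` of study samples.

    QC pool samples are removed from the output. CV uses the sample SD (n-1).
    The presence denominator excludes QC pools.
    """
    if t.layer != "metabolome":
        raise FeatureTableError("QC filter applies to metabolome tables")
    qc_ids = [str(q) for q in qc_ids]
    missing = [q for q in qc_ids if q not in t.data.columns]
    if missing:
        raise FeatureTableError(f"QC sample ids not in table: {missing}")
    if len(qc_ids) < 2:
        raise FeatureTableError("need at least 2 QC pool samples")
    qc = t.data[qc_ids].to_numpy(dtype=float)
    study_cols = [c for c in t.data.columns if c not in set(qc_ids)]
    study = t.data[study_cols].to_numpy(dtype=float)

    qc_mean = qc.mean(axis=1)
    qc_sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(qc_mean > 0, qc_sd / qc_mean, np.inf)
    presence = (study > 0).mean(axis=1)
    keep = (cv < cv_max) & (presence > presence_min)
    if not keep.any():
        raise FeatureTableError("no metabolite features pass QC filtering")
    logger.info("QC filter retained %d/%d metabolite features",
                int(keep.sum()), t.n_features)
    data = t.data.loc[keep, study_cols]
    return t.with_data(data)


def pareto_log_transform(t: FeatureTable) -> FeatureTable:
    """log10(x + 1) then per-feature Pareto scaling: (y - mean) / sqrt(sd).

    Features with zero SD become all-zero (logged). SD is the sample SD (n-1).
    """
    if t.layer != "metabolome":
        raise FeatureTableError("Pareto/log transform applies to metabolome tables")
    y = np.log10(t.values() + 1.0)
    mean = y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0)
    if flat.any():
        logger.info("pareto_log: %d constant features set to zero", int(flat.sum()))
    scale = np.sqrt(np.where(sd > 0, sd, 1.0))
    out = np.where(sd > 0, (y - mean) / scale, 0.0)
    data = pd.DataFrame(out, index=t.data.index, columns=t.data.columns)
    return t.with_data(data, transform_tag="pareto_log")


def write_run_log(decisions: Mapping[str, object], path: str | Path) -> None:
    """Persist filter decisions (dropped samples/features, thresholds) as JSON."""
    Path(path).write_text(json.dumps(decisions, indent=2, default=str) + "\n")
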