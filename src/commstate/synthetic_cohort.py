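"""Synthetic longitudinal three-layer cohorts with known ground truth.

The generator emulates the structure of a dormitory-cohort gut-microbiome
study: ~93 subjects sampled at three timepoints, four discrete community
states (two Bacteroides-led, one Blautia-led, one Prevotella-led), genus
counts drawn from a Dirichlet-multinomial per state, an inferred-function
layer built as a noisy linear mixing of taxa, and a metabolome layer with
designed per-feature intraclass correlations plus replicate QC pools.

Because every layer is simulated from explicit parameters, downstream stages
(community typing, transition tests, variance decomposition, associations)
can be validated by parameter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_tables import FeatureTable, FeatureTableError

logger = logging.getLogger("commstate")

#: Genus indices 0..3 are the state-defining markers; index 4 is the optional
#: composition-stabilising genus used in dissimilarity-regression scenarios.
MARKER_GENERA = ("Bacteroides", "Bacteroides_B", "Blautia", "Prevotella")
STABILIZER_GENUS = "Faecalibacterium"

#: Median sequencing depth presets: small for fast tests, large mirroring
#: typical 16S study read depths.
DEPTH_MEDIAN_FAST = 5_000
DEPTH_MEDIAN_STUDY = 40_000


def _as_probs(p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
        raise FeatureTableError("baseline_probs must be a probability simplex")
    return p


@dataclass
class CohortConfig:
    """Generator parameters; defaults mirror the emulated study conditions.

    ``baseline_probs`` defaults to the observed baseline split 38/21/22/12 of
    93 subjects across the four states; ``stay_prob=0.72`` makes the chance of
    staying in the baseline state across both follow-ups ~0.52, i.e. about
    half of subjects experience at least one state shift.
    """

    n_subjects: int = 93
    n_timepoints: int = 3
    n_states: int = 4
    baseline_probs: Sequence[float] = (38 / 93, 21 / 93, 22 / 93, 12 / 93)
    stay_prob: float = 0.72
    transition_matrix: np.ndarray | None = None  # optional full K x K override
    n_genera: int = 60
    concentration: float = 50.0
    state_alphas: np.ndarray | None = None  # K x G; built from defaults if None
    depth_log_mean: float = float(np.log(DEPTH_MEDIAN_FAST))
    depth_log_sd: float = 0.3
    n_pathways: int = 120
    loading_noise_sd: float = 0.25
    n_metabolites: int = 200
    metabolome_icc_range: tuple[float, float] = (0.3, 0.9)
    metabolome_log_var: float = 0.04  # total per-feature variance on log10 scale
    n_qc_pools: int = 5
    qc_cv: float = 0.05
    stabilizer: bool = False  # subject-level composition stabiliser scenario
    seed: int = 0

    def __post_init__(self) -> None:
        probs = _as_probs(self.baseline_probs)
        if len(probs) != self.n_states:
            raise FeatureTableError("baseline_probs length must equal n_states")
        if not (0.0 < self.stay_prob < 1.0) and self.stay_prob != 1.0:
            raise FeatureTableError("stay_prob must lie in (0, 1]")
        if self.transition_matrix is not None:
            tm = np.asarray(self.transition_matrix, dtype=float)
            if tm.shape != (self.n_states, self.n_states):
                raise FeatureTableError("transition_matrix must be K x K")
            if (tm < 0).any() or np.abs(tm.sum(axis=1) - 1.0).max() > 1e-9:
                raise FeatureTableError("transition_matrix rows must be simplexes")


@dataclass
class CohortTruth:
    """Ground truth retained for recovery tests."""

    trajectories: pd.DataFrame  # subject_id x timepoint integer states (1-based)
    state_alphas: np.ndarray  # K x G
    pathway_loadings: np.ndarray  # n_pathways x G
    metabolite_icc: pd.Series  # feature_id -> designed ICC
    transition_matrix: np.ndarray  # K x K used for the state chain
    stabilizer_weight: pd.Series | None  # subject_id -> blend weight, if enabled
    seed: int


@dataclass
class Cohort:
    taxa: FeatureTable
    function: FeatureTable
    metabolome: FeatureTable
    metadata: pd.DataFrame
    truth: CohortTruth


def default_state_alphas(G: int, concentration: float = 50.0) -> np.ndarray:
    """Four Dirichlet parameter vectors with distinct dominant marker genera.

    State k's dominant marker (genus index k) carries 45% of the expected
    composition; a state-specific secondary block carries 10%; the remainder
    is spread evenly.  The dominant marker's expected relative abundance is
    therefore always more than 3x any non-marker genus.
    """
    if G < 8:
        raise FeatureTableError("need at least 8 genera for four marker states")
    n_states = 4
    block = max(1, G // 8)
    alphas = np.zeros((n_states, G))
    for k in range(n_states):
        mean = np.zeros(G)
        mean[k] = 0.45
        start = n_states + 1 + k * block  # skip markers and stabiliser slot
        sec = [(start + i) % G for i in range(block)]
        sec = [j for j in sec if j != k] or [(k + n_states) % G]
        mean[sec] += 0.10 / len(sec)
        rest = mean == 0
        mean[rest] = 0.45 / rest.sum()
        mean /= mean.sum()
        alphas[k] = mean * concentration
    if (alphas <= 0).any():
        raise FeatureTableError("internal error: non-positive alpha")
    return alphas


def genus_names(G: int) -> list[str]:
    names = list(MARKER_GENERA) + [STABILIZER_GENUS]
    names += [f"genus_{i:04d}" for i in range(len(names), G)]
    return names[:G]


def _transition_matrix(cfg: CohortConfig) -> np.ndarray:
    if cfg.transition_matrix is not None:
        return np.asarray(cfg.transition_matrix, dtype=float)
    K = cfg.n_states
    off = (1.0 - cfg.stay_prob) / (K - 1) if K > 1 else 0.0
    tm = np.full((K, K), off)
    np.fill_diagonal(tm, cfg.stay_prob if K > 1 else 1.0)
    return tm


def simulate_trajectories(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Subject state paths (n_subjects x n_timepoints), 0-based states."""
    probs = _as_probs(cfg.baseline_probs)
    tm = _transition_matrix(cfg)
    states = np.zeros((cfg.n_subjects, cfg.n_timepoints), dtype=int)
    states[:, 0] = rng.choice(cfg.n_states, size=cfg.n_subjects, p=probs)
    for t in range(1, cfg.n_timepoints):
        for i in range(cfg.n_subjects):
            states[i, t] = rng.choice(cfg.n_states, p=tm[states[i, t - 1]])
    return states


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Draw a full three-layer cohort plus metadata and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genera
    alphas = (
        np.asarray(cfg.state_alphas, dtype=float)
        if cfg.state_alphas is not None
        else default_state_alphas(G, cfg.concentration)
    )
    if alphas.shape != (cfg.n_states, G):
        raise FeatureTableError("state_alphas must be n_states x n_genera")
    if (alphas <= 0).any():
        raise FeatureTableError("state alphas must be strictly positive")

    states = simulate_trajectories(cfg, rng)
    genera = genus_names(G)
    stab_idx = genera.index(STABILIZER_GENUS) if STABILIZER_GENUS in genera else None

    stab_w = None
    if cfg.stabilizer:
        stab_w = rng.uniform(0.0, 1.0, size=cfg.n_subjects)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    taxa_cols: list[np.ndarray] = []
    props: list[np.ndarray] = []

    sexes = rng.choice(["female", "male"], size=cfg.n_subjects)
    races = rng.choice(["groupA", "groupB", "groupC"], size=cfg.n_subjects,
                       p=[0.5, 0.3, 0.2])
    bmis = rng.normal(24.0, 3.0, size=cfg.n_subjects).clip(16, 45)
    diet = rng.normal(0.0, 1.0, size=cfg.n_subjects)

    for i in range(cfg.n_subjects):
        base_p = None
        for t in range(cfg.n_timepoints):
            k = states[i, t]
            a = alphas[k].copy()
            if cfg.stabilizer and stab_idx is not None:
                a[stab_idx] *= 1.0 + 8.0 * stab_w[i]
            p = rng.dirichlet(a)
            if cfg.stabilizer:
                if base_p is None:
                    base_p = p
                else:
                    w = 0.8 * stab_w[i]
                    p = (1.0 - w) * p + w * base_p
            depth = int(np.round(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd)))
            depth = max(depth, 100)
            counts = rng.multinomial(depth, p)
            sid = f"S{i:03d}T{t + 1}"
            sample_ids.append(sid)
            taxa_cols.append(counts)
            props.append(counts / depth)
            meta_rows.append(
                dict(
                    sample_id=sid,
                    subject_id=f"subj{i:03d}",
                    timepoint=t + 1,
                    collection_day=int(t * 90 + rng.integers(0, 14)),
                    sex=sexes[i],
                    race_ethnicity=races[i],
                    bmi=float(np.round(bmis[i], 2)),
                    diet_score=float(np.round(diet[i], 3)),
                    is_qc_pool=False,
                )
            )

    taxa = FeatureTable(
        data=pd.DataFrame(np.column_stack(taxa_cols), index=genera, columns=sample_ids),
        layer="taxa",
    )

    # Function layer: sparse nonnegative mixing of genus relative abundances,
    # scaled to depth-like magnitude and perturbed by lognormal noise. Mixing
    # averages over genera, so per-feature cross-sample variance is lower than
    # in the taxa layer by construction.
    loadings = np.zeros((cfg.n_pathways, G))
    for m in range(cfg.n_pathways):
        support = rng.choice(G, size=min(10, G), replace=False)
        loadings[m, support] = rng.uniform(0.5, 1.5, size=len(support))
    prop_mat = np.column_stack(props)  # G x S
    noise = rng.lognormal(0.0, cfg.loading_noise_sd, size=(cfg.n_pathways, len(sample_ids)))
    func_vals = (loadings @ prop_mat) * 1e4 * noise
    function = FeatureTable(
        data=pd.DataFrame(
            func_vals,
            index=[f"pathway_{m:04d}" for m in range(cfg.n_pathways)],
            columns=sample_ids,
        ),
        layer="function",
    )

    # Metabolome: per-feature lognormal with subject random effect sized so the
    # between/(between+within) share on the log10 scale equals the drawn ICC.
    lo, hi = cfg.metabolome_icc_range
    icc = rng.uniform(lo, hi, size=cfg.n_metabolites)
    mu = rng.uniform(2.5, 4.5, size=cfg.n_metabolites)
    tau2 = cfg.metabolome_log_var
    sb = np.sqrt(icc * tau2)
    sw = np.sqrt((1.0 - icc) * tau2)
    b = rng.normal(0.0, 1.0, size=(cfg.n_metabolites, cfg.n_subjects)) * sb[:, None]
    met_names = [f"met_{m:04d}" for m in range(cfg.n_metabolites)]
    met_cols: dict[str, np.ndarray] = {}
    for i in range(cfg.n_subjects):
        for t in range(cfg.n_timepoints):
            e = rng.normal(0.0, 1.0, size=cfg.n_metabolites) * sw
            met_cols[f"S{i:03d}T{t + 1}"] = 10.0 ** (mu + b[:, i] + e)
    met = pd.DataFrame(met_cols, index=met_names)

    # QC pools: replicate injections around the global mean with CV qc_cv.
    global_mean = met.mean(axis=1).to_numpy()
    for q in range(cfg.n_qc_pools):
        z = rng.normal(0.0, 1.0, size=cfg.n_metabolites)
        qc_id = f"QC{q + 1:02d}"
        met[qc_id] = np.maximum(global_mean * (1.0 + cfg.qc_cv * z), 0.0)
        meta_rows.append(
            dict(
                sample_id=qc_id,
                subject_id="QC_POOL",
                timepoint=0,
                collection_day=0,
                sex="n/a",
                race_ethnicity="n/a",
                bmi=np.nan,
                diet_score=np.nan,
                is_qc_pool=True,
            )
        )
    metabolome = FeatureTable(data=met, layer="metabolome")

    metadata = pd.DataFrame(meta_rows)
    truth = CohortTruth(
        trajectories=pd.DataFrame(
            states + 1,
            index=[f"subj{i:03d}" for i in range(cfg.n_subjects)],
            columns=list(range(1, cfg.n_timepoints + 1)),
        ),
        state_alphas=alphas,
        pathway_loadings=loadings,
        metabolite_icc=pd.Series(icc, index=met_names),
        transition_matrix=_transition_matrix(cfg),
        stabilizer_weight=(
            pd.Series(stab_w, index=[f"subj{i:03d}" for i in range(cfg.n_subjects)])
            if stab_w is not None
            else None
        ),
        seed=cfg.seed,
    )
    return Cohort(taxa=taxa, function=function, metabolome=metabolome,
                  metadata=metadata, truth=truth)
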