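"""Community-state trajectories and the transition null model.

Builds per-subject state sequences from community assignments, classifies
stability, and tests whether observed state-to-state transitions deviate from
what the states' prevalences alone would predict: a chi-square goodness-of-fit
over all K^2 ordered (source, destination) categories with Pearson
standardized residuals flagged beyond +/-1.96.

The expected probability of an A-to-B transition is, by default, the number
of *possible* A-to-B pairings across consecutive timepoints divided by the
total number of possible pairings:

    P(A->B) = sum_t n_A(t) * n_B(t+1) / sum_t N_t * N_{t+1}

which accounts for the unequal distribution of samples across states.  A
``pooled_marginal`` mode (product of pooled state frequencies) is available
for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .diversity_distance import DistanceMatrix
from .dmm_typing import CommunityAssignment

logger = logging.getLogger("commstate")

RESIDUAL_CUTOFF = 1.96
EXPECTED_MODES = ("cross_pairing", "pooled_marginal")


class TransitionError(ValueError):
    pass


@dataclass
class Trajectory:
    subject_id: str
    states: tuple[int, ...]
    sample_ids: tuple[str, ...]

    @property
    def transitions(self) -> list[tuple[int, int]]:
        return list(zip(self.states[:-1], self.states[1:]))

    @property
    def is_stable(self) -> bool:
        return len(set(self.states)) == 1


def build_trajectories(
    assign: CommunityAssignment, meta: pd.DataFrame, timepoints: Sequence[int] = (1, 2, 3)
) -> list[Trajectory]:
    """One trajectory per subject with a complete set of assigned timepoints.

    Subjects missing any timepoint (or any assignment) are excluded and logged.
    Duplicate (subject, timepoint) pairs raise.
    """
    non_qc = meta.loc[~meta.get("is_qc_pool", pd.Series(False, index=meta.index))]
    dup = non_qc.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        row = non_qc.loc[dup].iloc[0]
        raise TransitionError(
            f"duplicate (subject, timepoint): ({row['subject_id']}, {row['timepoint']})"
        )
    labels = assign.labels
    trajectories: list[Trajectory] = []
    skipped = []
    for subject, grp in non_qc.groupby("subject_id", sort=True):
        by_tp = grp.set_index("timepoint")["sample_id"]
        if not all(tp in by_tp.index for tp in timepoints):
            skipped.append(subject)
            continue
        sids = tuple(str(by_tp.loc[tp]) for tp in timepoints)
        if not all(s in labels.index for s in sids):
            skipped.append(subject)
            continue
        states = tuple(int(labels.loc[s]) for s in sids)
        trajectories.append(Trajectory(subject_id=str(subject), states=states,
                                       sample_ids=sids))
    if skipped:
        logger.info("build_trajectories: excluded %d incomplete subject(s): %s",
                    len(skipped), skipped[:10])
    return trajectories


def classify_stability(trajs: Sequence[Trajectory]) -> pd.Series:
    """'stable-in-<state>' if all timepoints share one state, else 'shifted'."""
    out = {}
    for tr in trajs:
        out[tr.subject_id] = (
            f"stable-in-{tr.states[0]}" if tr.is_stable else "shifted"
        )
    s = pd.Series(out, name="stability")
    counts = s.value_counts()
    logger.info("stability classes: %s", counts.to_dict())
    return s


def _state_list(trajs: Sequence[Trajectory], states: Sequence[int] | None) -> list[int]:
    if states is not None:
        return sorted(int(s) for s in states)
    seen = sorted({s for tr in trajs for s in tr.states})
    return seen


def expected_transition_probabilities(
    trajs: Sequence[Trajectory],
    mode: str = "cross_pairing",
    states: Sequence[int] | None = None,
) -> pd.DataFrame:
    """K x K expected transition probabilities under the prevalence null.

    cross_pairing: P(A->B) proportional to the count of subjects in A at time t
    times the count in B at time t+1, summed over consecutive timepoint pairs.
    pooled_marginal: P(A->B) = f_A * f_B with f the pooled state frequency.
    """
    if mode not in EXPECTED_MODES:
        raise TransitionError(f"unknown mode {mode!r}")
    if not trajs or len(trajs[0].states) < 2:
        raise TransitionError("need at least one consecutive timepoint pair")
    state_set = _state_list(trajs, states)
    T = len(trajs[0].states)
    K = len(state_set)
    idx = {s: i for i, s in enumerate(state_set)}
    P = np.zeros((K, K))
    if mode == "cross_pairing":
        counts = np.zeros((T, K))
        for tr in trajs:
            for t, s in enumerate(tr.states):
                counts[t, idx[s]] += 1
        total = 0.0
        for t in range(T - 1):
            P += np.outer(counts[t], counts[t + 1])
            total += counts[t].sum() * counts[t + 1].sum()
        P /= total
    else:
        pooled = np.zeros(K)
        for tr in trajs:
            for s in tr.states:
                pooled[idx[s]] += 1
        f = pooled / pooled.sum()
        P = np.outer(f, f)
        P /= P.sum()
    return pd.DataFrame(P, index=state_set, columns=state_set)


@dataclass
class TransitionTally:
    """Observed/expected transition table with chi-square GOF diagnostics."""

    table: pd.DataFrame  # columns: source, dest, observed, expected_prob,
    #                       expected, residual, significant, low_expected
    chi2: float
    df: int
    p_value: float
    n_transitions: int
    mode: str


def transition_chisq(
    trajs: Sequence[Trajectory],
    expected_mode: str = "cross_pairing",
    states: Sequence[int] | None = None,
) -> TransitionTally:
    """Chi-square goodness-of-fit of observed vs prevalence-expected transitions.

    Runs over all K^2 ordered categories (16 for four states), df = K^2 - 1,
    with Pearson standardized residuals (O-E)/sqrt(E); |r| > 1.96 is flagged
    significant, and cells with E < 1 are flagged unreliable.
    """
    state_set = _state_list(trajs, states)
    K = len(state_set)
    idx = {s: i for i, s in enumerate(state_set)}
    O = np.zeros((K, K))
    for tr in trajs:
        for a, b in tr.transitions:
            O[idx[a], idx[b]] += 1
    n_trans = int(O.sum())
    if n_trans < 1:
        raise TransitionError("no transitions observed")
    P = expected_transition_probabilities(trajs, mode=expected_mode,
                                          states=state_set).to_numpy()
    E = P * n_trans
    if not (E > 0).any():
        raise TransitionError("all expected frequencies are zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(E > 0, (O - E) ** 2 / E, np.where(O > 0, np.inf, 0.0))
        resid = np.where(E > 0, (O - E) / np.sqrt(E), np.nan)
    stat = float(contrib.sum())
    df = K * K - 1
    p = float(chi2.sf(stat, df))
    rows = []
    for a in state_set:
        for b in state_set:
            i, j = idx[a], idx[b]
            rows.append(
                dict(
                    source=a,
                    dest=b,
                    observed=int(O[i, j]),
                    expected_prob=float(P[i, j]),
                    expected=float(E[i, j]),
                    residual=float(resid[i, j]) if np.isfinite(resid[i, j]) else np.nan,
                    significant=bool(np.isfinite(resid[i, j])
                                     and abs(resid[i, j]) > RESIDUAL_CUTOFF),
                    low_expected=bool(E[i, j] < 1),
                )
            )
    return TransitionTally(
        table=pd.DataFrame(rows),
        chi2=stat,
        df=df,
        p_value=p,
        n_transitions=n_trans,
        mode=expected_mode,
    )


def transition_dissimilarity(
    trajs: Sequence[Trajectory], dm: DistanceMatrix
) -> pd.DataFrame:
    """Median dissimilarity between source and destination samples per category.

    Reflects the compositional magnitude of each transition type; categories
    with no observed transitions are reported with NaN.
    """
    ids = set(dm.sample_ids)
    vals: dict[tuple[int, int], list[float]] = {}
    states = sorted({s for tr in trajs for s in tr.states})
    for tr in trajs:
        for t, (a, b) in enumerate(tr.transitions):
            sa, sb = tr.sample_ids[t], tr.sample_ids[t + 1]
            for s in (sa, sb):
                if s not in ids:
                    raise TransitionError(f"sample {s!r} missing from distance matrix")
            vals.setdefault((a, b), []).append(dm.get(sa, sb))
    rows = []
    for a in states:
        for b in states:
            v = vals.get((a, b), [])
            rows.append(dict(source=a, dest=b, n=len(v),
                             median_dissimilarity=float(np.median(v)) if v else np.nan))
    return pd.DataFrame(rows)


def empirical_markov(
    trajs: Sequence[Trajectory], states: Sequence[int] | None = None
) -> pd.DataFrame:
    """Row-normalized observed transition counts (the MLE transition matrix).

    Rows with no outgoing transitions are emitted as uniform and logged.
    """
    state_set = _state_list(trajs, states)
    K = len(state_set)
    idx = {s: i for i, s in enumerate(state_set)}
    C = np.zeros((K, K))
    for tr in trajs:
        for a, b in tr.transitions:
            C[idx[a], idx[b]] += 1
    if C.sum() < 1:
        raise TransitionError("no transitions observed")
    rowsum = C.sum(axis=1, keepdims=True)
    empty = rowsum[:, 0] == 0
    if empty.any():
        logger.warning("empirical_markov: %d state(s) with no outgoing transitions "
                       "emitted as uniform rows", int(empty.sum()))
    M = np.where(rowsum > 0, C / np.where(rowsum > 0, rowsum, 1), 1.0 / K)
    return pd.DataFrame(M, index=state_set, columns=state_set)
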