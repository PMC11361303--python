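"""Dirichlet-multinomial mixture (DMM) community typing.

Fits a finite mixture of Dirichlet-compound-multinomial components to a
core-genus count table by EM, scores each candidate number of components K
with a Laplace approximation to the negative log model evidence, and assigns
each sample to its maximum-responsibility community type.

Numerics
--------
All component densities are evaluated in log-gamma space.  Component
parameters are updated with a responsibility-weighted fixed-point iteration
(a generalized-EM step, so the negative log-likelihood is non-increasing
across iterations).  The evidence approximation works in log-alpha space, the
natural unconstrained parameterization for positive concentration parameters,
with a weak Normal(0, 10^2) prior on each log-concentration and mixture logit
so the marginal-likelihood integral is proper; the Hessian of the resulting
negative log posterior is computed analytically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp, polygamma, psi

from .feature_tables import FeatureTable, FeatureTableError, clr_transform

logger = logging.getLogger("commstate")

ALPHA_FLOOR = 1e-10
PRIOR_SD = 10.0  # weak prior on log-alphas and mixture logits


class DMMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dirichlet-multinomial density
# ---------------------------------------------------------------------------

def dm_log_likelihood(counts: np.ndarray, alpha: np.ndarray) -> float:
    """log DirMult(counts | alpha).

    = logG(A) - logG(N+A) + sum_j [logG(n_j + a_j) - logG(a_j)]
    with A = sum(alpha), N = sum(counts); evaluated with log-gamma so it is
    stable up to totals of ~1e6.
    """
    counts = np.asarray(counts, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if counts.shape != alpha.shape:
        raise DMMError("counts and alpha must have the same length")
    if (counts < 0).any():
        raise DMMError("counts must be nonnegative")
    if (alpha <= 0).any():
        raise DMMError("alpha must be strictly positive")
    N = counts.sum()
    if N <= 0:
        raise DMMError("counts must have positive total")
    A = alpha.sum()
    return float(
        gammaln(A) - gammaln(N + A) + (gammaln(counts + alpha) - gammaln(alpha)).sum()
    )


def _dm_loglik_matrix(X: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """S x K matrix of log DirMult(x_s | alpha_k)."""
    S = X.shape[0]
    K = alphas.shape[0]
    N = X.sum(axis=1)
    out = np.empty((S, K))
    for k in range(K):
        a = alphas[k]
        A = a.sum()
        out[:, k] = (
            gammaln(A)
            - gammaln(N + A)
            + (gammaln(X + a[None, :]) - gammaln(a)[None, :]).sum(axis=1)
        )
    return out


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------

@dataclass
class DMMFit:
    """Fitted mixture: weights, concentrations, responsibilities, diagnostics."""

    K: int
    weights: np.ndarray  # K
    alphas: np.ndarray  # K x G
    responsibilities: pd.DataFrame  # samples x K
    nll: float  # negative log-likelihood at the fitted mode
    nll_path: list[float]
    neg_log_evidence_laplace: float | None
    converged: bool
    n_iter: int
    seed: int
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise DMMError("mixture weights must sum to 1")
        if (self.alphas <= 0).any():
            raise DMMError("alphas must be positive")
        rows = self.responsibilities.to_numpy().sum(axis=1)
        if np.abs(rows - 1.0).max(initial=0.0) > 1e-9:
            raise DMMError("responsibility rows must sum to 1")


def _e_step(X: np.ndarray, weights: np.ndarray, alphas: np.ndarray):
    ll = _dm_loglik_matrix(X, alphas) + np.log(weights)[None, :]
    norm = logsumexp(ll, axis=1)
    r = np.exp(ll - norm[:, None])
    return r, -norm.sum()

def _weighted_alpha_update(
    X: np.ndarray, r_k: np.ndarray, alpha: np.ndarray,
    inner_iter: int = 25, inner_tol: float = 1e-6,
) -> np.ndarray:
    """Responsibility-weighted fixed-point update of one component's alphas.

    Each iteration multiplies alpha_j by the ratio of weighted digamma sums;
    this is a minorize-maximize step for the weighted DM log-likelihood.
    """
    N = X.sum(axis=1)
    w = r_k
    for _ in range(inner_iter):
        A = alpha.sum()
        num = (w[:, None] * (psi(X + alpha[None, :]) - psi(alpha)[None, :])).sum(axis=0)
        den = (w * (psi(N + A) - psi(A))).sum()
        if den <= 0:
            break
        new = alpha * num / den
        new = np.maximum(new, ALPHA_FLOOR)
        if np.max(np.abs(new - alpha) / np.maximum(alpha, 1e-8)) < inner_tol:
            alpha = new
            break
        alpha = new
    return alpha


def _init_alphas_from_labels(X: np.ndarray, labels: np.ndarray, K: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Moment-style initialization: per-cluster mean proportions x precision 20."""
    G = X.shape[1]
    props = (X + 0.5) / (X + 0.5).sum(axis=1, keepdims=True)
    alphas = np.empty((K, G))
    for k in range(K):
        mask = labels == k
        if not mask.any():
            mask = rng.choice(len(X), size=max(1, len(X) // K), replace=False)
            mean = props[mask].mean(axis=0)
        else:
            mean = props[mask].mean(axis=0)
        alphas[k] = np.maximum(mean, 1e-6) * 20.0
    return alphas


def fit_dmm(
    t: FeatureTable,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 5,
) -> DMMFit:
    """EM fit of a K-component Dirichlet-multinomial mixture to count data.

    The first restart seeds components by k-means on CLR-transformed
    proportions; the remaining restarts use random responsibilities.  The fit
    with the lowest negative log-likelihood is returned.
    """
    X = t.counts().T.astype(float)  # samples x features
    S, G = X.shape
    if S <= K:
        raise DMMError("need more samples than components")
    if (X.sum(axis=1) <= 0).any():
        raise DMMError("every sample must have a positive total count")

    best: DMMFit | None = None
    for restart in range(max(1, n_restarts)):
        rng = np.random.default_rng([seed, restart])
        if restart == 0 and K > 1:
            clr = clr_transform(t).values().T
            _, labels = kmeans2(clr, K, minit="++", seed=rng, missing="warn")
            alphas = _init_alphas_from_labels(X, labels, K, rng)
            weights = np.full(K, 1.0 / K)
        elif K == 1:
            alphas = _init_alphas_from_labels(X, np.zeros(S, dtype=int), 1, rng)
            weights = np.ones(1)
        else:
            r0 = rng.dirichlet(np.ones(K), size=S)
            labels = r0.argmax(axis=1)
            alphas = _init_alphas_from_labels(X, labels, K, rng)
            weights = np.full(K, 1.0 / K)

        nll_path: list[float] = []
        converged = False
        reinit_used = False
        it = 0
        for it in range(1, max_iter + 1):
            r, nll = _e_step(X, weights, alphas)
            nll_path.append(nll)
            # empty-component handling: reinitialize once, then drop
            small = r.sum(axis=0) / S < 1e-8
            if small.any():
                if not reinit_used:
                    reinit_used = True
                    for k in np.where(small)[0]:
                        pick = rng.integers(S)
                        alphas[k] = np.maximum(
                            (X[pick] + 0.5) / (X[pick] + 0.5).sum() * 20.0, 1e-6
                        )
                    weights = np.full(len(weights), 1.0 / len(weights))
                    logger.warning("re-initialized %d empty component(s)", small.sum())
                    continue
                keep = ~small
                logger.warning("dropping %d empty component(s)", small.sum())
                alphas = alphas[keep]
                weights = weights[keep] / weights[keep].sum()
                r, nll = _e_step(X, weights, alphas)
                nll_path.append(nll)
            weights = r.mean(axis=0)
            weights = np.maximum(weights, 1e-12)
            weights /= weights.sum()
            for k in range(len(weights)):
                alphas[k] = _weighted_alpha_update(X, r[:, k], alphas[k])
            if len(nll_path) >= 2:
                prev, cur = nll_path[-2], nll_path[-1]
                if abs(prev - cur) < tol * max(1.0, abs(prev)):
                    converged = True
                    break
        r, nll = _e_step(X, weights, alphas)
        nll_path.append(nll)
        if not converged:
            logger.warning("fit_dmm: K=%d restart %d hit max_iter", K, restart)
        fit = DMMFit(
            K=len(weights),
            weights=weights,
            alphas=alphas,
            responsibilities=pd.DataFrame(r, index=t.sample_ids),
            nll=nll,
            nll_path=nll_path,
            neg_log_evidence_laplace=None,
            converged=converged,
            n_iter=it,
            seed=seed,
            feature_ids=t.feature_ids,
        )
        if best is None or fit.nll < best.nll:
            best = fit
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Laplace evidence
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, K: int, G: int):
    beta = theta[: K * G].reshape(K, G)
    alphas = np.exp(beta)
    if K > 1:
        lam = np.concatenate([theta[K * G :], [0.0]])
        lam = lam - lam.max()
        w = np.exp(lam)
        weights = w / w.sum()
    else:
        weights = np.ones(1)
    return alphas, weights


def neg_log_posterior(theta: np.ndarray, X: np.ndarray, K: int) -> float:
    """NLL of the mixture plus the weak Normal prior, in (log-alpha, logit) space."""
    G = X.shape[1]
    alphas, weights = _unpack(theta, K, G)
    ll = _dm_loglik_matrix(X, alphas) + np.log(weights)[None, :]
    nll = -logsumexp(ll, axis=1).sum()
    d = len(theta)
    prior = 0.5 * np.sum(theta**2) / PRIOR_SD**2 + 0.5 * d * np.log(
        2 * np.pi * PRIOR_SD**2
    )
    return float(nll + prior)


def _grad_neg_log_posterior(theta: np.ndarray, X: np.ndarray, K: int) -> np.ndarray:
    G = X.shape[1]
    S = X.shape[0]
    alphas, weights = _unpack(theta, K, G)
    ll = _dm_loglik_matrix(X, alphas) + np.log(weights)[None, :]
    norm = logsumexp(ll, axis=1)
    r = np.exp(ll - norm[:, None])  # S x K
    N = X.sum(axis=1)
    grad = np.zeros_like(theta)
    for k in range(K):
        a = alphas[k]
        A = a.sum()
        # d log g_k / d beta_kj, per sample
        u = a[None, :] * (
            psi(X + a[None, :]) - psi(a)[None, :] + psi(A) - psi(N + A)[:, None]
        )
        grad[k * G : (k + 1) * G] = -(r[:, k][:, None] * u).sum(axis=0)
    if K > 1:
        grad[K * G :] = -(r[:, : K - 1] - weights[None, : K - 1]).sum(axis=0)
    grad += theta / PRIOR_SD**2
    return grad


def _hessian_neg_log_posterior(theta: np.ndarray, X: np.ndarray, K: int) -> np.ndarray:
    """Exact Hessian of the negative log posterior.

    Uses the mixture identity
        H[log p_s] = sum_k r_sk H[h_k] + sum_k r_sk g_sk g_sk' - gbar gbar'
    with h_k = log pi_k + log g_k, evaluated per sample and accumulated.
    """
    G = X.shape[1]
    S = X.shape[0]
    d = len(theta)
    alphas, weights = _unpack(theta, K, G)
    ll = _dm_loglik_matrix(X, alphas) + np.log(weights)[None, :]
    norm = logsumexp(ll, axis=1)
    r = np.exp(ll - norm[:, None])
    N = X.sum(axis=1)

    # per-component per-sample gradient blocks u[s,k,:] in beta space
    U = np.empty((S, K, G))
    dig_terms = np.empty((S, K, G))  # psi'(x+a) - psi'(a), for H diag
    constA = np.empty((K, 2))  # psi'(A), and per-sample psi'(N+A) handled below
    triA = np.empty((S, K))  # psi'(A) - psi'(N+A)
    for k in range(K):
        a = alphas[k]
        A = a.sum()
        base = psi(X + a[None, :]) - psi(a)[None, :]
        U[:, k, :] = a[None, :] * (base + psi(A) - psi(N + A)[:, None])
        dig_terms[:, k, :] = polygamma(1, X + a[None, :]) - polygamma(1, a)[None, :]
        triA[:, k] = polygamma(1, A) - polygamma(1, N + A)

    # lambda-block gradient of log pi_k (independent of s)
    if K > 1:
        V = np.zeros((K, K - 1))
        for k in range(K):
            V[k] = (np.arange(K - 1) == k).astype(float) - weights[: K - 1]
        Lam = -(np.diag(weights[: K - 1]) - np.outer(weights[: K - 1], weights[: K - 1]))
    H_logp = np.zeros((d, d))

    for s in range(S):
        Hs = np.zeros((d, d))
        gbar = np.zeros(d)
        for k in range(K):
            a = alphas[k]
            rk = r[s, k]
            sl = slice(k * G, (k + 1) * G)
            # H[h_k] beta block: outer(a,a)*triA + diag(a^2 * dig + u)
            blk = np.outer(a, a) * triA[s, k]
            blk[np.diag_indices(G)] += a**2 * dig_terms[s, k, :] + U[s, k, :]
            Hs[sl, sl] += rk * blk
            # gradient of h_k
            g = np.zeros(d)
            g[sl] = U[s, k, :]
            if K > 1:
                g[K * G :] = V[k]
            Hs += rk * np.outer(g, g)
            gbar += rk * g
        if K > 1:
            Hs[K * G :, K * G :] += Lam  # sum_k r_sk * Lam = Lam
        Hs -= np.outer(gbar, gbar)
        H_logp += Hs

    H = -H_logp
    H[np.diag_indices(d)] += 1.0 / PRIOR_SD**2
    return H


def laplace_neg_log_evidence(fit: DMMFit, t: FeatureTable,
                             refine: bool = True) -> float:
    """Laplace approximation to -log marginal likelihood of the fitted mixture.

    -log Z ~= f(theta*) - (d/2) log(2 pi) + 0.5 logdet H(theta*)
    where f is the negative log posterior in (log-alpha, mixture-logit)
    coordinates and theta* its mode (the EM solution, optionally refined by
    L-BFGS on f).  A non-positive-definite Hessian gets 1e-8 diagonal jitter.
    """
    X = t.counts().T.astype(float)
    K = fit.K
    G = X.shape[1]
    beta = np.log(np.maximum(fit.alphas, ALPHA_FLOOR)).ravel()
    if K > 1:
        w = np.maximum(fit.weights, 1e-12)
        lam = np.log(w[:-1]) - np.log(w[-1])
        theta = np.concatenate([beta, lam])
    else:
        theta = beta
    if refine:
        res = minimize(
            neg_log_posterior,
            theta,
            args=(X, K),
            jac=_grad_neg_log_posterior,
            method="L-BFGS-B",
            options=dict(maxiter=300, ftol=1e-12, gtol=1e-8),
        )
        theta = res.x
    f_mode = neg_log_posterior(theta, X, K)
    H = _hessian_neg_log_posterior(theta, X, K)
    d = len(theta)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(logdet):
        logger.warning("laplace: non-PD Hessian; adding 1e-8 jitter")
        H = H + 1e-8 * np.eye(d)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            # escalate jitter until PD; keeps the value finite and logged
            jit = 1e-6
            while sign <= 0 and jit < 1.0:
                sign, logdet = np.linalg.slogdet(H + jit * np.eye(d))
                jit *= 10
    return float(f_mode - 0.5 * d * np.log(2 * np.pi) + 0.5 * logdet)


# ---------------------------------------------------------------------------
# Model selection and assignment
# ---------------------------------------------------------------------------

def select_k(
    t: FeatureTable,
    k_range: Iterable[int] = range(1, 8),
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 5,
) -> tuple[DMMFit, pd.DataFrame]:
    """Fit every K in ``k_range`` and return the fit minimizing the Laplace
    negative log evidence, together with the full evidence-vs-K table.

    Ties closer than 1e-6 resolve to the smaller K.
    """
    rows = []
    fits: dict[int, DMMFit] = {}
    for K in k_range:
        fit = fit_dmm(t, K, seed=seed, tol=tol, max_iter=max_iter,
                      n_restarts=n_restarts)
        ev = laplace_neg_log_evidence(fit, t)
        fit.neg_log_evidence_laplace = ev
        fits[K] = fit
        rows.append(dict(K=K, fitted_K=fit.K, nll=fit.nll,
                         neg_log_evidence=ev, converged=fit.converged))
        logger.info("select_k: K=%d evidence=%.3f", K, ev)
    table = pd.DataFrame(rows)
    if table.empty:
        raise DMMError("empty k_range")
    best_ev = table["neg_log_evidence"].min()
    candidates = table.loc[table["neg_log_evidence"] <= best_ev + 1e-6, "K"]
    best_k = int(candidates.min())
    return fits[best_k], table


@dataclass
class CommunityAssignment:
    """Per-sample community type (1-based) and its posterior probability."""

    labels: pd.Series  # sample_id -> int state label in 1..K
    posterior: pd.Series  # sample_id -> max responsibility
    K: int


def assign_types(fit: DMMFit) -> CommunityAssignment:
    """Argmax-responsibility assignment; exact ties break to the lowest label."""
    r = fit.responsibilities.to_numpy()
    labels = r.argmax(axis=1)  # argmax already takes the first (lowest) on ties
    ties = (r == r.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("assign_types: %d tied sample(s) broken to lowest label",
                    int(ties.sum()))
    idx = fit.responsibilities.index
    return CommunityAssignment(
        labels=pd.Series(labels + 1, index=idx, name="state"),
        posterior=pd.Series(r.max(axis=1), index=idx, name="posterior"),
        K=fit.K,
    )


def match_labels(true_labels: pd.Series, predicted: pd.Series) -> float:
    """Best label-permutation agreement between two integer labelings."""
    from itertools import permutations

    common = true_labels.index.intersection(predicted.index)
    a = true_labels.loc[common].to_numpy()
    b = predicted.loc[common].to_numpy()
    states_a = np.unique(a)
    states_b = np.unique(b)
    k = max(len(states_a), len(states_b))
    if k > 8:
        raise DMMError("too many states for exhaustive permutation matching")
    all_states = np.unique(np.concatenate([states_a, states_b]))
    best = 0.0
    for perm in permutations(all_states):
        mapping = dict(zip(all_states, perm))
        acc = np.mean([mapping[x] == y for x, y in zip(b, a)])
        best = max(best, float(acc))
    return best
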