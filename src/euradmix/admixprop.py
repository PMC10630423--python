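"""Genome-wide ancestry estimation by binomial-likelihood clustering.

The model is the one behind ADMIXTURE/FRAPPE/STRUCTURE: each individual's
genotype at SNP ``s`` is Binomial(2, f_is) with ``f_is = Σ_k q_ik p_ks``,
``Q`` the individual ancestry fractions (simplex rows) and ``P`` the cluster
allele frequencies. Fitting is by alternating EM updates of Q and P
(FRAPPE-style), which monotonically increases the log-likelihood to the same
stationary points ADMIXTURE's block-relaxation reaches. Supervised mode
fixes the Q rows of labeled reference individuals to unit vectors so they
inform P only. The number of clusters is chosen by cross-validation:
genotype entries are masked at random, the model is fit on the rest, and
masked entries are scored by binomial deviance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .genio import MISSING, GenotypeSet

__all__ = ["AdmixtureModel", "fit_admixture", "cross_validate_k", "align_labels"]

P_EPS = 1e-6


@dataclass
class AdmixtureModel:
    Q: np.ndarray  # (n, K) simplex rows
    P: np.ndarray  # (K, S) in [P_EPS, 1-P_EPS]
    loglik: float
    K: int
    converged: bool
    iterations: int


def _loglik(G, mask, Q, P):
    F = np.clip(Q @ P, 1e-12, 1 - 1e-12)
    ll = np.where(mask, G * np.log(F) + (2 - G) * np.log1p(-F), 0.0)
    return float(ll.sum())


def fit_admixture(
    gset: GenotypeSet,
    K: int,
    supervised_labels=None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> AdmixtureModel:
    """Fit the K-cluster binomial admixture model by EM.

    ``supervised_labels``: optional per-sample array with ancestry codes in
    ``0..K-1`` for reference individuals and ``-1`` (or None entries) for
    samples whose ancestry is to be estimated; labeled rows of Q are fixed
    to unit vectors. Missing genotypes are excluded from the likelihood.
    Stops when the relative log-likelihood change drops below ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    G = gset.genotypes.astype(float)
    mask = gset.genotypes != MISSING
    G[~mask] = 0.0
    n, S = G.shape
    rng = np.random.default_rng(seed)

    fixed = np.zeros(n, dtype=bool)
    Q = rng.dirichlet(np.ones(K), size=n)
    if supervised_labels is not None:
        labels = np.array(
            [-1 if l is None else int(l) for l in supervised_labels], dtype=int
        )
        if labels.max() >= K or labels[labels >= 0].size and labels[labels >= 0].min() < 0:
            raise ValueError("supervised labels must lie in 0..K-1")
        fixed = labels >= 0
        Q[fixed] = np.eye(K)[labels[fixed]]

    # P initialized from perturbed sample frequencies
    with np.errstate(invalid="ignore"):
        base = np.where(mask, G, np.nan)
    p_hat = np.nanmean(base, axis=0) / 2.0
    p_hat = np.nan_to_num(p_hat, nan=0.5)
    P = np.clip(
        p_hat[None, :] + rng.normal(0, 0.05, size=(K, S)), P_EPS, 1 - P_EPS
    )

    two_minus = np.where(mask, 2.0 - G, 0.0)
    n_obs = 2.0 * mask.sum(axis=1)
    ll_old = _loglik(G, mask, Q, P)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        F = np.clip(Q @ P, 1e-12, 1 - 1e-12)
        A = np.where(mask, G / F, 0.0)
        B = two_minus / (1 - F)
        # E+M for P: expected ancestral allele counts
        num = P * (Q.T @ A)
        den = num + (1 - P) * (Q.T @ B)
        P = np.clip(np.where(den > 0, num / den, P), P_EPS, 1 - P_EPS)
        # E+M for Q (free rows only)
        F = np.clip(Q @ P, 1e-12, 1 - 1e-12)
        A = np.where(mask, G / F, 0.0)
        B = two_minus / (1 - F)
        Qnew = Q * (A @ P.T + B @ (1 - P).T) / n_obs[:, None]
        Qnew /= Qnew.sum(axis=1, keepdims=True)
        Q = np.where(fixed[:, None], Q, Qnew)
        ll = _loglik(G, mask, Q, P)
        if ll < ll_old - 1e-6 * max(abs(ll_old), 1.0):
            raise RuntimeError(f"EM log-likelihood decreased at iteration {it}")
        if abs(ll - ll_old) < tol * abs(ll_old):
            ll_old = ll
            converged = True
            break
        ll_old = ll
    return AdmixtureModel(
        Q=Q, P=P, loglik=ll_old, K=K, converged=converged, iterations=it
    )


def cross_validate_k(
    gset: GenotypeSet,
    k_range,
    folds: int = 5,
    holdout_frac: float = 0.1,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
):
    """Cross-validated binomial deviance as a function of K.

    Per fold, a random ``holdout_frac`` of genotype entries is masked, the
    model fit on the remainder, and held-out entries scored by mean binomial
    deviance under the fitted ``f_is``. Returns a dict {K: mean deviance};
    the most likely number of clusters is its argmin.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    G0 = gset.genotypes
    obs = G0 != MISSING
    n, S = G0.shape
    rng = np.random.default_rng(seed)
    cv = {k: [] for k in k_range}
    for fold in range(folds):
        hold = (rng.random(G0.shape) < holdout_frac) & obs
        if (obs & ~hold).sum(axis=1).min() == 0 or (obs & ~hold).sum(axis=0).min() == 0:
            raise ValueError("holdout masked an entire sample or SNP")
        masked = G0.copy()
        masked[hold] = MISSING
        train = GenotypeSet(masked, gset.variants, gset.samples)
        g = G0[hold].astype(float)
        for k in k_range:
            model = fit_admixture(
                train, k, seed=seed + 101 * fold, tol=tol, max_iter=max_iter
            )
            f = np.clip((model.Q @ model.P)[hold], 1e-9, 1 - 1e-9)
            dev = -2.0 * (g * np.log(f) + (2 - g) * np.log1p(-f))
            cv[k].append(dev.mean())
    return {k: float(np.mean(v)) for k, v in cv.items()}


def align_labels(model_a: AdmixtureModel, model_b: AdmixtureModel) -> tuple[int, ...]:
    """Cluster permutation mapping model_b onto model_a.

    Exhaustive search over K! permutations (K ≤ 6) minimizing the total
    absolute difference between P matrices; returns ``perm`` such that
    ``model_b.P[perm, :]`` matches ``model_a.P``.
    """
    if model_a.K != model_b.K:
        raise ValueError("models have different K")
    K = model_a.K
    if K > 6:
        raise ValueError("exhaustive alignment supported for K <= 6")
    best, best_cost = None, np.inf
    for perm in permutations(range(K)):
        cost = np.abs(model_a.P - model_b.P[list(perm)]).sum()
        if cost < best_cost:
            best, best_cost = perm, cost
    return best
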