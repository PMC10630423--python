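"""Population structure: PCA, projection, hull coverage, cluster counts.

PCA standardizes genotypes to unit Balding–Nichols variance
(``(g − 2p̂)/√(2p̂(1−p̂))``) so axes reflect drift rather than allele
frequency; target cohorts are projected onto a reference PC space with the
reference means/scales. Convex-hull coverage on PC1–PC2 measures how much of
a reference panel's diversity a target set spans; the Tibshirani gap
statistic estimates the number of clusters; Mantel's permutation test
compares distance matrices from competing PC spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint
from sklearn.cluster import KMeans

from .genio import MISSING, GenotypeSet

__all__ = [
    "PCModel",
    "pca_fit",
    "pca_project",
    "convex_hull_coverage",
    "gap_statistic",
    "mantel_test",
]


@dataclass
class PCModel:
    means: np.ndarray  # (S,) = 2*p_hat
    scales: np.ndarray  # (S,) = sqrt(2*p_hat*(1-p_hat))
    loadings: np.ndarray  # (S, d)
    scores: np.ndarray  # (n, d)
    pct_variance: np.ndarray  # (d,)


def _standardize(G: np.ndarray, means, scales, mean_impute: bool):
    X = G.astype(float)
    miss = G == MISSING
    if miss.any():
        if not mean_impute:
            raise ValueError("missing genotypes present; pass mean_impute=True")
        X[miss] = np.broadcast_to(means, X.shape)[miss]
    return (X - means) / scales


def pca_fit(gset: GenotypeSet, n_axes: int = 10, mean_impute: bool = False) -> PCModel:
    """PCA of the standardized genotype matrix.

    Sign convention: the largest-magnitude loading on each axis is positive,
    which makes fitted axes reproducible across runs and sample orderings.
    """
    n, S = gset.genotypes.shape
    if n_axes > min(n, S):
        raise ValueError("n_axes exceeds matrix rank bound")
    G = gset.genotypes
    miss = G == MISSING
    p_hat = np.where(
        miss.all(axis=0), 0.5, np.ma.masked_equal(G, MISSING).mean(axis=0) / 2.0
    )
    means = 2.0 * np.asarray(p_hat, dtype=float)
    scales = np.sqrt(np.maximum(means * (1 - means / 2), 1e-12))
    X = _standardize(G, means, scales, mean_impute=True if miss.any() else mean_impute)
    Xc = X - X.mean(axis=0)
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:n_axes].T
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(n_axes)])
    V = V * flip
    scores = Xc @ V
    var = sv**2
    pct = var[:n_axes] / var.sum() * 100.0
    return PCModel(means=means, scales=scales, loadings=V, scores=scores, pct_variance=pct)


def pca_project(targets: GenotypeSet, model: PCModel) -> np.ndarray:
    """Project a target cohort onto a fitted reference PC space.

    Targets are standardized with the *reference* means and scales, so
    reference samples projected onto their own model reproduce their scores.
    """
    if targets.n_variants != model.means.size:
        raise ValueError("target SNP set does not match the fitted model")
    X = _standardize(targets.genotypes, model.means, model.scales, mean_impute=True)
    # the fit centers standardized columns; their mean is 0 by construction
    return X @ model.loadings


def convex_hull_coverage(
    ref_scores: np.ndarray, target_scores: np.ndarray, mode: str = "intersection"
) -> float:
    """Fraction of the reference PC1–PC2 hull covered by the target hull.

    ``intersection`` (default): area(hull(target) ∩ hull(ref)) / area(hull(ref)),
    bounded at 1. ``ratio``: raw area(hull(target)) / area(hull(ref)), which
    can exceed 1 for targets spilling outside the reference.
    """
    ref = MultiPoint([tuple(p) for p in np.asarray(ref_scores)[:, :2]]).convex_hull
    tgt = MultiPoint([tuple(p) for p in np.asarray(target_scores)[:, :2]]).convex_hull
    if ref.area == 0:
        raise ValueError("degenerate (collinear) reference hull")
    if mode == "intersection":
        return float(ref.intersection(tgt).area / ref.area)
    if mode == "ratio":
        return float(tgt.area / ref.area)
    raise ValueError("mode must be 'intersection' or 'ratio'")


def _wk(points: np.ndarray, k: int, seed: int) -> float:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(points)
    return float(km.inertia_)


def gap_statistic(
    points: np.ndarray, k_max: int, n_ref: int = 50, seed: int = 0
):
    """Tibshirani gap statistic for the number of clusters.

    Reference sets are uniform over the bounding box of the data rotated to
    its principal axes. Returns ``(best_k, gap, s_k)`` where ``best_k`` is
    the smallest k with ``Gap(k) ≥ Gap(k+1) − s_{k+1}``.
    """
    points = np.asarray(points, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if len(points) < k_max:
        raise ValueError("fewer points than k_max")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)
    log_wk = np.array([np.log(_wk(points, k, seed)) for k in ks])

    center = points.mean(axis=0)
    _, _, Vt = np.linalg.svd(points - center, full_matrices=False)
    rot = (points - center) @ Vt.T
    lo, hi = rot.min(axis=0), rot.max(axis=0)
    ref_logs = np.empty((n_ref, k_max))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=rot.shape) @ Vt + center
        ref_logs[b] = [np.log(_wk(ref, k, seed)) for k in ks]
    gap = ref_logs.mean(axis=0) - log_wk
    sk = ref_logs.std(axis=0, ddof=0) * np.sqrt(1 + 1.0 / n_ref)
    best_k = int(ks[-1])
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            best_k = int(ks[i])
            break
    return best_k, gap, sk


def mantel_test(
    d1: np.ndarray, d2: np.ndarray, n_perm: int = 999, seed: int = 0
):
    """One-sided Mantel permutation test of two distance matrices.

    Pearson correlation of the upper triangles; p = (1 + #{perm ρ ≥ obs}) /
    (n_perm + 1) under simultaneous row/column permutations of ``d2``.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.shape[0] != d1.shape[1]:
        raise ValueError("distance matrices must be square and equal-sized")
    for d in (d1, d2):
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("inputs must be symmetric with zero diagonal")
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d1[iu]
    rng = np.random.default_rng(seed)

    def corr_with(mat):
        y = mat[iu]
        return np.corrcoef(x, y)[0, 1]

    obs = corr_with(d2)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(d2[np.ix_(perm, perm)]) >= obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return float(obs), float(p)
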