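"""Mixed-model association with a nested ladder of stratification controls.

The model is ``y = Xβ + u + ε`` with ``u ~ N(0, σg² K)`` for a genetic
relationship matrix (GRM) ``K`` and ``ε ~ N(0, σe² I)``. REML estimation
uses the EMMA spectral trick: one eigendecomposition of K, then a 1-D
search over the variance ratio δ = σg²/σe². The ML log-likelihood is also
computed so models differing in fixed effects can be compared by AIC.

The adjustment ladder mirrors standard stratification-control practice:
unadjusted OLS → GRM random effect → + reference-projected PCs → +
study-specific PCs → + locus-specific ancestry dosage (the covariate that
removes confounding at loci with extreme inter-ancestry frequency
differences, the lactase-persistence paradigm). Genomic-control λ summarizes
residual test-statistic inflation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genio import MISSING, GenotypeSet

__all__ = [
    "GRM",
    "AssocResult",
    "LMMFit",
    "compute_grm",
    "fit_lmm",
    "test_snp",
    "genomic_control_lambda",
    "nested_adjustment_scan",
]

CHI2_1_MEDIAN = 0.4549364231195724


@dataclass
class GRM:
    """Genetic relationship matrix with a cached eigendecomposition."""

    matrix: np.ndarray

    _eig: tuple | None = None

    def eig(self):
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.matrix)
            vals = np.clip(vals, 0.0, None)  # guard tiny negative eigenvalues
            self._eig = (vals, vecs)
        return self._eig


@dataclass
class AssocResult:
    beta: float
    se: float
    p: float
    adjustment: str
    loglik_ml: float
    aic: float
    n: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.959963984540054 * self.se, self.beta + 1.959963984540054 * self.se)


@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    sigma_g2: float
    sigma_e2: float
    loglik_reml: float
    loglik_ml: float
    df_resid: int

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0

    @property
    def aic(self) -> float:
        """AIC from the ML likelihood: 2k − 2ℓ, k = p fixed + 2 variance."""
        k = len(self.beta) + 2
        return 2 * k - 2 * self.loglik_ml


def compute_grm(gset: GenotypeSet, exclude: np.ndarray | None = None) -> GRM:
    """GRM = X Xᵀ / S from SNPs standardized by √(2p̂(1−p̂)).

    Monomorphic SNPs raise; ``exclude`` drops listed variant indices (e.g.
    the tested focal SNP) from the kinship estimate.
    """
    keep = np.ones(gset.n_variants, dtype=bool)
    if exclude is not None:
        keep[np.asarray(exclude)] = False
    G = gset.genotypes[:, keep].astype(float)
    miss = G == MISSING
    G[miss] = np.nan
    p = np.nanmean(G, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNPs included; filter them first")
    X = (np.where(np.isnan(G), 2 * p, G) - 2 * p) / np.sqrt(2 * p * (1 - p))
    return GRM(matrix=(X @ X.T) / X.shape[1])


def _rotated_fit(yt, Xt, svals, delta):
    w = 1.0 / (delta * svals + 1.0)
    XtW = Xt * w[:, None]
    xtx = XtW.T @ Xt
    beta = np.linalg.solve(xtx, XtW.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(w * r**2))
    return beta, rss, xtx


def _neg_reml(delta, yt, Xt, svals, logdet_xx0):
    n, p = Xt.shape
    _, rss, xtx = _rotated_fit(yt, Xt, svals, delta)
    sigma2 = rss / (n - p)
    ld_v = float(np.sum(np.log(delta * svals + 1.0)))
    sign, ld_xx = np.linalg.slogdet(xtx)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma2)
        + ld_v
        + ld_xx
        - logdet_xx0
        + (n - p)
    )
    return -ll


def fit_lmm(y: np.ndarray, covariates: np.ndarray, grm: GRM | None) -> LMMFit:
    """REML fit of the single-GRM linear mixed model.

    ``covariates`` is the full fixed-effect design matrix X (including the
    intercept column). With ``grm=None`` the model collapses to OLS
    (σg² = 0). Returns fixed effects with GLS standard errors, variance
    components, and both REML and ML log-likelihoods (the latter for AIC).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient fixed-effect design")

    if grm is None:
        svals = np.zeros(n)
        yt, Xt = y, X
        delta = 0.0
    else:
        svals, U = grm.eig()
        yt = U.T @ y
        Xt = U.T @ X
        sign, logdet_xx0 = np.linalg.slogdet(X.T @ X)
        res = minimize_scalar(
            lambda t: _neg_reml(np.exp(t), yt, Xt, svals, logdet_xx0),
            bounds=(np.log(1e-6), np.log(1e6)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        delta = float(np.exp(res.x))
        # collapse to exact OLS when the δ→0 boundary fits no worse
        if _neg_reml(1e-6, yt, Xt, svals, logdet_xx0) <= res.fun + 1e-9:
            delta = 0.0

    beta, rss, xtx = _rotated_fit(yt, Xt, svals, delta)
    sigma_e2 = rss / (n - p)
    cov = sigma_e2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))

    ld_v = float(np.sum(np.log(delta * svals + 1.0)))
    ll_reml = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma_e2) + ld_v + (n - p)
    )
    if grm is not None:
        sign, ld_xx = np.linalg.slogdet(xtx)
        sign0, ld0 = np.linalg.slogdet(X.T @ X)
        ll_reml -= 0.5 * (ld_xx - ld0)
    sigma_ml = rss / n
    ll_ml = -0.5 * (n * np.log(2 * np.pi * sigma_ml) + ld_v + n)
    return LMMFit(
        beta=beta,
        se=se,
        sigma_g2=delta * sigma_e2,
        sigma_e2=sigma_e2,
        loglik_reml=float(ll_reml),
        loglik_ml=float(ll_ml),
        df_resid=n - p,
    )


def test_snp(
    y: np.ndarray,
    base_covariates: np.ndarray | None,
    grm: GRM | None,
    snp_dosage: np.ndarray,
    local_dosage: np.ndarray | None = None,
    adjustment: str = "custom",
) -> AssocResult:
    """Wald test of one SNP's additive effect under the chosen adjustment.

    The design is [intercept | base_covariates | local_dosage | snp]; the
    reported coefficient is the SNP's. A SNP collinear with the covariates
    is reported as non-estimable (beta NaN, p 1.0) rather than raising.
    """
    n = len(y)
    cols = [np.ones(n)]
    if base_covariates is not None and np.size(base_covariates):
        cols.append(np.atleast_2d(np.asarray(base_covariates, dtype=float).reshape(n, -1)))
    if local_dosage is not None:
        cols.append(np.asarray(local_dosage, dtype=float).reshape(n, 1))
    X0 = np.column_stack(cols)
    g = np.asarray(snp_dosage, dtype=float).reshape(n, 1)
    X = np.column_stack([X0, g])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return AssocResult(
            beta=float("nan"), se=float("nan"), p=1.0, adjustment=adjustment,
            loglik_ml=float("nan"), aic=float("nan"), n=n,
        )
    fit = fit_lmm(y, X, grm)
    b = float(fit.beta[-1])
    se = float(fit.se[-1])
    t = b / se
    p = 2 * stats.t.sf(abs(t), df=fit.df_resid)
    return AssocResult(
        beta=b, se=se, p=float(p), adjustment=adjustment,
        loglik_ml=fit.loglik_ml, aic=fit.aic, n=n,
    )


def genomic_control_lambda(pvals: np.ndarray) -> float:
    """λ = median observed χ²₁ / median null χ²₁ (0.4549…).

    λ near 1 indicates well-calibrated tests; λ > 1 residual stratification.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0,1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def nested_adjustment_scan(
    y: np.ndarray,
    grm: GRM,
    ref_pcs: np.ndarray,
    pop_pcs: np.ndarray,
    local_dosage: np.ndarray,
    snp_dosage: np.ndarray,
) -> pd.DataFrame:
    """Fit the full adjustment ladder at one SNP.

    Rungs: unadjusted OLS; GRM; GRM + reference-projected PCs; GRM +
    study-specific PCs; GRM + PCs + local-ancestry dosage. Returns a table
    of β, 95% CI, p and AIC per rung plus the ΔAIC between the Ref_PC and
    Pop_PC models.
    """
    ladder = [
        ("unadjusted", None, None, None),
        ("GRM", grm, None, None),
        ("GRM+Ref_PCs", grm, ref_pcs, None),
        ("GRM+Pop_PCs", grm, pop_pcs, None),
        ("GRM+Ref_PCs+Local_Anc", grm, ref_pcs, local_dosage),
    ]
    rows = []
    aics = {}
    for label, K, pcs, local in ladder:
        try:
            res = test_snp(y, pcs, K, snp_dosage, local_dosage=local, adjustment=label)
        except Exception as exc:  # noqa: BLE001 - label the failing rung
            raise RuntimeError(f"ladder rung '{label}' failed: {exc}") from exc
        lo, hi = res.ci95
        aics[label] = res.aic
        rows.append((label, res.beta, res.se, lo, hi, res.p, res.aic, res.n))
    out = pd.DataFrame(
        rows, columns=["adjustment", "beta", "se", "ci_lo", "ci_hi", "p", "aic", "n"]
    )
    out.attrs["delta_aic_ref_vs_pop"] = aics["GRM+Ref_PCs"] - aics["GRM+Pop_PCs"]
    return out
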