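"""Population differentiation and admixture-evidence statistics.

Implements the Hudson ratio-of-sums F_ST estimator, per-SNP F_IT (total
inbreeding, elevated by Wahlund structure and assortative mating), the
F_ST–F_IT rank correlation that diagnoses ancestry-assortative mating, and
Patterson's f3 admixture test with a block jackknife over contiguous SNP
blocks (z ≤ −3 flags formal evidence of admixture).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genio import MISSING, GenotypeSet

__all__ = [
    "F3Result",
    "hudson_fst",
    "per_snp_hudson_fst",
    "per_snp_fit",
    "fst_fit_correlation",
    "f3_statistic",
]


def _fst_terms(p1, p2, n1=None, n2=None):
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    # finite-sample correction when haploid sample counts are supplied
    if n1 is not None:
        num = num - p1 * (1 - p1) / (np.asarray(n1) - 1)
    if n2 is not None:
        num = num - p2 * (1 - p2) / (np.asarray(n2) - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(p1, p2, n1=None, n2=None) -> float:
    """Hudson F_ST as a ratio of sums over SNPs.

    ``num = (p1-p2)^2`` (minus ``p(1-p)/(n-1)`` sampling corrections when
    haploid counts ``n1``/``n2`` are given), ``den = p1(1-p2) + p2(1-p1)``.
    Pass bare frequency vectors (no counts) for model/cluster frequencies.
    """
    num, den = _fst_terms(p1, p2, n1, n2)
    total_den = den.sum()
    if total_den == 0:
        raise ValueError("all denominators zero (identical fixed frequencies)")
    return float(num.sum() / total_den)


def per_snp_hudson_fst(p1, p2) -> np.ndarray:
    """Per-SNP Hudson F_ST ratio; NaN where the denominator vanishes."""
    num, den = _fst_terms(p1, p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def per_snp_fit(gset: GenotypeSet, total_freqs=None) -> np.ndarray:
    """Per-SNP F_IT = 1 − H_obs/H_exp in the total cohort.

    ``H_exp = 2 p̂ (1 − p̂)`` with p̂ from the full cohort (or supplied).
    Monomorphic SNPs are returned as NaN. Missing genotypes are excluded per
    SNP.
    """
    G = gset.genotypes
    miss = G == MISSING
    n_obs = (~miss).sum(axis=0).astype(float)
    if total_freqs is None:
        total_freqs = gset.allele_frequencies()
    p = np.asarray(total_freqs, dtype=float)
    h_exp = 2 * p * (1 - p)
    h_obs = ((G == 1) & ~miss).sum(axis=0) / np.maximum(n_obs, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = 1.0 - h_obs / h_exp
    fit = np.where(h_exp == 0, np.nan, fit)
    return fit


def fst_fit_correlation(gset: GenotypeSet, north_freqs, south_freqs):
    """Spearman correlation across SNPs of F_ST(N,S) with cohort F_IT.

    A positive rank correlation — stronger homozygosity excess at more
    north–south differentiated SNPs — is the signature of ancestry-
    assortative mating. Returns ``(rho, two-sided p)``.
    """
    fst = per_snp_hudson_fst(north_freqs, south_freqs)
    fit = per_snp_fit(gset)
    ok = np.isfinite(fst) & np.isfinite(fit)
    if ok.sum() < 100:
        raise ValueError("need at least 100 SNPs with defined F_ST and F_IT")
    if np.std(fst[ok]) == 0 or np.std(fit[ok]) == 0:
        raise ValueError("constant statistic vector")
    rho, p = stats.spearmanr(fst[ok], fit[ok])
    return float(rho), float(p)


@dataclass
class F3Result:
    """f3(A, B; C) with block-jackknife uncertainty."""

    f3: float
    se: float
    z: float
    n_blocks: int
    block_size: int

    @property
    def significant(self) -> bool:
        """Formal evidence of admixture at the conventional z ≤ −3 rule."""
        return self.z <= -3.0


def f3_statistic(
    target_freqs,
    target_size: int,
    srcA_freqs,
    srcB_freqs,
    block_size_snps: int = 500,
) -> F3Result:
    """Patterson's f3 = E[(c−a)(c−b)] with finite-sample bias correction.

    ``target_size`` is the number of sampled chromosome copies of the target
    (2 × diploids); the per-SNP correction subtracts ``ĥ_c / n_c`` with
    ``ĥ_c = c(1−c)·n_c/(n_c−1)``, the unbiased target heterozygosity.
    Uncertainty comes from a leave-one-block-out jackknife over contiguous
    blocks of ``block_size_snps`` SNPs; significantly negative z (≤ −3) is
    evidence that the target is admixed between sources related to A and B.
    """
    a = np.asarray(srcA_freqs, dtype=float)
    b = np.asarray(srcB_freqs, dtype=float)
    c = np.asarray(target_freqs, dtype=float)
    n_c = float(target_size)
    if n_c < 2:
        raise ValueError("target_size must be >= 2 chromosome copies")
    h_c = c * (1 - c) * n_c / (n_c - 1)
    terms = (c - a) * (c - b) - h_c / n_c
    S = terms.size
    n_blocks = S // block_size_snps
    if n_blocks < 2:
        raise ValueError("fewer than 2 jackknife blocks; reduce block size")
    used = terms[: n_blocks * block_size_snps].reshape(n_blocks, block_size_snps)
    block_means = used.mean(axis=1)
    f3 = float(terms.mean())
    total = used.sum()
    # delete-one-block estimates on the truncated SNP set
    m = block_size_snps
    loo = (total - used.sum(axis=1)) / (m * (n_blocks - 1))
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)))
    z = f3 / se if se > 0 else np.nan
    return F3Result(f3=f3, se=se, z=float(z), n_blocks=n_blocks, block_size=m)
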