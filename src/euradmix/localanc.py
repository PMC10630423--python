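"""Two-way locus-specific ancestry by haplotype HMM posterior decoding.

Each phased haplotype is modeled as a two-state (North/South) hidden Markov
chain along the genetic map: between adjacent markers separated by ``d``
Morgans the chain stays put with extra probability ``exp(-G·d)`` and
otherwise re-draws its state from the haplotype's genome-wide ancestry prior
α — the transition structure implied by a single admixture pulse ``G``
generations ago. Emissions are Bernoulli draws from reference panel allele
frequencies. Posterior decoding by the forward–backward algorithm yields
per-marker ancestry probabilities; summing the "North" posterior over an
individual's two haplotypes gives the locus-specific ancestry *dosage* in
[0, 2] used as an association covariate.

The recursion is normalized at every marker (scaled forward–backward), so it
is underflow-free for arbitrarily long chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeSet

__all__ = ["LocalAncestryPosterior", "reference_emissions", "infer_local_ancestry"]


@dataclass
class LocalAncestryPosterior:
    posteriors: np.ndarray  # (2n, S, 2) per-haplotype state posteriors
    dosage: np.ndarray  # (n, S) expected count of state-0 ("North") alleles
    generations: float
    prior_alpha: np.ndarray  # (2n, 2)
    loglik_forward: np.ndarray  # (2n,) total log-likelihood from forward pass
    loglik_backward: np.ndarray  # (2n,) same quantity from the backward pass

    def dosage_frame(self, sample_ids, marker_ids) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, columns=list(marker_ids))
        df.insert(0, "id", list(sample_ids))
        return df


def reference_emissions(
    parental_gset: GenotypeSet, labels, pseudocount: float = 0.5
) -> np.ndarray:
    """Per-ancestry allele frequencies with additive smoothing.

    ``p̂_k,s = (ALT count + pseudocount) / (2 n_k + 2 pseudocount)`` over the
    samples labeled ``k``; the pseudocount keeps emissions away from 0/1 so
    no single marker can be infinitely informative.
    """
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    G = parental_gset.genotypes
    out = np.empty((len(groups), parental_gset.n_variants))
    for gi, g in enumerate(groups):
        rows = G[labels == g].astype(float)
        if rows.size == 0:
            raise ValueError(f"no samples labeled {g}")
        rows[rows < 0] = np.nan
        count = np.nansum(rows, axis=0)
        n_obs = 2.0 * np.sum(~np.isnan(rows), axis=0)
        out[gi] = (count + pseudocount) / (n_obs + 2 * pseudocount)
    return out


def infer_local_ancestry(
    haplotypes: np.ndarray,
    ref_freqs: np.ndarray,
    map_cM: np.ndarray,
    chrom: np.ndarray,
    G: float = 50.0,
    prior_alpha=None,
    mask_markers=None,
) -> LocalAncestryPosterior:
    """Forward–backward posterior decoding of two-way local ancestry.

    Parameters
    ----------
    haplotypes:
        ``(2n, S)`` phased alleles in {0,1}; rows 2i, 2i+1 belong to
        individual ``i``.
    ref_freqs:
        ``(2, S)`` reference allele frequencies (state 0 = "North").
    map_cM, chrom:
        marker genetic positions and chromosome labels; recursions restart at
        chromosome boundaries from the prior.
    G:
        generations since admixture (transition rate per Morgan); default 50.
    prior_alpha:
        per-haplotype ``(2n, 2)`` (or per-individual ``(n, 2)``) stationary
        ancestry prior; default uniform.
    mask_markers:
        marker indices whose emissions are made uninformative (both states
        0.5). Use this to compute a leave-one-out ancestry dosage for a
        tested SNP: otherwise a strongly differentiated variant determines
        its own posterior and conditioning on the dosage absorbs the
        genotype signal itself.
    """
    H = np.asarray(haplotypes, dtype=np.int8)
    if H.ndim != 2:
        raise ValueError("haplotypes must be a (2n, S) matrix")
    n_hap, S = H.shape
    if ref_freqs.shape != (2, S):
        raise ValueError("ref_freqs must be (2, S)")
    if map_cM.shape[0] != S or chrom.shape[0] != S:
        raise ValueError("map/chromosome labels must align with markers")
    if prior_alpha is None:
        alpha = np.full((n_hap, 2), 0.5)
    else:
        alpha = np.asarray(prior_alpha, dtype=float)
        if alpha.shape == (n_hap // 2, 2):
            alpha = np.repeat(alpha, 2, axis=0)
        if alpha.shape != (n_hap, 2):
            raise ValueError("prior_alpha must be per-haplotype or per-individual")

    if mask_markers is not None:
        ref_freqs = ref_freqs.copy()
        ref_freqs[:, np.asarray(mask_markers)] = 0.5

    # emission likelihoods per marker: (n_hap, S, 2)
    pN, pS = ref_freqs[0], ref_freqs[1]
    emitN = np.where(H == 1, pN, 1 - pN)
    emitS = np.where(H == 1, pS, 1 - pS)

    post = np.empty((n_hap, S, 2))
    ll_f = np.zeros(n_hap)
    ll_b = np.zeros(n_hap)

    for ch in dict.fromkeys(chrom):
        cols = np.flatnonzero(chrom == ch)
        m = cols.size
        d_morgan = np.diff(map_cM[cols]) / 100.0
        stay = np.exp(-G * d_morgan)
        eN = emitN[:, cols]
        eS = emitS[:, cols]

        # scaled forward
        f = np.empty((n_hap, m, 2))
        cnorm = np.empty((n_hap, m))
        f0 = np.stack([alpha[:, 0] * eN[:, 0], alpha[:, 1] * eS[:, 0]], axis=1)
        cnorm[:, 0] = f0.sum(axis=1)
        f[:, 0] = f0 / cnorm[:, 0][:, None]
        for t in range(1, m):
            s = stay[t - 1]
            mix = f[:, t - 1].sum(axis=1)  # = 1 after scaling
            pred = s * f[:, t - 1] + (1 - s) * mix[:, None] * alpha
            cur = pred * np.stack([eN[:, t], eS[:, t]], axis=1)
            cnorm[:, t] = cur.sum(axis=1)
            f[:, t] = cur / cnorm[:, t][:, None]
        ll_f += np.log(cnorm).sum(axis=1)

        # scaled backward; reuse forward scalings for the posterior
        b = np.empty((n_hap, m, 2))
        b[:, m - 1] = 1.0
        dnorm = np.empty((n_hap, m))
        dnorm[:, m - 1] = 1.0
        for t in range(m - 2, -1, -1):
            s = stay[t]
            nxt = b[:, t + 1] * np.stack([eN[:, t + 1], eS[:, t + 1]], axis=1)
            contrib = s * nxt + ((1 - s) * (alpha * nxt).sum(axis=1))[:, None]
            dnorm[:, t] = contrib.sum(axis=1)
            b[:, t] = contrib / dnorm[:, t][:, None]
        first = alpha * np.stack([eN[:, 0], eS[:, 0]], axis=1) * b[:, 0]
        ll_b += np.log(first.sum(axis=1)) + np.log(dnorm[:, :-1]).sum(axis=1)

        pr = f * b
        pr /= pr.sum(axis=2, keepdims=True)
        post[:, cols, :] = pr

    dosage = post[0::2, :, 0] + post[1::2, :, 0]
    return LocalAncestryPosterior(
        posteriors=post,
        dosage=dosage,
        generations=float(G),
        prior_alpha=alpha,
        loglik_forward=ll_f,
        loglik_backward=ll_b,
    )
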