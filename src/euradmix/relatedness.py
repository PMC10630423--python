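"""Pairwise IBD/kinship estimation and relative pruning.

Method-of-moments IBD estimation in the PLINK style: for each pair, observed
identity-by-state (IBS) counts are equated to their expectations given
allele frequencies under IBD sharing of 0, 1 or 2 alleles, solved
sequentially, clamped to [0,1] and renormalized. The kinship coefficient is
Φ = ½δ2 + ¼δ1. Pairs with Φ at or above 0.0884 (first/second degree) form a
relatedness graph from which an edge-free subset is kept by iteratively
removing the highest-degree vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeSet

__all__ = [
    "KinshipEstimate",
    "estimate_ibd_moments",
    "kinship_from_ibd",
    "prune_related",
    "kinship_table",
]

RELATED_PHI = 0.0884  # first- and second-degree relatives


@dataclass
class KinshipEstimate:
    i: int
    j: int
    delta0: float
    delta1: float
    delta2: float
    phi: float


def kinship_from_ibd(delta1: float, delta2: float) -> float:
    """Φ = ½δ2 + ¼δ1."""
    if not (0 <= delta1 <= 1 and 0 <= delta2 <= 1):
        raise ValueError("deltas must lie in [0,1]")
    if delta1 + delta2 > 1 + 1e-12:
        raise ValueError("delta1 + delta2 exceeds 1")
    return 0.5 * delta2 + 0.25 * delta1


def _project_simplex(d0, d1, d2):
    d = np.clip(np.array([d0, d1, d2]), 0.0, 1.0)
    s = d.sum()
    if s == 0:
        return np.array([1.0, 0.0, 0.0])
    return d / s


def estimate_ibd_moments(
    gset: GenotypeSet, freqs: np.ndarray | None = None
) -> list[KinshipEstimate]:
    """PLINK-style method-of-moments δ0/δ1/δ2 and Φ for every sample pair.

    ``freqs`` are per-SNP ALT frequencies from a reference (e.g. the
    generative panel) or, by default, the sample itself. Expected IBS
    probabilities given IBD state use the standard binomial expressions; δ
    estimates are clamped and renormalized to the simplex.
    """
    if freqs is None:
        freqs = gset.allele_frequencies()
    p = np.asarray(freqs, dtype=float)
    q = 1 - p
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs; IBS expectations undefined")
    p, q = p[poly], q[poly]
    G = gset.genotypes[:, poly]

    # expected per-SNP IBS class probabilities given IBD state
    e_ibs0_ibd0 = 2 * p**2 * q**2
    e_ibs1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e_ibs2_ibd0 = p**4 + q**4 + 4 * p**2 * q**2
    e_ibs1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e_ibs2_ibd1 = p**3 + q**3 + p**2 * q + p * q**2

    n = gset.n_samples
    out = []
    for i in range(n):
        gi = G[i]
        for j in range(i + 1, n):
            gj = G[j]
            ok = (gi != MISSING) & (gj != MISSING)
            s = ok.sum()
            if s == 0:
                continue
            diff = np.abs(gi[ok] - gj[ok])
            n_ibs0 = float(np.sum(diff == 2))
            n_ibs1 = float(np.sum(diff == 1))
            n_ibs2 = float(np.sum(diff == 0))
            frac = s / len(p)  # scale expectations to observed SNP count
            E00 = e_ibs0_ibd0[ok].sum()
            d0 = n_ibs0 / E00 if E00 > 0 else 0.0
            E11 = e_ibs1_ibd1[ok].sum()
            d1 = (n_ibs1 - d0 * e_ibs1_ibd0[ok].sum()) / E11 if E11 > 0 else 0.0
            d2 = (
                n_ibs2 - d0 * e_ibs2_ibd0[ok].sum() - d1 * e_ibs2_ibd1[ok].sum()
            ) / s
            d0, d1, d2 = _project_simplex(d0, d1, d2)
            out.append(
                KinshipEstimate(
                    i=i, j=j, delta0=d0, delta1=d1, delta2=d2,
                    phi=kinship_from_ibd(d1, d2),
                )
            )
    return out


def prune_related(
    kinships: list[KinshipEstimate], threshold: float = RELATED_PHI, n_samples=None
) -> np.ndarray:
    """Indices of an edge-free (no related pair) subset of samples.

    Builds the graph with edges Φ ≥ threshold and iteratively removes the
    highest-degree vertex (ties broken by smallest sample index) until no
    edge remains. On realistic sparse relatedness graphs this keeps the same
    set as exact maximum-independent-set search while staying linear-time.
    """
    nodes = set()
    edges = []
    for k in kinships:
        nodes.add(k.i)
        nodes.add(k.j)
        if k.phi >= threshold:
            edges.append((k.i, k.j))
    if n_samples is not None:
        nodes |= set(range(n_samples))
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    removed = set()
    while True:
        deg = {
            v: len(adj[v] - removed) for v in adj if v not in removed
        }
        worst = max(deg.items(), key=lambda kv: (kv[1], -kv[0]), default=None)
        if worst is None or worst[1] == 0:
            break
        removed.add(worst[0])
    keep = sorted(v for v in nodes if v not in removed)
    return np.array(keep, dtype=int)


def kinship_table(kinships: list[KinshipEstimate], sample_ids=None) -> pd.DataFrame:
    rows = []
    for k in kinships:
        a = sample_ids[k.i] if sample_ids is not None else k.i
        b = sample_ids[k.j] if sample_ids is not None else k.j
        rows.append((a, b, k.delta0, k.delta1, k.delta2, k.phi))
    return pd.DataFrame(
        rows, columns=["id1", "id2", "delta0", "delta1", "delta2", "phi"]
    )
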