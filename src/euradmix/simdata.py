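"""Synthetic admixed cohorts with known ground truth.

The generator emulates the statistical structure of a European-American-style
cohort: three ancestral clusters differentiated at subcontinental F_ST
(~0.03), individuals carrying continuous three-way admixture proportions
along a north–south geographic gradient, a single admixture pulse tens of
generations ago, optional ancestry-assortative mating, ancestry-confounded
quantitative traits, and one focal SNP with extreme inter-ancestry frequency
differentiation (the lactase-persistence paradigm, ~0.93 vs ~0.03).

Model summary
-------------
* Cluster allele frequencies follow the Balding–Nichols model: for ancestral
  frequency ``p`` and per-cluster drift ``F``, the cluster frequency is
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)``. Two clusters with drifts ``F_i, F_j``
  have expected pairwise Hudson F_ST of ``(F_i + F_j)/2``; the drift matrix
  passed by the user holds the *pairwise* targets and per-cluster drifts are
  solved from them (see :func:`solve_cluster_drifts`).
* Ancestry tracts along each haplotype follow a Markov jump process on the
  genetic map with jump rate ``G`` per Morgan and jump targets drawn from the
  individual's admixture vector α (self-jumps included), the stationary
  process implied by a single admixture pulse ``G`` generations ago.
* Alleles are drawn Bernoulli from the tract ancestry's cluster frequency,
  independently across markers given the tracts (no background LD).

The default genome is 22 chromosomes × 100 cM with uniform recombination
(1 cM/Mb), which supports leave-one-chromosome-out jackknives downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeSet

__all__ = [
    "AncestralPanel",
    "CohortTruth",
    "TraitTable",
    "solve_cluster_drifts",
    "draw_ancestral_frequencies",
    "plant_differentiated_snp",
    "simulate_admixed_cohort",
    "simulate_trait",
    "simulate_offspring",
    "gradient_alpha_sampler",
    "write_truth_tables",
]

DEFAULT_N_CHROM = 22
DEFAULT_CHROM_CM = 100.0
BP_PER_CM = 1_000_000  # uniform 1 cM/Mb map


@dataclass
class AncestralPanel:
    """Per-ancestry allele frequencies plus the generative drift parameters.

    ``drift`` holds the pairwise F_ST targets between clusters (zero
    diagonal); ``cluster_F`` the per-cluster Balding–Nichols drifts solved
    from them. ``map_cM``/``chrom``/``bp`` describe the marker map; ``focal``
    flags planted high-differentiation SNPs.
    """

    freqs: np.ndarray  # (K, S)
    drift: np.ndarray  # (K, K) pairwise F_ST targets
    cluster_F: np.ndarray  # (K,)
    map_cM: np.ndarray  # (S,)
    chrom: np.ndarray  # (S,) str labels
    bp: np.ndarray  # (S,) int positions
    snp_ids: np.ndarray  # (S,) str
    focal: np.ndarray = field(default=None)  # (S,) bool

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.focal is None:
            self.focal = np.zeros(self.n_snps, dtype=bool)
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("allele frequencies must lie in [0,1]")
        if np.any(np.diag(self.drift) != 0):
            raise ValueError("drift diagonal must be zero")
        for ch in np.unique(self.chrom):
            m = self.map_cM[self.chrom == ch]
            if np.any(np.diff(m) < 0):
                raise ValueError(f"map positions decreasing on chromosome {ch}")

    @property
    def n_ancestries(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[1]

    @property
    def focal_index(self) -> int | None:
        idx = np.flatnonzero(self.focal)
        return int(idx[0]) if idx.size else None

    def variant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.bp,
                "id": self.snp_ids,
                "ref": "A",
                "alt": "G",
                "cM": self.map_cM,
                "focal": self.focal,
            }
        )


@dataclass
class CohortTruth:
    """Generative ground truth for a simulated cohort."""

    alpha: np.ndarray  # (n, K) true admixture proportions
    tracts: np.ndarray  # (2n, S) int8 ancestry label per haplotype/marker
    generations: int
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None
    pedigree: np.ndarray | None = None  # (n, 2) parent indices or -1

    def __post_init__(self) -> None:
        if not np.allclose(self.alpha.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("alpha rows must sum to 1")


@dataclass
class TraitTable:
    """Simulated quantitative trait with its generative coefficients."""

    values: np.ndarray
    beta_anc: float
    beta_snp: float
    noise_sd: float

    def to_frame(self, sample_ids) -> pd.DataFrame:
        return pd.DataFrame({"id": sample_ids, "trait": self.values})


# ---------------------------------------------------------------------------
# Ancestral frequencies
# ---------------------------------------------------------------------------


def solve_cluster_drifts(pairwise: np.ndarray) -> np.ndarray:
    """Per-cluster Balding–Nichols drifts from pairwise F_ST targets.

    Uses E[F_ST(i,j)] = (F_i + F_j)/2: at K=3 the system F_i + F_j = 2·d_ij
    is exactly determined; at K=2 it is under-determined and drift is split
    equally; larger K uses nonnegative least squares.
    """
    pairwise = np.asarray(pairwise, dtype=float)
    K = pairwise.shape[0]
    if not np.allclose(pairwise, pairwise.T):
        raise ValueError("drift matrix must be symmetric")
    if np.any((pairwise < 0) | (pairwise >= 1)):
        raise ValueError("drift entries must lie in [0,1)")
    if K == 1:
        return np.zeros(1)
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    A = np.zeros((len(pairs), K))
    b = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        A[r, i] = A[r, j] = 1.0
        b[r] = 2.0 * pairwise[i, j]
    if K == 2:
        return np.full(2, pairwise[0, 1])
    from scipy.optimize import nnls

    F, _ = nnls(A, b)
    return F


def _default_map(n_snps: int, n_chrom: int, chrom_cm: float):
    """Evenly spaced markers over `n_chrom` chromosomes of `chrom_cm` cM."""
    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps % n_chrom] += 1
    chrom, cm = [], []
    for c in range(n_chrom):
        m = per[c]
        chrom.extend([str(c + 1)] * m)
        cm.append((np.arange(m) + 0.5) * chrom_cm / max(m, 1))
    cm = np.concatenate(cm) if cm else np.empty(0)
    chrom = np.array(chrom)
    bp = np.round(cm * BP_PER_CM).astype(np.int64) + 1
    return chrom, cm, bp


def draw_ancestral_frequencies(
    n_snps: int,
    drift: np.ndarray,
    freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
    n_chrom: int = DEFAULT_N_CHROM,
    chrom_cm: float = DEFAULT_CHROM_CM,
) -> AncestralPanel:
    """Draw per-cluster allele frequencies under the Balding–Nichols model.

    The ancestral frequency of each SNP is uniform on ``freq_range``
    (default (0.05, 0.95) to avoid monomorphic sites); each cluster's
    frequency is a Beta draw with mean ``p`` and variance ``F·p(1-p)``
    around it (``F = 0`` copies ``p`` exactly).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = freq_range
    if not (0 < lo < hi < 1):
        raise ValueError("freq_range must be a subinterval of (0,1)")
    drift = np.atleast_2d(np.asarray(drift, dtype=float))
    F = solve_cluster_drifts(drift)
    K = len(F)
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    freqs = np.empty((K, n_snps))
    for k in range(K):
        if F[k] <= 0:
            freqs[k] = p
        else:
            a = p * (1 - F[k]) / F[k]
            b = (1 - p) * (1 - F[k]) / F[k]
            freqs[k] = rng.beta(a, b)
    chrom, cm, bp = _default_map(n_snps, n_chrom, chrom_cm)
    ids = np.array([f"snp{i+1}" for i in range(n_snps)])
    return AncestralPanel(
        freqs=freqs,
        drift=drift,
        cluster_F=F,
        map_cM=cm,
        chrom=chrom,
        bp=bp,
        snp_ids=ids,
    )


def plant_differentiated_snp(
    panel: AncestralPanel,
    freq_by_ancestry: np.ndarray,
    map_position: tuple[str, float] | None = None,
) -> AncestralPanel:
    """Insert one focal SNP with exact ancestry-specific frequencies.

    ``map_position`` is ``(chrom, cM)``; default is the middle of the first
    chromosome. The SNP is flagged in panel metadata as the focal
    "LCT-like" variant.
    """
    freq_by_ancestry = np.asarray(freq_by_ancestry, dtype=float)
    if freq_by_ancestry.shape != (panel.n_ancestries,):
        raise ValueError("freq_by_ancestry must have one entry per ancestry")
    if np.any((freq_by_ancestry < 0) | (freq_by_ancestry > 1)):
        raise ValueError("frequencies must lie in [0,1]")
    if map_position is None:
        ch = panel.chrom[0]
        cm = float(np.median(panel.map_cM[panel.chrom == ch]))
    else:
        ch, cm = str(map_position[0]), float(map_position[1])
    on_chrom = panel.map_cM[panel.chrom == ch]
    if on_chrom.size == 0 or not (on_chrom.min() <= cm <= on_chrom.max()):
        raise ValueError(f"position {cm} cM outside map range of chromosome {ch}")
    # insertion point keeps the map sorted within the chromosome
    idx_chrom = np.flatnonzero(panel.chrom == ch)
    offset = np.searchsorted(panel.map_cM[idx_chrom], cm)
    at = int(idx_chrom[0] + offset)
    return AncestralPanel(
        freqs=np.insert(panel.freqs, at, freq_by_ancestry, axis=1),
        drift=panel.drift,
        cluster_F=panel.cluster_F,
        map_cM=np.insert(panel.map_cM, at, cm),
        chrom=np.insert(panel.chrom, at, ch),
        bp=np.insert(panel.bp, at, int(round(cm * BP_PER_CM)) + 1),
        snp_ids=np.insert(panel.snp_ids, at, "focal"),
        focal=np.insert(panel.focal, at, True),
    )


# ---------------------------------------------------------------------------
# Admixture proportion samplers
# ---------------------------------------------------------------------------


def gradient_alpha_sampler(noise: float = 0.08):
    """Three-way admixture proportions along a north–south gradient.

    Individuals receive latitude ~ U(36, 60) and longitude ~ U(-10, 30)
    degrees; northern ancestry rises with latitude and the two southern
    ancestries split along longitude, with Dirichlet-style jitter of scale
    ``noise``. Returns a callable ``sampler(n, rng) -> (alpha, lat, lon)``.
    """

    def sampler(n: int, rng: np.random.Generator):
        lat = rng.uniform(36.0, 60.0, n)
        lon = rng.uniform(-10.0, 30.0, n)
        w_n = (lat - 36.0) / 24.0
        w_e = (lon + 10.0) / 40.0
        base = np.column_stack([w_n, (1 - w_n) * (1 - w_e), (1 - w_n) * w_e])
        alpha = np.clip(base + rng.normal(0, noise, base.shape), 1e-3, None)
        alpha /= alpha.sum(axis=1, keepdims=True)
        return alpha, lat, lon

    return sampler


def _resolve_alphas(alpha_sampler, n_ind: int, K: int, rng):
    """Accept an (n,K) array, a Dirichlet concentration, or a callable."""
    lat = lon = None
    if callable(alpha_sampler):
        out = alpha_sampler(n_ind, rng)
        alpha = out[0] if isinstance(out, tuple) else out
        if isinstance(out, tuple) and len(out) == 3:
            lat, lon = out[1], out[2]
    else:
        arr = np.asarray(alpha_sampler, dtype=float)
        if arr.ndim == 1:
            if len(arr) != K:
                raise ValueError("concentration length must equal K")
            alpha = rng.dirichlet(arr, size=n_ind)
        else:
            alpha = arr
            if alpha.shape != (n_ind, K):
                raise ValueError(f"alpha matrix must be ({n_ind}, {K})")
    if not np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("alpha rows must lie on the simplex")
    if alpha.shape[1] != K:
        raise ValueError("alpha has wrong number of ancestries")
    return alpha / alpha.sum(axis=1, keepdims=True), lat, lon


# ---------------------------------------------------------------------------
# Tract and genotype simulation
# ---------------------------------------------------------------------------


def _simulate_tracts_one_chrom(
    rng, alphas: np.ndarray, cm: np.ndarray, G: int
) -> np.ndarray:
    """Ancestry labels at markers `cm` for haplotypes with stationary `alphas`.

    Markov jump process: breakpoints Poisson with rate G per Morgan; each
    segment's ancestry drawn from the haplotype's alpha (self-jumps allowed).
    """
    H = alphas.shape[0]
    S = cm.size
    L = (cm.max() - cm.min()) / 100.0 if S else 0.0
    pos_m = (cm - cm.min()) / 100.0
    out = np.empty((H, S), dtype=np.int8)
    n_breaks = rng.poisson(G * L, size=H)
    cum = alphas.cumsum(axis=1)
    for h in range(H):
        nb = n_breaks[h]
        breaks = np.sort(rng.uniform(0.0, L, nb))
        u = rng.random(nb + 1)
        seg_anc = (u[:, None] > cum[h][None, :]).sum(axis=1).astype(np.int8)
        out[h] = seg_anc[np.searchsorted(breaks, pos_m, side="right")]
    return out


def simulate_admixed_cohort(
    panel: AncestralPanel,
    n_ind: int,
    alpha_sampler,
    generations: int,
    assortment_r: float | None = None,
    seed: int = 0,
):
    """Simulate phased genotypes for an admixed cohort.

    Each haplotype's ancestry tracts follow a Markov jump process along the
    genetic map (rate ``generations`` per Morgan, stationary distribution =
    the individual's α); alleles are Bernoulli draws from the tract
    ancestry's cluster frequency.

    With ``assortment_r=None`` (default) both haplotypes of an individual
    share the individual's sampled α — the classic admixture model, which
    carries a Wahlund homozygosity excess at differentiated SNPs whenever α
    varies across individuals. A numeric ``assortment_r`` instead treats the
    cohort as an *offspring generation*: each individual's two haplotypes
    are stationary at the α of two mates whose first-ancestry proportions
    are rank-correlated at ``assortment_r`` through a Gaussian copula.
    ``assortment_r=0`` is random mating (haplotype ancestries independent,
    per-SNP F_IT centered at 0); larger values create the excess
    homozygosity at ancestry-differentiated SNPs that ancestry-assortative
    mating produces.

    Returns ``(GenotypeSet, CohortTruth)``.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if assortment_r is not None and not 0.0 <= assortment_r <= 1.0:
        raise ValueError("assortment_r must lie in [0,1]")
    rng = np.random.default_rng(seed)
    K = panel.n_ancestries
    alpha, lat, lon = _resolve_alphas(alpha_sampler, n_ind, K, rng)

    if assortment_r is not None:
        # Gaussian-copula rank matching of mate first-ancestry proportions;
        # offspring keep the first mate's coordinates
        alpha2, _, _ = _resolve_alphas(alpha_sampler, n_ind, K, rng)
        z1 = rng.normal(size=n_ind)
        z2 = assortment_r * z1 + np.sqrt(1 - assortment_r**2) * rng.normal(size=n_ind)
        perm1 = np.argsort(alpha[:, 0])[np.argsort(np.argsort(z1))]
        mate1 = alpha[perm1]
        if lat is not None:
            lat, lon = lat[perm1], lon[perm1]
        mate2 = alpha2[np.argsort(alpha2[:, 0])[np.argsort(np.argsort(z2))]]
        hap_alpha = np.empty((2 * n_ind, K))
        hap_alpha[0::2] = mate1
        hap_alpha[1::2] = mate2
        alpha = 0.5 * (mate1 + mate2)
    else:
        hap_alpha = np.repeat(alpha, 2, axis=0)

    S = panel.n_snps
    tracts = np.empty((2 * n_ind, S), dtype=np.int8)
    haps = np.empty((2 * n_ind, S), dtype=np.int8)
    for ch in dict.fromkeys(panel.chrom):
        cols = np.flatnonzero(panel.chrom == ch)
        t = _simulate_tracts_one_chrom(rng, hap_alpha, panel.map_cM[cols], generations)
        tracts[:, cols] = t
        f = panel.freqs[:, cols]
        haps[:, cols] = (rng.random((2 * n_ind, cols.size)) < f[t, np.arange(cols.size)[None, :]]).astype(np.int8)

    genotypes = haps[0::2] + haps[1::2]
    samples = pd.DataFrame({"id": [f"ind{i+1}" for i in range(n_ind)]})
    if lat is not None:
        samples["lat"] = lat
        samples["lon"] = lon
    gset = GenotypeSet(
        genotypes=genotypes,
        haplotypes=haps,
        variants=panel.variant_table(),
        samples=samples,
    )
    truth = CohortTruth(
        alpha=alpha, tracts=tracts, generations=generations, lat=lat, lon=lon
    )
    return gset, truth


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def simulate_trait(
    truth: CohortTruth,
    genotypes: GenotypeSet,
    beta_anc: float,
    beta_snp: float,
    noise_sd: float,
    seed: int = 0,
) -> TraitTable:
    """trait = beta_anc·α_first + beta_snp·g_focal + N(0, noise_sd).

    ``α_first`` is the first (northern) ancestry proportion; the focal SNP is
    the variant flagged in the genotype metadata. The generative coefficients
    are stored for recovery tests.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    y = beta_anc * truth.alpha[:, 0] + rng.normal(0, noise_sd, len(truth.alpha))
    if beta_snp != 0.0:
        if "focal" not in genotypes.variants or not genotypes.variants["focal"].any():
            raise ValueError("no focal SNP present but beta_snp != 0")
        j = int(np.flatnonzero(genotypes.variants["focal"].to_numpy())[0])
        y = y + beta_snp * genotypes.genotypes[:, j]
    return TraitTable(values=y, beta_anc=beta_anc, beta_snp=beta_snp, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------


def simulate_offspring(
    parents: GenotypeSet, pairs: list[tuple[int, int]], seed: int = 0
) -> GenotypeSet:
    """Generate offspring by meiosis with Poisson crossovers on the cM map.

    Each transmitted haplotype starts on a random parental haplotype and
    switches at crossover points drawn Poisson along the genetic map.
    Parents must be phased.
    """
    if not parents.is_phased:
        raise ValueError("parents must be phased")
    rng = np.random.default_rng(seed)
    cm = parents.variants["cM"].to_numpy(dtype=float)
    chrom = parents.variants["chrom"].to_numpy()
    S = parents.n_variants
    n_off = len(pairs)
    haps = np.empty((2 * n_off, S), dtype=np.int8)
    for o, (pa, pb) in enumerate(pairs):
        for which, parent in enumerate((pa, pb)):
            h0 = parents.haplotypes[2 * parent]
            h1 = parents.haplotypes[2 * parent + 1]
            gamete = np.empty(S, dtype=np.int8)
            for ch in dict.fromkeys(chrom):
                cols = np.flatnonzero(chrom == ch)
                c = cm[cols]
                L = (c.max() - c.min()) / 100.0
                xovers = np.sort(rng.uniform(0.0, L, rng.poisson(L)))
                phase0 = rng.integers(2)
                seg = (phase0 + np.searchsorted(xovers, (c - c.min()) / 100.0)) % 2
                gamete[cols] = np.where(seg == 0, h0[cols], h1[cols])
            haps[2 * o + which] = gamete
    genotypes = haps[0::2] + haps[1::2]
    samples = pd.DataFrame({"id": [f"off{o+1}" for o in range(n_off)]})
    return GenotypeSet(
        genotypes=genotypes,
        haplotypes=haps,
        variants=parents.variants,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Truth table output
# ---------------------------------------------------------------------------


def write_truth_tables(truth: CohortTruth, gset: GenotypeSet, prefix: str) -> None:
    """Write alpha / tract / coordinate tables as TSV next to `prefix`."""
    K = truth.alpha.shape[1]
    df = pd.DataFrame(truth.alpha, columns=[f"alpha{k}" for k in range(K)])
    df.insert(0, "id", gset.samples["id"].to_numpy())
    if truth.lat is not None:
        df["lat"] = truth.lat
        df["lon"] = truth.lon
    df.to_csv(f"{prefix}.alpha.tsv", sep="\t", index=False)
    np.savetxt(f"{prefix}.tracts.tsv", truth.tracts, fmt="%d", delimiter="\t")
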