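"""Genotype container, file formats, and marker/sample quality control.

The exchange object for the whole pipeline is :class:`GenotypeSet`: a diploid
genotype matrix (0/1/2 counts of the ALT allele, ``-1`` for missing) with an
optional phased haplotype matrix, plus variant and sample metadata tables.

Formats handled: VCF v4.2 (biallelic SNPs only), PLINK-style 4-column genetic
maps, ADMIXTURE-compatible whitespace ``.Q``/``.P`` matrices, and TSV sample /
trait tables. Readers accept plain or gzip-compressed files.

QC follows the usual GWAS curation defaults: per-sample missingness
(``mind``), per-SNP missingness (``geno``), minor allele frequency (``maf``),
Hardy–Weinberg exact-test p (``hwe``), applied in that order, followed by
windowed greedy LD pruning (``--indep-pairwise``-style).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GenotypeSet",
    "GeneticMap",
    "read_vcf",
    "write_vcf",
    "read_genetic_map",
    "write_genetic_map",
    "read_qp_matrices",
    "write_qp_matrices",
    "qc_filter",
    "ld_prune",
    "hwe_exact_midp",
]

MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "cM"]


@dataclass
class GenotypeSet:
    """Diploid genotypes with optional phased haplotypes and metadata.

    Attributes
    ----------
    genotypes:
        ``(n, S)`` int8 array of ALT-allele counts; ``-1`` marks missing.
    haplotypes:
        optional ``(2n, S)`` int8 array of phased alleles in {0, 1}; rows
        ``2i`` and ``2i+1`` are the two haplotypes of individual ``i``.
    variants:
        DataFrame with columns chrom, pos (1-based), id, ref, alt, cM.
    samples:
        DataFrame with at least a column ``id``; optionally ``population``,
        ``lat``, ``lon``.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.validate()

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def validate(self) -> None:
        n, s = self.genotypes.shape
        if len(self.variants) != s:
            raise ValueError(
                f"variant table has {len(self.variants)} rows for {s} genotype columns"
            )
        if len(self.samples) != n:
            raise ValueError(
                f"sample table has {len(self.samples)} rows for {n} genotype rows"
            )
        if self.haplotypes is not None:
            if self.haplotypes.shape != (2 * n, s):
                raise ValueError("haplotype matrix must be (2n, S)")
            g = self.haplotypes[0::2] + self.haplotypes[1::2]
            obs = self.genotypes
            ok = (obs == MISSING) | (g == obs)
            if not ok.all():
                raise ValueError("genotypes disagree with haplotype sums")
        for ch, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not nondecreasing on chromosome {ch}")

    # -- convenience ---------------------------------------------------------

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP ALT frequency ignoring missing genotypes."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        return np.asarray(g.mean(axis=0) / 2.0)

    def take_variants(self, idx: np.ndarray) -> "GenotypeSet":
        idx = np.asarray(idx)
        return GenotypeSet(
            genotypes=self.genotypes[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=self.samples,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeSet":
        idx = np.asarray(idx)
        hap_idx = np.repeat(idx * 2, 2)
        hap_idx[1::2] += 1
        return GenotypeSet(
            genotypes=self.genotypes[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[hap_idx],
            variants=self.variants,
            samples=self.samples.iloc[idx].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str) -> GenotypeSet:
    """Read a biallelic-SNP VCF into a :class:`GenotypeSet`.

    ``|``-separated GT fields are treated as phased; if every genotype in the
    file is phased a haplotype matrix is populated. ``.`` alleles become
    missing. Multiallelic or non-SNP records raise ``ValueError``.
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    genos: list[np.ndarray] = []
    haps: list[np.ndarray] = []
    rows = []
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS}; split or drop it first"
            )
        if len(var.REF) != 1 or len(var.ALT[0]) != 1 or var.ALT[0] not in "ACGT":
            raise ValueError(f"non-SNP record at {var.CHROM}:{var.POS}")
        gt = np.array(var.genotypes, dtype=object)  # rows: [a1, a2, phased]
        a1 = np.array([row[0] for row in gt], dtype=np.int8)
        a2 = np.array([row[1] for row in gt], dtype=np.int8)
        phased = np.array([bool(row[2]) for row in gt])
        g = np.where((a1 < 0) | (a2 < 0), MISSING, a1.clip(0) + a2.clip(0)).astype(
            np.int8
        )
        genos.append(g)
        if not phased.all() or (a1 < 0).any() or (a2 < 0).any():
            all_phased = False
        hap = np.empty(2 * n, dtype=np.int8)
        hap[0::2] = a1
        hap[1::2] = a2
        haps.append(hap)
        rows.append(
            (var.CHROM, var.POS, var.ID or ".", var.REF, var.ALT[0], np.nan)
        )
    vcf.close()
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    genotypes = (
        np.column_stack(genos) if genos else np.empty((n, 0), dtype=np.int8)
    )
    haplotypes = np.column_stack(haps) if (haps and all_phased) else None
    samples = pd.DataFrame({"id": sample_ids})
    return GenotypeSet(genotypes, variants, samples, haplotypes=haplotypes)


def write_vcf(gset: GenotypeSet, path: str) -> None:
    """Write a minimal VCF v4.2 with deterministic field ordering.

    Phased sets emit ``a|b`` genotypes from the haplotype matrix; unphased
    sets emit ``a/b`` with the canonical ordering 0/1 for heterozygotes;
    missing genotypes are ``./.``.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for ch in dict.fromkeys(gset.variants["chrom"]):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in gset.samples["id"])
            + "\n"
        )
        phased = gset.is_phased
        G = gset.genotypes
        H = gset.haplotypes
        unphased_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, row in enumerate(gset.variants.itertuples(index=False)):
            if phased:
                a1 = H[0::2, j]
                a2 = H[1::2, j]
                cells = [f"{x}|{y}" for x, y in zip(a1, a2)]
            else:
                cells = [unphased_code[int(g)] for g in G[:, j]]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """PLINK ``.map``-style table with linear interpolation in bp."""

    table: pd.DataFrame  # columns: chrom, id, cM, bp

    def __post_init__(self) -> None:
        for ch, grp in self.table.groupby("chrom", sort=False):
            if (np.diff(grp["cM"].to_numpy()) < 0).any():
                raise ValueError(f"decreasing cM on chromosome {ch}")

    def interpolate(self, chrom, bp: np.ndarray) -> np.ndarray:
        """cM for arbitrary bp positions; clamped beyond map ends."""
        grp = self.table[self.table["chrom"] == chrom]
        if grp.empty:
            raise KeyError(f"chromosome {chrom} not in map")
        return np.interp(
            np.asarray(bp, dtype=float),
            grp["bp"].to_numpy(dtype=float),
            grp["cM"].to_numpy(dtype=float),
        )


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_genetic_map(path: str) -> GeneticMap:
    """Read a 4-column whitespace map file: chrom, id, cM, bp."""
    with _open_text(path) as fh:
        table = pd.read_csv(
            fh,
            sep=r"\s+",
            header=None,
            names=["chrom", "id", "cM", "bp"],
            dtype={"chrom": str, "id": str, "cM": float, "bp": int},
        )
    return GeneticMap(table)


def write_genetic_map(gset: GenotypeSet, path: str) -> None:
    v = gset.variants
    with open(path, "w") as fh:
        for row in v.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t{row.cM:.6f}\t{row.pos}\n")


# ---------------------------------------------------------------------------
# ADMIXTURE-style Q/P matrices
# ---------------------------------------------------------------------------


def read_qp_matrices(path_q: str, path_p: str, n_variants: int | None = None):
    """Read whitespace ``.Q`` (n × K) and ``.P`` (S × K) matrices.

    Returns ``(Q, P)`` with ``P`` transposed to the internal ``K × S``
    orientation. Q rows must lie on the simplex up to 1e-6 (renormalized) and
    the K dimensions must agree.
    """
    Q = np.loadtxt(path_q, ndmin=2)
    P_file = np.loadtxt(path_p, ndmin=2)
    if Q.shape[1] != P_file.shape[1]:
        raise ValueError(
            f"K mismatch: Q has {Q.shape[1]} columns, P has {P_file.shape[1]}"
        )
    if n_variants is not None and P_file.shape[0] != n_variants:
        raise ValueError(
            f"P has {P_file.shape[0]} rows for {n_variants} variants "
            "(is it transposed?)"
        )
    rowsum = Q.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) >= 1e-6):
        raise ValueError("Q row sums deviate from 1 by >= 1e-6")
    Q = Q / rowsum[:, None]
    return Q, P_file.T.copy()


def write_qp_matrices(Q: np.ndarray, P: np.ndarray, path_q: str, path_p: str) -> None:
    """Write ADMIXTURE-compatible files (P stored as S × K)."""
    np.savetxt(path_q, Q, fmt="%.10f")  # row sums must stay within 1e-6 of 1
    np.savetxt(path_p, np.asarray(P).T, fmt="%.6f")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def hwe_exact_midp(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Mid-p Hardy–Weinberg exact test for one biallelic SNP.

    Enumerates the conditional distribution of heterozygote counts given
    allele counts and sums probabilities of outcomes no more likely than the
    observed one, counting the observed outcome at half weight (mid-p).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    # log-probabilities of all het counts with the parity of n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    n_a = n_rare
    n_b = 2 * n - n_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln((n_b - hets) / 2 + 1)
        + hets * np.log(2)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.searchsorted(hets, n_het)
    p_obs = p[obs]
    mask = p <= p_obs * (1 + 1e-12)
    return float(p[mask].sum() - 0.5 * p_obs)


def qc_filter(
    gset: GenotypeSet,
    maf: float = 0.01,
    geno: float = 0.05,
    mind: float = 0.05,
    hwe_p: float = 1e-6,
    exempt_ids=None,
) -> GenotypeSet:
    """Apply marker/sample QC in the order mind → geno → maf → hwe.

    Thresholds mirror common GWAS curation: drop individuals with genotype
    missingness > ``mind``, then SNPs with missingness > ``geno``, minor
    allele frequency < ``maf``, or Hardy–Weinberg mid-p < ``hwe_p``.

    ``exempt_ids``: variant ids excluded from the SNP-level filters. A
    strongly ancestry-differentiated variant carries a large Wahlund
    homozygote excess in an admixed cohort and can fail the HWE filter for
    structural (not technical) reasons; exempt it when it is the variant
    under study.
    """
    for name, val in (("maf", maf), ("geno", geno), ("mind", mind)):
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must lie in [0,1]")
    G = gset.genotypes
    miss = G == MISSING

    keep_ind = np.flatnonzero(miss.mean(axis=1) <= mind)
    if keep_ind.size == 0:
        raise ValueError("mind filter removed every sample")
    out = gset.take_samples(keep_ind) if keep_ind.size < gset.n_samples else gset

    G = out.genotypes
    miss = G == MISSING
    keep = miss.mean(axis=0) <= geno

    freq = out.allele_frequencies()
    mafs = np.minimum(freq, 1 - freq)
    keep &= mafs >= maf

    for j in np.flatnonzero(keep):
        gj = G[:, j]
        gj = gj[gj != MISSING]
        n_het = int(np.sum(gj == 1))
        n_ref = int(np.sum(gj == 0))
        n_alt = int(np.sum(gj == 2))
        if hwe_exact_midp(n_het, n_ref, n_alt) < hwe_p:
            keep[j] = False

    if exempt_ids is not None:
        keep |= out.variants["id"].isin(list(exempt_ids)).to_numpy()

    return out.take_variants(np.flatnonzero(keep))


def ld_prune(
    gset: GenotypeSet,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.8,
) -> GenotypeSet:
    """Greedy windowed LD pruning on genotype r².

    Within each window of ``window`` SNPs (slid by ``step``), for every pair
    with squared Pearson correlation of genotype counts above ``r2_max`` the
    later SNP (larger index) is dropped. Missing genotypes are mean-imputed
    for the correlation only.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step >= window:
        raise ValueError("step must be smaller than window")
    G = gset.genotypes.astype(float)
    G[gset.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(col_mean, inds[1])
    G -= G.mean(axis=0)

    S = gset.n_variants
    keep = np.ones(S, dtype=bool)
    # pruning respects chromosome boundaries
    chrom = gset.variants["chrom"].to_numpy()
    start_of_chrom = np.r_[0, np.flatnonzero(chrom[1:] != chrom[:-1]) + 1, S]
    for c0, c1 in zip(start_of_chrom[:-1], start_of_chrom[1:]):
        lo = c0
        while lo < c1:
            hi = min(lo + window, c1)
            idx = np.flatnonzero(keep[lo:hi]) + lo
            if idx.size >= 2:
                X = G[:, idx]
                sd = X.std(axis=0)
                sd[sd == 0] = np.inf
                R = (X.T @ X) / len(X) / np.outer(sd, sd)
                r2 = R**2
                for a in range(len(idx)):
                    if not keep[idx[a]]:
                        continue
                    for b in range(a + 1, len(idx)):
                        if keep[idx[b]] and r2[a, b] > r2_max:
                            keep[idx[b]] = False
            if hi == c1:
                break
            lo += step
    return gset.take_variants(np.flatnonzero(keep))
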