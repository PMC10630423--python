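"""Format round-trips and QC filter behavior."""

import gzip

import numpy as np
import pandas as pd
import pytest

from euradmix import genio, simdata
from euradmix.genio import (
    GenotypeSet,
    hwe_exact_midp,
    ld_prune,
    qc_filter,
    read_genetic_map,
    read_qp_matrices,
    read_vcf,
    write_qp_matrices,
    write_vcf,
)


class TestVcf:
    def test_handcrafted_vcf_parsed(self, tiny_vcf):
        g = read_vcf(str(tiny_vcf))
        assert g.genotypes.shape == (2, 3)
        assert np.array_equal(g.genotypes, [[0, 1, 2], [1, 2, 0]])
        # record with GT "1|0" -> genotype 1, haplotypes (1, 0)
        assert g.haplotypes[2, 0] == 1 and g.haplotypes[3, 0] == 0
        assert list(g.variants["pos"]) == [100, 200, 300]

    @pytest.mark.parametrize("mode", ["phased", "unphased", "missing"])
    def test_round_trip_byte_identical(self, tmp_path, small_panel, mode):
        gset, _ = simdata.simulate_admixed_cohort(
            small_panel.__class__(
                freqs=small_panel.freqs[:, :50],
                drift=small_panel.drift,
                cluster_F=small_panel.cluster_F,
                map_cM=small_panel.map_cM[:50],
                chrom=small_panel.chrom[:50],
                bp=small_panel.bp[:50],
                snp_ids=small_panel.snp_ids[:50],
            ),
            6,
            np.tile([0.5, 0.5], (6, 1)),
            10,
            seed=31,
        )
        if mode == "unphased":
            gset = GenotypeSet(gset.genotypes, gset.variants, gset.samples)
        elif mode == "missing":
            G = gset.genotypes.copy()
            G[0, 0] = genio.MISSING
            gset = GenotypeSet(G, gset.variants, gset.samples)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(gset, str(p1))
        back = read_vcf(str(p1))
        assert np.array_equal(back.genotypes, gset.genotypes)
        write_vcf(back, str(p2))
        body1 = [l for l in p1.read_text().splitlines() if not l.startswith("##")]
        body2 = [l for l in p2.read_text().splitlines() if not l.startswith("##")]
        assert body1 == body2

    def test_multiallelic_rejected(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\t.\tA\tG,T\t.\t.\t.\tGT\t1/2\n"
        )
        path = tmp_path / "multi.vcf"
        path.write_text(text)
        with pytest.raises(ValueError, match="multiallelic"):
            read_vcf(str(path))


class TestGeneticMap:
    def test_interpolation_and_clamping(self, tmp_path):
        path = tmp_path / "test.map"
        path.write_text("1\ts1\t0.0\t1000\n1\ts2\t2.0\t3000\n")
        gmap = read_genetic_map(str(path))
        assert gmap.interpolate("1", [2000])[0] == pytest.approx(1.0)  # midpoint
        assert gmap.interpolate("1", [500])[0] == pytest.approx(0.0)  # clamp left
        assert gmap.interpolate("1", [3000])[0] == pytest.approx(2.0)  # exact

    def test_decreasing_cm_rejected(self, tmp_path):
        path = tmp_path / "bad.map"
        path.write_text("1\ts1\t2.0\t1000\n1\ts2\t1.0\t3000\n")
        with pytest.raises(ValueError, match="decreasing"):
            read_genetic_map(str(path))

    def test_gzip_accepted(self, tmp_path):
        path = tmp_path / "test.map.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("1\ts1\t0.0\t1000\n")
        gmap = read_genetic_map(str(path))
        assert len(gmap.table) == 1


class TestQpMatrices:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet([1, 1, 1], 10)
        P = rng.uniform(0.1, 0.9, (3, 40))
        write_qp_matrices(Q, P, tmp_path / "x.Q", tmp_path / "x.P")
        Q2, P2 = read_qp_matrices(tmp_path / "x.Q", tmp_path / "x.P", n_variants=40)
        assert np.allclose(Q, Q2, atol=1e-6)
        assert np.allclose(P, P2, atol=1e-6)

    def test_transposed_p_rejected(self, tmp_path):
        np.savetxt(tmp_path / "x.Q", np.ones((5, 1)))
        np.savetxt(tmp_path / "x.P", np.full((1, 40), 0.5).T.reshape(40, 1).T)
        with pytest.raises(ValueError):
            read_qp_matrices(tmp_path / "x.Q", tmp_path / "x.P", n_variants=40)

    def test_bad_row_sum_rejected(self, tmp_path):
        np.savetxt(tmp_path / "x.Q", np.array([[0.6, 0.6]]))
        np.savetxt(tmp_path / "x.P", np.full((4, 2), 0.5))
        with pytest.raises(ValueError, match="row sums"):
            read_qp_matrices(tmp_path / "x.Q", tmp_path / "x.P")


def _toy_gset(G, cm=None):
    G = np.asarray(G, dtype=np.int8)
    n, S = G.shape
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * S,
            "pos": np.arange(1, S + 1) * 100,
            "id": [f"v{j}" for j in range(S)],
            "ref": "A",
            "alt": "G",
            "cM": cm if cm is not None else np.arange(S, dtype=float),
        }
    )
    samples = pd.DataFrame({"id": [f"s{i}" for i in range(n)]})
    return GenotypeSet(G, variants, samples)


class TestHweMidp:
    def test_matches_monte_carlo_pairing_oracle(self):
        # oracle: shuffle 2n alleles into pairs, tabulate het counts
        rng = np.random.default_rng(42)
        n, n_alt = 10, 6
        alleles = np.array([1] * n_alt + [0] * (2 * n - n_alt))
        hets = np.empty(40_000, dtype=int)
        for r in range(len(hets)):
            perm = rng.permutation(alleles).reshape(n, 2)
            hets[r] = np.sum(perm.sum(axis=1) == 1)
        obs_het = 2
        probs = np.bincount(hets, minlength=2 * n + 1) / len(hets)
        p_obs = probs[obs_het]
        mc_midp = probs[probs <= p_obs + 1e-12].sum() - 0.5 * p_obs
        n_hom_alt = (n_alt - obs_het) // 2
        got = hwe_exact_midp(obs_het, n - obs_het - n_hom_alt, n_hom_alt)
        assert got == pytest.approx(mc_midp, abs=0.02)

    def test_extreme_homozygote_excess_significant(self):
        # 25 AA + 25 aa, zero hets: wildly out of HWE
        assert hwe_exact_midp(0, 25, 25) < 1e-6


class TestQcFilter:
    def test_low_maf_removed(self):
        G = np.zeros((100, 3), dtype=np.int8)
        G[:50, 0] = 1  # MAF 0.25
        G[0, 1] = 1  # MAF 0.005
        G[:20, 2] = 1  # MAF 0.10
        out = qc_filter(_toy_gset(G))
        assert list(out.variants["id"]) == ["v0", "v2"]

    def test_hwe_violation_removed(self):
        rng = np.random.default_rng(1)
        good = rng.binomial(2, 0.5, size=(50, 2)).astype(np.int8)
        bad = np.array([0] * 25 + [2] * 25, dtype=np.int8)[:, None]
        out = qc_filter(_toy_gset(np.hstack([good, bad])))
        assert out.n_variants == 2

    def test_clean_input_unchanged_and_idempotent(self, admixed_cohort):
        gset, _ = admixed_cohort
        once = qc_filter(gset)
        twice = qc_filter(once)
        assert np.array_equal(once.genotypes, twice.genotypes)

    def test_all_samples_removed_raises(self):
        G = np.full((3, 10), genio.MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            qc_filter(_toy_gset(G))


class TestLdPrune:
    def test_duplicated_snp_column_pruned(self):
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.4, size=(80, 5)).astype(np.int8)
        G = np.hstack([base, base[:, [0]]])  # duplicate of column 0
        out = ld_prune(_toy_gset(G), window=6, step=2)
        assert out.n_variants == 5
        assert "v0" in list(out.variants["id"])  # the earlier copy is kept

    def test_independent_snps_untouched(self):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, 0.5, size=(500, 20)).astype(np.int8)
        # brute-force confirm independence before asserting no pruning
        X = G - G.mean(axis=0)
        R = np.corrcoef(X.T) ** 2
        np.fill_diagonal(R, 0)
        assert R.max() < 0.8
        out = ld_prune(_toy_gset(G))
        assert out.n_variants == 20

    def test_three_identical_keep_one(self):
        rng = np.random.default_rng(4)
        col = rng.binomial(2, 0.5, size=(60, 1)).astype(np.int8)
        G = np.hstack([col, col, col])
        out = ld_prune(_toy_gset(G), window=3, step=1)
        assert out.n_variants == 1
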