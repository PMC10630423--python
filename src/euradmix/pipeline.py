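"""Orchestration of the three headline experiments on synthetic cohorts.

* ``run_coverage_demo`` — fit a reference PCA and measure how much of the
  reference panel's PC1–PC2 convex hull nested sub-panels cover.
* ``run_admixture_demo`` — cross-validate the number of ancestry clusters,
  estimate supervised ancestry proportions, cluster F_ST, ancestry–geography
  rank correlations, f3 admixture tests and the F_ST–F_IT assortative-mating
  signature.
* ``run_association_demo`` — the full stratification story: simulate a
  confounded trait, QC, prune relatives, compute the GRM, both PC flavors
  and locus-specific ancestry dosages, then walk the nested adjustment
  ladder at the focal SNP and report genomic-control λ for a small GWAS with
  and without local-ancestry covariates.

Every demo is deterministic given its :class:`ScenarioConfig` seed; configs
round-trip to TOML.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import admixprop, assoc, dating, localanc, popstats, relatedness, simdata, structure
from .genio import GenotypeSet, qc_filter, write_qp_matrices

__all__ = [
    "ScenarioConfig",
    "run_coverage_demo",
    "run_admixture_demo",
    "run_association_demo",
    "run_dating_demo",
]

# pairwise cluster F_ST targets: North-SW 0.033, North-SE 0.032, SW-SE 0.028
DEFAULT_DRIFT = [[0.0, 0.033, 0.032], [0.033, 0.0, 0.028], [0.032, 0.028, 0.0]]
# focal-SNP frequencies: the lactase-persistence pattern, ~0.93 North vs ~0.03 South
DEFAULT_FOCAL_FREQS = [0.931, 0.029, 0.029]


@dataclass
class ScenarioConfig:
    """Seeded configuration for one synthetic experiment."""

    seed: int = 0
    n_ind: int = 400
    n_snps: int = 4000
    drift: list = field(default_factory=lambda: [row[:] for row in DEFAULT_DRIFT])
    generations: int = 50
    # None = classic shared-alpha cohort; a float in [0,1] switches to the
    # offspring-generation mating model (0 = random mating)
    assortment_r: float | None = None
    beta_anc: float = 1.0
    beta_snp: float = 0.0
    noise_sd: float = 1.0
    focal_freqs: list = field(default_factory=lambda: list(DEFAULT_FOCAL_FREQS))
    n_pcs: int = 4
    out_dir: str = "euradmix_out"

    def to_toml(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                val = getattr(self, f.name)
                if val is None:  # TOML has no null; absent key = default None
                    continue
                fh.write(f"{f.name} = {json.dumps(val)}\n")

    @classmethod
    def from_toml(cls, path: str) -> "ScenarioConfig":
        with open(path, "rb") as fh:
            return cls(**tomllib.load(fh))


def _outdir(config: ScenarioConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _panel_and_reference(config: ScenarioConfig, rng):
    """Ancestral panel plus near-pure reference individuals per cluster."""
    panel = simdata.draw_ancestral_frequencies(
        config.n_snps, np.array(config.drift), seed=int(rng.integers(2**31))
    )
    K = panel.n_ancestries
    n_per = max(config.n_ind // (3 * K), 20)
    alpha = np.vstack([np.tile(np.eye(K)[k], (n_per, 1)) for k in range(K)])
    ref, _ = simdata.simulate_admixed_cohort(
        panel, len(alpha), alpha, generations=config.generations,
        seed=int(rng.integers(2**31)),
    )
    labels = np.repeat(np.arange(K), n_per)
    return panel, ref, labels


def run_coverage_demo(config: ScenarioConfig) -> dict:
    """Convex-hull coverage of nested sub-panels over a reference PC space."""
    rng = np.random.default_rng(config.seed)
    panel, ref, labels = _panel_and_reference(config, rng)
    if ref.n_samples < 3:
        raise ValueError("reference panel too small for a hull")
    model = structure.pca_fit(ref, n_axes=2)
    scores = model.scores
    rows = [("full_panel", structure.convex_hull_coverage(scores, scores))]
    for k in range(panel.n_ancestries):
        sub = scores[labels == k]
        rows.append((f"cluster{k}_only", structure.convex_hull_coverage(scores, sub)))
    for k in range(panel.n_ancestries):
        sub = scores[labels != k]
        rows.append((f"drop_cluster{k}", structure.convex_hull_coverage(scores, sub)))
    table = pd.DataFrame(rows, columns=["panel", "coverage"])
    out = _outdir(config)
    table.to_csv(out / "coverage.tsv", sep="\t", index=False)
    np.savetxt(out / "ref_scores.tsv", scores, delimiter="\t")
    return {"coverage": table, "pct_variance": model.pct_variance.tolist()}


def run_admixture_demo(config: ScenarioConfig, k_range=(1, 2, 3, 4)) -> dict:
    """Cluster-count CV, supervised Q, cluster F_ST, geography, f3, F_IT."""
    rng = np.random.default_rng(config.seed)
    panel, ref, labels = _panel_and_reference(config, rng)
    gset, truth = simdata.simulate_admixed_cohort(
        panel,
        config.n_ind,
        simdata.gradient_alpha_sampler(),
        generations=config.generations,
        assortment_r=config.assortment_r,
        seed=int(rng.integers(2**31)),
    )

    cv = admixprop.cross_validate_k(gset, k_range, seed=config.seed)
    best_k = min(cv, key=cv.get)

    # supervised run: reference individuals fixed to their cluster
    combined = GenotypeSet(
        np.vstack([ref.genotypes, gset.genotypes]),
        gset.variants,
        pd.concat([ref.samples, gset.samples], ignore_index=True),
    )
    sup_labels = np.r_[labels, np.full(gset.n_samples, -1)]
    model = admixprop.fit_admixture(
        combined, panel.n_ancestries, supervised_labels=sup_labels, seed=config.seed
    )
    Q_targets = model.Q[ref.n_samples:]

    K = panel.n_ancestries
    fst_rows = [
        (i, j, popstats.hudson_fst(model.P[i], model.P[j]))
        for i in range(K)
        for j in range(i + 1, K)
    ]

    geo = {}
    if truth.lat is not None:
        for k in range(K):
            rho_lat, p_lat = stats.spearmanr(Q_targets[:, k], truth.lat)
            rho_lon, p_lon = stats.spearmanr(Q_targets[:, k], truth.lon)
            geo[f"cluster{k}"] = {
                "rho_lat": float(rho_lat), "p_lat": float(p_lat),
                "rho_lon": float(rho_lon), "p_lon": float(p_lon),
            }

    target_freqs = gset.allele_frequencies()
    f3_rows = []
    for i in range(K):
        for j in range(i + 1, K):
            r = popstats.f3_statistic(
                target_freqs, 2 * gset.n_samples, panel.freqs[i], panel.freqs[j],
                block_size_snps=max(gset.n_variants // 20, 50),
            )
            f3_rows.append((i, j, r.f3, r.se, r.z, r.significant))

    south = 0.5 * (panel.freqs[1] + panel.freqs[2]) if K >= 3 else panel.freqs[1]
    rho_fit, p_fit = popstats.fst_fit_correlation(gset, panel.freqs[0], south)

    out = _outdir(config)
    order = np.argsort(-Q_targets[:, 0])  # descending northern ancestry
    write_qp_matrices(Q_targets[order], model.P, out / "targets.Q", out / "model.P")
    pd.DataFrame(f3_rows, columns=["srcA", "srcB", "f3", "se", "z", "significant"]).to_csv(
        out / "f3.tsv", sep="\t", index=False
    )
    return {
        "cv": cv,
        "best_k": best_k,
        "Q": Q_targets,
        "truth_alpha": truth.alpha,
        "cluster_fst": pd.DataFrame(fst_rows, columns=["i", "j", "fst"]),
        "geography": geo,
        "f3": f3_rows,
        "fst_fit_rho": rho_fit,
        "fst_fit_p": p_fit,
    }


def run_dating_demo(config: ScenarioConfig, n_snps_per_chrom: int = 1500) -> dict:
    """Weighted-LD dating of a two-way single-pulse cohort."""
    rng = np.random.default_rng(config.seed)
    panel = simdata.draw_ancestral_frequencies(
        22 * n_snps_per_chrom, np.array([[0.0, 0.1], [0.1, 0.0]]),
        seed=int(rng.integers(2**31)),
    )
    alpha = np.full((config.n_ind, 2), 0.5)
    gset, _ = simdata.simulate_admixed_cohort(
        panel, config.n_ind, alpha, generations=config.generations,
        seed=int(rng.integers(2**31)),
    )
    est = dating.date_with_jackknife(gset, panel.freqs[0] - panel.freqs[1])
    out = _outdir(config)
    pd.DataFrame(
        [(est.generations, est.se, est.z, est.significant)],
        columns=["generations", "se", "z", "significant"],
    ).to_csv(out / "date.tsv", sep="\t", index=False)
    return {"estimate": est, "true_generations": config.generations}


def run_association_demo(config: ScenarioConfig, n_gwas_snps: int = 0) -> dict:
    """End-to-end stratified-association experiment at the focal SNP."""
    rng = np.random.default_rng(config.seed)
    panel, ref, labels = _panel_and_reference(config, rng)
    panel = simdata.plant_differentiated_snp(panel, np.array(config.focal_freqs))
    ref_f, _ = simdata.simulate_admixed_cohort(
        panel,
        ref.n_samples,
        np.vstack([np.tile(np.eye(3)[k], (ref.n_samples // 3, 1)) for k in range(3)]),
        generations=config.generations,
        seed=int(rng.integers(2**31)),
    )
    gset, truth = simdata.simulate_admixed_cohort(
        panel,
        config.n_ind,
        simdata.gradient_alpha_sampler(),
        generations=config.generations,
        assortment_r=config.assortment_r,
        seed=int(rng.integers(2**31)),
    )
    trait = simdata.simulate_trait(
        truth, gset, config.beta_anc, config.beta_snp, config.noise_sd,
        seed=int(rng.integers(2**31)),
    )

    # the focal variant is exempt from SNP-level QC: its Wahlund homozygote
    # excess is structural, and it is the variant under study
    gset_qc = qc_filter(gset, exempt_ids=["focal"])
    focal_j = int(np.flatnonzero(gset_qc.variants["focal"].to_numpy())[0])

    kin = relatedness.estimate_ibd_moments(gset_qc, freqs=None)
    keep = relatedness.prune_related(kin, n_samples=gset_qc.n_samples)
    gset_qc = gset_qc.take_samples(keep)
    pos = {s: i for i, s in enumerate(gset.samples["id"])}
    orig = np.array([pos[s] for s in gset_qc.samples["id"]])
    y = trait.values[orig]
    alpha_kept = truth.alpha[orig]

    grm = assoc.compute_grm(gset_qc, exclude=[focal_j])

    ref_model = structure.pca_fit(
        ref_f.take_variants(
            gset.variants.index[gset.variants["id"].isin(gset_qc.variants["id"])].to_numpy()
        ),
        n_axes=config.n_pcs,
    )
    ref_pcs = structure.pca_project(gset_qc, ref_model)
    pop_pcs = structure.pca_fit(gset_qc, n_axes=config.n_pcs).scores

    # two-way local ancestry: North (cluster 0) vs merged South references
    col_idx = gset.variants.index[gset.variants["id"].isin(gset_qc.variants["id"])].to_numpy()
    pN = panel.freqs[0][col_idx]
    pS = 0.5 * (panel.freqs[1][col_idx] + panel.freqs[2][col_idx])
    alpha2 = np.column_stack([alpha_kept[:, 0], 1 - alpha_kept[:, 0]])
    lap = localanc.infer_local_ancestry(
        gset_qc.haplotypes,
        np.vstack([pN, pS]),
        gset_qc.variants["cM"].to_numpy(),
        gset_qc.variants["chrom"].to_numpy(),
        G=float(config.generations),
        prior_alpha=alpha2,
    )
    # leave-one-out dosage at the tested SNP so the covariate carries
    # ancestry information but not the focal allele itself
    lap_loo = localanc.infer_local_ancestry(
        gset_qc.haplotypes,
        np.vstack([pN, pS]),
        gset_qc.variants["cM"].to_numpy(),
        gset_qc.variants["chrom"].to_numpy(),
        G=float(config.generations),
        prior_alpha=alpha2,
        mask_markers=[focal_j],
    )
    local_focal = lap_loo.dosage[:, focal_j]

    ladder = assoc.nested_adjustment_scan(
        y, grm, ref_pcs, pop_pcs, local_focal, gset_qc.genotypes[:, focal_j]
    )

    report = {
        "ladder": ladder,
        "delta_aic_ref_vs_pop": ladder.attrs["delta_aic_ref_vs_pop"],
        "n_kept": len(keep),
    }

    d_ref = np.sqrt(((ref_pcs[:, None, :] - ref_pcs[None, :, :]) ** 2).sum(-1))
    d_pop = np.sqrt(((pop_pcs[:, None, :] - pop_pcs[None, :, :]) ** 2).sum(-1))
    rho, p_mantel = structure.mantel_test(d_ref, d_pop, n_perm=199, seed=config.seed)
    report["mantel_rho"] = rho
    report["mantel_p"] = p_mantel

    if n_gwas_snps:
        cols = rng.choice(
            np.setdiff1d(np.arange(gset_qc.n_variants), [focal_j]),
            size=min(n_gwas_snps, gset_qc.n_variants - 1),
            replace=False,
        )
        pv_plain, pv_local = [], []
        for j in cols:
            g = gset_qc.genotypes[:, j]
            pv_plain.append(assoc.test_snp(y, None, None, g, adjustment="unadjusted").p)
            pv_local.append(
                assoc.test_snp(
                    y, ref_pcs, grm, g, local_dosage=lap.dosage[:, j],
                    adjustment="full",
                ).p
            )
        report["lambda_unadjusted"] = assoc.genomic_control_lambda(np.array(pv_plain))
        report["lambda_adjusted"] = assoc.genomic_control_lambda(np.array(pv_local))

    out = _outdir(config)
    ladder.to_csv(out / "ladder.tsv", sep="\t", index=False)
    return report
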