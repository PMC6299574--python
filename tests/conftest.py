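import numpy as np
import pandas as pd
import pytest

from popmeth.methio import GenotypeMatrix, MethylationMatrix, make_sample_table
from popmeth.simdata import (
    PlantedEffectMap,
    PopulationSpec,
    default_daf_profiles,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """156-sample cohort with one planted meQTL, one population shift, one
    cis eQTL and one cis eQTM (annotations arranged so links are in window)."""
    daf = default_daf_profiles(100, seed=3)
    n_cpgs, n_genes = 50, 10
    rng = np.random.default_rng(7)
    cpg_annot = pd.DataFrame(
        {
            "chrom": daf["chrom"].to_numpy()[rng.integers(0, len(daf), n_cpgs)],
            "pos": 1,
            "enhancer": rng.random(n_cpgs) < 0.3,
            "promoter": rng.random(n_cpgs) < 0.3,
        },
        index=pd.Index([f"cg{i + 1:06d}" for i in range(n_cpgs)], name="cpg_id"),
    )
    # anchor each CpG near a random SNP on its chromosome
    for i, cg in enumerate(cpg_annot.index):
        chrom_snps = daf[daf["chrom"] == cpg_annot.loc[cg, "chrom"]]
        cpg_annot.loc[cg, "pos"] = int(chrom_snps["pos"].iloc[i % len(chrom_snps)]) + 500
    # pin the planted meQTL CpG next to rs5
    cpg_annot.loc["cg000001", ["chrom", "pos"]] = [daf.loc["rs5", "chrom"], daf.loc["rs5", "pos"] + 200]
    gene_annot = pd.DataFrame(
        {
            "chrom": [daf["chrom"].iloc[i * 7] for i in range(n_genes)],
            "tss": [int(daf["pos"].iloc[i * 7]) + 1000 for i in range(n_genes)],
            "is_tf": [False] * n_genes,
        },
        index=pd.Index([f"gene{i + 1:04d}" for i in range(n_genes)], name="gene_id"),
    )
    # eQTL gene0002 near rs30; eQTM cg000003 near gene0003's TSS
    gene_annot.loc["gene0002", ["chrom", "tss"]] = [daf.loc["rs30", "chrom"], int(daf.loc["rs30", "pos"]) + 800]
    cpg_annot.loc["cg000003", ["chrom", "pos"]] = [
        gene_annot.loc["gene0003", "chrom"],
        int(gene_annot.loc["gene0003", "tss"]) + 400,
    ]
    effects = PlantedEffectMap(
        meqtl_effects=[("rs5", "cg000001", 1.0)],
        population_shifts=[("cg000002", 0.2)],
        eqtl_effects=[("rs30", "gene0002", 0.8)],
        eqtm_links=[("cg000003", "gene0003", -1.0)],
    )
    spec = PopulationSpec(daf_profiles=daf)
    geno, meth, expr_ns, expr_stim, samples, truth = simulate_cohort(
        spec, effects, seed=11, cpg_annotation=cpg_annot, gene_annotation=gene_annot
    )
    return {
        "genotypes": geno,
        "methylation": meth,
        "expr_ns": expr_ns,
        "expr_stim": expr_stim,
        "samples": samples,
        "truth": truth,
        "daf": daf,
    }


@pytest.fixture()
def tiny_meth():
    """4 probes x 3 samples with detection p-values and exclusion flags."""
    beta = pd.DataFrame(
        np.array(
            [
                [0.1, 0.5, 0.9, 0.3],
                [0.2, 0.6, 0.8, 0.4],
                [0.15, 0.55, 0.85, 0.35],
            ]
        ),
        index=["s1", "s2", "s3"],
        columns=["p1", "p2", "p3", "p4"],
    )
    det = pd.DataFrame(np.zeros((3, 4)), index=beta.index, columns=beta.columns)
    annot = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [100, 200, 300, 400],
            "cross_hybridizing": [False] * 4,
            "sex_chromosome": [False] * 4,
            "snp_overlap": [False] * 4,
        },
        index=beta.columns,
    )
    return MethylationMatrix(beta.copy(), det.copy(), annot.copy())


@pytest.fixture()
def two_pop_samples():
    rng = np.random.default_rng(0)
    n = 40
    ids = [f"s{i}" for i in range(n)]
    pops = ["AFB"] * (n // 2) + ["EUB"] * (n // 2)
    cov = pd.DataFrame(
        rng.standard_normal((n, 2)), index=ids, columns=["sv1", "sv2"]
    )
    return make_sample_table(ids, pops, rng.uniform(20, 50, n), cov)
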