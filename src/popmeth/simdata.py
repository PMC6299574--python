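"""Synthetic genotype-methylation-expression cohorts with planted structure.

Every downstream stage of the pipeline (differential methylation, QTL/QTM
mapping, specificity classification, enrichment, mediation) is validated on
data generated here, where the ground truth — which SNP drives which CpG,
which CpG drives which gene, which CpGs differ between populations — is known
by construction.

Two generators are provided:

* :func:`simulate_causal_trio` implements the standardized causal construction
  used for mediation benchmarking: a genotype G is standardized; methylation
  is built as ``M = sqrt(alpha)*G_std + sqrt(1-alpha)*eps``; expression as
  ``E = sqrt(gamma*beta)*M_std + sqrt(gamma*tau)*G_std +
  sqrt(1-gamma*(beta+tau))*zeta`` with standard-normal residuals. ``alpha``
  is the fraction of methylation variance explained by genotype, ``gamma``
  the total fraction of expression variance explained jointly by G and M,
  and ``beta``/``tau`` the mediated and direct shares of that fraction
  (``beta + tau = 1`` on the benchmark grid).

* :func:`simulate_cohort` builds a full two-population cohort (default
  78 + 78 samples) with LD-structured genotypes, CpG methylation carrying
  planted cis/trans genetic effects and population mean shifts, and gene
  expression carrying planted eQTL/eQTM/mediation links plus a stimulated
  condition for response-QTM tests.

Genotypes within an LD block follow a Gaussian-copula AR(1) haplotype model:
each haplotype draws a latent Gaussian vector with correlation
``exp(-distance/ld_decay)`` between adjacent SNPs and thresholds it at the
population allele frequency, giving correct marginal frequencies and
distance-decaying LD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from popmeth.methio import (
    ExpressionMatrix,
    GenotypeMatrix,
    MethylationMatrix,
    beta_to_m,
    m_to_beta,
    make_sample_table,
)

SCENARIOS = ("mediation", "direct_only", "independent", "null")


@dataclass
class SimulationParams:
    """Parameters of the standardized causal-trio construction.

    alpha : fraction of methylation variance explained by genotype, in [0,1].
    beta : mediated share of the explained expression variance, in [0,1].
    tau : direct (genetic) share, in [0,1]. On the benchmark grid
        ``beta + tau = 1``; other settings are allowed but flagged.
    gamma : total fraction of expression variance explained by G and M
        jointly, in [0,1]. Requires ``gamma*(beta+tau) <= 1``.
    n_samples : number of individuals to draw (>= 10).
    seed : RNG seed.
    scenario : one of "mediation", "direct_only", "independent", "null".
    """

    alpha: float
    beta: float
    tau: float
    gamma: float
    n_samples: int
    seed: int = 0
    scenario: str = "mediation"

    def __post_init__(self):
        for name in ("alpha", "beta", "tau", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.gamma * (self.beta + self.tau) > 1.0 + 1e-12:
            raise ValueError("gamma*(beta+tau) > 1: negative noise weight")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.scenario == "mediation" and abs(self.beta + self.tau - 1.0) > 1e-9:
            warnings.warn("mediation scenario usually has beta + tau = 1")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def simulate_causal_trio(
    params: SimulationParams,
    genotype_freq: float = 0.3,
    rng: np.random.Generator | None = None,
    on_monomorphic: str = "resample",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one (genotype, methylation, expression) trio of length n_samples.

    The genotype is binomial(2, genotype_freq); methylation and expression
    follow the standardized causal construction described in the module
    docstring. For the ``direct_only`` scenario the mediated share is forced
    to 0, for ``independent`` methylation receives no genetic effect, and for
    ``null`` expression is pure noise (gamma = 0).

    Returns aligned vectors (G dosage, M, E); seeded runs are reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    alpha, beta, tau, gamma = params.alpha, params.beta, params.tau, params.gamma
    if params.scenario == "direct_only":
        beta = 0.0
    elif params.scenario == "independent":
        alpha = 0.0
        beta = 0.0
    elif params.scenario == "null":
        gamma = 0.0
    n = params.n_samples

    g = rng.binomial(2, genotype_freq, size=n).astype(float)
    tries = 0
    while g.std() == 0:
        if on_monomorphic == "error":
            raise ValueError("monomorphic genotype draw")
        tries += 1
        if tries > 1000:
            raise ValueError("could not draw a polymorphic genotype")
        g = rng.binomial(2, genotype_freq, size=n).astype(float)
    g_std = _standardize(g)

    eps = rng.standard_normal(n)
    m = np.sqrt(alpha) * g_std + np.sqrt(1.0 - alpha) * eps
    m_std = _standardize(m)

    zeta = rng.standard_normal(n)
    noise_w = 1.0 - gamma * (beta + tau)
    e = np.sqrt(gamma * beta) * m_std + np.sqrt(gamma * tau) * g_std + np.sqrt(noise_w) * zeta
    return g, m, e


@dataclass
class PopulationSpec:
    """Cohort layout for :func:`simulate_cohort`.

    daf_profiles : DataFrame indexed by SNP id with columns ``daf_afb`` and
        ``daf_eub`` (derived-allele frequencies per population) and optional
        ``chrom``/``pos``; if positions are absent SNPs are laid out on
        pseudo-chromosomes in blocks of ``ld_block_length``.
    ld_decay : latent-correlation decay length in bp (copula AR(1)).
    """

    labels: tuple[str, str] = ("AFB", "EUB")
    n_per_pop: tuple[int, int] = (78, 78)
    daf_profiles: pd.DataFrame | None = None
    ld_block_length: int = 1_000_000
    ld_decay: float = 20_000.0
    age_ranges: tuple[tuple[float, float], tuple[float, float]] = ((20.0, 50.0), (20.0, 50.0))

    def validate(self):
        if self.daf_profiles is not None:
            f = self.daf_profiles[["daf_afb", "daf_eub"]].to_numpy()
            if ((f < 0) | (f > 1)).any():
                raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class PlantedEffectMap:
    """Ground-truth ledger of the effects planted into a simulated cohort.

    meqtl_effects : list of (snp_id, cpg_id, effect in M units per derived allele)
    eqtl_effects : list of (snp_id, gene_id, effect in log2-expression units)
    eqtm_links : list of (cpg_id, gene_id, coupling in log2 units per M sd;
        sign encodes direction)
    population_shifts : list of (cpg_id, delta_beta) mean beta differences
        (AFB minus EUB)
    trans_hubs : list of (snp_id, tuple of cpg_ids, effect) distant-control hubs
    response_effects : list of (cpg_id, gene_id, coupling) links between basal
        methylation and the stimulated-vs-basal expression fold change
    """

    meqtl_effects: list = field(default_factory=list)
    eqtl_effects: list = field(default_factory=list)
    eqtm_links: list = field(default_factory=list)
    population_shifts: list = field(default_factory=list)
    trans_hubs: list = field(default_factory=list)
    response_effects: list = field(default_factory=list)


def _copula_genotypes(rng, freqs: np.ndarray, positions: np.ndarray, n: int, decay: float) -> np.ndarray:
    """Draw n diploid dosage rows for one LD block via the copula AR(1) model."""
    from scipy.stats import norm

    m = len(freqs)
    thresh = norm.ppf(freqs)
    rho = np.exp(-np.abs(np.diff(positions)) / decay) if m > 1 else np.array([])
    haps = np.empty((2 * n, m))
    z = rng.standard_normal(2 * n)
    haps[:, 0] = z
    for j in range(1, m):
        innov = rng.standard_normal(2 * n)
        z = rho[j - 1] * z + np.sqrt(1 - rho[j - 1] ** 2) * innov
        haps[:, j] = z
    alleles = (haps < thresh).astype(np.int8)
    return (alleles[0::2] + alleles[1::2]).astype(float)


def default_daf_profiles(
    n_snps: int,
    seed: int,
    fraction_differentiated: float = 0.2,
    block_length: int = 1_000_000,
    snps_per_block: int = 20,
) -> pd.DataFrame:
    """Frequency profiles for a cohort: mostly shared frequencies, a fraction
    with population-differentiated derived-allele frequencies."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.05, 0.95, size=n_snps)
    daf_afb = base.copy()
    daf_eub = base.copy()
    k = int(round(fraction_differentiated * n_snps))
    idx = rng.choice(n_snps, size=k, replace=False)
    shift = rng.uniform(0.2, 0.5, size=k) * rng.choice([-1, 1], size=k)
    daf_eub[idx] = np.clip(daf_eub[idx] + shift, 0.02, 0.98)
    chrom = [f"chr{1 + i // (snps_per_block * 50)}" for i in range(n_snps)]
    pos = [
        (i // snps_per_block) % 50 * block_length + 10_000 + (i % snps_per_block) * 2_000
        for i in range(n_snps)
    ]
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "daf_afb": daf_afb, "daf_eub": daf_eub},
        index=pd.Index([f"rs{i + 1}" for i in range(n_snps)], name="snp_id"),
    )


def simulate_cohort(
    spec: PopulationSpec,
    effects: PlantedEffectMap,
    seed: int,
    cpg_annotation: pd.DataFrame | None = None,
    gene_annotation: pd.DataFrame | None = None,
    n_cpgs: int | None = None,
    n_genes: int | None = None,
    meth_noise_sd: float = 0.5,
    expr_noise_sd: float = 0.5,
    age_effect_sd: float = 0.0,
    n_surrogate: int = 2,
):
    """Generate a full two-population cohort with planted effects.

    Genotypes are drawn per population from ``spec.daf_profiles`` with LD
    within blocks; methylation is built on the M scale as baseline + planted
    genetic effects + population shifts + Gaussian noise and stored as beta;
    expression is built on the log2 scale with planted eQTL and eQTM links,
    plus a stimulated condition carrying planted response effects.

    Returns ``(genotypes, methylation, expression_ns, expression_stim,
    samples, truth)`` where ``truth`` echoes the planted-effect map.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    labels = spec.labels
    n_a, n_b = spec.n_per_pop

    daf = spec.daf_profiles
    if daf is None:
        daf = default_daf_profiles(200, seed=rng.integers(2**31))
    snp_ids = daf.index

    sample_ids = [f"{labels[0]}{i + 1:03d}" for i in range(n_a)] + [
        f"{labels[1]}{i + 1:03d}" for i in range(n_b)
    ]
    population = [labels[0]] * n_a + [labels[1]] * n_b

    # --- genotypes, block by block, population by population
    if "chrom" not in daf.columns or "pos" not in daf.columns:
        daf = daf.copy()
        daf["chrom"] = "chr1"
        daf["pos"] = np.arange(len(daf)) * 2000 + 1
    block_key = list(
        zip(daf["chrom"], (daf["pos"].astype(int) - 1) // int(spec.ld_block_length))
    )
    dos = np.empty((n_a + n_b, len(daf)))
    for key in dict.fromkeys(block_key):  # preserve order
        cols = np.array([i for i, k in enumerate(block_key) if k == key])
        pos = daf["pos"].to_numpy()[cols]
        fa = daf["daf_afb"].to_numpy()[cols]
        fb = daf["daf_eub"].to_numpy()[cols]
        dos[:n_a, cols] = _copula_genotypes(rng, fa, pos, n_a, spec.ld_decay)
        dos[n_a:, cols] = _copula_genotypes(rng, fb, pos, n_b, spec.ld_decay)
    snp_info = pd.DataFrame(
        {
            "chrom": daf["chrom"],
            "pos": daf["pos"].astype(int),
            "ref": "A",
            "alt": "G",
            "ancestral": "A",
            "derived": "G",
        },
        index=snp_ids,
    )
    genotypes = GenotypeMatrix(
        pd.DataFrame(dos, index=pd.Index(sample_ids, name="sample_id"), columns=snp_ids),
        snp_info,
    )

    # --- CpG layout
    if cpg_annotation is None:
        if n_cpgs is None:
            n_cpgs = 100
        anchors = rng.choice(len(daf), size=n_cpgs, replace=True)
        cpg_annotation = pd.DataFrame(
            {
                "chrom": daf["chrom"].to_numpy()[anchors],
                "pos": daf["pos"].to_numpy()[anchors] + rng.integers(-5000, 5000, size=n_cpgs),
                "enhancer": rng.random(n_cpgs) < 0.2,
                "promoter": rng.random(n_cpgs) < 0.2,
            },
            index=pd.Index([f"cg{i + 1:06d}" for i in range(n_cpgs)], name="cpg_id"),
        )
        cpg_annotation["pos"] = cpg_annotation["pos"].clip(lower=1)
    cpg_ids = cpg_annotation.index

    # --- methylation on M scale
    n_samp = n_a + n_b
    mu0 = rng.uniform(-3, 3, size=len(cpg_ids))
    M = np.tile(mu0, (n_samp, 1))
    ages = np.concatenate(
        [rng.uniform(*spec.age_ranges[0], size=n_a), rng.uniform(*spec.age_ranges[1], size=n_b)]
    )
    if age_effect_sd > 0:
        age_coef = rng.normal(0, age_effect_sd, size=len(cpg_ids))
        M += np.outer((ages - ages.mean()) / ages.std(), age_coef)

    cpg_pos = {c: i for i, c in enumerate(cpg_ids)}
    snp_pos = {s: i for i, s in enumerate(snp_ids)}
    for snp, cpg, eff in effects.meqtl_effects:
        M[:, cpg_pos[cpg]] += eff * dos[:, snp_pos[snp]]
    for snp, cpgs, eff in effects.trans_hubs:
        for cpg in cpgs:
            M[:, cpg_pos[cpg]] += eff * dos[:, snp_pos[snp]]
    is_afb = np.array([p == labels[0] for p in population])
    clamped = 0
    # population shift: applied to AFB on the M scale, sized so the mean beta
    # difference (AFB - EUB) at the baseline equals the requested delta-beta
    for cpg, dbeta in effects.population_shifts:
        j = cpg_pos[cpg]
        b0 = m_to_beta(np.array([mu0[j]]))[0]
        b1 = np.clip(b0 + dbeta, 1e-4, 1 - 1e-4)
        if abs((b1 - b0) - dbeta) > 1e-9:
            clamped += 1
        M[is_afb, j] += beta_to_m(np.array([b1]))[0] - mu0[j]
    if clamped:
        warnings.warn(f"{clamped} population shift(s) clamped to keep beta in (0, 1)")
    M += rng.normal(0, meth_noise_sd, size=M.shape)
    beta = np.clip(m_to_beta(M), 1e-6, 1 - 1e-6)
    methylation = MethylationMatrix(
        pd.DataFrame(beta, index=pd.Index(sample_ids, name="sample_id"), columns=cpg_ids),
        annotation=cpg_annotation,
    )

    # --- expression on log2 scale
    if gene_annotation is None:
        if n_genes is None:
            n_genes = 30
        anchors = rng.choice(len(daf), size=n_genes, replace=True)
        gene_annotation = pd.DataFrame(
            {
                "chrom": daf["chrom"].to_numpy()[anchors],
                "tss": daf["pos"].to_numpy()[anchors] + rng.integers(-5000, 5000, size=n_genes),
                "is_tf": rng.random(n_genes) < 0.1,
            },
            index=pd.Index([f"gene{i + 1:04d}" for i in range(n_genes)], name="gene_id"),
        )
        gene_annotation["tss"] = gene_annotation["tss"].clip(lower=1)
    gene_ids = gene_annotation.index
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    base = rng.uniform(2, 6, size=len(gene_ids))
    Y = np.tile(base, (n_samp, 1))
    M_std = (M - M.mean(axis=0)) / np.where(M.std(axis=0) == 0, 1, M.std(axis=0))
    for snp, gene, eff in effects.eqtl_effects:
        Y[:, gene_pos[gene]] += eff * dos[:, snp_pos[snp]]
    for cpg, gene, coupling in effects.eqtm_links:
        Y[:, gene_pos[gene]] += coupling * M_std[:, cpg_pos[cpg]]
    Y += rng.normal(0, expr_noise_sd, size=Y.shape)
    fpkm_ns = np.exp2(Y)

    # stimulated condition: global response + planted methylation-coupled response
    resp = rng.normal(1.0, 0.5, size=len(gene_ids))
    Y_stim = Y + resp
    for cpg, gene, coupling in effects.response_effects:
        Y_stim[:, gene_pos[gene]] += coupling * M_std[:, cpg_pos[cpg]]
    Y_stim += rng.normal(0, expr_noise_sd, size=Y_stim.shape)
    fpkm_stim = np.exp2(Y_stim)

    expr_ns = ExpressionMatrix(
        pd.DataFrame(fpkm_ns, index=pd.Index(sample_ids, name="sample_id"), columns=gene_ids),
        gene_annotation,
        condition="NS",
    )
    expr_stim = ExpressionMatrix(
        pd.DataFrame(fpkm_stim, index=pd.Index(sample_ids, name="sample_id"), columns=gene_ids),
        gene_annotation,
        condition="STIM",
    )

    covariates = pd.DataFrame(
        rng.standard_normal((n_samp, n_surrogate)),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"sv{i + 1}" for i in range(n_surrogate)],
    )
    samples = make_sample_table(sample_ids, population, ages, covariates)
    return genotypes, methylation, expr_ns, expr_stim, samples, effects


def simulate_ld_pair(freq: float, r2: float, n: int, seed: int) -> np.ndarray:
    """Draw an n x 2 dosage matrix of a causal SNP and a proxy at target R^2.

    Haplotype alleles at the proxy copy the causal allele and are flipped to
    an independent draw with the probability that yields haplotype
    correlation sqrt(r2) (exact for matching frequencies).
    """
    rng = np.random.default_rng(seed)
    r = np.sqrt(r2)
    haps = np.empty((2 * n, 2), dtype=np.int8)
    a = rng.random(2 * n) < freq
    flip = rng.random(2 * n) > r
    b = np.where(flip, rng.random(2 * n) < freq, a)
    haps[:, 0] = a
    haps[:, 1] = b
    return (haps[0::2] + haps[1::2]).astype(float)


def simulate_gwas_catalog(
    genotypes: GenotypeMatrix,
    n_traits: int,
    hit_fraction: float,
    enrichment_in,
    seed: int,
    odds_multiplier: float = 1.0,
    n_categories: int = 5,
    ld_r2_min: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a GWAS-catalog-like hit table and a pairwise LD (R^2) table.

    Hits are drawn Bernoulli per SNP with probability ``hit_fraction``,
    multiplied (on the odds scale) by ``odds_multiplier`` for SNPs in
    ``enrichment_in``. Each hit receives a trait, a parent category, and a
    genome-wide-significant p-value. The LD table reports dosage-correlation
    R^2 for same-chromosome SNP pairs with R^2 >= ``ld_r2_min``.
    """
    if not 0.0 <= hit_fraction <= 1.0:
        raise ValueError("hit_fraction must lie in [0, 1]")
    if len(genotypes.snp_ids) == 0:
        raise ValueError("empty SNP universe")
    rng = np.random.default_rng(seed)
    enrichment_in = set(enrichment_in)

    base_odds = hit_fraction / (1.0 - hit_fraction) if hit_fraction < 1 else np.inf
    rows = []
    for snp in genotypes.snp_ids:
        odds = base_odds * (odds_multiplier if snp in enrichment_in else 1.0)
        p_hit = 1.0 if np.isinf(odds) else odds / (1.0 + odds)
        if rng.random() < p_hit:
            trait = f"trait{rng.integers(n_traits) + 1}"
            cat = f"category{rng.integers(n_categories) + 1}"
            rows.append({"snp": snp, "trait": trait, "parent_category": cat, "p": 10.0 ** rng.uniform(-30, -8)})
    gwas = pd.DataFrame(rows, columns=["snp", "trait", "parent_category", "p"])

    dos = genotypes.dosages.to_numpy()
    info = genotypes.snp_info
    ld_rows = []
    for chrom, grp in info.groupby("chrom", sort=False):
        idx = [genotypes.snp_ids.get_loc(s) for s in grp.index]
        sub = dos[:, idx]
        sd = sub.std(axis=0)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        sub = sub[:, ok]
        ids = np.array(grp.index)[ok]
        corr = np.corrcoef(sub.T)
        r2 = corr**2
        iu = np.triu_indices(len(ids), k=1)
        keep = r2[iu] >= ld_r2_min
        for a, b, v in zip(iu[0][keep], iu[1][keep], r2[iu][keep]):
            ld_rows.append({"snp_a": ids[a], "snp_b": ids[b], "r2": float(v)})
    ld = pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"])
    return gwas, ld
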