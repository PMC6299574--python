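"""cis/trans meQTL, eQTL and eQTM mapping with permutation FDR.

Associations between molecular features (CpG M values, log2 expression, or
log2 fold-change responses) and predictors (SNP dosages or CpG M values) are
tested within a genomic window of the feature's anchor (CpG position or gene
TSS). Genotype predictors are tested twice — an additive linear model with
covariates, and a Kruskal-Wallis rank test across genotype classes on
covariate-residualized values — and a significant association must pass both.
Methylation predictors are tested by Spearman rank correlation.

Significance thresholds are calibrated by permutation: feature values are
shuffled within each population, the mapping re-run, and the per-feature
minimum p-value retained; the FDR at a candidate threshold t is the mean
permuted count of features with min-p <= t over the observed count, and the
reported threshold is the largest candidate with FDR at or below the target
(feature-level FDR). Secondary signals are found by stepwise conditioning:
the feature is residualized on the lead SNP and the window re-mapped until
no SNP passes the threshold.

The linear test uses the Frisch-Waugh-Lovell reduction: feature and dosage
are both residualized on the covariates and the partial correlation is
converted to a t statistic with n - k - 1 degrees of freedom, which is
exactly the covariate-adjusted additive model's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from popmeth.methio import GenotypeMatrix, MethylationMatrix

#: Candidate grid for permutation-FDR thresholds: {1, 5} x 10^-k, k = 2..12.
DEFAULT_P_GRID = tuple(
    sorted(c * 10.0**-k for k in range(2, 13) for c in (1.0, 5.0))
)

SCOPES = ("joint", "AFB", "EUB")

RECORD_COLUMNS = [
    "feature_id",
    "predictor_id",
    "distance",
    "beta",
    "p_linear",
    "p_kw",
    "rho_spearman",
    "p_spearman",
    "scope",
    "conditional_rank",
]


def _covariate_matrix(samples: pd.DataFrame, covariate_names, add_ancestry: bool) -> np.ndarray:
    cols = [np.ones(len(samples))]
    for name in covariate_names:
        cols.append(samples[name].to_numpy(dtype=float))
    if add_ancestry:
        pops = sorted(samples["population"].unique())
        cols.append((samples["population"] == pops[0]).astype(float).to_numpy())
    return np.column_stack(cols)


def residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of Y on the covariate matrix X."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef


def _kw_pvalues(values: np.ndarray, dosages: np.ndarray) -> np.ndarray:
    """Kruskal-Wallis p for one value vector against each dosage column.

    Values are ranked once; rank sums per genotype class are accumulated with
    indicator products, with the standard tie correction. Columns with fewer
    than two genotype classes get NaN.
    """
    n = len(values)
    r = stats.rankdata(values)
    # tie correction depends only on the value vector
    _, counts = np.unique(values, return_counts=True)
    tie_c = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    classes = np.rint(dosages).astype(int)
    stat = np.zeros(dosages.shape[1])
    k_classes = np.zeros(dosages.shape[1], dtype=int)
    for cls in (0, 1, 2):
        mask = classes == cls
        n_g = mask.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rsum = r @ mask
            stat += np.where(n_g > 0, rsum**2 / np.maximum(n_g, 1), 0.0)
        k_classes += (n_g > 0).astype(int)
    h = (12.0 / (n * (n + 1))) * stat - 3.0 * (n + 1)
    if tie_c > 0:
        h = h / tie_c
    p = np.full(dosages.shape[1], np.nan)
    ok = k_classes >= 2
    p[ok] = stats.chi2.sf(h[ok], k_classes[ok] - 1)
    return p


def _linear_test(rf: np.ndarray, rg: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Effect size and p-value of the residualized additive model.

    rf : residualized feature (n,); rg : residualized dosages (n, m);
    df : residual degrees of freedom (n - covariates - 2).
    """
    gss = (rg**2).sum(axis=0)
    fss = (rf**2).sum()
    cross = rg.T @ rf
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(gss > 0, cross / gss, np.nan)
        r = np.where((gss > 0) & (fss > 0), cross / np.sqrt(gss * fss), np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, p


@dataclass
class CisMapConfig:
    window: int = 100_000
    maf_min: float = 0.05
    covariate_names: tuple = ("age", "sv1", "sv2", "gpc1", "gpc2")
    run_kw: bool = True


def _scope_samples(samples: pd.DataFrame, scope: str) -> pd.Index:
    if scope == "joint":
        return samples.index
    return samples.index[samples["population"] == scope]


def map_cis(
    features: pd.DataFrame,
    feature_anchors: pd.DataFrame,
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    config: CisMapConfig | None = None,
    scope: str = "joint",
) -> pd.DataFrame:
    """Map cis associations between features and SNPs within a window.

    Parameters
    ----------
    features : DataFrame, samples x features
        M values (meQTL), log2 expression (eQTL), or log2 fold changes (reQTL).
    feature_anchors : DataFrame indexed by feature id
        Columns ``chrom`` and ``pos`` (CpG position or gene TSS).
    scope : "joint" (all samples, ancestry covariate added) or a population
        label (that population only).

    SNPs below the MAF threshold in the analyzed samples are excluded;
    SNPs with fewer than two genotype classes are skipped. Returns one
    record per feature-SNP pair with both test p-values.
    """
    config = config or CisMapConfig()
    if config.window <= 0:
        raise ValueError("window must be positive")
    idx = _scope_samples(samples, scope)
    sub_samples = samples.loc[idx]
    feat = features.loc[idx]
    dos_all = genotypes.dosages.loc[idx]

    maf = genotypes.maf(samples=idx)
    snp_ok = maf >= config.maf_min
    info = genotypes.snp_info.loc[snp_ok[snp_ok].index]

    covs = [c for c in config.covariate_names if c in sub_samples.columns]
    X = _covariate_matrix(sub_samples, covs, add_ancestry=(scope == "joint"))
    n, k = X.shape
    df = n - k - 1

    rF = residualize(feat.to_numpy(), X)
    dos_np = dos_all[info.index].to_numpy()
    rG_all = residualize(dos_np, X)
    snp_index = {s: j for j, s in enumerate(info.index)}

    # group SNPs by chromosome, sorted by position, for window lookups
    by_chrom = {
        chrom: grp.sort_values("pos") for chrom, grp in info.groupby("chrom", sort=False)
    }

    records = []
    for fi, fid in enumerate(features.columns):
        anchor = feature_anchors.loc[fid]
        grp = by_chrom.get(anchor["chrom"])
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, anchor["pos"] - config.window, side="left")
        hi = np.searchsorted(pos, anchor["pos"] + config.window, side="right")
        if hi <= lo:
            continue
        snps = grp.index[lo:hi]
        cols = [snp_index[s] for s in snps]
        rg = rG_all[:, cols]
        beta, p_lin = _linear_test(rF[:, fi], rg, df)
        if config.run_kw:
            vals = rF[:, fi]
            p_kw = _kw_pvalues(vals, dos_np[:, cols])
        else:
            p_kw = np.full(len(cols), np.nan)
        dist = pos[lo:hi] - int(anchor["pos"])
        for j, snp in enumerate(snps):
            if np.isnan(beta[j]):
                continue
            records.append(
                (fid, snp, int(dist[j]), beta[j], p_lin[j], p_kw[j], np.nan, np.nan, scope, 1)
            )
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def map_all_scopes(features, feature_anchors, genotypes, samples, config=None) -> pd.DataFrame:
    """Run joint + per-population mappings and concatenate the records."""
    pops = sorted(samples["population"].unique())
    frames = [
        map_cis(features, feature_anchors, genotypes, samples, config, scope)
        for scope in ("joint", *pops)
    ]
    return pd.concat(frames, ignore_index=True)


def feature_min_p(records: pd.DataFrame, p_col: str = "p_linear") -> pd.Series:
    """Most significant p per feature across predictors and scopes."""
    return records.groupby("feature_id")[p_col].min()


@dataclass
class FdrThreshold:
    test_family: str
    p_star: float | None
    fdr_level: float
    n_permutations: int
    fdr_at_grid: dict = field(default_factory=dict)
    permuted_minima: list = field(default_factory=list)

    @property
    def attained(self) -> bool:
        return self.p_star is not None


def permute_within_population(values: pd.DataFrame, samples: pd.DataFrame, rng) -> pd.DataFrame:
    """Shuffle sample rows of a feature matrix within each population."""
    perm = np.arange(len(values))
    pos = {sid: i for i, sid in enumerate(values.index)}
    for _, grp in samples.groupby("population", sort=False):
        ids = [pos[s] for s in grp.index if s in pos]
        shuffled = rng.permutation(ids)
        perm[ids] = shuffled
    return pd.DataFrame(values.to_numpy()[perm], index=values.index, columns=values.columns)


def permutation_fdr(
    observed_min_p: pd.Series,
    features: pd.DataFrame,
    samples: pd.DataFrame,
    mapping,
    n_perm: int = 100,
    fdr_level: float = 0.05,
    candidate_grid=DEFAULT_P_GRID,
    seed: int = 0,
    test_family: str = "cis_meqtl",
) -> FdrThreshold:
    """Feature-level permutation FDR threshold.

    ``mapping`` is a closure taking a (permuted) feature matrix and returning
    the per-feature minimum p-value Series. The FDR at threshold t is the
    mean permuted discovery count divided by the observed discovery count;
    the returned ``p_star`` is the largest grid value with FDR <= fdr_level
    (None when no grid point attains it).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    grid = np.array(sorted(candidate_grid))
    obs = observed_min_p.to_numpy()
    obs_counts = np.array([(obs <= t).sum() for t in grid])

    perm_minima = []
    perm_counts = np.zeros((n_perm, len(grid)))
    for b in range(n_perm):
        permuted = permute_within_population(features, samples, rng)
        minima = mapping(permuted).to_numpy()
        perm_minima.append(minima)
        perm_counts[b] = [(minima <= t).sum() for t in grid]

    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(obs_counts > 0, perm_counts.mean(axis=0) / obs_counts, np.nan)
    fdr_at_grid = {float(t): (float(f) if np.isfinite(f) else None) for t, f in zip(grid, fdr)}
    ok = np.isfinite(fdr) & (fdr <= fdr_level)
    p_star = float(grid[ok].max()) if ok.any() else None
    return FdrThreshold(
        test_family=test_family,
        p_star=p_star,
        fdr_level=fdr_level,
        n_permutations=n_perm,
        fdr_at_grid=fdr_at_grid,
        permuted_minima=perm_minima,
    )


def significant_records(records: pd.DataFrame, p_star_linear: float, p_star_kw: float | None = None) -> pd.DataFrame:
    """Keep records passing the linear threshold and (for genotype predictors)
    the Kruskal-Wallis threshold: the dual-test significance rule."""
    keep = records["p_linear"] <= p_star_linear
    if p_star_kw is not None:
        keep &= records["p_kw"].fillna(1.0) <= p_star_kw
    return records[keep].copy()


def lead_predictor(records: pd.DataFrame) -> pd.DataFrame:
    """Best predictor per feature: smallest p_linear, then largest |beta|,
    then smallest |distance| as the final deterministic tie-break."""
    r = records.copy()
    r["_abs_beta"] = -r["beta"].abs()
    r["_abs_dist"] = r["distance"].abs()
    r = r.sort_values(["feature_id", "p_linear", "_abs_beta", "_abs_dist"], kind="mergesort")
    return r.groupby("feature_id", sort=False).head(1).drop(columns=["_abs_beta", "_abs_dist"])


def stepwise_conditional(
    feature_id,
    features: pd.DataFrame,
    feature_anchors: pd.DataFrame,
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    p_star: float,
    config: CisMapConfig | None = None,
    scope: str = "joint",
    max_rank: int = 5,
) -> pd.DataFrame:
    """Find independent cis signals for one feature by stepwise conditioning.

    The window is mapped, the lead SNP recorded if it passes ``p_star`` on
    both tests, the feature residualized on that SNP's dosage, and the
    process repeated until no SNP passes or ``max_rank`` is reached.
    Returns the ordered records (possibly empty) with conditional_rank set.
    """
    config = config or CisMapConfig()
    idx = _scope_samples(samples, scope)
    feat = features.loc[idx, [feature_id]].copy()
    found = []
    for rank in range(1, max_rank + 1):
        recs = map_cis(feat, feature_anchors, genotypes, samples.loc[idx], config, scope)
        if recs.empty:
            break
        best = lead_predictor(recs).iloc[0]
        if best["p_linear"] > p_star or (
            config.run_kw and not np.isnan(best["p_kw"]) and best["p_kw"] > p_star
        ):
            break
        rec = best.copy()
        rec["conditional_rank"] = rank
        found.append(rec)
        g = genotypes.dosages.loc[idx, [best["predictor_id"]]].to_numpy()
        X = np.column_stack([np.ones(len(g)), g])
        feat.iloc[:, 0] = residualize(feat.to_numpy(), X)[:, 0]
    return pd.DataFrame(found, columns=RECORD_COLUMNS) if found else pd.DataFrame(columns=RECORD_COLUMNS)


def trans_candidate_snps(
    genotypes: GenotypeMatrix,
    gene_info: pd.DataFrame,
    cis_eqtl_records: pd.DataFrame | None,
    tss_window: int = 10_000,
) -> pd.Index:
    """Trans-mapping SNP universe: cis-eQTL SNPs of transcription-factor genes
    plus all SNPs within ``tss_window`` of an expressed TF gene's TSS."""
    tf = gene_info[gene_info.get("is_tf", pd.Series(False, index=gene_info.index))]
    snps = set()
    if cis_eqtl_records is not None and not cis_eqtl_records.empty:
        tf_recs = cis_eqtl_records[cis_eqtl_records["feature_id"].isin(tf.index)]
        snps.update(tf_recs["predictor_id"])
    info = genotypes.snp_info
    for _, gene in tf.iterrows():
        near = info[
            (info["chrom"] == gene["chrom"]) & ((info["pos"] - gene["tss"]).abs() <= tss_window)
        ]
        snps.update(near.index)
    if not snps:
        raise ValueError("empty trans-mapping SNP universe")
    return pd.Index([s for s in genotypes.snp_ids if s in snps])


def map_trans(
    meth: MethylationMatrix,
    genotypes: GenotypeMatrix,
    candidate_snps: pd.Index,
    samples: pd.DataFrame,
    trans_min: int = 1_000_000,
    covariate_names=("age", "sv1", "sv2", "gpc1", "gpc2"),
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Trans meQTL scan: Kruskal-Wallis tests of candidate SNPs against all
    CpGs at least ``trans_min`` away or on another chromosome.

    Run on all samples jointly; CpG M values are residualized on ancestry and
    covariates before ranking.
    """
    idx = samples.index.intersection(meth.sample_ids)
    samples = samples.loc[idx]
    covs = [c for c in covariate_names if c in samples.columns]
    X = _covariate_matrix(samples, covs, add_ancestry=True)
    M = residualize(meth.m.loc[idx].to_numpy(), X)
    dos = genotypes.dosages.loc[idx]
    maf = genotypes.maf(samples=idx)
    candidate_snps = pd.Index([s for s in candidate_snps if maf[s] >= maf_min])
    if len(candidate_snps) == 0:
        raise ValueError("no candidate SNPs pass the MAF filter")
    annot = meth.annotation
    info = genotypes.snp_info

    records = []
    cpg_chrom = annot["chrom"].to_numpy()
    cpg_posv = annot["pos"].to_numpy()
    cpg_ids = np.asarray(annot.index)
    col_of = {c: i for i, c in enumerate(meth.cpg_ids)}
    for snp in candidate_snps:
        srow = info.loc[snp]
        far = (cpg_chrom != srow["chrom"]) | (np.abs(cpg_posv - srow["pos"]) >= trans_min)
        if not far.any():
            continue
        g = dos[snp].to_numpy()[:, None]
        cols = [col_of[c] for c in cpg_ids[far]]
        for c_id, col in zip(cpg_ids[far], cols):
            p_kw = _kw_pvalues(M[:, col], g)[0]
            if np.isnan(p_kw):
                continue
            same = srow["chrom"] == annot.loc[c_id, "chrom"]
            dist = int(srow["pos"] - annot.loc[c_id, "pos"]) if same else np.nan
            records.append((c_id, snp, dist, np.nan, np.nan, p_kw, np.nan, np.nan, "joint", 1))
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def fold_change(fpkm_stim, fpkm_ns):
    """Stimulation response with a +1 pseudocount guarding low FPKM.

    diff = log2((1 + FPKM_stim) / (1 + FPKM_ns)); fold = 2^diff.
    """
    s = np.asarray(fpkm_stim, dtype=float)
    n = np.asarray(fpkm_ns, dtype=float)
    if (s < 0).any() or (n < 0).any():
        raise ValueError("FPKM must be non-negative")
    diff = np.log2(1.0 + s) - np.log2(1.0 + n)
    return diff, np.exp2(diff)


def _spearman_block(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and t-approximation p of x against each column of Y."""
    n = len(x)
    rx = stats.rankdata(x)
    rY = np.apply_along_axis(stats.rankdata, 0, Y)
    rx = rx - rx.mean()
    rY = rY - rY.mean(axis=0)
    denom = np.sqrt((rx**2).sum() * (rY**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rx @ rY / denom, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return rho, p


def map_eqtm(
    expression: pd.DataFrame,
    meth: MethylationMatrix,
    gene_anchors: pd.DataFrame,
    samples: pd.DataFrame,
    window: int = 100_000,
    scope: str = "joint",
) -> pd.DataFrame:
    """eQTM scan: Spearman correlation of each gene's expression (or response
    fold change) with CpG M values within ``window`` of its TSS.

    Constant expression vectors are skipped. Rank correlation needs no
    covariate model; scopes subset the samples (joint uses all).
    """
    idx = _scope_samples(samples, scope).intersection(expression.index)
    expr = expression.loc[idx]
    M = meth.m.loc[idx]
    annot = meth.annotation
    by_chrom = {chrom: grp.sort_values("pos") for chrom, grp in annot.groupby("chrom", sort=False)}
    col_of = {c: i for i, c in enumerate(M.columns)}
    M_np = M.to_numpy()

    records = []
    for gene in expr.columns:
        anchor = gene_anchors.loc[gene]
        grp = by_chrom.get(anchor["chrom"])
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        tss = int(anchor["tss"] if "tss" in anchor.index else anchor["pos"])
        lo = np.searchsorted(pos, tss - window, side="left")
        hi = np.searchsorted(pos, tss + window, side="right")
        if hi <= lo:
            continue
        x = expr[gene].to_numpy()
        if x.std() == 0:
            continue
        cpgs = grp.index[lo:hi]
        cols = [col_of[c] for c in cpgs]
        rho, p = _spearman_block(x, M_np[:, cols])
        dist = pos[lo:hi] - tss
        for j, cpg in enumerate(cpgs):
            if np.isnan(rho[j]):
                continue
            records.append((gene, cpg, int(dist[j]), np.nan, np.nan, np.nan, rho[j], p[j], scope, 1))
    return pd.DataFrame(records, columns=RECORD_COLUMNS)
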