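"""Enrichment analyses: genomic-context odds ratios and GWAS-hit enrichment.

Context enrichment compares a CpG set against the full annotation background
with a 2x2 table (Fisher's exact test, Woolf-logit confidence interval).
GWAS enrichment tests whether a SNP set (e.g. meQTLs) overlaps trait hits
more than expected: both query and background are LD-pruned, and the null is
built by resampling background SNPs that match the query's allele-frequency
histogram in 5% bins. The fold is observed over the resample mean; the
p-value comes from a normal fit to the resample distribution, and the
confidence interval from bootstrap resampling of the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContextEnrichment:
    category: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_fisher: float
    table: tuple
    zero_cell_corrected: bool = False


def context_enrichment(query_cpgs, annotation: pd.DataFrame, category: str) -> ContextEnrichment:
    """Odds-ratio enrichment of a CpG set in one annotation category.

    The query's in/out-of-category odds are compared against the *general
    distribution* of the full annotated background (the reference column
    counts every background CpG, query included), so the odds ratio answers
    "how does the query's composition compare with the array as a whole".
    A zero cell triggers the Haldane-Anscombe 0.5 correction for the CI,
    flagged in the result.
    """
    query = pd.Index(query_cpgs)
    if len(query) == 0:
        raise ValueError("empty query set")
    missing = query.difference(annotation.index)
    if len(missing):
        raise ValueError(f"query CpGs absent from background: {list(missing[:5])}")
    in_cat = annotation[category].astype(bool)
    is_query = annotation.index.isin(query)
    a = int((is_query & in_cat).sum())  # query, in category
    b = int((is_query & ~in_cat).sum())
    c = int(in_cat.sum())  # whole background, in category
    d = int((~in_cat).sum())
    odds_ratio, p = stats.fisher_exact([[a, b], [c, d]])
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    log_or = np.log((aa * dd) / (bb * cc))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.975)
    return ContextEnrichment(
        category=category,
        odds_ratio=float(odds_ratio) if not corrected else float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_fisher=float(p),
        table=(a, b, c, d),
        zero_cell_corrected=corrected,
    )


def ld_prune(
    snps,
    ld: pd.DataFrame,
    r2_threshold: float = 0.8,
    scores: pd.Series | None = None,
    positions: pd.Series | None = None,
) -> list:
    """Greedy LD pruning: keep one SNP per correlated group.

    SNPs are visited in order of ascending score (p-value) when ``scores``
    is given, else ascending position, else input order; a SNP is kept iff
    its R^2 with every previously kept SNP is below the threshold. The LD
    table lists pairs (snp_a, snp_b, r2); unlisted pairs are treated as
    unlinked.
    """
    snps = list(snps)
    # symmetric neighbor lookup above threshold
    high = ld[ld["r2"] >= r2_threshold]
    neighbors: dict = {}
    for a, b in zip(high["snp_a"], high["snp_b"]):
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    if scores is not None:
        order = sorted(snps, key=lambda s: (scores.get(s, np.inf), str(s)))
    elif positions is not None:
        order = sorted(snps, key=lambda s: (positions.get(s, np.inf), str(s)))
    else:
        order = snps
    kept, kept_set = [], set()
    for s in order:
        if neighbors.get(s, set()) & kept_set:
            continue
        kept.append(s)
        kept_set.add(s)
    return kept


@dataclass
class GwasEnrichment:
    category: str
    fold: float
    ci_low: float
    ci_high: float
    p_normal_fit: float
    n_resamples: int
    observed_count: int
    resample_mean: float
    resample_sd: float


def _bin_histogram(freqs: np.ndarray, bin_width: float) -> np.ndarray:
    return np.floor(np.clip(freqs, 0, 1 - 1e-12) / bin_width).astype(int)


def gwas_enrichment(
    query_snps,
    gwas_table: pd.DataFrame,
    background_snps,
    freqs: pd.Series,
    n_resamples: int = 10_000,
    bin_width: float = 0.05,
    seed: int = 0,
    categories=None,
) -> list[GwasEnrichment]:
    """Frequency-matched resampling enrichment of a SNP set in GWAS hits.

    For each parent category, the observed count is the number of query
    SNPs in that category's hit set. The expectation is estimated by
    ``n_resamples`` draws of |query| background SNPs matching the query's
    allele-frequency bin histogram exactly; the fold is observed over the
    resample mean, the one-sided p-value comes from a normal fit
    (method-of-moments) to the resample counts, and the 95% CI from
    bootstrap resampling of the query itself. Query and background are
    expected to be LD-pruned beforehand.
    """
    rng_null = np.random.default_rng(seed)
    rng_boot = np.random.default_rng(seed + 1)  # independent stream for the CI
    query = np.asarray(list(query_snps))
    background = np.asarray(list(background_snps))
    if len(query) == 0:
        raise ValueError("empty query set")
    qf = freqs.loc[query].to_numpy()
    bf = freqs.loc[background].to_numpy()
    qbins = _bin_histogram(qf, bin_width)
    bbins = _bin_histogram(bf, bin_width)
    bg_by_bin = {}
    for b in np.unique(qbins):
        pool = background[bbins == b]
        if len(pool) == 0:
            lo, hi = b * bin_width, (b + 1) * bin_width
            raise ValueError(f"query frequency bin [{lo:.2f}, {hi:.2f}) unrepresented in background")
        bg_by_bin[b] = pool
    bin_counts = {b: int((qbins == b).sum()) for b in np.unique(qbins)}

    hits_by_cat = {cat: set(grp["snp"]) for cat, grp in gwas_table.groupby("parent_category")}
    if categories is None:
        categories = sorted(hits_by_cat)

    # integer-coded background pools and per-category hit masks keep the
    # 10,000-draw loop in numpy
    code_of = {s: i for i, s in enumerate(background)}
    bin_pools = {b: np.array([code_of[s] for s in pool]) for b, pool in bg_by_bin.items()}
    hit_mask = {
        cat: np.isin(background, list(hits_by_cat.get(cat, set()))) for cat in categories
    }
    counts = {cat: np.zeros(n_resamples) for cat in categories}
    for i in range(n_resamples):
        draw = np.concatenate(
            [rng_null.choice(bin_pools[b], size=k, replace=False) for b, k in bin_counts.items()]
        )
        for cat in categories:
            counts[cat][i] = hit_mask[cat][draw].sum()

    boot_idx = rng_boot.integers(0, len(query), size=(n_resamples, len(query)))

    results = []
    for cat in categories:
        hit_set = hits_by_cat.get(cat, set())
        observed = int(sum(s in hit_set for s in query))
        mean = float(counts[cat].mean())
        sd = float(counts[cat].std(ddof=1))
        fold = observed / mean if mean > 0 else np.nan
        p = float(stats.norm.sf(observed, loc=mean, scale=sd)) if sd > 0 else (0.0 if observed > mean else 1.0)
        is_hit = np.asarray([s in hit_set for s in query], dtype=float)
        boot_counts = is_hit[boot_idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            boot_folds = boot_counts / mean if mean > 0 else np.full(n_resamples, np.nan)
        lo, hi = (np.percentile(boot_folds, [2.5, 97.5]) if mean > 0 else (np.nan, np.nan))
        results.append(
            GwasEnrichment(
                category=cat,
                fold=float(fold),
                ci_low=float(lo),
                ci_high=float(hi),
                p_normal_fit=p,
                n_resamples=n_resamples,
                observed_count=observed,
                resample_mean=mean,
                resample_sd=sd,
            )
        )
    return results


def expand_hits_by_ld(hit_snps, ld: pd.DataFrame, r2_threshold: float = 0.8) -> set:
    """Expand a GWAS hit set with all SNPs in LD (R^2 above threshold)."""
    hits = set(hit_snps)
    high = ld[ld["r2"] > r2_threshold]
    expanded = set(hits)
    expanded.update(high.loc[high["snp_a"].isin(hits), "snp_b"])
    expanded.update(high.loc[high["snp_b"].isin(hits), "snp_a"])
    return expanded
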