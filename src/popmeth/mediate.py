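"""Causal mediation of genetic effects on expression through DNA methylation.

A *trio* is a gene together with the SNPs that are simultaneously eQTLs of
the gene and meQTLs of at least one of its eQTM CpGs. When a trio carries
several SNPs (or CpGs), an elastic-net fit collapses them into a single
per-sample summary variable. Mediation is then estimated on the linear
system

    mediator model:  M = a*G + covariates + error
    outcome model:   Y = tau*G + b*M + covariates + error

where the average causal mediation effect (ACME) is the product a*b, the
average direct effect (ADE) is tau, and total = ACME + ADE (exact for the
linear specification). Uncertainty is propagated quasi-Bayesianly: model
coefficients are drawn from their estimated sampling distributions, the
ACME is the mean of the per-draw products, and the p-value for "a*b = 0"
comes from a normal fit to the draw distribution. A partial-correlation
test (E vs M given G) is provided as the simpler comparator, and
``benchmark_mediation`` scores both against planted truth on the simulation
grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from popmeth.diffmeth import bh_adjust
from popmeth.simdata import SimulationParams, simulate_causal_trio


@dataclass
class Trio:
    gene_id: str
    cpg_ids: frozenset
    snp_ids: frozenset
    scope: str = "joint"


def detect_trios(
    eqtl_records: pd.DataFrame,
    meqtl_records: pd.DataFrame,
    eqtm_records: pd.DataFrame,
) -> list[Trio]:
    """Intersect significant eQTL, meQTL, and eQTM sets into trios.

    A SNP joins a gene's trio iff it is an eQTL of the gene and a meQTL of
    a CpG that is itself an eQTM of that gene; all qualifying SNPs and CpGs
    for a gene are grouped into a single trio. The three record sets are
    assumed pre-filtered at their respective significance thresholds
    (columns ``feature_id`` / ``predictor_id`` as produced by the mapping
    module: eQTL gene~SNP, meQTL CpG~SNP, eQTM gene~CpG).
    """
    if eqtl_records.empty or meqtl_records.empty or eqtm_records.empty:
        return []
    cpgs_of_snp = meqtl_records.groupby("predictor_id")["feature_id"].agg(set)
    eqtm_cpgs_of_gene = eqtm_records.groupby("feature_id")["predictor_id"].agg(set)
    trios = []
    for gene, grp in eqtl_records.groupby("feature_id"):
        eqtm_cpgs = eqtm_cpgs_of_gene.get(gene, set())
        if not eqtm_cpgs:
            continue
        snps, cpgs = set(), set()
        for snp in set(grp["predictor_id"]):
            shared = cpgs_of_snp.get(snp, set()) & eqtm_cpgs
            if shared:
                snps.add(snp)
                cpgs.update(shared)
        if snps:
            trios.append(Trio(gene_id=gene, cpg_ids=frozenset(cpgs), snp_ids=frozenset(snps)))
    return trios


def elastic_net_summary(
    target: np.ndarray,
    predictors: np.ndarray,
    mixing: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
):
    """Elastic-net summary variable for a multi-predictor trio side.

    Fits a penalized linear model of ``target`` on ``predictors`` over a
    lambda path with k-fold cross-validation, picks lambda by the 1-SE rule
    (largest penalty whose CV error is within one standard error of the
    minimum), and returns the fitted linear combination as the per-sample
    summary. If every coefficient is zero at lambda_1se, falls back to
    lambda_min with a warning flag.

    Returns ``(summary, coefficients, info)``.
    """
    from sklearn.linear_model import ElasticNet, ElasticNetCV
    from sklearn.model_selection import KFold

    y = np.asarray(target, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if y.std() == 0:
        raise ValueError("constant target vector")
    if X.shape[1] < 2:
        raise ValueError("elastic-net summary needs >= 2 predictors")
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    enet_cv = ElasticNetCV(l1_ratio=mixing, cv=cv, alphas=100, max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet_cv.fit(X, y)
    mse_mean = enet_cv.mse_path_.mean(axis=1)
    mse_se = enet_cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(n_folds)
    alphas = enet_cv.alphas_
    i_min = int(np.argmin(mse_mean))
    within = mse_mean <= mse_mean[i_min] + mse_se[i_min]
    alpha_1se = float(alphas[within].max())

    def _fit(alpha):
        model = ElasticNet(alpha=alpha, l1_ratio=mixing, max_iter=50_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        return model

    model = _fit(alpha_1se)
    fallback = False
    if np.all(model.coef_ == 0):
        fallback = True
        warnings.warn("all coefficients zero at lambda_1se; falling back to lambda_min")
        model = _fit(float(alphas[i_min]))
    summary = model.predict(X)
    info = {
        "alpha_1se": alpha_1se,
        "alpha_min": float(alphas[i_min]),
        "lambda_min_fallback": fallback,
        "intercept": float(model.intercept_),
    }
    return summary, model.coef_.copy(), info


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    p_acme: float
    n_draws: int
    prop_mediated: float
    r2_meth: float
    r2_geno: float
    acme_draw_sd: float
    gene_id: str | None = None
    q_value: float | None = None
    mediated: bool | None = None


def _ols_with_cov(y: np.ndarray, X: np.ndarray):
    """OLS fit returning coefficients and their covariance matrix."""
    n, k = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ X.T @ y
    resid = y - X @ coef
    df = n - k
    if df < 1:
        raise ValueError("model has no residual degrees of freedom")
    s2 = float(resid @ resid) / df
    return coef, s2 * xtx_inv


def mediate(
    outcome: np.ndarray,
    mediator: np.ndarray,
    treatment: np.ndarray,
    covariates: np.ndarray | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    gene_id: str | None = None,
) -> MediationResult:
    """Quasi-Bayesian causal mediation estimate for one trio.

    Both models are fit by OLS; coefficient vectors are drawn from the
    multivariate-normal sampling distribution at the estimates; per draw
    ACME = (mediator-model treatment slope) x (outcome-model mediator
    slope) and ADE = outcome-model treatment slope. Point estimates are
    draw means; total = ACME + ADE (the linear-model identity, exact).
    The two-sided p-value for "ACME = 0" comes from a normal fit
    (mean/sd) to the ACME draw distribution. ``r2_meth`` and ``r2_geno``
    are the marginal variance shares of the outcome explained by mediator
    and treatment.
    """
    if n_draws < 100:
        warnings.warn("n_draws < 100 gives unstable mediation p-values")
    rng = np.random.default_rng(seed)
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(mediator, dtype=float)
    g = np.asarray(treatment, dtype=float)
    n = len(y)
    C = (
        np.asarray(covariates, dtype=float).reshape(n, -1)
        if covariates is not None
        else np.empty((n, 0))
    )
    ones = np.ones((n, 1))
    X_med = np.hstack([ones, g[:, None], C])
    X_out = np.hstack([ones, g[:, None], m[:, None], C])

    coef_med, cov_med = _ols_with_cov(m, X_med)
    coef_out, cov_out = _ols_with_cov(y, X_out)

    draws_med = rng.multivariate_normal(coef_med, cov_med, size=n_draws, method="cholesky")
    draws_out = rng.multivariate_normal(coef_out, cov_out, size=n_draws, method="cholesky")
    a_draws = draws_med[:, 1]  # treatment -> mediator
    tau_draws = draws_out[:, 1]  # direct effect
    b_draws = draws_out[:, 2]  # mediator -> outcome
    acme_draws = a_draws * b_draws

    acme = float(acme_draws.mean())
    ade = float(tau_draws.mean())
    total = float((acme_draws + tau_draws).mean())
    sd = float(acme_draws.std(ddof=1))
    p_acme = float(2 * stats.norm.sf(abs(acme), scale=sd)) if sd > 0 else float(acme == 0)

    r2_meth = float(np.corrcoef(y, m)[0, 1] ** 2) if m.std() > 0 else 0.0
    r2_geno = float(np.corrcoef(y, g)[0, 1] ** 2) if g.std() > 0 else 0.0
    prop = acme / total if total != 0 else np.nan
    return MediationResult(
        acme=acme,
        ade=ade,
        total=total,
        p_acme=p_acme,
        n_draws=n_draws,
        prop_mediated=float(prop),
        r2_meth=r2_meth,
        r2_geno=r2_geno,
        acme_draw_sd=sd,
        gene_id=gene_id,
    )


def mediate_trios(
    trios: list[Trio],
    expression: pd.DataFrame,
    methylation_m: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    fdr_level: float = 0.05,
) -> list[MediationResult]:
    """Run mediation across trios with BH correction at the given FDR.

    Single-SNP/single-CpG trios use the raw dosage / M value; multi-member
    sides are collapsed by :func:`elastic_net_summary` (methylation summary
    trained on expression, genotype summary trained on methylation).
    """
    results = []
    cov_np = covariates.to_numpy() if covariates is not None else None
    for i, trio in enumerate(sorted(trios, key=lambda t: t.gene_id)):
        y = expression[trio.gene_id].to_numpy()
        cpgs = sorted(trio.cpg_ids)
        snps = sorted(trio.snp_ids)
        if len(cpgs) == 1:
            m = methylation_m[cpgs[0]].to_numpy()
        else:
            m, _, _ = elastic_net_summary(y, methylation_m[cpgs].to_numpy(), seed=seed + i)
        if len(snps) == 1:
            g = dosages[snps[0]].to_numpy()
        else:
            g, _, _ = elastic_net_summary(m, dosages[snps].to_numpy(), seed=seed + i)
        results.append(
            mediate(y, m, g, cov_np, n_draws=n_draws, seed=seed + i, gene_id=trio.gene_id)
        )
    if results:
        q = bh_adjust(np.array([r.p_acme for r in results]))
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.mediated = bool(qv < fdr_level)
    return results


def partial_correlation_test(expression, methylation, genotype) -> tuple[float, float]:
    """First-order partial correlation of E and M given G, with its t-test p.

    pcor = (r_EM - r_EG*r_MG) / sqrt((1-r_EG^2)(1-r_MG^2)); the p-value uses
    t = pcor*sqrt((n-3)/(1-pcor^2)) on n-3 degrees of freedom.
    """
    e = np.asarray(expression, dtype=float)
    m = np.asarray(methylation, dtype=float)
    g = np.asarray(genotype, dtype=float)
    n = len(e)
    if n < 4:
        raise ValueError("need n >= 4")
    if e.std() == 0 or m.std() == 0 or g.std() == 0:
        raise ValueError("constant input vector")
    r_em = np.corrcoef(e, m)[0, 1]
    r_eg = np.corrcoef(e, g)[0, 1]
    r_mg = np.corrcoef(m, g)[0, 1]
    denom = np.sqrt((1 - r_eg**2) * (1 - r_mg**2))
    pcor = (r_em - r_eg * r_mg) / denom if denom > 0 else np.nan
    pcor = float(np.clip(pcor, -1.0, 1.0))
    if abs(pcor) >= 1.0:
        return pcor, 0.0
    t = pcor * np.sqrt((n - 3) / (1 - pcor**2))
    return pcor, float(2 * stats.t.sf(abs(t), n - 3))


def benchmark_mediation(
    grid: list[SimulationParams],
    n_replicates: int,
    n_samples: int,
    seed: int = 0,
    n_draws: int = 300,
    genotype_freq: float = 0.3,
) -> pd.DataFrame:
    """Score mediation vs partial correlation against planted truth.

    For each grid cell, half the replicates are simulated with the cell's
    parameters (mediated truth when alpha*beta > 0) and half with the
    mediated share set to zero (direct-only null). Both tests score each
    replicate (-log10 p) and the cell's ROC AUC is computed per method,
    along with sensitivity/specificity of each at p < 0.05. Cells whose
    truth is single-class get NaN AUCs and a flag.
    """
    from sklearn.metrics import roc_auc_score

    rows = []
    rng = np.random.default_rng(seed)
    for cell in grid:
        labels, p_med, p_pcor = [], [], []
        for rep in range(n_replicates):
            mediated_truth = rep % 2 == 0 and cell.alpha * cell.beta > 0
            params = SimulationParams(
                alpha=cell.alpha,
                beta=cell.beta if mediated_truth else 0.0,
                tau=cell.tau,
                gamma=cell.gamma,
                n_samples=n_samples,
                scenario="mediation" if mediated_truth else "direct_only",
            )
            g, m, e = simulate_causal_trio(params, genotype_freq, rng=rng)
            res = mediate(e, m, g, n_draws=n_draws, seed=int(rng.integers(2**31)))
            _, pp = partial_correlation_test(e, m, g)
            labels.append(mediated_truth)
            p_med.append(res.p_acme)
            p_pcor.append(pp)
        labels = np.array(labels)
        p_med = np.array(p_med)
        p_pcor = np.array(p_pcor)
        single_class = labels.all() or not labels.any()
        if single_class:
            auc_med = auc_pcor = np.nan
        else:
            score_med = -np.log10(np.maximum(p_med, 1e-300))
            score_pcor = -np.log10(np.maximum(p_pcor, 1e-300))
            auc_med = roc_auc_score(labels, score_med)
            auc_pcor = roc_auc_score(labels, score_pcor)
        pos = labels.sum()
        neg = len(labels) - pos
        rows.append(
            {
                "alpha": cell.alpha,
                "beta": cell.beta,
                "tau": cell.tau,
                "gamma": cell.gamma,
                "auc_mediation": auc_med,
                "auc_partial_correlation": auc_pcor,
                "sensitivity_mediation": (p_med[labels] < 0.05).mean() if pos else np.nan,
                "specificity_mediation": (p_med[~labels] >= 0.05).mean() if neg else np.nan,
                "sensitivity_pcor": (p_pcor[labels] < 0.05).mean() if pos else np.nan,
                "specificity_pcor": (p_pcor[~labels] >= 0.05).mean() if neg else np.nan,
                "single_class": single_class,
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
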