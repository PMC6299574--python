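"""Differential methylation between populations with moderated t-statistics.

Each CpG is fit by OLS on the M scale (``M ~ population + age + covariates``);
residual variances are shrunk toward a common prior by empirical-Bayes
moment matching (Smyth 2004), and sites are called differentially methylated
when the BH-adjusted moderated-t p-value and the raw mean beta difference
both pass their thresholds (defaults: adjusted p < 0.01, |delta beta| > 0.05).
The beta-scale difference is deliberately computed from raw group means,
unadjusted for covariates: M values carry the inference, beta values carry
the effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from popmeth.methio import MethylationMatrix


def build_design(samples: pd.DataFrame, covariate_names, population_col: str = "population") -> tuple[np.ndarray, list]:
    """Intercept + population indicator + named covariates; checks rank.

    The population indicator is 1 for the first population label in sorted
    order (AFB before EUB), so the coefficient is mean(AFB) - mean(EUB) on
    the modelling scale.
    """
    pops = sorted(samples[population_col].unique())
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {pops}")
    indicator = (samples[population_col] == pops[0]).astype(float).to_numpy()
    cols = [np.ones(len(samples)), indicator]
    names = ["intercept", f"population[{pops[0]}]"]
    for name in covariate_names:
        cols.append(samples[name].to_numpy(dtype=float))
        names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns by leave-one-out rank
        bad = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, names


def fit_population_model(
    meth: MethylationMatrix,
    samples: pd.DataFrame,
    covariate_names=("age",),
) -> pd.DataFrame:
    """Per-CpG OLS of M values on population + covariates.

    Returns a DataFrame indexed by CpG id with columns ``effect`` (population
    coefficient, M units), ``se``, ``df`` (residual degrees of freedom),
    ``s2`` (residual variance), and ``t``/``p`` (ordinary t-test).
    """
    samples = samples.loc[meth.sample_ids]
    X, _ = build_design(samples, covariate_names)
    Y = meth.m.to_numpy()
    n, k = X.shape
    if n - k < 1:
        raise ValueError("not enough residual degrees of freedom")
    for pop, grp in samples.groupby("population"):
        if len(grp) < 2:
            raise ValueError(f"population {pop} has fewer than 2 samples")

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y  # k x p
    resid = Y - X @ coef
    df = n - k
    s2 = (resid**2).sum(axis=0) / df
    v_pop = xtx_inv[1, 1]
    effect = coef[1]
    se = np.sqrt(v_pop * s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"effect": effect, "se": se, "df": float(df), "s2": s2, "t": t, "p": p},
        index=meth.cpg_ids,
    )


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(-dif / y < 1e-8):
            break
    return y


def ebayes_moderate(fit: pd.DataFrame, var_floor: float = 1e-12) -> tuple[float, float, pd.DataFrame]:
    """Empirical-Bayes shrinkage of residual variances (moderated t).

    The observed residual variances are modelled as scaled F draws around a
    prior (d0, s0^2); the prior is estimated by moment-matching the log
    variances (mean and variance of log s^2 against digamma/trigamma
    expressions). Posterior variances are the precision-weighted blend
    ``(d0*s0^2 + df*s^2) / (d0 + df)`` and the moderated t uses df + d0
    degrees of freedom. Identical variances land on the d0 = inf branch
    (posterior = common variance) rather than erroring.

    Returns ``(d0, s0_sq, table)`` where the table adds ``s2_post``,
    ``t_moderated``, ``p_moderated`` to the input columns.
    """
    if len(fit) < 10:
        raise ValueError("need >= 10 features for moment matching")
    s2 = np.maximum(fit["s2"].to_numpy(), var_floor)
    df = fit["df"].to_numpy()
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(np.array([evar]))[0]
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    else:
        # no excess dispersion beyond sampling noise: infinite prior df, and
        # the posterior collapses to the common (geometric-mean) variance
        d0 = np.inf
        s0_sq = float(np.exp(z.mean()))
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)

    scale = np.sqrt(s2_post / s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(fit["se"].to_numpy() > 0, fit["effect"].to_numpy() / (fit["se"].to_numpy() * scale), 0.0)
    if np.isinf(d0):
        p_mod = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p_mod = 2 * stats.t.sf(np.abs(t_mod), df_total)
    out = fit.copy()
    out["s2_post"] = s2_post
    out["t_moderated"] = t_mod
    out["p_moderated"] = p_mod
    return float(d0), s0_sq, out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class DmsThresholds:
    alpha_dms: float = 0.01  # adjusted-p threshold
    delta_min: float = 0.05  # minimum |mean beta difference|

    def __post_init__(self):
        if not (0 < self.alpha_dms < 1) or not (0 < self.delta_min < 1):
            raise ValueError("thresholds must lie in (0, 1)")


def extract_dms(
    moderated: pd.DataFrame,
    meth: MethylationMatrix,
    samples: pd.DataFrame,
    thresholds: DmsThresholds | None = None,
) -> pd.DataFrame:
    """Call differentially methylated sites (DMS).

    A CpG is a DMS when its BH-adjusted moderated p-value is below
    ``alpha_dms`` and the absolute difference in raw mean beta between
    populations exceeds ``delta_min``. ``delta_beta`` is signed first
    population minus second (sorted label order, AFB - EUB); ``hyper_in``
    names the population with the higher mean beta (or "none" for non-DMS).
    """
    thresholds = thresholds or DmsThresholds()
    samples = samples.loc[meth.sample_ids]
    pops = sorted(samples["population"].unique())
    beta = meth.beta
    mean_a = beta.loc[samples["population"] == pops[0]].mean(axis=0)
    mean_b = beta.loc[samples["population"] == pops[1]].mean(axis=0)
    delta_beta = (mean_a - mean_b).reindex(moderated.index)

    out = moderated.copy()
    out["p_adjusted"] = bh_adjust(out["p_moderated"].to_numpy())
    out["delta_beta"] = delta_beta
    out["is_dms"] = (out["p_adjusted"] < thresholds.alpha_dms) & (
        out["delta_beta"].abs() > thresholds.delta_min
    )
    out["hyper_in"] = np.where(
        ~out["is_dms"], "none", np.where(out["delta_beta"] > 0, pops[0], pops[1])
    )
    return out


def dms_scan(
    meth: MethylationMatrix,
    samples: pd.DataFrame,
    covariate_names=("age", "sv1", "sv2"),
    thresholds: DmsThresholds | None = None,
) -> pd.DataFrame:
    """Full scan: per-CpG OLS, EB moderation, BH adjustment, DMS call."""
    fit = fit_population_model(meth, samples, covariate_names)
    _, _, moderated = ebayes_moderate(fit)
    return extract_dms(moderated, meth, samples, thresholds)
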