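"""Population-genetic summaries and population-specificity of genetic effects.

Covers per-SNP derived-allele frequencies (DAF) and their between-population
difference, Hudson-style FST, the ExpDiff ratio quantifying how much of an
observed population methylation difference a meQTL explains, and a Bayesian
model-selection classifier for population-specific genetic effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from popmeth.methio import GenotypeMatrix


def hudson_fst(p1, p2):
    """Per-SNP Hudson FST from two population allele frequencies.

    FST = (p1 - p2)^2 / (p1(1-p2) + p2(1-p1)), i.e. 1 - Hw/Hb with
    within- and between-population heterozygosity computed from the plugin
    frequencies. Symmetric in population order; 0 for identical frequencies;
    1 for a fixed difference. NaN where both populations are monomorphic for
    the same allele (Hb = 0).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def allele_frequencies(genotypes: GenotypeMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-population derived-allele frequencies, their difference, and FST.

    Dosages count the derived allele (or the alternate allele when the
    ancestral state is unannotated, flagged in ``derived_is_known``).
    ``delta_daf`` is the second sorted population minus the first
    (EUB - AFB for the default labels).
    """
    pops = sorted(samples["population"].unique())
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    freqs = {}
    for pop in pops:
        ids = samples.index[samples["population"] == pop].intersection(genotypes.sample_ids)
        if len(ids) == 0:
            raise ValueError(f"no genotyped samples in population {pop}")
        freqs[pop] = genotypes.dosages.loc[ids].mean(axis=0) / 2.0
    out = pd.DataFrame(
        {
            f"daf_{pops[0].lower()}": freqs[pops[0]],
            f"daf_{pops[1].lower()}": freqs[pops[1]],
        }
    )
    out["delta_daf"] = freqs[pops[1]] - freqs[pops[0]]
    out["fst"] = hudson_fst(freqs[pops[0]].to_numpy(), freqs[pops[1]].to_numpy())
    if "ancestral" in genotypes.snp_info.columns:
        out["derived_is_known"] = genotypes.snp_info["ancestral"].notna()
    else:
        out["derived_is_known"] = False
    return out


def exp_diff(beta: float, delta_daf: float, delta_meth: float) -> dict:
    """ExpDiff = beta * delta_DAF / delta_Meth.

    ``beta`` is the meQTL effect of the derived allele on methylation,
    ``delta_daf`` the EUB - AFB derived-allele frequency difference, and
    ``delta_meth`` the observed EUB - AFB mean methylation difference. The
    ratio estimates the share of the population methylation difference that
    the meQTL accounts for; it is not bounded to [0, 1] because independent
    effects can oppose the genetic one. ``delta_meth = 0`` yields an
    undefined, flagged record (excluded from summary means).
    """
    if delta_meth == 0:
        return {"exp_diff": np.nan, "defined": False, "beta": beta, "delta_daf": delta_daf, "delta_meth": delta_meth}
    return {
        "exp_diff": beta * delta_daf / delta_meth,
        "defined": True,
        "beta": beta,
        "delta_daf": delta_daf,
        "delta_meth": delta_meth,
    }


def mean_exp_diff(records: pd.DataFrame) -> float:
    """Mean ExpDiff over defined records (the headline genetic-contribution
    summary for a DMS set)."""
    ok = records[records["defined"]]
    return float(ok["exp_diff"].mean())


def _profiled_gaussian_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """Maximized log-likelihood of a Gaussian linear model (profiled variance)."""
    n = len(y)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ coef) ** 2).sum())
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


@dataclass
class SpecificityCall:
    posterior_shared: float
    posterior_first_specific: float
    posterior_second_specific: float
    call: str
    populations: tuple


def classify_specificity(
    meth_values: np.ndarray,
    dosages: np.ndarray,
    samples: pd.DataFrame,
    threshold: float = 0.9,
) -> SpecificityCall:
    """Classify a SNP-CpG effect as shared or population-specific.

    Three Gaussian linear models of the (M-scale) methylation values are
    compared: (i) a common SNP effect plus population intercept, (ii) the
    SNP dosage active only in the second population (zeroed elsewhere), and
    (iii) active only in the first. All three have the same dimension, so
    with equal priors the posterior of each model is the softmax of its
    maximized log-likelihood. A specific call requires that model's
    posterior to exceed ``threshold``; "shared" is assigned whenever the
    common-effect model has the top posterior; anything else is
    "undetermined".
    """
    y = np.asarray(meth_values, dtype=float)
    g = np.asarray(dosages, dtype=float)
    if y.std() == 0:
        raise ValueError("constant methylation vector")
    pops = sorted(samples["population"].unique())
    in_first = (samples["population"] == pops[0]).to_numpy()
    if g.std() == 0:
        raise ValueError("monomorphic SNP")
    pop_col = in_first.astype(float)
    ones = np.ones(len(y))
    g_first = np.where(in_first, g, 0.0)
    g_second = np.where(~in_first, g, 0.0)

    logliks = np.array(
        [
            _profiled_gaussian_loglik(y, np.column_stack([ones, pop_col, g])),
            _profiled_gaussian_loglik(y, np.column_stack([ones, pop_col, g_second])),
            _profiled_gaussian_loglik(y, np.column_stack([ones, pop_col, g_first])),
        ]
    )
    post = np.exp(logliks - logsumexp(logliks))
    if post[1] > threshold:
        call = f"{pops[1]}_specific"
    elif post[2] > threshold:
        call = f"{pops[0]}_specific"
    elif np.argmax(post) == 0:
        call = "shared"
    else:
        call = "undetermined"
    return SpecificityCall(
        posterior_shared=float(post[0]),
        posterior_first_specific=float(post[2]),
        posterior_second_specific=float(post[1]),
        call=call,
        populations=tuple(pops),
    )
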