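"""Data containers, beta/M conversion, probe & sample QC, and TSV/BED/VCF I/O.

Methylation is stored on the beta scale (methylated fraction in [0, 1]); the
M value, its base-2 logit, is the derived view used for statistics. Genomic
positions are 1-based in memory and in TSV; BED output is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Illumina-style genomic-context flags carried by CpG annotation tables.
CONTEXT_FLAGS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "ExonBnd", "3UTR")
#: Regulatory-state flags (monocyte ChromHMM-like).
REGULATORY_FLAGS = ("enhancer", "promoter")
#: Probe-exclusion flags applied before any statistics.
EXCLUSION_FLAGS = ("cross_hybridizing", "sex_chromosome", "snp_overlap")

BETA_EPS = 1e-6


class QcError(ValueError):
    """Raised when QC removes all samples or required inputs are missing."""


def beta_to_m(beta, clamp: bool = True):
    """Convert beta values (methylated fraction) to M values (base-2 logit).

    M = log2(beta / (1 - beta)). M values give near-constant variance across
    the methylation range and are used for all linear modelling; beta values
    are kept for effect-size reporting.

    Parameters
    ----------
    beta : array-like
        Values in [0, 1].
    clamp : bool
        If True, values at or beyond {0, 1} are clamped to
        [1e-6, 1 - 1e-6] with a warning; if False they raise.
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    at_bound = (b <= BETA_EPS) | (b >= 1 - BETA_EPS)
    if np.any(at_bound):
        if not clamp:
            raise ValueError("beta values at {0, 1} with clamp=False")
        warnings.warn(f"clamped {int(at_bound.sum())} beta value(s) to ({BETA_EPS}, {1 - BETA_EPS})")
        b = np.clip(b, BETA_EPS, 1 - BETA_EPS)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    # expm-style stable logistic in base 2
    out = np.empty_like(m, dtype=float)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    out[~pos] = np.exp2(m[~pos]) / (1.0 + np.exp2(m[~pos]))
    return out


@dataclass
class MethylationMatrix:
    """samples x CpGs beta-value matrix with optional detection p-values.

    Attributes
    ----------
    beta : DataFrame
        Samples in rows, CpG ids in columns, values in [0, 1].
    detection_p : DataFrame or None
        Same shape as ``beta``; probability that the probe signal is
        indistinguishable from background for that sample.
    annotation : DataFrame or None
        Indexed by CpG id with columns ``chrom``, ``pos`` plus boolean flag
        columns drawn from CONTEXT_FLAGS / REGULATORY_FLAGS / EXCLUSION_FLAGS.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None

    def __post_init__(self):
        if self.beta.columns.duplicated().any() or self.beta.index.duplicated().any():
            raise ValueError("sample and CpG ids must be unique")
        vals = self.beta.to_numpy()
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
            raise ValueError("beta values must be finite and in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def m(self) -> pd.DataFrame:
        """M-value view (base-2 logit of beta)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return pd.DataFrame(
                beta_to_m(self.beta.to_numpy()), index=self.beta.index, columns=self.beta.columns
            )

    def subset(self, samples=None, cpgs=None) -> "MethylationMatrix":
        beta = self.beta
        det = self.detection_p
        if samples is not None:
            beta = beta.loc[samples]
            det = det.loc[samples] if det is not None else None
        if cpgs is not None:
            beta = beta[cpgs]
            det = det[cpgs] if det is not None else None
        annot = self.annotation.loc[beta.columns] if self.annotation is not None else None
        return MethylationMatrix(beta, det, annot)


@dataclass
class GenotypeMatrix:
    """samples x SNPs additive dosage matrix (count of the derived allele).

    ``snp_info`` is indexed by SNP id with columns ``chrom``, ``pos``,
    ``ref``, ``alt``, ``ancestral``, ``derived``. Dosages count the derived
    allele where the ancestral state is known, else the alternate allele
    (flagged by ``ancestral`` being NA).
    """

    dosages: pd.DataFrame
    snp_info: pd.DataFrame

    def __post_init__(self):
        if not self.dosages.columns.equals(self.snp_info.index):
            self.snp_info = self.snp_info.loc[self.dosages.columns]

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def maf(self, samples=None) -> pd.Series:
        d = self.dosages if samples is None else self.dosages.loc[samples]
        f = d.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)


@dataclass
class ExpressionMatrix:
    """samples x genes FPKM matrix for one condition.

    ``gene_info`` is indexed by gene id with columns ``chrom``, ``tss`` and
    optionally ``is_tf`` (transcription-factor flag used by trans mapping).
    """

    fpkm: pd.DataFrame
    gene_info: pd.DataFrame
    condition: str = "NS"

    @property
    def log2(self) -> pd.DataFrame:
        """log2(1 + FPKM), the scale used for association testing."""
        return np.log2(1.0 + self.fpkm)


def make_sample_table(sample_ids, population, age, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the per-sample table: population label, age, covariates."""
    tab = pd.DataFrame({"population": population, "age": age}, index=pd.Index(sample_ids, name="sample_id"))
    if covariates is not None:
        tab = tab.join(covariates)
    return tab


def downsample_equal_groups(samples: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Randomly drop samples from the larger population until group sizes match."""
    rng = np.random.default_rng(seed)
    counts = samples["population"].value_counts()
    n_keep = counts.min()
    keep = []
    for pop, grp in samples.groupby("population", sort=False):
        ids = grp.index.to_numpy()
        if len(ids) > n_keep:
            ids = rng.choice(ids, size=n_keep, replace=False)
        keep.extend(ids)
    return samples.loc[samples.index.intersection(pd.Index(keep))]


def qc_filter(
    meth: MethylationMatrix,
    sample_fail_fraction: float = 0.05,
    detection_threshold: float = 1e-3,
) -> tuple[MethylationMatrix, dict]:
    """Apply probe and sample quality filters, in a fixed order.

    1. Drop probes flagged cross-hybridizing, on a sex chromosome, or
       overlapping a common SNP (per the annotation's exclusion flags).
    2. Drop samples for which more than ``sample_fail_fraction`` of the
       remaining probes have detection p > ``detection_threshold``.
    3. Drop probes with detection p > ``detection_threshold`` in one or more
       remaining samples.

    Returns the filtered matrix and a report dict with counts removed at
    each step. Re-applying the filter to its own output is a no-op.
    """
    if not (0 < sample_fail_fraction < 1) or not (0 < detection_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    report = {}
    beta = meth.beta
    det = meth.detection_p
    annot = meth.annotation

    # step 1: annotation exclusion flags
    if annot is not None:
        flags = [f for f in EXCLUSION_FLAGS if f in annot.columns]
        bad = annot[flags].any(axis=1) if flags else pd.Series(False, index=annot.index)
        drop1 = annot.index[bad].intersection(beta.columns)
    else:
        drop1 = pd.Index([])
    report["probes_flagged"] = len(drop1)
    beta = beta.drop(columns=drop1)
    if det is not None:
        det = det.drop(columns=drop1)

    if det is None:
        raise QcError("detection p-values required for sample/probe detection filters")

    # step 2: failing samples
    fail_frac = (det > detection_threshold).mean(axis=1)
    bad_samples = fail_frac.index[fail_frac > sample_fail_fraction]
    report["samples_removed"] = len(bad_samples)
    beta = beta.drop(index=bad_samples)
    det = det.drop(index=bad_samples)
    if beta.shape[0] == 0:
        raise QcError("all samples removed by detection-rate filter")

    # step 3: failing probes among remaining samples
    bad_probes = det.columns[(det > detection_threshold).any(axis=0)]
    report["probes_failed_detection"] = len(bad_probes)
    beta = beta.drop(columns=bad_probes)
    det = det.drop(columns=bad_probes)

    report["n_samples_kept"] = beta.shape[0]
    report["n_probes_kept"] = beta.shape[1]
    annot_out = annot.loc[beta.columns] if annot is not None else None
    return MethylationMatrix(beta, det, annot_out), report


# ---------------------------------------------------------------------------
# I/O: TSV matrices, BED annotation, minimal VCF

def write_matrix_tsv(df: pd.DataFrame, path, orientation: str = "samples_x_features") -> None:
    """Write a matrix TSV with an orientation declaration in a header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# orientation: {orientation}\n")
        df.to_csv(fh, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a matrix TSV written by :func:`write_matrix_tsv`.

    Matrices are returned samples x features regardless of stored orientation.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        orientation = "samples_x_features"
        if first.startswith("#"):
            if "orientation:" in first:
                orientation = first.split("orientation:")[1].strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if orientation == "features_x_samples":
        df = df.T
    return df


def write_bed(annot: pd.DataFrame, path) -> None:
    """Write feature positions as BED (0-based, half-open), sorted by position."""
    bed = pd.DataFrame(
        {
            "chrom": annot["chrom"],
            "start": annot["pos"].astype(int) - 1,
            "end": annot["pos"].astype(int),
            "name": annot.index,
        }
    ).sort_values(["chrom", "start"])
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal diploid VCF with GT genotypes and AA INFO."""
    info = geno.snp_info
    samples = list(geno.sample_ids)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(info["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        order = info.sort_values(["chrom", "pos"]).index
        dos = geno.dosages
        for snp in order:
            row = info.loc[snp]
            aa = row.get("ancestral")
            info_col = f"AA={aa}" if isinstance(aa, str) else "."
            gts = "\t".join(gt_map[int(d)] for d in dos[snp])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row.get('ref', 'A')}\t"
                f"{row.get('alt', 'G')}\t.\tPASS\t{info_col}\tGT\t{gts}\n"
            )


def read_vcf(path, sample_ids=None) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (alternate-allele dosages; derived
    allele resolved from the AA INFO field when present)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = sample_ids if sample_ids is not None else vcf.samples
    rows, meta = [], []
    for var in vcf:
        aa = var.INFO.get("AA")
        alt = var.ALT[0] if var.ALT else "."
        dos = var.gt_types.astype(float)  # 0=hom ref,1=het,2=?,3=hom alt
        dos[dos == 2] = np.nan
        dos[dos == 3] = 2
        if aa is not None and aa == alt:
            dos = 2 - dos  # count the derived (= reference) allele
            derived = var.REF
        else:
            derived = alt
        rows.append(dos)
        meta.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": alt,
                "ancestral": aa,
                "derived": derived,
            }
        )
    info = pd.DataFrame(meta).set_index("snp_id")
    dosages = pd.DataFrame(np.array(rows).T, index=pd.Index(samples, name="sample_id"), columns=info.index)
    return GenotypeMatrix(dosages, info)
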