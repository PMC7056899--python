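"""Marker and sample quality control.

Four sequential filters, in PLINK 1.9's fixed internal order: individual
missingness, then on the surviving individuals SNP missingness,
Hardy-Weinberg exact test, and minor allele frequency.  A report records
counts before/after and attributes every excluded SNP to the first filter it
fails in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genotype_io import GenotypeDataset

__all__ = ["QCThresholds", "QCReport", "hwe_exact_pvalue", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; defaults follow common SNP-array practice."""

    max_individual_missing: float = 0.20
    max_snp_missing: float = 0.10
    hwe_p_min: float = 1e-6
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_individual_missing", "max_snp_missing", "hwe_p_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_individuals_before: int
    n_individuals_after: int
    n_snps_before: int
    n_snps_after: int
    excluded_individuals_missing: list[str] = field(default_factory=list)
    excluded_snps_missing: list[str] = field(default_factory=list)
    excluded_snps_hwe: list[str] = field(default_factory=list)
    excluded_snps_maf: list[str] = field(default_factory=list)

    @property
    def exclusion_counts(self) -> dict[str, int]:
        return {
            "individual_missing": len(self.excluded_individuals_missing),
            "snp_missing": len(self.excluded_snps_missing),
            "snp_hwe": len(self.excluded_snps_hwe),
            "snp_maf": len(self.excluded_snps_maf),
        }

    def to_dict(self) -> dict:
        return {
            "individuals": {"before": self.n_individuals_before, "after": self.n_individuals_after},
            "snps": {"before": self.n_snps_before, "after": self.n_snps_after},
            "exclusions": self.exclusion_counts,
            "excluded_individual_ids": self.excluded_individuals_missing,
            "excluded_snp_ids": {
                "missing": self.excluded_snps_missing,
                "hwe": self.excluded_snps_hwe,
                "maf": self.excluded_snps_maf,
            },
        }


def hwe_exact_pvalue(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test conditional on allele counts.

    Sums the probabilities of all heterozygote configurations at least as
    improbable as the observed one, given the total minor-allele count
    (Wigginton-style exact test, no mid-p correction).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    # log-weight of a configuration with h heterozygotes:
    #   log[ n! / (hom1! h! hom2!) * 2^h ]; normalization cancels.
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hom_minor - hets
    logw = (
        hets * math.log(2.0)
        - gammaln(hom_minor + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(hom_major + 1.0)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[hets == n_het][0]
    # tolerance guards against ties lost to rounding
    p = w[w <= w_obs * (1 + 1e-12)].sum() / w.sum()
    return float(min(p, 1.0))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    out = np.empty(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        out[j] = hwe_exact_pvalue(n0, n1, n2) if (n0 + n1 + n2) else 1.0
    return out


def apply_qc(dataset: GenotypeDataset, thresholds: QCThresholds | None = None
             ) -> tuple[GenotypeDataset, QCReport]:
    """Filter individuals then SNPs; returns the surviving dataset and a report.

    Pass order: (1) individuals by missing rate, then on the remaining
    individuals (2) SNPs by missing rate, (3) SNPs by HWE exact p, (4) SNPs
    by MAF.  SNP statistics are recomputed after individual removal.  A SNP
    failing several filters is attributed to the first in this order.
    """
    thr = thresholds or QCThresholds()
    X = dataset.dosages
    n, m = X.shape
    if n == 0 or m == 0:
        raise ValueError("empty dataset")
    miss = np.isnan(X)

    ind_rate = miss.mean(axis=1)
    ind_keep = ind_rate <= thr.max_individual_missing
    ind_ids = dataset.individual_ids.to_numpy()
    excluded_inds = list(ind_ids[~ind_keep])
    X = X[ind_keep]
    miss = miss[ind_keep]
    if X.shape[0] == 0:
        raise ValueError("no data passes QC: every individual exceeds the missingness threshold")

    snp_ids = dataset.markers["snp_id"].to_numpy()
    snp_miss_rate = miss.mean(axis=0)
    fail_missing = snp_miss_rate > thr.max_snp_missing

    pvals = _hwe_pvalues(X)
    fail_hwe = (pvals < thr.hwe_p_min) & ~fail_missing

    with np.errstate(invalid="ignore"):
        nonmiss = (~miss).sum(axis=0)
        p_hat = np.nansum(X, axis=0) / (2.0 * np.maximum(nonmiss, 1))
    maf = np.minimum(p_hat, 1.0 - p_hat)
    maf[nonmiss == 0] = 0.0
    fail_maf = (maf < thr.maf_min) & ~fail_missing & ~fail_hwe

    snp_keep = ~(fail_missing | fail_hwe | fail_maf)
    if not snp_keep.any():
        raise ValueError("no data passes QC: every SNP fails a filter")

    out = GenotypeDataset(
        X[:, snp_keep].copy(),
        dataset.markers.loc[snp_keep].reset_index(drop=True).copy(),
        dataset.samples.loc[ind_keep].reset_index(drop=True).copy(),
    )
    report = QCReport(
        n_individuals_before=n,
        n_individuals_after=out.n_individuals,
        n_snps_before=m,
        n_snps_after=out.n_markers,
        excluded_individuals_missing=excluded_inds,
        excluded_snps_missing=list(snp_ids[fail_missing]),
        excluded_snps_hwe=list(snp_ids[fail_hwe]),
        excluded_snps_maf=list(snp_ids[fail_maf]),
    )
    return out, report
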