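"""SNP quality control and the VanRaden method-2 genomic relationship matrix.

Dosages are coded 0/1/2 copies of the counted allele; missing values are
NaN. QC removes SNPs by call rate, minor allele frequency and deviation
from Hardy-Weinberg proportions, then animals by call rate, and finally
mean-imputes any residual missing dosages per SNP. The GRM standardises
each SNP by its own heterozygosity:

    G = (1/m) * sum_i z_i z_i' / (2 p_i (1 - p_i)),   z_i = dosage_i - 2 p_i

with p_i the observed allele frequency of SNP i and m the SNP count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QcThresholds:
    """QC cut-offs; defaults follow routine 50k-chip practice."""

    snp_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-8
    animal_call_rate_min: float = 0.90

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


def allele_frequencies(dosages: pd.DataFrame) -> pd.Series:
    """Observed counted-allele frequency per SNP from non-missing dosages."""
    return dosages.mean(axis=0, skipna=True) / 2.0


def _hwe_pvalues(dosages: pd.DataFrame) -> np.ndarray:
    """Chi-square (1 df) goodness-of-fit p-values against HW proportions.

    Only integer-coded genotypes enter the test; fractional (imputed)
    dosages carry no genotype class, which keeps the filter idempotent.
    """
    d = dosages.to_numpy(dtype=float)
    obs = np.stack([np.nansum(d == g, axis=0) for g in (0.0, 1.0, 2.0)])
    n = obs.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (obs[1] + 2.0 * obs[2]) / (2.0 * n)
        exp = np.stack([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(axis=0)
    return np.where(n > 0, stats.chi2.sf(chi2, df=1), 1.0)


def qc_filter(
    dosages: pd.DataFrame, thresholds: QcThresholds | None = None
) -> tuple[pd.DataFrame, dict]:
    """Filter a dosage matrix (animals x SNPs) and mean-impute the rest.

    Order of operations: SNP call rate -> MAF -> HWE -> animal call rate
    -> per-SNP mean imputation of residual missing dosages.

    Returns the filtered matrix and an exclusion report listing removed
    SNP/animal ids per criterion.
    """
    t = thresholds or QcThresholds()
    vals = dosages.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_range = np.logical_or(vals < 0, vals > 2) & ~np.isnan(vals)
    if out_of_range.any():
        raise ValueError(
            "dosages must be coded 0/1/2 (or mean-imputed in [0, 2]) or NaN"
        )
    report: dict = {}

    call = dosages.notna().mean(axis=0)
    drop = call[call < t.snp_call_rate_min].index
    report["snp_call_rate"] = list(map(str, drop))
    g = dosages.drop(columns=drop)

    p = allele_frequencies(g)
    maf = np.minimum(p, 1 - p)
    drop = maf[maf < t.maf_min].index
    report["snp_maf"] = list(map(str, drop))
    g = g.drop(columns=drop)

    hwe_p = pd.Series(_hwe_pvalues(g), index=g.columns)
    drop = hwe_p[hwe_p < t.hwe_p_min].index
    report["snp_hwe"] = list(map(str, drop))
    g = g.drop(columns=drop)

    if g.shape[1] == 0:
        raise ValueError("quality control removed every SNP")

    acall = g.notna().mean(axis=1)
    drop = acall[acall < t.animal_call_rate_min].index
    report["animal_call_rate"] = list(map(str, drop))
    g = g.drop(index=drop)

    n_imputed = int(g.isna().to_numpy().sum())
    report["n_mean_imputed"] = n_imputed
    if n_imputed:
        g = g.fillna(g.mean(axis=0))
    report["n_snps_kept"] = g.shape[1]
    report["n_animals_kept"] = g.shape[0]
    return g, report


def compute_grm(dosages: pd.DataFrame) -> pd.DataFrame:
    """VanRaden method-2 GRM from a complete post-QC dosage matrix.

    Each SNP is centred by twice its observed allele frequency and scaled
    by its expected heterozygosity, so the diagonal averages ~1 under
    Hardy-Weinberg equilibrium.
    """
    m = dosages.to_numpy(dtype=float)
    if np.isnan(m).any():
        raise ValueError("missing dosages present; run qc_filter first")
    p = m.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "monomorphic SNPs present (p in {0,1}); run qc_filter first"
        )
    z = m - 2.0 * p
    w = 1.0 / (2.0 * p * (1.0 - p))
    g = (z * w) @ z.T / m.shape[1]
    return pd.DataFrame(g, index=dosages.index, columns=dosages.index)
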