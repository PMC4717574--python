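"""SNP-, sample- and phenotype-level quality control.

Filters and default thresholds mirror stringent biobank practice: SNPs are
dropped for overall missingness > 2 %, platform-specific missingness bias
(Fisher's exact test, P < 1e-100), departure from Hardy-Weinberg equilibrium
(exact test, P < 1e-50), or minor allele frequency < 0.05; samples for
missingness > 5 % or an autosomal heterozygosity rate more than 3 SD from
the cohort mean; phenotype records for heights more than 3 SD from their
own gender's mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact

from .exceptions import DataError
from .simulate import GenotypeMatrix


@dataclass
class QCThresholds:
    snp_missing_max: float = 0.02
    platform_fisher_p_min: float = 1e-100
    hwe_p_min: float = 1e-50
    maf_min: float = 0.05
    sample_missing_max: float = 0.05
    het_sd_max: float = 3.0
    pheno_sd_max: float = 3.0


@dataclass
class QCReport:
    """Per-filter exclusion counts plus surviving id lists."""

    n_input: int = 0
    excluded: dict = field(default_factory=dict)
    surviving_ids: list = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_input - len(self.surviving_ids)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "excluded": dict(self.excluded),
            "n_surviving": len(self.surviving_ids),
        }


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test (Wigginton-style conditional enumeration).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    Monomorphic sites have a single attainable outcome, so p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DataError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor allele count
    het = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - het) // 2
    hom_major = n - het - hom_minor
    # log P(het | n, n_minor) up to a constant
    logp = het * np.log(2.0) - (
        gammaln(hom_minor + 1) + gammaln(het + 1) + gammaln(hom_major + 1)
    )
    logp -= logsumexp(logp)
    p_obs = logp[het == n_Aa]
    if p_obs.size == 0:
        raise DataError("inconsistent genotype counts")
    keep = logp <= p_obs[0] + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def platform_missingness_test(miss_1: int, ok_1: int, miss_2: int, ok_2: int) -> float:
    """Two-sided Fisher exact p for platform-specific missingness bias."""
    if min(miss_1, ok_1, miss_2, ok_2) < 0:
        raise DataError("counts must be non-negative")
    if miss_1 + ok_1 == 0 or miss_2 + ok_2 == 0:
        raise DataError("both platforms must have samples")
    _, p = fisher_exact([[miss_1, ok_1], [miss_2, ok_2]], alternative="two-sided")
    return float(p)


def _genotype_counts(dosages: np.ndarray):
    """(n2, n1, n0, n_missing) per SNP for int dosage matrix with -1 missing."""
    n2 = (dosages == 2).sum(axis=0)
    n1 = (dosages == 1).sum(axis=0)
    n0 = (dosages == 0).sum(axis=0)
    nm = (dosages == -1).sum(axis=0)
    return n2, n1, n0, nm


def snp_qc(G: GenotypeMatrix, thresholds: QCThresholds = None):
    """Apply SNP filters: missingness -> platform bias -> HWE -> MAF.

    MAF is computed on the samples present in ``G`` (the analysis subset).
    SNP order is preserved.
    """
    t = thresholds or QCThresholds()
    if G.n_snps == 0:
        raise DataError("empty genotype matrix")
    n = G.n_samples
    keep = np.ones(G.n_snps, dtype=bool)
    report = QCReport(n_input=G.n_snps)

    n2, n1, n0, nm = _genotype_counts(G.dosages)
    miss_rate = nm / n
    fail = keep & (miss_rate > t.snp_missing_max)
    report.excluded["missingness"] = int(fail.sum())
    keep &= ~fail

    platforms = np.unique(G.sample_platform)
    n_bias = 0
    if len(platforms) >= 2:
        on_p1 = G.sample_platform == platforms[0]
        d1, d2 = G.dosages[on_p1], G.dosages[~on_p1]
        m1 = (d1 == -1).sum(axis=0)
        m2 = (d2 == -1).sum(axis=0)
        tot1, tot2 = d1.shape[0], d2.shape[0]
        suspects = np.flatnonzero(keep & ((m1 > 0) | (m2 > 0)))
        for j in suspects:
            p = platform_missingness_test(m1[j], tot1 - m1[j], m2[j], tot2 - m2[j])
            if p < t.platform_fisher_p_min:
                keep[j] = False
                n_bias += 1
    report.excluded["platform_bias"] = n_bias

    n_hwe = 0
    for j in np.flatnonzero(keep):
        if hwe_exact_test(int(n2[j]), int(n1[j]), int(n0[j])) < t.hwe_p_min:
            keep[j] = False
            n_hwe += 1
    report.excluded["hwe"] = n_hwe

    typed = n2 + n1 + n0
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (2.0 * n2 + n1) / (2.0 * typed)
    maf = np.minimum(freq, 1.0 - freq)
    maf[typed == 0] = 0.0
    fail = keep & (maf < t.maf_min)
    report.excluded["maf"] = int(fail.sum())
    keep &= ~fail

    if not keep.any():
        warnings.warn("all SNPs removed by QC", stacklevel=2)
    out = G.subset(snp_mask=keep)
    out.snp_meta = out.snp_meta.assign(freq=freq[keep])
    report.surviving_ids = out.snp_meta["snp_id"].tolist()
    return out, report


def sample_qc(G: GenotypeMatrix, thresholds: QCThresholds = None):
    """Remove samples with missingness > 5 % or outlying heterozygosity.

    The heterozygosity rate (fraction of typed genotypes that are
    heterozygous) is compared across samples; values more than
    ``het_sd_max`` SD from the mean are excluded.
    """
    t = thresholds or QCThresholds()
    if G.n_samples == 0:
        raise DataError("empty genotype matrix")
    m = G.n_snps
    nm = (G.dosages == -1).sum(axis=1)
    miss_rate = nm / m
    keep = miss_rate <= t.sample_missing_max
    report = QCReport(n_input=G.n_samples)
    report.excluded["missingness"] = int((~keep).sum())

    typed = m - nm
    het = (G.dosages == 1).sum(axis=1) / np.maximum(typed, 1)
    mu, sd = het[keep].mean(), het[keep].std()
    if sd > 0:
        z = np.abs(het - mu) / sd
        fail = keep & (z > t.het_sd_max)
    else:
        fail = np.zeros_like(keep)
    report.excluded["heterozygosity"] = int(fail.sum())
    keep &= ~fail

    out = G.subset(sample_mask=keep)
    report.surviving_ids = list(out.sample_ids)
    return out, report


def phenotype_outlier_filter(phenos: pd.DataFrame, sd_max: float = 3.0):
    """Drop records strictly more than ``sd_max`` SD from their gender mean.

    Means and SDs are computed on the input set in a single pass; a gender
    with fewer than two records is passed through unfiltered with a warning.
    """
    if len(phenos) == 0:
        report = QCReport(n_input=0)
        report.excluded["height_outlier"] = 0
        return phenos.copy(), report
    if not {"sex", "height"} <= set(phenos.columns):
        raise DataError("phenotype table must have 'sex' and 'height' columns")
    keep = np.ones(len(phenos), dtype=bool)
    for sex, grp in phenos.groupby("sex"):
        if len(grp) < 2:
            warnings.warn(f"gender '{sex}' has < 2 records; passed through", stacklevel=2)
            continue
        mu, sd = grp["height"].mean(), grp["height"].std()
        if sd == 0:
            continue
        z = np.abs(phenos.loc[phenos["sex"] == sex, "height"] - mu) / sd
        keep[phenos.index.get_indexer(z.index[z > sd_max])] = False
    report = QCReport(n_input=len(phenos))
    report.excluded["height_outlier"] = int((~keep).sum())
    out = phenos.loc[keep].reset_index(drop=True)
    id_col = "sample_id" if "sample_id" in out.columns else out.columns[0]
    report.surviving_ids = out[id_col].tolist()
    return out, report
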