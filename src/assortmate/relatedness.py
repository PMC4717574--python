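"""Genotype standardization, GRM construction, LD pruning, PCA and the
ethnicity-core / couple-relatedness filters.

The genomic relationship matrix follows the standard SNP-BLUP algebra:
z_ij = (d_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)) and A = Z Z^T / M, so that the
GRM model V = A sigma_g^2 + I sigma_e^2 is exactly the SNP-effects model
with sigma_g^2 = M sigma_u^2.  Missing dosages are mean-imputed (z = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import ConfigError, DataError
from .simulate import GenotypeMatrix


@dataclass
class StandardizedGenotypes:
    z: np.ndarray          # samples x SNPs, column mean ~0 / var ~1
    M: int                 # SNP count
    freqs: np.ndarray      # allele frequencies used for centring/scaling
    sample_ids: np.ndarray = None


@dataclass
class GRM:
    A: np.ndarray
    sample_ids: np.ndarray
    n_markers: int

    def __post_init__(self):
        if self.A.shape[0] != self.A.shape[1]:
            raise DataError("GRM must be square")
        if len(self.sample_ids) != self.A.shape[0]:
            raise DataError("sample_ids must match GRM dimension")

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids])
        except KeyError as exc:
            raise DataError(f"sample {exc.args[0]!r} not in GRM") from exc

    def subset(self, ids) -> "GRM":
        idx = self.index_of(ids)
        return GRM(self.A[np.ix_(idx, idx)], np.asarray(ids), self.n_markers)


@dataclass
class PCProjection:
    eigenvalues: np.ndarray   # non-increasing
    eigenvectors: np.ndarray  # samples x k, orthonormal columns
    k: int
    sample_ids: np.ndarray = None


def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Sample allele frequency per SNP, ignoring missing (-1) entries."""
    d = dosages.astype(float)
    d[d < 0] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(d, axis=0) / 2.0


def standardize_genotypes(
    G: GenotypeMatrix, freqs: np.ndarray = None
) -> StandardizedGenotypes:
    """z = (dosage - 2p) / sqrt(2 p (1-p)); missing entries become 0.

    ``freqs`` may be supplied (e.g. training-set frequencies when scoring a
    holdout sample); otherwise the sample frequencies are used.
    """
    p = allele_frequencies(G.dosages) if freqs is None else np.asarray(freqs, float)
    mono = ~(np.isfinite(p)) | (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = G.snp_meta["snp_id"].iloc[int(np.flatnonzero(mono)[0])]
        raise DataError(f"monomorphic SNP cannot be standardized: {bad}")
    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = (G.dosages - 2.0 * p) / denom
    z[G.dosages == -1] = 0.0
    return StandardizedGenotypes(z=z, M=z.shape[1], freqs=p, sample_ids=G.sample_ids)


def compute_grm(Z: StandardizedGenotypes) -> GRM:
    """A = Z Z^T / M with exact symmetry enforced."""
    if Z.M < 1:
        raise DataError("need at least one marker")
    A = Z.z @ Z.z.T / Z.M
    A = 0.5 * (A + A.T)
    ids = Z.sample_ids if Z.sample_ids is not None else np.arange(A.shape[0])
    return GRM(A=A, sample_ids=np.asarray(ids), n_markers=Z.M)


def ld_prune(
    G: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> list:
    """Greedy sliding-window LD pruning on dosage correlations.

    Within each window, for every pair with squared correlation above
    ``r2_max`` the later SNP is dropped; the earlier SNP is always kept, so
    the result is deterministic and order-stable.  Returns surviving SNP ids.
    """
    if window < 2:
        raise ConfigError("window must be >= 2")
    m = G.n_snps
    d = G.dosages.astype(float)
    d[d < 0] = np.nan
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d) - col_mean
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    d /= sd
    keep = np.ones(m, dtype=bool)
    n = d.shape[0]
    for start in range(0, max(1, m - 1), step):
        idx = np.flatnonzero(keep[start : start + window]) + start
        if len(idx) < 2:
            continue
        r = d[:, idx].T @ d[:, idx] / n
        r2 = r**2
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if keep[idx[b]] and r2[a, b] > r2_max:
                    keep[idx[b]] = False
        if start + window >= m:
            break
    return G.snp_meta["snp_id"][keep].tolist()


def grm_pca(A: GRM, k: int = 20) -> PCProjection:
    """Top-k eigenpairs of the GRM with a fixed sign convention.

    Eigenvectors are unit norm; the sign is chosen so each vector's
    largest-magnitude entry is positive.
    """
    n = A.A.shape[0]
    if k > n:
        raise ConfigError(f"k = {k} exceeds sample count {n}")
    w, v = scipy.linalg.eigh(A.A, subset_by_index=(n - k, n - 1))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    flips = np.sign(v[np.abs(v).argmax(axis=0), np.arange(k)])
    flips[flips == 0] = 1.0
    v = v * flips
    return PCProjection(eigenvalues=w, eigenvectors=v, k=k, sample_ids=A.sample_ids)


def ethnic_core_filter(
    pcs: PCProjection,
    self_report,
    sd_max: float = 3.0,
    core_label: str = "White-British",
) -> list:
    """Keep samples with the core self-report label whose every PC projection
    lies within ``sd_max`` SD of that PC's mean (computed among the
    label-matching samples)."""
    labels = np.asarray(self_report)
    if len(labels) != pcs.eigenvectors.shape[0]:
        raise DataError("self_report length must match PC projection")
    in_label = labels == core_label
    proj = pcs.eigenvectors
    mu = proj[in_label].mean(axis=0)
    sd = proj[in_label].std(axis=0)
    sd[sd == 0] = np.inf
    within = (np.abs(proj - mu) / sd <= sd_max).all(axis=1)
    keep = in_label & within
    ids = pcs.sample_ids if pcs.sample_ids is not None else np.arange(len(labels))
    return list(np.asarray(ids)[keep])


def couple_relatedness_filter(
    couples: pd.DataFrame, A: GRM, r_max: float = 0.0625
) -> pd.DataFrame:
    """Retain couples with GRM relatedness strictly below ``r_max``.

    Couples with a member absent from the GRM are dropped with a warning;
    related individuals remain in the GRM sample, just not as couples.
    """
    lookup = {s: i for i, s in enumerate(A.sample_ids)}
    keep = []
    n_missing = 0
    for _, row in couples.iterrows():
        fi = lookup.get(row["female_id"])
        mi = lookup.get(row["male_id"])
        if fi is None or mi is None:
            n_missing += 1
            keep.append(False)
            continue
        keep.append(A.A[fi, mi] < r_max)
    if n_missing:
        warnings.warn(f"{n_missing} couples dropped: member absent from GRM", stacklevel=2)
    return couples.loc[np.asarray(keep, bool)].reset_index(drop=True)
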