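"""Synthetic cohorts of genotyped couples with height-driven assortment.

The generator emulates a biobank-style cohort after genotype QC: biallelic
autosomal SNP dosages in Hardy-Weinberg equilibrium with a minor-allele
frequency floor, an additive polygenic architecture for height
(P = A + E with var(A)/var(P) = h2), male-female couples whose heights
correlate at a configurable level because mate choice is driven by the
phenotype itself, and within-couple structured covariates (shared household,
nearby birthplaces, correlated ages, shared deprivation) that the couple-swap
permutation is designed to destroy.

Couple formation follows the phenotype-driven (ante-dependence) picture
A_i -> P_i -> P_partner: each individual receives a matching score equal to
their sex-standardized height plus independent noise, and the sexes are
paired by score rank.  Noise variance (1 - r)/r makes the expected couple
height correlation r; an empirical calibration loop then nudges the implied
correlation until the realized one is within 0.02 of the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import plink
from .exceptions import ConfigError, DataError

# Distinct per-operation stream keys so that every stage draws from an
# independent stream of the single SimConfig seed.
_STREAM_GENO = 1
_STREAM_HEIGHT = 2
_STREAM_COUPLE = 3
_STREAM_COVAR = 4
_STREAM_GEO = 5


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults are the study conditions of the analysis this package
    reproduces: couple height correlation 0.26, height heritability 0.8,
    MAF in [0.05, 0.5] (rare variants excluded), a 13 cm male-female mean
    height difference and strongly correlated ages within couples.
    """

    n_couples: int = 2000
    n_snps: int = 5000
    maf_low: float = 0.05
    maf_high: float = 0.5
    h2_height: float = 0.8
    causal_fraction: float = 0.1
    target_rp: float = 0.26
    sex_mean_shift: float = 13.0
    height_sd: float = 7.0
    geo_clusters: int = 5
    cross_cluster_frac: float = 0.2
    age_corr: float = 0.9
    fst: float = 0.0
    geo_range_m: float = 200e3
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_couples < 1 or self.n_snps < 1:
            raise ConfigError("n_couples and n_snps must be >= 1")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigError("require 0 < maf_low <= maf_high <= 0.5")
        if not (0.0 <= self.h2_height <= 1.0):
            raise ConfigError("h2_height must lie in [0, 1]")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ConfigError("causal_fraction must lie in (0, 1]")
        if not (0.0 <= self.target_rp < 1.0):
            raise ConfigError("target_rp must lie in [0, 1)")
        if not (0.0 <= self.fst < 1.0):
            raise ConfigError("fst must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.geo_clusters < 1:
            raise ConfigError("geo_clusters must be >= 1")
        if not (0.0 <= self.cross_cluster_frac <= 1.0):
            raise ConfigError("cross_cluster_frac must lie in [0, 1]")
        if self.geo_range_m <= 0:
            raise ConfigError("geo_range_m must be positive")
        if not (-1.0 <= self.age_corr <= 1.0):
            raise ConfigError("age_corr must lie in [-1, 1]")


@dataclass
class GenotypeMatrix:
    """Sample x SNP biallelic dosages with per-SNP metadata.

    ``dosages`` is int8 with values {0, 1, 2} and -1 for missing.
    ``cluster`` records the (sub)population each sample was drawn from; it
    is uniform 0 when fst = 0.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: np.ndarray
    sample_platform: np.ndarray = None
    cluster: np.ndarray = None

    def __post_init__(self):
        n, m = self.dosages.shape
        if len(self.snp_meta) != m:
            raise DataError("snp_meta length must equal the SNP count")
        if len(self.sample_ids) != n:
            raise DataError("sample_ids length must equal the sample count")
        if len(np.unique(self.sample_ids)) != n:
            raise DataError("sample_ids must be unique")
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            raise DataError("dosages must be in {0, 1, 2} or -1 (missing)")
        if self.sample_platform is None:
            self.sample_platform = np.full(n, "A", dtype=object)
        if self.cluster is None:
            self.cluster = np.zeros(n, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_by_ids(self, ids) -> "GenotypeMatrix":
        """Subset samples in the exact order of ``ids``."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([lookup[s] for s in ids])
        except KeyError as exc:
            raise DataError(f"sample {exc.args[0]!r} not in genotype matrix") from exc
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            snp_meta=self.snp_meta,
            sample_ids=self.sample_ids[idx],
            sample_platform=self.sample_platform[idx],
            cluster=self.cluster[idx],
        )

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        vm = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(sm, vm)],
            snp_meta=self.snp_meta.loc[vm].reset_index(drop=True),
            sample_ids=self.sample_ids[sm],
            sample_platform=self.sample_platform[sm],
            cluster=self.cluster[sm],
        )


def cluster_centres(config: SimConfig):
    """Geographic cluster centres (metres) on a ~500 x 800 km grid.

    Deterministic given the seed and shared by genotype simulation and
    covariate attachment.
    """
    rng = np.random.default_rng([_STREAM_GEO, config.seed])
    east = rng.uniform(100e3, 600e3, size=config.geo_clusters)
    north = rng.uniform(100e3, 900e3, size=config.geo_clusters)
    return east, north


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw biallelic dosages in HWE, binomial(2, p) with p ~ U(maf bounds).

    With ``fst > 0`` allele frequencies are differentiated across
    ``geo_clusters`` subpopulations under an isolation-by-distance model:
    per-SNP frequency deviations are Gaussian with variance
    fst * p(1-p) per cluster and correlation exp(-d / geo_range_m) between
    clusters at centre distance d, so genetic similarity decays smoothly
    with geography.  With the default fst = 0 the cohort is panmictic.
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_GENO, config.seed])
    n = 2 * config.n_couples
    m = config.n_snps
    p = rng.uniform(config.maf_low, config.maf_high, size=m)

    # Female i and male i share couple-slot i; cluster is assigned per slot so
    # that within-cluster pairing keeps couples geographically coherent.
    slot_cluster = np.arange(config.n_couples) % config.geo_clusters
    cluster = np.empty(n, dtype=int)
    cluster[0::2] = slot_cluster  # females at even indices
    cluster[1::2] = slot_cluster  # males at odd indices

    if config.fst > 0.0:
        east, north = cluster_centres(config)
        d = np.hypot(east[:, None] - east[None, :], north[:, None] - north[None, :])
        K = np.exp(-d / config.geo_range_m) + 1e-9 * np.eye(config.geo_clusters)
        L = np.linalg.cholesky(K)
        eps = rng.standard_normal((config.geo_clusters, m))
        scale = np.sqrt(config.fst * p * (1.0 - p))
        pc = np.clip(p[None, :] + scale[None, :] * (L @ eps), 1e-3, 1 - 1e-3)
        dosages = rng.binomial(2, pc[cluster, :]).astype(np.int8)
    else:
        dosages = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)

    if config.missing_rate > 0.0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = -1

    snp_meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(m)],
            "chrom": np.repeat(np.arange(1, 23), -(-m // 22))[:m],
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
            "freq": p,
            "platform": "both",
        }
    )
    sample_ids = np.array([f"id{i:06d}" for i in range(n)])
    platform = np.where(rng.random(n) < 0.33, "arrayA", "arrayB").astype(object)
    return GenotypeMatrix(dosages, snp_meta, sample_ids, platform, cluster)


def simulate_heights(G: GenotypeMatrix, config: SimConfig) -> pd.DataFrame:
    """Additive heights P = A + E with var(A)/var(P) = h2_height.

    A draws on a random causal subset of standardized dosages, rescaled so
    the sample variance of A is exactly h2 on the standardized phenotype
    scale; E is independent normal.  Sexes alternate along the sample order
    and males receive ``sex_mean_shift`` (cm).  The true additive value is
    kept (column ``additive_value``) for downstream truth checks.
    """
    config.validate()
    if G.n_samples == 0:
        raise DataError("empty genotype matrix")
    rng = np.random.default_rng([_STREAM_HEIGHT, config.seed])
    n, m = G.dosages.shape

    if config.h2_height > 0.0:
        n_causal = max(1, int(round(config.causal_fraction * m)))
        causal = rng.choice(m, size=n_causal, replace=False)
        dos = G.dosages[:, causal].astype(float)
        dos[dos < 0] = np.nan
        col_mean = np.nanmean(dos, axis=0)
        col_sd = np.nanstd(dos, axis=0)
        col_sd[col_sd == 0] = 1.0
        z = (dos - col_mean) / col_sd
        z[np.isnan(z)] = 0.0
        beta = rng.standard_normal(n_causal)
        A = z @ beta
        sd_A = A.std()
        if sd_A > 0:
            A *= np.sqrt(config.h2_height) / sd_A
    else:
        A = np.zeros(n)

    E = rng.standard_normal(n) * np.sqrt(max(0.0, 1.0 - config.h2_height))
    P = A + E
    sex = np.where(np.arange(n) % 2 == 0, "female", "male")
    height = 165.0 + config.height_sd * P + np.where(sex == "male", config.sex_mean_shift, 0.0)
    return pd.DataFrame(
        {
            "sample_id": G.sample_ids,
            "sex": sex,
            "height": height,
            "additive_value": config.height_sd * A,
            "cluster": G.cluster,
        }
    )


def _rank_match(score_f: np.ndarray, score_m: np.ndarray):
    """Pair females and males by rank of their matching scores."""
    return np.argsort(score_f, kind="stable"), np.argsort(score_m, kind="stable")


def form_couples(phenos: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Pair the sexes by noisy-rank matching on standardized height.

    Score s = z_height + noise with noise variance (1 - r)/r so that rank
    pairing yields couple height correlation ~= r; an empirical loop adjusts
    the implied correlation until the realized one is within 0.02 of
    ``target_rp``.  Pairing is predominantly within geographic cluster
    (couples share local environment); a fraction ``cross_cluster_frac`` of
    couple slots joins a mixed pool and may pair across clusters.
    target_rp = 0 gives random pairing.
    """
    config.validate()
    phenos = phenos if "cluster" in phenos.columns else phenos.assign(cluster=0)
    females = phenos[phenos["sex"] == "female"].reset_index(drop=True)
    males = phenos[phenos["sex"] == "male"].reset_index(drop=True)
    if len(females) != len(males):
        raise DataError("form_couples requires equal numbers of males and females")
    rng = np.random.default_rng([_STREAM_COUPLE, config.seed])

    # pairing pools: slot i contributes female i and male i to the same pool,
    # which is the slot's cluster or the mixed pool (-1)
    pool = females["cluster"].to_numpy().copy()
    if males["cluster"].to_numpy().shape == pool.shape and config.cross_cluster_frac > 0:
        mixed = rng.random(len(pool)) < config.cross_cluster_frac
        pool = np.where(mixed, -1, pool)

    # sex-standardized heights (sex shift cancels)
    zf = (females["height"] - females["height"].mean()) / females["height"].std()
    zm = (males["height"] - males["height"].mean()) / males["height"].std()
    zf, zm = zf.to_numpy(), zm.to_numpy()

    def pair_at(r_eff: float):
        f_order = np.empty(len(females), dtype=int)
        for c in np.unique(pool):
            fi = np.flatnonzero(pool == c)
            mi = fi
            if len(fi) != len(mi):
                raise DataError("unbalanced sexes within a pairing pool")
            if r_eff <= 0.0:
                pf, pm = rng.permutation(len(fi)), rng.permutation(len(mi))
            else:
                sigma = np.sqrt((1.0 - r_eff) / r_eff)
                sf = zf[fi] + sigma * rng.standard_normal(len(fi))
                sm = zm[mi] + sigma * rng.standard_normal(len(mi))
                pf, pm = _rank_match(sf, sm)
            f_order[fi[pf]] = mi[pm]  # female fi[pf[k]] paired to male mi[pm[k]]
        return f_order

    target = config.target_rp
    r_eff = target
    f_to_m = pair_at(r_eff)
    realized = 0.0 if target == 0.0 else _couple_corr(females, males, f_to_m)
    if target > 0.0:
        for _ in range(25):
            if abs(realized - target) <= 0.02:
                break
            r_eff = float(np.clip(r_eff * target / max(realized, 1e-6), 1e-6, 0.999))
            f_to_m = pair_at(r_eff)
            realized = _couple_corr(females, males, f_to_m)

    return pd.DataFrame(
        {
            "household_id": [f"H{k:06d}" for k in range(len(females))],
            "female_id": females["sample_id"].to_numpy(),
            "male_id": males["sample_id"].to_numpy()[f_to_m],
            "female_height": females["height"].to_numpy(),
            "male_height": males["height"].to_numpy()[f_to_m],
            "cluster": females["cluster"].to_numpy(),
        }
    )


def _couple_corr(females: pd.DataFrame, males: pd.DataFrame, f_to_m: np.ndarray) -> float:
    hf = females["height"].to_numpy()
    hm = males["height"].to_numpy()[f_to_m]
    return float(np.corrcoef(hf, hm)[0, 1])


def attach_covariates(
    couples: pd.DataFrame, phenos: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Attach household, birthplace, age, deprivation and pairing covariates.

    Both couple members share a household id; each individual's birthplace is
    drawn around their own genetic cluster's centre (scatter 50 km), so
    mostly-within-cluster couples are born near each other; ages are
    correlated at ``age_corr`` within couples; the Townsend deprivation score
    is a shared couple value plus individual noise.  Returns a new phenotype
    table (one row per individual) with the covariates filled in.
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_COVAR, config.seed])
    ph = phenos.set_index("sample_id", drop=False)
    n_c = len(couples)

    centres_e, centres_n = cluster_centres(config)

    ph["household_id"] = ""
    for col in ("age", "townsend", "birth_east", "birth_north"):
        ph[col] = np.nan
    ph["father_age"] = 0
    ph["mother_age"] = 0
    ph["lives_with_partner"] = True
    ph["ethnicity"] = "White-British"

    cl_all = ph["cluster"].to_numpy() if "cluster" in ph.columns else np.zeros(len(ph), int)
    ph["birth_east"] = centres_e[cl_all] + rng.normal(0, 50e3, size=len(ph))
    ph["birth_north"] = centres_n[cl_all] + rng.normal(0, 50e3, size=len(ph))

    zf_age = rng.standard_normal(n_c)
    zm_age = config.age_corr * zf_age + np.sqrt(max(0.0, 1 - config.age_corr**2)) * rng.standard_normal(n_c)
    age_f = 55.0 + 8.0 * zf_age
    age_m = 55.0 + 8.0 * zm_age
    town = rng.normal(0.0, 3.0, size=n_c)
    cohab = rng.random(n_c) < 0.92

    fid = couples["female_id"].to_numpy()
    mid = couples["male_id"].to_numpy()
    ph.loc[fid, "household_id"] = couples["household_id"].to_numpy()
    ph.loc[mid, "household_id"] = couples["household_id"].to_numpy()
    ph.loc[fid, "age"] = age_f
    ph.loc[mid, "age"] = age_m
    ph.loc[fid, "townsend"] = town + rng.normal(0, 0.5, size=n_c)
    ph.loc[mid, "townsend"] = town + rng.normal(0, 0.5, size=n_c)
    ph.loc[fid, "father_age"] = rng.integers(75, 95, size=n_c)
    ph.loc[fid, "mother_age"] = rng.integers(72, 92, size=n_c)
    ph.loc[mid, "father_age"] = rng.integers(75, 95, size=n_c)
    ph.loc[mid, "mother_age"] = rng.integers(72, 92, size=n_c)
    ph.loc[fid, "lives_with_partner"] = cohab
    ph.loc[mid, "lives_with_partner"] = cohab
    return ph.reset_index(drop=True)


def simulate_cohort(config: SimConfig):
    """Convenience wrapper: genotypes -> heights -> couples -> covariates.

    Returns ``(G, phenos, couples)``, fully determined by ``config.seed``.
    """
    G = simulate_genotypes(config)
    phenos = simulate_heights(G, config)
    couples = form_couples(phenos, config)
    phenos = attach_covariates(couples, phenos, config)
    return G, phenos, couples


# ---------------------------------------------------------------------------
# on-disk cohort (PLINK + TSV)

PHENO_COLUMNS = [
    "IID", "sex", "age", "height", "townsend", "household_id",
    "birth_east", "birth_north", "platform", "additive_value",
    "father_age", "mother_age", "lives_with_partner", "ethnicity", "cluster",
]


def write_cohort(G: GenotypeMatrix, phenos: pd.DataFrame, couples: pd.DataFrame, prefix: str) -> None:
    """Write PLINK .bed/.bim/.fam plus phenotype and couples TSVs."""
    ids_g = set(G.sample_ids)
    ids_p = set(phenos["sample_id"])
    if ids_g != ids_p:
        raise DataError("genotype and phenotype sample sets differ")
    missing = (set(couples["female_id"]) | set(couples["male_id"])) - ids_g
    if missing:
        raise DataError(f"couples reference unknown samples: {sorted(missing)[:5]}")
    plink._check_writable(prefix + ".bed")
    plink.write_bed(prefix + ".bed", G.dosages)
    plink.write_bim(prefix + ".bim", G.snp_meta)
    sex = phenos.set_index("sample_id").loc[G.sample_ids, "sex"].to_numpy()
    plink.write_fam(prefix + ".fam", G.sample_ids, sex)

    out = phenos.rename(columns={"sample_id": "IID"}).copy()
    out["platform"] = pd.Series(G.sample_platform, index=phenos.index)
    cols = [c for c in PHENO_COLUMNS if c in out.columns]
    out[cols].to_csv(prefix + ".pheno.tsv", sep="\t", index=False)
    couples.rename(columns={"female_id": "female_IID", "male_id": "male_IID"}).to_csv(
        prefix + ".couples.tsv", sep="\t", index=False
    )


def read_cohort(prefix: str):
    """Read back a cohort written by :func:`write_cohort`."""
    fam = plink.read_fam(prefix + ".fam")
    bim = plink.read_bim(prefix + ".bim")
    dosages = plink.read_bed(prefix + ".bed", len(fam), len(bim))
    phenos = pd.read_csv(prefix + ".pheno.tsv", sep="\t", dtype={"IID": str})
    phenos = phenos.rename(columns={"IID": "sample_id"})
    couples = pd.read_csv(prefix + ".couples.tsv", sep="\t", dtype=str)
    couples = couples.rename(columns={"female_IID": "female_id", "male_IID": "male_id"})
    for col in ("female_height", "male_height"):
        if col in couples.columns:
            couples[col] = couples[col].astype(float)
    if "cluster" in couples.columns:
        couples["cluster"] = couples["cluster"].astype(int)
    meta = bim.copy()
    meta["freq"] = np.nan
    meta["platform"] = "both"
    platform = (
        phenos.set_index("sample_id").loc[fam["iid"], "platform"].to_numpy()
        if "platform" in phenos.columns
        else None
    )
    cluster = (
        phenos.set_index("sample_id").loc[fam["iid"], "cluster"].to_numpy()
        if "cluster" in phenos.columns
        else None
    )
    G = GenotypeMatrix(
        dosages=dosages,
        snp_meta=meta[["snp_id", "chrom", "pos", "a1", "a2", "freq", "platform"]],
        sample_ids=fam["iid"].to_numpy(),
        sample_platform=platform,
        cluster=cluster,
    )
    return G, phenos, couples
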