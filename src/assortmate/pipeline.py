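"""End-to-end mate-choice analysis: couple identification, fixed-effects
design, univariate/bivariate GREML of (own height, partner height), BLUP
partner-height prediction, GWAS effect correlation, permutation control and
the closed-form theory scalars.

Every individual in a couple serves once as a focal individual; "partner's
height" is treated as the focal individual's own trait, so a cohort of C
couples yields 2C focal records over one GRM.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError
from .simulate import SimConfig, GenotypeMatrix, simulate_cohort
from .qc import QCThresholds, snp_qc, sample_qc, phenotype_outlier_filter
from .relatedness import (
    GRM,
    standardize_genotypes,
    compute_grm,
    ld_prune,
    grm_pca,
    ethnic_core_filter,
    couple_relatedness_filter,
)
from .greml import UnivariateGREML, UnivariateFit, snp_effects_from_estimator
from .bivariate import BivariateGREML, BivariateFit
from .permutation import swap_males, covariate_dependence_tests, relatedness_distance_regression
from . import theory

logger = logging.getLogger("assortmate")

DEFAULT_COVARIATES = tuple(f"PC{i}" for i in range(1, 21)) + ("sex", "age", "townsend")


@dataclass
class Cohort:
    """Genotypes + per-individual phenotypes + couple table."""

    G: GenotypeMatrix
    phenos: pd.DataFrame
    couples: pd.DataFrame


@dataclass
class AnalysisConfig:
    covariates: tuple = DEFAULT_COVARIATES
    n_pcs: int = 20
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    reml_options: dict = field(default_factory=dict)
    r_max: float = 0.0625
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.2
    holdout_fraction: float = 0.2
    n_perm: int = 1000
    seed: int = 0


# ---------------------------------------------------------------------------
# couples and designs

def identify_couples(phenos: pd.DataFrame, mode: str = "genotyped_pairs") -> pd.DataFrame:
    """Households with exactly two opposite-sex members become couples.

    ``prediction_pairs`` mode additionally requires an age difference under
    10 years, differing reported parental ages (a sibling guard) and a
    cohabitation flag for both members.
    """
    if mode not in ("genotyped_pairs", "prediction_pairs"):
        raise ConfigError(f"unknown mode {mode!r}")
    rows = []
    for hh, grp in phenos.groupby("household_id", sort=True):
        if hh == "" or pd.isna(hh) or len(grp) != 2:
            continue
        sexes = set(grp["sex"])
        if sexes != {"male", "female"}:
            continue
        f = grp[grp["sex"] == "female"].iloc[0]
        m = grp[grp["sex"] == "male"].iloc[0]
        if mode == "prediction_pairs":
            if abs(f["age"] - m["age"]) >= 10:
                continue
            if not (bool(f.get("lives_with_partner", True)) and bool(m.get("lives_with_partner", True))):
                continue
            same_parents = (
                f.get("father_age", 0) == m.get("father_age", 0)
                and f.get("mother_age", 0) == m.get("mother_age", 0)
            )
            if same_parents:
                continue
        rows.append(
            {
                "household_id": hh,
                "female_id": f["sample_id"],
                "male_id": m["sample_id"],
                "female_height": f["height"],
                "male_height": m["height"],
            }
        )
    return pd.DataFrame(rows, columns=["household_id", "female_id", "male_id", "female_height", "male_height"])


def focal_records(couples: pd.DataFrame, phenos: pd.DataFrame) -> pd.DataFrame:
    """Two focal records per couple: each member once, with partner height."""
    f = pd.DataFrame(
        {
            "sample_id": couples["female_id"],
            "partner_id": couples["male_id"],
            "own_height": couples["female_height"],
            "partner_height": couples["male_height"],
        }
    )
    m = pd.DataFrame(
        {
            "sample_id": couples["male_id"],
            "partner_id": couples["female_id"],
            "own_height": couples["male_height"],
            "partner_height": couples["female_height"],
        }
    )
    focal = pd.concat([f, m], ignore_index=True)
    if focal["sample_id"].duplicated().any():
        raise DataError("an individual appears in more than one couple")
    extra = phenos.set_index("sample_id")
    cols = [c for c in ("sex", "age", "townsend", "additive_value") if c in extra.columns]
    for c in cols:
        focal[c] = extra.loc[focal["sample_id"], c].to_numpy()
    return focal


def build_design(cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES, pcs=None):
    """Intercept + covariate design matrix with rank checking.

    ``PC<k>`` covariate names draw on ``pcs`` (a PCProjection aligned to the
    cohort row order); ``sex`` is coded 0 = female, 1 = male.  Returns
    (X, labels).  Raises on duplicate or collinear columns, naming them.
    """
    covariates = list(covariates)
    if len(set(covariates)) != len(covariates):
        dupes = sorted({c for c in covariates if covariates.count(c) > 1})
        raise ConfigError(f"duplicate covariates: {dupes}")
    n = len(cohort)
    cols, labels = [np.ones(n)], ["intercept"]
    for name in covariates:
        if name.startswith("PC") and name[2:].isdigit():
            if pcs is None:
                raise ConfigError(f"covariate {name} requested but no PCs supplied")
            k = int(name[2:]) - 1
            if k >= pcs.eigenvectors.shape[1]:
                raise ConfigError(f"{name} exceeds available PCs ({pcs.eigenvectors.shape[1]})")
            cols.append(pcs.eigenvectors[:, k])
        elif name == "sex":
            cols.append((cohort["sex"] == "male").to_numpy(float))
        elif name in cohort.columns:
            cols.append(cohort[name].to_numpy(float))
        else:
            raise ConfigError(f"unknown covariate {name!r}")
        labels.append(name)
    X = np.column_stack(cols)
    # name collinear columns via QR
    _, R = np.linalg.qr(X)
    bad = np.flatnonzero(np.abs(np.diag(R)) < 1e-8 * max(1.0, np.abs(np.diag(R)).max()))
    if bad.size:
        raise DataError(f"collinear design columns: {[labels[i] for i in bad]}")
    return X, labels


# ---------------------------------------------------------------------------
# GREML analyses on a cohort

def cohort_grm(cohort: Cohort):
    """Standardized genotypes and GRM over the focal individuals, focal order."""
    focal = focal_records(cohort.couples, cohort.phenos)
    sub = cohort.G.subset_by_ids(focal["sample_id"].to_numpy())
    Z = standardize_genotypes(sub)
    return focal, Z, compute_grm(Z)


def run_mate_choice_univariate(
    cohort: Cohort, covariates=("sex",), pcs=None, reml_options=None
) -> UnivariateFit:
    """Univariate GREML of partner height over all focal individuals."""
    focal, _, A = cohort_grm(cohort)
    X, _ = build_design(focal, covariates, pcs=pcs)
    est = UnivariateGREML(**(reml_options or {}))
    est.fit(X, focal["partner_height"].to_numpy(), grm=A)
    return est.fit_result_


def run_mate_choice_bivariate(
    cohort: Cohort, covariates=("sex",), pcs=None, reml_options=None
) -> BivariateFit:
    """Bivariate GREML of (own height, partner height) on the shared GRM."""
    focal, _, A = cohort_grm(cohort)
    X, _ = build_design(focal, covariates, pcs=pcs)
    est = BivariateGREML(**(reml_options or {}))
    est.fit(X, focal["own_height"].to_numpy(), X, focal["partner_height"].to_numpy(), grm=A)
    return est.fit_result_


def bivariate_report_rows(fit: BivariateFit) -> dict:
    """Summary formatted like the standard five-row bivariate table."""
    return {
        "h2_Height": (fit.h2_1, fit.se_h2_1),
        "h2_Height choice": (fit.h2_2, fit.se_h2_2),
        "r_G": (fit.r_g, fit.se_r_g),
        "r_E": (fit.r_e, fit.se_r_e),
        "r_P": (fit.r_p, fit.se_r_p),
    }


def predict_partner_height(
    train_cohort: Cohort,
    holdout_G: GenotypeMatrix,
    holdout_partner_height: np.ndarray,
    h2_choice: float,
    covariates=("sex",),
    pcs=None,
    reml_options=None,
):
    """BLUP polygenic prediction of the partner's height in a holdout set.

    Fits own height by univariate GREML on the training cohort, converts the
    fit to per-SNP effects, scores the genotyped holdout individuals (whose
    partners are not in the training GRM) and correlates the score with the
    partner's measured height.  Returns (accuracy, ratio_to_max, fit) with
    ratio_to_max = accuracy / sqrt(h2_choice).
    """
    focal, Z, A = cohort_grm(train_cohort)
    X, _ = build_design(focal, covariates, pcs=pcs)
    est = UnivariateGREML(**(reml_options or {}))
    est.fit(X, focal["own_height"].to_numpy(), grm=A)
    fit = est.fit_result_
    if fit.sigma_g2 <= 1e-6 * (fit.sigma_g2 + fit.sigma_e2):
        raise DataError("zero genetic variance in training fit: predictions undefined")
    a = snp_effects_from_estimator(est, Z)
    Zh = standardize_genotypes(holdout_G, freqs=Z.freqs)
    scores = Zh.z @ a
    if np.std(scores) == 0:
        raise DataError("zero-variance predictions")
    accuracy = float(np.corrcoef(scores, np.asarray(holdout_partner_height, float))[0, 1])
    if h2_choice <= 0:
        raise DataError("h2_choice must be positive for the ratio")
    return accuracy, accuracy / float(np.sqrt(h2_choice)), fit


def greedy_unrelated_subset(A: GRM, r_max: float = 0.0625) -> np.ndarray:
    """Boolean mask of a pairwise-unrelated subset (drop most-connected first)."""
    n = A.A.shape[0]
    rel = (A.A > r_max) & ~np.eye(n, dtype=bool)
    keep = np.ones(n, dtype=bool)
    degree = rel.sum(axis=1)
    while True:
        active = degree * keep
        worst = int(np.argmax(active))
        if active[worst] == 0:
            break
        keep[worst] = False
        degree -= rel[worst]
        degree[worst] = 0
    return keep


def gwas_effect_correlation(cohort: Cohort, covariates=("sex",), pcs=None, r_max: float = 0.0625) -> float:
    """Correlation across SNPs of single-marker effects for the two traits.

    Runs covariate-adjusted per-SNP least squares for own height and for
    partner height on a greedily built unrelated subset (pairwise GRM
    relatedness <= r_max) and returns the Pearson correlation of the two
    effect vectors.
    """
    focal, Z, A = cohort_grm(cohort)
    keep = greedy_unrelated_subset(A, r_max)
    X, _ = build_design(focal, covariates, pcs=pcs)
    X = X[keep]
    z = Z.z[keep]
    proj = X @ np.linalg.lstsq(X, z, rcond=None)[0]
    z_res = z - proj
    effects = []
    for trait in ("own_height", "partner_height"):
        y = focal[trait].to_numpy()[keep]
        y_res = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        denom = (z_res**2).sum(axis=0)
        denom[denom == 0] = np.inf
        effects.append(z_res.T @ y_res / denom)
    return float(np.corrcoef(effects[0], effects[1])[0, 1])


# ---------------------------------------------------------------------------
# full pipeline

def run_full_pipeline(sim_config: SimConfig, analysis: AnalysisConfig = None, outdir=None) -> dict:
    """simulate -> QC -> GRM/PCA -> filters -> GREML + prediction +
    permutation + theory; returns a JSON-serializable report bundle."""
    analysis = analysis or AnalysisConfig(seed=sim_config.seed)
    report = {"sim_config": _asdict(sim_config)}
    t_start = time.time()

    def stage(name):
        logger.info("stage %-18s t=%.1fs", name, time.time() - t_start)

    try:
        stage("simulate")
        G, phenos, couples = simulate_cohort(sim_config)

        stage("qc")
        G, snp_report = snp_qc(G, analysis.thresholds)
        G, sample_report = sample_qc(G, analysis.thresholds)
        phenos = phenos[phenos["sample_id"].isin(G.sample_ids)].reset_index(drop=True)
        phenos, pheno_report = phenotype_outlier_filter(phenos, analysis.thresholds.pheno_sd_max)
        ids = set(phenos["sample_id"])
        couples = couples[
            couples["female_id"].isin(ids) & couples["male_id"].isin(ids)
        ].reset_index(drop=True)
        report["qc"] = {
            "snp": snp_report.to_dict(),
            "sample": sample_report.to_dict(),
            "phenotype": pheno_report.to_dict(),
            "n_couples_after_qc": len(couples),
        }

        stage("grm_pca")
        cohort = Cohort(G, phenos, couples)
        focal, Z, A = cohort_grm(cohort)
        pruned = ld_prune(
            cohort_genotypes(cohort), analysis.ld_window, analysis.ld_step, analysis.ld_r2_max
        )
        G_pruned = cohort_genotypes(cohort).subset(
            snp_mask=cohort_genotypes(cohort).snp_meta["snp_id"].isin(pruned).to_numpy()
        )
        A_pruned = compute_grm(standardize_genotypes(G_pruned))
        k = min(analysis.n_pcs, A_pruned.A.shape[0])
        pcs = grm_pca(A_pruned, k=k)
        report["pca"] = {"n_pruned_snps": len(pruned), "k": k}

        stage("filters")
        ethnicity = (
            cohort.phenos.set_index("sample_id")
            .loc[pcs.sample_ids, "ethnicity"]
            .to_numpy()
            if "ethnicity" in cohort.phenos.columns
            else np.full(len(pcs.sample_ids), "White-British")
        )
        core = set(ethnic_core_filter(pcs, ethnicity))
        couples = couples[
            couples["female_id"].isin(core) & couples["male_id"].isin(core)
        ].reset_index(drop=True)
        couples = couple_relatedness_filter(couples, A, analysis.r_max)
        cohort = Cohort(G, phenos, couples)
        focal, Z, A = cohort_grm(cohort)
        pcs = _reindex_pcs(pcs, focal["sample_id"].to_numpy())
        report["filters"] = {"n_core": len(core), "n_couples_final": len(couples)}

        realized_rp = float(
            np.corrcoef(couples["female_height"], couples["male_height"])[0, 1]
        )
        report["realized_rp"] = realized_rp

        pc_names = tuple(f"PC{i}" for i in range(1, k + 1))
        covs = tuple(c for c in analysis.covariates if not c.startswith("PC")) + pc_names
        covs = tuple(c for c in covs if c == "sex" or c in focal.columns or c.startswith("PC"))
        X, labels = build_design(focal, covs, pcs=pcs)

        stage("univariate")
        uni_est = UnivariateGREML(**analysis.reml_options)
        uni_est.fit(X, focal["partner_height"].to_numpy(), grm=A)
        report["univariate_mate_choice"] = uni_est.fit_result_.to_dict()

        stage("bivariate")
        biv_est = BivariateGREML(**analysis.reml_options)
        biv_est.fit(X, focal["own_height"].to_numpy(), X, focal["partner_height"].to_numpy(), grm=A)
        report["bivariate"] = biv_est.fit_result_.to_dict()
        report["bivariate_table"] = {
            k_: list(v) for k_, v in bivariate_report_rows(biv_est.fit_result_).items()
        }

        stage("prediction")
        n_hold = max(2, int(round(analysis.holdout_fraction * len(couples))))
        rng = np.random.default_rng(analysis.seed)
        hold_idx = np.sort(rng.choice(len(couples), size=n_hold, replace=False))
        hold_mask = np.zeros(len(couples), bool)
        hold_mask[hold_idx] = True
        train = Cohort(G, phenos, couples[~hold_mask].reset_index(drop=True))
        hold = couples[hold_mask]
        h2c = max(report["univariate_mate_choice"]["h2"], 1e-6)
        accuracy, ratio, own_fit = predict_partner_height(
            train,
            G.subset_by_ids(hold["female_id"].to_numpy()),
            hold["male_height"].to_numpy(),
            h2c,
            covariates=("sex",),
        )
        report["prediction"] = {
            "accuracy": accuracy,
            "ratio_to_max": ratio,
            "h2_own_height": own_fit.h2,
            "n_holdout": int(n_hold),
        }

        stage("gwas")
        report["gwas_effect_correlation"] = gwas_effect_correlation(
            cohort, covariates=("sex",), r_max=analysis.r_max
        )

        stage("permutation")
        swap = swap_males(couples)
        cov_types = {"age": "continuous", "townsend": "continuous"}
        dep_obs = covariate_dependence_tests(
            swap.original, phenos, cov_types, n_perm=analysis.n_perm, seed=analysis.seed
        )
        dep_perm = covariate_dependence_tests(
            swap.permuted, phenos, cov_types, n_perm=analysis.n_perm, seed=analysis.seed
        )
        slope_obs, p_obs = relatedness_distance_regression(swap.original, A, phenos)
        slope_perm, p_perm = relatedness_distance_regression(swap.permuted, A, phenos)
        report["permutation"] = {
            "dependence_observed": dep_obs.to_dict(orient="records"),
            "dependence_swapped": dep_perm.to_dict(orient="records"),
            "relatedness_distance": {
                "observed": [slope_obs, p_obs],
                "swapped": [slope_perm, p_perm],
            },
            "rp_observed": realized_rp,
            "rp_swapped": float(
                np.corrcoef(swap.permuted["female_height"], swap.permuted["male_height"])[0, 1]
            ),
        }

        stage("theory")
        report["theory"] = theory.theory_table(
            h2=report["bivariate"]["h2_1"], r_p=realized_rp
        )
    except Exception as exc:
        raise type(exc)(f"pipeline failed: {exc}") from exc

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    stage("done")
    return report


def cohort_genotypes(cohort: Cohort) -> GenotypeMatrix:
    """Genotypes restricted to coupled individuals (for pruning/PCA)."""
    focal_ids = set(cohort.couples["female_id"]) | set(cohort.couples["male_id"])
    return cohort.G.subset(sample_mask=np.isin(cohort.G.sample_ids, list(focal_ids)))


def _reindex_pcs(pcs, order):
    lookup = {s: i for i, s in enumerate(pcs.sample_ids)}
    idx = np.array([lookup[s] for s in order])
    from .relatedness import PCProjection

    return PCProjection(
        eigenvalues=pcs.eigenvalues,
        eigenvectors=pcs.eigenvectors[idx],
        k=pcs.k,
        sample_ids=np.asarray(order),
    )


def _asdict(obj):
    from dataclasses import asdict

    return asdict(obj)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    return str(o)
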