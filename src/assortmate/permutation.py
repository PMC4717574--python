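"""Couple-swap permutation control and within-couple dependence diagnostics.

The swap preserves the height-assortment structure while destroying any
within-couple genetic or environmental structure due to assortment on other
factors (geography, age, socio-economic status): couples are ordered by
(female height, male height) and the male partners of successive couples are
exchanged — male 1 with 2, 3 with 4, and so on — so each new couple pairs
individuals of nearly identical heights who never actually shared a
household.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score

from .exceptions import DataError
from .relatedness import GRM

__all__ = [
    "SwapResult",
    "swap_males",
    "covariate_dependence_tests",
    "relatedness_distance_regression",
]


@dataclass
class SwapResult:
    original: pd.DataFrame
    permuted: pd.DataFrame
    male_mapping: dict  # original male id -> male id now in that household


def swap_males(couples: pd.DataFrame) -> SwapResult:
    """Swap male partners between successive height-sorted couples.

    Couples are sorted lexicographically by (female height, male height),
    stable for ties; males are exchanged within pairs (1,2), (3,4), ...; an
    odd trailing couple is left unchanged.  The multiset of males is
    preserved and each male appears exactly once afterwards.
    """
    if len(couples) < 2:
        return SwapResult(couples.copy(), couples.copy(), {})
    for col in ("female_height", "male_height"):
        if col not in couples.columns or couples[col].isna().any():
            raise DataError(f"swap_males requires complete '{col}'")
    order = couples.sort_values(
        ["female_height", "male_height"], kind="stable"
    ).reset_index(drop=True)
    permuted = order.copy()
    n = len(order)
    male_cols = [c for c in ("male_id", "male_height") if c in order.columns]
    for a in range(0, n - 1, 2):
        b = a + 1
        permuted.loc[a, male_cols], permuted.loc[b, male_cols] = (
            order.loc[b, male_cols].tolist(),
            order.loc[a, male_cols].tolist(),
        )
    mapping = dict(zip(order["male_id"], permuted["male_id"]))
    return SwapResult(original=order, permuted=permuted, male_mapping=mapping)


def covariate_dependence_tests(
    couples: pd.DataFrame,
    phenos: pd.DataFrame,
    covariates: dict,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-couple dependence statistics per covariate.

    ``covariates`` maps column name -> 'continuous' | 'categorical'.
    Continuous covariates get the between-partner Pearson correlation with
    its analytic two-sided p-value; categorical covariates get the plug-in
    mutual information (natural log) of the within-couple contingency table
    with a permutation p-value, p = (1 + #{perm MI >= observed}) / (n_perm + 1),
    from permutations of the female values.  Constant covariates report
    statistic 0, p = 1.
    """
    ph = phenos.set_index("sample_id")
    rng = np.random.default_rng(seed)
    rows = []
    for col, kind in covariates.items():
        f = ph.loc[couples["female_id"], col].to_numpy()
        m = ph.loc[couples["male_id"], col].to_numpy()
        if kind == "continuous":
            f = f.astype(float)
            m = m.astype(float)
            if np.std(f) == 0 or np.std(m) == 0:
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.pearsonr(f, m)
            rows.append((col, kind, float(stat), float(p), 0))
        elif kind == "categorical":
            if len(np.unique(f)) < 2 or len(np.unique(m)) < 2:
                rows.append((col, kind, 0.0, 1.0, n_perm))
                continue
            mi_obs = mutual_info_score(f, m)
            exceed = 0
            for _ in range(n_perm):
                mi_p = mutual_info_score(rng.permutation(f), m)
                if mi_p >= mi_obs:
                    exceed += 1
            p = (1.0 + exceed) / (n_perm + 1.0)
            rows.append((col, kind, float(mi_obs), float(p), n_perm))
        else:
            raise DataError(f"unknown covariate type {kind!r} for {col!r}")
    return pd.DataFrame(
        rows, columns=["covariate", "type", "statistic", "p_value", "n_permutations"]
    )


def relatedness_distance_regression(
    couples: pd.DataFrame, A: GRM, phenos: pd.DataFrame
):
    """OLS of within-couple GRM relatedness on birthplace distance.

    Distance is planar Euclidean on (birth_east, birth_north) in metres.
    Returns (slope, two-sided p-value for zero slope).
    """
    if len(couples) < 3:
        raise DataError("need at least 3 couples for the regression")
    ph = phenos.set_index("sample_id")
    for col in ("birth_east", "birth_north"):
        if col not in ph.columns:
            raise DataError(f"phenotype table lacks '{col}'")
    fi = A.index_of(couples["female_id"])
    mi = A.index_of(couples["male_id"])
    rel = A.A[fi, mi]
    de = ph.loc[couples["female_id"], "birth_east"].to_numpy() - ph.loc[
        couples["male_id"], "birth_east"
    ].to_numpy()
    dn = ph.loc[couples["female_id"], "birth_north"].to_numpy() - ph.loc[
        couples["male_id"], "birth_north"
    ].to_numpy()
    dist = np.hypot(de, dn)
    if np.std(rel) == 0 or np.std(dist) == 0:
        return 0.0, 1.0
    res = stats.linregress(dist, rel)
    return float(res.slope), float(res.pvalue)
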