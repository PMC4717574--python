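"""Couple swap and dependence diagnostics."""

import numpy as np
import pandas as pd
import pytest

import assortmate as am
from assortmate.exceptions import DataError
from assortmate.permutation import swap_males, covariate_dependence_tests
from assortmate.relatedness import GRM, standardize_genotypes, compute_grm


def couples_frame(fh, mh, ids=None):
    n = len(fh)
    return pd.DataFrame(
        {
            "household_id": [f"h{i}" for i in range(n)],
            "female_id": [f"f{i}" for i in range(n)],
            "male_id": ids or [f"m{i}" for i in range(n)],
            "female_height": fh,
            "male_height": mh,
        }
    )


class TestSwap:
    def test_manual_trace(self):
        c = couples_frame([150, 155, 160, 165], [160, 170, 165, 180])
        res = swap_males(c)
        got = list(zip(res.permuted["female_height"], res.permuted["male_height"]))
        assert got == [(150, 170), (155, 160), (160, 180), (165, 165)]

    def test_single_couple_unchanged(self):
        c = couples_frame([160], [175])
        res = swap_males(c)
        assert res.permuted.equals(res.original)

    def test_male_multiset_preserved_and_odd_tail(self):
        rng = np.random.default_rng(0)
        c = couples_frame(rng.normal(165, 7, 11), rng.normal(178, 7, 11))
        res = swap_males(c)
        assert sorted(res.permuted["male_id"]) == sorted(c["male_id"])
        assert not res.permuted["male_id"].duplicated().any()
        # the last sorted couple is unchanged for odd counts
        assert res.permuted.iloc[-1]["male_id"] == res.original.iloc[-1]["male_id"]

    def test_missing_heights_rejected(self):
        c = couples_frame([160.0, np.nan], [175.0, 180.0])
        with pytest.raises(DataError):
            swap_males(c)

    def test_marginals_exact_and_correlation_preserved(self):
        rng = np.random.default_rng(1)
        n = 4000
        f = rng.normal(165, 7, n)
        m = 0.26 * (f - 165) + rng.normal(178, 7 * np.sqrt(1 - 0.26**2), n)
        c = couples_frame(f, m)
        r_before = np.corrcoef(c["female_height"], c["male_height"])[0, 1]
        res = swap_males(c)
        assert sorted(res.permuted["female_height"]) == sorted(f)
        assert sorted(res.permuted["male_height"]) == sorted(m)
        r_after = np.corrcoef(res.permuted["female_height"], res.permuted["male_height"])[0, 1]
        assert abs(r_after - r_before) < 0.03

    def test_swap_of_swap_keeps_correlation(self):
        rng = np.random.default_rng(2)
        n = 2000
        f = rng.normal(165, 7, n)
        m = 0.3 * (f - 165) + rng.normal(178, 7, n)
        c = couples_frame(f, m)
        r0 = np.corrcoef(c["female_height"], c["male_height"])[0, 1]
        twice = swap_males(swap_males(c).permuted).permuted
        r2 = np.corrcoef(twice["female_height"], twice["male_height"])[0, 1]
        assert abs(r2 - r0) < 0.03


class TestDependence:
    def phenos_for(self, couples, fvals, mvals, col):
        ids = list(couples["female_id"]) + list(couples["male_id"])
        return pd.DataFrame(
            {"sample_id": ids, col: np.concatenate([fvals, mvals])}
        )

    def test_identical_categorical_attains_minimal_p(self):
        rng = np.random.default_rng(3)
        n = 300
        cats = rng.integers(0, 4, n)
        c = couples_frame(rng.normal(165, 7, n), rng.normal(178, 7, n))
        ph = self.phenos_for(c, cats, cats, "region")
        rep = covariate_dependence_tests(c, ph, {"region": "categorical"}, n_perm=1000, seed=0)
        row = rep.iloc[0]
        assert row["p_value"] == pytest.approx(1 / 1001)
        # MI of identical variables equals the marginal entropy
        _, counts = np.unique(cats, return_counts=True)
        pk = counts / n
        assert row["statistic"] == pytest.approx(-(pk * np.log(pk)).sum(), rel=1e-9)

    def test_constant_covariate(self):
        n = 50
        rng = np.random.default_rng(4)
        c = couples_frame(rng.normal(165, 7, n), rng.normal(178, 7, n))
        ph = self.phenos_for(c, np.ones(n), np.ones(n), "flag")
        rep = covariate_dependence_tests(c, ph, {"flag": "continuous"}, seed=0)
        assert rep.iloc[0]["statistic"] == 0.0 and rep.iloc[0]["p_value"] == 1.0

    def test_permutation_p_valid_under_independence(self):
        # under independent covariates, P(p <= alpha) <= alpha + 1/(n_perm+1)
        rng = np.random.default_rng(5)
        n, n_perm, reps = 80, 59, 200
        pvals = []
        for r in range(reps):
            c = couples_frame(rng.normal(165, 7, n), rng.normal(178, 7, n))
            ph = self.phenos_for(c, rng.integers(0, 3, n), rng.integers(0, 3, n), "cat")
            rep = covariate_dependence_tests(
                c, ph, {"cat": "categorical"}, n_perm=n_perm, seed=r
            )
            pvals.append(rep.iloc[0]["p_value"])
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25):
            bound = alpha + 1.0 / (n_perm + 1)
            # allow binomial MC noise on 200 replicates
            assert (pvals <= alpha).mean() <= bound + 3 * np.sqrt(bound * (1 - bound) / reps)

    def test_swap_destroys_covariate_dependence(self):
        cfg = am.SimConfig(n_couples=800, n_snps=50, age_corr=0.9, seed=34)
        G, ph, couples = am.simulate_cohort(cfg)
        res = swap_males(couples)
        types = {"age": "continuous", "townsend": "continuous"}
        obs = covariate_dependence_tests(res.original, ph, types, seed=0)
        perm = covariate_dependence_tests(res.permuted, ph, types, seed=0)
        for cov in ("age", "townsend"):
            r_obs = obs.loc[obs["covariate"] == cov, "statistic"].iloc[0]
            r_perm = perm.loc[perm["covariate"] == cov, "statistic"].iloc[0]
            assert r_obs > 0.5
            assert abs(r_perm) < 0.2


class TestRelatednessDistance:
    def cohort_with_structure(self):
        cfg = am.SimConfig(
            n_couples=400, n_snps=600, fst=0.08, geo_clusters=6, seed=35
        )
        G, ph, couples = am.simulate_cohort(cfg)
        G, _ = am.snp_qc(G)  # drift can create sub-MAF or monomorphic sites
        A = compute_grm(standardize_genotypes(G))
        return G, ph, couples, A

    def test_negative_slope_attenuated_by_swap(self):
        G, ph, couples, A = self.cohort_with_structure()
        slope_obs, p_obs = am.relatedness_distance_regression(couples, A, ph)
        assert slope_obs < 0 and p_obs < 0.05
        res = swap_males(couples)
        slope_perm, _ = am.relatedness_distance_regression(res.permuted, A, ph)
        assert abs(slope_perm) < abs(slope_obs)

    def test_constant_relatedness_zero_slope(self):
        rng = np.random.default_rng(6)
        n = 20
        c = couples_frame(rng.normal(165, 7, n), rng.normal(178, 7, n))
        ids = list(c["female_id"]) + list(c["male_id"])
        ph = pd.DataFrame(
            {
                "sample_id": ids,
                "birth_east": rng.uniform(0, 1e5, 2 * n),
                "birth_north": rng.uniform(0, 1e5, 2 * n),
            }
        )
        A = GRM(np.eye(2 * n), np.array(ids), 10)
        slope, p = am.relatedness_distance_regression(c, A, ph)
        assert slope == 0.0 and p == 1.0

    def test_too_few_couples(self):
        c = couples_frame([160.0, 162.0], [175.0, 177.0])
        with pytest.raises(DataError):
            am.relatedness_distance_regression(c, GRM(np.eye(4), np.array(["f0","f1","m0","m1"]), 1), None)
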