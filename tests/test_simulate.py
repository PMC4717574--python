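"""Synthetic-cohort generator: HWE, additive architecture, assortment,
covariate structure, determinism and PLINK round-trips."""

import numpy as np
import pandas as pd
import pytest

import assortmate as am
from assortmate.exceptions import ConfigError, DataError


class TestGenotypes:
    def test_mean_dosage_at_half_frequency(self):
        cfg = am.SimConfig(n_couples=2000, n_snps=50, maf_low=0.5, maf_high=0.5, seed=1)
        G = am.simulate_genotypes(cfg)
        assert abs(G.dosages.mean() - 1.0) < 0.02

    def test_hwe_class_frequencies(self):
        # p = 0.2: expected genotype classes (0.64, 0.32, 0.04)
        cfg = am.SimConfig(n_couples=5000, n_snps=20, maf_low=0.2, maf_high=0.2, seed=2)
        G = am.simulate_genotypes(cfg)
        n = G.dosages.size
        freqs = [(G.dosages == k).sum() / n for k in (0, 1, 2)]
        assert np.allclose(freqs, [0.64, 0.32, 0.04], atol=0.01)

    def test_hwe_at_every_maf(self):
        cfg = am.SimConfig(n_couples=4000, n_snps=60, seed=3)
        G = am.simulate_genotypes(cfg)
        d = G.dosages
        p_hat = d.mean(axis=0) / 2
        het = (d == 1).mean(axis=0)
        expected = 2 * p_hat * (1 - p_hat)
        # binomial sampling error on the het fraction at n = 8000
        se = np.sqrt(expected * (1 - expected) / d.shape[0])
        assert np.all(np.abs(het - expected) < 5 * se + 1e-3)

    def test_invalid_maf_bounds(self):
        with pytest.raises(ConfigError):
            am.simulate_genotypes(am.SimConfig(maf_low=0.0))
        with pytest.raises(ConfigError):
            am.simulate_genotypes(am.SimConfig(maf_low=0.3, maf_high=0.2))

    def test_missingness_injection(self):
        cfg = am.SimConfig(n_couples=500, n_snps=100, missing_rate=0.05, seed=4)
        G = am.simulate_genotypes(cfg)
        assert abs((G.dosages == -1).mean() - 0.05) < 0.01


class TestHeights:
    def test_full_heritability_means_no_environment(self):
        cfg = am.SimConfig(n_couples=500, n_snps=200, h2_height=1.0, seed=5)
        G = am.simulate_genotypes(cfg)
        ph = am.simulate_heights(G, cfg)
        shift = np.where(ph["sex"] == "male", cfg.sex_mean_shift, 0.0)
        resid = ph["height"] - 165.0 - shift - ph["additive_value"]
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_zero_heritability_means_no_genetics(self):
        cfg = am.SimConfig(n_couples=500, n_snps=200, h2_height=0.0, seed=5)
        G = am.simulate_genotypes(cfg)
        ph = am.simulate_heights(G, cfg)
        assert np.allclose(ph["additive_value"], 0.0)

    def test_variance_ratio_matches_h2(self):
        cfg = am.SimConfig(
            n_couples=10000, n_snps=300, h2_height=0.8, causal_fraction=1.0, seed=6
        )
        G = am.simulate_genotypes(cfg)
        ph = am.simulate_heights(G, cfg)
        females = ph[ph["sex"] == "female"]
        ratio = np.var(females["additive_value"]) / np.var(females["height"])
        assert abs(ratio - 0.8) < 0.02

    def test_h2_out_of_range(self):
        with pytest.raises(ConfigError):
            am.SimConfig(h2_height=1.2).validate()


class TestCouples:
    def test_target_correlation_realized(self):
        cfg = am.SimConfig(n_couples=10000, n_snps=60, target_rp=0.26, seed=8)
        G, ph, couples = am.simulate_cohort(cfg)
        r = np.corrcoef(couples["female_height"], couples["male_height"])[0, 1]
        assert abs(r - 0.26) <= 0.02

    def test_random_pairing(self):
        cfg = am.SimConfig(n_couples=3000, n_snps=60, target_rp=0.0, seed=9)
        G, ph, couples = am.simulate_cohort(cfg)
        r = np.corrcoef(couples["female_height"], couples["male_height"])[0, 1]
        assert abs(r) < 0.05

    def test_near_comonotone_pairing(self):
        cfg = am.SimConfig(n_couples=3000, n_snps=200, target_rp=0.95, seed=10)
        G = am.simulate_genotypes(cfg)
        ph = am.simulate_heights(G, cfg)
        couples = am.form_couples(ph, cfg)
        r = np.corrcoef(couples["female_height"], couples["male_height"])[0, 1]
        assert r > 0.9

    def test_target_rp_one_rejected(self):
        with pytest.raises(ConfigError):
            am.SimConfig(target_rp=1.0).validate()

    def test_unbalanced_sexes_rejected(self):
        cfg = am.SimConfig(n_couples=50, n_snps=30, seed=11)
        G = am.simulate_genotypes(cfg)
        ph = am.simulate_heights(G, cfg)
        with pytest.raises(DataError):
            am.form_couples(ph.iloc[1:], cfg)

    def test_breeding_value_correlation_matches_theory(self):
        cfg = am.SimConfig(
            n_couples=8000, n_snps=200, h2_height=0.8, causal_fraction=1.0,
            target_rp=0.26, seed=12,
        )
        G, ph, couples = am.simulate_cohort(cfg)
        av = ph.set_index("sample_id")["additive_value"]
        corr = np.corrcoef(
            av.loc[couples["female_id"]], av.loc[couples["male_id"]]
        )[0, 1]
        rp = np.corrcoef(couples["female_height"], couples["male_height"])[0, 1]
        expected = am.expected_breeding_value_correlation(rp, 0.8)
        assert abs(corr - expected) < 3.0 / np.sqrt(cfg.n_couples)


class TestCovariates:
    def test_age_correlation(self, small_cohort):
        cfg, G, ph, couples = small_cohort
        cfg2 = am.SimConfig(n_couples=3000, n_snps=30, age_corr=0.9, seed=13)
        _, ph2, couples2 = am.simulate_cohort(cfg2)
        ages = ph2.set_index("sample_id")["age"]
        r = np.corrcoef(ages.loc[couples2["female_id"]], ages.loc[couples2["male_id"]])[0, 1]
        assert abs(r - 0.9) < 0.05

    def test_within_couple_distance_smaller_than_random(self, small_cohort):
        _, G, ph, couples = small_cohort
        p = ph.set_index("sample_id")
        fe = p.loc[couples["female_id"], ["birth_east", "birth_north"]].to_numpy()
        ma = p.loc[couples["male_id"], ["birth_east", "birth_north"]].to_numpy()
        within = np.hypot(*(fe - ma).T).mean()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(couples))
        random_pairs = np.hypot(*(fe - ma[perm]).T).mean()
        assert within < random_pairs

    def test_household_shared(self, small_cohort):
        _, G, ph, couples = small_cohort
        hh = ph.set_index("sample_id")["household_id"]
        assert (hh.loc[couples["female_id"]].to_numpy() == hh.loc[couples["male_id"]].to_numpy()).all()

    def test_determinism(self):
        cfg = am.SimConfig(n_couples=100, n_snps=80, seed=14)
        G1, ph1, c1 = am.simulate_cohort(cfg)
        G2, ph2, c2 = am.simulate_cohort(cfg)
        assert np.array_equal(G1.dosages, G2.dosages)
        pd.testing.assert_frame_equal(ph1, ph2)
        pd.testing.assert_frame_equal(c1, c2)


class TestCohortIO:
    def test_round_trip(self, small_cohort, tmp_path):
        _, G, ph, couples = small_cohort
        prefix = str(tmp_path / "cohort")
        am.write_cohort(G, ph, couples, prefix)
        with open(prefix + ".bed", "rb") as fh:
            assert fh.read(3) == bytes([0x6C, 0x1B, 0x01])
        G2, ph2, c2 = am.read_cohort(prefix)
        assert np.array_equal(G.dosages, G2.dosages)
        assert list(G.sample_ids) == list(G2.sample_ids)
        assert list(G.snp_meta["snp_id"]) == list(G2.snp_meta["snp_id"])

    def test_round_trip_with_missing(self, tmp_path):
        cfg = am.SimConfig(n_couples=40, n_snps=60, missing_rate=0.1, seed=15)
        G, ph, couples = am.simulate_cohort(cfg)
        prefix = str(tmp_path / "m")
        am.write_cohort(G, ph, couples, prefix)
        G2, _, _ = am.read_cohort(prefix)
        assert np.array_equal(G.dosages, G2.dosages)

    def test_mismatched_sample_sets(self, small_cohort, tmp_path):
        _, G, ph, couples = small_cohort
        with pytest.raises(DataError):
            am.write_cohort(G, ph.iloc[1:], couples, str(tmp_path / "x"))
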