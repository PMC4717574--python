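"""Quality-control filters and their exact tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import chi2

import assortmate as am
from assortmate.exceptions import DataError
from assortmate.simulate import GenotypeMatrix


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force conditional enumeration over heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    probs = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        logp = het * np.log(2.0) - (
            gammaln(hom_minor + 1) + gammaln(het + 1) + gammaln(hom_major + 1)
        )
        probs[het] = logp
    mx = max(probs.values())
    total = sum(np.exp(v - mx) for v in probs.values())
    norm = {k: np.exp(v - mx) / total for k, v in probs.items()}
    p_obs = norm[n_Aa]
    return min(1.0, sum(p for p in norm.values() if p <= p_obs * (1 + 1e-12)))


def make_genotypes(dosages, platforms=None):
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": 1,
            "pos": np.arange(m) + 1,
            "a1": "A",
            "a2": "G",
            "freq": np.nan,
            "platform": "both",
        }
    )
    ids = np.array([f"i{k}" for k in range(n)])
    return GenotypeMatrix(d, meta, ids, None if platforms is None else np.asarray(platforms, object))


class TestHWEExact:
    @pytest.mark.parametrize(
        "counts", [(25, 50, 25), (50, 0, 50), (10, 20, 70), (3, 5, 2), (100, 10, 1)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert am.hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-10
        )

    def test_perfect_hwe_is_not_rejected(self):
        assert am.hwe_exact_test(25, 50, 25) > 0.9

    def test_monomorphic_site(self):
        assert am.hwe_exact_test(100, 0, 0) == 1.0

    def test_het_deficit_rejected(self):
        assert am.hwe_exact_test(50, 0, 50) < 1e-20

    def test_all_zero_counts(self):
        with pytest.raises(DataError):
            am.hwe_exact_test(0, 0, 0)

    def test_chi_square_agreement_at_large_counts(self):
        # away from boundaries the exact and chi-square tests agree closely
        for counts in [(640, 340, 60), (450, 430, 120)]:
            n = sum(counts)
            p = (2 * counts[0] + counts[1]) / (2 * n)
            exp = np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2]) * n
            x2 = float((((np.array(counts) - exp) ** 2) / exp).sum())
            p_chi = float(chi2.sf(x2, df=1))
            p_exact = am.hwe_exact_test(*counts)
            assert p_exact == pytest.approx(p_chi, rel=0.1)


class TestPlatformTest:
    def test_identical_rates(self):
        assert am.platform_missingness_test(5, 95, 5, 95) == 1.0

    def test_strong_bias(self):
        assert am.platform_missingness_test(0, 100, 50, 50) < 1e-12

    def test_empty_platform(self):
        with pytest.raises(DataError):
            am.platform_missingness_test(0, 0, 5, 95)

    def test_threshold_application_excludes_extreme_bias(self):
        # SNP missing on one platform only, at a scale where p < 1e-100
        rng = np.random.default_rng(0)
        n = 800
        platforms = np.array(["P1"] * (n // 2) + ["P2"] * (n // 2))
        d = rng.binomial(2, 0.3, size=(n, 2)).astype(np.int8)
        d[platforms == "P1", 0] = -1  # total platform-1 dropout for SNP 0
        G = make_genotypes(d, platforms)
        thr = am.QCThresholds(snp_missing_max=0.9)  # let it reach the bias filter
        out, rep = am.snp_qc(G, thr)
        assert rep.excluded["platform_bias"] == 1
        assert "s0" not in list(out.snp_meta["snp_id"])


class TestSnpQC:
    def test_missingness_and_maf_filters(self):
        rng = np.random.default_rng(1)
        n = 400
        good = rng.binomial(2, 0.3, size=(n, 1))
        missing = rng.binomial(2, 0.3, size=(n, 1))
        missing[: int(0.03 * n)] = -1  # 3 % missing
        rare = np.zeros((n, 1), dtype=np.int8)
        rare[:32] = 1  # MAF = 32/800 = 0.04 exactly
        G = make_genotypes(np.hstack([good, missing, rare]))
        out, rep = am.snp_qc(G)
        assert list(out.snp_meta["snp_id"]) == ["s0"]
        assert rep.excluded["missingness"] == 1
        assert rep.excluded["maf"] >= 1
        # surviving SNP's dosages unchanged
        assert np.array_equal(out.dosages[:, 0], G.dosages[:, 0])

    def test_hwe_filter(self):
        n = 3000
        # extreme heterozygote deficit: half hom-ref, half hom-alt
        d = np.concatenate([np.zeros(n // 2), np.full(n // 2, 2)]).astype(np.int8)
        good = np.random.default_rng(2).binomial(2, 0.4, size=n).astype(np.int8)
        G = make_genotypes(np.column_stack([d, good]))
        out, rep = am.snp_qc(G)
        assert rep.excluded["hwe"] == 1
        assert list(out.snp_meta["snp_id"]) == ["s1"]

    def test_idempotent_and_conserved(self):
        cfg = am.SimConfig(n_couples=150, n_snps=120, missing_rate=0.01, seed=3)
        G = am.simulate_genotypes(cfg)
        out1, rep1 = am.snp_qc(G)
        out2, rep2 = am.snp_qc(out1)
        assert list(out1.snp_meta["snp_id"]) == list(out2.snp_meta["snp_id"])
        assert rep1.n_excluded + len(rep1.surviving_ids) == rep1.n_input


class TestSampleQC:
    def test_missingness_filter(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, size=(50, 200)).astype(np.int8)
        d[0, : int(0.06 * 200)] = -1  # 6 % missing
        G = make_genotypes(d)
        out, rep = am.sample_qc(G)
        assert "i0" not in list(out.sample_ids)
        assert rep.excluded["missingness"] == 1

    def test_heterozygosity_outlier(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.5, size=(200, 400)).astype(np.int8)
        d[0] = 1  # everything heterozygous
        G = make_genotypes(d)
        out, rep = am.sample_qc(G)
        assert "i0" not in list(out.sample_ids)
        assert rep.excluded["heterozygosity"] >= 1

    def test_clean_samples_retained(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.3, size=(80, 100)).astype(np.int8)
        G = make_genotypes(d)
        out, rep = am.sample_qc(G)
        assert rep.n_excluded <= 2  # only chance 3-SD het outliers


class TestPhenotypeFilter:
    def make_phenos(self, male_z=None):
        rng = np.random.default_rng(7)
        n = 500
        sex = np.array(["male", "female"] * (n // 2))
        height = np.where(sex == "male", 178.0, 165.0) + rng.normal(0, 7, n)
        ph = pd.DataFrame({"sample_id": [f"p{i}" for i in range(n)], "sex": sex, "height": height})
        return ph

    def test_outlier_removed(self):
        ph = self.make_phenos()
        males = ph["sex"] == "male"
        mu, sd = ph.loc[males, "height"].mean(), ph.loc[males, "height"].std()
        outlier_idx = ph.index[males][0]
        ph.loc[outlier_idx, "height"] = mu + 4.0 * sd
        out, rep = am.phenotype_outlier_filter(ph)
        assert rep.excluded["height_outlier"] >= 1
        assert ph.loc[outlier_idx, "sample_id"] not in set(out["sample_id"])

    def test_strict_inequality_at_the_boundary(self):
        # a record at exactly sd_max SD survives; just beyond it is removed
        ph = self.make_phenos()
        males = ph["sex"] == "male"
        z = (ph.loc[males, "height"] - ph.loc[males, "height"].mean()) / ph.loc[
            males, "height"
        ].std()
        z_max = float(np.abs(z).max())
        out_eq, rep_eq = am.phenotype_outlier_filter(ph, sd_max=z_max)
        out_lt, rep_lt = am.phenotype_outlier_filter(ph, sd_max=z_max * (1 - 1e-9))
        assert rep_eq.excluded["height_outlier"] == 0
        assert rep_lt.excluded["height_outlier"] >= 1

    def test_empty_input(self):
        out, rep = am.phenotype_outlier_filter(pd.DataFrame(columns=["sample_id", "sex", "height"]))
        assert len(out) == 0 and rep.n_input == 0

    def test_single_record_gender_warns(self):
        ph = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "sex": ["male", "female", "female"],
             "height": [175.0, 160.0, 166.0]}
        )
        with pytest.warns(UserWarning):
            out, _ = am.phenotype_outlier_filter(ph)
        assert "a" in set(out["sample_id"])
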