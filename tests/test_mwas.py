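import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidsig import synthetic as syn
from lipidsig.mwas import MwasDesign, associate, mwsl, residualize, summarize


def make_design(rng, n=300, m=5, beta=0.0, maf=0.3):
    idx = pd.Index([f"I{i}" for i in range(n)])
    g = pd.DataFrame({"SNP000": rng.binomial(2, maf, size=n).astype(float)},
                     index=idx)
    cov = pd.DataFrame({"age": rng.normal(50, 8, n),
                        "sex": rng.integers(0, 2, n).astype(float),
                        "cohort": np.where(rng.random(n) < 0.5, "A", "B")},
                       index=idx)
    f = rng.normal(0, 1, size=(n, m))
    f[:, 0] += beta * g["SNP000"].to_numpy()
    feats = pd.DataFrame(f, index=idx, columns=[f"M{j}" for j in range(m)])
    return MwasDesign(genotypes=g, covariates=cov, features=feats)


class TestResidualize:
    def test_zero_pcs_only_center(self, rng):
        idx = pd.Index(range(20))
        feats = pd.DataFrame(rng.normal(size=(20, 3)), index=idx)
        pcs = pd.DataFrame(np.zeros((20, 2)) + [[1e-9, -1e-9]] * 20, index=idx)
        cohort = ["A"] * 20
        with pytest.raises(ValueError):  # constant-ish PCs are rank-deficient
            residualize(feats, pcs, cohort)

    def test_linear_combination_removed(self, rng):
        idx = pd.Index(range(50))
        pcs = pd.DataFrame(rng.normal(size=(50, 3)), index=idx)
        feats = pd.DataFrame({"f": pcs @ np.array([1.0, -2.0, 0.5]) + 3.0},
                             index=idx)
        out = residualize(feats, pcs, ["A"] * 50)
        assert np.linalg.norm(out["f"]) < 1e-8 * np.linalg.norm(feats["f"])

    def test_residuals_orthogonal_to_pcs_per_cohort(self, rng):
        idx = pd.Index(range(120))
        pcs = pd.DataFrame(rng.normal(size=(120, 4)), index=idx)
        feats = pd.DataFrame(rng.normal(size=(120, 6)), index=idx)
        cohort = np.where(np.arange(120) < 60, "A", "B")
        out = residualize(feats, pcs, cohort)
        for c in ("A", "B"):
            rows = idx[cohort == c]
            corr = out.loc[rows].T @ pcs.loc[rows]
            assert np.abs(corr.to_numpy()).max() < 1e-8


class TestAssociate:
    def test_exact_linear_feature(self, rng):
        d = make_design(rng, n=200, m=1)
        d.features["M0"] = 2.0 * d.genotypes["SNP000"]
        res = associate(d)
        assert res["beta"].iloc[0] == pytest.approx(2.0, abs=1e-10)
        assert res["p"].iloc[0] < 1e-100

    def test_planted_beta_within_two_se(self, rng):
        d = make_design(rng, n=2000, m=5, beta=0.3)
        res = associate(d).set_index("feature")
        assert abs(res.loc["M0", "beta"] - 0.3) < 2 * res.loc["M0", "se"]

    def test_null_p_uniform(self):
        ps = []
        for rep in range(40):
            d = make_design(np.random.default_rng(rep), n=400, m=1)
            ps.append(associate(d)["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_confounding_corrected_by_cohort_covariate(self, rng):
        # feature depends on cohort; genotype frequency differs by cohort
        n = 2000
        idx = pd.Index(range(n))
        cohort = np.where(np.arange(n) < n // 2, "A", "B")
        maf = np.where(cohort == "A", 0.1, 0.4)
        g = pd.DataFrame({"SNP000": rng.binomial(2, maf).astype(float)}, index=idx)
        feats = pd.DataFrame({"M0": rng.normal(0, 1, n)
                              + np.where(cohort == "A", 0.0, 1.0)}, index=idx)
        cov = pd.DataFrame({"age": rng.normal(50, 5, n),
                            "sex": rng.integers(0, 2, n).astype(float),
                            "cohort": cohort}, index=idx)
        adj = associate(MwasDesign(genotypes=g, covariates=cov, features=feats))
        naive_beta = np.polyfit(g["SNP000"], feats["M0"], 1)[0]
        assert abs(adj["beta"].iloc[0]) < 2 * adj["se"].iloc[0]
        assert naive_beta > 4 * adj["se"].iloc[0]  # unadjusted is biased

    def test_collinear_covariates_rejected(self, rng):
        d = make_design(rng)
        d.covariates["age"] = d.covariates["sex"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            associate(d)


class TestMwsl:
    def test_partial_correlation_matches_full_regression(self, rng):
        # the permutation scan's p for the identity permutation must equal
        # the covariate-adjusted regression p from associate()
        d = make_design(rng, n=150, m=4)
        from lipidsig.mwas import _covariate_matrix, _residualizer
        C = _covariate_matrix(d.covariates)
        proj = _residualizer(C)
        F = proj(d.features.to_numpy())
        g = proj(d.genotypes["SNP000"].to_numpy()[:, None])[:, 0]
        Fu = F / np.linalg.norm(F, axis=0)
        gu = g / np.linalg.norm(g)
        r = Fu.T @ gu
        dof = 150 - (C.shape[1] + 1)
        t = r * np.sqrt(dof / (1 - r ** 2))
        p_fwl = 2 * stats.t.sf(np.abs(t), dof)
        p_reg = associate(d)["p"].to_numpy()
        assert np.allclose(np.sort(p_fwl), np.sort(p_reg), rtol=1e-10)

    def test_single_feature_threshold_near_fwer(self, rng):
        d = make_design(rng, n=400, m=1)
        out = mwsl(d, "SNP000", n_perm=2000, fwer=0.05, seed=0)
        assert out["mwsl"] == pytest.approx(0.05, abs=0.015)

    def test_independent_features_match_order_statistics(self, rng):
        m = 10
        d = make_design(rng, n=500, m=m)
        out = mwsl(d, "SNP000", n_perm=3000, fwer=0.05, seed=1)
        expected = 1 - (1 - 0.05) ** (1 / m)  # Sidak for independent tests
        assert out["mwsl"] == pytest.approx(expected, rel=0.35)
        assert out["effective_tests"] == pytest.approx(m, rel=0.4)

    def test_duplicated_features_collapse_to_block_count(self, rng):
        d1 = make_design(rng, n=500, m=4)
        # duplicate each feature 5x: min-p distribution unchanged
        dup = pd.concat([d1.features] * 5, axis=1)
        dup.columns = [f"M{j}" for j in range(20)]
        d2 = MwasDesign(genotypes=d1.genotypes, covariates=d1.covariates,
                        features=dup)
        t1 = mwsl(d1, "SNP000", n_perm=1500, fwer=0.05, seed=2)
        t2 = mwsl(d2, "SNP000", n_perm=1500, fwer=0.05, seed=2)
        assert t2["mwsl"] == pytest.approx(t1["mwsl"], rel=1e-9)

    def test_seeded_determinism(self, rng):
        d = make_design(rng, n=200, m=3)
        a = mwsl(d, "SNP000", n_perm=500, fwer=0.05, seed=7)
        b = mwsl(d, "SNP000", n_perm=500, fwer=0.05, seed=7)
        assert a["mwsl"] == b["mwsl"]

    def test_joint_row_permutation_invariance(self, rng):
        d = make_design(rng, n=200, m=3)
        perm = rng.permutation(200)
        d2 = MwasDesign(genotypes=d.genotypes.iloc[perm],
                        covariates=d.covariates.iloc[perm],
                        features=d.features.iloc[perm])
        r1 = associate(d).sort_values("feature").reset_index(drop=True)
        r2 = associate(d2).sort_values("feature").reset_index(drop=True)
        assert np.allclose(r1["beta"], r2["beta"])
        assert np.allclose(r1["p"], r2["p"])


class TestSummarize:
    def test_class_proportions(self):
        res = pd.DataFrame({
            "snp": ["S1"] * 10,
            "feature": [f"M{i}" for i in range(10)],
            "significant": [True] * 10,
        })
        class_map = {f"M{i}": ("lipid" if i < 7 else "amino acid")
                     for i in range(10)}
        out = summarize(res, class_map)
        assert out["class_proportions_percent"]["lipid"] == pytest.approx(70.0)
        assert out["per_snp"] == {"S1": 10}

    def test_empty_results_flagged(self):
        res = pd.DataFrame({"snp": [], "feature": [], "significant": []})
        out = summarize(res, {})
        assert out["n_significant"] == 0
        assert not out["proportions_defined"]

    def test_counts_equal_group_by_oracle(self, rng):
        snps = rng.choice(["S1", "S2", "S3"], size=50)
        sig = rng.random(50) < 0.5
        res = pd.DataFrame({"snp": snps,
                            "feature": [f"M{i}" for i in range(50)],
                            "significant": sig})
        out = summarize(res, {})
        oracle = {}
        for s, ok in zip(snps, sig):
            if ok:
                oracle[s] = oracle.get(s, 0) + 1
        assert out["per_snp"] == oracle


class TestFwerCalibrationSmall:
    def test_null_family_wise_error_near_nominal(self):
        # reduced-scale version of the headline calibration experiment
        hits = 0
        reps = 60
        for rep in range(reps):
            cfg = syn.SimConfig(seed=5000 + rep, n_individuals=250,
                                n_mwas_features=60, n_blocks=6,
                                block_rho=0.7, snp_beta=0.0)
            design, _ = syn.gen_mwas_cohort(cfg)
            res = associate(design)
            th = mwsl(design, "SNP000", n_perm=400, fwer=0.05, seed=rep)
            hits += bool((res["p"] < th["mwsl"]).any())
        # binomial 99% bound around 0.05 at 60 reps
        assert stats.binomtest(hits, reps, 0.05).pvalue > 0.01
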