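"""Two-sample MR: harmonization, LD pruning, estimators, diagnostics,
orchestration rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chipewas import simulate_mqtl_system, simulate_outcome_gwas
from chipewas.datamodel import PipelineConfig
from chipewas.mr import (
    LdSource,
    egger_regression,
    harmonize,
    iv_heterogeneity,
    ivw_mr,
    run_mr,
    select_ivs,
    wald_ratio,
)


def _mqtl(rows):
    return pd.DataFrame(rows, columns=["snp_id", "probe_id", "beta_x", "se_x",
                                       "p_x", "effect_allele", "chromosome",
                                       "position"])


def _outcome(rows):
    return pd.DataFrame(rows, columns=["snp_id", "outcome", "beta_y", "se_y",
                                       "p_y", "effect_allele"])


class TestHarmonize:
    def test_same_alleles_identity(self):
        m = _mqtl([("rs1", "cg1", 0.2, 0.02, 1e-20, "A", "chr1", 100)])
        o = _outcome([("rs1", "BMI", 0.1, 0.01, 1e-5, "A")])
        aligned, dropped = harmonize(m, o)
        assert dropped == 0 and aligned["beta_y"].iloc[0] == 0.1

    def test_swapped_alleles_flip_sign(self):
        m = _mqtl([("rs1", "cg1", 0.2, 0.02, 1e-20, "A", "chr1", 100)])
        o = _outcome([("rs1", "BMI", 0.1, 0.01, 1e-5, "G")])
        aligned, dropped = harmonize(m, o)
        assert dropped == 0 and aligned["beta_y"].iloc[0] == -0.1

    def test_unresolvable_allele_dropped(self):
        m = _mqtl([("rs1", "cg1", 0.2, 0.02, 1e-20, "A", "chr1", 100)])
        m["other_allele"] = "G"
        o = _outcome([("rs1", "BMI", 0.1, 0.01, 1e-5, "T")])
        aligned, dropped = harmonize(m, o)
        assert dropped == 1 and aligned.empty


class TestSelectIvs:
    @staticmethod
    def _geno_pair(r_target, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.binomial(2, 0.3, n).astype(float)
        noise = rng.binomial(2, 0.3, n).astype(float)
        b = np.where(rng.random(n) < r_target, a, noise)
        return pd.DataFrame({"rs1": a, "rs2": b})

    def test_perfectly_correlated_keeps_lower_p(self):
        geno = pd.DataFrame({"rs1": [0.0, 1, 2, 0, 1], "rs2": [0.0, 1, 2, 0, 1]})
        m = _mqtl([
            ("rs1", "cg1", 0.2, 0.02, 1e-20, "A", "chr1", 100),
            ("rs2", "cg1", 0.2, 0.02, 1e-15, "A", "chr1", 200),
        ])
        kept = select_ivs(m, LdSource(geno))
        assert list(kept["snp_id"]) == ["rs1"]

    def test_uncorrelated_keeps_all(self):
        rng = np.random.default_rng(5)
        geno = pd.DataFrame(rng.binomial(2, 0.4, (5000, 3)).astype(float),
                            columns=["rs1", "rs2", "rs3"])
        # verify near-zero LD for this draw, then prune
        ld = LdSource(geno)
        m = _mqtl([
            (f"rs{i}", "cg1", 0.2, 0.02, 1e-20, "A", "chr1", 100 * i)
            for i in (1, 2, 3)
        ])
        if all(ld.r2(a, b) < 0.01 for a, b in [("rs1", "rs2"), ("rs1", "rs3"), ("rs2", "rs3")]):
            assert len(select_ivs(m, ld)) == 3

    def test_greedy_invariant_on_toy_system(self):
        # 6 SNPs, blocks {rs1,rs2}, {rs3,rs4}, {rs5}, {rs6}
        rng = np.random.default_rng(9)
        n = 3000
        base1 = rng.binomial(2, 0.3, n).astype(float)
        base2 = rng.binomial(2, 0.4, n).astype(float)
        geno = pd.DataFrame({
            "rs1": base1, "rs2": base1,
            "rs3": base2, "rs4": base2,
            "rs5": rng.binomial(2, 0.3, n).astype(float),
            "rs6": rng.binomial(2, 0.5, n).astype(float),
        })
        ld = LdSource(geno)
        ps = {"rs1": 1e-30, "rs2": 1e-20, "rs3": 1e-15, "rs4": 1e-25,
              "rs5": 1e-12, "rs6": 1e-18}
        m = _mqtl([
            (s, "cg1", 0.2, 0.02, p, "A", "chr1", i * 100)
            for i, (s, p) in enumerate(ps.items())
        ])
        kept = select_ivs(m, ld)
        kept_ids = list(kept["snp_id"])
        # no retained pair violates the r2 threshold
        for i, a in enumerate(kept_ids):
            for b in kept_ids[i + 1:]:
                assert ld.r2(a, b) < 0.01
        # every dropped SNP conflicts with a retained, better-p SNP
        for s in set(ps) - set(kept_ids):
            assert any(
                ld.r2(s, k) >= 0.01 and ps[k] < ps[s] for k in kept_ids
            )

    def test_snp_absent_from_ld_source_dropped(self):
        geno = pd.DataFrame({"rs1": [0.0, 1, 2, 1]})
        m = _mqtl([
            ("rs1", "cg1", 0.2, 0.02, 1e-20, "A", "chr1", 100),
            ("rsX", "cg1", 0.2, 0.02, 1e-25, "A", "chr1", 200),
        ])
        kept = select_ivs(m, LdSource(geno))
        assert list(kept["snp_id"]) == ["rs1"]

    def test_r2_table_dialect(self):
        table = pd.DataFrame(
            [("rs1", "rs2", 0.95), ("rs1", "rs3", 0.001), ("rs2", "rs3", 0.002)],
            columns=["snp_a", "snp_b", "r2"],
        )
        m = _mqtl([
            ("rs1", "cg1", 0.2, 0.02, 1e-30, "A", "chr1", 100),
            ("rs2", "cg1", 0.2, 0.02, 1e-20, "A", "chr1", 200),
            ("rs3", "cg1", 0.2, 0.02, 1e-25, "A", "chr1", 300),
        ])
        kept = select_ivs(m, LdSource(table, kind="r2_table"))
        assert set(kept["snp_id"]) == {"rs1", "rs3"}


class TestWaldRatio:
    def test_unit_exposure(self):
        beta, se, _ = wald_ratio(1.0, 0.01, 0.5, 0.02)
        assert beta == 0.5 and se == 0.02

    def test_antisymmetry_in_exposure_sign(self):
        b1, *_ = wald_ratio(0.2, 0.01, 0.1, 0.02)
        b2, *_ = wald_ratio(-0.2, 0.01, 0.1, 0.02)
        assert b1 == -b2

    def test_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIvwMr:
    @staticmethod
    def _aligned(bx, by, sy):
        return pd.DataFrame({"beta_x": bx, "beta_y": by, "se_y": sy,
                             "se_x": 0.01})

    def test_identical_ivs_collapse_to_wald(self):
        k = 4
        a = self._aligned([0.2] * k, [0.1] * k, [0.02] * k)
        beta, se, _ = ivw_mr(a)
        wb, wse, _ = wald_ratio(0.2, 0.01, 0.1, 0.02)
        assert beta == pytest.approx(wb, abs=1e-12)
        assert se == pytest.approx(wse / np.sqrt(k), abs=1e-12)

    def test_weighted_mean_of_wald_ratios(self):
        a = self._aligned([0.2, 0.4], [0.1, 0.1], [0.02, 0.05])
        beta, se, _ = ivw_mr(a)
        w = [0.2**2 / 0.02**2, 0.4**2 / 0.05**2]
        ratios = [0.1 / 0.2, 0.1 / 0.4]
        beta_o = sum(wi * ri for wi, ri in zip(w, ratios)) / sum(w)
        assert beta == pytest.approx(beta_o, abs=1e-12)
        assert se == pytest.approx(1 / np.sqrt(sum(w)), abs=1e-12)

    def test_allele_coding_invariance(self, rng):
        bx = rng.normal(0.2, 0.05, 5)
        by = rng.normal(0.1, 0.02, 5)
        sy = rng.uniform(0.01, 0.03, 5)
        b1, s1, _ = ivw_mr(self._aligned(bx, by, sy))
        flip = np.array([1, -1, 1, -1, 1.0])
        b2, s2, _ = ivw_mr(self._aligned(bx * flip, by * flip, sy))
        assert b1 == pytest.approx(b2, abs=1e-12)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_recovery_and_coverage(self):
        theta = 0.3
        _, mqtl, _ = simulate_mqtl_system(n_cpgs=1, ivs_per_cpg=5, rng_seed=30)
        estimates, covered = [], 0
        reps = 500
        for rep in range(reps):
            out, _ = simulate_outcome_gwas(mqtl, mr_theta=theta, se_y=0.02,
                                           rng_seed=31 + rep)
            aligned = mqtl.merge(out, on="snp_id")
            b, s, _ = ivw_mr(aligned)
            estimates.append(b)
            covered += abs(b - theta) < 1.959963984540054 * s
        mc_se = np.std(estimates, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(estimates) - theta) < 3 * mc_se
        assert 0.92 <= covered / reps <= 0.98


class TestEggerAndHeterogeneity:
    def test_line_through_origin_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        a = pd.DataFrame({"beta_x": bx, "beta_y": 0.5 * bx,
                          "se_y": [0.02, 0.03, 0.02, 0.04]})
        intercept, slope, _ = egger_regression(a)
        assert intercept == pytest.approx(0.0, abs=1e-10)
        assert slope == pytest.approx(0.5, abs=1e-10)

    def test_matches_wls_normal_equations(self, rng):
        for _ in range(100):
            k = rng.integers(3, 8)
            bx = rng.uniform(0.05, 0.4, k)
            by = rng.normal(0.1, 0.05, k)
            sy = rng.uniform(0.01, 0.05, k)
            a = pd.DataFrame({"beta_x": bx, "beta_y": by, "se_y": sy})
            intercept, slope, p_int = egger_regression(a)
            W = np.diag(1 / sy**2)
            X = np.column_stack([np.ones(k), bx])
            coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
            assert intercept == pytest.approx(coef[0], abs=1e-10)
            assert slope == pytest.approx(coef[1], abs=1e-10)
            resid = by - X @ coef
            sigma2 = resid @ W @ resid / (k - 2)
            se_int = np.sqrt(sigma2 * np.linalg.inv(X.T @ W @ X)[0, 0])
            p_o = 2 * stats.t.sf(abs(coef[0] / se_int), k - 2)
            assert p_int == pytest.approx(p_o, abs=1e-10)

    def test_identical_ratios_q_zero(self):
        a = pd.DataFrame({"beta_x": [0.2, 0.4], "beta_y": [0.1, 0.2],
                          "se_y": [0.02, 0.02]})
        q, p = iv_heterogeneity(a, 0.5)
        assert q == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_q_term_by_term(self):
        a = pd.DataFrame({"beta_x": [0.2, 0.5], "beta_y": [0.08, 0.30],
                          "se_y": [0.02, 0.03]})
        ratios = np.array([0.4, 0.6])
        w = np.array([0.2**2 / 0.02**2, 0.5**2 / 0.03**2])
        beta_mr = 0.52
        q, _ = iv_heterogeneity(a, beta_mr)
        assert q == pytest.approx(np.sum(w * (ratios - beta_mr) ** 2), abs=1e-12)

    def test_het_p_uniform_under_no_pleiotropy(self):
        _, mqtl, _ = simulate_mqtl_system(n_cpgs=1, ivs_per_cpg=5, rng_seed=40)
        pvals = []
        for rep in range(500):
            out, _ = simulate_outcome_gwas(mqtl, mr_theta=0.3, se_y=0.02,
                                           rng_seed=41 + rep)
            aligned = mqtl.merge(out, on="snp_id")
            beta_mr, *_ = ivw_mr(aligned)
            pvals.append(iv_heterogeneity(aligned, beta_mr)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRunMr:
    @staticmethod
    def _system(theta, n_cpgs=6, seed=50, se_y=0.02, ivs_per_cpg=5):
        geno, mqtl, _ = simulate_mqtl_system(
            n_cpgs=n_cpgs, ivs_per_cpg=ivs_per_cpg, rng_seed=seed
        )
        out, truth = simulate_outcome_gwas(mqtl, mr_theta=theta, se_y=se_y,
                                           rng_seed=seed + 1)
        return geno, mqtl, out, truth

    def test_single_iv_uses_wald(self):
        geno, mqtl, out, _ = self._system(0.4, n_cpgs=2, ivs_per_cpg=1)
        res = run_mr(sorted(mqtl["probe_id"].unique()), mqtl, LdSource(geno),
                     {"trait": out})
        assert (res["method"] == "wald").all()
        assert (res["n_iv"] == 1).all()

    def test_planted_effects_significant(self):
        geno, mqtl, out, _ = self._system(0.5, n_cpgs=8)
        res = run_mr(sorted(mqtl["probe_id"].unique()), mqtl, LdSource(geno),
                     {"trait": out})
        retained = res[~res["excluded"]]
        assert (retained["significant"].mean()) >= 0.8

    def test_null_yields_no_significant(self):
        geno, mqtl, out, _ = self._system(0.0, n_cpgs=8, seed=60)
        res = run_mr(sorted(mqtl["probe_id"].unique()), mqtl, LdSource(geno),
                     {"trait": out})
        retained = res[~res["excluded"]]
        assert retained["significant"].sum() == 0

    def test_no_instruments_reason(self):
        geno, mqtl, out, _ = self._system(0.3, n_cpgs=2)
        weak = mqtl.copy()
        weak.loc[weak["probe_id"] == "cg000000", "p_x"] = 0.5
        res = run_mr(["cg000000"], weak, LdSource(geno), {"trait": out})
        assert res["excluded"].iloc[0]
        assert res["exclusion_reason"].iloc[0] == "no instruments"

    def test_exclusion_monotone_in_threshold(self):
        geno, mqtl, out, _ = self._system(0.3, n_cpgs=8, seed=70, se_y=0.05)
        cpgs = sorted(mqtl["probe_id"].unique())
        strict = run_mr(cpgs, mqtl, LdSource(geno), {"trait": out},
                        PipelineConfig(iv_exclusion_p=0.05))
        lax = run_mr(cpgs, mqtl, LdSource(geno), {"trait": out},
                     PipelineConfig(iv_exclusion_p=0.01))
        assert lax["excluded"].sum() <= strict["excluded"].sum()

    def test_fdr_significant_subset_of_nominal(self):
        geno, mqtl, out, _ = self._system(0.2, n_cpgs=8, seed=80, se_y=0.05)
        res = run_mr(sorted(mqtl["probe_id"].unique()), mqtl, LdSource(geno),
                     {"trait": out})
        sig = res[res["significant"].fillna(False)]
        assert (sig["p_mr"] < 0.05).all()

    def test_directional_pleiotropy_triggers_egger_exclusion(self):
        geno, mqtl, _ = simulate_mqtl_system(n_cpgs=1, ivs_per_cpg=6, rng_seed=90)
        mqtl = mqtl.assign(beta_x=mqtl["beta_x"].abs())
        # pleiotropy proportional-to-nothing: constant alpha, tiny noise
        out, _ = simulate_outcome_gwas(mqtl, mr_theta=0.3,
                                       pleiotropy_alpha=0.2, se_y=0.001,
                                       rng_seed=91)
        res = run_mr(["cg000000"], mqtl, LdSource(geno), {"trait": out})
        r = res.iloc[0]
        assert r["excluded"]
        assert "Egger" in r["exclusion_reason"] or "heterogeneity" in r["exclusion_reason"]
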