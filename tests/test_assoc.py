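"""Association scans: Wald logistic fits against independent oracles,
inflation factor, eligibility rules, collapse consistency."""

import numpy as np
import pytest
from scipy.stats import chi2

from cgwas.assoc import (
    inflation_factor,
    logistic_additive,
    run_cgwas,
    run_scan,
)
from cgwas.dec import ClusterAssignment
from cgwas.simulate import SimConfig, simulate_cohort, simulate_genotypes


def cochran_armitage_p(dosage, status):
    """Score (trend) test on hard-call dosages; independent of the Wald path."""
    d = np.asarray(dosage, float)
    y = np.asarray(status, float)
    n, r = len(y), y.sum()
    num = (d * y).sum() - r * d.sum() / n
    var = r * (n - r) / n**2 * ((d**2).sum() - d.sum() ** 2 / n) * n / (n - 1)
    return float(chi2.sf(num**2 / var, df=1))


class TestLogisticAdditive:
    def test_mirrored_samples_give_zero_beta(self):
        d = np.array([0, 0, 1, 1, 2, 2, 0, 1], float)
        y = np.array([1, 0, 1, 0, 1, 0, 0, 1], float)
        # identical dosage distribution in cases and controls
        d2 = np.concatenate([d[y == 1], d[y == 1]])
        y2 = np.r_[np.ones(4), np.zeros(4)]
        rec = logistic_additive(d2, y2)
        assert abs(rec.beta) < 1e-8
        assert rec.or_ == pytest.approx(1.0)

    def test_complete_separation_flagged(self):
        d = np.r_[np.full(30, 2.0), np.full(30, 0.0)]
        y = np.r_[np.ones(30), np.zeros(30)]
        rec = logistic_additive(d, y)
        assert not rec.converged

    def test_beta_matches_direct_likelihood_maximization(self, rng):
        d = np.concatenate(
            [rng.binomial(2, 0.3, 200), rng.binomial(2, 0.1, 200)]
        ).astype(float)
        y = np.r_[np.ones(200), np.zeros(200)]
        rec = logistic_additive(d, y)

        def nll(params):
            b0, b1 = params
            eta = b0 + b1 * d
            return -(y * eta - np.log1p(np.exp(eta))).sum()

        from scipy.optimize import minimize

        opt = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert rec.beta == pytest.approx(opt.x[1], abs=1e-4)

    def test_wald_close_to_trend_test(self, rng):
        """Wald and score (trend) tests are asymptotically equivalent under
        local alternatives; compare them where that approximation applies
        (moderate significance), not in the extreme tail where the two
        statistics provably diverge at any sample size."""
        checked = 0
        for _ in range(40):
            f = rng.uniform(0.05, 0.5)
            delta = rng.uniform(0.0, 0.05)
            d = np.concatenate(
                [rng.binomial(2, min(f + delta, 0.5), 300), rng.binomial(2, f, 300)]
            ).astype(float)
            y = np.r_[np.ones(300), np.zeros(300)]
            if d.std() == 0:
                continue
            rec = logistic_additive(d, y)
            ca = cochran_armitage_p(d, y)
            if ca < 0.01:
                continue
            assert rec.p == pytest.approx(ca, rel=0.15)
            checked += 1
        assert checked >= 20

    def test_matches_statsmodels_logit(self, small_cohort):
        """Batched Newton fits agree with an established GLM implementation
        on both beta and its standard error."""
        import statsmodels.api as sm

        _cfg, gm, _pheno, truth = small_cohort
        res = run_scan(gm, truth.case_ids, truth.control_ids)
        rows = gm.sample_rows(truth.case_ids + truth.control_ids)
        y = np.r_[np.ones(len(truth.case_ids)), np.zeros(len(truth.control_ids))]
        rec = res.records.set_index("id")
        for vid in rec.index[:20]:
            j = gm.variants.index[gm.variants["id"] == vid][0]
            d = gm.dosages[rows, j].astype(float)
            fit = sm.Logit(y, sm.add_constant(d)).fit(disp=0)
            assert rec.loc[vid, "beta"] == pytest.approx(fit.params[1], abs=1e-6)
            assert rec.loc[vid, "se"] == pytest.approx(fit.bse[1], rel=1e-5)

    def test_single_status_rejected(self):
        with pytest.raises(ValueError):
            logistic_additive([0, 1, 2], [1, 1, 1])

    def test_parameter_recovery_within_3_se(self):
        cfg = SimConfig(n_cases=600, n_controls=600, n_subgroups=1, n_variants=20,
                        causal_spec=[(4, 0, 2.0)], seed=17)
        gm, _p, truth = simulate_cohort(cfg)
        y = np.r_[np.ones(600), np.zeros(600)]
        rec = logistic_additive(gm.dosages[:, 4].astype(float), y)
        assert abs(rec.beta - np.log(2.0)) < 3 * rec.se


class TestInflationFactor:
    def test_reference_quantile(self):
        assert inflation_factor([0.5] * 7) == pytest.approx(1.0)

    def test_all_ones_give_zero(self):
        assert inflation_factor([1.0, 1.0]) == 0.0

    def test_null_calibration(self, rng):
        p = rng.uniform(size=10000)
        assert inflation_factor(p) == pytest.approx(1.0, abs=0.05)

    def test_permutation_invariant(self, rng):
        p = rng.uniform(size=500)
        assert inflation_factor(p) == inflation_factor(p[::-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            inflation_factor([])


class TestRunScan:
    def test_planted_pooled_effect_attains_minimum_p(self):
        cfg = SimConfig(n_cases=1000, n_controls=1000, n_subgroups=1, n_variants=100,
                        maf_range=(0.2, 0.2), causal_spec=[(7, 0, 2.0)], seed=23)
        gm, _p, truth = simulate_cohort(cfg)
        res = run_scan(gm, truth.case_ids, truth.control_ids)
        best = res.records.loc[res.records["p"].idxmin()]
        assert best["id"] == "var000007"

    def test_monomorphic_in_scan_skipped(self):
        gm = simulate_genotypes(40, 30, (0.2, 0.4), seed=6)
        dos = gm.dosages.copy()
        dos[:, 3] = 0.0
        from cgwas.genotypes import GenotypeMatrix

        gm2 = GenotypeMatrix(gm.sample_ids, gm.variants, dos)
        res = run_scan(gm2, gm.sample_ids[:20], gm.sample_ids[20:])
        assert "var000003" not in set(res.records["id"])
        assert res.n_skipped_monomorphic >= 1

    def test_unknown_ids_error(self, small_cohort):
        _cfg, gm, _pheno, truth = small_cohort
        with pytest.raises(KeyError):
            run_scan(gm, ["nobody"], truth.control_ids)

    def test_null_scan_type_one_error(self):
        cfg = SimConfig(n_cases=500, n_controls=500, n_subgroups=1, n_variants=20000,
                        causal_spec=[], seed=29)
        gm, _p, truth = simulate_cohort(cfg)
        res = run_scan(gm, truth.case_ids, truth.control_ids)
        from scipy.stats import binom

        hits = int((res.records["p"] < 1e-4).sum())
        lo, hi = binom.ppf([0.025, 0.975], len(res.records), 1e-4)
        assert lo <= hits <= hi


class TestRunCgwas:
    @staticmethod
    def _assignment(case_ids, sizes):
        labels = np.concatenate([[i] * s for i, s in enumerate(sizes)]).astype(int)
        Q = np.eye(len(sizes))[labels]
        return ClusterAssignment(Q, labels, list(case_ids[: sum(sizes)]))

    def test_more_than_nine_cases_rule(self, small_cohort):
        _cfg, gm, _pheno, truth = small_cohort
        asg = self._assignment(truth.case_ids, [9, 10, 181])
        res = run_cgwas(gm, asg, truth.control_ids, min_cases=10)
        assert {s.label for s in res.scans} == {"cluster1", "cluster2"}
        assert res.skipped_clusters == {"0": 9}

    def test_collapse_to_pooled_when_k_is_one(self, small_cohort):
        _cfg, gm, _pheno, truth = small_cohort
        asg = self._assignment(truth.case_ids, [len(truth.case_ids)])
        res = run_cgwas(gm, asg, truth.control_ids, min_cases=1)
        pooled = run_scan(gm, truth.case_ids, truth.control_ids)
        assert len(res.scans) == 1
        rc, rp = res.scans[0].records, pooled.records
        np.testing.assert_array_equal(rc["id"], rp["id"])
        np.testing.assert_allclose(rc["beta"], rp["beta"], rtol=0, atol=0)
        assert res.scans[0].lambda_ == pooled.lambda_

    def test_mean_lambda_is_arithmetic_mean(self, small_cohort):
        _cfg, gm, _pheno, truth = small_cohort
        asg = self._assignment(truth.case_ids, [50, 50, 100])
        res = run_cgwas(gm, asg, truth.control_ids)
        lams = [s.lambda_ for s in res.scans]
        assert res.mean_lambda == pytest.approx(np.mean(lams))

    def test_subgroup_specific_variant_found_per_cluster_not_pooled(self):
        cfg = SimConfig(
            n_cases=2000, n_controls=875, n_subgroups=2, subgroup_weights=(0.03, 0.97),
            n_variants=200, causal_spec=[(0, 0, 8.0)], seed=31,
        )
        gm, _p, truth = simulate_cohort(cfg)
        sub_ids = [truth.case_ids[i] for i in np.flatnonzero(truth.subgroup_labels == 0)]
        rest = [truth.case_ids[i] for i in np.flatnonzero(truth.subgroup_labels == 1)]
        labels = np.r_[np.zeros(len(sub_ids), int), np.ones(len(rest), int)]
        Q = np.eye(2)[labels]
        asg = ClusterAssignment(Q, labels, sub_ids + rest)
        res = run_cgwas(gm, asg, truth.control_ids)
        pooled = run_scan(gm, truth.case_ids, truth.control_ids)
        p_cluster = res.scans[0].records.set_index("id").loc["var000000", "p"]
        p_pooled = pooled.records.set_index("id").loc["var000000", "p"]
        assert p_cluster < 5e-8
        assert p_pooled > p_cluster

    def test_zero_eligible_clusters_warns_empty(self, small_cohort):
        _cfg, gm, _pheno, truth = small_cohort
        asg = self._assignment(truth.case_ids, [3, 4])
        with pytest.warns(UserWarning, match="minimum case count"):
            res = run_cgwas(gm, asg, truth.control_ids, min_cases=10)
        assert res.scans == []
        assert len(res.significant) == 0
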