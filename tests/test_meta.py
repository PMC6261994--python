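import numpy as np
import pytest
from scipy import stats as sps

from crosspop import meta
from crosspop import simulate as sim
from crosspop import gencorr
from crosspop.io import PopulationStats


class TestQcFilter:
    @pytest.mark.parametrize(
        "record,reason",
        [
            ({"SNP": "a", "POS": 1, "INFO": 0.49}, "imputation"),
            ({"SNP": "a", "POS": 1, "EAF": 0.995}, "maf"),
            ({"SNP": "a", "POS": 1, "CALL_RATE": 0.90}, "call_rate"),
        ],
    )
    def test_failing_records_removed_with_reason(self, stats_factory, record, reason):
        filtered, report = meta.qc_filter(stats_factory([record]))
        assert len(filtered) == 0
        assert report.dropped == {reason: 1}

    def test_boundary_values_retained(self, stats_factory):
        stats = stats_factory(
            [{"SNP": "a", "POS": 1, "CALL_RATE": 0.95, "INFO": 0.5, "EAF": 0.01}]
        )
        filtered, report = meta.qc_filter(stats)
        assert len(filtered) == 1
        assert report.n_dropped == 0


class TestLambdaGc:
    def test_definitional_cases(self):
        z_unit = np.full(200, np.sqrt(0.45494))
        assert meta.compute_lambda_gc(z_unit) == pytest.approx(1.0)
        z_double = np.full(200, np.sqrt(0.90988))
        assert meta.compute_lambda_gc(z_double) == pytest.approx(2.0)

    def test_null_simulation(self):
        z = np.random.default_rng(0).standard_normal(100_000)
        assert meta.compute_lambda_gc(z) == pytest.approx(1.0, abs=0.02)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            meta.compute_lambda_gc(np.ones(50))


class TestLdscIntercept:
    @staticmethod
    def _null_chi2(rng, ell, n, m, h2=0.0, confound=0.0):
        # chi2 with mean 1 + n h2 ell / m + confound
        ncp = n * h2 * ell / m
        return sps.ncx2.rvs(1, ncp, random_state=rng) + confound

    def test_null_intercept_near_one(self):
        rng = np.random.default_rng(1)
        ell = rng.uniform(1, 50, 5_000)
        chi2 = self._null_chi2(rng, ell, 50_000, 5_000)
        intercept, _ = meta.estimate_ldsc_intercept(chi2, ell, 50_000)
        assert intercept == pytest.approx(1.0, abs=0.05)

    def test_confounding_shifts_intercept(self):
        rng = np.random.default_rng(2)
        ell = rng.uniform(1, 50, 5_000)
        chi2 = self._null_chi2(rng, ell, 50_000, 5_000, confound=0.2)
        intercept, _ = meta.estimate_ldsc_intercept(chi2, ell, 50_000)
        assert intercept == pytest.approx(1.2, abs=0.05)

    def test_polygenicity_separated_from_confounding(self):
        # h2 > 0 inflates lambda_gc but not the intercept; averaged over
        # replicates to damp the sampling noise of a single draw
        rng = np.random.default_rng(3)
        intercepts, lams = [], []
        for _ in range(5):
            ell = rng.uniform(1, 50, 20_000)
            chi2 = self._null_chi2(rng, ell, 50_000, 20_000, h2=0.1)
            intercept, _ = meta.estimate_ldsc_intercept(chi2, ell, 50_000)
            intercepts.append(intercept)
            lams.append(np.median(chi2) / meta.CHI2_1_MEDIAN)
        assert min(lams) > 1.05
        assert np.mean(intercepts) == pytest.approx(1.0, abs=0.05)

    def test_too_few_snps_refused(self):
        with pytest.raises(ValueError):
            meta.estimate_ldsc_intercept(np.ones(100), np.ones(100), 1000)


class TestCorrectionFactor:
    def _study(self, stats_factory, n, lam, intercept):
        stats = stats_factory([{"SNP": "a", "POS": 1, "N": n}])
        return meta.StudyResult("s", stats, lambda_gc=lam, ldsc_intercept=intercept)

    def test_large_study_uses_intercept(self, stats_factory):
        study = self._study(stats_factory, 130_000, 1.24, 1.06)
        factor, label, inflated = meta.choose_correction_factor(study)
        assert (factor, label) == (1.06, "ldsc_intercept")
        assert not inflated

    def test_small_study_uses_lambda(self, stats_factory):
        study = self._study(stats_factory, 2_500, 1.05, 1.20)
        factor, label, _ = meta.choose_correction_factor(study)
        assert (factor, label) == (1.05, "lambda_gc")

    def test_deflating_factor_floored_at_one(self, stats_factory):
        study = self._study(stats_factory, 130_000, 1.0, 0.94)
        factor, _, _ = meta.choose_correction_factor(study)
        assert factor == 1.0

    def test_corrected_null_study_has_unit_lambda(self, stats_factory):
        rng = np.random.default_rng(4)
        inflation = 1.3
        z = rng.standard_normal(10_000) * np.sqrt(inflation)
        rows = [
            {"SNP": f"s{i}", "POS": i + 1, "BETA": zi * 0.01, "SE": 0.01}
            for i, zi in enumerate(z)
        ]
        stats = stats_factory(rows)
        lam = meta.compute_lambda_gc(z)
        corrected = meta.apply_correction(stats, lam)
        z_corr = corrected.table["BETA"] / corrected.table["SE"]
        assert meta.compute_lambda_gc(z_corr) == pytest.approx(1.0, abs=0.03)


class TestIvwAndCochran:
    def test_ivw_closed_forms(self):
        beta, se, _ = meta.ivw_meta([1.0, 3.0], [1.0, 1.0])
        assert (beta, se) == (pytest.approx(2.0), pytest.approx(np.sqrt(0.5)))
        beta, se, _ = meta.ivw_meta([0.5, 0.5], [0.1, 0.2])
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(1 / np.sqrt(125))

    def test_single_study_identity(self):
        beta, se, _ = meta.ivw_meta([0.7], [0.2])
        assert (beta, se) == (pytest.approx(0.7), pytest.approx(0.2))

    def test_all_infinite_se_rejected(self):
        with pytest.raises(ValueError):
            meta.ivw_meta([1.0], [np.inf])

    def test_cochran_closed_forms(self):
        q, df, p = meta.cochran_q([1.0, -1.0], [1.0, 1.0])
        assert q == pytest.approx(2.0)
        assert p == pytest.approx(0.15730, abs=1e-4)
        q, df, p = meta.cochran_q([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert (q, df, p) == (pytest.approx(0.0, abs=1e-12), 2, pytest.approx(1.0))

    def test_cochran_needs_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            meta.cochran_q([1.0], [1.0])

    def test_cochran_type_i_error_calibrated(self):
        rng = np.random.default_rng(5)
        n_rep = 10_000
        b1 = rng.standard_normal(n_rep)
        b2 = rng.standard_normal(n_rep)
        # vectorized two-study Q with unit SEs
        q = (b1 - b2) ** 2 / 2.0
        rate = np.mean(q > sps.chi2.isf(0.05, 1))
        ci = 2.576 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < ci


class TestPipelines:
    def test_meta_analyze_handles_missing_snps(self, stats_factory):
        s1 = stats_factory(
            [{"SNP": "a", "POS": 1, "BETA": 0.2, "SE": 0.1},
             {"SNP": "b", "POS": 2, "BETA": 0.1, "SE": 0.1}]
        )
        s2 = stats_factory([{"SNP": "a", "POS": 1, "BETA": 0.4, "SE": 0.1}])
        result = meta.meta_analyze([s1, s2])
        a = result.table.set_index("SNP").loc["a"]
        b = result.table.set_index("SNP").loc["b"]
        assert a["K"] == 2 and b["K"] == 1
        assert a["BETA"] == pytest.approx(0.3)

    def test_reporting_filter_rules(self, stats_factory):
        import pandas as pd

        table = pd.DataFrame(
            {
                "SNP": ["a", "b", "c"],
                "CHR": "1",
                "POS": [1, 2, 3],
                "BETA": 0.1,
                "SE": 0.1,
                "P": 0.5,
                "Q_HET": 1.0,
                "P_HET": [1e-7, 0.5, 0.5],
                "N_EFF": [1000, 490, 1000],
                "K": 2,
            }
        )
        result = meta.MetaResult("SBP", table, n_total=1000)
        kept = meta.reporting_filter(result)
        assert list(kept.table["SNP"]) == ["c"]

    def test_followup_selection_union(self, stats_factory):
        import pandas as pd

        def mk(snp_ps):
            table = pd.DataFrame(
                {
                    "SNP": list(snp_ps),
                    "CHR": "1",
                    "POS": range(1, len(snp_ps) + 1),
                    "BETA": 0.1,
                    "SE": 0.1,
                    "P": list(snp_ps.values()),
                    "Q_HET": 0.0,
                    "P_HET": 1.0,
                    "N_EFF": 1000,
                    "K": 1,
                }
            )
            return meta.MetaResult("t", table)

        per_trait = {
            "SBP": mk({"a": 1e-6, "b": 2e-5}),
            "DBP": mk({"a": 0.5, "b": 2e-5, "c": 1e-7}),
        }
        assert meta.select_followup(per_trait) == {"a", "c"}

    @pytest.mark.parametrize(
        "args,expected_validated,expected_fail",
        [
            ((3e-9, 0.01, 1e-3, True, 19), True, []),
            ((3e-9, 0.01, 0.01, True, 19), False, ["iii_lookup_support"]),
            ((3e-9, 0.01, 1e-3, False, 19), False, ["iv_direction_concordance"]),
            ((1e-7, 0.01, 1e-3, True, 19), False, ["i_combined_significance"]),
        ],
    )
    def test_validation_criteria(self, args, expected_validated, expected_fail):
        result = meta.validate_signal(*args)
        assert result.validated is expected_validated
        assert result.failed == expected_fail

    def test_missing_component_not_evaluable(self):
        with pytest.raises(ValueError, match="p_stage2"):
            meta.validate_signal(1e-9, np.nan, 0.001, True, 19)


def test_bonferroni_threshold():
    assert meta.bonferroni_threshold(19) == pytest.approx(0.05 / 19)
    with pytest.raises(ValueError):
        meta.bonferroni_threshold(0)
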