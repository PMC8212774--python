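import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fosfopk as fp
from fosfopk.covariates import (
    MEDIAN_CSF_PROTEIN,
    PopulationParameters,
    typical_parameter_arrays,
)


class TestAllometricFactor:
    @pytest.mark.parametrize(
        "weight,exponent,expected",
        [
            (70.0, 0.75, 1.0),
            (2.805, 0.75, (2.805 / 70.0) ** 0.75),
            (2.805, 1.0, 2.805 / 70.0),
        ],
    )
    def test_examples(self, weight, exponent, expected):
        assert fp.allometric_factor(weight, exponent) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            fp.allometric_factor(0.0, 0.75)
        with pytest.raises(ValueError):
            fp.allometric_factor(-1.0, 1.0)


class TestRenalMaturation:
    def test_half_maturation_at_tm50(self):
        assert fp.renal_maturation(47.7) == pytest.approx(0.5, abs=1e-12)

    def test_direct_evaluation(self):
        # independent arithmetic: x = (40/47.7)^3.4 / (1 + (40/47.7)^3.4)
        r = (40.0 / 47.7) ** 3.4
        assert fp.renal_maturation(40.0) == pytest.approx(r / (1 + r), rel=1e-12)
        assert fp.renal_maturation(40.0) == pytest.approx(0.355, abs=5e-4)

    def test_saturation(self):
        assert fp.renal_maturation(1e8) == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(min_value=20.0, max_value=200.0), st.floats(min_value=0.01, max_value=50.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, pma, delta):
        lo = fp.renal_maturation(pma)
        hi = fp.renal_maturation(pma + delta)
        assert 0.0 < lo < hi < 1.0

    def test_nonpositive_pma_rejected(self):
        with pytest.raises(ValueError):
            fp.renal_maturation(0.0)


class TestPnaMaturation:
    def test_day_zero_equals_theta_m(self):
        assert fp.pna_maturation(0.0, 0.449, 0.117) == pytest.approx(0.449, abs=1e-12)

    def test_clearance_rise_day1_to_day5(self):
        # first-week maturation: ~36% clearance increase from day 1 to day 5
        ratio = fp.pna_maturation(5, 0.449, 0.117) / fp.pna_maturation(1, 0.449, 0.117)
        assert round(100 * (ratio - 1)) == 36

    def test_full_maturation_limit(self):
        assert fp.pna_maturation(1e6, 0.449, 0.117) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=60.0), st.floats(min_value=0.01, max_value=30.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, pna, delta):
        lo = fp.pna_maturation(pna, 0.449, 0.117)
        hi = fp.pna_maturation(pna + delta, 0.449, 0.117)
        assert 0.449 <= lo < hi < 1.0

    @pytest.mark.parametrize("theta_m,theta_n", [(0.0, 0.1), (1.5, 0.1), (0.5, 0.0), (0.5, -1)])
    def test_bad_parameters_rejected(self, theta_m, theta_n):
        with pytest.raises(ValueError):
            fp.pna_maturation(1.0, theta_m, theta_n)


class TestTypicalSerumCreatinine:
    def test_one_year(self):
        # ln(1) = 0, so only the intercept and sqrt terms remain
        assert fp.typical_serum_creatinine(1.0) == pytest.approx(
            -2.37330 + 23.93581, rel=1e-9
        )

    def test_day_three(self):
        pna = 3 / 365.25
        expected = -2.37330 - 12.91367 * math.log(pna) + 23.93581 * math.sqrt(pna)
        assert fp.typical_serum_creatinine(pna) == pytest.approx(expected, rel=1e-12)
        assert fp.typical_serum_creatinine(pna) == pytest.approx(61.8, abs=0.1)

    def test_positive_over_first_year(self):
        ages = np.linspace(1 / 365.25, 1.0, 200)
        assert np.all(fp.typical_serum_creatinine(ages) > 0)

    def test_zero_age_rejected(self):
        with pytest.raises(ValueError):
            fp.typical_serum_creatinine(0.0)


class TestScrCovariateFactor:
    def test_standardised_ratio_is_one(self):
        tscr = fp.typical_serum_creatinine(0.5)
        assert fp.scr_covariate_factor(tscr, 0.5, 1.7) == pytest.approx(1.0, rel=1e-12)

    def test_null_coefficient(self):
        assert fp.scr_covariate_factor(99.0, 0.2, 0.0) == pytest.approx(1.0, abs=1e-15)

    def test_doubled_creatinine(self):
        tscr = fp.typical_serum_creatinine(1.0)
        assert fp.scr_covariate_factor(2 * tscr, 1.0, 1.0) == pytest.approx(2.0, rel=1e-9)

    def test_nonpositive_scr_rejected(self):
        with pytest.raises(ValueError):
            fp.scr_covariate_factor(0.0, 1.0, 1.0)


class TestCsfUptake:
    def test_median_protein_leaves_ratio_unchanged(self):
        assert fp.csf_uptake(0.321, MEDIAN_CSF_PROTEIN, -0.952) == pytest.approx(
            0.321, abs=1e-12
        )

    def test_elevated_protein(self):
        # independent arithmetic through logit -> perturb -> inverse logit
        logit = math.log(0.321 / 0.679)
        expected = 1.0 / (1.0 + math.exp(-logit * (1 - 0.952 * 1.0)))
        assert fp.csf_uptake(0.321, 1.94, -0.952) == pytest.approx(expected, rel=1e-12)
        assert fp.csf_uptake(0.321, 1.94, -0.952) == pytest.approx(0.491, abs=1e-3)

    @given(st.floats(min_value=0.0, max_value=2.5), st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing_in_protein(self, protein, delta):
        # negative coefficient times negative logit: uptake rises with protein
        lo = fp.csf_uptake(0.321, protein, -0.952)
        hi = fp.csf_uptake(0.321, protein + delta, -0.952)
        assert 0.0 < lo < hi < 1.0

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=50, deadline=None)
    def test_zero_perturbation_roundtrip(self, uptk):
        assert fp.csf_uptake(uptk, MEDIAN_CSF_PROTEIN, -0.952) == pytest.approx(
            uptk, abs=1e-12
        )

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_ratio_rejected(self, bad):
        with pytest.raises(ValueError):
            fp.csf_uptake(bad, 1.0, -0.952)


class TestIndividualTypicalParameters:
    def test_standard_adult_limit(self, ref_pop, adult_reference):
        assert adult_reference.cl == pytest.approx(ref_pop.cl_std, rel=1e-6)
        assert adult_reference.v2 == pytest.approx(ref_pop.v2_std, rel=1e-12)
        assert adult_reference.q1 == pytest.approx(ref_pop.q1_std, rel=1e-12)
        assert adult_reference.uptk == pytest.approx(ref_pop.uptk, abs=1e-12)

    def test_median_trial_neonate_clearance(self, ref_pop):
        cov = fp.SubjectCovariates(weight=2.805, postnatal_age=1.0, postmenstrual_age=40.0)
        ind = fp.individual_typical_parameters(ref_pop, cov)
        # independent product: allometry x PMA maturation x PNA function
        r = (40.0 / 47.7) ** 3.4
        expected = (
            8.94
            * (2.805 / 70.0) ** 0.75
            * (r / (1 + r))
            * (0.449 + 0.551 * (1 - math.exp(-0.117)))
        )
        assert ind.cl == pytest.approx(expected, rel=1e-12)
        assert ind.cl == pytest.approx(0.145, abs=2e-3)

    def test_missing_scr_leaves_clearance_unchanged(self, ref_pop):
        with_scr = fp.SubjectCovariates(
            weight=3.0, postnatal_age=2.0, gestational_age=40.0, serum_creatinine=80.0
        )
        without = fp.SubjectCovariates(weight=3.0, postnatal_age=2.0, gestational_age=40.0)
        a = fp.individual_typical_parameters(ref_pop, with_scr)
        b = fp.individual_typical_parameters(ref_pop, without)
        assert a.cl == b.cl

    def test_missing_csf_protein_uses_median(self, ref_pop):
        cov = fp.SubjectCovariates(weight=3.0, postnatal_age=2.0, gestational_age=40.0)
        ind = fp.individual_typical_parameters(ref_pop, cov)
        assert ind.uptk == pytest.approx(ref_pop.uptk, abs=1e-12)

    @given(
        wt=st.floats(min_value=1.5, max_value=6.0),
        pma=st.floats(min_value=34.0, max_value=46.0),
        pna=st.floats(min_value=0.0, max_value=25.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_clearance_increases_in_each_covariate(self, ref_pop, wt, pma, pna):
        def cl(w, m, n):
            c = fp.SubjectCovariates(weight=w, postnatal_age=n, postmenstrual_age=m)
            return fp.individual_typical_parameters(ref_pop, c).cl

        base = cl(wt, pma, pna)
        assert cl(wt + 0.5, pma, pna) > base
        assert cl(wt, pma + 1.0, pna) > base
        assert cl(wt, pma, pna + 1.0) > base

    def test_vectorised_path_matches_scalar(self, ref_pop):
        covs = [
            fp.SubjectCovariates(weight=2.0, postnatal_age=0.0, gestational_age=36.0),
            fp.SubjectCovariates(
                weight=4.1, postnatal_age=9.0, gestational_age=41.0, csf_protein=1.9
            ),
        ]
        arrays = typical_parameter_arrays(ref_pop, covs)
        for i, cov in enumerate(covs):
            ind = fp.individual_typical_parameters(ref_pop, cov)
            for name in ("cl", "v2", "q1", "v3", "q2", "v4", "uptk", "ka", "f"):
                assert arrays[name][i] == pytest.approx(getattr(ind, name), rel=1e-12)


class TestDomainTypes:
    def test_pma_derived_from_ga_and_pna(self):
        cov = fp.SubjectCovariates(weight=3.0, postnatal_age=7.0, gestational_age=40.0)
        assert cov.postmenstrual_age == pytest.approx(41.0, abs=1e-12)

    def test_inconsistent_ages_rejected(self):
        with pytest.raises(ValueError, match="PMA"):
            fp.SubjectCovariates(
                weight=3.0, postnatal_age=7.0, gestational_age=40.0, postmenstrual_age=40.5
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(weight=-1.0, postnatal_age=1.0, gestational_age=40.0),
            dict(weight=3.0, postnatal_age=-1.0, gestational_age=40.0),
            dict(weight=3.0, postnatal_age=1.0),
        ],
    )
    def test_invalid_covariates_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fp.SubjectCovariates(**kwargs)

    def test_fixed_members_immutable(self, ref_pop):
        with pytest.raises(ValueError, match="fixed"):
            ref_pop.with_updates(q2_std=0.02)
        with pytest.raises(ValueError, match="fixed"):
            ref_pop.with_updates(tm50=50.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(cl_std=-1.0),
            dict(uptk=1.2),
            dict(f=0.0),
            dict(theta_m=0.0),
            dict(theta_n=-0.1),
            dict(omega_cl=-0.1),
        ],
    )
    def test_invalid_population_parameters_rejected(self, ref_pop, kwargs):
        base = {
            "cl_std": 8.94, "v2_std": 19.1, "q1_std": 8.01, "v3_std": 7.53,
            "uptk": 0.321, "ka": 0.0987, "f": 0.478,
            "theta_m": 0.449, "theta_n": 0.117, "theta_pr": -0.952,
        }
        base.update(kwargs)
        with pytest.raises(ValueError):
            PopulationParameters(**base)
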