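"""QI engine: cohort assembly, proportions, stratified OR, standards."""

import numpy as np
import pandas as pd
import pytest

import fedqi as fq
from fedqi.federation import RegistryNode
from fedqi.qi import (
    QI_DEFINITIONS,
    QIDefinition,
    assemble_cohort,
    crude_proportion,
    evaluate_qi,
    pss_proportion,
    score_standards,
    stratified_odds_ratio,
)

from conftest import toy_frame


def preop_mri_toy():
    """Six records: three operated without PST (one with MRI), one operated
    with PST, one not operated, one operated with unknown tumour size."""
    return toy_frame([
        {"any_operation": True, "n_breast_operations": 1, "bct": True,
         "preop_mri": True},
        {"any_operation": True, "n_breast_operations": 1, "bct": True},
        {"any_operation": True, "n_breast_operations": 1, "bct": True},
        {"any_operation": True, "n_breast_operations": 1, "bct": True,
         "pst": True},
        {},
        {"any_operation": True, "n_breast_operations": 1, "bct": True,
         "pt": "unknown"},
    ])


class TestAssembly:
    def test_preop_mri_toy_cohort(self):
        qi = QI_DEFINITIONS["QI6a"]
        eligible = assemble_cohort(preop_mri_toy(), qi)
        assert len(eligible) == 3
        assert qi.numerator(eligible).sum() == 1

    def test_no_mastectomies_makes_reconstruction_qi_not_applicable(self):
        frame = toy_frame([{"any_operation": True,
                            "n_breast_operations": 1, "bct": True}] * 4)
        qi = QI_DEFINITIONS["QI9c"]
        assert assemble_cohort(frame, qi).empty
        assert score_standards(None, qi) == "not_applicable"

    def test_radiotherapy_qi_excludes_distant_metastasis(self):
        frame = toy_frame([
            {"any_operation": True, "n_breast_operations": 1, "bct": True,
             "postop_radiotherapy": True},
            {"any_operation": True, "n_breast_operations": 1, "bct": True,
             "postop_radiotherapy": True, "distant_metastasis": True},
        ])
        eligible = assemble_cohort(frame, QI_DEFINITIONS["QI10a"])
        assert len(eligible) == 1
        assert not eligible["distant_metastasis"].any()

    def test_single_operation_qi_excludes_reconstruction_and_dcis(self):
        frame = toy_frame([
            {"any_operation": True, "n_breast_operations": 1},
            {"any_operation": True, "n_breast_operations": 1,
             "mastectomy": True, "any_reconstruction": True},
            {"any_operation": True, "n_breast_operations": 2,
             "dcis_only": True},
        ])
        assert len(assemble_cohort(frame, QI_DEFINITIONS["QI9a"])) == 1


class TestProportions:
    def test_zero_of_ten(self):
        p, (lo, hi) = crude_proportion(0, 10)
        assert p == 0.0 and lo == 0.0 and hi > 0

    def test_thirty_seven_of_hundred(self):
        p, ci = crude_proportion(37, 100)
        assert p == 0.37
        assert ci[0] < 0.37 < ci[1]

    def test_toy_cohort_crude_is_one_third(self):
        qi = QI_DEFINITIONS["QI6a"]
        eligible = assemble_cohort(preop_mri_toy(), qi)
        p, _ = crude_proportion(int(qi.numerator(eligible).sum()),
                                len(eligible))
        assert p == pytest.approx(1 / 3)

    def test_single_stratum_equals_crude_exactly(self):
        num, den = np.array([13]), np.array([40])
        pss, ci = pss_proportion(num, den)
        crude, _ = crude_proportion(13, 40)
        assert pss == crude
        assert ci is None  # CI undefined with one occupied stratum

    def test_stratum_mean(self):
        pss, ci = pss_proportion([2, 4, 6], [10, 10, 10])
        assert pss == pytest.approx(0.4)
        assert ci[0] < 0.4 < ci[1]

    def test_empty_strata_excluded(self):
        pss, _ = pss_proportion([2, 0, 6], [10, 0, 10])
        assert pss == pytest.approx(0.4)


class TestStratifiedOR:
    def test_single_stratum_equals_crude_cross_product(self):
        """The worked 2x2 with 37%-vs-17.5% marginals: MH on one stratum is
        the crude odds ratio 2.769, printed as 2.8."""
        table = np.array([[370, 630], [175, 825]], dtype=float) * 10
        oratio, ci = stratified_odds_ratio([table])
        assert oratio == pytest.approx((370 * 825) / (630 * 175), rel=1e-12)
        assert round(oratio, 1) == 2.8
        assert ci[0] < oratio < ci[1]

    def test_identical_rates_give_unit_odds_ratio(self):
        tables = [np.array([[30, 70], [15, 35]]),
                  np.array([[8, 2], [16, 4]])]
        oratio, _ = stratified_odds_ratio(tables)
        assert oratio == pytest.approx(1.0)

    def test_matches_hand_computed_mh_sums(self):
        # MH = (10*25/60 + 8*4/20) / (20*5/60 + 2*6/20) = 173/68
        tables = [np.array([[10, 20], [5, 25]]),
                  np.array([[8, 2], [6, 4]])]
        oratio, _ = stratified_odds_ratio(tables)
        assert oratio == pytest.approx(173 / 68, rel=1e-12)

    def test_double_zero_case_strata_are_dropped(self):
        tables = [np.array([[10, 20], [5, 25]]),
                  np.array([[0, 12], [0, 9]])]
        oratio, _ = stratified_odds_ratio(tables)
        assert oratio == pytest.approx((10 * 25) / (20 * 5), rel=1e-12)

    def test_all_degenerate_reports_none(self):
        oratio, ci = stratified_odds_ratio([np.array([[0, 5], [0, 7]])])
        assert oratio is None and ci is None


class TestStandards:
    @pytest.mark.parametrize(
        "qi_id, estimate, verdict",
        [
            ("QI10a", 0.957, "meets_target"),   # target 95%
            ("QI10a", 0.949, "meets_standard"),
            ("QI9c", 0.36, "below_standard"),   # standard 40%
            ("QI6a", 0.10, "meets_standard"),   # boundary counts as met
            ("QI6b", 0.90, "meets_target"),
            ("QI6b", 0.59, "below_standard"),
        ],
    )
    def test_verdicts(self, qi_id, estimate, verdict):
        assert score_standards(estimate, QI_DEFINITIONS[qi_id]) == verdict


class TestEvaluate:
    @pytest.mark.parametrize("qi_id", list(QI_DEFINITIONS))
    def test_numerator_implies_denominator_on_generated_data(
        self, qi_id, small_scenario
    ):
        qi = QI_DEFINITIONS[qi_id]
        for cohort in small_scenario:
            frame = cohort.frame
            outside = qi.numerator(frame) & ~qi.denominator(frame)
            assert not outside.any()

    def test_crude_evaluation_without_stratification(self, small_nodes):
        qi = QI_DEFINITIONS["QI9a"]
        eligible = [n.subset(lambda f: fq.qi.eligible_mask(f, qi), "QI9a")
                    for n in small_nodes]
        result = evaluate_qi(eligible, qi)
        assert result.strata_used == 1
        for country in ("NL", "NO"):
            est = result.per_country[country]
            assert est["pss"] == est["crude"]  # single stratum collapse
            assert 0 <= est["crude"] <= 1
        assert result.odds_ratio > 0
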