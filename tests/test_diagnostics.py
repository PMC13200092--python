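"""Cutoff application, Se/Sp, Youden, Rogan-Gladen adjustment, panel wiring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from b12status.diagnostics import (
    AGE_SPECIFIC,
    CutoffSpec,
    TRADITIONAL_PANEL,
    UninformativeTestError,
    adjusted_prevalence,
    apply_cutoff,
    evaluate_panel,
    predictive_values,
    sens_spec,
    summaries_to_frame,
    youden,
)
from b12status.survey import ProportionEstimate, SurveyDesign
from b12status.synthetic import SyntheticConfig, generate_population, split_cycles

from conftest import equal_weight_design

AGE_RULE = CutoffSpec(
    AGE_SPECIFIC, ">",
    (((20.0, 40.0), 250.0), ((40.0, 70.0), 290.0), ((70.0, float("inf")), 320.0)),
    "age-specific MMA",
)


def _frame(mma, age):
    return pd.DataFrame({"mma_nmol_L": mma, "age": age,
                         "b12_pmol_L": 300.0, "thcy_umol_L": 9.0})


class TestApplyCutoff:
    def test_strict_inequality_at_threshold(self):
        spec = CutoffSpec("mma", ">", 376.0, "MMA >376")
        got = apply_cutoff(spec, _frame([376.0, 376.1], [50, 50]))
        assert got.tolist() == [False, True]

    def test_lower_direction_strict(self):
        spec = CutoffSpec("b12", "<", 148.0, "B-12 <148")
        frame = pd.DataFrame({"b12_pmol_L": [148.0, 147.9], "age": [50, 50]})
        assert apply_cutoff(spec, frame).tolist() == [False, True]

    @pytest.mark.parametrize(
        "age,mma,expected",
        [(35, 260.0, True), (70, 300.0, False), (45, 291.0, True), (25, 250.0, False)],
    )
    def test_age_specific_dispatch(self, age, mma, expected):
        assert apply_cutoff(AGE_RULE, _frame([mma], [age])).tolist() == [expected]

    def test_age_bands_must_tile(self):
        with pytest.raises(ValueError, match="tile"):
            CutoffSpec(AGE_SPECIFIC, ">", (((20.0, 40.0), 250.0), ((50.0, float("inf")), 320.0)), "bad")


class TestSensSpec:
    def test_perfect_and_inverted_tests(self):
        ref = np.array([True, True, False, False])
        design = equal_weight_design(4)
        se, sp = sens_spec(ref, ref, design)
        assert (se.estimate, sp.estimate) == (1.0, 1.0)
        se, sp = sens_spec(~ref, ref, design)
        assert (se.estimate, sp.estimate) == (0.0, 0.0)

    def test_weighted_hand_fixture(self):
        # 12 records; hand-computed weighted fractions
        ref = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0], bool)
        test = np.array([1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 1, 0], bool)
        w = np.array([2, 1, 1, 2, 1, 1, 2, 1, 1, 1, 1, 3], float)
        design = SurveyDesign(np.repeat("S1", 12),
                              np.array([f"P{i % 2}" for i in range(12)]), w)
        se, sp = sens_spec(test, ref, design)
        assert se.estimate == pytest.approx((2 + 1 + 2) / 6)
        assert sp.estimate == pytest.approx((1 + 1 + 1 + 1 + 1 + 3) / 11)


class TestYouden:
    @pytest.mark.parametrize(
        "se,sp,expected",
        [(0.852, 0.923, 0.775), (1.0, 1.0, 1.0), (0.5, 0.5, 0.0)],
    )
    def test_identity(self, se, sp, expected):
        assert youden(se, sp) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            youden(1.2, 0.5)


class TestAdjustedPrevalence:
    def test_reference_against_itself(self):
        est = adjusted_prevalence(0.0274, 1.0, 1.0)
        assert est.adjusted == pytest.approx(0.0274, abs=1e-15)
        assert not est.clamped

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p=st.floats(0.0, 1.0))
    def test_identity_at_perfect_test(self, p):
        assert adjusted_prevalence(p, 1.0, 1.0).adjusted == pytest.approx(p, abs=1e-12)

    def test_direct_formula(self):
        got = adjusted_prevalence(0.0981, 0.852, 0.923).adjusted
        assert got == pytest.approx((0.0981 + 0.923 - 1) / (0.852 + 0.923 - 1), abs=1e-12)

    def test_uninformative_test_rejected(self):
        with pytest.raises(UninformativeTestError):
            adjusted_prevalence(0.1, 0.5, 0.5)

    def test_clamping_flagged(self):
        est = adjusted_prevalence(0.01, 0.9, 0.95)  # apparent below false-positive rate
        assert est.clamped and est.adjusted == 0.0

    def test_increasing_in_specificity_when_se_exceeds_apparent(self):
        # d(adjusted)/d(sp) has the sign of (se - apparent); grid kept inside
        # the informative, unclamped region
        grid = np.linspace(0.91, 0.99, 20)
        vals = [adjusted_prevalence(0.10, 0.85, sp).adjusted for sp in grid]
        assert np.all(np.diff(vals) > 0)

    def test_ci_propagates_all_three_variances(self):
        app = ProportionEstimate(0.10, 0.01, 0.08, 0.12)
        se_tr = ProportionEstimate(0.85, 0.02, 0.80, 0.89)
        sp_tr = ProportionEstimate(0.92, 0.01, 0.90, 0.94)
        narrow = adjusted_prevalence(app, 0.85, 0.92)
        wide = adjusted_prevalence(app, se_tr, sp_tr)
        assert wide.adjusted == pytest.approx(narrow.adjusted)
        assert (wide.adjusted_ci_high - wide.adjusted_ci_low) > (
            narrow.adjusted_ci_high - narrow.adjusted_ci_low
        )


class TestPredictiveValues:
    def test_high_specificity_cutoff_ppv(self):
        ppv, npv = predictive_values(0.549, 0.991, 0.0274)
        expected = 0.549 * 0.0274 / (0.549 * 0.0274 + 0.009 * 0.9726)
        assert ppv == pytest.approx(expected, abs=1e-12)
        assert 0.60 < ppv < 0.67  # "about 60%" regime
        assert npv > 0.98

    def test_ppv_vanishes_at_zero_prevalence(self):
        ppv, _ = predictive_values(0.9, 0.95, 0.0)
        assert ppv == 0.0

    def test_perfect_test(self):
        assert predictive_values(1.0, 1.0, 0.3) == (1.0, 1.0)


@pytest.fixture(scope="module")
def panel_run():
    pop = generate_population(
        SyntheticConfig(n_strata=12, n_per_psu=150, prevalence_inadequate=0.10,
                        mma_age_slope=0.0, renal_impairment_rate=0.0, seed=21)
    )
    train, valid = split_cycles(pop, 0.5)
    truth = {
        id_: s == "inadequate"
        for id_, s in zip(pop.truth["id"], pop.truth["truth_status"])
    }

    def scorer(frame):
        return np.array([truth[i] for i in frame["id"]])

    cfg = pop.config
    boundary = _theoretical_best_mma_cutoff(cfg)
    specs = (CutoffSpec("mma", ">", boundary, "MMA at generative boundary"),) + TRADITIONAL_PANEL
    rows = evaluate_panel(
        specs, train.frame, valid.frame, scorer,
        SurveyDesign.from_frame(train.frame), SurveyDesign.from_frame(valid.frame),
    )
    return cfg, rows


class TestEvaluatePanel:
    def test_row_count_is_panel_size_plus_reference(self, panel_run):
        _, rows = panel_run
        assert len(rows) == 1 + 1 + len(TRADITIONAL_PANEL)
        assert rows[0].is_reference

    def test_reference_row_apparent_equals_adjusted(self, panel_run):
        _, rows = panel_run
        ref = rows[0].prevalence
        assert ref.adjusted == ref.apparent.estimate
        assert (ref.se_used, ref.sp_used) == (1.0, 1.0)

    def test_youden_identity_every_row(self, panel_run):
        _, rows = panel_run
        for r in rows[1:]:
            assert r.youden == pytest.approx(
                r.sensitivity.estimate + r.specificity.estimate - 1.0, abs=1e-12
            )

    def test_boundary_cutoff_youden_near_theoretical_max(self, panel_run):
        cfg, rows = panel_run
        j_star = _theoretical_best_mma_youden(cfg)
        row = next(r for r in rows if "generative boundary" in r.cutoff.label)
        assert row.youden == pytest.approx(j_star, abs=0.06)

    def test_summary_frame_renders_percent_scale(self, panel_run):
        _, rows = panel_run
        table = summaries_to_frame(rows)
        assert table["apparent_prevalence_pct"].iloc[0] > 1.0  # percent, not proportion
        assert table.shape[0] == len(rows)


def _mma_j(cfg, log_t):
    mu_a, mu_i = cfg.marker_log_means_adequate[1], cfg.marker_log_means_inadequate[1]
    sd = cfg.marker_log_sds[1]
    se = 1 - stats.norm.cdf((log_t - mu_i) / sd)
    sp = stats.norm.cdf((log_t - mu_a) / sd)
    return se + sp - 1


def _theoretical_best_mma_cutoff(cfg):
    res = optimize.minimize_scalar(
        lambda t: -_mma_j(cfg, t), bounds=(1.5, 3.5), method="bounded"
    )
    return float(10**res.x)


def _theoretical_best_mma_youden(cfg):
    return float(_mma_j(cfg, np.log10(_theoretical_best_mma_cutoff(cfg))))
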