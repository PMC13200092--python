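"""Weighted ROC/AUC, model fitting, optimum-cutoff derivation."""

import numpy as np
import pytest
import statsmodels.api as sm

from b12status.roc import (
    HIGHER,
    LOWER,
    MARKER_COLUMNS,
    OneClassError,
    _best_threshold,
    compare_auc,
    fit_marker_model,
    optimum_cutoff,
    weighted_auc,
    weighted_roc,
)
from b12status.roc import test_positive as strict_positive
from b12status.survey import SurveyDesign, make_replicate_weights

from conftest import equal_weight_design


def pair_statistic(score, label, weights):
    """Brute-force weighted concordance: oracle for the trapezoidal AUC."""
    s = np.asarray(score, float)
    y = np.asarray(label, bool)
    w = np.asarray(weights, float)
    sp, wp = s[y], w[y]
    sn, wn = s[~y], w[~y]
    gt = (sp[:, None] > sn[None, :]).astype(float)
    eq = (sp[:, None] == sn[None, :]).astype(float)
    num = np.sum(wp[:, None] * wn[None, :] * (gt + 0.5 * eq))
    return num / (wp.sum() * wn.sum())


class TestWeightedRoc:
    def test_hand_enumerated_curve(self):
        curve = weighted_roc([1, 2, 3, 4], [0, 0, 1, 1], np.ones(4), HIGHER)
        pts = set(zip(*curve.points()))
        assert pts == {(0, 0), (0, 0.5), (0, 1), (0.5, 1), (1, 1)}

    def test_hand_enumerated_weighted_curve(self):
        # weights [1,1,3,1]: positives carry weights 3 and 1
        curve = weighted_roc([1, 2, 3, 4], [0, 0, 1, 1], [1, 1, 3, 1], HIGHER)
        pts = list(zip(curve.thresholds, curve.one_minus_spec_at, curve.sens_at))
        assert pts == [(4, 0, 0), (3, 0, 0.25), (2, 0, 1.0), (1, 0.5, 1.0)]

    def test_separable_data_passes_through_corner(self):
        curve = weighted_roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], np.ones(6), HIGHER)
        assert any(fpr == 0 and se == 1 for fpr, se in zip(*curve.points()))
        assert weighted_auc(curve) == 1.0

    def test_ties_move_together(self):
        curve = weighted_roc([1, 1, 1, 2], [0, 1, 0, 1], np.ones(4), HIGHER)
        # threshold 1 calls only the score-2 record positive; threshold below
        # unifies the tied group, so (2/3 fpr, 1/2 sens) never appears alone
        assert list(curve.thresholds) == [2, 1]
        assert curve.sens_at.tolist() == [0.0, 0.5]

    def test_one_class_input_names_empty_class(self):
        with pytest.raises(OneClassError, match="positive"):
            weighted_roc([1, 2], [0, 0], np.ones(2), HIGHER)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=4000)
        y = rng.random(4000) < 0.5
        auc = weighted_auc(weighted_roc(s, y, np.ones(4000), HIGHER))
        assert auc == pytest.approx(0.5, abs=0.03)


class TestAucOracle:
    def test_trapezoid_equals_pair_statistic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(10, 200)
            s = rng.normal(size=n).round(1)  # rounding forces ties
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            w = rng.uniform(0.2, 5.0, n)
            auc = weighted_auc(weighted_roc(s, y, w, HIGHER))
            assert auc == pytest.approx(pair_statistic(s, y, w), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        s = rng.lognormal(5, 1, 300)
        y = rng.random(300) < 0.3
        w = rng.uniform(0.5, 3, 300)
        a1 = weighted_auc(weighted_roc(s, y, w, HIGHER))
        a2 = weighted_auc(weighted_roc(np.log10(s), y, w, HIGHER))
        assert a1 == a2

    def test_orientation_duality_on_tie_free_data(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=200)
        y = rng.random(200) < 0.5
        w = rng.uniform(0.5, 2, 200)
        a_hi = weighted_auc(weighted_roc(s, y, w, HIGHER))
        a_lo = weighted_auc(weighted_roc(s, y, w, LOWER))
        assert a_hi + a_lo == pytest.approx(1.0, abs=1e-12)


class TestFitMarkerModel:
    def _setup(self, small_population):
        pop = small_population
        ref = (pop.truth["truth_status"] == "inadequate").to_numpy()
        return pop.frame, SurveyDesign.from_frame(pop.frame), ref

    def test_single_marker_is_identity_with_orientation(self, small_population):
        frame, design, ref = self._setup(small_population)
        m = fit_marker_model(("b12",), frame, design, ref)
        assert m.orientation == LOWER and m.method == "identity"
        np.testing.assert_array_equal(m.score, frame["b12_pmol_L"].to_numpy())

    def test_duplicated_marker_same_roc_as_single(self, small_population):
        frame, design, ref = self._setup(small_population)
        single = fit_marker_model(("mma",), frame, design, ref)
        dup = fit_marker_model(("mma", "mma"), frame, design, ref)
        a1 = weighted_auc(weighted_roc(single.score, ref, design, single.orientation))
        a2 = weighted_auc(weighted_roc(dup.score, ref, design, dup.orientation))
        assert a2 == pytest.approx(a1, abs=1e-9)

    def test_equal_weights_match_unweighted_logit_oracle(self, small_population):
        frame, _, ref = self._setup(small_population)
        design = equal_weight_design(len(frame))
        m = fit_marker_model(("b12", "mma"), frame, design, ref)
        X = sm.add_constant(
            np.column_stack(
                [np.log10(frame["b12_pmol_L"]), np.log10(frame["mma_nmol_L"])]
            )
        )
        oracle = sm.Logit(ref.astype(float), X).fit(disp=0)
        got = np.array([m.coefficients["const"], m.coefficients["b12"], m.coefficients["mma"]])
        np.testing.assert_allclose(got, oracle.params, atol=1e-6)

    def test_three_marker_nests_single(self, small_population):
        frame, design, ref = self._setup(small_population)
        triple = fit_marker_model(("mma", "thcy", "b12"), frame, design, ref)
        single = fit_marker_model(("mma",), frame, design, ref)
        a3 = weighted_auc(weighted_roc(triple.score, ref, design, triple.orientation))
        a1 = weighted_auc(weighted_roc(single.score, ref, design, single.orientation))
        assert a3 >= a1 - 0.005


class TestOptimumCutoff:
    def test_hand_enumerable_distance_minimizer(self):
        # 8 points, strictly better corner at threshold 5
        s = np.array([1, 2, 3, 4, 5, 6, 7, 8], float)
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1])
        w = np.ones(8)
        curve = weighted_roc(s, y, w, HIGHER)
        d2 = (1 - curve.sens_at) ** 2 + curve.one_minus_spec_at**2
        assert _best_threshold(curve) == curve.thresholds[np.argmin(d2)] == 5.0

    def test_tie_broken_toward_higher_specificity(self):
        # two thresholds achieve the same distance; pick the lower-fpr one
        s = np.array([1, 2, 3, 4], float)
        y = np.array([0, 1, 0, 1])
        w = np.ones(4)
        curve = weighted_roc(s, y, w, HIGHER)
        d2 = (1 - curve.sens_at) ** 2 + curve.one_minus_spec_at**2
        ties = np.flatnonzero(d2 == d2.min())
        assert len(ties) > 1
        best = _best_threshold(curve)
        k = list(curve.thresholds).index(best)
        assert curve.one_minus_spec_at[k] == curve.one_minus_spec_at[ties].min()

    def test_separable_toy_recovers_boundary(self):
        s = np.repeat([1.0, 2.0, 10.0, 11.0], 2)
        y = np.repeat([0, 0, 1, 1], 2)
        design = equal_weight_design(8)
        reps = make_replicate_weights(design, B=60, seed=0)
        res = optimum_cutoff(s, y, design, reps, HIGHER, "mma")
        assert res.cutoff == 2.0  # strict '>' at the top negative
        assert res.youden == pytest.approx(1.0)
        assert res.direction == ">"
        assert res.sensitivity.estimate == 1.0 and res.specificity.estimate == 1.0

    def test_strict_inequality_convention(self):
        assert not strict_positive(376.0, 376.0, HIGHER)
        assert strict_positive(376.1, 376.0, HIGHER)
        assert not strict_positive(148.0, 148.0, LOWER)


class TestCompareAuc:
    def test_model_against_itself_p_is_one(self, small_population):
        pop = small_population
        ref = (pop.truth["truth_status"] == "inadequate").to_numpy()
        design = SurveyDesign.from_frame(pop.frame)
        reps = make_replicate_weights(design, B=60, seed=2)
        m = fit_marker_model(("mma",), pop.frame, design, ref)
        p, est_a, est_b = compare_auc(m, m, pop.frame, design, reps, ref)
        assert p == 1.0
        assert est_a.auc == est_b.auc

    def test_nested_models_significant_on_structured_data(self, split_population):
        train, _ = split_population
        from b12status.io import _reference_scorer
        from b12status.indicators import Cb12Constants

        ref = _reference_scorer(Cb12Constants.packaged_default())(train.frame)
        design = SurveyDesign.from_frame(train.frame)
        reps = make_replicate_weights(design, B=200, seed=3)
        triple = fit_marker_model(("mma", "thcy", "b12"), train.frame, design, ref)
        single = fit_marker_model(("thcy",), train.frame, design, ref)
        p, est3, est1 = compare_auc(triple, single, train.frame, design, reps, ref)
        assert est3.auc > est1.auc
        assert p < 0.05

    def test_null_scores_not_significant(self):
        rng = np.random.default_rng(11)
        n = 400
        frame_scores = rng.normal(size=(n, 2))
        y = rng.random(n) < 0.3
        # many PSUs so the replicate distribution is not degenerate
        design = equal_weight_design(n, n_psus=50)
        reps = make_replicate_weights(design, B=200, seed=4)
        from b12status.roc import MarkerModel, auc_replicates
        from b12status.survey import bootstrap_pvalue_difference

        reps_auc = []
        for k in range(2):
            m = MarkerModel(("mma",), HIGHER, frame_scores[:, k])
            reps_auc.append(auc_replicates(m, None, design, reps, y))
        p = bootstrap_pvalue_difference(*reps_auc)
        assert p > 0.01
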