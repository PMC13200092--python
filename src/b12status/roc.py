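"""Survey-weighted ROC analysis, AUC, model grid, and optimum cutoffs.

The ROC machinery is threshold-explicit: candidate thresholds are the unique
observed score values, a test is positive when the score is strictly beyond
the threshold in the marker's direction of abnormality (``> t`` for markers
that rise in deficiency, ``< t`` for B-12), and tied scores change
classification together.  The area is the trapezoidal integral of the curve,
which equals the weighted concordance (pair) statistic — an identity used as
a test oracle, not assumed.

Multi-marker scores come from survey-weighted logistic regression on log10
concentrations; single markers bypass fitting entirely, so their ROC/AUC are
invariant to any strictly monotone transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .survey import (
    ProportionEstimate,
    ReplicateWeights,
    SurveyDesign,
    bootstrap_pvalue_difference,
    percentile_ci,
    weighted_proportion,
)

__all__ = [
    "RocCurve",
    "AucEstimate",
    "MarkerModel",
    "CutoffResult",
    "MARKER_COLUMNS",
    "MARKER_ORIENTATION",
    "weighted_roc",
    "weighted_auc",
    "fit_marker_model",
    "optimum_cutoff",
    "compare_auc",
    "auc_replicates",
    "auc_with_ci",
]

HIGHER = "higher_is_positive"
LOWER = "lower_is_positive"

MARKER_COLUMNS = {"b12": "b12_pmol_L", "mma": "mma_nmol_L", "thcy": "thcy_umol_L"}
# Direction of abnormality: B-12 falls in deficiency, MMA and tHcy rise.
MARKER_ORIENTATION = {"b12": LOWER, "mma": HIGHER, "thcy": HIGHER}


class OneClassError(ValueError):
    pass


@dataclass(frozen=True)
class RocCurve:
    """Weighted ROC curve over the observed thresholds.

    ``thresholds`` are ordered from strictest to loosest; ``sens_at[k]`` and
    ``one_minus_spec_at[k]`` give the operating point of the rule "positive
    iff score strictly beyond thresholds[k]".  The implicit final operating
    point (everyone positive) is (1, 1).
    """

    orientation: str
    thresholds: np.ndarray
    sens_at: np.ndarray
    one_minus_spec_at: np.ndarray

    def __post_init__(self):
        if self.orientation not in (HIGHER, LOWER):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        for name in ("thresholds", "sens_at", "one_minus_spec_at"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.sens_at) < -1e-12) or np.any(
            np.diff(self.one_minus_spec_at) < -1e-12
        ):
            raise ValueError("curve coordinates must be non-decreasing")

    def points(self) -> Tuple[np.ndarray, np.ndarray]:
        """(1-specificity, sensitivity) pairs including the (1,1) endpoint."""
        x = np.append(self.one_minus_spec_at, 1.0)
        y = np.append(self.sens_at, 1.0)
        return x, y

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sens_at,
                "one_minus_specificity": self.one_minus_spec_at,
            }
        )


def _resolve_weights(design, weights):
    if weights is not None:
        return np.asarray(weights, dtype=float)
    if isinstance(design, SurveyDesign):
        return design.weight
    return np.asarray(design, dtype=float)


def weighted_roc(score, reference, design, orientation=HIGHER, weights=None) -> RocCurve:
    """Weighted ROC curve of a score against a binary reference label.

    ``design`` may be a SurveyDesign or a plain weight vector; ``weights``
    overrides it (used for bootstrap replicates).  Zero weights are allowed
    in overrides and contribute nothing.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(reference).astype(bool)
    w = _resolve_weights(design, weights)
    if not (len(s) == len(y) == len(w)):
        raise ValueError("score, reference, weights must have equal length")

    pos_w = float(np.sum(w[y]))
    neg_w = float(np.sum(w[~y]))
    if pos_w <= 0:
        raise OneClassError("no positive-weight reference-positive records")
    if neg_w <= 0:
        raise OneClassError("no positive-weight reference-negative records")

    # strictest-first ordering: descending values for higher_is_positive
    order = np.argsort(s, kind="mergesort")
    if orientation == HIGHER:
        order = order[::-1]
    s_ord, y_ord, w_ord = s[order], y[order], w[order]
    uniq, first_idx = np.unique(
        -s_ord if orientation == HIGHER else s_ord, return_index=True
    )
    thresholds = -uniq if orientation == HIGHER else uniq

    cum_pos = np.cumsum(w_ord * y_ord)
    cum_neg = np.cumsum(w_ord * ~y_ord)
    # operating point of "strictly beyond t_k": everything before group k
    prev = first_idx - 1
    sens = np.where(prev >= 0, cum_pos[np.maximum(prev, 0)], 0.0) / pos_w
    fpr = np.where(prev >= 0, cum_neg[np.maximum(prev, 0)], 0.0) / neg_w
    return RocCurve(orientation, thresholds, sens, fpr)


def weighted_auc(curve: RocCurve) -> float:
    """Trapezoidal area under the weighted ROC curve.

    The curve starts at (0,0) — the strictest threshold calls nothing
    positive — and :meth:`RocCurve.points` appends the (1,1) endpoint.
    """
    x, y = curve.points()
    return float(np.trapezoid(y, x))


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    ci_low: float
    ci_high: float
    B: int


@dataclass
class MarkerModel:
    """A scoring rule over records: single marker passthrough or a
    survey-weighted logistic combination."""

    markers: Tuple[str, ...]
    orientation: str
    score: np.ndarray
    coefficients: Optional[Dict[str, float]] = None
    converged: bool = True
    method: str = "identity"

    @property
    def label(self) -> str:
        return "+".join(self.markers)


def _logistic_score(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted-ML logistic linear predictor; ridge fallback on trouble."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit(
                maxiter=100
            )
            params = np.asarray(res.params, dtype=float)
            ok = bool(res.converged) and np.all(np.isfinite(params))
        except Exception:
            ok = False
        if not ok:
            res = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit_regularized(
                alpha=1e-3, L1_wt=0.0, maxiter=200
            )
            params = np.asarray(res.params, dtype=float)
            return X @ params, params, False, "irls-ridge-fallback"
    return X @ params, params, True, "irls-weighted-ml"


def fit_marker_model(
    markers: Sequence[str],
    records: pd.DataFrame,
    design: SurveyDesign,
    reference,
) -> MarkerModel:
    """Score records with a marker subset.

    One marker: the concentration itself, oriented by its direction of
    abnormality.  Two or more: linear predictor of a survey-weighted logistic
    regression of the reference label on log10 concentrations (higher score =
    more likely inadequate).  Non-convergence or separation triggers a
    flagged ridge refit, never a silent failure.
    """
    markers = tuple(markers)
    if not markers:
        raise ValueError("need at least one marker")
    for m in markers:
        if m not in MARKER_COLUMNS:
            raise ValueError(f"unknown marker {m!r}")

    if len(markers) == 1:
        m = markers[0]
        return MarkerModel(
            markers,
            MARKER_ORIENTATION[m],
            records[MARKER_COLUMNS[m]].to_numpy(dtype=float),
        )

    y = np.asarray(reference).astype(float)
    X = np.column_stack(
        [np.ones(len(records))]
        + [np.log10(records[MARKER_COLUMNS[m]].to_numpy(dtype=float)) for m in markers]
    )
    score, params, converged, method = _logistic_score(X, y, design.weight)
    coef = {"const": float(params[0])}
    coef.update({m: float(params[i + 1]) for i, m in enumerate(markers)})
    return MarkerModel(markers, HIGHER, score, coef, converged, method)


def _refit_score(model: MarkerModel, records: pd.DataFrame, reference, w: np.ndarray):
    """Per-replicate score: refit multi-marker models, reuse single-marker."""
    if len(model.markers) == 1:
        return model.score
    keep = w > 0
    y = np.asarray(reference).astype(float)
    X = np.column_stack(
        [np.ones(len(records))]
        + [
            np.log10(records[MARKER_COLUMNS[m]].to_numpy(dtype=float))
            for m in model.markers
        ]
    )
    score = np.full(len(records), np.nan)
    s, _, _, _ = _logistic_score(X[keep], y[keep], w[keep])
    score[keep] = s
    return score


def auc_replicates(
    model: MarkerModel,
    records: pd.DataFrame,
    design: SurveyDesign,
    replicates: ReplicateWeights,
    reference,
) -> np.ndarray:
    """Replicate-weight AUCs (multi-marker models are refit per replicate)."""
    y = np.asarray(reference).astype(bool)
    out = np.full(replicates.n_replicates, np.nan)
    for b in range(replicates.n_replicates):
        w = replicates.matrix[:, b]
        if np.sum(w[y]) <= 0 or np.sum(w[~y]) <= 0:
            continue  # a replicate dropped an entire class; leave NaN
        score = _refit_score(model, records, reference, w)
        keep = w > 0
        curve = weighted_roc(score[keep], y[keep], w[keep], model.orientation)
        out[b] = weighted_auc(curve)
    return out


def auc_with_ci(
    model: MarkerModel,
    records: pd.DataFrame,
    design: SurveyDesign,
    replicates: ReplicateWeights,
    reference,
    replicate_aucs: Optional[np.ndarray] = None,
) -> AucEstimate:
    curve = weighted_roc(model.score, reference, design, model.orientation)
    auc = weighted_auc(curve)
    if replicate_aucs is None:
        replicate_aucs = auc_replicates(model, records, design, replicates, reference)
    lo, hi = percentile_ci(replicate_aucs)
    return AucEstimate(auc, lo, hi, replicates.n_replicates)


@dataclass(frozen=True)
class CutoffResult:
    marker: str
    cutoff: float
    direction: str  # "<" or ">"
    ci_low: float
    ci_high: float
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    youden: float

    def __post_init__(self):
        j = self.sensitivity.estimate + self.specificity.estimate - 1.0
        if abs(j - self.youden) > 1e-9:
            raise ValueError("youden must equal Se + Sp - 1")


def _best_threshold(curve: RocCurve) -> float:
    """Closest-to-corner threshold; ties broken toward higher specificity."""
    d2 = (1.0 - curve.sens_at) ** 2 + curve.one_minus_spec_at**2
    best = np.flatnonzero(d2 <= d2.min() + 1e-15)
    if len(best) > 1:
        best = best[np.argsort(curve.one_minus_spec_at[best], kind="mergesort")]
    return float(curve.thresholds[best[0]])


def test_positive(score, cutoff: float, orientation: str) -> np.ndarray:
    """Strict-inequality positivity call matching the '<' / '>' convention."""
    s = np.asarray(score, dtype=float)
    return s > cutoff if orientation == HIGHER else s < cutoff


def optimum_cutoff(
    score,
    reference,
    design: SurveyDesign,
    replicates: ReplicateWeights,
    orientation: str,
    marker: str = "",
) -> CutoffResult:
    """Closest-to-corner optimum cutoff with a bootstrap CI.

    The CI re-derives the optimum on every replicate-weight vector (the
    reported interval is for the cutoff itself); Se/Sp at the chosen cutoff
    carry Taylor-logit CIs.
    """
    y = np.asarray(reference).astype(bool)
    curve = weighted_roc(score, y, design, orientation)
    cutoff = _best_threshold(curve)

    reps = np.full(replicates.n_replicates, np.nan)
    for b in range(replicates.n_replicates):
        w = replicates.matrix[:, b]
        if np.sum(w[y]) <= 0 or np.sum(w[~y]) <= 0:
            continue
        keep = w > 0
        c = weighted_roc(
            np.asarray(score, dtype=float)[keep], y[keep], w[keep], orientation
        )
        reps[b] = _best_threshold(c)
    lo, hi = percentile_ci(reps)

    pos = test_positive(score, cutoff, orientation)
    se = weighted_proportion(pos.astype(float), design, domain=y)
    sp = weighted_proportion((~pos).astype(float), design, domain=~y)
    return CutoffResult(
        marker,
        cutoff,
        ">" if orientation == HIGHER else "<",
        lo,
        hi,
        se,
        sp,
        se.estimate + sp.estimate - 1.0,
    )


def compare_auc(
    model_a: MarkerModel,
    model_b: MarkerModel,
    records: pd.DataFrame,
    design: SurveyDesign,
    replicates: ReplicateWeights,
    reference,
    reps_a: Optional[np.ndarray] = None,
    reps_b: Optional[np.ndarray] = None,
):
    """Percentile-bootstrap comparison of two models' weighted AUCs.

    Returns (p_value, AucEstimate for a, AucEstimate for b).  Replicate AUC
    vectors may be passed in to share work across many pairwise comparisons.
    """
    if reps_a is None:
        reps_a = auc_replicates(model_a, records, design, replicates, reference)
    if reps_b is None:
        reps_b = auc_replicates(model_b, records, design, replicates, reference)
    est_a = auc_with_ci(model_a, records, design, replicates, reference, reps_a)
    est_b = auc_with_ci(model_b, records, design, replicates, reference, reps_b)
    ok = np.isfinite(reps_a) & np.isfinite(reps_b)
    p = bootstrap_pvalue_difference(reps_a[ok], reps_b[ok])
    return p, est_a, est_b
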