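"""Cutoff-panel evaluation: Se/Sp/Youden, predictive values, and apparent vs
misclassification-adjusted prevalence.

The adjustment is the Rogan-Gladen estimator: with an apparent (test-based)
prevalence p, and a cutoff's sensitivity Se and specificity Sp estimated on an
independent training sample,

    adjusted = (p + Sp - 1) / (Se + Sp - 1),

clamped to [0, 1] with a flag.  Its CI combines the three estimates'
variances by the delta method (training and validation samples independent)
and is reported on the logit scale, consistent with the Taylor-logit
intervals used everywhere else in the package.

Cutoffs follow the strict-inequality convention of their notation: a value
exactly at a "<148" or ">376" threshold is test-negative.  Percentages are
proportions internally; rendering x100 happens only at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .survey import ProportionEstimate, SurveyDesign, Z_95, weighted_proportion
from .roc import MARKER_COLUMNS

__all__ = [
    "CutoffSpec",
    "PrevalenceEstimate",
    "DiagnosticSummary",
    "apply_cutoff",
    "sens_spec",
    "youden",
    "adjusted_prevalence",
    "predictive_values",
    "evaluate_panel",
    "TRADITIONAL_PANEL",
]

AGE_SPECIFIC = "age_specific_mma"


class UninformativeTestError(ValueError):
    """Se + Sp <= 1: the Rogan-Gladen denominator is non-positive."""


@dataclass(frozen=True)
class CutoffSpec:
    """One cutoff rule: a marker, a direction, and a threshold.

    For the age-specific MMA rule, ``threshold`` is a list of
    ((age_low, age_high), threshold) bands that must cover all ages >= 20
    without overlap; ``age_high = inf`` for the open top band.
    """

    marker: str  # b12 | mma | thcy | age_specific_mma
    direction: str  # "<" or ">"
    threshold: Union[float, Tuple[Tuple[Tuple[float, float], float], ...]]
    label: str
    source: str = ""

    def __post_init__(self):
        if self.direction not in ("<", ">"):
            raise ValueError("direction must be '<' or '>'")
        if self.marker == AGE_SPECIFIC:
            bands = tuple((tuple(map(float, b)), float(t)) for b, t in self.threshold)
            object.__setattr__(self, "threshold", bands)
            edges = sorted(bands)
            if edges[0][0][0] > 20.0:
                raise ValueError("age-specific bands must start at or below age 20")
            for (b1, _), (b2, _) in zip(edges, edges[1:]):
                if b2[0] != b1[1]:
                    raise ValueError("age-specific bands must tile without gaps/overlap")
            if not np.isinf(edges[-1][0][1]):
                raise ValueError("top age band must be open-ended (inf)")
        elif self.marker not in MARKER_COLUMNS:
            raise ValueError(f"unknown marker {self.marker!r}")


# Traditional cutoffs evaluated alongside the ROC-derived optima.
TRADITIONAL_PANEL: Tuple[CutoffSpec, ...] = (
    CutoffSpec("b12", "<", 148.0, "B-12 <148 pmol/L", "low B-12"),
    CutoffSpec("b12", "<", 223.0, "B-12 <223 pmol/L", "inadequate B-12"),
    CutoffSpec("b12", "<", 126.0, "B-12 <126 pmol/L", "high risk of deficiency"),
    CutoffSpec("b12", "<", 287.0, "B-12 <287 pmol/L", "not optimal status"),
    CutoffSpec("mma", ">", 376.0, "MMA >376 nmol/L", "elevated MMA"),
    CutoffSpec("mma", ">", 271.0, "MMA >271 nmol/L", "elevated MMA"),
    CutoffSpec(
        AGE_SPECIFIC,
        ">",
        (((20.0, 40.0), 250.0), ((40.0, 70.0), 290.0), ((70.0, float("inf")), 320.0)),
        "MMA > age-specific",
        "age-specific MMA reference",
    ),
    CutoffSpec("thcy", ">", 13.0, "tHcy >13 umol/L", "elevated tHcy"),
)


def apply_cutoff(spec: CutoffSpec, records: pd.DataFrame) -> np.ndarray:
    """Test-positive indicator under the cutoff (strict inequality)."""
    if spec.marker == AGE_SPECIFIC:
        age = records["age"].to_numpy(dtype=float)
        mma = records["mma_nmol_L"].to_numpy(dtype=float)
        thr = np.full(len(records), np.nan)
        for (lo, hi), t in spec.threshold:
            thr[(age >= lo) & (age < hi)] = t
        if np.any(np.isnan(thr)):
            raise ValueError("record age outside all age-specific bands")
        return mma > thr
    values = records[MARKER_COLUMNS[spec.marker]].to_numpy(dtype=float)
    return values > spec.threshold if spec.direction == ">" else values < spec.threshold


def sens_spec(
    test_positive, reference_positive, design: SurveyDesign
) -> Tuple[ProportionEstimate, ProportionEstimate]:
    """Weighted sensitivity and specificity with Taylor-logit CIs."""
    test = np.asarray(test_positive).astype(bool)
    ref = np.asarray(reference_positive).astype(bool)
    if not ref.any() or ref.all():
        raise ValueError("both reference classes must be non-empty")
    se = weighted_proportion(test.astype(float), design, domain=ref)
    sp = weighted_proportion((~test).astype(float), design, domain=~ref)
    return se, sp


def youden(se: float, sp: float) -> float:
    """Youden's index J = Se + Sp - 1."""
    if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0,1]")
    return se + sp - 1.0


@dataclass(frozen=True)
class PrevalenceEstimate:
    apparent: Optional[ProportionEstimate]
    adjusted: float
    adjusted_ci_low: float
    adjusted_ci_high: float
    se_used: float
    sp_used: float
    clamped: bool = False
    method: str = "rogan-gladen; delta-method logit CI"


def _as_est(x) -> Tuple[float, float]:
    if isinstance(x, ProportionEstimate):
        return x.estimate, x.se
    return float(x), 0.0


def adjusted_prevalence(apparent, se_training, sp_training) -> PrevalenceEstimate:
    """Rogan-Gladen misclassification-corrected prevalence.

    Arguments may be plain proportions or :class:`ProportionEstimate`s; when
    standard errors are available the CI propagates all three variances by
    the delta method on the adjusted scale, then transforms to logit bounds.
    """
    p, var_p = _as_est(apparent)[0], _as_est(apparent)[1] ** 2
    se, var_se = _as_est(se_training)[0], _as_est(se_training)[1] ** 2
    sp, var_sp = _as_est(sp_training)[0], _as_est(sp_training)[1] ** 2

    denom = se + sp - 1.0
    if denom <= 0.0:
        raise UninformativeTestError(
            f"Se + Sp = {se + sp:.4f} <= 1: cutoff carries no information"
        )
    theta = (p + sp - 1.0) / denom
    clamped = not 0.0 <= theta <= 1.0
    theta_c = float(np.clip(theta, 0.0, 1.0))

    # delta method: d/dp = 1/D, d/dse = -theta/D, d/dsp = (1-theta)/D
    var_theta = (var_p + theta**2 * var_se + (1.0 - theta) ** 2 * var_sp) / denom**2
    se_theta = float(np.sqrt(var_theta))

    if theta_c in (0.0, 1.0) or se_theta == 0.0:
        lo = hi = theta_c
    else:
        logit = np.log(theta_c / (1.0 - theta_c))
        half = Z_95 * se_theta / (theta_c * (1.0 - theta_c))
        expit = lambda t: float(1.0 / (1.0 + np.exp(-t)))
        lo, hi = expit(logit - half), expit(logit + half)

    app = apparent if isinstance(apparent, ProportionEstimate) else None
    return PrevalenceEstimate(app, theta_c, lo, hi, se, sp, clamped)


def predictive_values(se: float, sp: float, prevalence: float) -> Tuple[float, float]:
    """Positive and negative predictive value at a stated prevalence."""
    for name, v in (("se", se), ("sp", sp), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    p = prevalence
    ppv_den = se * p + (1.0 - sp) * (1.0 - p)
    npv_den = sp * (1.0 - p) + (1.0 - se) * p
    ppv = se * p / ppv_den if ppv_den > 0 else float("nan")
    npv = sp * (1.0 - p) / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


@dataclass
class DiagnosticSummary:
    cutoff: CutoffSpec
    sensitivity: Optional[ProportionEstimate]
    specificity: Optional[ProportionEstimate]
    youden: Optional[float]
    prevalence: PrevalenceEstimate
    ppv: Optional[float] = None
    npv: Optional[float] = None
    is_reference: bool = False


REFERENCE_SPEC = CutoffSpec(
    "mma", ">", float("nan"), "3cB-12 <= -0.5 (reference)", "combined indicator"
)


def evaluate_panel(
    cutoffs: Sequence[CutoffSpec],
    training: pd.DataFrame,
    validation: pd.DataFrame,
    reference_scorer: Callable[[pd.DataFrame], np.ndarray],
    training_design: SurveyDesign,
    validation_design: SurveyDesign,
) -> List[DiagnosticSummary]:
    """Evaluate a cutoff panel against the combined-indicator reference.

    Per cutoff: Se/Sp/Youden and apparent prevalence on the validation
    sample; the adjustment reuses Se/Sp re-estimated on the training sample.
    The output opens with the reference row (Se = Sp = 1 by construction, so
    apparent = adjusted).  Predictive values are evaluated at the reference
    prevalence.
    """
    ref_train = np.asarray(reference_scorer(training)).astype(bool)
    ref_valid = np.asarray(reference_scorer(validation)).astype(bool)

    ref_prev = weighted_proportion(ref_valid.astype(float), validation_design)
    rows = [
        DiagnosticSummary(
            REFERENCE_SPEC,
            None,
            None,
            None,
            PrevalenceEstimate(
                ref_prev,
                ref_prev.estimate,
                ref_prev.ci_low,
                ref_prev.ci_high,
                1.0,
                1.0,
                method="reference (Se = Sp = 1 by construction)",
            ),
            is_reference=True,
        )
    ]

    for spec in cutoffs:
        se_tr, sp_tr = sens_spec(apply_cutoff(spec, training), ref_train, training_design)
        test_v = apply_cutoff(spec, validation)
        se_v, sp_v = sens_spec(test_v, ref_valid, validation_design)
        apparent = weighted_proportion(test_v.astype(float), validation_design)
        prev = adjusted_prevalence(apparent, se_tr, sp_tr)
        ppv, npv = predictive_values(
            se_v.estimate, sp_v.estimate, ref_prev.estimate
        )
        rows.append(
            DiagnosticSummary(
                spec,
                se_v,
                sp_v,
                youden(se_v.estimate, sp_v.estimate),
                prev,
                ppv,
                npv,
            )
        )
    return rows


def summaries_to_frame(rows: Sequence[DiagnosticSummary]) -> pd.DataFrame:
    """Reporting-layer table: percentages rendered x100, full precision kept."""
    recs = []
    for r in rows:
        prev = r.prevalence
        app = prev.apparent
        recs.append(
            {
                "cutoff": r.cutoff.label,
                "sensitivity_pct": None if r.sensitivity is None else 100 * r.sensitivity.estimate,
                "sensitivity_ci_low_pct": None if r.sensitivity is None else 100 * r.sensitivity.ci_low,
                "sensitivity_ci_high_pct": None if r.sensitivity is None else 100 * r.sensitivity.ci_high,
                "specificity_pct": None if r.specificity is None else 100 * r.specificity.estimate,
                "specificity_ci_low_pct": None if r.specificity is None else 100 * r.specificity.ci_low,
                "specificity_ci_high_pct": None if r.specificity is None else 100 * r.specificity.ci_high,
                "youden": r.youden,
                "apparent_prevalence_pct": None if app is None else 100 * app.estimate,
                "apparent_ci_low_pct": None if app is None else 100 * app.ci_low,
                "apparent_ci_high_pct": None if app is None else 100 * app.ci_high,
                "adjusted_prevalence_pct": 100 * prev.adjusted,
                "adjusted_ci_low_pct": 100 * prev.adjusted_ci_low,
                "adjusted_ci_high_pct": 100 * prev.adjusted_ci_high,
                "se_used_pct": 100 * prev.se_used,
                "sp_used_pct": 100 * prev.sp_used,
                "clamped": prev.clamped,
                "ppv_pct": None if r.ppv is None else 100 * r.ppv,
                "npv_pct": None if r.npv is None else 100 * r.npv,
                "adjustment_method": prev.method,
                "is_reference": r.is_reference,
            }
        )
    return pd.DataFrame(recs)
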