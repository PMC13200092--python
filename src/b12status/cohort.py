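"""Inclusion/exclusion cascade building the analytic sample.

Exclusions are applied sequentially in a fixed, documented order, and each
record is attributed to the first criterion it fails:

1. incomplete biomarker panel (missing any of B-12, MMA, tHcy);
2. age < 20 y;
3. pregnant and/or lactating (missing flags count as not pregnant/lactating,
   mirroring survey skip patterns: exclusions apply only when eligibility is
   explicitly met);
4. abnormal renal function (eGFR < 60 mL/(min x 1.73 m2) or albuminuria),
   applied only under the ``normal_only`` restriction; records whose renal
   inputs are missing cannot be classified and are excluded at this step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

from .indicators import classify_renal, egfr_values

__all__ = ["AnalyticSample", "build_analytic_sample", "EXCLUSION_ORDER", "EmptySampleError"]

EXCLUSION_ORDER = (
    "incomplete_markers",
    "age_under_20",
    "pregnant_or_lactating",
    "abnormal_renal",
)

NORMAL_ONLY = "normal_only"
ALL_ADULTS = "all_adults"


class EmptySampleError(ValueError):
    """All records were excluded; downstream estimators are undefined."""


@dataclass
class AnalyticSample:
    records: pd.DataFrame
    exclusion_log: List[Tuple[str, int]]
    renal_restriction: str

    @property
    def n(self) -> int:
        return len(self.records)

    def attrition_frame(self) -> pd.DataFrame:
        rows = [("input", self.n + sum(c for _, c in self.exclusion_log))]
        rows += [(f"excluded_{name}", c) for name, c in self.exclusion_log]
        rows.append(("included", self.n))
        return pd.DataFrame(rows, columns=["step", "count"])


def _fail_masks(frame: pd.DataFrame, renal_restriction: str) -> dict:
    marker_cols = ["b12_pmol_L", "mma_nmol_L", "thcy_umol_L"]
    incomplete = frame[marker_cols].isna().any(axis=1).to_numpy()
    under_20 = (frame["age"].to_numpy(dtype=float) < 20.0) | frame["age"].isna().to_numpy()
    preg = frame["pregnant"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    lact = frame["lactating"].astype("boolean").fillna(False).to_numpy(dtype=bool)

    if renal_restriction == NORMAL_ONLY:
        cre = frame["creatinine_mg_dL"]
        alb = frame["albuminuria"]
        missing_renal = cre.isna().to_numpy() | alb.isna().to_numpy()
        abnormal = np.ones(len(frame), dtype=bool)
        ok = ~missing_renal
        if ok.any():
            egfr = egfr_values(
                cre.to_numpy(dtype=float)[ok],
                frame["age"].to_numpy(dtype=float)[ok],
                (frame["sex"].to_numpy() == "female")[ok],
            )
            abnormal_ok = (
                classify_renal(egfr, alb.to_numpy()[ok].astype(bool)) == "abnormal"
            )
            abnormal[ok] = abnormal_ok
    elif renal_restriction == ALL_ADULTS:
        abnormal = np.zeros(len(frame), dtype=bool)
    else:
        raise ValueError(
            f"renal_restriction must be {NORMAL_ONLY!r} or {ALL_ADULTS!r}, "
            f"got {renal_restriction!r}"
        )

    return {
        "incomplete_markers": incomplete,
        "age_under_20": under_20,
        "pregnant_or_lactating": preg | lact,
        "abnormal_renal": abnormal,
    }


def build_analytic_sample(
    records: pd.DataFrame, renal_restriction: str = NORMAL_ONLY
) -> AnalyticSample:
    """Apply the exclusion cascade; idempotent on its own output."""
    masks = _fail_masks(records, renal_restriction)
    remaining = np.ones(len(records), dtype=bool)
    log: List[Tuple[str, int]] = []
    for name in EXCLUSION_ORDER:
        hit = remaining & masks[name]
        log.append((name, int(hit.sum())))
        remaining &= ~hit
    if not remaining.any():
        raise EmptySampleError("exclusion cascade removed every record")
    included = records.loc[remaining].reset_index(drop=True)
    return AnalyticSample(included, log, renal_restriction)
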