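"""Vitamin B-12 status indicators and renal-function classification.

This module computes the combined indicator of vitamin B-12 status (cB-12),
classifies status at the epidemiological inadequate/adequate boundary, and
implements the race-free CKD-EPI creatinine eGFR equation used to define
normal renal function.

The combined indicator integrates the circulating markers — total cobalamin
(B-12, pmol/L), methylmalonic acid (MMA, nmol/L), total homocysteine
(tHcy, µmol/L), and optionally holotranscobalamin (holoTC, pmol/L) — with the
participant's age.  The canonical 4-marker form is

    4cB-12 = log10[(holoTC × B-12) / (MMA × tHcy)] − age_factor(age)

When holoTC is unavailable (the common population-survey situation) a
modified 3-marker form on the same scale is used.  Its numeric constants are
not hard-coded: they live in a versioned :class:`Cb12Constants` object which
every computation requires explicitly and which is echoed into result files
for provenance.  The packaged default is a documented transcription choice
(see ``constants/cb12_constants.yaml`` and docs/methods.md); analyses of real
data should load constants verified against the combined-indicator
literature (Fedosov et al.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "MarkerPanel",
    "Cb12Constants",
    "Cb12Score",
    "RenalInputs",
    "CkdEpiParams",
    "CKD_EPI_2021",
    "MissingMarkerError",
    "MarkerDomainError",
    "cb12_four_marker",
    "cb12_three_marker",
    "cb12_three_marker_values",
    "classify_status",
    "egfr_ckdepi",
    "egfr_values",
    "classify_renal",
    "albuminuria_from_acr",
    "INADEQUATE",
    "ADEQUATE",
]

INADEQUATE = "inadequate"
ADEQUATE = "adequate"

DEFAULT_STATUS_CUTOFF = -0.5


class MissingMarkerError(ValueError):
    """A required biomarker is absent from the panel."""


class MarkerDomainError(ValueError):
    """A biomarker concentration is outside the log domain (must be > 0)."""


@dataclass(frozen=True)
class MarkerPanel:
    """One participant's biomarker panel.

    Units: b12 pmol/L, mma nmol/L, thcy µmol/L, holotc pmol/L, age years.
    """

    b12: float
    mma: float
    thcy: float
    age: float
    holotc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        for name in ("b12", "mma", "thcy"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise MarkerDomainError(
                    f"marker {name!r} must be strictly positive, got {v}"
                )
        if self.holotc is not None and not self.holotc > 0:
            raise MarkerDomainError(
                f"marker 'holotc' must be strictly positive, got {self.holotc}"
            )


@dataclass(frozen=True)
class Cb12Constants:
    """Versioned constants of the combined-indicator equations.

    The 3-marker form is the parametric family

        3cB-12 = e_b·log10(B-12) + e_m·log10(MMA) + e_t·log10(tHcy)
                 + offset − age_factor(age)

    with ``age_factor(age) = Σ_k c_k (age/100)^k``.  The 4-marker form uses
    the printed log-ratio skeleton with the same age factor.  Constants are
    explicit configuration: computations never fall back to hidden defaults,
    and the object is serialized into every results manifest.
    """

    version: str
    citation: str
    three_marker_exponents: dict  # keys b12, mma, thcy
    three_marker_offset: float
    age_factor_coeffs: tuple  # polynomial coefficients in (age/100), ascending
    status_cutoff: float = DEFAULT_STATUS_CUTOFF

    def __post_init__(self) -> None:
        exps = self.three_marker_exponents
        missing = {"b12", "mma", "thcy"} - set(exps)
        if missing:
            raise ValueError(f"three_marker_exponents missing {sorted(missing)}")
        if not exps["b12"] > 0:
            raise ValueError("b12 exponent must be positive (score rises with B-12)")
        if not (exps["mma"] < 0 and exps["thcy"] < 0):
            raise ValueError("mma and thcy exponents must be negative")
        object.__setattr__(self, "age_factor_coeffs", tuple(self.age_factor_coeffs))

    def age_factor(self, age):
        """Age term subtracted from the score; polynomial in age/100."""
        a = np.asarray(age, dtype=float) / 100.0
        out = np.zeros_like(a)
        for k, c in enumerate(self.age_factor_coeffs):
            out = out + c * a**k
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_factor_coeffs"] = list(self.age_factor_coeffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Cb12Constants":
        d = dict(d)
        d["age_factor_coeffs"] = tuple(d["age_factor_coeffs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Cb12Constants":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def packaged_default(cls) -> "Cb12Constants":
        """Load the constants file shipped with the package."""
        ref = resources.files("b12status").joinpath("constants/cb12_constants.yaml")
        with ref.open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class Cb12Score:
    value: float
    n_markers: int
    status: str
    status_cutoff: float = DEFAULT_STATUS_CUTOFF

    def __post_init__(self) -> None:
        expected = INADEQUATE if self.value <= self.status_cutoff else ADEQUATE
        if self.status != expected:
            raise ValueError(
                f"status {self.status!r} inconsistent with value {self.value} "
                f"at cutoff {self.status_cutoff}"
            )


def classify_status(value, cutoff: float = DEFAULT_STATUS_CUTOFF):
    """Classify cB-12: inadequate iff value <= cutoff (boundary inclusive).

    Accepts a scalar, an array, or a :class:`Cb12Score` (whose own cutoff is
    then used unless one is passed explicitly).
    """
    if isinstance(value, Cb12Score):
        cutoff = value.status_cutoff if cutoff == DEFAULT_STATUS_CUTOFF else cutoff
        value = value.value
    arr = np.asarray(value, dtype=float)
    out = np.where(arr <= cutoff, INADEQUATE, ADEQUATE)
    return out if arr.ndim else str(out)


def cb12_four_marker(panel: MarkerPanel, constants: Cb12Constants) -> Cb12Score:
    """4-marker combined indicator: log10[(holoTC·B-12)/(MMA·tHcy)] − age factor."""
    if panel.holotc is None:
        raise MissingMarkerError(
            "holoTC is missing; use cb12_three_marker for the 3-marker form"
        )
    value = (
        math.log10((panel.holotc * panel.b12) / (panel.mma * panel.thcy))
        - constants.age_factor(panel.age)
    )
    cutoff = constants.status_cutoff
    return Cb12Score(value, 4, classify_status(value, cutoff), cutoff)


def cb12_three_marker_values(b12, mma, thcy, age, constants: Cb12Constants):
    """Vectorized 3cB-12 over arrays of concentrations and ages."""
    b12 = np.asarray(b12, dtype=float)
    mma = np.asarray(mma, dtype=float)
    thcy = np.asarray(thcy, dtype=float)
    for name, arr in (("b12", b12), ("mma", mma), ("thcy", thcy)):
        if np.any(~(arr > 0)):
            raise MarkerDomainError(f"marker {name!r} has non-positive values")
    e = constants.three_marker_exponents
    return (
        e["b12"] * np.log10(b12)
        + e["mma"] * np.log10(mma)
        + e["thcy"] * np.log10(thcy)
        + constants.three_marker_offset
        - constants.age_factor(age)
    )


def cb12_three_marker(panel: MarkerPanel, constants: Cb12Constants) -> Cb12Score:
    """Modified 3-marker combined indicator (holoTC unavailable)."""
    value = float(
        cb12_three_marker_values(panel.b12, panel.mma, panel.thcy, panel.age, constants)
    )
    cutoff = constants.status_cutoff
    return Cb12Score(value, 3, classify_status(value, cutoff), cutoff)


# ---------------------------------------------------------------------------
# Renal function


@dataclass(frozen=True)
class RenalInputs:
    """Inputs of the eGFR/albuminuria renal classification."""

    creatinine: float  # serum creatinine, mg/dL
    age: float
    sex: str  # "female" | "male"
    albuminuria: bool

    def __post_init__(self) -> None:
        if not self.creatinine > 0:
            raise ValueError(f"creatinine must be > 0, got {self.creatinine}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass(frozen=True)
class CkdEpiParams:
    """Coefficients of the race-free CKD-EPI creatinine equation (2021).

    eGFR = scale · min(Scr/κ, 1)^α · max(Scr/κ, 1)^β · age_base^age · sex_mult
    with sex-specific κ and α; units mL/(min × 1.73 m²).
    """

    scale: float = 142.0
    kappa_female: float = 0.7
    kappa_male: float = 0.9
    alpha_female: float = -0.241
    alpha_male: float = -0.302
    beta: float = -1.200
    age_base: float = 0.9938
    female_multiplier: float = 1.012

    def to_dict(self) -> dict:
        return asdict(self)


CKD_EPI_2021 = CkdEpiParams()

EGFR_NORMAL_THRESHOLD = 60.0  # mL/(min × 1.73 m²)


def egfr_values(creatinine, age, female, params: CkdEpiParams = CKD_EPI_2021):
    """Vectorized race-free CKD-EPI eGFR. `female` is boolean (array-like)."""
    scr = np.asarray(creatinine, dtype=float)
    if np.any(~(scr > 0)):
        raise ValueError("creatinine must be strictly positive")
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=bool)
    kappa = np.where(female, params.kappa_female, params.kappa_male)
    alpha = np.where(female, params.alpha_female, params.alpha_male)
    ratio = scr / kappa
    out = (
        params.scale
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** params.beta
        * params.age_base**age
        * np.where(female, params.female_multiplier, 1.0)
    )
    return out if out.ndim else float(out)


def egfr_ckdepi(r: RenalInputs, params: CkdEpiParams = CKD_EPI_2021) -> float:
    """Race-free CKD-EPI creatinine eGFR for one participant (age >= 18)."""
    if r.age < 18:
        raise ValueError("CKD-EPI creatinine equation applies to adults (age >= 18)")
    return float(egfr_values(r.creatinine, r.age, r.sex == "female", params))


def classify_renal(egfr, albuminuria, threshold: float = EGFR_NORMAL_THRESHOLD):
    """Normal renal function iff eGFR >= threshold AND albuminuria absent.

    Boundary inclusive: eGFR exactly at the threshold is normal.
    """
    egfr_arr = np.asarray(egfr, dtype=float)
    alb = np.asarray(albuminuria, dtype=bool)
    out = np.where((egfr_arr >= threshold) & ~alb, "normal", "abnormal")
    return out if egfr_arr.ndim or alb.ndim else str(out)


def albuminuria_from_acr(acr_mg_g, threshold: float = 30.0):
    """Urinary albumin/creatinine ratio (mg/g) to albuminuria indicator.

    The default threshold (ACR >= 30 mg/g) follows the National Kidney
    Foundation staging convention; it is configuration, not a constant baked
    into the classifier.
    """
    arr = np.asarray(acr_mg_g, dtype=float)
    out = arr >= threshold
    return out if arr.ndim else bool(out)
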