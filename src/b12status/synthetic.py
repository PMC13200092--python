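"""Seeded synthetic survey populations with known vitamin B-12 ground truth.

Emulates the statistical structure the downstream analysis assumes: a
stratified design with (by default) two PSUs per stratum and unequal
log-normal examination weights; mutually correlated, approximately log-normal
biomarker distributions; a low-prevalence latent "inadequate" class that
lowers B-12 and raises MMA/tHcy; an age trend in MMA; and a renal-impairment
subgroup with elevated MMA and tHcy independent of B-12 status.  Creatinine
and albuminuria are generated by exact inversion of the CKD-EPI classifier so
the intended renal flag is reproduced downstream without ambiguity.

Truth labels (latent class, renal flag) live in a sidecar frame so the
analysis pipeline proper never sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Tuple

import numpy as np
import pandas as pd

from .indicators import CKD_EPI_2021, CkdEpiParams, egfr_values, classify_renal

__all__ = ["SyntheticConfig", "SyntheticPopulation", "generate_population", "split_cycles"]

MARKERS = ("b12", "mma", "thcy")

# Participant CSV schema shared with cli_io.
SCHEMA_COLUMNS = [
    "id", "age", "sex", "pregnant", "lactating",
    "b12_pmol_L", "mma_nmol_L", "thcy_umol_L",
    "creatinine_mg_dL", "albuminuria",
    "stratum", "psu", "weight", "cycle",
]


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration.

    Marker locations/scales are on the log10 scale in the analysis units
    (B-12 pmol/L, MMA nmol/L, tHcy µmol/L).  Defaults define the package's
    reference study conditions: ~3% latent prevalence, class separations
    giving single-marker discrimination in the low-to-mid 0.9s, 15 strata of
    2 PSUs × 120 participants.
    """

    n_strata: int = 15
    psus_per_stratum: int = 2
    n_per_psu: int = 120
    prevalence_inadequate: float = 0.03
    marker_log_means_adequate: Tuple[float, float, float] = (2.60, 2.09, 0.90)
    marker_log_means_inadequate: Tuple[float, float, float] = (2.18, 2.55, 1.22)
    marker_log_sds: Tuple[float, float, float] = (0.22, 0.20, 0.17)
    marker_correlation: Tuple[Tuple[float, ...], ...] = (
        (1.0, -0.30, -0.25),
        (-0.30, 1.0, 0.35),
        (-0.25, 0.35, 1.0),
    )
    age_range: Tuple[float, float] = (20.0, 85.0)
    mma_age_slope: float = 0.02  # log10 MMA per decade, centred at age 50
    renal_impairment_rate: float = 0.08
    renal_mma_shift: float = 0.15
    renal_thcy_shift: float = 0.12
    pregnancy_rate: float = 0.06  # among females aged 20-44
    weight_dispersion: float = 0.5  # CV of weights around equal allocation
    base_weight: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strata", "psus_per_stratum", "n_per_psu"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        for name in ("renal_impairment_rate", "pregnancy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InvalidConfigError(f"{name} must be in [0,1), got {v}")
        if not 0.0 <= self.prevalence_inadequate < 1.0:
            raise InvalidConfigError("prevalence_inadequate must be in [0,1)")
        corr = np.asarray(self.marker_correlation, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise InvalidConfigError("marker_correlation must be a symmetric 3x3 matrix")
        if np.min(np.linalg.eigvalsh(corr)) <= 0:
            raise InvalidConfigError("marker_correlation is not positive-definite")
        lo_a, lo_i = self.marker_log_means_adequate, self.marker_log_means_inadequate
        if not (lo_i[0] < lo_a[0] and lo_i[1] > lo_a[1] and lo_i[2] > lo_a[2]):
            raise InvalidConfigError(
                "inadequate class must have lower B-12 and higher MMA/tHcy means"
            )
        if not all(s > 0 for s in self.marker_log_sds):
            raise InvalidConfigError("marker_log_sds must be positive")
        if not self.age_range[0] < self.age_range[1]:
            raise InvalidConfigError("age_range must be increasing")
        if self.weight_dispersion < 0:
            raise InvalidConfigError("weight_dispersion must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marker_correlation"] = [list(r) for r in self.marker_correlation]
        return d

    @property
    def n_records(self) -> int:
        return self.n_strata * self.psus_per_stratum * self.n_per_psu


@dataclass
class SyntheticPopulation:
    """Generated records plus the ground-truth sidecar.

    ``frame`` follows the participant CSV schema; ``truth`` carries per-record
    latent status and renal flag, indexed like ``frame``.
    """

    frame: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig
    seed: int
    nominal_total: float

    def weighted_truth_prevalence(self) -> float:
        w = self.frame["weight"].to_numpy()
        y = (self.truth["truth_status"] == "inadequate").to_numpy(dtype=float)
        return float(np.sum(w * y) / np.sum(w))

    def validate(self) -> None:
        if (self.frame["weight"] <= 0).any():
            raise ValueError("all weights must be strictly positive")
        if self.frame["stratum"].isna().any() or self.frame["psu"].isna().any():
            raise ValueError("every record needs a stratum and PSU")


def _invert_egfr(target_egfr, age, female, params: CkdEpiParams):
    """Serum creatinine producing exactly the target eGFR for age/sex."""
    target = np.asarray(target_egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=bool)
    kappa = np.where(female, params.kappa_female, params.kappa_male)
    alpha = np.where(female, params.alpha_female, params.alpha_male)
    # eGFR at Scr = kappa (both power pieces equal 1)
    at_knot = params.scale * params.age_base**age * np.where(
        female, params.female_multiplier, 1.0
    )
    ratio = np.where(
        target <= at_knot,
        (target / at_knot) ** (1.0 / params.beta),   # Scr above kappa
        (target / at_knot) ** (1.0 / alpha),          # Scr below kappa
    )
    return kappa * ratio


def generate_population(config: SyntheticConfig) -> SyntheticPopulation:
    """Draw one population; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_records

    strata = np.repeat(
        [f"S{i + 1:02d}" for i in range(config.n_strata)],
        config.psus_per_stratum * config.n_per_psu,
    )
    psus = np.tile(
        np.repeat([f"P{j + 1}" for j in range(config.psus_per_stratum)], config.n_per_psu),
        config.n_strata,
    )

    age = rng.uniform(*config.age_range, size=n)
    female = rng.random(n) < 0.5
    sex = np.where(female, "female", "male")

    eligible = female & (age >= 20) & (age <= 44)
    pregnant = eligible & (rng.random(n) < config.pregnancy_rate)
    lactating = eligible & ~pregnant & (rng.random(n) < config.pregnancy_rate / 2)

    inadequate = rng.random(n) < config.prevalence_inadequate

    mu_a = np.asarray(config.marker_log_means_adequate)
    mu_i = np.asarray(config.marker_log_means_inadequate)
    mu = np.where(inadequate[:, None], mu_i, mu_a)
    sds = np.asarray(config.marker_log_sds)
    corr = np.asarray(config.marker_correlation, dtype=float)
    chol = np.linalg.cholesky(np.diag(sds) @ corr @ np.diag(sds))
    logs = mu + rng.standard_normal((n, 3)) @ chol.T

    logs[:, 1] += config.mma_age_slope * (age - 50.0) / 10.0

    renal_impaired = rng.random(n) < config.renal_impairment_rate
    logs[renal_impaired, 1] += config.renal_mma_shift
    logs[renal_impaired, 2] += config.renal_thcy_shift

    markers = 10.0**logs

    # Renal inputs generated backwards from the intended flag so the eGFR /
    # albuminuria classifier reproduces it exactly downstream.
    low_egfr = renal_impaired & (rng.random(n) < 0.75)
    target = rng.uniform(65.0, 115.0, size=n)            # renal-normal default
    target[low_egfr] = rng.uniform(25.0, 59.0, size=int(low_egfr.sum()))
    albuminuria = np.zeros(n, dtype=bool)
    albuminuria[renal_impaired & ~low_egfr] = True
    albuminuria[low_egfr] = rng.random(int(low_egfr.sum())) < 0.4
    creatinine = _invert_egfr(target, age, female, CKD_EPI_2021)

    check = classify_renal(egfr_values(creatinine, age, female), albuminuria)
    assert np.array_equal(check == "abnormal", renal_impaired)

    cv = config.weight_dispersion
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        weight = config.base_weight * rng.lognormal(-(sigma**2) / 2, sigma, size=n)
    else:
        weight = np.full(n, config.base_weight)

    frame = pd.DataFrame(
        {
            "id": [f"p{i + 1:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "pregnant": pregnant,
            "lactating": lactating,
            "b12_pmol_L": markers[:, 0],
            "mma_nmol_L": markers[:, 1],
            "thcy_umol_L": markers[:, 2],
            "creatinine_mg_dL": creatinine,
            "albuminuria": albuminuria,
            "stratum": strata,
            "psu": psus,
            "weight": weight,
            "cycle": "all",
        }
    )[SCHEMA_COLUMNS]
    truth = pd.DataFrame(
        {
            "id": frame["id"],
            "truth_status": np.where(inadequate, "inadequate", "adequate"),
            "renal_impaired": renal_impaired,
        }
    )
    pop = SyntheticPopulation(frame, truth, config, config.seed, float(weight.sum()))
    pop.validate()
    return pop


def split_cycles(
    pop: SyntheticPopulation, fraction_training: float
) -> Tuple[SyntheticPopulation, SyntheticPopulation]:
    """Partition whole strata into a training and a validation cycle.

    Each split's weights are rescaled to sum to the parent population total,
    mirroring how multi-year and single-cycle survey weights each represent
    the same target population.
    """
    if not 0.0 < fraction_training < 1.0:
        raise ValueError("fraction_training must be in (0,1)")
    strata = sorted(pop.frame["stratum"].unique())
    if len(strata) < 2:
        raise ValueError("need at least 2 strata to split into cycles")
    k = int(round(fraction_training * len(strata)))
    k = min(max(k, 1), len(strata) - 1)
    train_strata = set(strata[:k])

    out = []
    for name, keep in (("training", True), ("validation", False)):
        mask = pop.frame["stratum"].isin(train_strata)
        if not keep:
            mask = ~mask
        frame = pop.frame.loc[mask].copy()
        frame["cycle"] = name
        frame["weight"] *= pop.nominal_total / frame["weight"].sum()
        truth = pop.truth.loc[mask].copy()
        sub = SyntheticPopulation(
            frame.reset_index(drop=True),
            truth.reset_index(drop=True),
            pop.config,
            pop.seed,
            pop.nominal_total,
        )
        sub.validate()
        out.append(sub)
    return out[0], out[1]
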