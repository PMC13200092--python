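"""Design-based estimation for stratified multistage samples.

Provides weighted domain proportions with Taylor-linearized standard errors
and logit-transformed confidence intervals, the Rao-Wu-Yue rescaled
stratified-PSU bootstrap (as replicate weights), percentile bootstrap
intervals, and paired bootstrap p-values.  Variance estimation treats PSUs as
sampled with replacement within strata, the standard approximation for
surveys of the NHANES type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "ReplicateWeights",
    "ProportionEstimate",
    "weighted_proportion",
    "make_replicate_weights",
    "percentile_ci",
    "bootstrap_pvalue_difference",
    "Z_95",
]

Z_95 = 1.959964  # normal 97.5th percentile, as conventionally rounded


class SinglePsuStratumError(ValueError):
    """A stratum contributes a single PSU; collapse or combine strata before
    variance estimation / bootstrap resampling."""


@dataclass(frozen=True)
class SurveyDesign:
    """Per-record design variables: stratum, PSU nested in stratum, weight."""

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        stratum = np.asarray(self.stratum)
        psu = np.asarray(self.psu)
        weight = np.asarray(self.weight, dtype=float)
        if not (len(stratum) == len(psu) == len(weight)):
            raise ValueError("stratum, psu, weight must have equal length")
        if np.any(~(weight > 0)):
            raise ValueError("weights must be strictly positive")
        object.__setattr__(self, "stratum", stratum)
        object.__setattr__(self, "psu", psu)
        object.__setattr__(self, "weight", weight)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurveyDesign":
        return cls(
            frame["stratum"].to_numpy(),
            frame["psu"].to_numpy(),
            frame["weight"].to_numpy(dtype=float),
        )

    def __len__(self) -> int:
        return len(self.weight)

    def psu_codes(self):
        """Integer codes: stratum index per record, global PSU index per record."""
        strata, s_idx = np.unique(self.stratum, return_inverse=True)
        combo = np.char.add(
            np.char.add(self.stratum.astype(str), "\x1f"), self.psu.astype(str)
        )
        psus, p_idx = np.unique(combo, return_inverse=True)
        # stratum index of each global PSU
        psu_stratum = np.zeros(len(psus), dtype=int)
        psu_stratum[p_idx] = s_idx
        return s_idx, p_idx, psu_stratum, len(strata), len(psus)


@dataclass(frozen=True)
class ProportionEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 1.0):
            raise ValueError(
                f"invalid interval ordering: "
                f"({self.ci_low}, {self.estimate}, {self.ci_high})"
            )


def _taylor_se_ratio(z: np.ndarray, design: SurveyDesign) -> float:
    """With-replacement stratified SE of a total of linearized scores z.

    z is the per-record linearized contribution; PSU totals are formed within
    strata and the usual (n_h/(n_h-1)) * sum of squared deviations applies.
    """
    s_idx, p_idx, psu_stratum, n_strata, n_psus = design.psu_codes()
    psu_tot = np.bincount(p_idx, weights=z, minlength=n_psus)
    var = 0.0
    for h in range(n_strata):
        tot_h = psu_tot[psu_stratum == h]
        n_h = len(tot_h)
        if n_h < 2:
            raise SinglePsuStratumError(
                f"stratum {h} has a single PSU; combine strata before "
                "variance estimation"
            )
        var += n_h / (n_h - 1) * np.sum((tot_h - tot_h.mean()) ** 2)
    return float(np.sqrt(var))


def weighted_proportion(
    y,
    design: SurveyDesign,
    domain=None,
    level: float = 0.95,
) -> ProportionEstimate:
    """Weighted domain proportion with Taylor-logit confidence interval.

    estimate = sum(w*y)/sum(w) over the domain; the SE comes from stratified
    with-replacement linearization of the ratio estimator (records outside
    the domain contribute zero scores but the design structure is kept); the
    CI is computed on the logit scale and back-transformed.  Degenerate
    estimates (0 or 1) are returned with a collapsed CI and flagged.
    """
    y = np.asarray(y, dtype=float)
    if domain is None:
        domain = np.ones(len(y), dtype=bool)
    domain = np.asarray(domain, dtype=bool)
    if not domain.any():
        raise ValueError("domain is empty")
    if np.any((y[domain] != 0) & (y[domain] != 1)):
        raise ValueError("y must be a 0/1 indicator within the domain")

    w = design.weight
    wd = w * domain
    total = wd.sum()
    p = float(np.sum(wd * y) / total)

    z_scores = wd * (y - p) / total
    se = _taylor_se_ratio(z_scores, design)

    if p in (0.0, 1.0) or se == 0.0:
        return ProportionEstimate(p, se, p, p, degenerate=True)

    zq = stats.norm.ppf(0.5 + level / 2) if level != 0.95 else Z_95
    logit = np.log(p / (1 - p))
    half = zq * se / (p * (1 - p))
    lo, hi = logit - half, logit + half
    expit = lambda t: 1.0 / (1.0 + np.exp(-t))
    return ProportionEstimate(p, se, float(expit(lo)), float(expit(hi)))


@dataclass(frozen=True)
class ReplicateWeights:
    """B replicate weight vectors over the same records (records x B)."""

    matrix: np.ndarray
    seed: int
    method: str = "rao-wu-yue-rescaled"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("replicate weights must be a 2-D records-by-B matrix")
        if np.any(m < 0):
            raise ValueError("replicate weights must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def n_replicates(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self, ids) -> pd.DataFrame:
        """Wide export for audit: record id + one column per replicate."""
        df = pd.DataFrame(
            self.matrix, columns=[f"rep{b + 1:04d}" for b in range(self.n_replicates)]
        )
        df.insert(0, "id", np.asarray(ids))
        return df


def make_replicate_weights(
    design: SurveyDesign, B: int = 2000, seed: int = 0
) -> ReplicateWeights:
    """Rao-Wu-Yue rescaled stratified PSU bootstrap replicate weights.

    Within each stratum of n_h PSUs, n_h - 1 PSUs are resampled with
    replacement; the weight multiplier for records in PSU j is
    (n_h/(n_h-1)) * (times PSU j was drawn), whose expectation is 1, so each
    record's replicate weight is unbiased for its base weight.  With the
    NHANES-style n_h = 2, every replicate doubles one PSU of each stratum and
    zeroes the other.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    s_idx, p_idx, psu_stratum, n_strata, n_psus = design.psu_codes()

    multipliers = np.empty((n_psus, B))
    for h in range(n_strata):
        members = np.flatnonzero(psu_stratum == h)
        n_h = len(members)
        if n_h < 2:
            raise SinglePsuStratumError(
                f"stratum index {h} has a single PSU; combine strata before "
                "bootstrap resampling"
            )
        draws = rng.integers(0, n_h, size=(n_h - 1, B))
        counts = np.zeros((n_h, B))
        for j in range(n_h):
            counts[j] = (draws == j).sum(axis=0)
        multipliers[members] = n_h / (n_h - 1) * counts

    matrix = design.weight[:, None] * multipliers[p_idx]
    rep = ReplicateWeights(matrix, seed)
    totals = matrix.sum(axis=0)
    base = design.weight.sum()
    if np.any(totals > 3 * base) or np.any(totals < base / 3):
        raise ValueError("replicate totals outside sanity bound (factor 3 of base)")
    return rep


def percentile_ci(values, level: float = 0.95):
    """Empirical percentile interval of replicate statistic values.

    Uses linear interpolation between order statistics (numpy's default
    quantile definition); requires at least 50 finite replicates.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if len(finite) < 50:
        raise ValueError(
            f"need >= 50 finite replicate values for a percentile CI, got {len(finite)}"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(finite, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def bootstrap_pvalue_difference(stat_a, stat_b) -> float:
    """Two-sided percentile-bootstrap p-value for a paired AUC/statistic
    difference, floored at 1/B.

    p = min(1, max(2 * min(P(diff <= 0), P(diff >= 0)), 1/B)).
    """
    a = np.asarray(stat_a, dtype=float)
    b = np.asarray(stat_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must have equal length (paired)")
    diff = a - b
    diff = diff[np.isfinite(diff)]
    B = len(diff)
    if B == 0:
        raise ValueError("no finite replicate differences")
    frac_le = np.mean(diff <= 0)
    frac_ge = np.mean(diff >= 0)
    p = 2.0 * min(frac_le, frac_ge)
    return float(min(1.0, max(p, 1.0 / B)))
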