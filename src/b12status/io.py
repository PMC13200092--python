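"""File I/O, run configuration, and the two-phase train/validate pipeline.

The native input is a documented participant CSV schema (one row per
participant; blank cells are missing):

    id, age, sex, pregnant, lactating, b12_pmol_L, mma_nmol_L, thcy_umol_L,
    creatinine_mg_dL, albuminuria, stratum, psu, weight, cycle

``run_pipeline`` ties the stages together: cohort exclusions -> combined
indicator reference -> weighted ROC model grid -> optimum cutoffs (training)
-> cutoff panel with apparent/adjusted prevalence (validation).  Every output
carries the configuration echo, the cB-12 constants version, and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import NORMAL_ONLY, build_analytic_sample
from .diagnostics import (
    AGE_SPECIFIC,
    CutoffSpec,
    TRADITIONAL_PANEL,
    evaluate_panel,
    summaries_to_frame,
)
from .indicators import CKD_EPI_2021, Cb12Constants, cb12_three_marker_values, classify_renal, classify_status, egfr_values
from .roc import (
    MARKER_COLUMNS,
    MARKER_ORIENTATION,
    auc_replicates,
    auc_with_ci,
    fit_marker_model,
    optimum_cutoff,
)
from .survey import SurveyDesign, bootstrap_pvalue_difference, make_replicate_weights
from .synthetic import SCHEMA_COLUMNS, SyntheticConfig, generate_population, split_cycles

logger = logging.getLogger("b12status")

__all__ = [
    "ParticipantRecord",
    "RunConfig",
    "SchemaError",
    "read_participants",
    "write_participants",
    "score_participants",
    "run_pipeline",
    "PipelineResult",
    "MODEL_GRID",
]

NUMERIC_COLUMNS = [
    "age", "b12_pmol_L", "mma_nmol_L", "thcy_umol_L", "creatinine_mg_dL", "weight",
]
BOOLEAN_COLUMNS = ["pregnant", "lactating", "albuminuria"]

# Table-1-style grid: three singles, three pairs, one triple.
MODEL_GRID: Tuple[Tuple[str, ...], ...] = (
    ("b12",), ("mma",), ("thcy",),
    ("b12", "mma"), ("b12", "thcy"), ("mma", "thcy"),
    ("mma", "thcy", "b12"),
)


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant row of the CSV schema (missing values are None)."""

    id: str
    age: float
    sex: str
    pregnant: Optional[bool]
    lactating: Optional[bool]
    b12_pmol_L: Optional[float]
    mma_nmol_L: Optional[float]
    thcy_umol_L: Optional[float]
    creatinine_mg_dL: Optional[float]
    albuminuria: Optional[bool]
    stratum: str
    psu: str
    weight: float
    cycle: str


def _parse_bool(raw: pd.Series, col: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False, "": None}
    lowered = raw.str.strip().str.lower()
    bad = ~lowered.isin(mapping)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"column {col!r}, row {row}: cannot parse boolean {raw.iloc[row]!r}"
        )
    return lowered.map(mapping)


def read_participants(path) -> pd.DataFrame:
    """Read and type-check a participant CSV; fail loudly on schema problems."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMA_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    raw = raw[SCHEMA_COLUMNS]

    out = pd.DataFrame(index=raw.index)
    for col in SCHEMA_COLUMNS:
        if col in NUMERIC_COLUMNS:
            stripped = raw[col].str.strip()
            vals = pd.to_numeric(stripped.replace("", np.nan), errors="coerce")
            bad = vals.isna() & (stripped != "")
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"column {col!r}, row {row}: malformed numeric {raw[col].iloc[row]!r}"
                )
            out[col] = vals.astype(float)
        elif col in BOOLEAN_COLUMNS:
            out[col] = _parse_bool(raw[col], col)
        else:
            out[col] = raw[col]

    if out["weight"].isna().any() or (out["weight"] <= 0).any():
        row = int(np.flatnonzero((out["weight"].isna() | (out["weight"] <= 0)).to_numpy())[0])
        raise SchemaError(f"row {row}: weight must be present and strictly positive")
    return out


def write_participants(frame: pd.DataFrame, path) -> None:
    frame = frame[SCHEMA_COLUMNS]
    frame.to_csv(path, index=False, float_format="%.10g")


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])[SCHEMA_COLUMNS]


def frame_to_records(frame: pd.DataFrame) -> List[ParticipantRecord]:
    def _nan_to_none(v):
        return None if pd.isna(v) else v

    return [
        ParticipantRecord(**{k: _nan_to_none(row[k]) for k in SCHEMA_COLUMNS})
        for _, row in frame.iterrows()
    ]


def score_participants(frame: pd.DataFrame, constants: Cb12Constants) -> pd.DataFrame:
    """Add eGFR, renal class, 3cB-12 score, and status columns."""
    out = frame.copy()
    ok_renal = out["creatinine_mg_dL"].notna()
    egfr = np.full(len(out), np.nan)
    if ok_renal.any():
        egfr[ok_renal] = egfr_values(
            out.loc[ok_renal, "creatinine_mg_dL"].to_numpy(dtype=float),
            out.loc[ok_renal, "age"].to_numpy(dtype=float),
            (out.loc[ok_renal, "sex"] == "female").to_numpy(),
        )
    out["egfr"] = egfr
    alb = out["albuminuria"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    renal = np.where(
        np.isnan(egfr) | out["albuminuria"].isna(),
        "unknown",
        classify_renal(np.nan_to_num(egfr), alb),
    )
    out["renal_function"] = renal

    ok = out[["b12_pmol_L", "mma_nmol_L", "thcy_umol_L"]].notna().all(axis=1)
    score = np.full(len(out), np.nan)
    if ok.any():
        score[ok.to_numpy()] = cb12_three_marker_values(
            out.loc[ok, "b12_pmol_L"], out.loc[ok, "mma_nmol_L"],
            out.loc[ok, "thcy_umol_L"], out.loc[ok, "age"], constants,
        )
    out["cb12_3marker"] = score
    out["b12_status"] = np.where(
        np.isnan(score), "unknown", classify_status(np.nan_to_num(score), constants.status_cutoff)
    )
    return out


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (exactly one data source).

    Either ``training_path``/``validation_path`` point at participant CSVs,
    or ``simulate`` holds a :class:`SyntheticConfig` plus a training split
    fraction.
    """

    training_path: Optional[str] = None
    validation_path: Optional[str] = None
    simulate: Optional[SyntheticConfig] = None
    fraction_training: float = 2.0 / 3.0
    renal_restriction: str = NORMAL_ONLY
    constants: Optional[Cb12Constants] = None
    panel: Tuple[CutoffSpec, ...] = TRADITIONAL_PANEL
    bootstrap_b: int = 2000
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        has_files = self.training_path is not None and self.validation_path is not None
        if has_files == (self.simulate is not None):
            raise ValueError(
                "exactly one of {training+validation paths, simulate block} required"
            )
        if self.constants is None:
            self.constants = Cb12Constants.packaged_default()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            sim = dict(kwargs["simulate"])
            for key in ("marker_log_means_adequate", "marker_log_means_inadequate",
                        "marker_log_sds", "age_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "marker_correlation" in sim:
                sim["marker_correlation"] = tuple(tuple(r) for r in sim["marker_correlation"])
            kwargs["simulate"] = SyntheticConfig(**sim)
        if kwargs.get("constants_path"):
            kwargs["constants"] = Cb12Constants.from_yaml(kwargs.pop("constants_path"))
        else:
            kwargs.pop("constants_path", None)
        if "panel" in kwargs:
            kwargs["panel"] = tuple(
                CutoffSpec(**{**spec, "threshold": _parse_threshold(spec["threshold"])})
                for spec in kwargs["panel"]
            )
        return cls(**kwargs)

    def echo(self) -> dict:
        d = {
            "training_path": self.training_path,
            "validation_path": self.validation_path,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "fraction_training": self.fraction_training,
            "renal_restriction": self.renal_restriction,
            "bootstrap_b": self.bootstrap_b,
            "seed": self.seed,
            "panel": [
                {"marker": c.marker, "direction": c.direction,
                 "threshold": c.threshold if np.isscalar(c.threshold) else list(map(list, c.threshold)),
                 "label": c.label, "source": c.source}
                for c in self.panel
            ],
        }
        return d


def _parse_threshold(t):
    if isinstance(t, (int, float)):
        return float(t)
    return tuple((tuple(band), float(v)) for band, v in t)


@dataclass
class PipelineResult:
    auc_table: pd.DataFrame
    auc_pairwise: pd.DataFrame
    cutoff_table: pd.DataFrame
    panel_table: pd.DataFrame
    attrition_training: pd.DataFrame
    attrition_validation: pd.DataFrame
    manifest: dict
    cutoffs: list
    summaries: list


def _reference_scorer(constants: Cb12Constants):
    def scorer(frame: pd.DataFrame) -> np.ndarray:
        score = cb12_three_marker_values(
            frame["b12_pmol_L"], frame["mma_nmol_L"], frame["thcy_umol_L"],
            frame["age"], constants,
        )
        return score <= constants.status_cutoff

    return scorer


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full training/validation workflow."""
    t0 = time.perf_counter()
    stage_ns = {}

    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        pop = generate_population(sim)
        training_pop, validation_pop = split_cycles(pop, config.fraction_training)
        training_raw, validation_raw = training_pop.frame, validation_pop.frame
    else:
        training_raw = read_participants(config.training_path)
        validation_raw = read_participants(config.validation_path)
    stage_ns["input"] = (len(training_raw), len(validation_raw))

    train_sample = build_analytic_sample(training_raw, config.renal_restriction)
    valid_sample = build_analytic_sample(validation_raw, config.renal_restriction)
    training, validation = train_sample.records, valid_sample.records
    stage_ns["analytic"] = (len(training), len(validation))
    logger.info("analytic samples: training n=%d validation n=%d", len(training), len(validation))

    constants = config.constants
    scorer = _reference_scorer(constants)
    ref_train = scorer(training)

    train_design = SurveyDesign.from_frame(training)
    valid_design = SurveyDesign.from_frame(validation)
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    train_reps = make_replicate_weights(
        train_design, config.bootstrap_b, seed=int(seeds[0].generate_state(1)[0] % 2**31)
    )

    # Table-1-style AUC grid with shared replicate AUC matrix
    models, rep_aucs, auc_rows = [], {}, []
    for spec in MODEL_GRID:
        model = fit_marker_model(spec, training, train_design, ref_train)
        reps = auc_replicates(model, training, train_design, train_reps, ref_train)
        est = auc_with_ci(model, training, train_design, train_reps, ref_train, reps)
        models.append(model)
        rep_aucs[model.label] = reps
        auc_rows.append(
            {"model": model.label, "auc": est.auc, "ci_low": est.ci_low,
             "ci_high": est.ci_high, "B": est.B, "fit_method": model.method,
             "converged": model.converged}
        )
    auc_table = pd.DataFrame(auc_rows)

    pair_rows = []
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            a, b = models[i], models[j]
            ra, rb = rep_aucs[a.label], rep_aucs[b.label]
            ok = np.isfinite(ra) & np.isfinite(rb)
            pair_rows.append(
                {"model_a": a.label, "model_b": b.label,
                 "p_value": bootstrap_pvalue_difference(ra[ok], rb[ok])}
            )
    auc_pairwise = pd.DataFrame(pair_rows)
    stage_ns["auc_grid"] = (len(auc_table), len(auc_pairwise))

    # Training-phase optimum cutoffs (Table-2-style)
    cutoff_rows, cutoff_results, optimum_specs = [], [], []
    for marker in ("b12", "mma", "thcy"):
        score = training[MARKER_COLUMNS[marker]].to_numpy(dtype=float)
        res = optimum_cutoff(
            score, ref_train, train_design, train_reps, MARKER_ORIENTATION[marker], marker
        )
        cutoff_results.append(res)
        optimum_specs.append(
            CutoffSpec(marker, res.direction, res.cutoff,
                       f"{marker} {res.direction}{res.cutoff:g} (optimum)", "ROC-derived")
        )
        cutoff_rows.append(
            {"marker": marker, "direction": res.direction, "cutoff": res.cutoff,
             "cutoff_ci_low": res.ci_low, "cutoff_ci_high": res.ci_high,
             "sensitivity_pct": 100 * res.sensitivity.estimate,
             "sensitivity_ci_low_pct": 100 * res.sensitivity.ci_low,
             "sensitivity_ci_high_pct": 100 * res.sensitivity.ci_high,
             "specificity_pct": 100 * res.specificity.estimate,
             "specificity_ci_low_pct": 100 * res.specificity.ci_low,
             "specificity_ci_high_pct": 100 * res.specificity.ci_high,
             "youden": res.youden}
        )
    cutoff_table = pd.DataFrame(cutoff_rows)

    # Validation-phase panel (Table-3-style): optima first, then tradition
    panel = tuple(optimum_specs) + tuple(config.panel)
    summaries = evaluate_panel(
        panel, training, validation, scorer, train_design, valid_design
    )
    panel_table = summaries_to_frame(summaries)
    stage_ns["panel"] = (len(panel_table), 0)

    manifest = {
        "package": "b12status",
        "version": __version__,
        "seed": config.seed,
        "bootstrap_b": config.bootstrap_b,
        "config": config.echo(),
        "cb12_constants": constants.to_dict(),
        "ckd_epi": CKD_EPI_2021.to_dict(),
        "bootstrap_method": train_reps.method,
        "stage_counts": stage_ns,
    }

    result = PipelineResult(
        auc_table, auc_pairwise, cutoff_table, panel_table,
        train_sample.attrition_frame(), valid_sample.attrition_frame(),
        manifest, cutoff_results, summaries,
    )
    if config.out_dir is not None:
        _write_bundle(result, config)
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return result


def _write_bundle(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    result.auc_table.to_csv(out / "auc_table.csv", index=False, float_format=fmt)
    result.auc_pairwise.to_csv(out / "auc_pairwise.csv", index=False, float_format=fmt)
    result.cutoff_table.to_csv(out / "cutoff_table.csv", index=False, float_format=fmt)
    result.panel_table.to_csv(out / "panel_table.csv", index=False, float_format=fmt)
    result.attrition_training.to_csv(out / "attrition_training.csv", index=False)
    result.attrition_validation.to_csv(out / "attrition_validation.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
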