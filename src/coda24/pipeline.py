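"""End-to-end pipeline: CSVs in, fitted tables and substitution estimates out.

Ties the stages together deterministically: read (or simulate) the daily and
survey CSVs, build one closed composition per included child, fit the
compositional regressions for every outcome and dominant-behaviour
rotation, and tabulate one-to-one time-reallocation estimates around the
cohort's geometric-mean day. All artifacts are plain CSV/JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import BEHAVIOURS_4, BEHAVIOURS_5
from .models import DEFAULT_COVARIATES, ilr1_summaries, model_report
from .preprocessing import (
    OUTCOMES,
    build_child_records,
    read_daily_csv,
    read_survey_csv,
    records_to_frame,
)
from .substitution import (
    reference_composition,
    reallocation_curve,
    substitution_frame,
    substitution_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and analysis settings for one pipeline run."""

    daily_csv: str
    survey_csv: str
    out_dir: str
    disaggregate: bool = False  # split sedentary into screen + quiet play
    outcomes: tuple[str, ...] = OUTCOMES
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    minutes_grid: tuple[float, ...] = (10.0, 20.0, 30.0)
    curve_outcome: str = "total_difficulties"
    curve_max_minutes: float = 30.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        bad = [o for o in self.outcomes if o not in OUTCOMES]
        if bad:
            raise ValueError(f"unknown outcomes: {bad}")

    @property
    def behaviours(self) -> tuple[str, ...]:
        return BEHAVIOURS_5 if self.disaggregate else BEHAVIOURS_4


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run preprocess -> fit -> substitute and write all artifacts.

    Writes composition.csv, fits.json, table1.csv, substitutions.csv and
    curves.csv under ``cfg.out_dir``; returns the artifact paths. Raises on
    schema mismatch or an empty cohort after the inclusion filters.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    days = read_daily_csv(cfg.daily_csv)
    surveys = read_survey_csv(cfg.survey_csv)
    records, counts = build_child_records(days, surveys,
                                          disaggregate=cfg.disaggregate)
    for k, v in counts.items():
        logger.info("preprocess: %s = %d", k, v)
    if not records:
        raise ValueError("no children remain after wear/completeness filters")
    logger.info("included n = %d", len(records))

    paths: dict[str, Path] = {}
    comp_df = records_to_frame(records)
    paths["composition"] = out / "composition.csv"
    comp_df.to_csv(paths["composition"], index=False, float_format="%.6g")

    behaviours = cfg.behaviours
    per_outcome = {}
    fits_payload = {}
    for outcome in cfg.outcomes:
        summaries, fits = ilr1_summaries(
            records, outcome, behaviours, cfg.covariates, cfg.alpha)
        per_outcome[outcome] = (summaries, fits)
        fits_payload[outcome] = {
            f.spec.dominant: {
                "beta": {k: float(v) for k, v in f.beta.items()},
                "cov_beta": f.cov_beta.round(10).values.tolist(),
                "coef_names": list(f.beta.index),
                "sigma2": f.sigma2, "df_resid": f.df_resid, "n": f.n,
                "r2_nocov": f.r2_nocov, "p_overall": f.p_overall, "r2c": f.r2c,
            }
            for f in fits
        }
    paths["fits"] = out / "fits.json"
    paths["fits"].write_text(json.dumps(fits_payload, indent=1, sort_keys=True))

    paths["table1"] = out / "table1.csv"
    model_report(per_outcome).to_csv(paths["table1"], index=False)

    base = reference_composition(records)
    sub_by_outcome = {}
    for outcome in cfg.outcomes:
        _, fits = per_outcome[outcome]
        sub_by_outcome[outcome] = substitution_table(
            fits[0], base, cfg.minutes_grid, cfg.alpha)
    paths["substitutions"] = out / "substitutions.csv"
    substitution_frame(sub_by_outcome).to_csv(
        paths["substitutions"], index=False, float_format="%.6g")

    # per-pair curves for the headline outcome (band plot export)
    _, fits = per_outcome[cfg.curve_outcome]
    curve_rows = []
    for src in behaviours:
        for dst in behaviours:
            if src == dst:
                continue
            for e in reallocation_curve(fits[0], base, src, dst,
                                        cfg.curve_max_minutes, 1.0, cfg.alpha):
                curve_rows.append({
                    "outcome": cfg.curve_outcome, "from": src, "to": dst,
                    "minutes": e.reallocation.minutes, "delta": e.delta,
                    "ci_low": e.ci_low, "ci_high": e.ci_high,
                })
    paths["curves"] = out / "curves.csv"
    pd.DataFrame(curve_rows).to_csv(paths["curves"], index=False,
                                    float_format="%.6g")
    return paths
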