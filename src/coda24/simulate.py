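"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

No raw cohort is publicly deposited, so every stage of the pipeline is
exercised against generated data with recorded ground truth. The generator
emulates a preschool cohort:

* a latent 24-hour composition per child — sleep drawn from a truncated
  normal (mean 687.9, SD 75.5 min), wake behaviours logistic-normally
  scattered around the cohort means (sedentary 291.3, light-intensity
  activities and games 334.2, energetic play 39.4 min/day) and closed into
  the waking window;
* seven day-level accelerometer records per child with compositional
  day-to-day jitter, non-wear, and occasional low-wear (invalid) days, so
  the wear-criteria filter and proportional non-wear reallocation have real
  work to do;
* a parent survey with night/day sleep, zero-inflated usual weekly screen
  and quiet-play minutes, demographics, and SDQ subscale scores generated
  linearly from the ilr coordinates of the latent composition (small R²,
  as observed in cohorts of this kind) plus covariate effects and noise.

SDQ total difficulties is always the sum of the four difficulty subscales,
so its true ilr coefficients are the sums of the subscale coefficients; a
shared residual component across subscales (a parent-rating "halo") brings
the total's residual SD up to the observed ~4.5.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import BEHAVIOURS_4, Composition, close
from .preprocessing import (
    DIFFICULTY_SUBSCALES,
    SDQ_SUBSCALES,
    ChildRecord,
    DAILY_COLUMNS,
    SURVEY_COLUMNS,
)
from .substitution import InfeasibleReallocation, Reallocation

__all__ = [
    "OutcomeModel",
    "GeneratorConfig",
    "GroundTruth",
    "generate_records",
    "generate_cohort",
    "truth_substitution_delta",
]

WAKE_PARTS = ("sedentary", "light_games", "energetic")


@dataclass(frozen=True)
class OutcomeModel:
    """Linear generating model for one SDQ subscale.

    `beta_ilr` is expressed in the pivot basis with sleep dominant and the
    remaining behaviours in declared order (sedentary, light-intensity
    activities and games, energetic play).
    """

    beta_ilr: tuple[float, float, float]
    beta_age: float
    beta_male: float
    beta_edu_certificate: float
    beta_edu_tertiary: float
    resid_sd: float
    target_mean: float


def _default_outcomes() -> dict[str, OutcomeModel]:
    # First ilr coefficients follow the magnitudes reported for cohorts of
    # this kind; residual SDs and means match the observed subscale
    # descriptives. The four difficulty subscales sum to a total-difficulties
    # ilr1 of -2.65.
    return {
        "emotional": OutcomeModel((-0.16, 0.3, -0.25), -0.05, -0.10, -0.05, -0.10, 1.3, 1.4),
        "conduct": OutcomeModel((-0.70, 0.4, 0.05), -0.10, 0.15, -0.05, -0.15, 1.7, 2.1),
        "hyperactivity": OutcomeModel((-1.08, 0.9, -0.08), -0.20, 0.40, -0.10, -0.25, 2.0, 3.9),
        "peer": OutcomeModel((-0.71, 0.5, -0.15), -0.05, 0.05, -0.05, -0.10, 1.3, 1.3),
        "prosocial": OutcomeModel((0.58, -0.3, -0.02), 0.10, -0.30, 0.05, 0.10, 1.7, 7.4),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort."""

    n: int = 1073
    seed: int = 0
    # latent composition
    mean_wake: dict[str, float] = field(
        default_factory=lambda: {"sedentary": 291.3, "light_games": 334.2,
                                 "energetic": 39.4})
    wake_log_sd: dict[str, float] = field(
        default_factory=lambda: {"sedentary": 0.21, "light_games": 0.14,
                                 "energetic": 0.36})
    sleep_mean: float = 687.9
    sleep_sd: float = 75.5
    sleep_bounds: tuple[float, float] = (300.0, 900.0)
    # day-level records
    # Mean non-wear chosen so mean valid-day wear matches the sum of the
    # configured wake means (waking window 752.1 - 664.9 = 87.2 min).
    days_per_child: int = 7
    day_log_sd: float = 0.12
    nonwear_mean_min: float = 87.0
    p_low_wear_day: float = 0.05
    energetic_split: tuple[float, float, float] = (0.5, 0.2, 0.3)  # walk/run/mvg
    # survey
    p_nap: float = 0.6
    nap_mean: float = 75.0
    nap_sd: float = 25.0
    screen_frac_beta: tuple[float, float] = (5.0, 5.0)
    p_zero_screen: float = 0.009
    p_zero_quiet: float = 0.039
    p_missing_report: float = 0.009
    report_log_sd: float = 0.2
    # covariates
    age_range: tuple[float, float] = (2.0, 5.0)
    p_male: float = 0.511
    education_probs: tuple[float, float, float] = (0.138, 0.280, 0.582)
    # outcomes
    outcomes: dict[str, OutcomeModel] = field(default_factory=_default_outcomes)
    shared_resid_sd: float = 0.72
    discretize: bool = False

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for p in (self.p_low_wear_day, self.p_nap, self.p_zero_screen,
                  self.p_zero_quiet, self.p_missing_report, self.p_male):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError("education probabilities must sum to 1")
        if any(sd <= 0 for sd in self.wake_log_sd.values()) or self.sleep_sd <= 0:
            raise ValueError("scale parameters must be positive")
        total_mean = sum(self.mean_wake.values()) + self.sleep_mean
        if not 1000.0 <= total_mean <= 1800.0:
            raise ValueError(
                f"mean parts sum to {total_mean:.0f} min; not a plausible day")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters and latent per-child compositions of a cohort."""

    behaviours: tuple[str, ...]
    dominant: str
    beta: dict[str, dict]  # outcome -> {intercept, ilr, covariates...}
    mean_composition: dict[str, float]
    latent_compositions: np.ndarray = field(repr=False)

    def to_json(self) -> str:
        payload = {
            "behaviours": list(self.behaviours),
            "dominant": self.dominant,
            "beta": self.beta,
            "mean_composition": self.mean_composition,
            "latent_compositions": np.round(self.latent_compositions, 6).tolist(),
        }
        return json.dumps(payload, indent=1)


def _pivot_ilr(parts: Sequence[float]) -> np.ndarray:
    """Pivot coordinates by the explicit scalar formula, dominant part first.

    Deliberately independent of the matrix-based transform in the
    composition module so it can serve as an oracle.
    """
    x = np.asarray(parts, dtype=float)
    D = len(x)
    out = np.empty(D - 1)
    for j in range(1, D):
        r = D - j
        gm = math.exp(np.mean(np.log(x[j:])))
        out[j - 1] = math.sqrt(r / (r + 1)) * math.log(x[j - 1] / gm)
    return out


def _fraction_offsets(cfg: GeneratorConfig) -> np.ndarray:
    m = tuple(cfg.mean_wake[k] for k in WAKE_PARTS)
    sd = tuple(cfg.wake_log_sd[k] for k in WAKE_PARTS)
    return _fraction_offsets_cached(m, sd, cfg.day_log_sd).copy()


@functools.lru_cache(maxsize=32)
def _fraction_offsets_cached(
    m: tuple[float, ...], sd: tuple[float, ...], day_log_sd: float
) -> np.ndarray:
    """Log-scale offsets making mean generated wake fractions hit the target.

    Renormalising independent lognormal parts inflates the expected share of
    high-variance small parts (energetic play) by a few percent. A short
    deterministic fixed point — driven by the config only, with its own
    fixed-seed sampler — solves for offsets so that the mean wake fraction
    of each behaviour (child scatter and day jitter included) matches the
    fraction implied by the configured mean minutes.
    """
    m = np.asarray(m)
    sd = np.asarray(sd)
    target = m / m.sum()
    rng = np.random.default_rng(987654321)
    eta = rng.standard_normal((120_000, 3))
    nu = rng.standard_normal((120_000, 3))
    delta = np.zeros(3)
    for _ in range(4):
        w = m * np.exp(delta + eta * sd - sd ** 2 / 2)
        w = w * np.exp(nu * day_log_sd)
        f = w / w.sum(axis=1, keepdims=True)
        realised = f.mean(axis=0)
        delta += np.log(target / realised)
    return delta


def _latent_cohort(cfg: GeneratorConfig, rng: np.random.Generator):
    """Latent compositions (n x 4, order sleep/sed/lg/en), covariates, outcomes."""
    n = cfg.n
    lo, hi = cfg.sleep_bounds
    a, b = (lo - cfg.sleep_mean) / cfg.sleep_sd, (hi - cfg.sleep_mean) / cfg.sleep_sd
    sleep = stats.truncnorm.rvs(a, b, loc=cfg.sleep_mean, scale=cfg.sleep_sd,
                                size=n, random_state=rng)
    mean_wake = np.array([cfg.mean_wake[k] for k in WAKE_PARTS])
    log_sd = np.array([cfg.wake_log_sd[k] for k in WAKE_PARTS])
    # centre the logistic-normal so realised mean wake fractions equal the
    # configured means' fractions (renormalisation biases small parts up)
    offset = _fraction_offsets(cfg)
    wake = mean_wake * np.exp(
        offset + rng.standard_normal((n, 3)) * log_sd - log_sd ** 2 / 2)
    wake_scaled = wake * ((1440.0 - sleep) / wake.sum(axis=1))[:, None]
    comp = np.column_stack([sleep, wake_scaled])  # closed to 1440

    age = rng.uniform(*cfg.age_range, size=n)
    male = (rng.random(n) < cfg.p_male).astype(float)
    edu = rng.choice(3, size=n, p=list(cfg.education_probs))
    edu_cert = (edu == 1).astype(float)
    edu_tert = (edu == 2).astype(float)

    # ilr under the dominant-sleep pivot basis (vectorised scalar formula)
    from .composition import ilr_coords, pivot_basis
    basis = pivot_basis(BEHAVIOURS_4, "sleep")
    Z = ilr_coords(comp / 1440.0, basis.matrix)

    mean_comp_vals = close(
        {"sleep": cfg.sleep_mean, **cfg.mean_wake}, 1440.0).values
    z_mean = ilr_coords(mean_comp_vals[None, :] / 1440.0, basis.matrix)[0]
    age_mean = float(np.mean(cfg.age_range))
    edu_p = cfg.education_probs

    shared = rng.standard_normal(n) * cfg.shared_resid_sd
    outcomes: dict[str, np.ndarray] = {}
    beta_truth: dict[str, dict] = {}
    for name, m in cfg.outcomes.items():
        b = np.asarray(m.beta_ilr)
        # intercept calibrated so the population mean matches the target
        intercept = (m.target_mean - b @ z_mean - m.beta_age * age_mean
                     - m.beta_male * cfg.p_male
                     - m.beta_edu_certificate * edu_p[1]
                     - m.beta_edu_tertiary * edu_p[2])
        y = (intercept + Z @ b + m.beta_age * age + m.beta_male * male
             + m.beta_edu_certificate * edu_cert + m.beta_edu_tertiary * edu_tert
             + rng.standard_normal(n) * m.resid_sd)
        if name in DIFFICULTY_SUBSCALES:
            y = y + shared
        outcomes[name] = y
        beta_truth[name] = {
            "intercept": float(intercept), "ilr": b.tolist(),
            "age_years": m.beta_age, "sex_male": m.beta_male,
            "edu_certificate": m.beta_edu_certificate,
            "edu_tertiary": m.beta_edu_tertiary, "resid_sd": m.resid_sd,
        }
    # total difficulties: sum of the four difficulty subscales, so its true
    # coefficients are the summed subscale coefficients
    beta_truth["total_difficulties"] = {
        k: (
            [sum(beta_truth[s]["ilr"][j] for s in DIFFICULTY_SUBSCALES)
             for j in range(3)] if k == "ilr"
            else sum(beta_truth[s][k] for s in DIFFICULTY_SUBSCALES)
        )
        for k in ("intercept", "ilr", "age_years", "sex_male",
                  "edu_certificate", "edu_tertiary")
    }
    covariates = {"age": age, "male": male, "edu_cert": edu_cert,
                  "edu_tert": edu_tert}
    truth = GroundTruth(
        behaviours=BEHAVIOURS_4, dominant="sleep", beta=beta_truth,
        mean_composition=dict(zip(BEHAVIOURS_4, mean_comp_vals)),
        latent_compositions=comp,
    )
    return comp, covariates, outcomes, truth


def _discretize_sdq(y: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(y), 0, 10)


def generate_records(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[ChildRecord], GroundTruth]:
    """Direct record-level generation: latent compositions, no day-level noise.

    The clean path for parameter-recovery experiments; set
    ``cfg.discretize=True`` to round and clip SDQ scores to their integer
    ranges as a survey would record them.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    comp, cov, outcomes, truth = _latent_cohort(cfg, rng)
    sub = {k: (_discretize_sdq(v) if cfg.discretize else v)
           for k, v in outcomes.items()}
    records = []
    edu_names = np.array(["secondary", "certificate", "tertiary"])
    edu_idx = (cov["edu_cert"] + 2 * cov["edu_tert"]).astype(int)
    for i in range(cfg.n):
        out = {k: float(sub[k][i]) for k in SDQ_SUBSCALES}
        out["total_difficulties"] = float(
            sum(out[k] for k in DIFFICULTY_SUBSCALES))
        records.append(ChildRecord(
            child_id=f"c{i:05d}",
            composition=Composition(dict(zip(BEHAVIOURS_4, comp[i])), 1440.0),
            age_years=float(cov["age"][i]),
            sex="male" if cov["male"][i] else "female",
            parent_education=str(edu_names[edu_idx[i]]),
            outcomes=out,
        ))
    return records, truth


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Full cohort: day-level accelerometer rows plus a survey table.

    Returns (daily, survey, truth) with the exact column contracts consumed
    by the preprocessing module. Deterministic for a fixed config and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    comp, cov, outcomes, truth = _latent_cohort(cfg, rng)
    n = cfg.n
    sleep = comp[:, 0]
    wake_parts = comp[:, 1:]  # sed, lg, en closed into waking window

    walk_f, run_f, mvg_f = cfg.energetic_split
    k = cfg.days_per_child
    nd = n * k
    child = np.repeat(np.arange(n), k)
    day = np.tile(np.arange(k), n)
    wake_window = 1440.0 - sleep[child]
    frac = wake_parts / wake_parts.sum(axis=1, keepdims=True)
    day_frac = frac[child] * np.exp(
        rng.standard_normal((nd, 3)) * cfg.day_log_sd)
    day_frac /= day_frac.sum(axis=1, keepdims=True)
    # regular days keep >= 8 h wear; invalid days are injected explicitly.
    # Gamma(4) keeps the mean at nonwear_mean_min with a short tail, so the
    # feasibility cap below almost never binds.
    nonwear = np.minimum(
        rng.gamma(4.0, cfg.nonwear_mean_min / 4.0, nd), wake_window - 481.0)
    low = rng.random(nd) < cfg.p_low_wear_day
    wear = np.where(low, rng.uniform(60.0, 470.0, nd), wake_window - nonwear)
    classes = day_frac * wear[:, None]
    daily = pd.DataFrame({
        "child_id": np.array([f"c{i:05d}" for i in range(n)])[child],
        "date": np.array([f"d{j + 1}" for j in range(k)])[day],
        "is_weekend": day >= k - 2,
        "wear_min": wear,
        "sedentary_min": classes[:, 0],
        "light_games_min": classes[:, 1],
        "walking_min": classes[:, 2] * walk_f,
        "running_min": classes[:, 2] * run_f,
        "mv_games_min": classes[:, 2] * mvg_f,
    }, columns=DAILY_COLUMNS)

    nap = np.where(rng.random(n) < cfg.p_nap,
                   np.clip(rng.normal(cfg.nap_mean, cfg.nap_sd, n), 10.0, 180.0),
                   0.0)
    nap = np.minimum(nap, sleep - 60.0)
    sleep_night = sleep - nap

    frac_screen = rng.beta(*cfg.screen_frac_beta, size=n)
    reported_sed = wake_parts[:, 0] * np.exp(
        rng.standard_normal(n) * cfg.report_log_sd)
    screen_weekly = 7.0 * frac_screen * reported_sed
    quiet_weekly = 7.0 * (1.0 - frac_screen) * reported_sed
    screen_weekly = np.where(rng.random(n) < cfg.p_zero_screen, 0.0, screen_weekly)
    quiet_weekly = np.where(rng.random(n) < cfg.p_zero_quiet, 0.0, quiet_weekly)
    missing = rng.random(n) < cfg.p_missing_report

    sdq_int = {k: _discretize_sdq(v) for k, v in outcomes.items()}
    edu_names = np.array(["secondary", "certificate", "tertiary"])
    edu_idx = (cov["edu_cert"] + 2 * cov["edu_tert"]).astype(int)
    survey = pd.DataFrame({
        "child_id": [f"c{i:05d}" for i in range(n)],
        "sleep_night_min": np.round(sleep_night, 1),
        "sleep_day_min": np.round(nap, 1),
        "screen_weekly_min": np.where(missing, np.nan, np.round(screen_weekly, 1)),
        "quiet_weekly_min": np.where(missing, np.nan, np.round(quiet_weekly, 1)),
        "age_years": np.round(cov["age"], 2),
        "sex": np.where(cov["male"] == 1.0, "male", "female"),
        "parent_education": edu_names[edu_idx],
        "sdq_emotional": sdq_int["emotional"].astype(int),
        "sdq_conduct": sdq_int["conduct"].astype(int),
        "sdq_hyperactivity": sdq_int["hyperactivity"].astype(int),
        "sdq_peer": sdq_int["peer"].astype(int),
        "sdq_prosocial": sdq_int["prosocial"].astype(int),
    }, columns=SURVEY_COLUMNS)
    return daily, survey, truth


def truth_substitution_delta(
    truth: GroundTruth,
    base: Composition,
    r: Reallocation,
    outcome: str = "total_difficulties",
) -> float:
    """Exact outcome change under the generating coefficients.

    Computed with the explicit scalar pivot formula — an independent code
    path from the estimation machinery — so it can serve as the recovery
    target for the fitted substitution estimates.
    """
    names = truth.behaviours
    if base.names != names:
        raise ValueError("base composition does not match ground-truth behaviours")
    moved_from = base[r.from_behaviour] - r.minutes
    if moved_from <= 0:
        raise InfeasibleReallocation(
            f"{r.minutes} min from {r.from_behaviour} infeasible")
    order = (truth.dominant,) + tuple(b for b in names if b != truth.dominant)

    def coords(c: Composition) -> np.ndarray:
        return _pivot_ilr([c[b] for b in order])

    moved = base.replace(**{r.from_behaviour: moved_from,
                            r.to_behaviour: base[r.to_behaviour] + r.minutes})
    d = coords(moved) - coords(base)
    beta = np.asarray(truth.beta[outcome]["ilr"])
    return float(beta @ d)
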