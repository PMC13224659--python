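"""Compositional linear regression of SDQ outcomes on pivot coordinates.

For each outcome the same linear model is fitted once per "rotation" — once
with each movement behaviour as the dominant part of the pivot basis. All
rotations are orthogonal re-parameterisations of one model, so fitted
values, residuals and R² coincide exactly; what changes is the first
coefficient, ilr1, which quantifies the association of relatively more of
the dominant behaviour (against the geometric mean of the rest) with the
outcome. Overall model significance and R² are taken from the fit without
covariates; the adjusted R² (R2c here, in the sense "with covariates") and
the ilr1 coefficients come from the fit adjusted for child age, sex and
parent education.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition import PivotBasis, ilr_coords, pivot_basis
from .preprocessing import ChildRecord, EDUCATION_LEVELS

__all__ = [
    "DesignSpec",
    "CompositionalFit",
    "Ilr1Summary",
    "design_matrix",
    "fit_compositional_lm",
    "ilr1_summaries",
    "model_report",
    "format_estimate_ci",
]

#: default covariate block: age continuous, male indicator, education
#: dummies with secondary school as the reference level.
DEFAULT_COVARIATES = ("age_years", "sex_male", "edu_certificate", "edu_tertiary")


@dataclass(frozen=True)
class DesignSpec:
    """What to regress on what: outcome, behaviour set, rotation, covariates."""

    outcome: str
    behaviours: tuple[str, ...]
    dominant: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        if self.dominant not in self.behaviours:
            raise ValueError(f"dominant {self.dominant!r} not in behaviour set")


@dataclass(frozen=True)
class CompositionalFit:
    """OLS results for one outcome under one dominant-behaviour rotation."""

    spec: DesignSpec
    basis: PivotBasis
    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma2: float
    df_resid: int
    n: int
    r2_nocov: float
    p_overall: float
    r2c: float
    fitted: np.ndarray = field(repr=False)

    @property
    def ilr_names(self) -> list[str]:
        return [f"ilr{j + 1}" for j in range(len(self.spec.behaviours) - 1)]

    @property
    def beta_ilr(self) -> np.ndarray:
        return self.beta[self.ilr_names].to_numpy()

    @property
    def cov_ilr(self) -> np.ndarray:
        return self.cov_beta.loc[self.ilr_names, self.ilr_names].to_numpy()


@dataclass(frozen=True)
class Ilr1Summary:
    dominant: str
    estimate: float
    ci_low: float
    ci_high: float
    significant: bool


def _covariate_columns(records: Sequence[ChildRecord]) -> pd.DataFrame:
    """Encode covariates: male=1, education dummies vs secondary reference."""
    return pd.DataFrame({
        "age_years": [r.age_years for r in records],
        "sex_male": [1.0 if r.sex == "male" else 0.0 for r in records],
        "edu_certificate": [1.0 if r.parent_education == "certificate" else 0.0
                            for r in records],
        "edu_tertiary": [1.0 if r.parent_education == "tertiary" else 0.0
                         for r in records],
    })


def design_matrix(
    records: Sequence[ChildRecord], spec: DesignSpec, basis: PivotBasis
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build [const, ilr coords, covariates] and the outcome vector."""
    comps = np.array([r.composition.values for r in records])
    Z = ilr_coords(comps, basis.matrix)
    X = pd.DataFrame(Z, columns=[f"ilr{j + 1}" for j in range(Z.shape[1])])
    cov = _covariate_columns(records)
    for c in spec.covariates:
        X[c] = cov[c].to_numpy()
    X.insert(0, "const", 1.0)
    y = np.array([r.outcomes[spec.outcome] for r in records])
    return X, y


def fit_compositional_lm(
    records: Sequence[ChildRecord], spec: DesignSpec
) -> CompositionalFit:
    """Fit one compositional OLS model (with and without covariates).

    The covariate-adjusted fit supplies the coefficients, their covariance
    and R2c; the companion covariate-free fit supplies the overall F-test
    p-value of the ilr block and its R².
    """
    for r in records:
        if r.composition.names != tuple(spec.behaviours):
            raise ValueError(
                f"record {r.child_id} behaviour set {r.composition.names} "
                f"differs from spec {spec.behaviours}"
            )
    basis = pivot_basis(spec.behaviours, spec.dominant)
    X, y = design_matrix(records, spec, basis)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} coefficients")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        # name the collinear columns via correlation of residualised columns
        raise ValueError(
            f"rank-deficient design (rank {rank} < {k}); columns: {list(X.columns)}"
        )
    full = sm.OLS(y, X).fit()
    ilr_cols = ["const"] + [c for c in X.columns if c.startswith("ilr")]
    nocov = sm.OLS(y, X[ilr_cols]).fit()

    def _r2(res) -> float:
        # constant outcome: no variance to explain
        return 0.0 if res.centered_tss <= 1e-12 else float(res.rsquared)

    return CompositionalFit(
        spec=spec,
        basis=basis,
        beta=full.params,
        cov_beta=full.cov_params(),
        sigma2=float(full.mse_resid),
        df_resid=int(full.df_resid),
        n=n,
        r2_nocov=_r2(nocov),
        p_overall=float(nocov.f_pvalue) if nocov.df_model > 0 else float("nan"),
        r2c=_r2(full),
        fitted=np.asarray(full.fittedvalues),
    )


def ilr1_summaries(
    records: Sequence[ChildRecord],
    outcome: str,
    behaviours: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> tuple[list[Ilr1Summary], list[CompositionalFit]]:
    """ilr1 estimate and t-based CI for every dominant-behaviour rotation."""
    from scipy import stats

    summaries: list[Ilr1Summary] = []
    fits: list[CompositionalFit] = []
    for dom in behaviours:
        spec = DesignSpec(outcome=outcome, behaviours=tuple(behaviours),
                          dominant=dom, covariates=tuple(covariates))
        fit = fit_compositional_lm(records, spec)
        est = float(fit.beta["ilr1"])
        se = float(np.sqrt(fit.cov_beta.loc["ilr1", "ilr1"]))
        tq = stats.t.ppf(1 - alpha / 2, fit.df_resid)
        lo, hi = est - tq * se, est + tq * se
        summaries.append(Ilr1Summary(
            dominant=dom, estimate=est, ci_low=lo, ci_high=hi,
            significant=not (lo <= 0.0 <= hi),
        ))
        fits.append(fit)
    return summaries, fits


def format_estimate_ci(est: float, lo: float, hi: float) -> str:
    """Render an estimate with its CI as e.g. ``-2.65 (-4.26, -1.05)``."""
    return f"{est:.2f} ({lo:.2f}, {hi:.2f})"


def model_report(
    per_outcome: dict[str, tuple[list[Ilr1Summary], list[CompositionalFit]]],
) -> pd.DataFrame:
    """One row per outcome mirroring the overall-fit table layout.

    Columns: outcome, p_overall, r2_nocov, r2c, then one ``ilr1 (NAME)``
    estimate-with-CI string per dominant behaviour, with matching
    ``significant (NAME)`` flags.
    """
    rows = []
    for outcome, (summaries, fits) in per_outcome.items():
        if not fits:
            continue
        row: dict[str, object] = {
            "outcome": outcome,
            "p_overall": round(fits[0].p_overall, 3),
            "r2_nocov": round(fits[0].r2_nocov, 3),
            "r2c": round(fits[0].r2c, 3),
        }
        for s in summaries:
            row[f"ilr1 ({s.dominant})"] = format_estimate_ci(
                s.estimate, s.ci_low, s.ci_high)
            row[f"significant ({s.dominant})"] = s.significant
        rows.append(row)
    return pd.DataFrame(rows)
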