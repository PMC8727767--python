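"""Quasi-Bayesian Monte-Carlo mediation analysis (potential-outcomes framework).

Tests whether the maximum burst suppression ratio mediates the effect of a
sedative (barbiturates or propofol, coded as given on the day of the
patient's maximum BSR) on dichotomized outcome, controlling for the maximum
GCS -- and the reverse direction with the medication flag as mediator.

The procedure follows the standard simulation algorithm for causal
mediation:

1. fit a mediator model (linear when the mediator is the continuous max
   BSR, logistic when it is a binary medication flag) on treatment +
   covariates, and an outcome logistic model on treatment + mediator +
   covariates (no treatment-mediator interaction by default);
2. draw ``n_sims`` parameter vectors from each model's asymptotic normal
   sampling distribution (quasi-Bayesian approximation);
3. per draw, simulate potential mediator values under treatment 0 and 1
   (with residual error for the linear model, Bernoulli draws for the
   logistic one) and evaluate expected potential outcomes under the four
   treatment x mediator-regime combinations;
4. average over observations: the average causal mediation effect
   ACME(t) = E[Y(t, M(1)) - Y(t, M(0))], the average direct effect
   ADE(t) = E[Y(1, M(t)) - Y(0, M(t))] and the total effect
   E[Y(1, M(1)) - Y(0, M(0))], all on the probability (risk-difference)
   scale; percentile intervals and simulation p-values come from the
   distribution of per-draw averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from sibskit.cohort import CohortTable
from sibskit.inference import median_split

__all__ = ["MediationSpec", "MediationResult", "code_medication", "run_mediation"]

_BINARY_MEDIATORS = {"barbiturates", "propofol", "treatment"}


@dataclass(frozen=True)
class MediationSpec:
    """Configuration of one mediation analysis.

    ``treatment`` and ``mediator`` name columns of the analysis table
    (``barbiturates``/``propofol``/``max_bsr`` on the cohort fixture);
    ``outcome`` is ``'discharge'``/``'chronic'`` for cohort tables or a
    binary column name for flat tables.  ``covariates`` defaults to the
    maximum GCS.
    """

    treatment: str
    mediator: str
    outcome: str
    covariates: Tuple[str, ...] = ("max_gcs",)
    n_sims: int = 1000
    seed: Optional[int] = None
    interaction: bool = False
    control_value: float = 0.0       # treatment level for "control" potential outcomes
    treat_value: float = 1.0         # treatment level for "treated" potential outcomes

    def __post_init__(self) -> None:
        if self.treatment == self.mediator:
            raise ValueError("treatment and mediator must differ")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")


@dataclass
class MediationResult:
    """ACME/ADE/total-effect estimates on the probability scale."""

    acme_control: float
    acme_treated: float
    ade_control: float
    ade_treated: float
    total_effect: float
    ci: Dict[str, Tuple[float, float]]
    p: Dict[str, float]
    n_sims: int
    n_obs: int
    seed: Optional[int]
    flags: Tuple[str, ...] = ()

    @property
    def acme(self) -> float:
        """Average of the control/treated mediation effects."""
        return 0.5 * (self.acme_control + self.acme_treated)

    @property
    def ade(self) -> float:
        return 0.5 * (self.ade_control + self.ade_treated)


def code_medication(cohort: CohortTable) -> pd.DataFrame:
    """Binary same-day medication indicators per patient.

    The packaged fixture already encodes whether each sedative was given on
    the day of the patient's maximum BSR, so the flags pass through; rows
    with missing medication data are dropped with a warning.
    """
    df = cohort.df
    meds = df[["patient_id", "barbiturates", "propofol"]].copy()
    missing = meds[["barbiturates", "propofol"]].isna().any(axis=1)
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} patient(s) with missing medication data",
            stacklevel=2)
        meds = meds[~missing]
    meds["barbiturates"] = meds["barbiturates"].astype(int)
    meds["propofol"] = meds["propofol"].astype(int)
    return meds.set_index("patient_id")


def _interval_and_p(draws: np.ndarray) -> Tuple[Tuple[float, float], float]:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    p_le = np.mean(draws <= 0.0)
    p_ge = np.mean(draws >= 0.0)
    return (float(lo), float(hi)), float(min(1.0, 2.0 * min(p_le, p_ge)))


def _prepare_table(data: Union[CohortTable, pd.DataFrame],
                   spec: MediationSpec) -> Tuple[pd.DataFrame, np.ndarray]:
    if isinstance(data, CohortTable):
        if spec.outcome not in ("discharge", "chronic"):
            raise ValueError("cohort outcomes must be 'discharge' or 'chronic'")
        df = data.complete_cases(spec.outcome).copy()
        y = median_split(df[f"gose_{spec.outcome}"], spec.outcome)
        df = df.loc[y.index]
        y = y.to_numpy()
    else:
        df = data.copy()
        y = df[spec.outcome].to_numpy(dtype=float)
    cols = [spec.treatment, spec.mediator, *spec.covariates]
    complete = df[cols].notna().all(axis=1)
    if not complete.all():
        warnings.warn(f"excluding {int((~complete).sum())} incomplete case(s)",
                      stacklevel=2)
        y = y[complete.to_numpy()]
        df = df[complete]
    out = df[cols].astype(float)
    if out[spec.treatment].nunique() < 2:
        raise ValueError("treatment must take at least two distinct values")
    return out, np.asarray(y, dtype=float)


def run_mediation(data: Union[CohortTable, pd.DataFrame],
                  spec: MediationSpec) -> MediationResult:
    """Run one quasi-Bayesian mediation analysis.

    Returns point estimates (means over simulation draws), 95% percentile
    intervals and simulation p-values for ACME (control/treated), ADE
    (control/treated) and the total effect.  Perfect separation in either
    component model is flagged on the result, not raised.
    """
    df, y = _prepare_table(data, spec)
    n = len(df)
    if n < 10:
        raise ValueError(f"too few complete cases for mediation ({n})")
    rng = np.random.default_rng(spec.seed)
    t = df[spec.treatment].to_numpy()
    m = df[spec.mediator].to_numpy()
    covs = df[list(spec.covariates)].to_numpy()
    mediator_binary = spec.mediator in _BINARY_MEDIATORS or set(np.unique(m)) <= {0.0, 1.0}
    flags = []

    # --- component models -------------------------------------------------
    Xm = np.column_stack([np.ones(n), t, covs])
    if mediator_binary:
        med_fit = sm.GLM(m, Xm, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
        sigma = None
    else:
        med_fit = sm.OLS(m, Xm).fit()
        sigma = float(np.sqrt(med_fit.scale))
    cols_y = [np.ones(n), t, m]
    if spec.interaction:
        cols_y.append(t * m)
    cols_y.append(covs)
    Xy = np.column_stack(cols_y)
    out_fit = sm.GLM(y, Xy, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
    for name, fit in (("mediator", med_fit), ("outcome", out_fit)):
        if np.abs(np.asarray(fit.params)).max() > 1e3:
            flags.append(f"possible separation in {name} model")

    # --- quasi-Bayesian parameter draws ------------------------------------
    S = spec.n_sims
    bm = rng.multivariate_normal(np.asarray(med_fit.params),
                                 np.asarray(med_fit.cov_params()), size=S)
    by = rng.multivariate_normal(np.asarray(out_fit.params),
                                 np.asarray(out_fit.cov_params()), size=S)

    def mediator_draw(treat_val: float) -> np.ndarray:
        """Potential mediator values, n x S."""
        Xt = np.column_stack([np.ones(n), np.full(n, treat_val), covs])
        lp = Xt @ bm.T                       # n x S
        if mediator_binary:
            pr = 1.0 / (1.0 + np.exp(-lp))
            return (rng.random((n, S)) < pr).astype(float)
        return lp + rng.normal(0.0, sigma, size=(n, S))

    M0 = mediator_draw(spec.control_value)
    M1 = mediator_draw(spec.treat_value)

    def outcome_prob(treat_val: float, M: np.ndarray) -> np.ndarray:
        """Expected potential outcome, n x S."""
        lp = (by[:, 0][None, :]
              + by[:, 1][None, :] * treat_val
              + by[:, 2][None, :] * M)
        j = 3
        if spec.interaction:
            lp = lp + by[:, j][None, :] * treat_val * M
            j += 1
        lp = lp + covs @ by[:, j:].T
        return 1.0 / (1.0 + np.exp(-lp))

    Y00 = outcome_prob(spec.control_value, M0)
    Y01 = outcome_prob(spec.control_value, M1)
    Y10 = outcome_prob(spec.treat_value, M0)
    Y11 = outcome_prob(spec.treat_value, M1)

    draws = {
        "acme_control": (Y01 - Y00).mean(axis=0),
        "acme_treated": (Y11 - Y10).mean(axis=0),
        "ade_control": (Y10 - Y00).mean(axis=0),
        "ade_treated": (Y11 - Y01).mean(axis=0),
        "total_effect": (Y11 - Y00).mean(axis=0),
    }
    ci, pvals, point = {}, {}, {}
    for key, d in draws.items():
        point[key] = float(d.mean())
        ci[key], pvals[key] = _interval_and_p(d)
    return MediationResult(
        acme_control=point["acme_control"], acme_treated=point["acme_treated"],
        ade_control=point["ade_control"], ade_treated=point["ade_treated"],
        total_effect=point["total_effect"], ci=ci, p=pvals,
        n_sims=S, n_obs=n, seed=spec.seed, flags=tuple(flags),
    )
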