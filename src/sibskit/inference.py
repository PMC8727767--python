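"""Outcome dichotomization, exhaustive logistic model sets, AICc multi-model inference.

Glasgow Outcome Scale extended (GOSe) scores are dichotomized at their
sample median: discharge 1-2 vs. 3-4 (favourable = GOSe >= 3) and chronic
1-4 vs. 5-8 (favourable = GOSe >= 5).  All 2^4 = 16 logistic regression
models over subsets of {max BSR, max GCS, sex, age at injury} (intercept
always included) are fitted by maximum likelihood, ranked by the
small-sample corrected Akaike information criterion

    AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1),

and models within ``window_delta`` (default 5) AICc units of the leader form
the confidence window over which Akaike weights ``exp(-delta/2)`` are
normalized.  Parameter estimates are conditionally model-averaged: a term's
average is taken over only the window models containing it, with weights
renormalized within that subset, and its unconditional standard error pools
within-model variance and between-model coefficient spread.  The adjusted
standard error additionally scales each model's variance by the square of
``t(0.975, n-k) / z(0.975)`` before pooling, a small-sample degrees-of-
freedom correction; z-scores and two-sided normal p-values are derived from
the adjusted SE.

Sex enters as an indicator with M = 0, F = 1 (log-likelihoods, AICc, weights
and the remaining coefficients are invariant to this coding); age enters as
the age-bin midpoint in years.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from sibskit.cohort import CohortTable

__all__ = [
    "CANDIDATE_TERMS",
    "ModelFit",
    "ModelSet",
    "median_split",
    "fit_logistic",
    "aicc",
    "enumerate_models",
    "average_parameters",
    "conditional_average",
    "pearson_r",
    "chi_squared_2x2",
]

#: Candidate predictors and the cohort columns they map to.
CANDIDATE_TERMS: Dict[str, str] = {
    "age": "age_mid",
    "max_bsr": "max_bsr",
    "sex": "female",
    "max_gcs": "max_gcs",
}

_MEDIAN_CUTOFF = {"discharge": 3, "chronic": 5}


def median_split(gose: Union[Sequence, pd.Series], timepoint: str) -> pd.Series:
    """Dichotomize GOSe scores at the sample median split.

    Returns a 0/1 series (1 = favourable: GOSe >= 3 at discharge, >= 5 at
    chronic follow-up) indexed like the input with missing scores dropped.
    A constant result (all one class) is allowed but triggers a warning,
    since downstream logistic fits are degenerate.
    """
    if timepoint not in _MEDIAN_CUTOFF:
        raise ValueError(f"timepoint must be 'discharge' or 'chronic', got {timepoint!r}")
    s = pd.Series(gose, dtype=float).dropna()
    if ((s < 1) | (s > 8)).any():
        raise ValueError("GOSe scores must lie in [1, 8]")
    y = (s >= _MEDIAN_CUTOFF[timepoint]).astype(int)
    if y.nunique() < 2:
        warnings.warn("degenerate median split: all outcomes identical", stacklevel=2)
    return y


@dataclass
class ModelFit:
    """One fitted logistic model (intercept always present)."""

    terms: Tuple[str, ...]
    params: pd.Series                # log-odds, index: const + terms
    vcov: pd.DataFrame
    llf: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    separation: bool = False

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index)


@dataclass
class ModelSet:
    """All 16 candidate fits for one timepoint, with deltas and window weights."""

    fits: List[ModelFit]
    delta: np.ndarray
    weight: np.ndarray
    window_delta: float
    timepoint: str
    n: int
    errors: Dict[Tuple[str, ...], str] = field(default_factory=dict)

    @property
    def window(self) -> List[ModelFit]:
        return [f for f, d in zip(self.fits, self.delta) if d <= self.window_delta]

    def window_weights(self) -> np.ndarray:
        return self.weight[self.delta <= self.window_delta]

    def to_dataframe(self) -> pd.DataFrame:
        """Model-ranking table: one row per fit, sorted by AICc."""
        rows = []
        for fit, d, w in zip(self.fits, self.delta, self.weight):
            row = {"outcome": self.timepoint, "intercept": fit.params["const"]}
            for term in CANDIDATE_TERMS:
                row[term] = fit.params.get(term, np.nan)
            row.update({"df": fit.k, "logLik": fit.llf, "AICc": fit.aicc,
                        "delta": d, "weight": w})
            rows.append(row)
        return pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)


def fit_logistic(design: pd.DataFrame, y: Sequence, terms: Optional[Tuple[str, ...]] = None,
                 maxiter: int = 100) -> ModelFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``design`` holds the predictor columns only (an intercept is added);
    convergence at score/parameter tolerance 1e-10.  Perfect separation is
    flagged on the returned fit (diverging coefficients) rather than raised.
    """
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    if np.isnan(X.to_numpy()).any() or np.isnan(y).any():
        raise ValueError("design matrix and outcome must be complete")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=maxiter, tol=1e-10)
    mu = res.fittedvalues
    separation = bool(np.all(np.abs(mu - y) < 1e-6)) or bool(
        np.abs(res.params.to_numpy()).max() > 1e3)
    return ModelFit(
        terms=tuple(terms if terms is not None else design.columns),
        params=res.params,
        vcov=res.cov_params(),
        llf=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
        converged=bool(res.converged),
        separation=separation,
    )


def aicc(logLik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n <= k+1 (n={n}, k={k})")
    return -2.0 * logLik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _analysis_frame(cohort: CohortTable, timepoint: str) -> Tuple[pd.DataFrame, pd.Series]:
    df = cohort.complete_cases(timepoint).copy()
    df["female"] = (df["sex"] == "F").astype(float)
    outcome_col = f"gose_{timepoint}"
    y = median_split(df[outcome_col], timepoint)
    return df.loc[y.index], y


def enumerate_models(cohort: CohortTable, timepoint: str,
                     window_delta: float = 5.0) -> ModelSet:
    """Fit all 16 term subsets and rank them by AICc.

    Chronic analyses drop patients with missing chronic GOSe (complete-case,
    n = 30 on the packaged fixture).  Akaike weights are normalized over the
    ``delta <= window_delta`` window; models outside the window carry weight
    0.  A fit that fails is recorded in ``errors`` and excluded from
    ranking.
    """
    df, y = _analysis_frame(cohort, timepoint)
    if len(y) < 10:
        raise ValueError(f"too few complete cases for {timepoint} ({len(y)})")
    term_names = list(CANDIDATE_TERMS)
    fits: List[ModelFit] = []
    errors: Dict[Tuple[str, ...], str] = {}
    for r in range(len(term_names) + 1):
        for subset in itertools.combinations(term_names, r):
            cols = [CANDIDATE_TERMS[t] for t in subset]
            design = df[cols].copy()
            design.columns = list(subset)
            try:
                fit = fit_logistic(design, y.to_numpy(), terms=subset)
                if not np.isfinite(fit.aicc):
                    raise ValueError("non-finite AICc (degenerate likelihood)")
                fits.append(fit)
            except Exception as exc:  # keep the set usable
                errors[subset] = str(exc)
    if not fits:
        raise ValueError("every candidate model failed to fit")
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    in_window = delta <= window_delta
    raw = np.where(in_window, np.exp(-delta / 2.0), 0.0)
    weight = raw / raw[in_window].sum()
    return ModelSet(fits=fits, delta=delta, weight=weight,
                    window_delta=window_delta, timepoint=timepoint,
                    n=int(len(y)), errors=errors)


def average_parameters(model_set: ModelSet) -> pd.DataFrame:
    """Conditional (subset) model averaging over the AICc confidence window.

    For each term (and the intercept), averages are taken over only the
    window models containing the term, with weights renormalized within that
    subset.  Columns: ``beta_avg`` (log-odds), ``odds_ratio``, ``se``
    (unconditional), ``adj_se`` (small-sample t-adjusted), ``z``
    (|beta|/adj_se) and two-sided normal ``p``.
    """
    window = model_set.window
    wts = model_set.window_weights()
    if len(window) == 0:
        raise ValueError("empty AICc window")
    z975 = stats.norm.ppf(0.975)
    rows = []
    for term, key in [("intercept", "const")] + [(t, t) for t in CANDIDATE_TERMS]:
        betas, vars_, adj_vars, w = [], [], [], []
        for fit, wi in zip(window, wts):
            if key in fit.params.index:
                betas.append(fit.params[key])
                v = float(fit.vcov.loc[key, key])
                vars_.append(v)
                c = stats.t.ppf(0.975, df=fit.n - fit.k) / z975
                adj_vars.append(v * c * c)
                w.append(wi)
        if not w:
            continue  # term absent from every window model
        w = np.asarray(w) / np.sum(w)
        betas, vars_, adj_vars = map(np.asarray, (betas, vars_, adj_vars))
        beta_avg = float(np.sum(w * betas))
        spread = (betas - beta_avg) ** 2
        se = float(np.sum(w * np.sqrt(vars_ + spread)))
        adj_se = float(np.sum(w * np.sqrt(adj_vars + spread)))
        z = abs(beta_avg) / adj_se if adj_se > 0 else np.inf
        rows.append({
            "term": term, "beta_avg": beta_avg,
            "odds_ratio": float(np.exp(beta_avg)),
            "se": se, "adj_se": adj_se, "z": z,
            "p": float(2.0 * stats.norm.sf(z)),
            "n_models": int(len(betas)),
        })
    return pd.DataFrame(rows).set_index("term")


def conditional_average(betas: Sequence[float], weights: Sequence[float]) -> float:
    """Conditionally averaged coefficient from per-model betas and Akaike weights.

    Weights are renormalized over the supplied models (those containing the
    term), so externally tabulated model rows can be averaged directly.
    """
    b = np.asarray(betas, dtype=float)
    w = np.asarray(weights, dtype=float)
    if b.shape != w.shape or b.size == 0:
        raise ValueError("betas and weights must be equal-length and non-empty")
    return float(np.sum(w * b) / np.sum(w))


def pearson_r(x: Sequence, y: Sequence) -> Tuple[float, float]:
    """Sample Pearson correlation with two-sided p from the t-transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def chi_squared_2x2(table: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, 1 df, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined with a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)
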