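"""Risk-factor and prognosis models for the wall-thickness indices.

Two estimator families live here:

* :class:`GammaIdentityGLM` — maximum-likelihood Gamma GLM with an identity
  link, the model used to relate MadWT (a strictly positive, right-skewed
  thickness in mm) to cardiovascular risk factors; coefficients are additive
  in mm per SD of each standardized predictor.
* :class:`CoxPH` — Cox proportional-hazards regression (Efron ties, via
  lifelines) with Wald CIs, Harrell's C, ΔC-index with paired-bootstrap
  inference, and VIF / Schoenfeld-trend diagnostics.

Prognosis models are built stepwise: Model 1 is the biomarker alone, Model 2
adds cardiovascular risk factors, Model 3 adds LVEDVi and LVEF, and the
exploratory Model 4 additionally adjusts for LVMi.  Effects are reported per
unit (mm) or per analysis-sample SD; the SD map is kept so the two scales
interconvert exactly (HR_SD = HR_unit ** SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "GammaIdentityGLM",
    "CoxPH",
    "ModelSpec",
    "CoxResult",
    "DiagnosticsReport",
    "standardize",
    "fit_gamma_glm",
    "fit_cox",
    "concordance",
    "delta_cindex",
    "diagnostics",
]

CVRF = ["age", "male", "white", "bmi", "smoker", "hyperlipidaemia", "hypertension", "diabetes"]
CMR_STANDARD = ["LVEDVi", "LVEF"]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(
    table: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Divide each variable by its analysis-sample SD; return the SD map.

    The SD is computed on the rows given (i.e. after exclusions, before
    modelling) so per-unit and per-SD hazard ratios interconvert exactly.
    """
    out = table.copy()
    sd_map: dict[str, float] = {}
    for v in variables:
        sd = float(out[v].std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"variable {v!r} has zero or undefined SD")
        out[v] = out[v] / sd
        sd_map[v] = sd
    return out, sd_map


# ---------------------------------------------------------------------------
# Gamma GLM
# ---------------------------------------------------------------------------

class GammaIdentityGLM(BaseEstimator):
    """Identity-link Gamma regression of a positive biomarker.

    Parameters
    ----------
    add_intercept : bool
        Prepend a constant column (default True).

    Attributes
    ----------
    coef_, bse_, pvalues_ : ndarray
        Coefficients (intercept first when present), standard errors, Wald p.
    conf_int_ : ndarray of shape (p, 2)
        95% Wald confidence intervals.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def fit(self, X, y):
        y = np.asarray(y, float)
        if np.any(y <= 0):
            raise ValueError("Gamma GLM requires a strictly positive outcome")
        X = pd.DataFrame(X).copy()
        if self.add_intercept:
            X = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            # identity link outside the canonical Gamma domain is the point
            # of this model; positivity of the fit is checked below
            warnings.simplefilter("ignore")
            model = sm.GLM(
                y, X, family=sm.families.Gamma(link=sm.families.links.Identity())
            )
        res = model.fit(maxiter=200)
        if not res.converged:
            raise RuntimeError(
                f"Gamma GLM did not converge ({res.fit_history['iteration']} "
                f"iterations, deviance trace {res.fit_history['deviance'][-5:]})"
            )
        mu = np.asarray(res.mu)
        if np.any(mu <= 0):
            raise RuntimeError("fitted identity-link Gamma means are not all positive")
        self.result_ = res
        self.feature_names_in_ = np.asarray(X.columns)
        self.coef_ = np.asarray(res.params)
        self.bse_ = np.asarray(res.bse)
        self.pvalues_ = np.asarray(res.pvalues)
        self.conf_int_ = np.asarray(res.conf_int())
        return self

    def predict(self, X):
        X = pd.DataFrame(X).copy()
        if self.add_intercept:
            X = sm.add_constant(X, has_constant="add")
        return np.asarray(self.result_.predict(X))


def fit_gamma_glm(cohort: pd.DataFrame, outcome: str, predictors: list[str]) -> GammaIdentityGLM:
    """Convenience wrapper: complete-case fit of ``outcome ~ predictors``."""
    rows = cohort[[outcome, *predictors]].dropna()
    return GammaIdentityGLM().fit(rows[predictors], rows[outcome])


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

class CoxPH(BaseEstimator):
    """Cox proportional-hazards estimator (partial likelihood, Efron ties).

    sklearn-style front end over ``lifelines.CoxPHFitter``: ``fit(X, y)``
    where ``y`` is an (n, 2) array of ``[time, event]`` (or a DataFrame with
    those columns).  ``predict`` returns the linear predictor (log partial
    hazard), i.e. higher = higher risk.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    @staticmethod
    def _split_y(y):
        y = np.asarray(y, float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be an (n, 2) array of [time, event]")
        return y[:, 0], y[:, 1].astype(int)

    def fit(self, X, y):
        time, event = self._split_y(y)
        if np.any(time <= 0):
            raise ValueError("event/censoring times must be > 0")
        if event.sum() == 0:
            raise ValueError("no events in the data; Cox model is undefined")
        X = pd.DataFrame(X).reset_index(drop=True)
        df = X.copy()
        df["__time"], df["__event"] = time, event
        fitter = CoxPHFitter(alpha=self.alpha)
        try:
            fitter.fit(df, duration_col="__time", event_col="__event")
        except Exception as err:  # lifelines raises on separation / collinearity
            raise RuntimeError(f"Cox partial-likelihood fit failed: {err}") from err
        self.fitter_ = fitter
        self.feature_names_in_ = np.asarray(X.columns)
        self.coef_ = fitter.params_.to_numpy()
        self.bse_ = fitter.standard_errors_.to_numpy()
        self.hazard_ratios_ = np.exp(self.coef_)
        self.conf_int_ = np.exp(fitter.confidence_intervals_.to_numpy())
        self.pvalues_ = fitter.summary["p"].to_numpy()
        self.n_events_ = int(event.sum())
        risk = self.predict(X)
        self.cindex_ = concordance(risk, time, event)
        self._train_X, self._train_time, self._train_event = X, time, event
        return self

    def predict(self, X):
        X = pd.DataFrame(X, columns=self.feature_names_in_)
        return X.to_numpy(float) @ self.coef_


@dataclass
class ModelSpec:
    """Stepwise prognosis model: biomarker plus level-dependent adjustments."""

    endpoint: str
    biomarker: str
    level: int = 1
    extra: list[str] = field(default_factory=list)

    def predictors(self) -> list[str]:
        preds = [self.biomarker]
        if self.level >= 2:
            preds += CVRF
        if self.level >= 3:
            preds += CMR_STANDARD
        if self.level >= 4:
            preds += ["LVMi"]
        return preds + list(self.extra)


@dataclass
class CoxResult:
    """Fitted stepwise Cox model with per-predictor effects and C-index."""

    spec: ModelSpec
    scaling: str  # 'sd' or 'unit'
    table: pd.DataFrame  # log_hr, hr, ci_low, ci_high, p per predictor
    sd_map: dict
    cindex: float
    n: int
    n_events: int
    model: CoxPH


def fit_cox(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    per: str = "sd",
    standardize_vars: list[str] | None = None,
) -> CoxResult:
    """Fit one stepwise Cox model on complete-case rows.

    ``per='sd'`` standardizes the continuous biomarkers listed in
    ``standardize_vars`` (default: the model's biomarker plus LVEDVi, LVEF,
    LVMi where present) to analysis-sample SD units.
    """
    preds = spec.predictors()
    tcol, ecol = f"time_{spec.endpoint}", f"event_{spec.endpoint}"
    rows = cohort[[tcol, ecol, *preds]].dropna().reset_index(drop=True)
    sd_map: dict[str, float] = {}
    if per == "sd":
        cont = standardize_vars
        if cont is None:
            cont = [p for p in [spec.biomarker, "LVEDVi", "LVEF", "LVMi"] if p in preds]
        rows, sd_map = standardize(rows, cont)
    elif per != "unit":
        raise ValueError("per must be 'sd' or 'unit'")
    model = CoxPH().fit(rows[preds], rows[[tcol, ecol]])
    table = pd.DataFrame(
        {
            "log_hr": model.coef_,
            "hr": model.hazard_ratios_,
            "ci_low": model.conf_int_[:, 0],
            "ci_high": model.conf_int_[:, 1],
            "p": model.pvalues_,
        },
        index=preds,
    )
    return CoxResult(
        spec=spec,
        scaling=per,
        table=table,
        sd_map=sd_map,
        cindex=model.cindex_,
        n=len(rows),
        n_events=model.n_events_,
        model=model,
    )


def fit_model_sequence(
    cohort: pd.DataFrame,
    endpoint: str,
    biomarker: str,
    levels: tuple[int, ...] = (1, 2, 3, 4),
    per: str = "sd",
) -> dict[int, CoxResult]:
    """Fit nested Models 1-4 on identical complete-case rows.

    Rows are restricted to those complete for the largest model so that
    C-indices of nested models are comparable; nesting of predictor sets is
    asserted.
    """
    specs = {lv: ModelSpec(endpoint, biomarker, level=lv) for lv in levels}
    largest = specs[max(levels)]
    cols = set(largest.predictors())
    prev: set[str] = set()
    for lv in sorted(levels):
        cur = set(specs[lv].predictors())
        if not prev <= cur:
            raise AssertionError("stepwise models must be nested")
        prev = cur
    tcol, ecol = f"time_{endpoint}", f"event_{endpoint}"
    rows = cohort[[tcol, ecol, *sorted(cols)]].dropna().reset_index(drop=True)
    return {lv: fit_cox(rows, specs[lv], per=per) for lv in sorted(levels)}


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance(risk, time, event) -> float:
    """Harrell's C over usable pairs; risk ties count 0.5."""
    risk, time = np.asarray(risk, float), np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    if not event.any():
        raise ValueError("concordance undefined: no usable pairs (no events)")
    try:
        # lifelines scores 'higher prediction = longer survival'; negate risk
        return float(_lifelines_cindex(time, -risk, event))
    except ZeroDivisionError as err:
        raise ValueError("concordance undefined: no usable pairs") from err


@dataclass
class DeltaCResult:
    delta: float
    p: float
    c_ref: float
    c_aug: float
    se: float


def delta_cindex(
    risk_ref,
    risk_aug,
    time,
    event,
    n_boot: int = 1000,
    seed=None,
) -> DeltaCResult:
    """ΔC = C(aug) − C(ref) with a paired-bootstrap z test.

    Both risk vectors must come from models fitted on the same rows; the
    bootstrap resamples subjects, recomputing both C-indices on each
    resample, and the p-value is a two-sided normal test of ΔC against 0
    using the bootstrap SE.  Identical risk vectors give ΔC = 0, p = 1.
    """
    risk_ref, risk_aug = np.asarray(risk_ref, float), np.asarray(risk_aug, float)
    time, event = np.asarray(time, float), np.asarray(event).astype(int)
    if not (len(risk_ref) == len(risk_aug) == len(time) == len(event)):
        raise ValueError("risk_ref, risk_aug, time and event must share rows")
    c_ref = concordance(risk_ref, time, event)
    c_aug = concordance(risk_aug, time, event)
    delta = c_aug - c_ref
    if np.array_equal(risk_ref, risk_aug):
        return DeltaCResult(0.0, 1.0, c_ref, c_aug, 0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(time)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if event[idx].sum() == 0:
            boot[b] = 0.0
            continue
        boot[b] = concordance(risk_aug[idx], time[idx], event[idx]) - concordance(
            risk_ref[idx], time[idx], event[idx]
        )
    se = float(boot.std(ddof=1))
    if se == 0:
        return DeltaCResult(float(delta), 1.0, c_ref, c_aug, 0.0)
    p = float(2.0 * stats.norm.sf(abs(delta) / se))
    return DeltaCResult(float(delta), p, c_ref, c_aug, se)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    vif: pd.Series
    schoenfeld: pd.DataFrame  # slope + p per predictor


def diagnostics(result: CoxResult | CoxPH) -> DiagnosticsReport:
    """VIF per predictor and Schoenfeld-residual time-trend test.

    VIF comes from auxiliary OLS regressions of each design column on the
    others (plus an intercept); an (effectively) collinear column reports
    ``inf``.  Schoenfeld residuals (per event) are regressed on event time;
    a small slope p flags a proportional-hazards violation.
    """
    model = result.model if isinstance(result, CoxResult) else result
    X = model._train_X
    A = X.to_numpy(float)
    n, p = A.shape
    vif = {}
    ones = np.ones((n, 1))
    for j, name in enumerate(X.columns):
        yj = A[:, j]
        others = np.hstack([ones, np.delete(A, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
        vif[name] = float(1.0 / (1.0 - r2)) if r2 < 1.0 - 1e-12 else np.inf
    df = X.copy()
    df["__time"], df["__event"] = model._train_time, model._train_event
    resid = model.fitter_.compute_residuals(df, kind="schoenfeld")
    etimes = df.loc[resid.index, "__time"].to_numpy()
    rows = {}
    for name in X.columns:
        sl = stats.linregress(etimes, resid[name].to_numpy())
        rows[name] = {"slope": sl.slope, "p": sl.pvalue}
    return DiagnosticsReport(vif=pd.Series(vif), schoenfeld=pd.DataFrame(rows).T)
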