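"""Simulated cohorts with known covariate effects and hazard structure.

The generator emulates a population-imaging cohort: covariates drawn from the
configured means/SDs/prevalences, hypertension assigned by a logistic model in
age and BMI (which induces the confounding the matching stage needs),
wall-thickness biomarkers from identity-link Gamma models whose means are
linear in standardized covariates, and per-endpoint event times from a Weibull
proportional-hazards model with per-SD log hazard ratios.  Administrative
censoring at ``admin_censor_years`` minus a uniform entry jitter reproduces a
follow-up distribution with median near 5.7 years.

Every cohort is returned together with a :class:`GroundTruth` record of the
coefficients and per-subject latent linear predictors; fitting code never
reads it.

Two biomarker modes exist:

* ``segment_level=True`` (default): 16 segmental thicknesses are generated per
  subject (a subject mean plus a normalized heterogeneity pattern scaled to a
  Gamma-distributed target MadWT) and the indices are derived through the
  same QC + index code the measurement pipeline uses.
* ``segment_level=False``: MadWT and MeanWT are drawn directly from the Gamma
  models and MaxWT is built structurally as
  ``MeanWT + MadWT * (factor + noise)``; exact for estimator-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from ..indices import wt_indices_frame
from .activity import default_activity_params, generate_activity

__all__ = ["CohortSimConfig", "GroundTruth", "default_config", "generate_cohort"]

ENDPOINTS = ("MACE", "HF", "arrhythmia", "death")


@dataclass
class CohortSimConfig:
    """Full parameterization of a simulated cohort (see module docstring)."""

    n: int = 37080
    seed: int | None = None
    segment_level: bool = True

    # covariates: name -> ("normal", mean, sd) or ("bernoulli", prevalence)
    covariates: dict = field(default_factory=dict)
    # hypertension logistic model: per-SD coefficients + target prevalence
    htn_prevalence: float = 0.274
    htn_logistic_coef: dict = field(
        default_factory=lambda: {"age": 0.45, "bmi": 0.55}
    )

    # identity-link Gamma biomarker models: coefficients in mm per SD of the
    # continuous covariate (binary covariates enter as 0/1 indicators)
    madwt_target_mean: float = 0.97
    madwt_shape: float = 10.0
    madwt_coef: dict = field(
        default_factory=lambda: {
            "age": 0.045, "male": 0.05, "bmi": 0.035, "hypertension": 0.12,
            "smoker": 0.05, "diabetes": 0.05, "height": 0.01, "white": -0.03,
            "log_tpa": 0.015,
        }
    )
    meanwt_target_mean: float = 7.15
    meanwt_shape: float = 45.0
    meanwt_coef: dict = field(
        default_factory=lambda: {
            "age": 0.22, "male": 0.55, "bmi": 0.30, "hypertension": 0.30,
            "smoker": 0.10, "diabetes": 0.15, "height": 0.05,
        }
    )
    maxwt_factor: float = 2.2
    maxwt_noise_sd: float = 0.25

    # post-hoc additive shifts applied to named biomarker columns in
    # hypertensive subjects only; lets experiments shift a single biomarker
    # without propagating through the structural links
    htn_shift: dict = field(default_factory=dict)

    # auxiliary biomarkers: name -> (dist, loc, scale, htn_delta)
    aux_biomarkers: dict = field(
        default_factory=lambda: {
            "LVEDVi": ("lognormal", np.log(77.5), 0.169, -2.0),
            "LVEF": ("normal", 59.7, 5.9, 0.2),
            "GLS": ("normal", 18.0, 2.3, -0.3),
            "nativeT1": ("normal", 931.0, 17.0, 0.0),
        }
    )
    lvmi_log_median: float = np.log(44.7)
    lvmi_log_sigma: float = 0.15
    lvmi_meanwt_exponent: float = 1.0

    # hazard model: endpoint -> dict(shape, scale (None -> calibrated),
    #   target_fraction, log_hr: {column: per-SD log hazard ratio})
    hazard_model: dict = field(
        default_factory=lambda: {
            "MACE": {"shape": 1.3, "scale": None, "target_fraction": 0.017,
                     "log_hr": {"MadWT": 0.25, "age": 0.45}},
            "HF": {"shape": 1.3, "scale": None, "target_fraction": 0.006,
                   "log_hr": {"MadWT": 0.26, "age": 0.50}},
            "arrhythmia": {"shape": 1.3, "scale": None, "target_fraction": 0.025,
                           "log_hr": {"MadWT": 0.285, "age": 0.50}},
            "death": {"shape": 1.3, "scale": None, "target_fraction": 0.015,
                      "log_hr": {"age": 0.60}},
        }
    )
    # reference (mean, sd) used to standardize columns entering the hazard
    hazard_scaling: dict = field(default_factory=dict)

    admin_censor_years: float = 7.5
    entry_jitter_years: float = 3.2

    activity_params: dict = field(default_factory=default_activity_params)
    # scaling of log1p(TPA) used when it enters a biomarker linear predictor
    log_tpa_mean: float = 7.60
    log_tpa_sd: float = 0.65

    def __post_init__(self) -> None:
        if not self.covariates:
            self.covariates = {
                "age": ("normal", 64.6, 7.7),
                "male": ("bernoulli", 0.481),
                "white": ("bernoulli", 0.971),
                "smoker": ("bernoulli", 0.035),
                "height": ("normal", 170.0, 9.4),
                "bmi": ("normal", 26.5, 4.4),
                "hyperlipidaemia": ("bernoulli", 0.318),
                "diabetes": ("bernoulli", 0.061),
            }
        self.validate()
        if not self.hazard_scaling:
            self.hazard_scaling = {
                "MadWT": (self.madwt_target_mean,
                          self.madwt_target_mean / np.sqrt(self.madwt_shape)),
                "MeanWT": (self.meanwt_target_mean,
                           self.meanwt_target_mean / np.sqrt(self.meanwt_shape)),
                "age": (64.6, 7.7),
            }

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be > 0")
        for name, spec in self.covariates.items():
            if spec[0] == "bernoulli" and not 0.0 <= spec[1] <= 1.0:
                raise ValueError(f"prevalence of {name} must be in [0, 1]")
        if not 0.0 <= self.htn_prevalence <= 1.0:
            raise ValueError("htn_prevalence must be in [0, 1]")
        if self.madwt_shape <= 0 or self.meanwt_shape <= 0:
            raise ValueError("Gamma shapes must be > 0")
        if self.admin_censor_years <= self.entry_jitter_years:
            raise ValueError("admin censoring must exceed the entry jitter")


@dataclass
class GroundTruth:
    """True generative parameters and latent predictors of a simulated cohort."""

    biomarker_coef: dict
    hazard: dict  # endpoint -> {shape, scale, log_hr}
    eta: dict  # endpoint -> per-subject latent linear predictor
    htn_intercept: float
    config: CohortSimConfig


# ---------------------------------------------------------------------------
# deterministic calibrations
# ---------------------------------------------------------------------------

def _solve_htn_intercept(config: CohortSimConfig) -> float:
    """Intercept of the hypertension logistic model hitting the prevalence.

    Marginalizes over the (independent standard normal) standardized age and
    BMI with Gauss-Hermite quadrature.
    """
    coefs = np.array(list(config.htn_logistic_coef.values()))
    if coefs.size == 0:
        return float(special.logit(config.htn_prevalence))
    x, w = np.polynomial.hermite_e.hermegauss(31)
    w = w / w.sum()
    # tensor-product quadrature over the standardized covariates
    grids = np.meshgrid(*([x] * len(coefs)), indexing="ij")
    weights = np.ones(grids[0].shape)
    for axis in range(len(coefs)):
        shape = [1] * len(coefs)
        shape[axis] = -1
        weights = weights * w.reshape(shape)
    lin = sum(c * g for c, g in zip(coefs, grids))

    def mean_prev(b0):
        return float((special.expit(b0 + lin) * weights).sum()) - config.htn_prevalence

    return float(optimize.brentq(mean_prev, -20, 20))


def calibrate_weibull_scale(
    target_fraction: float,
    shape: float,
    censor_lo: float,
    censor_hi: float,
    eta_sd: float,
) -> float:
    """Weibull scale (years) giving the target marginal event fraction.

    The expected fraction integrates the Weibull PH event probability over
    administrative censoring times C ~ U(censor_lo, censor_hi) and a normal
    approximation eta ~ N(0, eta_sd^2) of the hazard linear predictor.
    """
    x, w = np.polynomial.hermite_e.hermegauss(31)
    w = w / w.sum()
    eta = eta_sd * x
    c = np.linspace(censor_lo, censor_hi, 65)[:-1] + (censor_hi - censor_lo) / 128

    def frac(log_scale):
        lam = np.exp(log_scale)
        p = 1.0 - np.exp(-np.outer((c / lam) ** shape, np.exp(eta)))
        return float(p.mean(axis=0) @ w) - target_fraction

    return float(np.exp(optimize.brentq(frac, -3, 12)))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _standardized(df: pd.DataFrame, name: str, config: CohortSimConfig) -> np.ndarray:
    """Column scaled to z-units for linear predictors (binary stay 0/1)."""
    if name == "log_tpa":
        return (np.log1p(df["TPA"].to_numpy()) - config.log_tpa_mean) / config.log_tpa_sd
    spec = config.covariates.get(name)
    if spec is not None:
        if spec[0] == "bernoulli":
            return df[name].to_numpy().astype(float)
        return (df[name].to_numpy() - spec[1]) / spec[2]
    if name == "hypertension":
        return df[name].to_numpy().astype(float)
    mean, sd = config.hazard_scaling[name]
    return (df[name].to_numpy() - mean) / sd


def _linear_predictor(
    df: pd.DataFrame, coef: dict, target_mean: float, config: CohortSimConfig
) -> np.ndarray:
    intercept = target_mean
    for name, c in coef.items():
        spec = config.covariates.get(name)
        if spec is not None and spec[0] == "bernoulli":
            intercept -= c * spec[1]
        elif name == "hypertension":
            intercept -= c * config.htn_prevalence
        # z-scored continuous covariates have mean ~0: no intercept correction
    lp = np.full(len(df), intercept)
    for name, c in coef.items():
        lp += c * _standardized(df, name, config)
    return lp


def _gamma_mean(rng, shape: float, mean: np.ndarray) -> np.ndarray:
    if np.any(mean <= 0):
        bad = int(np.argmax(mean <= 0))
        raise ValueError(
            f"identity-link Gamma mean is non-positive (first offender: subject "
            f"{bad}, mean {mean[bad]:.3f}); adjust the biomarker coefficients"
        )
    return rng.gamma(shape, mean / shape)


def generate_cohort(
    config: CohortSimConfig | None = None, seed=None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one cohort; returns ``(table, ground_truth)``.

    ``seed`` overrides ``config.seed`` and may be an int or a Generator.
    Generation is bit-reproducible for a fixed seed.
    """
    config = config or CohortSimConfig()
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n

    df = pd.DataFrame({"subject_id": np.arange(n)})
    for name, spec in config.covariates.items():
        if spec[0] == "normal":
            df[name] = rng.normal(spec[1], spec[2], n)
        else:
            df[name] = (rng.random(n) < spec[1]).astype(int)
    df["weight"] = df.bmi * (df.height / 100.0) ** 2

    b0 = _solve_htn_intercept(config)
    lin = np.full(n, b0)
    for name, c in config.htn_logistic_coef.items():
        lin += c * _standardized(df, name, config)
    df["hypertension"] = (rng.random(n) < special.expit(lin)).astype(int)

    df = pd.concat([df, generate_activity(n, config.activity_params, rng)], axis=1)

    lp_mad = _linear_predictor(df, config.madwt_coef, config.madwt_target_mean, config)
    lp_mean = _linear_predictor(df, config.meanwt_coef, config.meanwt_target_mean, config)

    if config.segment_level:
        subj_mean = _gamma_mean(rng, config.meanwt_shape, lp_mean)
        subj_mad = _gamma_mean(rng, config.madwt_shape, lp_mad)
        g = rng.standard_normal((n, 16))
        d = g - g.mean(axis=1, keepdims=True)
        d /= np.abs(d).mean(axis=1, keepdims=True)
        wt = subj_mean[:, None] + subj_mad[:, None] * d
        np.maximum(wt, 0.5, out=wt)  # physical floor; essentially never binds
        seg_cols = [f"wt_{i:02d}" for i in range(1, 17)]
        df[seg_cols] = wt
        idx = wt_indices_frame(wt, qc=True)
        df[["MadWT", "MaxWT", "MeanWT"]] = idx[["MadWT", "MaxWT", "MeanWT"]].to_numpy()
        df["n_valid_segments"] = idx["n_valid"].to_numpy()
    else:
        df["MadWT"] = _gamma_mean(rng, config.madwt_shape, lp_mad)
        df["MeanWT"] = _gamma_mean(rng, config.meanwt_shape, lp_mean)
        factor = np.maximum(
            0.3, config.maxwt_factor + rng.normal(0.0, config.maxwt_noise_sd, n)
        )
        df["MaxWT"] = df.MeanWT + df.MadWT * factor

    for col, delta in config.htn_shift.items():
        df[col] = df[col] + delta * df.hypertension

    lvmi = np.exp(rng.normal(config.lvmi_log_median, config.lvmi_log_sigma, n))
    df["LVMi"] = lvmi * (df.MeanWT / config.meanwt_target_mean) ** config.lvmi_meanwt_exponent
    for name, (dist, loc, scale, htn_delta) in config.aux_biomarkers.items():
        if dist == "lognormal":
            df[name] = np.exp(rng.normal(loc, scale, n))
        else:
            df[name] = rng.normal(loc, scale, n)
        df[name] = df[name] + htn_delta * df.hypertension
    df["LVEF"] = df["LVEF"].clip(25.0, 85.0)
    df["LVMVR"] = df.LVMi / df.LVEDVi

    # survival endpoints
    censor = config.admin_censor_years - rng.uniform(0, config.entry_jitter_years, n)
    eta_store: dict[str, np.ndarray] = {}
    hazard_truth: dict[str, dict] = {}
    for endpoint, hm in config.hazard_model.items():
        eta = np.zeros(n)
        for name, beta in hm["log_hr"].items():
            eta += beta * _standardized(df, name, config)
        scale = hm.get("scale")
        if scale is None:
            eta_sd = float(np.sqrt(sum(b * b for b in hm["log_hr"].values())))
            scale = calibrate_weibull_scale(
                hm["target_fraction"],
                hm["shape"],
                config.admin_censor_years - config.entry_jitter_years,
                config.admin_censor_years,
                eta_sd,
            )
        t = scale * (-np.log(rng.random(n)) * np.exp(-eta)) ** (1.0 / hm["shape"])
        df[f"time_{endpoint}"] = np.minimum(t, censor)
        df[f"event_{endpoint}"] = (t <= censor).astype(int)
        eta_store[endpoint] = eta
        hazard_truth[endpoint] = {
            "shape": hm["shape"], "scale": float(scale), "log_hr": dict(hm["log_hr"])
        }

    truth = GroundTruth(
        biomarker_coef={
            "MadWT": dict(config.madwt_coef), "MeanWT": dict(config.meanwt_coef)
        },
        hazard=hazard_truth,
        eta=eta_store,
        htn_intercept=b0,
        config=config,
    )
    return df, truth


def default_config(**overrides) -> CohortSimConfig:
    """The defaults, optionally overridden field-by-field."""
    cfg = CohortSimConfig()
    return replace(cfg, **overrides) if overrides else cfg
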