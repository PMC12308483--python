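"""Propensity-score-matched hypertension comparisons in activity strata.

The question this stage answers: within the most physically active subjects
(top 10% / 1% by questionnaire MET-min/week or accelerometer mean vector), do
hypertensive and non-hypertensive hearts differ in wall-thickness
heterogeneity once the usual confounders of hypertension are balanced away?

The pipeline is: logistic propensity model for hypertension given
confounders, greedy 1:1 nearest-neighbour matching on the score without
replacement (treated processed in descending score order, no caliper),
standardized-mean-difference balance diagnostics, and per-biomarker
Mann-Whitney U comparisons with bootstrap median CIs at a Bonferroni-adjusted
alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PropensityMatcher",
    "MatchResult",
    "ComparisonTable",
    "estimate_propensity",
    "match_pairs",
    "select_top_active",
    "compare_biomarkers",
]

log = logging.getLogger(__name__)

CONFOUNDERS = ["age", "male", "white", "height", "bmi", "smoker", "hyperlipidaemia", "diabetes"]
BIOMARKERS = ["MadWT", "MaxWT", "MeanWT", "LVMi", "LVEDVi", "LVMVR", "LVEF", "GLS", "nativeT1"]


@dataclass
class MatchResult:
    """1:1 matched pairs with balance diagnostics."""

    pairs: pd.DataFrame  # treated_id, control_id, score_diff
    coef: pd.Series  # propensity model coefficients
    smd_pre: pd.Series
    smd_post: pd.Series
    n_unmatched_treated: int = 0


@dataclass
class ComparisonTable:
    table: pd.DataFrame
    alpha_family: int
    alpha_adjusted: float


def _smd(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """Standardized mean difference with the pooled two-group SD."""
    denom = np.sqrt((np.var(x_t, ddof=1) + np.var(x_c, ddof=1)) / 2.0)
    if denom == 0:
        return 0.0
    return float((x_t.mean() - x_c.mean()) / denom)


class PropensityMatcher(BaseEstimator):
    """Fit a hypertension propensity model and greedily match 1:1.

    ``fit(X, treated)`` fits the logistic model and performs the matching;
    ``scores_``, ``match_result_`` hold the outputs.  Matching is greedy
    nearest-neighbour on |score difference| without replacement, treated
    subjects processed in descending score order, ties broken by position,
    and no caliper (every treated subject is matched while controls last).
    """

    def __init__(self, confounders: list[str] | None = None):
        self.confounders = confounders

    @staticmethod
    def _usable(X, treated, cols):
        """Drop confounders the logistic MLE cannot identify.

        Constant columns, and binary columns with an empty treated-by-level
        cell (quasi-separation: the coefficient diverges), are excluded with
        a log entry; in small strata rare indicators routinely hit this.
        """
        keep, dropped = [], []
        for c in cols:
            x = X[c].to_numpy(float)
            if np.unique(x).size <= 1:
                dropped.append(c)
            elif set(np.unique(x)) <= {0.0, 1.0} and (
                min(
                    ((treated == t) & (x == v)).sum()
                    for t in (0, 1)
                    for v in (0.0, 1.0)
                )
                == 0
            ):
                dropped.append(c)
            else:
                keep.append(c)
        if dropped:
            log.warning("propensity model dropped unidentifiable confounders: %s", dropped)
        if not keep:
            raise ValueError("no usable confounders for the propensity model")
        return keep, dropped

    def fit(self, X: pd.DataFrame, treated):
        X = pd.DataFrame(X).reset_index(drop=True)
        treated = np.asarray(treated).astype(int)
        cols = self.confounders or [c for c in CONFOUNDERS if c in X.columns]
        cols, self.dropped_confounders_ = self._usable(X, treated, cols)
        design = sm.add_constant(X[cols].astype(float), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            try:
                res = sm.Logit(treated, design).fit(disp=0, maxiter=100)
            except Exception as err:
                raise RuntimeError(
                    f"propensity model failed (separation or non-convergence): {err}"
                ) from err
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("propensity logistic regression did not converge")
        self.result_ = res
        self.scores_ = np.asarray(res.predict(design))
        self.match_result_ = match_pairs(
            self.scores_, treated, ids=X.index.to_numpy(), covariates=X[cols]
        )
        self.match_result_.coef = res.params
        return self

    def matched_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Rows of X participating in a matched pair, with a 'treated' flag."""
        X = pd.DataFrame(X).reset_index(drop=True)
        pairs = self.match_result_.pairs
        t = X.loc[pairs.treated_id].assign(matched_treated=1)
        c = X.loc[pairs.control_id].assign(matched_treated=0)
        return pd.concat([t, c], axis=0)


def estimate_propensity(
    cohort: pd.DataFrame, confounders: list[str] | None = None, treated_col: str = "hypertension"
) -> np.ndarray:
    """Propensity scores in (0, 1) from a logistic model."""
    m = PropensityMatcher(confounders=confounders)
    m.fit(cohort, cohort[treated_col])
    return m.scores_


def match_pairs(
    scores: np.ndarray,
    treated: np.ndarray,
    ids: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Treated subjects are processed in descending score order (ties by id);
    each takes the unused control with the smallest |score difference|
    (ties by control id).  With fewer controls than treated, the surplus
    treated remain unmatched (logged).
    """
    scores = np.asarray(scores, float)
    treated = np.asarray(treated).astype(bool)
    if ids is None:
        ids = np.arange(len(scores))
    ids = np.asarray(ids)
    t_idx, c_idx = np.flatnonzero(treated), np.flatnonzero(~treated)
    if t_idx.size == 0 or c_idx.size == 0:
        raise ValueError("both treated and control groups must be non-empty")

    # descending score, stable so equal scores keep id order
    order = t_idx[np.argsort(-scores[t_idx], kind="stable")]
    c_scores = scores[c_idx]
    used = np.zeros(c_idx.size, bool)
    rows = []
    for t in order:
        if used.all():
            break
        d = np.abs(c_scores - scores[t])
        d[used] = np.inf
        j = int(np.argmin(d))  # argmin takes the first minimum: id-order ties
        used[j] = True
        rows.append((ids[t], ids[c_idx[j]], float(d[j])))
    n_unmatched = t_idx.size - len(rows)
    if n_unmatched:
        log.warning("greedy matching left %d treated subjects unmatched", n_unmatched)
    pairs = pd.DataFrame(rows, columns=["treated_id", "control_id", "score_diff"])

    smd_pre = smd_post = pd.Series(dtype=float)
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
        pos = pd.Series(np.arange(len(ids)), index=ids)
        ti, ci = pos[pairs.treated_id].to_numpy(), pos[pairs.control_id].to_numpy()
        smd_pre = pd.Series(
            {c: _smd(covariates[c].to_numpy()[treated], covariates[c].to_numpy()[~treated])
             for c in covariates.columns}
        )
        smd_post = pd.Series(
            {c: _smd(covariates[c].to_numpy()[ti], covariates[c].to_numpy()[ci])
             for c in covariates.columns}
        )
    return MatchResult(
        pairs=pairs, coef=pd.Series(dtype=float), smd_pre=smd_pre,
        smd_post=smd_post, n_unmatched_treated=n_unmatched,
    )


def select_top_active(
    cohort: pd.DataFrame, metric: str, fraction: float
) -> pd.DataFrame:
    """Rows at or above the (1 − fraction) quantile of an activity metric.

    ``metric`` is one of TPA, vigorous_MET or accel_mean; the accelerometer
    metric is restricted to subjects with valid (≥72 h calibrated) wear data.
    Ties at the threshold are all included; ``fraction=1`` returns the
    (metric-valid) cohort unchanged.
    """
    if metric not in ("TPA", "vigorous_MET", "accel_mean"):
        raise ValueError(f"unknown activity metric {metric!r}")
    rows = cohort
    if metric == "accel_mean":
        rows = rows[rows["accel_valid"].astype(bool)]
    rows = rows[np.isfinite(rows[metric])]
    if rows.empty:
        raise ValueError(f"no rows with a valid {metric} value")
    if fraction >= 1.0:
        return rows
    thresh = np.quantile(rows[metric].to_numpy(), 1.0 - fraction)
    out = rows[rows[metric] >= thresh]
    if out.empty:
        raise ValueError(f"empty top-{fraction:g} stratum for {metric}")
    return out


def _bootstrap_median_ci(x: np.ndarray, n_boot: int, rng, level: float = 0.95):
    idx = rng.integers(0, len(x), (n_boot, len(x)))
    meds = np.median(x[idx], axis=1)
    lo, hi = np.quantile(meds, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for n ≤ 20 per group, else the
    tie-corrected normal approximation."""
    method = "exact" if max(len(x), len(y)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_biomarkers(
    matched: pd.DataFrame,
    biomarkers: list[str] | None = None,
    group_col: str = "hypertension",
    n_boot: int = 2000,
    alpha_family: int | None = None,
    seed=None,
) -> ComparisonTable:
    """Median contrasts between matched hypertensive / non-hypertensive groups.

    Per biomarker: group medians with percentile-bootstrap 95% CIs, two-sided
    Mann-Whitney U p, the relative difference
    (median_HTN − median_nonHTN) / median_nonHTN, and a significance flag at
    the Bonferroni-adjusted level 0.05 / alpha_family (family defaults to the
    number of biomarkers compared).  All-NaN biomarkers are skipped with a
    log entry.
    """
    biomarkers = biomarkers or [b for b in BIOMARKERS if b in matched.columns]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grp = matched[group_col].astype(bool)
    rows = {}
    kept = []
    for b in biomarkers:
        x = matched.loc[grp, b].dropna().to_numpy(float)
        y = matched.loc[~grp, b].dropna().to_numpy(float)
        if x.size == 0 or y.size == 0:
            log.warning("biomarker %s skipped: no finite values in a group", b)
            continue
        kept.append(b)
        u, p = mann_whitney(x, y)
        mx, my = float(np.median(x)), float(np.median(y))
        ci_x = _bootstrap_median_ci(x, n_boot, rng)
        ci_y = _bootstrap_median_ci(y, n_boot, rng)
        rows[b] = {
            "median_htn": mx, "ci_htn_low": ci_x[0], "ci_htn_high": ci_x[1],
            "median_non": my, "ci_non_low": ci_y[0], "ci_non_high": ci_y[1],
            "U": u, "p": p,
            "rel_diff": (mx - my) / my if my != 0 else np.nan,
        }
    family = alpha_family if alpha_family is not None else len(kept)
    alpha_adj = 0.05 / family
    table = pd.DataFrame(rows).T
    table["significant"] = table["p"] < alpha_adj
    return ComparisonTable(table=table, alpha_family=family, alpha_adjusted=alpha_adj)
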