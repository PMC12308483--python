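"""Segment-level QC and wall-thickness / activity / volumetric indices.

The heterogeneity biomarker is MadWT: over the valid AHA segments, the mean of
the absolute deviations of each segment's maximal wall thickness from their
mean.  MeanWT is the mean and MaxWT the maximum of the same values.  Subjects
with fewer than 12 valid segmental measurements are excluded (indices NaN).

QC removes, within each subject, segmental values strictly above the upper
Tukey-style fence Q3 + 3*IQR of that subject's measured segments (quantiles by
linear interpolation between order statistics).  Low values are never removed;
quantiles are not recomputed after removal, so the filter is one-pass and
idempotent.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._types import ActivityProfile, SegmentalWTProfile, VolumetricIndices, WTIndices

__all__ = [
    "qc_segments",
    "compute_wt_indices",
    "compute_tpa",
    "index_volumetrics",
    "SegmentOutlierFilter",
    "WallThicknessIndexer",
    "wt_indices_frame",
]

MIN_VALID_SEGMENTS = 12
IQR_FENCE_FACTOR = 3.0


def _fence_mask(wt: np.ndarray, scope_values: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of values strictly above Q3 + 3*IQR (True = outlier)."""
    ref = wt if scope_values is None else scope_values
    finite = ref[np.isfinite(ref)]
    if finite.size == 0:
        return np.zeros(wt.shape, bool)
    q1, q3 = np.quantile(finite, [0.25, 0.75])  # linear interpolation
    fence = q3 + IQR_FENCE_FACTOR * (q3 - q1)
    with np.errstate(invalid="ignore"):
        return np.isfinite(wt) & (wt > fence)


def qc_segments(profile: SegmentalWTProfile) -> SegmentalWTProfile:
    """Remove within-subject upper-fence outliers from a segmental profile.

    Returns a new profile with outliers set to NaN and recorded in
    ``removed_segments``.  A profile already carrying ``qc_applied`` is
    returned unchanged (the fence is deliberately not recomputed on the
    filtered values).
    """
    if profile.qc_applied:
        return profile
    if profile.n_measured < 1:
        raise ValueError("profile has no measured segments")
    bad = _fence_mask(profile.wt)
    wt = profile.wt.copy()
    wt[bad] = np.nan
    removed = sorted(set(profile.removed_segments) | set((np.flatnonzero(bad) + 1).tolist()))
    return replace(profile, wt=wt, removed_segments=removed, qc_applied=True)


def compute_wt_indices(
    profile: SegmentalWTProfile, min_valid: int = MIN_VALID_SEGMENTS
) -> WTIndices:
    """MadWT / MaxWT / MeanWT over the valid segments of a (QC'd) profile."""
    valid = profile.wt[np.isfinite(profile.wt)]
    n_valid = valid.size
    if n_valid < min_valid:
        return WTIndices(
            MadWT=np.nan,
            MaxWT=np.nan,
            MeanWT=np.nan,
            n_valid_segments=n_valid,
            removed_segments=list(profile.removed_segments),
            excluded=True,
        )
    mean = float(valid.mean())
    return WTIndices(
        MadWT=float(np.abs(valid - mean).mean()),
        MaxWT=float(valid.max()),
        MeanWT=mean,
        n_valid_segments=n_valid,
        removed_segments=list(profile.removed_segments),
        excluded=False,
    )


def compute_tpa(activity: ActivityProfile | None = None, **kw) -> ActivityProfile:
    """Total physical activity in MET-min/week from questionnaire items.

    TPA = 3.3 * walking_min * walking_days
        + 4.0 * moderate_min * moderate_days
        + 8.0 * vigorous_min * vigorous_days
    """
    if activity is None:
        activity = ActivityProfile(TPA=0.0, vigorous_MET=0.0, **kw)
    items = np.array(
        [
            activity.walking_min,
            activity.walking_days,
            activity.moderate_min,
            activity.moderate_days,
            activity.vigorous_min,
            activity.vigorous_days,
        ],
        dtype=float,
    )
    if np.any(items < 0):
        raise ValueError("activity minutes and days must be non-negative")
    vig = 8.0 * activity.vigorous_min * activity.vigorous_days
    tpa = (
        3.3 * activity.walking_min * activity.walking_days
        + 4.0 * activity.moderate_min * activity.moderate_days
        + vig
    )
    return replace(activity, TPA=float(tpa), vigorous_MET=float(vig))


def du_bois_bsa(height_cm: float, weight_kg: float) -> float:
    return 0.007184 * height_cm**0.725 * weight_kg**0.425


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    return float(np.sqrt(height_cm * weight_kg / 3600.0))


def index_volumetrics(
    lvm_g: float,
    lvedv_ml: float,
    lvef_pct: float,
    height_cm: float,
    weight_kg: float,
    bsa_formula: str = "du_bois",
) -> VolumetricIndices:
    """BSA-indexed LV mass and volume plus the mass-to-volume ratio."""
    vals = np.array([lvm_g, lvedv_ml, lvef_pct, height_cm, weight_kg], float)
    if np.any(vals <= 0):
        raise ValueError("all volumetric inputs must be positive")
    bsa = {"du_bois": du_bois_bsa, "mosteller": mosteller_bsa}[bsa_formula](
        height_cm, weight_kg
    )
    return VolumetricIndices(
        LVMi=lvm_g / bsa,
        LVEDVi=lvedv_ml / bsa,
        LVMVR=lvm_g / lvedv_ml,
        LVEF=lvef_pct,
        BSA=bsa,
    )


# ---------------------------------------------------------------------------
# vectorised, pipeline-composable forms
# ---------------------------------------------------------------------------

class SegmentOutlierFilter(BaseEstimator, TransformerMixin):
    """Upper-fence segment QC on an (n_subjects, 16) thickness matrix.

    ``scope='subject'`` (default) computes the Q3 + 3*IQR fence within each
    row; ``scope='cohort'`` uses a single fence over all measured values.
    Transform returns a copy with outliers set to NaN.
    """

    def __init__(self, scope: str = "subject"):
        self.scope = scope

    def fit(self, X, y=None):
        if self.scope not in ("subject", "cohort"):
            raise ValueError("scope must be 'subject' or 'cohort'")
        X = np.asarray(X, float)
        if self.scope == "cohort":
            finite = X[np.isfinite(X)]
            q1, q3 = np.quantile(finite, [0.25, 0.75])
            self.fence_ = q3 + IQR_FENCE_FACTOR * (q3 - q1)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, float).copy()
        if self.scope == "cohort":
            with np.errstate(invalid="ignore"):
                X[X > self.fence_] = np.nan
            return X
        q1 = np.nanquantile(X, 0.25, axis=1, keepdims=True)
        q3 = np.nanquantile(X, 0.75, axis=1, keepdims=True)
        fence = q3 + IQR_FENCE_FACTOR * (q3 - q1)
        with np.errstate(invalid="ignore"):
            X[X > fence] = np.nan
        return X


class WallThicknessIndexer(BaseEstimator, TransformerMixin):
    """Map an (n_subjects, 16) thickness matrix to MadWT / MaxWT / MeanWT.

    Stateless transformer (fit is a no-op) so it composes with sklearn
    pipelines after :class:`SegmentOutlierFilter`.  Rows with fewer than
    ``min_valid`` finite segments yield NaN indices.
    """

    def __init__(self, min_valid: int = MIN_VALID_SEGMENTS):
        self.min_valid = min_valid

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        n_valid = np.isfinite(X).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=1)
            mad = np.nanmean(np.abs(X - mean[:, None]), axis=1)
            mx = np.nanmax(np.where(np.isfinite(X), X, -np.inf), axis=1)
        excluded = n_valid < self.min_valid
        out = np.column_stack([mad, mx, mean])
        out[excluded] = np.nan
        return out


def wt_indices_frame(
    wt: pd.DataFrame | np.ndarray, qc: bool = True, min_valid: int = MIN_VALID_SEGMENTS
) -> pd.DataFrame:
    """Cohort-level convenience: 16 thickness columns -> indices DataFrame."""
    index = wt.index if isinstance(wt, pd.DataFrame) else None
    X = np.asarray(wt, float)
    if qc:
        X = SegmentOutlierFilter().fit_transform(X)
    vals = WallThicknessIndexer(min_valid=min_valid).fit_transform(X)
    out = pd.DataFrame(vals, columns=["MadWT", "MaxWT", "MeanWT"], index=index)
    out["n_valid"] = np.isfinite(X).sum(axis=1)
    out["excluded"] = out["n_valid"] < min_valid
    return out
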