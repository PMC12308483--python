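"""Domain containers shared across the pipeline.

Conventions used throughout the package:

* Label volumes are ``(n_slices, n_rows, n_cols)`` integer arrays; slice 0 is
  the most basal slice when ``base_to_apex`` is True.
* In-plane coordinates are in millimetres, ``(row_mm, col_mm) = index * spacing``,
  with voxel centres at integer indices.
* Angles are in degrees measured from the image "up" direction (decreasing row
  index), increasing counter-clockwise in the displayed image, i.e. the standard
  AHA bull's-eye convention when the short-axis stack is viewed from the apex.
* AHA segments are numbered 1-16: basal 1-6 and mid 7-12 in 60 deg sectors,
  apical 13-16 in 90 deg sectors, sector 1/7/13 starting at the anterior RV
  insertion and numbering counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_SEGMENTS = 16
#: default integer labels in phantom / input volumes
DEFAULT_LABELS = {"background": 0, "cavity": 1, "myocardium": 2, "rv": 3}


@dataclass
class PhantomSpec:
    """Design of an analytic stepped-annulus LV phantom.

    Each short-axis slice is an annulus: cavity inside ``endo_radius``, myocardium
    out to a per-angle epicardial radius that is piecewise constant over the AHA
    sectors of that slice's level, so segment ``s`` has design wall thickness
    ``sector_thickness[s-1]`` (mm).
    """

    n_slices: int = 9
    slice_thickness: float = 8.0
    in_plane_spacing: float = 1.0
    endo_radius: float = 20.0
    sector_thickness: np.ndarray = field(
        default_factory=lambda: np.full(N_SEGMENTS, 8.0)
    )
    rv_insertion_angle: float = 0.0
    grid_size: int = 96
    paint_rv: bool = False
    rv_angular_halfwidth: float = 25.0
    rv_radial_extent: float = 4.0

    def __post_init__(self) -> None:
        self.sector_thickness = np.asarray(self.sector_thickness, dtype=float)
        if self.sector_thickness.shape != (N_SEGMENTS,):
            raise ValueError(
                f"sector_thickness must have {N_SEGMENTS} entries, "
                f"got {self.sector_thickness.shape}"
            )
        if np.any(self.sector_thickness <= 0):
            raise ValueError("all sector thicknesses must be > 0")
        if self.endo_radius <= 0:
            raise ValueError("endo_radius must be > 0")
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel spacing must be > 0")
        if self.n_slices < 3:
            raise ValueError("n_slices must be >= 3 so every AHA level is populated")
        # epicardium (plus any painted RV) must fit inside the grid
        half_extent = (self.grid_size - 1) / 2.0 * self.in_plane_spacing
        outer = self.endo_radius + self.sector_thickness
        if self.paint_rv:
            outer = outer + self.rv_radial_extent
        worst = int(np.argmax(outer))
        if outer[worst] > half_extent:
            raise ValueError(
                f"epicardium of segment {worst + 1} (radius {outer[worst]:.1f} mm) "
                f"exceeds the {self.grid_size}-voxel grid (half extent "
                f"{half_extent:.1f} mm); enlarge grid_size"
            )


@dataclass
class LabelMaskStack:
    """A short-axis label volume with the metadata geometry needs."""

    label_volume: np.ndarray
    in_plane_spacing: float
    slice_thickness: float
    base_to_apex: bool = True
    rv_insertion_angle: float | None = None
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label_volume must be 3-D (slices, rows, cols)")
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel spacing must be > 0")

    @property
    def n_slices(self) -> int:
        return self.label_volume.shape[0]

    def myocardium_slices(self) -> np.ndarray:
        """Indices of slices containing myocardium, in base-to-apex order."""
        myo = self.label_map["myocardium"]
        has = np.flatnonzero((self.label_volume == myo).any(axis=(1, 2)))
        if not self.base_to_apex:
            has = has[::-1]
        return has


@dataclass
class SegmentalWTProfile:
    """Per-segment maximal end-diastolic wall thickness (mm), AHA 1-16 order.

    ``wt[s-1]`` is NaN when segment ``s`` could not be measured or was removed
    by quality control.
    """

    wt: np.ndarray
    subject_id: str | int = 0
    removed_segments: list[int] = field(default_factory=list)
    qc_applied: bool = False

    def __post_init__(self) -> None:
        self.wt = np.asarray(self.wt, dtype=float)
        if self.wt.shape != (N_SEGMENTS,):
            raise ValueError(f"wt must have {N_SEGMENTS} entries, got {self.wt.shape}")
        measured = self.wt[np.isfinite(self.wt)]
        if measured.size and np.any(measured <= 0):
            raise ValueError("measured wall thicknesses must be > 0")

    @property
    def n_measured(self) -> int:
        return int(np.isfinite(self.wt).sum())


@dataclass
class WTIndices:
    """Wall-thickness heterogeneity indices for one subject (mm)."""

    MadWT: float
    MaxWT: float
    MeanWT: float
    n_valid_segments: int
    removed_segments: list[int] = field(default_factory=list)
    excluded: bool = False


@dataclass
class VolumetricIndices:
    """BSA-indexed LV volumetrics."""

    LVMi: float
    LVEDVi: float
    LVMVR: float
    LVEF: float
    BSA: float


@dataclass
class ActivityProfile:
    """Questionnaire + accelerometer physical-activity summary for one subject."""

    walking_min: float = 0.0
    walking_days: float = 0.0
    moderate_min: float = 0.0
    moderate_days: float = 0.0
    vigorous_min: float = 0.0
    vigorous_days: float = 0.0
    TPA: float = 0.0
    vigorous_MET: float = 0.0
    accel_mean: float | None = None
    accel_valid: bool = False
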