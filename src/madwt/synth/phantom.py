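"""Analytic stepped-annulus LV phantoms with known per-segment thickness.

Each short-axis slice is an annulus centred on the grid: cavity inside the
endocardial radius, myocardium between the endocardial radius and a per-angle
epicardial radius that steps across the AHA sectors of the slice's level, so
every segment has an exactly known design thickness.  The phantoms stand in
for end-diastolic segmentation masks of a short-axis cine stack and give the
measurement code an analytic oracle.
"""

from __future__ import annotations

import numpy as np

from .._types import LabelMaskStack, PhantomSpec
from ..geometry import allocate_slices, angle_of, segment_of_angles

__all__ = ["generate_phantom"]


def generate_phantom(spec: PhantomSpec) -> LabelMaskStack:
    """Rasterise a :class:`PhantomSpec` into a short-axis label stack.

    Voxels are labelled by the position of their centre: cavity where
    ``r < endo_radius``, myocardium where ``endo_radius <= r < endo_radius +
    sector_thickness[segment(theta)]``.  When ``spec.paint_rv`` is set, an RV
    wedge is painted immediately outside the epicardium, centred on
    ``rv_insertion_angle - rv_angular_halfwidth`` so that the wedge's
    counter-clockwise edge sits exactly at the anterior insertion angle.
    """
    g = spec.grid_size
    sp = spec.in_plane_spacing
    centre = (g - 1) / 2.0 * sp
    rr, cc = np.meshgrid(np.arange(g) * sp, np.arange(g) * sp, indexing="ij")
    dr, dc = rr - centre, cc - centre
    rad = np.hypot(dr, dc)
    theta = angle_of(dr, dc)

    levels = allocate_slices(spec.n_slices)
    vol = np.zeros((spec.n_slices, g, g), dtype=np.int16)
    labels = {"background": 0, "cavity": 1, "myocardium": 2, "rv": 3}

    for z, level in enumerate(levels):
        seg = segment_of_angles(theta, level, spec.rv_insertion_angle)
        outer = spec.endo_radius + spec.sector_thickness[seg - 1]
        sl = np.zeros((g, g), dtype=np.int16)
        sl[rad < spec.endo_radius] = labels["cavity"]
        sl[(rad >= spec.endo_radius) & (rad < outer)] = labels["myocardium"]
        if spec.paint_rv:
            rel = (theta - spec.rv_insertion_angle) % 360.0
            in_wedge = rel >= 360.0 - 2.0 * spec.rv_angular_halfwidth
            rv_zone = in_wedge & (rad >= outer) & (rad < outer + spec.rv_radial_extent)
            sl[rv_zone] = labels["rv"]
        vol[z] = sl

    return LabelMaskStack(
        label_volume=vol,
        in_plane_spacing=sp,
        slice_thickness=spec.slice_thickness,
        base_to_apex=True,
        rv_insertion_angle=spec.rv_insertion_angle,
        label_map=labels,
    )
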