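"""Per-view perimeter/area curves and LS / FAC / EF computation.

End-diastole (ED) is the phase with the largest 3D LV blood-pool
volume and end-systole (ES) the phase with the smallest; both are
selected once per study from the 3D segmentation (a per-view
slice-area option exists behind a flag).  Longitudinal strain is the
fractional change of the endocardial perimeter between those phases,

    LS = (P_ES - P_ED) / P_ED,

negative for a shortening ventricle, and is reported per view and per
perimeter method.  Fractional area change uses the LV pixel area of
the view slice, FAC = (A_ED - A_ES)/A_ED, and ejection fraction the 3D
voxel volumes, EF = (EDV - ESV)/EDV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contouring import measure_all
from .reslicing import CineSegmentation, PlaneDefinition, reslice

METHODS = ("naive", "hull", "spline")


@dataclass
class ViewCurve:
    """Perimeter and cavity-area time curves for one long-axis view."""

    view: str
    perimeters_mm: dict  # method -> per-phase length (mm)
    areas_mm2: np.ndarray
    ed: int
    es: int
    compliant: bool = True

    def __post_init__(self):
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        n = len(self.areas_mm2)
        for m, p in self.perimeters_mm.items():
            self.perimeters_mm[m] = np.asarray(p, dtype=float)
            if len(self.perimeters_mm[m]) != n:
                raise ValueError(f"{m} perimeter curve length != phase count")
        if self.ed == self.es:
            raise ValueError("ED and ES phases must differ")


@dataclass
class StrainResult:
    """Study-level strain summary: LS per view and method, FAC, EF."""

    ls: dict  # view -> {method: fraction}
    fac: dict  # view -> fraction
    ef: float
    ed: int
    es: int
    compliant: dict = field(default_factory=dict)  # view -> bool


def select_ed_es(cine: CineSegmentation) -> tuple:
    """(ED, ES) phase indices from the 3D LV volume curve.

    ED = argmax, ES = argmin, earliest phase on ties.  A constant
    volume curve yields ED=0, ES=1 with a warning (LS will be 0).
    """
    vols = cine.lv_volumes_ml()
    ed = int(np.argmax(vols))
    es = int(np.argmin(vols))
    if es == ed:
        warnings.warn("LV volume constant across phases; ES set to the "
                      "earliest non-ED phase", stacklevel=2)
        es = 1 if ed == 0 else 0
    return ed, es


def auto_extent_mm(cine: CineSegmentation, plane: PlaneDefinition,
                   margin_mm: float = 12.0) -> tuple:
    """In-plane extent covering every labelled voxel, plus a margin."""
    idx = np.argwhere(cine.frames[0] > 0)
    world = idx @ cine.affine[:3, :3].T + cine.affine[:3, 3]
    rel = world - plane.origin_mm
    px = np.abs(rel @ plane.x_dir)
    py = np.abs(rel @ plane.y_dir)
    return (2 * (px.max() + margin_mm), 2 * (py.max() + margin_mm))


def build_view_curve(
    cine: CineSegmentation,
    plane: PlaneDefinition,
    pixel_spacing: float | None = None,
    extent_mm=None,
    closing_radius_px: float = 10.0,
    downsample: int = 5,
    ed_es: tuple | None = None,
    per_view_ed_es: bool = False,
) -> ViewCurve:
    """Reslice every phase along one plane and measure all methods."""
    if extent_mm is None:
        extent_mm = auto_extent_mm(cine, plane)
    perims = {m: [] for m in METHODS}
    areas = []
    compliant = True
    for t, frame in enumerate(cine.frames):
        sl = reslice(frame, cine.affine, plane, pixel_spacing, extent_mm,
                     phase=t)
        contours = measure_all(sl, closing_radius_px, downsample)
        for m in METHODS:
            perims[m].append(contours[m].length_mm)
            compliant &= contours[m].compliant
        areas.append(sl.lv_area_mm2())
    areas = np.asarray(areas)
    if per_view_ed_es:
        ed, es = int(np.argmax(areas)), int(np.argmin(areas))
        if ed == es:
            es = 1 if ed == 0 else 0
    elif ed_es is not None:
        ed, es = ed_es
    else:
        ed, es = select_ed_es(cine)
    return ViewCurve(plane.view, perims, areas, ed, es, compliant)


def longitudinal_strain(curve: ViewCurve, method: str) -> float:
    """LS = (P_ES - P_ED)/P_ED for one view and perimeter method."""
    p = curve.perimeters_mm[method]
    p_ed, p_es = p[curve.ed], p[curve.es]
    if p_ed <= 0:
        raise ValueError(f"non-positive ED perimeter for {curve.view}/{method}")
    return float((p_es - p_ed) / p_ed)


def fractional_area_change(curve: ViewCurve) -> float:
    """FAC = (A_ED - A_ES)/A_ED from the slice LV pixel area."""
    a_ed, a_es = curve.areas_mm2[curve.ed], curve.areas_mm2[curve.es]
    if a_ed <= 0:
        raise ValueError(f"zero ED cavity area for view {curve.view}")
    return float((a_ed - a_es) / a_ed)


def ejection_fraction(cine: CineSegmentation,
                      ed_es: tuple | None = None) -> float:
    """EF = (EDV - ESV)/EDV from the 3D LV voxel volumes."""
    vols = cine.lv_volumes_ml()
    if ed_es is None:
        ed, es = select_ed_es(cine)
    else:
        ed, es = ed_es
    if vols[ed] <= 0:
        raise ValueError("zero end-diastolic volume")
    return float((vols[ed] - vols[es]) / vols[ed])


def compute_strain(
    cine: CineSegmentation,
    planes,
    pixel_spacing: float | None = None,
    extent_mm=None,
    closing_radius_px: float = 10.0,
    downsample: int = 5,
    per_view_ed_es: bool = False,
) -> StrainResult:
    """Full per-study strain analysis over all provided views."""
    ed, es = select_ed_es(cine)
    ls, fac, compliant = {}, {}, {}
    for plane in planes:
        curve = build_view_curve(
            cine, plane, pixel_spacing, extent_mm, closing_radius_px,
            downsample, ed_es=(ed, es), per_view_ed_es=per_view_ed_es,
        )
        ls[plane.view] = {m: longitudinal_strain(curve, m) for m in METHODS}
        fac[plane.view] = fractional_area_change(curve)
        compliant[plane.view] = curve.compliant
    ef = ejection_fraction(cine, (ed, es))
    return StrainResult(ls=ls, fac=fac, ef=ef, ed=ed, es=es,
                        compliant=compliant)
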