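"""Synthetic 4D left-heart phantom with analytic strain ground truth.

The phantom renders a contracting left ventricle as a half-ellipsoid
blood pool (flat top = mitral plane, apex pointing down the long axis)
with a fixed half-ellipsoidal left atrium sitting on the other side of
the plane.  Contraction is an isotropic linear scaling ``s(t)`` of the
LV about the centre of the mitral annulus, so the mitral plane stays
fixed and every long-axis contour scales exactly by ``s``: for uniform
contraction the true longitudinal strain is ``s(ES) - 1``, the true
fractional area change is ``1 - s(ES)^2`` and the true ejection
fraction is ``1 - s(ES)^3``.

Two artefact generators emulate the failure modes the perimeter
smoothing methods exist to correct:

* papillary muscles — inward spherical-cap bites carved out of the
  blood pool at mid-ventricular level, which a convex hull bridges;
* endocardial surface texture — smooth band-limited random radial
  perturbation of the surface, fixed in the tissue frame (default RMS
  amplitude 0.8 mm), which a spline fit smooths;
* per-frame boundary noise — an independent band-limited perturbation
  per cardiac phase (default RMS 0.6 mm, about one clinical voxel),
  emulating each phase being reconstructed and segmented independently.

Regional hypokinesis is modelled by letting the contraction deficit
depend on direction: inside an angular sector about the long axis the
deficit ``1 - s(t)`` is multiplied by a reduction factor, with
raised-cosine transitions at the sector edges and a fade-out toward the
apex (where all azimuths meet, so the deformed surface must stay
continuous).  Views whose plane azimuth falls in the sector see reduced
|LS|; this provides view-level wall-motion-abnormality ground truth.

Ground truth (perimeters, LS, FAC, EF, abnormality flags) is computed
analytically from the smooth papillary-free, texture-free geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .reslicing import (
    LABEL_LA,
    LABEL_LV,
    CineSegmentation,
    PlaneDefinition,
    VIEW_TAGS,
)

#: azimuth (deg) of each long-axis view plane about the LV long axis
VIEW_AZIMUTH_DEG = {"2CH": 0.0, "3CH": 60.0, "4CH": 120.0}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic study.

    Defaults describe a mid-sized adult LV imaged over one cardiac
    cycle at 10% RR intervals with papillary muscles and endocardial
    texture present; tests switch artefacts off explicitly where an
    artefact-free geometry is required.
    """

    grid_shape: tuple = (72, 72, 88)
    voxel_spacing_mm: float = 1.25
    lv_semi_axes_mm: tuple = (25.0, 25.0, 45.0)  # (x, y, long axis)
    la_semi_axes_mm: tuple = (27.0, 27.0, 25.0)  # base covers the mitral orifice
    n_phases: int = 10
    scale_es: float = 0.8
    scale_profile: np.ndarray | None = None  # s(t); default sin^2 dip to scale_es
    papillary_count: int = 2
    papillary_depth_mm: float = 6.0
    papillary_width_mm: float = 14.0
    papillary_level: float = -0.55  # z of insertions, fraction of long axis
    papillary_azimuth_deg: float | None = None  # first bite; None = random
    texture_amplitude_mm: float = 0.8
    texture_correlation_deg: float = 12.0
    frame_noise_mm: float = 0.6  # per-phase independent boundary noise (RMS)
    abnormal_sector_deg: tuple | None = None  # (centre, full width) azimuth
    abnormal_deficit_factor: float = 0.0  # deficit multiplier inside sector
    seed: int = 0

    def __post_init__(self):
        if self.n_phases < 2:
            raise ValueError("need at least 2 phases")
        if min(self.lv_semi_axes_mm) <= 0 or min(self.la_semi_axes_mm) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.scale_profile is None:
            t = np.arange(self.n_phases)
            self.scale_profile = 1.0 - (1.0 - self.scale_es) * np.sin(
                np.pi * t / self.n_phases
            ) ** 2
        self.scale_profile = np.asarray(self.scale_profile, dtype=float)
        if len(self.scale_profile) != self.n_phases:
            raise ValueError("scale profile length must equal n_phases")
        if np.any(self.scale_profile <= 0) or np.any(self.scale_profile > 1):
            raise ValueError("scale profile must lie in (0, 1]")


@dataclass
class PhantomTruth:
    """Analytic ground truth from the smooth phantom geometry."""

    perimeter_mm: dict  # view -> per-phase open-contour length (mm)
    ls: dict  # view -> true longitudinal strain (fraction)
    fac: dict  # view -> true fractional area change
    ef: float
    ed_phase: int
    es_phase: int
    abnormal_view: dict  # view -> bool
    abnormal_study: bool = field(init=False)

    def __post_init__(self):
        self.abnormal_study = any(self.abnormal_view.values())


def _sector_weight(theta: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Raised-cosine membership of azimuth ``theta`` (rad) in the
    abnormal sector; 1 inside, 0 outside, smooth 15 deg shoulders."""
    if spec.abnormal_sector_deg is None:
        return np.zeros_like(np.asarray(theta, dtype=float))
    centre, width = np.deg2rad(spec.abnormal_sector_deg[0]), np.deg2rad(
        spec.abnormal_sector_deg[1]
    )
    trans = np.deg2rad(15.0)
    d = np.abs((np.asarray(theta) - centre + np.pi) % (2 * np.pi) - np.pi)
    w = np.clip((width / 2 + trans - d) / trans, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * w)


def _apex_taper(phi) -> np.ndarray:
    """Raised-cosine fade-out of the contraction deficit toward the apex
    (polar angle ``phi`` measured from the long axis).  All azimuths meet
    at the apex, so the deficit must vanish there for the deformed
    surface to stay continuous."""
    lo, hi = np.deg2rad(10.0), np.deg2rad(35.0)
    g = np.clip((np.asarray(phi, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * g)


def _scale_field(theta, phi, phase: int, spec: PhantomSpec):
    """Direction-dependent linear scale factor at one phase.

    ``theta`` is the azimuth about the long axis, ``phi`` the polar
    angle from the apex direction."""
    s = spec.scale_profile[phase]
    if spec.abnormal_sector_deg is None:
        return np.full_like(np.asarray(theta, dtype=float), s)
    s_ab = 1.0 - spec.abnormal_deficit_factor * (1.0 - s)
    w = _sector_weight(theta, spec) * _apex_taper(phi)
    return s + (s_ab - s) * w


class _Texture:
    """Seeded band-limited random function on the unit sphere,
    normalised to the requested RMS amplitude (mm)."""

    def __init__(self, amplitude_mm: float, correlation_deg: float,
                 rng: np.random.Generator):
        self.amp = amplitude_mm
        k = max(1.0, 180.0 / max(correlation_deg, 1.0))
        n_modes = 24
        self.freq = rng.uniform(0.5 * k, k, n_modes)
        v = rng.normal(size=(n_modes, 3))
        self.axes = v / np.linalg.norm(v, axis=1, keepdims=True)
        self.phase = rng.uniform(0, 2 * np.pi, n_modes)
        self.coef = rng.normal(size=n_modes)
        if self.amp > 0:
            probe = rng.normal(size=(4096, 3))
            probe /= np.linalg.norm(probe, axis=1, keepdims=True)
            self._norm = self._raw(probe).std()
        else:
            self._norm = 1.0

    def _raw(self, dirs: np.ndarray) -> np.ndarray:
        out = np.zeros(len(dirs))
        for f, ax, ph, c in zip(self.freq, self.axes, self.phase, self.coef):
            out += c * np.cos(f * (dirs @ ax) + ph)
        return out

    def __call__(self, dirs: np.ndarray) -> np.ndarray:
        if self.amp == 0:
            return np.zeros(len(dirs))
        return self.amp * self._raw(dirs) / self._norm


def _papillary_spheres(spec: PhantomSpec, rng: np.random.Generator):
    """Centres and radii (reference frame, mm) of the papillary bites.

    Each bite is the spherical cap of depth ``d`` and chord width ``w``
    intruding into the cavity: sphere radius R = (d^2 + (w/2)^2)/(2d),
    centre at distance R - d outside the endocardial surface along the
    outward normal.
    """
    if spec.papillary_count == 0 or spec.papillary_depth_mm <= 0:
        return []
    a, b, c = spec.lv_semi_axes_mm
    d = spec.papillary_depth_mm
    w = spec.papillary_width_mm
    radius = (d**2 + (w / 2) ** 2) / (2 * d)
    out = []
    if spec.papillary_azimuth_deg is None:
        theta0 = rng.uniform(0, 2 * np.pi)
    else:
        theta0 = np.deg2rad(spec.papillary_azimuth_deg)
    for i in range(spec.papillary_count):
        th = theta0 + 2 * np.pi * i / spec.papillary_count
        z = spec.papillary_level * c
        rho = np.sqrt(max(1.0 - (z / c) ** 2, 0.0))
        p = np.array([a * rho * np.cos(th), b * rho * np.sin(th), z])
        n = p / np.array([a**2, b**2, c**2])
        n /= np.linalg.norm(n)
        out.append((p + (radius - d) * n, radius))
    return out


def _check_fit(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    sp = spec.voxel_spacing_mm
    a, b, c = spec.lv_semi_axes_mm
    al, bl, cl = spec.la_semi_axes_mm
    tex = (spec.texture_amplitude_mm + spec.frame_noise_mm) * 3.0  # ~3 sigma
    half_x, half_y = nx * sp / 2, ny * sp / 2
    below = c + tex + 2 * sp
    above = cl + 2 * sp
    if below + above > nz * sp:
        raise ValueError(
            f"geometry exceeds grid along long axis at phase 0: needs "
            f"{below + above:.1f} mm, grid has {nz * sp:.1f} mm"
        )
    for t in range(spec.n_phases):
        s = float(spec.scale_profile[t])
        if s * max(a, al) + tex + 2 * sp > half_x or s * max(b, bl) + tex + 2 * sp > half_y:
            raise ValueError(f"geometry exceeds grid in-plane at phase {t}")


def generate_phantom(spec: PhantomSpec):
    """Render the 4D label volumes, plane definitions and ground truth.

    Returns
    -------
    (CineSegmentation, list[PlaneDefinition], PhantomTruth)
    """
    _check_fit(spec)
    children = np.random.SeedSequence(spec.seed).spawn(2 + spec.n_phases)
    rng = np.random.default_rng(children[0])
    texture = _Texture(spec.texture_amplitude_mm, spec.texture_correlation_deg,
                       np.random.default_rng(children[1]))
    frame_noise = [
        _Texture(spec.frame_noise_mm, spec.texture_correlation_deg,
                 np.random.default_rng(children[2 + t]))
        for t in range(spec.n_phases)
    ]
    spheres = _papillary_spheres(spec, rng)

    nx, ny, nz = spec.grid_shape
    sp = spec.voxel_spacing_mm
    a, b, c = spec.lv_semi_axes_mm
    al, bl, cl = spec.la_semi_axes_mm

    # mitral-annulus centre p0 at world origin; apex toward -z
    k0 = nz - int(np.ceil((cl + 3 * sp) / sp)) - 1
    centre_idx = np.array([nx // 2, ny // 2, k0], dtype=float)
    affine = np.eye(4)
    affine[:3, :3] *= sp
    affine[:3, 3] = -centre_idx * sp

    xs = (np.arange(nx) - centre_idx[0]) * sp
    ys = (np.arange(ny) - centre_idx[1]) * sp
    zs = (np.arange(nz) - centre_idx[2]) * sp
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    theta = np.arctan2(Y, X)
    phi = np.arctan2(np.hypot(X, Y), -Z)  # polar angle from apex direction

    # LA is fixed across phases
    la = ((X / al) ** 2 + (Y / bl) ** 2 + (Z / cl) ** 2 <= 1.0) & (Z > 0)

    frames = []
    for t in range(spec.n_phases):
        s = _scale_field(theta, phi, t, spec)
        ux, uy, uz = X / s, Y / s, Z / s
        f = np.sqrt((ux / a) ** 2 + (uy / b) ** 2 + (uz / c) ** 2)
        lv = (Z <= 0) & (f > 0)
        r = np.sqrt(ux**2 + uy**2 + uz**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            excess = np.where(f > 0, r * (1.0 - 1.0 / f), -np.inf)
        if spec.texture_amplitude_mm > 0 or spec.frame_noise_mm > 0:
            cand = lv & (f <= 1.5)
            dirs = np.stack([ux[cand], uy[cand], uz[cand]], axis=1)
            nrm = np.linalg.norm(dirs, axis=1, keepdims=True)
            nrm[nrm == 0] = 1.0
            dirs /= nrm
            tex = np.zeros(lv.shape)
            # tissue texture scales with the wall; per-frame imaging noise
            # is a world-space displacement, hence divided by the scale
            tex[cand] = texture(dirs) + frame_noise[t](dirs) / s[cand]
            lv &= excess <= tex
        else:
            lv &= f <= 1.0
        lv |= (X == 0) & (Y == 0) & (Z == 0)  # centre voxel (f == 0)
        for m, radius in spheres:
            lv &= (ux - m[0]) ** 2 + (uy - m[1]) ** 2 + (uz - m[2]) ** 2 > radius**2
        if not lv.any():
            raise ValueError(f"degenerate (zero-volume) LV at phase {t}")
        frame = np.zeros(spec.grid_shape, dtype=np.uint8)
        frame[lv] = LABEL_LV
        frame[la & ~lv] = LABEL_LA
        frames.append(frame)

    cine = CineSegmentation(frames=frames, affine=affine)
    planes = [
        PlaneDefinition(
            view=v,
            origin_mm=np.array([0.0, 0.0, (cl - c) / 2.0]),
            x_dir=np.array(
                [np.cos(np.deg2rad(VIEW_AZIMUTH_DEG[v])),
                 np.sin(np.deg2rad(VIEW_AZIMUTH_DEG[v])), 0.0]
            ),
            y_dir=np.array([0.0, 0.0, 1.0]),
        )
        for v in VIEW_TAGS
    ]
    truth = analytic_truth(spec)
    return cine, planes, truth


# ---------------------------------------------------------------------------
# analytic truth


def _quarter_arc(rho: float, c: float) -> float:
    """Arc length of a quarter ellipse with semi-axes (rho, c)."""
    val, _ = quad(
        lambda t: np.sqrt((rho * np.sin(t)) ** 2 + (c * np.cos(t)) ** 2),
        0.0,
        np.pi / 2,
        limit=200,
    )
    return float(val)


def _view_radius(spec: PhantomSpec, alpha: float) -> float:
    """In-plane transverse semi-axis of the cavity cross-section at
    azimuth ``alpha``."""
    a, b, _ = spec.lv_semi_axes_mm
    return a * b / np.hypot(b * np.cos(alpha), a * np.sin(alpha))


def _view_truth_curves(spec: PhantomSpec, alpha: float, n_pts: int = 4000):
    """Per-phase open-contour length (mm) and cavity area (mm^2) of the
    smooth geometry in the view plane at azimuth ``alpha``.

    The reference contour is the half-ellipse through the long axis;
    each boundary point in direction (azimuth, polar angle) is scaled by
    the local factor, and length/area are evaluated numerically (the
    scale varies along the contour in regional-abnormality phantoms)."""
    rho = _view_radius(spec, alpha)
    c = spec.lv_semi_axes_mm[2]
    t = np.linspace(0.0, np.pi / 2, n_pts)
    x = rho * np.sin(t)  # in-plane transverse offset, >= 0
    z = -c * np.cos(t)  # depth below the mitral plane
    phi = np.arctan2(x, -z)
    perims = np.empty(spec.n_phases)
    areas = np.empty(spec.n_phases)
    for ph in range(spec.n_phases):
        s1 = _scale_field(np.full_like(t, alpha), phi, ph, spec)
        s2 = _scale_field(np.full_like(t, alpha + np.pi), phi, ph, spec)
        # polygon: base -> apex on side 1, apex -> base on side 2
        px = np.concatenate([(s1 * x)[::-1], -(s2 * x)])
        pz = np.concatenate([(s1 * z)[::-1], (s2 * z)])
        perims[ph] = np.hypot(np.diff(px), np.diff(pz)).sum()
        # shoelace about the annulus centre (on the closing base edge)
        areas[ph] = 0.5 * abs(
            np.sum(px[:-1] * pz[1:] - px[1:] * pz[:-1])
        )
    return perims, areas


def _true_volumes(spec: PhantomSpec, n_theta: int = 360, n_phi: int = 200):
    """Per-phase cavity volume of the smooth geometry, by spherical
    integration of the scaled boundary radius about the annulus centre."""
    a, b, c = spec.lv_semi_axes_mm
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    phi = (np.arange(n_phi) + 0.5) * (np.pi / 2) / n_phi
    TH, PHI = np.meshgrid(th, phi, indexing="ij")
    # reference boundary radius of the half-ellipsoid in direction
    # (theta, phi): apex at phi = 0, base plane at phi = pi/2
    sin_p, cos_p = np.sin(PHI), np.cos(PHI)
    r_ref = 1.0 / np.sqrt(
        (sin_p * np.cos(TH) / a) ** 2
        + (sin_p * np.sin(TH) / b) ** 2
        + (cos_p / c) ** 2
    )
    dth = 2 * np.pi / n_theta
    dphi = (np.pi / 2) / n_phi
    vols = np.empty(spec.n_phases)
    for ph in range(spec.n_phases):
        s = _scale_field(TH, PHI, ph, spec)
        vols[ph] = np.sum((s * r_ref) ** 3 / 3.0 * sin_p) * dth * dphi
    return vols


def analytic_truth(spec: PhantomSpec) -> PhantomTruth:
    """Ground-truth perimeters, LS, FAC and EF of the smooth geometry.

    A view plane at azimuth ``alpha`` meets the surface at azimuths
    ``alpha`` and ``alpha + pi``.  Under uniform contraction every
    quantity has a closed form (quarter-ellipse arcs and areas scaled by
    ``s``); with a regional abnormality the scale varies along the
    contour and the curves are integrated numerically.
    """
    c = spec.lv_semi_axes_mm[2]
    n = spec.n_phases
    uniform = spec.abnormal_sector_deg is None
    perims, areas = {}, {}
    for view, az in VIEW_AZIMUTH_DEG.items():
        alpha = np.deg2rad(az)
        if uniform:
            rho = _view_radius(spec, alpha)
            q = _quarter_arc(rho, c)
            qa = np.pi * rho * c / 4.0
            s = spec.scale_profile
            perims[view] = 2 * q * s
            areas[view] = 2 * qa * s**2
        else:
            perims[view], areas[view] = _view_truth_curves(spec, alpha)

    if uniform:
        a, b = spec.lv_semi_axes_mm[:2]
        vol = (2.0 / 3.0) * np.pi * a * b * c * spec.scale_profile**3
    else:
        vol = _true_volumes(spec)
    ed = int(np.argmax(vol))
    es = int(np.argmin(vol))
    if es == ed:
        es = 1 if ed == 0 else 0
    ls = {v: float((perims[v][es] - perims[v][ed]) / perims[v][ed]) for v in perims}
    fac = {v: float((areas[v][ed] - areas[v][es]) / areas[v][ed]) for v in areas}
    ef = float((vol[ed] - vol[es]) / vol[ed])

    abnormal = {}
    for view, az in VIEW_AZIMUTH_DEG.items():
        w = _sector_weight(np.deg2rad(np.array([az, az + 180.0])), spec)
        abnormal[view] = bool(
            spec.abnormal_deficit_factor < 1.0
            and spec.abnormal_sector_deg is not None
            and w.max() > 0.5
        )
    return PhantomTruth(
        perimeter_mm=perims, ls=ls, fac=fac, ef=ef,
        ed_phase=ed, es_phase=es, abnormal_view=abnormal,
    )
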