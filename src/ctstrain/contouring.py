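"""LV endocardial contour extraction and perimeter measurement.

From a long-axis label slice, the LV endocardial boundary is extracted
as an ordered pixel chain, the mitral-valve segment (LV pixels adjacent
to the left atrium) is removed to open the contour, and the perimeter is
measured by three methods:

``naive``
    The raw boundary polyline through pixel centres; diagonal steps
    contribute sqrt(2) times the pixel spacing.  Papillary-muscle
    indentations and surface texture both inflate this length.
``hull``
    The LV mask is morphologically closed with a disk structuring
    element (default radius 10 pixels), filled to its convex hull, and
    the boundary polyline of that mask is measured.  The hull bridges
    papillary indentations but the measurement remains sensitive to
    digitisation and to the texture envelope of the surface.
``spline``
    A natural cubic spline is fit through the boundary chain of the
    hull-filled mask after downsampling (default: every 5th point),
    parameterised by cumulative chord length; its arc length smooths
    residual texture.

A boundary pixel is an LV pixel with at least one non-LV 4-neighbour;
the chain is traced with 8-connectivity.  The mitral interface is the
set of boundary pixels with an LA pixel in their 8-neighbourhood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import ConvexHull

from .reslicing import LABEL_LA, LABEL_LV, LaxSlice

log = logging.getLogger(__name__)

# clockwise Moore neighbourhood starting north
_DIRS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)
_N4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclass
class EndoContour:
    """An LV endocardial contour with its measured length.

    ``points_mm`` is an ordered polyline in slice coordinates
    (row, col) * pixel spacing.  Open contours run between the two
    mitral insertion points; ``closed`` marks contours where no LA was
    found (the view is then non-compliant).
    """

    points_mm: np.ndarray
    method: str
    closed: bool = False
    compliant: bool = True
    fallback: str | None = None

    def __post_init__(self):
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if len(self.points_mm) < 1:
            raise ValueError("contour needs at least one point")

    @property
    def length_mm(self) -> float:
        pts = self.points_mm
        if len(pts) < 2:
            return 0.0
        segs = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        if self.closed:
            segs += float(np.linalg.norm(pts[-1] - pts[0]))
        return float(segs)


def _largest_lv_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected LV component, holes filled."""
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("slice contains no LV pixels")
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        log.info("slice has %d LV components; keeping largest", n)
        mask = lab == keep
    return ndimage.binary_fill_holes(mask)


def _boundary_mask(comp: np.ndarray) -> np.ndarray:
    """Pixels of ``comp`` with >= 1 outside 4-neighbour (grid edge counts)."""
    inner = comp.copy()
    for dr, dc in _N4:
        inner &= np.roll(
            np.pad(comp, 1), (dr, dc), axis=(0, 1)
        )[1:-1, 1:-1]
    return comp & ~inner


_DIR_INDEX = {tuple(d): i for i, d in enumerate(_DIRS)}


def _moore_trace(comp: np.ndarray) -> np.ndarray:
    """Ordered closed trace of the outer boundary (Moore-neighbour walk
    with Jacob's stopping criterion).  Pixels may repeat on 1-px spurs."""
    rows, cols = np.nonzero(comp)
    r0 = int(rows.min())
    c0 = int(cols[rows == r0].min())
    start = (r0, c0)

    def inside(p):
        r, c = p
        return 0 <= r < comp.shape[0] and 0 <= c < comp.shape[1] and comp[r, c]

    cur = start
    back = (r0 - 1, c0)  # background pixel north of the start
    start_back = back
    chain = [start]
    max_steps = 8 * int(comp.sum()) + 8
    for _ in range(max_steps):
        k0 = _DIR_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        prev = back
        nxt = None
        for k in range(1, 9):
            d = (k0 + k) % 8
            cand = (cur[0] + _DIRS[d][0], cur[1] + _DIRS[d][1])
            if inside(cand):
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated pixel
            return np.array(chain)
        chain.append(nxt)
        cur, back = nxt, prev
        if cur == start and back == start_back:
            return np.array(chain[:-1])
    return np.array(chain)


def extract_lv_boundary(sl: LaxSlice) -> np.ndarray:
    """Ordered closed chain of LV boundary pixels (row, col).

    The chain covers exactly the pixels of the largest LV connected
    component that have a background or LA 4-neighbour, ordered by an
    8-connected walk around the component.
    """
    comp = _largest_lv_component(sl.lv_mask)
    b4 = _boundary_mask(comp)
    if b4.sum() == 1:
        return np.argwhere(b4)
    trace = _moore_trace(comp)
    # keep only true 4-boundary pixels, first occurrence, preserving order
    seen = set()
    chain = []
    for r, c in trace:
        if b4[r, c] and (r, c) not in seen:
            seen.add((r, c))
            chain.append((r, c))
    # any 4-boundary pixel the trace missed (should not happen for simple
    # shapes) is appended next to its nearest chain neighbour
    missing = [tuple(p) for p in np.argwhere(b4) if tuple(p) not in seen]
    if missing:
        log.warning("boundary trace missed %d pixels; reinserting", len(missing))
        for p in missing:
            d = np.linalg.norm(np.array(chain) - np.array(p), axis=1)
            chain.insert(int(np.argmin(d)) + 1, p)
    return np.array(chain)


def mv_interface(sl: LaxSlice, boundary: np.ndarray) -> np.ndarray:
    """Indices of boundary pixels with an LA pixel in their 8-neighbourhood."""
    la = np.pad(sl.la_mask, 1)
    idx = []
    for i, (r, c) in enumerate(boundary):
        if la[r : r + 3, c : c + 3].any():
            idx.append(i)
    return np.array(idx, dtype=int)


def _longest_circular_run(idx: np.ndarray, n: int) -> np.ndarray:
    """Longest circularly-contiguous run within sorted indices of a cycle
    of length ``n``."""
    if len(idx) == 0:
        return idx
    s = np.sort(idx)
    if len(s) == n:
        return s
    gaps = np.diff(np.concatenate([s, [s[0] + n]]))
    # the run ends where the largest gap starts
    end = int(np.argmax(gaps))
    order = np.concatenate([s[end + 1 :], s[: end + 1]])
    return order


def _open_chain(boundary: np.ndarray, mv_idx: np.ndarray,
                keep_insertions: bool = False) -> np.ndarray:
    """Remove the mitral run from a closed chain, returning the open
    remainder in cyclic order (endpoints adjacent to the removed run).

    With ``keep_insertions`` the first and last pixels of the mitral run
    (the insertion points) are retained as the endpoints of the open
    curve."""
    n = len(boundary)
    run = _longest_circular_run(mv_idx, n)
    drop = set(int(i) for i in mv_idx)
    if len(run) != len(mv_idx):
        log.info("mitral interface not circularly contiguous (%d/%d in main run)",
                 len(run), len(mv_idx))
    if keep_insertions:
        drop -= {int(run[0]), int(run[-1])}
        start = int(run[-1])
    else:
        start = (int(run[-1]) + 1) % n
    order = [(start + k) % n for k in range(n)]
    keep = [i for i in order if i not in drop]
    return boundary[keep]


def perimeter_naive(sl: LaxSlice) -> EndoContour:
    """Method A: raw boundary polyline, mitral segment removed."""
    boundary = extract_lv_boundary(sl)
    mv = mv_interface(sl, boundary)
    if len(mv) == 0:
        warnings.warn("no LA adjacency found; returning closed contour "
                      "(view non-compliant)", stacklevel=2)
        return EndoContour(boundary * sl.pixel_spacing, "naive",
                           closed=True, compliant=False)
    open_chain = _open_chain(boundary, mv)
    return EndoContour(open_chain * sl.pixel_spacing, "naive")


def close_mask_disk(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Binary closing with a Euclidean disk, via two distance transforms.

    Equivalent to dilation then erosion with the disk structuring
    element {offset : |offset| <= radius}, but O(n) in image size.
    """
    if radius_px <= 0:
        return mask.copy()
    pad = int(np.ceil(radius_px)) + 1
    m = np.pad(mask, pad)
    dil = ndimage.distance_transform_edt(~m) <= radius_px
    clo = ndimage.distance_transform_edt(dil) > radius_px
    return clo[pad:-pad, pad:-pad]


def hull_slice(sl: LaxSlice, closing_radius_px: float = 10.0) -> LaxSlice:
    """Papillary-corrected slice: the LV mask closed with a disk of
    ``closing_radius_px`` and filled to its convex hull; the LA labels
    are carried over unchanged (LV wins where the hull overlaps)."""
    comp = _largest_lv_component(sl.lv_mask)
    closed_mask = close_mask_disk(comp, closing_radius_px)
    bpts = np.argwhere(_boundary_mask(closed_mask)).astype(float)
    if len(bpts) >= 3 and np.linalg.matrix_rank(bpts - bpts[0]) == 2:
        hull = ConvexHull(bpts)
        lv = _rasterize_hull(closed_mask.shape, bpts[hull.vertices])
        lv |= closed_mask  # rasterisation never loses mask pixels
    else:  # degenerate (line or point) region: closing only
        lv = closed_mask
    labels = np.zeros_like(sl.labels)
    labels[sl.la_mask] = LABEL_LA
    labels[lv] = LABEL_LV
    return LaxSlice(labels, sl.pixel_spacing, sl.view, sl.phase)


def _opened_chain_mm(sl: LaxSlice, keep_insertions: bool = False):
    """(points_mm, closed_flag) of the boundary chain after mitral
    removal; closed (and non-compliant) when the slice has no LA."""
    boundary = extract_lv_boundary(sl)
    mv = mv_interface(sl, boundary)
    if len(mv) == 0:
        return boundary * sl.pixel_spacing, True
    return _open_chain(boundary, mv, keep_insertions) * sl.pixel_spacing, False


def perimeter_hull(sl: LaxSlice, closing_radius_px: float = 10.0) -> EndoContour:
    """Method B: boundary polyline of the disk-closed, convex-hull-filled
    LV mask, re-opened at the mitral interface.

    Papillary indentations vanish under the hull, but the measurement
    keeps the staircase digitisation and the surface-texture envelope of
    the mask boundary — the residual error the spline corrects.
    """
    hsl = hull_slice(sl, closing_radius_px)
    pts_mm, closed = _opened_chain_mm(hsl)
    if closed:
        warnings.warn("no LA adjacency found; returning closed hull contour "
                      "(view non-compliant)", stacklevel=2)
    return EndoContour(pts_mm, "hull", closed=closed, compliant=not closed)


def perimeter_spline(
    sl: LaxSlice,
    closing_radius_px: float = 10.0,
    downsample: int = 5,
    min_points: int = 8,
) -> EndoContour:
    """Method C: natural cubic spline through the downsampled boundary
    chain of the hull-filled mask; arc length by dense sampling.

    The chain is opened at the mitral interface with the two insertion
    pixels retained as end knots; the spline is parameterised by
    cumulative chord length with natural end conditions (zero second
    derivative at the insertions).  A contour with no mitral opening is
    fit with a periodic spline instead.  If fewer than ``min_points``
    knots remain after downsampling, the hull length is returned with a
    warning.
    """
    hsl = hull_slice(sl, closing_radius_px)
    pts_mm, closed = _opened_chain_mm(hsl, keep_insertions=True)
    ds = _downsample_keep_ends(pts_mm, downsample, closed=closed)
    if len(ds) < min_points:
        warnings.warn("fewer than %d points after downsampling; falling back "
                      "to hull perimeter" % min_points, stacklevel=2)
        hc = perimeter_hull(sl, closing_radius_px)
        return EndoContour(hc.points_mm, "spline", closed=hc.closed,
                           compliant=hc.compliant, fallback="hull")
    dense = _spline_curve(ds, closed=closed)
    return EndoContour(dense, "spline", closed=closed, compliant=not closed)


def _rasterize_hull(shape, verts: np.ndarray) -> np.ndarray:
    """Filled pixel mask of a convex polygon given in pixel coordinates."""
    from skimage.draw import polygon

    rr, cc = polygon(verts[:, 0], verts[:, 1], shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    # polygon() excludes some boundary pixels; add the vertices themselves
    vi = np.round(verts).astype(int)
    m[np.clip(vi[:, 0], 0, shape[0] - 1), np.clip(vi[:, 1], 0, shape[1] - 1)] = True
    return m


def _downsample_keep_ends(pts: np.ndarray, k: int, closed: bool) -> np.ndarray:
    if k <= 1:
        return pts
    idx = list(range(0, len(pts), k))
    if not closed and idx[-1] != len(pts) - 1:
        idx.append(len(pts) - 1)
    return pts[idx]


def _spline_curve(knots_mm: np.ndarray, closed: bool, oversample: int = 20
                  ) -> np.ndarray:
    """Evaluate a chord-length-parameterised cubic spline densely."""
    pts = knots_mm
    if closed:
        pts = np.vstack([pts, pts[:1]])
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0),
                                                        axis=1))])
    # collapse coincident knots (zero chord) to keep t strictly increasing
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, pts = t[keep], pts[keep]
    if len(pts) < 4:
        return pts
    bc = "periodic" if closed else "natural"
    cs = CubicSpline(t, pts, bc_type=bc)
    n_dense = max(oversample * len(pts), 400)
    return cs(np.linspace(t[0], t[-1], n_dense))


def measure_all(sl: LaxSlice, closing_radius_px: float = 10.0,
                downsample: int = 5) -> dict:
    """All three perimeter methods on one slice -> {method: EndoContour}."""
    return {
        "naive": perimeter_naive(sl),
        "hull": perimeter_hull(sl, closing_radius_px),
        "spline": perimeter_spline(sl, closing_radius_px, downsample),
    }


def render_slice(sl: LaxSlice, contours=None, path=None):
    """Debug rendering of a slice and its contours to a PNG (optional
    review aid; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    extent = (0, sl.labels.shape[1] * sl.pixel_spacing,
              sl.labels.shape[0] * sl.pixel_spacing, 0)
    ax.imshow(sl.labels.astype(float), cmap="gray", extent=extent,
              interpolation="nearest")
    for c in contours or []:
        ax.plot(c.points_mm[:, 1], c.points_mm[:, 0], lw=1.2,
                label=f"{c.method} ({c.length_mm:.1f} mm)")
    if contours:
        ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel("mm")
    ax.set_title(f"{sl.view} phase {sl.phase}")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
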