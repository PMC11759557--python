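"""Local cardiac coordinate frames and myocyte/sheetlet angle maps.

From short-axis endo/epi contours a per-voxel orthonormal frame is built:
R (radial, endocardium -> epicardium), C (circumferential, tangent to the
contour) and L (longitudinal, the slice normal pointing apex -> base), with
C = L x R so that {R, C, L} is right-handed.  Transmural depth runs from
0% at the endocardium to 100% at the epicardium.

All angles are projection angles of tensor eigenvectors onto this frame:

* helix angle (HA): elevation of e1's wall-tangent-plane projection out of
  the imaging plane; positive = right-handed helix (subendocardial type);
* transverse angle (TA): in-plane tilt of e1 from the circumferential
  direction toward the cavity, normally ~0 deg;
* sheetlet angle (E2A): angle of e2's projection within the radial /
  cross-myocyte plane, quoted as an absolute value in [0, 90] deg.

Eigenvector sign ambiguity is removed inside each angle function, so
e -> -e never changes a reported angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate
from scipy.spatial import cKDTree

from .dwi_io import LVContours

__all__ = [
    "LocalFrameField",
    "AngleMaps",
    "build_local_frames",
    "helix_angle",
    "transverse_angle",
    "sheetlet_angle",
    "angle_maps",
]

#: relative eigenvalue gap below which the e2/e3 assignment is unreliable
E2_E3_DEGENERACY_TOL = 0.02


@dataclass
class LocalFrameField:
    """Per-voxel {R, C, L} frame, transmural depth and wall thickness.

    Arrays are (rows, cols, 3) for the unit vectors, (rows, cols) for
    depth (percent, 0 = endo) and wall thickness (mm).  ``valid`` marks
    voxels where the frame is well defined (non-degenerate depth gradient).
    """

    radial: np.ndarray
    circumferential: np.ndarray
    longitudinal: np.ndarray
    depth: np.ndarray
    wall_thickness: np.ndarray
    valid: np.ndarray


def _resample_closed(points: np.ndarray, n: int = 4000) -> np.ndarray:
    """Resample a closed polygon with a periodic cubic spline.

    Dense resampling makes nearest-point distances accurate to well below
    the voxel scale even when the stored contour has only ~100 vertices.
    """
    pts = np.asarray(points, float)
    if pts.shape[0] < 4:
        pts = np.repeat(pts, 2, axis=0)
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=0, per=True)
    u = np.linspace(0, 1, n, endpoint=False)
    x, y = interpolate.splev(u, tck)
    return np.column_stack([x, y])


def _ring_distance(tree: cKDTree, ring: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Signed distance from points to a densely-sampled closed CCW polyline.

    Nearest vertex via KD-tree, then exact point-to-segment distance on
    that vertex's two adjacent segments — correct as long as the true
    foot lies on one of them, which dense resampling guarantees for
    smooth contours.  Positive inside the ring, negative outside, so the
    field stays smooth across the contour (needed when differentiating
    the transmural depth near the wall surfaces).
    """
    n = ring.shape[0]
    idx = tree.query(pts)[1]
    best = np.full(pts.shape[0], np.inf)
    sign = np.ones(pts.shape[0])
    for a, b in ((idx - 1, idx), (idx, (idx + 1) % n)):
        p0 = ring[a % n]
        seg = ring[b % n] - p0
        seg_len2 = np.maximum(np.sum(seg**2, axis=1), 1e-300)
        t = np.clip(np.sum((pts - p0) * seg, axis=1) / seg_len2, 0.0, 1.0)
        foot = p0 + t[:, None] * seg
        dist = np.linalg.norm(pts - foot, axis=1)
        closer = dist < best
        # CCW ring: positive cross => point left of segment => inside
        cross = seg[:, 0] * (pts[:, 1] - p0[:, 1]) - seg[:, 1] * (pts[:, 0] - p0[:, 0])
        sign = np.where(closer, np.where(cross >= 0, 1.0, -1.0), sign)
        best = np.where(closer, dist, best)
    return best * sign


def build_local_frames(
    contours: LVContours,
    grid_shape: tuple[int, int],
    pixel_spacing: float,
    mask: np.ndarray | None = None,
) -> LocalFrameField:
    """Build the per-voxel cardiac frame from endo/epi contours.

    Depth is the normalized distance between the contours,
    ``d = 100 * |p - p_endo| / (|p - p_endo| + |p - p_epi|)``, evaluated on
    the full grid; R is the in-plane unit gradient of the depth field
    (pointing endo -> epi), L the slice normal, C = L x R.
    """
    rows, cols = grid_shape
    xs = np.arange(rows) * pixel_spacing
    ys = np.arange(cols) * pixel_spacing
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])

    ring_endo = _resample_closed(contours.endo)
    ring_epi = _resample_closed(contours.epi)
    tree_endo = cKDTree(ring_endo)
    tree_epi = cKDTree(ring_epi)

    def depth_at(p: np.ndarray) -> np.ndarray:
        de = -_ring_distance(tree_endo, ring_endo, p)  # positive in the wall
        dp = _ring_distance(tree_epi, ring_epi, p)     # positive in the wall
        total = de + dp
        return 100.0 * de / np.where(total > 0, total, 1.0), total

    depth, total = depth_at(pts)
    depth = depth.reshape(grid_shape)
    total = total.reshape(grid_shape)

    # central differences of the continuous distance field at a step well
    # below the voxel size: O(h^2) truncation is then negligible and R is
    # accurate to ~1e-6 rad even near the contours
    h = 0.05 * pixel_spacing
    ex = np.array([h, 0.0])
    ey = np.array([0.0, h])
    gx = (depth_at(pts + ex)[0] - depth_at(pts - ex)[0]) / (2 * h)
    gy = (depth_at(pts + ey)[0] - depth_at(pts - ey)[0]) / (2 * h)
    gx = gx.reshape(grid_shape)
    gy = gy.reshape(grid_shape)
    norm = np.hypot(gx, gy)
    valid = norm > 1e-6
    safe = np.where(valid, norm, 1.0)
    radial = np.zeros(grid_shape + (3,))
    radial[..., 0] = gx / safe
    radial[..., 1] = gy / safe

    longitudinal = np.zeros_like(radial)
    longitudinal[..., 2] = 1.0
    circumferential = np.cross(longitudinal, radial)

    if mask is not None:
        valid = valid & mask
    return LocalFrameField(
        radial=radial,
        circumferential=circumferential,
        longitudinal=longitudinal,
        depth=depth,
        wall_thickness=total,
        valid=valid,
    )


# -- angle computations --------------------------------------------------------


def _dots(e, r, c, l):
    """Components of e in the local frame, broadcasting over leading dims."""
    e = np.asarray(e, float)
    return (
        np.sum(e * r, axis=-1),
        np.sum(e * c, axis=-1),
        np.sum(e * l, axis=-1),
    )


def helix_angle(e1, radial, circumferential, longitudinal):
    """Helix angle in degrees, range [-90, 90).

    e1 is projected into the wall-tangent (C-L) plane; the sign ambiguity
    is resolved by flipping so the circumferential component is >= 0.
    Voxels where e1 is (numerically) parallel to R return NaN.
    """
    er, ec, el = _dots(e1, radial, circumferential, longitudinal)
    tangent_norm = np.hypot(ec, el)
    flip = np.where(ec < 0, -1.0, 1.0)
    # on the knife edge ec == 0, pick el >= 0 so atan2 lands on +90
    flip = np.where((ec == 0) & (el < 0), -1.0, flip)
    ha = np.degrees(np.arctan2(flip * el, flip * ec))
    ha = np.where(ha >= 90.0, ha - 180.0, ha)  # fold +90 onto -90
    return np.where(tangent_norm > 1e-9, ha, np.nan)


def transverse_angle(e1, radial, circumferential, longitudinal):
    """Transverse angle in degrees: in-plane tilt of e1 off circumferential."""
    er, ec, el = _dots(e1, radial, circumferential, longitudinal)
    plane_norm = np.hypot(ec, er)
    flip = np.where(ec < 0, -1.0, 1.0)
    flip = np.where((ec == 0) & (er < 0), -1.0, flip)
    ta = np.degrees(np.arctan2(flip * er, flip * ec))
    return np.where(plane_norm > 1e-9, ta, np.nan)


def sheetlet_angle(e1, e2, radial, circumferential, longitudinal, signed=False):
    """Sheetlet (E2A) angle in degrees.

    The cross-myocyte direction x is perpendicular to e1's tangent-plane
    projection within the wall-tangent plane (x = R x e1proj); e2 is
    projected into the radial/cross-myocyte plane and its angle from x is
    reported, folded into [0, 90] unless ``signed``.
    """
    e1 = np.asarray(e1, float)
    e2 = np.asarray(e2, float)
    r, c, l = radial, circumferential, longitudinal
    e1r = np.sum(e1 * r, axis=-1)[..., None]
    e1proj = e1 - e1r * r
    nrm = np.linalg.norm(e1proj, axis=-1)
    degenerate = nrm < 1e-9
    e1proj = e1proj / np.where(degenerate, 1.0, nrm)[..., None]
    x = np.cross(r, e1proj)
    e2proj = e2 - np.sum(e2 * e1proj, axis=-1)[..., None] * e1proj
    comp_r = np.sum(e2proj * r, axis=-1)
    comp_x = np.sum(e2proj * x, axis=-1)
    small = np.hypot(comp_r, comp_x) < 1e-9
    ang = np.degrees(np.arctan2(comp_r, comp_x))
    if signed:
        # fold the axial (mod 180) ambiguity into (-90, 90]
        ang = np.where(ang > 90.0, ang - 180.0, ang)
        ang = np.where(ang <= -90.0, ang + 180.0, ang)
    else:
        ang = np.abs(ang)
        ang = np.where(ang > 90.0, 180.0 - ang, ang)
    return np.where(degenerate | small, np.nan, ang)


@dataclass
class AngleMaps:
    """HA/TA/E2A maps (degrees) with a low-confidence mask for E2A.

    ``e2a_low_confidence`` marks voxels whose lambda2/lambda3 gap is inside
    the degeneracy tolerance: there the e2/e3 assignment — and hence E2A —
    is unstable and should be excluded from summaries by cautious users.
    """

    ha: np.ndarray
    ta: np.ndarray
    e2a: np.ndarray
    e2a_low_confidence: np.ndarray


def angle_maps(eigensystem, frames: LocalFrameField, mask: np.ndarray,
               signed_e2a: bool = False) -> AngleMaps:
    """Compute HA/TA/E2A maps from a fitted eigensystem on the grid."""
    r, c, l = frames.radial, frames.circumferential, frames.longitudinal
    e1 = eigensystem.e1
    e2 = eigensystem.e2
    ha = helix_angle(e1, r, c, l)
    ta = transverse_angle(e1, r, c, l)
    e2a = sheetlet_angle(e1, e2, r, c, l, signed=signed_e2a)
    lam = eigensystem.eigenvalues
    with np.errstate(divide="ignore", invalid="ignore"):
        gap = np.abs(lam[..., 1] - lam[..., 2]) / np.where(
            lam[..., 1] != 0, np.abs(lam[..., 1]), 1.0
        )
    lowconf = (gap < E2_E3_DEGENERACY_TOL) & mask
    outside = ~(mask & frames.valid)
    for m in (ha, ta, e2a):
        m[outside] = np.nan
    return AngleMaps(ha=ha, ta=ta, e2a=e2a, e2a_low_confidence=lowconf)
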