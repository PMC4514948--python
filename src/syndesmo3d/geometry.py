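"""Measurement-plane construction and landmark morphometry.

The measurement procedure, on labeled bone surfaces in the canonical frame
(+x lateral, +y anterior, +z proximal):

1. fit **plane X** (the tibial plafond) by total least squares to the
   articular patch grown from a seed point on the distal tibia;
2. scan levels above plane X and, at each, detect the incisura fibularis as
   the dominant concavity of the tibial cross-section; **point A** is the
   anterior tubercle corner at the level where the incisura is most
   prominent (deepest), i.e. the level of maximal clear space;
3. **plane Y** passes through A parallel to plane X; its height above
   plane X is the parameter **XY**;
4. in plane Y: B and D are the fibular points nearest to A and to the
   posterior tubercle corner C; E is the deepest point of the incisura.
   TCS-A = |AB|, TCS-P = |CD|, IFD = dist(E, line AC);
5. **point F**, the proximal tip of the incisura, is found by tracking the
   notch upward until its depth falls below a visibility threshold;
   IFH = height of F above plane X.

All constructions work identically on analytic phantom surfaces and on
marching-cubes surfaces from segmented volumes; a 2-D re-measurement path
resamples the volume at plane Y and repeats step 4 on in-plane contours.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage.measure import find_contours

from .segmentation import BoneSurface, VoxelVolume, BONE_THRESHOLD_HU

#: Canonical anatomic frame (columns: lateral, anterior, proximal).
CANONICAL_FRAME = np.eye(3)
#: Minimum concavity depth for the incisura to count as present (mm).
NOTCH_VISIBILITY_MM = 0.5
#: Level-search window for point A above plane X (mm).
POINT_A_WINDOW = (4.0, 20.0)
#: Default level-search step, one CT reconstruction interval (mm).
DEFAULT_STEP_MM = 0.625
#: Contours with less in-plane area than this are slicing debris (mm^2).
MIN_CONTOUR_AREA_MM2 = 1.0


class GeometryError(RuntimeError):
    """Raised when a landmark construction fails on the given anatomy."""


# ---------------------------------------------------------------------------
# planes and in-plane frames
# ---------------------------------------------------------------------------

@dataclass
class AnatomicPlane:
    """A plane given by a point and a unit normal (mm)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if not norm > 0:
            raise ValueError("plane normal must be nonzero")
        self.normal = self.normal / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal

    def offset(self, distance: float) -> "AnatomicPlane":
        return AnatomicPlane(self.point + distance * self.normal, self.normal)


@dataclass
class PlaneFrame:
    """Orthonormal 2-D chart of a plane.

    Axes are the canonical lateral/anterior directions projected into the
    plane (Gram-Schmidt), so in-plane +u is lateral-ish and +v anterior-ish
    even on tilted planes or mirrored scenes.
    """

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @classmethod
    def for_plane(cls, plane: AnatomicPlane,
                  frame: np.ndarray = CANONICAL_FRAME) -> "PlaneFrame":
        n = plane.normal
        u = frame[:, 0] - (frame[:, 0] @ n) * n
        if np.linalg.norm(u) < 1e-9:  # lateral axis parallel to normal
            u = frame[:, 1] - (frame[:, 1] @ n) * n
        u = u / np.linalg.norm(u)
        v = frame[:, 1] - (frame[:, 1] @ n) * n - (frame[:, 1] @ u) * u
        if np.linalg.norm(v) < 1e-9:
            v = np.cross(n, u)
        v = v / np.linalg.norm(v)
        return cls(plane.point.copy(), u, v)

    def to_2d(self, points3: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points3) - self.origin
        return np.column_stack([rel @ self.u, rel @ self.v])

    def to_3d(self, points2: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points2)
        out = self.origin + np.outer(p[:, 0], self.u) + np.outer(p[:, 1],
                                                                 self.v)
        return out[0] if np.asarray(points2).ndim == 1 else out


@dataclass
class Contour:
    """A closed planar polyline in a plane chart (CCW, mm)."""

    points: np.ndarray          # (n, 2), first point not repeated
    frame: PlaneFrame
    label: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("contour needs >= 3 distinct points")
        if _shoelace(pts) < 0:
            pts = pts[::-1]
        self.points = pts

    @property
    def area(self) -> float:
        return _shoelace(self.points)

    def contains(self, point2: np.ndarray) -> bool:
        return Polygon(self.points).contains(Point(*point2))


@dataclass
class LandmarkSet:
    """Plane-Y landmarks A-E (and optionally F) as 3-D mm points."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    F: np.ndarray | None = None
    plane_y: AnatomicPlane | None = None
    tags: dict[str, str] = field(default_factory=dict)


@dataclass
class MeasurementRecord:
    """One subject x modality row of syndesmosis parameters (mm)."""

    modality: str
    subject_id: str = ""
    side: str = "right"
    xy: float | None = None
    tcs_a: float | None = None
    tcs_p: float | None = None
    tcs: float | None = None
    tfo: float | None = None
    ifd: float | None = None
    ifh: float | None = None

    def __post_init__(self) -> None:
        for name in ("xy", "tcs_a", "tcs_p", "tcs", "ifd", "ifh"):
            value = getattr(self, name)
            if value is not None and value < -1e-9:
                raise ValueError(f"{name} must be >= 0, got {value}")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id, "side": self.side,
            "modality": self.modality, "XY": self.xy, "TCS_A": self.tcs_a,
            "TCS_P": self.tcs_p, "TCS": self.tcs, "TFO": self.tfo,
            "IFD": self.ifd, "IFH": self.ifh,
        }


# ---------------------------------------------------------------------------
# small computational-geometry helpers
# ---------------------------------------------------------------------------

def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

def _nearest_on_polyline(point: np.ndarray, poly: np.ndarray
                         ) -> tuple[np.ndarray, float]:
    """Closest point on a closed polyline, evaluated on edges."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    ab = b - a
    denom = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-30)
    t = np.clip(((point - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    dist = np.linalg.norm(proj - point, axis=1)
    i = int(np.argmin(dist))
    return proj[i], float(dist[i])

def _convex_hull_indices(pts: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    return ConvexHull(pts).vertices  # CCW order

def _cross2(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

def _line_intersection(p1, d1, p2, d2) -> np.ndarray | None:
    denom = float(_cross2(d1, d2))
    if abs(denom) < 1e-9 * np.linalg.norm(d1) * np.linalg.norm(d2):
        return None
    t = float(_cross2(p2 - p1, d2)) / denom
    return p1 + t * d1


# ---------------------------------------------------------------------------
# plane X: the tibial plafond
# ---------------------------------------------------------------------------

def fit_plafond_plane(tibia: BoneSurface, articular_seed: np.ndarray,
                      max_normal_angle_deg: float = 30.0,
                      max_radius_mm: float = 25.0,
                      min_faces: int = 50) -> AnatomicPlane:
    """Total-least-squares plane through the distal articular patch.

    The patch grows over face adjacency from the face nearest the seed,
    keeping faces whose normals stay within ``max_normal_angle_deg`` of the
    seed face normal and within ``max_radius_mm`` (graph geodesic through
    face centers).  The fitted normal is oriented proximally (toward the
    tibial shaft).
    """
    mesh = tibia.mesh
    seed = np.asarray(articular_seed, dtype=float)
    # nearest face by exact point-triangle distance (brute force; meshes
    # here are small enough that no spatial index is needed)
    closest = trimesh.triangles.closest_point(
        mesh.triangles, np.tile(seed, (len(mesh.triangles), 1)))
    dist_all = np.linalg.norm(closest - seed, axis=1)
    seed_face = int(np.argmin(dist_all))
    if dist_all[seed_face] > 5.0:
        raise GeometryError(
            f"articular seed is {dist_all[seed_face]:.1f} mm from the "
            "tibial surface (must be within 5 mm)")
    normals = mesh.face_normals
    centers = mesh.triangles_center
    cos_limit = np.cos(np.deg2rad(max_normal_angle_deg))
    adjacency: dict[int, list[int]] = {}
    for f1, f2 in mesh.face_adjacency:
        adjacency.setdefault(int(f1), []).append(int(f2))
        adjacency.setdefault(int(f2), []).append(int(f1))
    ref = normals[seed_face]
    patch = {seed_face}
    queue = deque([seed_face])
    # the normal cone keeps the patch nearly flat, so straight-line
    # distance from the seed is a faithful stand-in for geodesic radius
    # (center-to-center graph distance badly overestimates it on meshes
    # with skinny triangles)
    while queue:
        face = queue.popleft()
        for nb in adjacency.get(face, ()):
            if nb in patch:
                continue
            if normals[nb] @ ref < cos_limit:
                continue
            if np.linalg.norm(centers[nb] - seed) > max_radius_mm:
                continue
            patch.add(nb)
            queue.append(nb)
    if len(patch) < min_faces:
        raise GeometryError(
            f"articular patch too small ({len(patch)} faces < {min_faces})")
    verts = np.unique(mesh.faces[list(patch)].ravel())
    pts = mesh.vertices[verts]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[-1]
    if normal @ (mesh.centroid - centroid) < 0:
        normal = -normal
    return AnatomicPlane(centroid, normal)


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------

def _section_polylines(mesh: trimesh.Trimesh, plane: AnatomicPlane
                       ) -> list[np.ndarray]:
    """Closed 3-D polylines of a mesh/plane section (robust to coplanar
    vertices via a tiny retry nudge)."""
    for eps in (0.0, 1e-6, -1e-6, 3e-6):
        try:
            path = mesh.section(plane_origin=plane.point
                                + eps * plane.normal,
                                plane_normal=plane.normal)
        except Exception:
            continue
        if path is None:
            if eps == 0.0:
                continue
            return []
        try:
            return [np.asarray(d) for d in path.discrete]
        except Exception:
            continue
    return []


def slice_contours(surfaces, plane: AnatomicPlane,
                   frame: np.ndarray = CANONICAL_FRAME,
                   min_area_mm2: float = MIN_CONTOUR_AREA_MM2
                   ) -> list[Contour]:
    """Planar cross-section contours per bone, in the plane's 2-D chart.

    Degenerate slivers (area below ``min_area_mm2``, e.g. a tangent graze)
    are filtered out; an empty result is returned, not raised, when the
    plane misses everything.
    """
    if isinstance(surfaces, (BoneSurface,)):
        surfaces = [surfaces]
    elif isinstance(surfaces, dict):
        surfaces = list(surfaces.values())
    chart = PlaneFrame.for_plane(plane, frame)
    out: list[Contour] = []
    for surf in surfaces:
        for poly3 in _section_polylines(surf.mesh, plane):
            pts2 = chart.to_2d(poly3)
            if len(pts2) < 3 or abs(_shoelace(
                    pts2 if not np.allclose(pts2[0], pts2[-1])
                    else pts2[:-1])) < min_area_mm2:
                continue
            out.append(Contour(pts2, chart, label=surf.label))
    return out


# ---------------------------------------------------------------------------
# the incisura and its tubercle corners
# ---------------------------------------------------------------------------

@dataclass
class _Incisura:
    """Dominant concavity of a tibial cross-section contour."""

    i_entry: int            # contour index of one hull-bridge endpoint
    i_exit: int             # contour index of the other endpoint
    arc: np.ndarray         # indices of notch points strictly between them
    depth: float            # max perpendicular deviation from the chord
    deepest: np.ndarray     # the deepest notch point (2-D)


def _find_incisura(contour: Contour,
                   min_depth_mm: float = NOTCH_VISIBILITY_MM
                   ) -> _Incisura | None:
    pts = contour.points
    n = len(pts)
    hull = list(_convex_hull_indices(pts))
    best: _Incisura | None = None
    for h in range(len(hull)):
        i, j = hull[h], hull[(h + 1) % len(hull)]
        gap = (j - i) % n
        if gap <= 1:
            continue  # adjacent on the contour: no bridged concavity
        arc = (np.arange(i + 1, i + gap) % n)
        chord = pts[j] - pts[i]
        length = np.linalg.norm(chord)
        if length < 1e-9:
            continue
        # CCW contour: the concavity deviates to the left of the hull edge
        dev = _cross2((chord / length)[None, :], pts[arc] - pts[i])
        depth = float(np.max(dev))
        if depth >= (best.depth if best else min_depth_mm):
            # qhull keeps only extreme points, so when the notch is cut into
            # a straight edge the bridge overshoots the true corners; trim
            # leading/trailing points that lie on the chord itself
            lo, hi = 0, len(arc)
            while lo < hi - 1 and dev[lo] <= 1e-6:
                lo += 1
            while hi - 1 > lo and dev[hi - 1] <= 1e-6:
                hi -= 1
            entry = int(arc[lo - 1]) if lo > 0 else int(i)
            exit_ = int(arc[hi]) if hi < len(arc) else int(j)
            arc_t = arc[lo:hi]
            deepest = pts[arc_t[int(np.argmax(dev[lo:hi]))]]
            best = _Incisura(i_entry=entry, i_exit=exit_, arc=arc_t,
                             depth=depth, deepest=deepest)
    return best


def tubercle_corner(tibia_contour: Contour, which: str,
                    min_depth_mm: float = NOTCH_VISIBILITY_MM,
                    snap_mm: float = 1.0) -> np.ndarray:
    """Corner of the anterior or posterior tubercle bounding the incisura.

    The corner is the intersection of the two supporting lines of the
    tubercle -- the convex-hull edge along its outer flank and the hull
    chord bridging the incisura -- snapped to the nearest contour vertex
    (within ``snap_mm``; the corner must lie on the bone).  For a polygonal
    tubercle both lines meet at the hull vertex itself.
    """
    if which not in ("anterior", "posterior"):
        raise ValueError("which must be 'anterior' or 'posterior'")
    inc = _find_incisura(tibia_contour, min_depth_mm)
    if inc is None:
        raise GeometryError("no incisura at this level")
    pts = tibia_contour.points
    entry, exit_ = pts[inc.i_entry], pts[inc.i_exit]
    # anterior endpoint: larger in-plane v (the anterior chart axis)
    if entry[1] >= exit_[1]:
        ant_idx, post_idx = inc.i_entry, inc.i_exit
    else:
        ant_idx, post_idx = inc.i_exit, inc.i_entry
    idx = ant_idx if which == "anterior" else post_idx
    corner_vertex = pts[idx]
    # supporting lines: hull edge on the non-notch side of this endpoint,
    # and the incisura-opening chord
    hull = list(_convex_hull_indices(pts))
    chord_dir = pts[inc.i_exit] - pts[inc.i_entry]
    if idx in hull:
        h = hull.index(idx)
        if idx == inc.i_entry:  # notch follows: flank precedes on the hull
            flank_other = pts[hull[h - 1]]
        else:
            flank_other = pts[hull[(h + 1) % len(hull)]]
        flank_dir = corner_vertex - flank_other
        corner = _line_intersection(pts[inc.i_entry], chord_dir,
                                    flank_other, flank_dir)
    else:
        # the corner sits on the interior of a hull edge (notch cut into a
        # straight flank): both supporting lines coincide at the vertex
        corner = None
    if corner is None or np.linalg.norm(corner - corner_vertex) > 2.0:
        corner = corner_vertex
    # project onto the bone
    d_vertex = np.linalg.norm(pts - corner, axis=1)
    i_near = int(np.argmin(d_vertex))
    if d_vertex[i_near] <= snap_mm:
        return pts[i_near].copy()
    snapped, _ = _nearest_on_polyline(corner, pts)
    return snapped


# ---------------------------------------------------------------------------
# point A, plane Y
# ---------------------------------------------------------------------------

def _tibia_contour_at(tibia: BoneSurface, plane: AnatomicPlane,
                      frame: np.ndarray) -> Contour | None:
    contours = slice_contours([tibia], plane, frame)
    if not contours:
        return None
    return max(contours, key=lambda c: c.area)


def locate_point_A(tibia: BoneSurface, plane_x: AnatomicPlane,
                   frame: np.ndarray = CANONICAL_FRAME,
                   window_mm: tuple[float, float] = POINT_A_WINDOW,
                   step_mm: float = DEFAULT_STEP_MM
                   ) -> tuple[np.ndarray, float]:
    """Point A and its height ``z*`` (= parameter XY) above plane X.

    Levels ``z`` in the window are scanned at ``step_mm``; at each level the
    anterior tubercle corner is built and the level maximizing incisura
    prominence (concavity depth, i.e. maximal clear-space/IFD level) is
    selected; ties break toward the most distal level.
    """
    zs = np.arange(window_mm[0], window_mm[1] + 1e-9, step_mm)
    best_depth, best_corner, best_z = -np.inf, None, None
    for z in zs:
        contour = _tibia_contour_at(tibia, plane_x.offset(float(z)), frame)
        if contour is None:
            continue
        inc = _find_incisura(contour)
        if inc is None:
            continue
        if inc.depth > best_depth + 1e-12:
            corner = tubercle_corner(contour, "anterior")
            best_depth, best_z = inc.depth, float(z)
            best_corner = contour.frame.to_3d(corner)
    if best_corner is None:
        raise GeometryError(
            "no level in the search window shows an incisura corner")
    z_star = float(plane_x.signed_distance(best_corner)[0])
    return best_corner, z_star


def build_plane_Y(plane_x: AnatomicPlane, point_a: np.ndarray
                  ) -> tuple[AnatomicPlane, float]:
    """Plane through A parallel to plane X; XY = height of A above plane X."""
    xy = float(plane_x.signed_distance(point_a)[0])
    if xy < 0:
        raise GeometryError(
            f"point A lies {-xy:.2f} mm below the plafond plane; "
            "landmark/plane inconsistency")
    return AnatomicPlane(np.asarray(point_a, dtype=float),
                         plane_x.normal), xy


# ---------------------------------------------------------------------------
# landmarks B-E and the 3-D measurements
# ---------------------------------------------------------------------------

def locate_landmarks(tibia_c: Contour, fibula_c: Contour | None,
                     point_a: np.ndarray) -> LandmarkSet:
    """Landmarks A-E in plane Y.

    B and D are nearest points on the fibular contour (evaluated on edges)
    to A and to the posterior tubercle corner C; E is the incisura point at
    maximal perpendicular distance from line AC, on the medial side.
    """
    if fibula_c is None:
        raise GeometryError("fibula not present at plane Y")
    a3 = np.asarray(point_a, dtype=float)
    chart = tibia_c.frame
    a2 = chart.to_2d(a3)[0]
    b2, _ = _nearest_on_polyline(a2, fibula_c.points)
    c2 = tubercle_corner(tibia_c, "posterior")
    d2, _ = _nearest_on_polyline(c2, fibula_c.points)
    inc = _find_incisura(tibia_c)
    if inc is None:
        raise GeometryError("no incisura in the tibial contour at plane Y")
    ac = c2 - a2
    nrm = np.linalg.norm(ac)
    if nrm < 1e-9:
        raise GeometryError("degenerate A-C chord")
    arc_pts = tibia_c.points[inc.arc]
    dev = _cross2((ac / nrm)[None, :], arc_pts - a2)
    # medial side of AC: the side the notch recedes toward
    side = 1.0 if np.max(dev) >= -np.min(dev) else -1.0
    e2 = arc_pts[int(np.argmax(side * dev))]
    return LandmarkSet(
        A=a3, B=chart.to_3d(b2), C=chart.to_3d(c2), D=chart.to_3d(d2),
        E=chart.to_3d(e2),
        tags={"A": "anterior tubercle corner",
              "B": "fibula nearest to A",
              "C": "posterior tubercle corner",
              "D": "fibula nearest to C",
              "E": "incisura deepest point"})


def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray
                         ) -> float:
    ab = b - a
    nrm = np.linalg.norm(ab)
    if nrm < 1e-12:
        return float(np.linalg.norm(p - a))
    return float(np.linalg.norm(np.cross(ab / nrm, p - a)))


def measure_3d(landmarks: LandmarkSet, plane_x: AnatomicPlane,
               plane_y: AnatomicPlane, subject_id: str = "",
               side: str = "right") -> MeasurementRecord:
    """TCS-A = |AB|, TCS-P = |CD|, IFD = dist(E, line AC),
    XY = height of plane Y, IFH = height of F (if located)."""
    xy = float(plane_x.signed_distance(plane_y.point)[0])
    ifh = None
    if landmarks.F is not None:
        ifh = float(plane_x.signed_distance(landmarks.F)[0])
    return MeasurementRecord(
        modality="3-D", subject_id=subject_id, side=side, xy=xy,
        tcs_a=float(np.linalg.norm(landmarks.A - landmarks.B)),
        tcs_p=float(np.linalg.norm(landmarks.C - landmarks.D)),
        ifd=_point_line_distance(landmarks.E, landmarks.A, landmarks.C),
        ifh=ifh)


# ---------------------------------------------------------------------------
# point F: proximal tip of the incisura
# ---------------------------------------------------------------------------

def locate_point_F(tibia: BoneSurface, plane_x: AnatomicPlane,
                   plane_y: AnatomicPlane,
                   frame: np.ndarray = CANONICAL_FRAME,
                   step_mm: float = 0.25,
                   min_depth_mm: float = NOTCH_VISIBILITY_MM
                   ) -> tuple[np.ndarray, float]:
    """Track the incisura upward from plane Y; F is the deepest-point of the
    notch at the most proximal level where its depth still exceeds the
    visibility threshold.  Returns (F, height of F above plane X)."""
    z0 = float(plane_x.signed_distance(plane_y.point)[0])
    z_max = float(np.max(plane_x.signed_distance(tibia.mesh.vertices)))
    last: tuple[np.ndarray, float] | None = None
    z = z0
    while z <= z_max + 1e-9:
        contour = _tibia_contour_at(tibia, plane_x.offset(z), frame)
        if contour is None:
            break
        inc = _find_incisura(contour, min_depth_mm)
        if inc is None or inc.depth <= min_depth_mm:
            break
        last = (contour.frame.to_3d(inc.deepest), z)
        z += step_mm
    else:
        raise GeometryError("incisura not closed within volume")
    if last is None:
        raise GeometryError("no visible incisura at or above plane Y")
    return last[0], last[1]


# ---------------------------------------------------------------------------
# 2-D axial re-measurement
# ---------------------------------------------------------------------------

def resample_plane(vol: VoxelVolume, plane: AnatomicPlane,
                   frame: np.ndarray = CANONICAL_FRAME,
                   pixel_mm: float | None = None
                   ) -> tuple[np.ndarray, PlaneFrame, float]:
    """One-voxel-thick oblique section of the volume at a plane (linearly
    interpolated).  Returns (image, chart, pixel size); image[i, j] samples
    chart coordinates (u0 + i*px, v0 + j*px)."""
    chart = PlaneFrame.for_plane(plane, frame)
    px = float(pixel_mm if pixel_mm is not None else min(vol.spacing))
    shape = np.array(vol.values.shape)
    corners_idx = np.stack(np.meshgrid(*[(0, s - 1) for s in shape],
                                       indexing="ij"), axis=-1).reshape(-1, 3)
    corners = np.asarray(vol.origin) + corners_idx * np.asarray(vol.spacing)
    uv = chart.to_2d(corners)
    u_lo, v_lo = uv.min(axis=0) - px
    u_hi, v_hi = uv.max(axis=0) + px
    # anchor the grid so in-plane samples coincide with voxel centers when
    # the plane is an axial slice of the volume
    u0 = np.floor(u_lo / px) * px
    v0 = np.floor(v_lo / px) * px
    nu = int(np.ceil((u_hi - u0) / px)) + 1
    nv = int(np.ceil((v_hi - v0) / px)) + 1
    uu, vv = np.meshgrid(u0 + np.arange(nu) * px, v0 + np.arange(nv) * px,
                         indexing="ij")
    pts3 = (chart.origin + uu[..., None] * chart.u + vv[..., None] * chart.v)
    idx = (pts3 - np.asarray(vol.origin)) / np.asarray(vol.spacing)
    image = ndimage.map_coordinates(np.asarray(vol.values, dtype=float),
                                    idx.reshape(-1, 3).T, order=1,
                                    cval=-1000.0).reshape(nu, nv)
    section_chart = PlaneFrame(chart.to_3d(np.array([u0, v0])),
                               chart.u, chart.v)
    return image, section_chart, px


def measure_axial_2d(vol: VoxelVolume, plane_y: AnatomicPlane,
                     seeds: dict[str, np.ndarray],
                     frame: np.ndarray = CANONICAL_FRAME,
                     threshold_hu: float = BONE_THRESHOLD_HU,
                     subject_id: str = "", side: str = "right"
                     ) -> MeasurementRecord:
    """Re-measure TCS-A, TCS-P and IFD on the 2-D oblique section at plane Y.

    The section is re-segmented in-plane at the bone threshold with
    sub-pixel (linearly interpolated) contours; bones are identified by the
    in-plane projections of the supplied seed points.
    """
    lo = np.asarray(vol.origin)
    hi = lo + (np.array(vol.values.shape) - 1) * np.asarray(vol.spacing)
    if np.any(plane_y.point < lo) or np.any(plane_y.point > hi):
        raise GeometryError("plane Y lies outside the volume")
    image, chart, px = resample_plane(vol, plane_y, frame)
    raw = find_contours(image, level=threshold_hu)
    contours: list[Contour] = []
    for rc in raw:
        if len(rc) < 4 or not np.allclose(rc[0], rc[-1]):
            continue  # open contour at the image boundary
        pts2 = rc[:-1] * px  # (row, col) -> (u, v) mm relative to chart
        if abs(_shoelace(pts2)) < MIN_CONTOUR_AREA_MM2:
            continue
        contours.append(Contour(pts2, chart))
    by_bone: dict[str, Contour] = {}
    for name in ("tibia", "fibula"):
        if name not in seeds:
            continue
        seed2 = chart.to_2d(np.asarray(seeds[name], dtype=float))[0]
        for contour in contours:
            if contour.contains(seed2):
                if (name not in by_bone
                        or contour.area > by_bone[name].area):
                    by_bone[name] = contour
    if "tibia" not in by_bone:
        raise GeometryError("tibia not found in the plane-Y section")
    if "fibula" not in by_bone:
        raise GeometryError("fibula not present at plane Y")
    tibia_c, fibula_c = by_bone["tibia"], by_bone["fibula"]
    a2 = tubercle_corner(tibia_c, "anterior")
    landmarks = locate_landmarks(tibia_c, fibula_c, chart.to_3d(a2))
    rec = measure_3d(landmarks, plane_y, plane_y, subject_id, side)
    return MeasurementRecord(
        modality="2-D axial", subject_id=subject_id, side=side,
        tcs_a=rec.tcs_a, tcs_p=rec.tcs_p, ifd=rec.ifd)


# ---------------------------------------------------------------------------
# convenience: full 3-D measurement on labeled surfaces
# ---------------------------------------------------------------------------

def measure_surfaces(surfaces: dict[str, BoneSurface] | list[BoneSurface],
                     articular_seed: np.ndarray,
                     frame: np.ndarray = CANONICAL_FRAME,
                     step_mm: float = DEFAULT_STEP_MM,
                     subject_id: str = "", side: str = "right"
                     ) -> tuple[MeasurementRecord, LandmarkSet,
                                AnatomicPlane, AnatomicPlane]:
    """Run the full 3-D chain on labeled tibia+fibula surfaces."""
    if isinstance(surfaces, list):
        surfaces = {s.label: s for s in surfaces}
    tibia, fibula = surfaces["tibia"], surfaces["fibula"]
    plane_x = fit_plafond_plane(tibia, articular_seed)
    point_a, _ = locate_point_A(tibia, plane_x, frame, step_mm=step_mm)
    plane_y, _ = build_plane_Y(plane_x, point_a)
    contours = slice_contours([tibia, fibula], plane_y, frame)
    tibia_c = max((c for c in contours if c.label == "tibia"),
                  key=lambda c: c.area, default=None)
    fibula_c = max((c for c in contours if c.label == "fibula"),
                   key=lambda c: c.area, default=None)
    if tibia_c is None:
        raise GeometryError("tibia contour missing at plane Y")
    landmarks = locate_landmarks(tibia_c, fibula_c, point_a)
    landmarks.plane_y = plane_y
    f_point, _ = locate_point_F(tibia, plane_x, plane_y, frame)
    landmarks.F = f_point
    record = measure_3d(landmarks, plane_x, plane_y, subject_id, side)
    return record, landmarks, plane_x, plane_y
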