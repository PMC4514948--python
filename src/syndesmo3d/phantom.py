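"""Parametric distal tibia/fibula/talus phantom with exact ground truth.

The phantom exists so that every morphometric parameter the pipeline measures
(XY, TCS-A, TCS-P, TFO, IFD, IFH) has an analytically known true value.  It
models, in a canonical right-ankle frame (+x lateral, +y anterior,
+z proximal, tibial plafond at z = 0):

* the distal **tibia** as an extruded polygon whose lateral face carries the
  incisura fibularis -- a parabolic notch between an anterior and a posterior
  tubercle.  The notch depth varies with height: it peaks exactly at the
  requested plane-Y height (``xy_true_mm``), so the level of maximal incisura
  prominence *is* the measurement plane, and it shrinks below 0.5 mm
  visibility exactly at ``ifh_true_mm``, which pins the incisura's proximal
  tip;
* the **fibula** as a circular cylinder whose center and radius are solved so
  that the nearest-point gaps from the anterior/posterior tubercle corners
  equal ``tcsa_true_mm``/``tcsp_true_mm`` and the AP-projection overlap with
  the anterior tubercle equals ``tfo_true_mm`` -- all in closed form;
* the **talus** as an ellipsoid below the plafond (present so segmentation
  has something to exclude).

Voxelization samples a signed-distance field and applies a partial-volume
ramp anchored so that the bone/soft-tissue threshold level (150 HU) falls
exactly on the analytic surface.  Optional debris blobs (< 500 mm^3, >= 5 mm
from any bone) exercise small-component removal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh

from .segmentation import VoxelVolume, BoneSurface
from .stats import RaterTable

# --- anatomy constants of the generator model (mm, plafond frame) ----------
XA_LAT = 16.0          # lateral x of the anterior tubercle corner (point A)
Y_ANT = 6.0            # y of the anterior tubercle corner
Y_POST = -6.0          # y of the posterior tubercle corner
R_FIBULA = 6.0         # fibula cross-section radius
FIBULA_Z_MIN = -3.0    # distal end of the fibula segment
K_PEAK = 0.008         # quadratic falloff of notch depth around plane Y, 1/mm
Z_KNEE = 21.0          # end of the quadratic zone (above the A-search window)
D_MID = 3.5            # notch depth at the start of the closing ramp
D_CLOSE = 0.5          # visibility threshold depth reached exactly at IFH
D_RIM = 0.2            # residual sub-visible dent above the incisura tip
TALUS_CENTER = np.array([-3.0, 0.0, -17.0])
TALUS_SEMI = np.array([13.0, 15.0, 11.0])
DEBRIS_CLEARANCE = 5.0  # minimum distance from debris to any bone surface

# body outline (CCW, +z view) from the anterior tubercle around the shaft to
# the posterior tubercle; the notch arc closes the loop
_BODY_TEMPLATE = np.array([
    [8.0, 15.0],
    [-14.0, 15.0],
    [-19.0, 11.0],
    [-20.0, 0.0],
    [-19.0, -11.0],
    [-14.0, -15.0],
    [-4.0, -15.0],
])
N_ARC = 41  # odd, so the deepest notch point is an exact vertex

#: Reference presets: ground truth set to the male/female cohort means.
PRESETS: dict[str, dict[str, float]] = {
    "male": dict(xy_true_mm=12.1, tcsa_true_mm=2.8, tcsp_true_mm=3.6,
                 ifd_true_mm=5.1, ifh_true_mm=35.1, tfo_true_mm=5.5),
    "female": dict(xy_true_mm=7.8, tcsa_true_mm=1.8, tcsp_true_mm=2.9,
                   ifd_true_mm=4.2, ifh_true_mm=33.7, tfo_true_mm=3.8),
}


def _cross2(a, b):
    """z-component of the 2-D cross product (numpy 2.x removed 2-D cross)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


class PhantomInfeasibleError(ValueError):
    """Requested parameter combination cannot be realized by the model."""


@dataclass
class PhantomSpec:
    """Everything the generator needs; the *_true_mm fields ARE the truth."""

    xy_true_mm: float = 12.1
    tcsa_true_mm: float = 2.8
    tcsp_true_mm: float = 3.6
    ifd_true_mm: float = 5.1
    ifh_true_mm: float = 35.1
    tfo_true_mm: float = 5.5
    side: str = "right"
    voxel_spacing_mm: tuple[float, float, float] = (0.625, 0.625, 0.625)
    plafond_tilt_deg: tuple[float, float] = (0.0, 0.0)
    bone_hu: float = 700.0
    soft_tissue_hu: float = 40.0
    edge_ref_hu: float = 150.0
    noise_sd_hu: float = 0.0
    n_debris: int = 0
    debris_volume_mm3: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        trues = dict(xy=self.xy_true_mm, tcsa=self.tcsa_true_mm,
                     tcsp=self.tcsp_true_mm, ifd=self.ifd_true_mm,
                     ifh=self.ifh_true_mm, tfo=self.tfo_true_mm)
        for name, v in trues.items():
            if not v > 0:
                raise PhantomInfeasibleError(f"{name}_true_mm must be > 0")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if not self.ifh_true_mm > self.xy_true_mm:
            raise PhantomInfeasibleError(
                "ifh_true_mm must exceed xy_true_mm (incisura tip proximal "
                "to plane Y)")
        if not (self.bone_hu > self.edge_ref_hu > self.soft_tissue_hu):
            raise PhantomInfeasibleError(
                "require bone_hu > threshold > soft_tissue_hu")
        if not self.debris_volume_mm3 < 500.0:
            raise PhantomInfeasibleError("debris_volume_mm3 must be < 500")
        if self.n_debris < 0:
            raise ValueError("n_debris must be >= 0")
        # generator-model constraints
        if not 4.5 <= self.xy_true_mm <= 19.5:
            raise PhantomInfeasibleError(
                "xy_true_mm must lie within the level-search window "
                "[4.5, 19.5] mm above the plafond")
        if self.ifh_true_mm < 25.0:
            raise PhantomInfeasibleError(
                "ifh_true_mm must be >= 25 mm (closing ramp sits above the "
                "level-search window)")
        _solve_cross_section(self)  # raises on geometric infeasibility
        for z in (0.0, Z_KNEE):
            if _notch_depth_quad(z, self) <= D_CLOSE + 0.1:
                raise PhantomInfeasibleError(
                    "notch depth profile dips below the visibility threshold "
                    "inside the distal zone; reduce xy/ifd mismatch")
        # the fibula (which sits inside the incisura) must clear the tibial
        # cross-section at every shared level
        c = _solve_cross_section(self)
        center = np.array([c["cx"], c["cy"]])
        # away from plane Y the notch is shallower and the interosseous gap
        # narrows; it must stay wide enough that voxelization at the default
        # spacing never bridges the bones (~2 voxels)
        min_gap = min(self.tcsa_true_mm, self.tcsp_true_mm, 1.3)
        for z in np.arange(0.0, _fibula_z_top(self) + 1e-9, 0.5):
            poly = tibia_cross_section(float(z), self, c)
            a = poly
            b = np.roll(poly, -1, axis=0)
            ab = b - a
            t = np.clip(((center - a) * ab).sum(axis=1)
                        / np.maximum((ab * ab).sum(axis=1), 1e-30), 0, 1)
            gap = np.min(np.linalg.norm(a + t[:, None] * ab - center,
                                        axis=1)) - c["r_fibula"]
            if gap < min_gap - 1e-6:
                raise PhantomInfeasibleError(
                    f"fibula would approach the tibia to {gap:.2f} mm at "
                    f"z={z:.1f} (closer than the requested clear space)")

    @property
    def z_top(self) -> float:
        return self.ifh_true_mm + 6.0


@dataclass
class RaterSimSpec:
    """Two-way random-effects rater simulation: y = mu_i + r_j + e_ijs."""

    n_subjects: int
    n_raters: int
    subject_sd: float
    rater_sd: float
    error_sd: float
    n_sessions: int = 1
    grand_mean: float = 5.0
    parameter: str = "simulated"
    modality: str = "3-D"
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_raters < 2:
            raise ValueError("need >= 2 subjects and >= 2 raters")
        if min(self.subject_sd, self.rater_sd, self.error_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


@dataclass
class PhantomTruth:
    """Analytic ground truth for one phantom, in the final (world) frame."""

    spec: PhantomSpec
    frame: np.ndarray               # anatomic axes (lateral/anterior/proximal)
    view_frame: np.ndarray          # lab/detector axes (side mirroring only)
    plane_x: tuple[np.ndarray, np.ndarray]   # (point, unit normal)
    plane_y: tuple[np.ndarray, np.ndarray]
    points: dict[str, np.ndarray]   # A..F (mm)
    seeds: dict[str, np.ndarray]    # interior point per bone
    articular_seed: np.ndarray      # on the plafond surface
    params: dict[str, dict[str, float | None]]  # per modality
    constants: dict[str, float]     # solved cross-section constants
    volumes_mm3: dict[str, float]   # analytic bone volumes

    def to_json(self, path: str | Path) -> None:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        payload = {
            "spec": asdict(self.spec),
            "frame": self.frame,
            "view_frame": self.view_frame,
            "plane_x": {"point": self.plane_x[0], "normal": self.plane_x[1]},
            "plane_y": {"point": self.plane_y[0], "normal": self.plane_y[1]},
            "points": self.points,
            "seeds": self.seeds,
            "articular_seed": self.articular_seed,
            "params": self.params,
            "constants": self.constants,
            "volumes_mm3": self.volumes_mm3,
        }
        Path(path).write_text(json.dumps(payload, default=conv, indent=2))


# ---------------------------------------------------------------------------
# cross-section model
# ---------------------------------------------------------------------------

def _solve_cross_section(spec: PhantomSpec) -> dict[str, float]:
    """Closed-form fibula placement realizing TCS-A, TCS-P and TFO.

    With the anterior tubercle corner fixed at ``A = (XA_LAT, Y_ANT)`` the
    projection overlap pins the fibula's medial border:
    ``cx - r = XA_LAT - tfo``.  The requested anterior gap then fixes the
    fibula center's y via ``|A - c| = r + tcsa``, and the posterior gap fixes
    the posterior tubercle corner x via ``|C - c| = r + tcsp``.
    """
    r = R_FIBULA
    u = spec.tfo_true_mm - r               # = XA_LAT - cx
    cx = XA_LAT - u
    disc_a = (r + spec.tcsa_true_mm) ** 2 - u ** 2
    if disc_a <= 1.0:
        raise PhantomInfeasibleError(
            "tfo_true_mm too large for the tubercle/fibula geometry "
            "(anterior gap unreachable)")
    cy = Y_ANT - float(np.sqrt(disc_a))
    if not -5.0 < cy < 5.0:
        raise PhantomInfeasibleError(
            "fibula center falls outside the incisura span; adjust "
            "tcsa/tfo combination")
    disc_c = (r + spec.tcsp_true_mm) ** 2 - (Y_POST - cy) ** 2
    if disc_c <= 1.0:
        raise PhantomInfeasibleError(
            "tcsp_true_mm unreachable given the fibula position implied by "
            "tcsa/tfo")
    xc_lat = cx - float(np.sqrt(disc_c))
    if not 2.0 < xc_lat < XA_LAT - 1.5:
        raise PhantomInfeasibleError(
            "posterior tubercle corner leaves its valid lateral band")
    # posterior tubercle must be a convex-hull vertex of the contour
    pc = np.array([xc_lat, Y_POST])
    pa = np.array([XA_LAT, Y_ANT])
    qpost = _BODY_TEMPLATE[-1]
    if float(_cross2(pc - qpost, pa - pc)) < 5.0:
        raise PhantomInfeasibleError(
            "posterior tubercle would be shadowed by the tibial shaft in "
            "the convex hull")
    chord = pa - pc
    length = float(np.linalg.norm(chord))
    medial = np.array([-chord[1], chord[0]]) / length
    mid = 0.5 * (pa + pc)
    deepest = mid + spec.ifd_true_mm * medial
    if deepest[0] < -12.0:
        raise PhantomInfeasibleError("ifd_true_mm cuts through the shaft")
    return dict(cx=cx, cy=cy, r_fibula=r, xa_lat=XA_LAT, xc_lat=xc_lat,
                chord_len=length)


def _notch_depth_quad(z: float, spec: PhantomSpec) -> float:
    return spec.ifd_true_mm - K_PEAK * (z - spec.xy_true_mm) ** 2


def notch_depth(z, spec: PhantomSpec):
    """Notch depth profile d(z): peak ``ifd`` at ``xy``, crosses the 0.5 mm
    visibility threshold exactly at ``ifh``, residual dent above."""
    z = np.asarray(z, dtype=float)
    ifh = spec.ifh_true_mm
    d_knee = _notch_depth_quad(Z_KNEE, spec)
    seg_quad = spec.ifd_true_mm - K_PEAK * (z - spec.xy_true_mm) ** 2
    seg_mid = d_knee + (D_MID - d_knee) * (z - Z_KNEE) / ((ifh - 3.0) - Z_KNEE)
    seg_close = D_MID + (D_CLOSE - D_MID) * (z - (ifh - 3.0)) / 3.0
    seg_rim = D_CLOSE + (D_RIM - D_CLOSE) * (z - ifh)
    out = np.where(z <= Z_KNEE, seg_quad,
                   np.where(z <= ifh - 3.0, seg_mid,
                            np.where(z <= ifh, seg_close,
                                     np.where(z <= ifh + 1.0, seg_rim,
                                              D_RIM))))
    return out if out.ndim else float(out)


def tibia_cross_section(z: float, spec: PhantomSpec,
                        constants: dict[str, float] | None = None
                        ) -> np.ndarray:
    """Closed CCW cross-section polygon of the tibia at height ``z`` (mm)."""
    c = constants or _solve_cross_section(spec)
    pa = np.array([c["xa_lat"], Y_ANT])
    pc = np.array([c["xc_lat"], Y_POST])
    d = float(notch_depth(z, spec))
    chord = pa - pc
    medial = np.array([-chord[1], chord[0]])
    medial /= np.linalg.norm(medial)
    t = np.linspace(0.0, 1.0, N_ARC)[1:-1, None]
    arc = pc + t * chord + (4.0 * d * t * (1.0 - t)) * medial
    body = _subdivide_edges(np.vstack([pa, _BODY_TEMPLATE, pc]))
    return np.vstack([body, arc])


def _subdivide_edges(outline: np.ndarray, max_len: float = 2.0,
                     bulge: float = 1e-3) -> np.ndarray:
    """Split long outline edges, nudging interior split points outward by a
    micron-scale bulge so no three vertices are ever exactly collinear
    (keeps hull/ear-clip constructions non-degenerate)."""
    pieces = []
    n = len(outline)
    for i in range(n - 1):  # the closing edge is the notch arc, not here
        a, b = outline[i], outline[i + 1]
        seg = b - a
        length = np.linalg.norm(seg)
        k = max(1, int(np.ceil(length / max_len)))
        outward = np.array([seg[1], -seg[0]]) / max(length, 1e-12)
        pieces.append(a[None, :])
        if k > 1:
            t = np.arange(1, k)[:, None] / k
            pieces.append(a + t * seg + bulge * outward)
    pieces.append(outline[-1][None, :])
    return np.vstack(pieces)


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def _earclip(points: np.ndarray) -> np.ndarray:
    """Ear-clipping triangulation of a simple CCW polygon (indices)."""
    n = len(points)
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 10 * n * n:
            raise RuntimeError("ear clipping failed; polygon not simple?")
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % m]
            a, b, c = points[i0], points[i1], points[i2]
            area2 = float(_cross2(b - a, c - a))
            if area2 <= 1e-12:
                continue  # reflex or degenerate corner
            others = [j for j in idx if j not in (i0, i1, i2)]
            if others:
                p = points[others]
                s1 = _cross2(b - a, p - a)
                s2 = _cross2(c - b, p - b)
                s3 = _cross2(a - c, p - c)
                if np.any((s1 > 1e-12) & (s2 > 1e-12) & (s3 > 1e-12)):
                    continue  # another vertex strictly inside the ear
            tris.append((i0, i1, i2))
            del idx[k]
            clipped = True
            break
        if not clipped:
            raise RuntimeError("ear clipping stalled on a degenerate polygon")
    tris.append((idx[0], idx[1], idx[2]))
    return np.array(tris, dtype=np.int64)


def _stack_rings(rings: list[np.ndarray], zs: np.ndarray) -> trimesh.Trimesh:
    """Watertight extrusion through corresponding rings plus end caps."""
    n = len(rings[0])
    verts = np.vstack([np.column_stack([r, np.full(n, z)])
                       for r, z in zip(rings, zs)])
    faces = []
    for k in range(len(rings) - 1):
        lo, hi = k * n, (k + 1) * n
        for i in range(n):
            j = (i + 1) % n
            faces.append((lo + i, lo + j, hi + j))
            faces.append((lo + i, hi + j, hi + i))
    bottom = _earclip(rings[0])
    top = _earclip(rings[-1])
    faces.extend((t[0], t[2], t[1]) for t in bottom)          # normal -z
    off = (len(rings) - 1) * n
    faces.extend((off + t[0], off + t[1], off + t[2]) for t in top)
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces),
                           process=False)
    return mesh


def _tibia_mesh(spec: PhantomSpec, constants: dict[str, float]
                ) -> trimesh.Trimesh:
    z_top = spec.z_top
    knots = [spec.xy_true_mm, Z_KNEE, spec.ifh_true_mm - 3.0,
             spec.ifh_true_mm, spec.ifh_true_mm + 1.0]
    zs = np.concatenate([np.arange(0.0, z_top, 1.0), [z_top], knots])
    zs = np.unique(np.round(zs[(zs >= 0) & (zs <= z_top)], 9))
    rings = [tibia_cross_section(z, spec, constants) for z in zs]
    return _stack_rings(rings, zs)


def _fibula_z_top(spec: PhantomSpec) -> float:
    # the fibula ends below the incisura's closing zone, where the shallow
    # notch would otherwise meet the fibular shaft sitting inside it
    return spec.ifh_true_mm - 2.0


def _fibula_mesh(spec: PhantomSpec, constants: dict[str, float],
                 n_circle: int = 512) -> trimesh.Trimesh:
    theta = np.linspace(0.0, 2.0 * np.pi, n_circle, endpoint=False)
    ring = np.column_stack([
        constants["cx"] + constants["r_fibula"] * np.cos(theta),
        constants["cy"] + constants["r_fibula"] * np.sin(theta)])
    zs = np.array([FIBULA_Z_MIN, _fibula_z_top(spec)])
    return _stack_rings([ring, ring], zs)


def _talus_mesh() -> trimesh.Trimesh:
    mesh = trimesh.creation.icosphere(subdivisions=3)
    mesh.vertices = mesh.vertices * TALUS_SEMI + TALUS_CENTER
    return mesh


def _world_transform(spec: PhantomSpec) -> np.ndarray:
    """Linear map from plafond frame to world: plafond tilt, then mirroring
    for a left ankle.  Orthogonal; its columns are the canonical axes."""
    a1, a2 = np.deg2rad(spec.plafond_tilt_deg)
    rx = np.array([[1, 0, 0],
                   [0, np.cos(a1), -np.sin(a1)],
                   [0, np.sin(a1), np.cos(a1)]])
    ry = np.array([[np.cos(a2), 0, np.sin(a2)],
                   [0, 1, 0],
                   [-np.sin(a2), 0, np.cos(a2)]])
    mat = rx @ ry
    if spec.side == "left":
        mat = np.diag([-1.0, 1.0, 1.0]) @ mat
    return mat


# ---------------------------------------------------------------------------
# truth assembly
# ---------------------------------------------------------------------------

def _analytic_truth(spec: PhantomSpec, constants: dict[str, float],
                    frame: np.ndarray) -> PhantomTruth:
    c = constants
    pa = np.array([c["xa_lat"], Y_ANT])
    pc = np.array([c["xc_lat"], Y_POST])
    center = np.array([c["cx"], c["cy"]])
    chord = pa - pc
    medial = np.array([-chord[1], chord[0]])
    medial /= np.linalg.norm(medial)
    mid = 0.5 * (pa + pc)
    xy = spec.xy_true_mm
    a3 = np.array([*pa, xy])
    c3 = np.array([*pc, xy])
    b2 = center + c["r_fibula"] * (pa - center) / np.linalg.norm(pa - center)
    d2 = center + c["r_fibula"] * (pc - center) / np.linalg.norm(pc - center)
    e2 = mid + spec.ifd_true_mm * medial
    f2 = mid + D_CLOSE * medial
    points = {
        "A": a3, "B": np.array([*b2, xy]), "C": c3,
        "D": np.array([*d2, xy]), "E": np.array([*e2, xy]),
        "F": np.array([*f2, spec.ifh_true_mm]),
    }
    seeds = {
        "tibia": np.array([-8.0, 0.0, 25.0]),
        "fibula": np.array([c["cx"], c["cy"], xy]),
        "talus": TALUS_CENTER.copy(),
    }
    articular_seed = np.array([-8.0, 0.0, 0.0])
    plane_x = (np.zeros(3), np.array([0.0, 0.0, 1.0]))
    plane_y = (np.array([0.0, 0.0, xy]), np.array([0.0, 0.0, 1.0]))

    untilted = np.allclose(spec.plafond_tilt_deg, (0.0, 0.0))
    tcs_rad = (c["cx"] - c["r_fibula"]) - c["xc_lat"]
    params = {
        "3-D": dict(XY=xy, TCS_A=spec.tcsa_true_mm, TCS_P=spec.tcsp_true_mm,
                    IFD=spec.ifd_true_mm, IFH=spec.ifh_true_mm),
        "2-D axial": dict(TCS_A=spec.tcsa_true_mm, TCS_P=spec.tcsp_true_mm,
                          IFD=spec.ifd_true_mm),
        "radiograph": dict(
            TFO=spec.tfo_true_mm if untilted else None,
            TCS=tcs_rad if untilted else None,
            IFH=None),  # filled below (depends on tilt)
    }

    # transform to world
    def tx(p):
        return frame @ np.asarray(p, dtype=float)

    points = {k: tx(v) for k, v in points.items()}
    seeds = {k: tx(v) for k, v in seeds.items()}
    articular_seed = tx(articular_seed)
    plane_x = (tx(plane_x[0]), frame @ plane_x[1])
    plane_y = (tx(plane_y[0]), frame @ plane_y[1])

    # radiographic incisura height: perpendicular distance, in the image,
    # of the projected tip F from the projected plafond edge line; the
    # detector frame carries only the side mirroring, so plafond tilt
    # foreshortens the projected height
    view_frame = (np.diag([-1.0, 1.0, 1.0]) if spec.side == "left"
                  else np.eye(3))
    lat, view, prox = view_frame[:, 0], view_frame[:, 1], view_frame[:, 2]
    n3 = plane_x[1]
    edge = np.cross(n3, view)
    edge2 = np.array([edge @ lat, edge @ prox])
    norm = np.linalg.norm(edge2)
    if norm > 1e-9:
        edge2 /= norm
        perp = np.array([-edge2[1], edge2[0]])
        n2 = np.array([n3 @ lat, n3 @ prox])
        if perp @ n2 < 0:
            perp = -perp
        rel = points["F"] - plane_x[0]
        params["radiograph"]["IFH"] = float(
            np.array([rel @ lat, rel @ prox]) @ perp)

    # analytic volumes
    body = np.vstack([pa, _BODY_TEMPLATE, pc])
    x, y = body[:, 0], body[:, 1]
    area0 = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    zq = np.linspace(0.0, spec.z_top, 4001)
    notch_area = (2.0 / 3.0) * c["chord_len"] * notch_depth(zq, spec)
    v_tibia = area0 * spec.z_top - float(np.trapezoid(notch_area, zq))
    v_fibula = (np.pi * c["r_fibula"] ** 2
                * (_fibula_z_top(spec) - FIBULA_Z_MIN))
    v_talus = 4.0 / 3.0 * np.pi * float(np.prod(TALUS_SEMI))
    return PhantomTruth(
        spec=spec, frame=frame, view_frame=view_frame,
        plane_x=plane_x, plane_y=plane_y,
        points=points, seeds=seeds, articular_seed=articular_seed,
        params=params, constants=dict(c),
        volumes_mm3=dict(tibia=v_tibia, fibula=v_fibula, talus=v_talus))


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _polygon_sdf(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Signed distance (negative inside) from 2-D points to a CCW polygon."""
    p = points[:, None, :]
    a = poly[None, :, :]
    b = np.roll(poly, -1, axis=0)[None, :, :]
    ab = b - a
    t = np.clip(np.einsum("pki,pki->pk", p - a, ab)
                / np.maximum(np.einsum("pki,pki->pk", ab, ab), 1e-30),
                0.0, 1.0)
    proj = a + t[..., None] * ab
    dist = np.min(np.linalg.norm(p - proj, axis=-1), axis=1)
    # even-odd crossing test
    x, y = points[:, 0], points[:, 1]
    ax, ay = poly[:, 0], poly[:, 1]
    bx, by = np.roll(ax, -1), np.roll(ay, -1)
    cond = (ay[None, :] > y[:, None]) != (by[None, :] > y[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = ax[None, :] + ((y[:, None] - ay[None, :])
                              / (by[None, :] - ay[None, :])) * (bx - ax)[None, :]
    inside = np.sum(cond & (x[:, None] < xint), axis=1) % 2 == 1
    return np.where(inside, -dist, dist)


def _tibia_sdf(p: np.ndarray, spec: PhantomSpec,
               constants: dict[str, float]) -> np.ndarray:
    c = constants
    pa = np.array([c["xa_lat"], Y_ANT])
    pc = np.array([c["xc_lat"], Y_POST])
    body = np.vstack([pa, _BODY_TEMPLATE, pc])  # straight-chord outline
    sdf = _polygon_sdf(p[:, :2], body)
    chord = pa - pc
    length = np.linalg.norm(chord)
    u = chord / length
    medial = np.array([-u[1], u[0]])
    rel = p[:, :2] - pc
    t = (rel @ u) / length
    w = rel @ medial
    h = 4.0 * notch_depth(p[:, 2], spec) * t * (1.0 - t)
    carve = np.where((t > 0.0) & (t < 1.0), h - w, -np.inf)
    sdf = np.maximum(sdf, carve)
    return np.maximum.reduce([sdf, -p[:, 2], p[:, 2] - spec.z_top])


def _fibula_sdf(p: np.ndarray, spec: PhantomSpec,
                constants: dict[str, float]) -> np.ndarray:
    c = constants
    radial = np.hypot(p[:, 0] - c["cx"], p[:, 1] - c["cy"]) - c["r_fibula"]
    return np.maximum.reduce([radial, FIBULA_Z_MIN - p[:, 2],
                              p[:, 2] - _fibula_z_top(spec)])


def _talus_sdf(p: np.ndarray) -> np.ndarray:
    q = (p - TALUS_CENTER) / TALUS_SEMI
    return (np.linalg.norm(q, axis=1) - 1.0) * float(np.min(TALUS_SEMI))


def _debris_centers(spec: PhantomSpec, bounds: np.ndarray) -> np.ndarray:
    """Deterministic debris slots >= 5 mm clear of every bone (corner
    columns outside the expanded bone bounding box)."""
    if spec.n_debris == 0:
        return np.zeros((0, 3))
    r = (3.0 * spec.debris_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    off = DEBRIS_CLEARANCE + r + 1.0
    corners = [(bounds[0, 0] - off, bounds[0, 1] - off),
               (bounds[1, 0] + off, bounds[0, 1] - off),
               (bounds[0, 0] - off, bounds[1, 1] + off),
               (bounds[1, 0] + off, bounds[1, 1] + off)]
    dz = max(2.0 * r + 3.0, 8.0)
    zlo, zhi = bounds[0, 2] + r + 1.0, bounds[1, 2] - r - 1.0
    n_levels = max(1, int((zhi - zlo) // dz) + 1)
    slots = [(cx, cy, zlo + lvl * dz)
             for lvl in range(n_levels) for (cx, cy) in corners]
    if spec.n_debris > len(slots):
        raise PhantomInfeasibleError(
            f"cannot place {spec.n_debris} debris components; "
            f"only {len(slots)} clear slots available")
    return np.array(slots[:spec.n_debris])


def voxelize(spec: PhantomSpec, constants: dict[str, float],
             frame: np.ndarray, bounds: np.ndarray) -> VoxelVolume:
    """Sample the phantom SDF onto a HU grid.

    The partial-volume ramp spans one voxel and is anchored so the
    ``edge_ref_hu`` level (the segmentation threshold) sits exactly on the
    analytic surface; noise is additive Gaussian clipped at air (-1000 HU).
    """
    spacing = np.asarray(spec.voxel_spacing_mm, dtype=float)
    debris_r = (3.0 * spec.debris_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    debris = _debris_centers(spec, bounds)
    margin = 3.0
    lo = bounds[0] - margin
    hi = bounds[1] + margin
    if len(debris):
        lo = np.minimum(lo, debris.min(axis=0) - debris_r - 2.0)
        hi = np.maximum(hi, debris.max(axis=0) + debris_r + 2.0)
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    xs = [lo[i] + np.arange(shape[i]) * spacing[i] for i in range(3)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
    pts_world = grid.reshape(-1, 3)
    pts = pts_world @ frame  # world -> plafond frame (frame is orthogonal)
    sdf = np.minimum(_tibia_sdf(pts, spec, constants),
                     _fibula_sdf(pts, spec, constants))
    sdf = np.minimum(sdf, _talus_sdf(pts))
    for center in debris:
        sdf = np.minimum(sdf,
                         np.linalg.norm(pts_world - center, axis=1) - debris_r)
    span = spec.bone_hu - spec.soft_tissue_hu
    f0 = (spec.edge_ref_hu - spec.soft_tissue_hu) / span
    # two-voxel ramp: wide enough that linear interpolation between voxel
    # centers reproduces the threshold crossing with little clipping bias,
    # narrow enough not to bridge the interosseous gaps
    ramp = 2.0 * float(np.max(spacing))
    frac = np.clip(f0 - sdf / ramp, 0.0, 1.0)
    hu = spec.soft_tissue_hu + span * frac
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, hu.shape)
        hu = np.maximum(hu, -1000.0)
    return VoxelVolume(hu.reshape(shape).astype(np.float32),
                       tuple(spacing), tuple(lo))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec, with_volume: bool = True
                     ) -> tuple[dict[str, BoneSurface], VoxelVolume | None,
                                PhantomTruth]:
    """Build the phantom: watertight surfaces, optional HU volume, truth.

    Surfaces are deterministic functions of the spec (the seed only drives
    voxel noise).  Raises :class:`PhantomInfeasibleError` for parameter
    combinations the model cannot realize.
    """
    spec.validate()
    constants = _solve_cross_section(spec)
    frame = _world_transform(spec)
    meshes = {
        "tibia": _tibia_mesh(spec, constants),
        "fibula": _fibula_mesh(spec, constants),
        "talus": _talus_mesh(),
    }
    flip = np.linalg.det(frame) < 0
    for mesh in meshes.values():
        mesh.vertices = mesh.vertices @ frame.T
        if flip:
            mesh.invert()
    surfaces = {name: BoneSurface(mesh, label=name)
                for name, mesh in meshes.items()}
    truth = _analytic_truth(spec, constants, frame)
    volume = None
    if with_volume:
        bounds = np.array([
            np.min([m.bounds[0] for m in meshes.values()], axis=0),
            np.max([m.bounds[1] for m in meshes.values()], axis=0)])
        volume = voxelize(spec, constants, frame, bounds)
    return surfaces, volume, truth


def make_preset_spec(preset: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Reference phantom spec for the 'male' or 'female' cohort means."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset '{preset}'; have {sorted(PRESETS)}")
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return PhantomSpec(seed=seed, **kwargs)


def simulate_rater_table(rspec: RaterSimSpec) -> RaterTable:
    """Two-way random-effects measurement table, reproducible by seed."""
    rspec.validate()
    rng = np.random.default_rng(rspec.seed)
    mu = rspec.grand_mean + rng.normal(0.0, rspec.subject_sd,
                                       rspec.n_subjects)
    rater = rng.normal(0.0, rspec.rater_sd, rspec.n_raters)
    err = rng.normal(0.0, rspec.error_sd,
                     (rspec.n_subjects, rspec.n_raters, rspec.n_sessions))
    values = mu[:, None, None] + rater[None, :, None] + err
    if rspec.n_sessions == 1:
        values = values[:, :, 0]
    return RaterTable(values=values, parameter=rspec.parameter,
                      modality=rspec.modality)
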