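"""Simulated non-weight-bearing AP radiograph by parallel projection.

The X-ray beam is modeled as an orthographic projection along the
anteroposterior axis onto the coronal (lateral x height) image plane; the
source geometry of a real radiograph (cone beam, magnification) is not
modeled, which keeps the view deterministic and is a stated fidelity limit.

Radiographic parameters at the plane-Y level ``h`` above the projected
plafond line:

* **TFO** (tibiofibular overlap) = lateral border of the anterior tibial
  tubercle minus medial border of the fibula (floored at 0);
* **TCS** (tibiofibular clear space) = medial border of the fibula minus
  lateral border of the posterior tubercle.  In a binary silhouette the
  posterior tubercle is occluded by the more lateral anterior tubercle, so
  its border is read from the projection of the posterior half of the tibia
  (the density edge a rater sees on film);
* **radiographic IFH** = height of the projected incisura tip above the
  plafond line.  The incisura edge is likewise invisible in a silhouette,
  so the 3-D notch-ridge track is projected instead.

Borders on the ``h``-line are exact extremes of the mesh section through the
line's pre-image plane (the limit of a dense ray scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import (AnatomicPlane, CANONICAL_FRAME, GeometryError,
                       MeasurementRecord, locate_point_F)
from .segmentation import BoneSurface


@dataclass
class ImageLine:
    """A line in the 2-D image plane: point + unit direction, with the
    proximal-pointing perpendicular."""

    point: np.ndarray
    direction: np.ndarray
    proximal: np.ndarray


@dataclass
class Silhouette:
    """Per-bone orthographic AP projections.

    Image coordinates are ``(x, z) = (p . lateral, p . proximal)`` of the
    anatomic frame; the beam runs along the anterior axis.  Outlines are
    built lazily (shapely union of projected faces); border queries section
    the meshes exactly and need no rasterization.
    """

    surfaces: dict[str, BoneSurface]
    frame: np.ndarray = field(default_factory=lambda: CANONICAL_FRAME.copy())
    #: anterior-axis coordinate splitting off the posterior half of a bone;
    #: None = the bone's own anteroposterior midpoint (translation invariant)
    posterior_split: float | None = None
    _outlines: dict = field(default_factory=dict, repr=False)

    @property
    def lateral(self) -> np.ndarray:
        return self.frame[:, 0]

    @property
    def view(self) -> np.ndarray:
        return self.frame[:, 1]

    @property
    def proximal(self) -> np.ndarray:
        return self.frame[:, 2]

    def to_image(self, points3: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points3)
        return np.column_stack([p @ self.lateral, p @ self.proximal])

    def outline(self, bone: str):
        """Closed projected outline of a bone as a shapely polygon."""
        if bone not in self._outlines:
            from shapely import union_all
            from shapely.geometry import Polygon

            mesh = self.surfaces[bone].mesh
            tri2 = self.to_image(mesh.vertices)[mesh.faces]
            # front-facing faces suffice for the union and halve the work
            facing = mesh.face_normals @ self.view < 0
            polys = [Polygon(t) for t in tri2[facing]
                     if abs((t[1][0]-t[0][0])*(t[2][1]-t[0][1])
                            - (t[1][1]-t[0][1])*(t[2][0]-t[0][0])) > 1e-9]
            self._outlines[bone] = union_all([p.buffer(0) for p in polys])
        return self._outlines[bone]

    def _line_borders(self, bone: str, line: ImageLine,
                      posterior_only: bool = False) -> tuple[float, float]:
        """(min, max) signed positions along an image line where the bone's
        projection meets it, via the line's pre-image plane."""
        mesh = self.surfaces[bone].mesh
        if posterior_only:
            y = mesh.triangles_center @ self.view
            split = (self.posterior_split if self.posterior_split is not None
                     else 0.5 * (y.min() + y.max()))
            keep = y <= split
            if not keep.any():
                raise GeometryError(f"no posterior half for '{bone}'")
            mesh = mesh.submesh([np.nonzero(keep)[0]], append=True)
        perp = line.proximal
        normal3 = perp[0] * self.lateral + perp[1] * self.proximal
        origin3 = (line.point @ np.array([1.0, 0.0])) * self.lateral \
            + (line.point @ np.array([0.0, 1.0])) * self.proximal
        segments = trimesh.intersections.mesh_plane(
            mesh, plane_normal=normal3, plane_origin=origin3)
        if len(segments) == 0:
            raise GeometryError(
                f"the h-line misses the {bone} silhouette")
        pts2 = self.to_image(np.asarray(segments).reshape(-1, 3))
        s = (pts2 - line.point) @ line.direction
        return float(s.min()), float(s.max())


def project_ap(surfaces: dict[str, BoneSurface] | list[BoneSurface],
               frame: np.ndarray = CANONICAL_FRAME,
               posterior_split: float | None = None) -> Silhouette:
    """Orthographic AP projection of the bone surfaces."""
    if isinstance(surfaces, list):
        surfaces = {s.label: s for s in surfaces}
    return Silhouette(surfaces=dict(surfaces), frame=np.asarray(frame),
                      posterior_split=posterior_split)


def project_plafond_line(sil: Silhouette, plane_x: AnatomicPlane
                         ) -> ImageLine:
    """The plafond edge in the image: projection of the plane-X direction
    perpendicular to the beam; its lateral-positive unit direction and the
    proximal perpendicular."""
    edge3 = np.cross(plane_x.normal, sil.view)
    d2 = sil.to_image(edge3)[0]
    nrm = np.linalg.norm(d2)
    if nrm < 1e-9:
        raise GeometryError("plafond plane projects edge-on ambiguously")
    d2 /= nrm
    if d2[0] < 0:
        d2 = -d2
    perp = np.array([-d2[1], d2[0]])
    n2 = sil.to_image(plane_x.normal)[0]
    if perp @ n2 < 0:
        perp = -perp
    return ImageLine(point=sil.to_image(plane_x.point)[0],
                     direction=d2, proximal=perp)


def measure_radiograph(sil: Silhouette, h: float,
                       plane_x: AnatomicPlane,
                       plane_y: AnatomicPlane | None = None,
                       subject_id: str = "", side: str = "right"
                       ) -> MeasurementRecord:
    """Radiographic TCS, TFO (and IFH, when plane Y is supplied) at height
    ``h`` above the plafond line.

    ``h`` comes from the 3-D pipeline (the plane-Y height XY); the plafond
    line is the projection of plane X.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    base = project_plafond_line(sil, plane_x)
    line = ImageLine(point=base.point + h * base.proximal,
                     direction=base.direction, proximal=base.proximal)
    _, tib_lat = sil._line_borders("tibia", line)
    fib_med, _ = sil._line_borders("fibula", line)
    _, post_lat = sil._line_borders("tibia", line, posterior_only=True)
    tfo = max(0.0, tib_lat - fib_med)
    tcs = fib_med - post_lat
    ifh = None
    if plane_y is not None:
        tip, _ = locate_point_F(sil.surfaces["tibia"], plane_x, plane_y,
                                frame=sil.frame)
        ifh = float((sil.to_image(tip)[0] - base.point) @ base.proximal)
    return MeasurementRecord(
        modality="radiograph", subject_id=subject_id, side=side,
        tcs=float(tcs), tfo=float(tfo), ifh=ifh)


def render_silhouette_pgm(sil: Silhouette, path, pixel_mm: float = 0.25
                          ) -> None:
    """Write a plain-text PGM of the projection for visual inspection."""
    import shapely

    outlines = {b: sil.outline(b) for b in sil.surfaces}
    bounds = np.array([o.bounds for o in outlines.values()])
    lo = bounds[:, :2].min(axis=0) - 2.0
    hi = bounds[:, 2:].max(axis=0) + 2.0
    nx = int(np.ceil((hi[0] - lo[0]) / pixel_mm))
    nz = int(np.ceil((hi[1] - lo[1]) / pixel_mm))
    xs = lo[0] + (np.arange(nx) + 0.5) * pixel_mm
    zs = lo[1] + (np.arange(nz) + 0.5) * pixel_mm
    xx, zz = np.meshgrid(xs, zs, indexing="ij")
    img = np.zeros((nx, nz), dtype=int)
    for i, outline in enumerate(outlines.values(), start=1):
        inside = shapely.contains_xy(outline, xx.ravel(), zz.ravel())
        img[inside.reshape(nx, nz)] += 60 * i
    img = np.clip(img, 0, 255)
    rows = img.T[::-1]  # proximal up
    with open(path, "w") as fh:
        fh.write(f"P2\n{nx} {nz}\n255\n")
        for row in rows:
            fh.write(" ".join(str(v) for v in row) + "\n")
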