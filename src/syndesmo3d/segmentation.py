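"""CT bone segmentation: density threshold, small-component removal,
isosurface extraction and seeded bone labeling.

The chain mirrors standard orthopedic CT post-processing: voxels at or above
a bone density threshold (default 150 HU) are kept, connected components with
physical volume below a cutoff (default 500 mm^3, strict less-than) are
discarded, and one closed triangulated surface per remaining component is
extracted at the threshold level with sub-voxel (linear) interpolation.
Bones are identified by interior seed points rather than interactive clicks.

Axis convention throughout the package (right-side canonical frame):
``+x`` lateral, ``+y`` anterior, ``+z`` proximal.  Volumes are stored with
array axes ``(x, y, z)`` and a diagonal mm affine (spacing + origin).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

#: Density threshold separating bone from soft tissue, in Hounsfield units.
BONE_THRESHOLD_HU = 150.0
#: Components smaller than this physical volume are removed (strict ``<``).
MIN_COMPONENT_MM3 = 500.0
#: 3-D connectivity used for component analysis (26-connected).
CONNECTIVITY_STRUCTURE = np.ones((3, 3, 3), dtype=bool)

BONE_LABELS = ("tibia", "fibula", "talus")


class SegmentationError(RuntimeError):
    """Raised for unrecoverable segmentation failures (bad seeds etc.)."""


@dataclass
class VoxelVolume:
    """A CT-like scalar volume in HU with mm geometry metadata.

    ``values[i, j, k]`` samples the point ``origin + (i, j, k) * spacing``
    in the canonical frame; ``axes`` records the orientation codes (the
    canonical frame is 'LAS'-like with +x lateral on a right ankle).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "canonical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of mm points (for interpolation)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    # --- I/O -----------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.values, dtype=np.float32),
                                 affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VoxelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(v) for v in affine[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=np.float32), spacing, origin)

    def to_metaimage(self, path: str | Path) -> None:
        import SimpleITK as sitk

        # SimpleITK uses (z, y, x) array order.
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(self.values, (2, 1, 0))))
        img.SetSpacing(tuple(float(s) for s in self.spacing))
        img.SetOrigin(tuple(float(o) for o in self.origin))
        sitk.WriteImage(img, str(path))

    @classmethod
    def from_metaimage(cls, path: str | Path) -> "VoxelVolume":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        return cls(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


@dataclass
class BoneLabelMap:
    """Integer label grid aligned with a source :class:`VoxelVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    names: dict[int, str] = field(default_factory=dict)


@dataclass
class BoneSurface:
    """A triangulated bone surface in mm, canonical frame.

    ``closed`` is False when the component touched the volume boundary and
    the surface had to be capped there.
    """

    mesh: trimesh.Trimesh
    label: str | None = None
    closed: bool = True

    def __post_init__(self) -> None:
        v = self.mesh.vertices
        if not np.all(np.isfinite(v)):
            raise ValueError("surface vertices must be finite")

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self.mesh.faces)

    def copy(self) -> "BoneSurface":
        return BoneSurface(self.mesh.copy(), self.label, self.closed)

    def save(self, path: str | Path) -> None:
        self.mesh.export(str(path))

    @classmethod
    def load(cls, path: str | Path, label: str | None = None) -> "BoneSurface":
        mesh = trimesh.load_mesh(str(path), process=False)
        return cls(mesh, label=label, closed=bool(mesh.is_watertight))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def threshold_bone(vol: VoxelVolume,
                   threshold_hu: float = BONE_THRESHOLD_HU) -> np.ndarray:
    """Binary bone mask: true where HU >= ``threshold_hu`` (no smoothing).

    A voxel exactly at the threshold is included.  An empty mask is legal
    (e.g. a soft-tissue-only volume) and only triggers a warning.
    """
    mask = np.asarray(vol.values) >= threshold_hu
    if not mask.any():
        warnings.warn(
            f"thresholding at {threshold_hu} HU produced an empty mask",
            stacklevel=2)
    return mask


def remove_small_components(mask: np.ndarray,
                            spacing: tuple[float, float, float],
                            min_volume_mm3: float = MIN_COMPONENT_MM3,
                            ) -> np.ndarray:
    """Drop 26-connected components with physical volume < ``min_volume_mm3``.

    The comparison is strict, so ``min_volume_mm3=0`` is the identity and a
    component of exactly the cutoff volume survives.
    """
    labeled, n = ndimage.label(mask, structure=CONNECTIVITY_STRUCTURE)
    if n == 0:
        return mask.copy()
    voxel_mm3 = float(np.prod(spacing))
    counts = np.bincount(labeled.ravel())
    keep = counts * voxel_mm3 >= min_volume_mm3
    keep[0] = False
    return keep[labeled]


def extract_surfaces(mask: np.ndarray,
                     spacing: tuple[float, float, float],
                     origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
                     hu_field: np.ndarray | None = None,
                     level_hu: float = BONE_THRESHOLD_HU,
                     ) -> list[BoneSurface]:
    """One closed isosurface per 26-connected component of ``mask``.

    When the original HU field is supplied the surface is placed at the
    ``level_hu`` crossing with linear interpolation (sub-voxel accuracy);
    otherwise the binary mask itself is contoured at 0.5.  Components are
    meshed on padded crops so each surface closes; a component touching the
    volume boundary is capped there and flagged ``closed=False``.
    """
    if not np.asarray(mask).any():
        raise SegmentationError("cannot extract surfaces from an empty mask")
    labeled, n = ndimage.label(mask, structure=CONNECTIVITY_STRUCTURE)
    spacing = tuple(float(s) for s in spacing)
    surfaces: list[BoneSurface] = []
    slices = ndimage.find_objects(labeled)
    for idx, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        comp = labeled[slc] == idx
        touches_boundary = any(
            s.start == 0 or s.stop == dim
            for s, dim in zip(slc, mask.shape))
        if hu_field is not None:
            field = np.array(hu_field[slc], dtype=float)
            background = level_hu - 100.0
            field[~comp] = background  # suppress neighbouring components
            level = level_hu
        else:
            field = comp.astype(float)
            background = 0.0
            level = 0.5
        field = np.pad(field, 1, constant_values=background)
        verts, faces, _, _ = marching_cubes(field, level=level,
                                            spacing=spacing)
        offset = (np.asarray(origin)
                  + (np.array([s.start for s in slc]) - 1.0)
                  * np.asarray(spacing))
        mesh = trimesh.Trimesh(vertices=verts + offset, faces=faces,
                               process=True)
        mesh.update_faces(mesh.nondegenerate_faces())
        if mesh.is_watertight and mesh.volume < 0:
            mesh.invert()
        surf = BoneSurface(mesh, closed=not touches_boundary)
        if touches_boundary:
            warnings.warn("surface touches volume boundary; capped and "
                          "flagged open", stacklevel=2)
        surfaces.append(surf)
    return surfaces


def _mesh_contains(mesh: trimesh.Trimesh, point: np.ndarray) -> bool:
    """Point-in-mesh by +z ray-crossing parity (no spatial index needed).

    The ray is always cast slightly off the query point: meshes from
    marching cubes are grid-aligned, so an exact ray routinely grazes
    shared triangle edges, which defeats the parity count.
    """
    p = np.asarray(point, dtype=float)
    tri = mesh.triangles
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    for jitter in ((1.3e-5, 2.7e-5), (-3.1e-5, 1.9e-5), (2.3e-5, -3.7e-5),
                   (-1.7e-5, -2.9e-5)):
        q = p[:2] + jitter
        d1 = ((b[:, 0] - a[:, 0]) * (q[1] - a[:, 1])
              - (b[:, 1] - a[:, 1]) * (q[0] - a[:, 0]))
        d2 = ((c[:, 0] - b[:, 0]) * (q[1] - b[:, 1])
              - (c[:, 1] - b[:, 1]) * (q[0] - b[:, 0]))
        d3 = ((a[:, 0] - c[:, 0]) * (q[1] - c[:, 1])
              - (a[:, 1] - c[:, 1]) * (q[0] - c[:, 0]))
        inside = ((d1 > 0) & (d2 > 0) & (d3 > 0)) | \
                 ((d1 < 0) & (d2 < 0) & (d3 < 0))
        # a graze: the ray passes within ~1e-9 of some candidate edge
        in_bbox = ((q[0] > np.minimum.reduce([a[:, 0], b[:, 0], c[:, 0]])
                    - 1e-6)
                   & (q[0] < np.maximum.reduce([a[:, 0], b[:, 0], c[:, 0]])
                      + 1e-6)
                   & (q[1] > np.minimum.reduce([a[:, 1], b[:, 1], c[:, 1]])
                      - 1e-6)
                   & (q[1] < np.maximum.reduce([a[:, 1], b[:, 1], c[:, 1]])
                      + 1e-6))
        near = in_bbox & (np.minimum.reduce(
            [np.abs(d1), np.abs(d2), np.abs(d3)]) < 1e-9)
        if (near & ~inside).any():
            continue  # retry with a different jitter
        if not inside.any():
            return False
        n = np.cross(b[inside] - a[inside], c[inside] - a[inside])
        denom = n[:, 2]
        ok = np.abs(denom) > 1e-12
        ai = a[inside]
        z_hit = ai[ok][:, 2] + (
            (n[ok][:, 0] * (ai[ok][:, 0] - q[0])
             + n[ok][:, 1] * (ai[ok][:, 1] - q[1])) / denom[ok])
        return bool(np.count_nonzero(z_hit > p[2]) % 2)
    return False


def label_bones(surfaces: list[BoneSurface],
                seed_points: dict[str, np.ndarray]) -> list[BoneSurface]:
    """Label surfaces tibia/fibula/talus by the seed each one contains.

    Every seed must fall inside exactly one surface and no surface may
    contain two seeds; surfaces containing no seed are labeled ``"other"``.
    The operation trusts the seeds: swapped seeds yield swapped labels.
    """
    out = [s.copy() for s in surfaces]
    owner: dict[int, str] = {}
    for name, point in seed_points.items():
        point = np.asarray(point, dtype=float).ravel()
        containing = [i for i, s in enumerate(out)
                      if _mesh_contains(s.mesh, point)]
        if not containing:
            raise SegmentationError(
                f"seed for '{name}' at {point.ravel()} lies inside no surface")
        if len(containing) > 1:
            raise SegmentationError(
                f"seed for '{name}' lies inside {len(containing)} surfaces")
        i = containing[0]
        if i in owner:
            raise SegmentationError(
                f"surface {i} contains seeds for both '{owner[i]}' "
                f"and '{name}'")
        owner[i] = name
        out[i].label = name
    for s in out:
        if s.label is None:
            s.label = "other"
    return out


def segment_volume(vol: VoxelVolume,
                   seed_points: dict[str, np.ndarray],
                   threshold_hu: float = BONE_THRESHOLD_HU,
                   min_volume_mm3: float = MIN_COMPONENT_MM3,
                   ) -> list[BoneSurface]:
    """Full chain: threshold -> small-component removal -> surfaces -> labels."""
    mask = threshold_bone(vol, threshold_hu)
    mask = remove_small_components(mask, vol.spacing, min_volume_mm3)
    surfaces = extract_surfaces(mask, vol.spacing, vol.origin,
                                hu_field=vol.values, level_hu=threshold_hu)
    return label_bones(surfaces, seed_points)


def save_label_manifest(surfaces: list[BoneSurface], directory: str | Path,
                        fmt: str = "ply") -> Path:
    """Write each surface as PLY/STL plus a JSON manifest of labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(surfaces):
        name = f"{s.label or 'surface'}_{i}.{fmt}"
        s.save(directory / name)
        manifest.append({"file": name, "label": s.label, "closed": s.closed})
    path = directory / "labels.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_labeled_surfaces(directory: str | Path) -> list[BoneSurface]:
    directory = Path(directory)
    manifest = json.loads((directory / "labels.json").read_text())
    out = []
    for entry in manifest:
        surf = BoneSurface.load(directory / entry["file"],
                                label=entry["label"])
        surf.closed = bool(entry.get("closed", surf.closed))
        out.append(surf)
    return out
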