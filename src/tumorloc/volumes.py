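"""Volume data model, file I/O, contour voxelization and isotropic resampling.

A :class:`Volume` is an axis-aligned 3D scalar grid with voxel spacing and a
world origin, both in millimetres.  The axis convention is fixed throughout
the package: index axis 0 = x (patient left-right), axis 1 = y
(anterior-posterior), axis 2 = z (inferior-superior), i.e. axial slices are
``data[:, :, k]`` stacked from feet to head.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "GTVStructure",
    "VolumeFormatError",
    "EmptyStructureError",
    "effective_diameter",
    "read_volume",
    "write_volume",
    "contours_to_mask",
    "resample_isotropic",
]


class VolumeFormatError(Exception):
    """Raised when an image file cannot be read or lacks required metadata."""


class EmptyStructureError(Exception):
    """Raised when a contour set or mask produces no voxels."""


def effective_diameter(v_gtv_mm3: float) -> float:
    """Diameter of the sphere whose volume equals ``v_gtv_mm3``.

    d = 2 * (3 V / 4 pi)^(1/3).  This is the scale used to parameterize the
    blob-structure-enhancement filter (sigma = d / 4).
    """
    if not np.isfinite(v_gtv_mm3) or v_gtv_mm3 <= 0:
        raise ValueError(f"GTV volume must be positive, got {v_gtv_mm3!r}")
    return 2.0 * (3.0 * v_gtv_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class Volume:
    """3D scalar image (HU or filter-response units) on a regular grid.

    Parameters
    ----------
    data
        Array indexed ``[ix, iy, iz]`` (x = left-right, y =
        anterior-posterior, z = inferior-superior).
    spacing
        Per-axis voxel size in mm, all entries > 0.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"Volume needs >= 2 voxels per axis, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be length-3")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"spacing entries must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_isotropic(self, spacing_mm: float | None = None, tol: float = 1e-6) -> bool:
        s = np.asarray(self.spacing)
        if spacing_mm is None:
            spacing_mm = s[0]
        return bool(np.allclose(s, spacing_mm, atol=tol, rtol=0))

    def index_to_world(self, idx) -> np.ndarray:
        """World coordinates (mm) of voxel indices (may be fractional)."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        """Continuous voxel indices of world coordinates (mm)."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.data.shape[axis])

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "Volume":
        return Volume(
            data=self.data.copy() if data is None else data,
            spacing=kw.get("spacing", self.spacing),
            origin=kw.get("origin", self.origin),
        )


@dataclass
class GTVStructure:
    """Gross-tumor-volume delineation aligned to a reference grid.

    Carries the binary mask together with the grid geometry of the volume it
    was drawn on, the treatment isocenter, and derived quantities: volume
    ``v_gtv`` in mm^3, effective diameter ``d`` in mm and the half-open
    circumscribing voxel box ``bbox = (min_idx, max_idx)``.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = "GTV"
    v_gtv: float = field(init=False)
    d: float = field(init=False)
    bbox: tuple[tuple[int, int, int], tuple[int, int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("GTV mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        n = int(self.mask.sum())
        if n == 0:
            raise EmptyStructureError("GTV mask is empty")
        self.v_gtv = n * float(np.prod(self.spacing))
        self.d = effective_diameter(self.v_gtv)
        idx = np.argwhere(self.mask)
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1  # half-open
        self.bbox = (tuple(int(v) for v in lo), tuple(int(v) for v in hi))

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def centroid_mm(self) -> np.ndarray:
        """Arithmetic mean of member voxel world coordinates."""
        idx = np.argwhere(self.mask)
        return np.asarray(self.origin) + idx.mean(axis=0) * np.asarray(self.spacing)

    def bbox_slices(self) -> tuple[slice, slice, slice]:
        lo, hi = self.bbox
        return tuple(slice(l, h) for l, h in zip(lo, hi))


# ---------------------------------------------------------------------------
# File I/O (NIfTI / MetaImage via SimpleITK; optional DICOM series)
# ---------------------------------------------------------------------------

def _to_sitk(v: Volume):
    import SimpleITK as sitk

    # SimpleITK arrays are indexed (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(v.data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in v.spacing))
    img.SetOrigin(tuple(float(o) for o in v.origin))
    return img


def _from_sitk(img) -> Volume:
    import SimpleITK as sitk

    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise VolumeFormatError(f"expected a 3D image, got {arr.ndim} dimensions")
    spacing = img.GetSpacing()
    origin = img.GetOrigin()
    if len(spacing) != 3:
        raise VolumeFormatError("image header is missing 3D spacing metadata")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise VolumeFormatError(
            "only axis-aligned volumes are supported (direction matrix is not identity)"
        )
    return Volume(data=np.transpose(arr, (2, 1, 0)), spacing=spacing, origin=origin)


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    A directory is treated as a DICOM series (best effort).  Integer voxel
    values are preserved bit-exact; spacing and origin come from the header.

    Raises
    ------
    VolumeFormatError
        If the file is missing, truncated, or lacks 3D metadata.
    """
    import SimpleITK as sitk

    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    try:
        if os.path.isdir(path):
            reader = sitk.ImageSeriesReader()
            files = reader.GetGDCMSeriesFileNames(path)
            if not files:
                raise VolumeFormatError(f"no DICOM series found in directory {path}")
            reader.SetFileNames(files)
            img = reader.Execute()
        else:
            img = sitk.ReadImage(path)
    except VolumeFormatError:
        raise
    except RuntimeError as exc:
        raise VolumeFormatError(f"cannot read image {path}: {exc}") from exc
    return _from_sitk(img)


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI or MetaImage, chosen by file extension."""
    import SimpleITK as sitk

    sitk.WriteImage(_to_sitk(v), os.fspath(path))


# ---------------------------------------------------------------------------
# Contours -> mask
# ---------------------------------------------------------------------------

def contours_to_mask(contours: dict, target: Volume, name: str = "GTV") -> GTVStructure:
    """Voxelize per-slice closed polygon contours onto ``target``'s grid.

    ``contours`` follows a small JSON dialect standing in for DICOM-RT
    structure sets::

        {"slices": [{"z_mm": float, "points_mm": [[x, y], ...]}, ...],
         "isocenter_mm": [x, y, z]}

    A voxel belongs to the structure iff its center lies inside the polygon of
    its slice (even-odd rule).  Slices map to the nearest grid plane within
    half a slice spacing.

    Raises
    ------
    EmptyStructureError
        If no polygon covers any voxel center.
    ValueError
        For degenerate (zero-area) polygons.
    """
    from matplotlib.path import Path as MplPath

    slices = contours.get("slices", [])
    if not slices:
        raise EmptyStructureError("contour set contains no slices")
    mask = np.zeros(target.shape, dtype=bool)
    xs = target.axis_coords(0)
    ys = target.axis_coords(1)
    zs = target.axis_coords(2)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    for sl in slices:
        pts = np.asarray(sl["points_mm"], dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            raise ValueError("each contour needs >= 3 (x, y) points")
        # shoelace area; zero-area polygons are degenerate
        x, y = pts[:, 0], pts[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area <= 0:
            raise ValueError("degenerate zero-area contour polygon")
        z = float(sl["z_mm"])
        k = int(np.argmin(np.abs(zs - z)))
        if abs(zs[k] - z) > 0.5 * target.spacing[2] + 1e-9:
            continue  # contour plane misses the grid
        # Path without codes is implicitly closed for point-inclusion tests
        inside = MplPath(pts).contains_points(centers)
        mask[:, :, k] |= inside.reshape(len(xs), len(ys))
    if not mask.any():
        raise EmptyStructureError("no contour polygon intersects the volume grid")
    iso = tuple(float(c) for c in contours.get("isocenter_mm", (0.0, 0.0, 0.0)))
    return GTVStructure(mask=mask, spacing=target.spacing, origin=target.origin,
                        isocenter=iso, name=name)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _keys_weights(frac: np.ndarray) -> list[np.ndarray]:
    """Keys cubic-convolution weights (a = -0.5) for taps at offsets -1..2."""
    a = -0.5
    t = frac  # distance of sample from left-hand integer node, in [0, 1)

    def k(x):
        ax = np.abs(x)
        w = np.where(
            ax < 1,
            (a + 2) * ax**3 - (a + 3) * ax**2 + 1,
            np.where(ax < 2, a * ax**3 - 5 * a * ax**2 + 8 * a * ax - 4 * a, 0.0),
        )
        return w

    return [k(t + 1), k(t), k(t - 1), k(t - 2)]


def _interp_along_axis(data: np.ndarray, coords: np.ndarray, axis: int,
                       method: str) -> np.ndarray:
    """Resample ``data`` along ``axis`` at fractional index positions ``coords``.

    Boundary handling is edge clamping (nearest-node replication).
    """
    n = data.shape[axis]
    coords = np.asarray(coords, dtype=float)
    i0 = np.floor(coords).astype(int)
    frac = coords - i0
    if method == "trilinear":
        taps = [(i0, 1.0 - frac), (i0 + 1, frac)]
    elif method == "tricubic":
        w = _keys_weights(frac)
        taps = [(i0 - 1, w[0]), (i0, w[1]), (i0 + 1, w[2]), (i0 + 2, w[3])]
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    shape = [1] * data.ndim
    shape[axis] = len(coords)
    out = np.zeros([len(coords) if ax == axis else s for ax, s in enumerate(data.shape)])
    for idx, w in taps:
        idx = np.clip(idx, 0, n - 1)
        out += np.take(data, idx, axis=axis) * w.reshape(shape)
    return out


def sample_at_world(v: Volume, coords_axes: tuple[np.ndarray, np.ndarray, np.ndarray],
                    method: str = "tricubic") -> np.ndarray:
    """Sample ``v`` on the tensor-product grid of per-axis world coordinates.

    Separable interpolation: one 1D pass per axis (Keys cubic or linear),
    clamped at the edges.  Used by resampling and by the rigid-shift
    degradation model.
    """
    out = np.asarray(v.data, dtype=float)
    for axis in range(3):
        idx = (np.asarray(coords_axes[axis], dtype=float) - v.origin[axis]) / v.spacing[axis]
        out = _interp_along_axis(out, idx, axis, method)
    return out


def resample_isotropic(v: Volume, target_spacing_mm: float,
                       method: str = "tricubic") -> Volume:
    """Resample to an isotropic grid at ``target_spacing_mm``.

    The output grid starts at the input origin and covers the same world
    extent (to within one output voxel).  ``method`` is ``"tricubic"`` (Keys
    cubic convolution, a = -0.5) or ``"trilinear"``.
    """
    if not np.isfinite(target_spacing_mm) or target_spacing_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing_mm!r}")
    if method not in ("tricubic", "trilinear"):
        raise ValueError(f"unknown interpolation method {method!r}")
    extents = [(n - 1) * s for n, s in zip(v.shape, v.spacing)]
    if any(target_spacing_mm > e for e in extents):
        raise ValueError(
            f"target spacing {target_spacing_mm} mm exceeds the volume extent {extents} mm"
        )
    coords = []
    for axis in range(3):
        n_out = int(np.floor(extents[axis] / target_spacing_mm)) + 1
        n_out = max(n_out, 2)
        coords.append(v.origin[axis] + target_spacing_mm * np.arange(n_out))
    data = sample_at_world(v, tuple(coords), method=method)
    return Volume(data=data, spacing=(target_spacing_mm,) * 3, origin=v.origin)
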