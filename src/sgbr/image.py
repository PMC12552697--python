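"""Voxel image container and file I/O.

Every field in the toolkit — CT intensities, label maps, implicit surface
fields, bone-density maps — travels as an :class:`ImageVolume`: a 3D array
plus physical voxel spacing and origin, all lengths in millimetres.

Conventions
-----------
* Axis order is (x, y, z) with x the fastest-varying index.
* Voxel *centers* sample the continuous field: the center of voxel
  ``(i, j, k)`` sits at ``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing``.
* Indices are 0-based.
* Label volumes use the closed vocabulary in :data:`LABELS`.
* Densities are g/cm^3; voxel volumes are mm^3 (1 cm^3 = 1000 mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

# Closed label vocabulary for segment/scaffold phantoms.
LABELS = {
    "void": 0,
    "host_bone": 1,
    "scaffold_solid": 2,
    "tcp_lattice": 3,
    "new_bone": 4,
    "screw": 5,
}

MM3_PER_CM3 = 1000.0


@dataclass
class ImageVolume:
    """A 3D scalar, label, or density field on a regular voxel grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values; dtype is free (float for intensities/fields,
        integer for labels/masks).
    spacing : tuple of float
        Voxel edge lengths in mm, strictly positive.
    origin : tuple of float
        Position (mm) of the low corner of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of voxel centers along each axis."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """Same grid metadata, new values."""
        return replace(self, values=np.asarray(values))

    def same_grid(self, other: "ImageVolume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def empty_like_grid(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    dtype=np.float64,
) -> ImageVolume:
    return ImageVolume(np.zeros(shape, dtype=dtype), spacing, origin)


# ---------------------------------------------------------------------------
# NIfTI I/O (nibabel). Spacing is carried in the affine diagonal, mm.
# ---------------------------------------------------------------------------

def read_nifti(path) -> ImageVolume:
    """Read a NIfTI volume into an ImageVolume (spacing from the header)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    origin = tuple(float(x) for x in affine[:3, 3])
    return ImageVolume(np.asarray(data), tuple(float(z) for z in zooms), origin)


def write_nifti(vol: ImageVolume, path) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    values = vol.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    nib.save(nib.Nifti1Image(values, affine), str(path))


# ---------------------------------------------------------------------------
# Surface / field export
# ---------------------------------------------------------------------------

def mask_to_stl(mask: ImageVolume, path, level: float = 0.5) -> None:
    """Export the iso-surface of a binary mask as an STL mesh.

    Marching cubes runs on the float-cast mask; vertex coordinates are
    scaled to mm using the voxel spacing.
    """
    from skimage.measure import marching_cubes
    import trimesh

    data = mask.values.astype(np.float32)
    if data.min() >= level or data.max() <= level:
        raise ValueError("mask has no iso-surface at the requested level")
    verts, faces, _, _ = marching_cubes(data, level=level, spacing=mask.spacing)
    verts = verts + np.asarray(mask.origin)
    trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(str(path))


def write_vtk_structured(path, vol: ImageVolume, fields: dict[str, np.ndarray]) -> None:
    """Write point/cell fields on the voxel grid as legacy-ASCII VTK.

    ``fields`` maps names to arrays shaped like ``vol.values`` (scalar per
    voxel) or ``vol.values.shape + (3,)`` (vector per voxel); written as
    CELL_DATA on a STRUCTURED_POINTS dataset.
    """
    nx, ny, nz = vol.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nsgbr field export\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write("ORIGIN {} {} {}\n".format(*vol.origin))
        fh.write("SPACING {} {} {}\n".format(*vol.spacing))
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr)
            if arr.shape == vol.shape:
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                flat = arr.reshape(-1, order="F")
                np.savetxt(fh, flat[:, None], fmt="%.6g")
            elif arr.shape == vol.shape + (3,):
                fh.write(f"VECTORS {name} float\n")
                flat = arr.reshape(-1, 3, order="F")
                np.savetxt(fh, flat, fmt="%.6g")
            else:
                raise ValueError(f"field {name!r} has incompatible shape {arr.shape}")
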