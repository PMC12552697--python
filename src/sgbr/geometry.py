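"""Scaffold geometry: TPMS implicit fields, beam lattices, and pore metrics.

Two scaffold families are triply periodic minimal surfaces (TPMS) defined by
implicit trigonometric fields — the (network) gyroid and the Schwarz
primitive surface — and one is a body-centred-cubic (BCC) beam lattice.
The solid phase is the sub-level set ``{field <= t}`` with the iso-level
``t`` calibrated by bisection to a target solid volume fraction.

Pore size follows the largest-sphere-through-the-void definition (twice the
peak of the Euclidean distance transform of the percolating void component,
evaluated periodically); strut size is the local thickness at the thinnest
point of the solid (twice the minimum distance-transform value on the solid
skeleton).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ImageVolume

TPMS_FAMILIES = ("gyroid", "schwarz_p")
FAMILIES = TPMS_FAMILIES + ("bcc_beam",)


class UnsupportedFamilyError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class ScaffoldSpec:
    """Parameters of one scaffold architecture.

    unit_cell_size and all lengths are mm; ``lattice_rotation`` (degrees,
    about the build/z axis) applies to the BCC beam lattice only.
    """

    family: str
    unit_cell_size: float
    target_volume_fraction: float = 0.5
    pore_size_nominal: float | None = None
    strut_or_beam_size: float | None = None
    lattice_rotation: float = 0.0
    voxel_spacing: float = 0.1

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise UnsupportedFamilyError(
                f"family {self.family!r} not one of {FAMILIES}"
            )
        if self.unit_cell_size <= 0:
            raise ValueError("unit_cell_size must be positive")
        if not 0 < self.target_volume_fraction < 1:
            raise ValueError("target_volume_fraction must lie in (0, 1)")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")
        if self.voxel_spacing > self.unit_cell_size / 8:
            raise ValueError(
                "voxel_spacing must be <= unit_cell_size/8 to resolve the cell"
            )
        if self.family == "bcc_beam":
            beam = self.strut_or_beam_size
            if beam is None:
                raise ValueError("bcc_beam requires strut_or_beam_size")
            if beam >= self.unit_cell_size / 2:
                raise ValueError("beam thickness must be < unit_cell_size/2")


# Shipped designs used throughout the study: the gyroid frame infill,
# the Schwarz P architecture of the earlier partial-defect scaffold, and
# the resorbable ceramic BCC lattice core.
GYROID_FRAME = dict(family="gyroid", unit_cell_size=3.5,
                    target_volume_fraction=0.5, pore_size_nominal=1.6)
SCHWARZ_P_SCAFFOLD = dict(family="schwarz_p", unit_cell_size=2.0,
                          target_volume_fraction=0.5, pore_size_nominal=1.0,
                          strut_or_beam_size=1.0)
BCC_TCP_LATTICE = dict(family="bcc_beam", unit_cell_size=1.875,
                       strut_or_beam_size=0.4, lattice_rotation=45.0)


def tpms_field(spec: ScaffoldSpec, grid: ImageVolume) -> ImageVolume:
    """Evaluate the implicit TPMS field at the voxel centers of ``grid``.

    gyroid:    sin X cos Y + sin Y cos Z + sin Z cos X
    schwarz_p: cos X + cos Y + cos Z

    with (X, Y, Z) = 2*pi/L * (x, y, z) and L the unit-cell size, so the
    field is L-periodic along each axis.
    """
    if spec.family not in TPMS_FAMILIES:
        raise UnsupportedFamilyError(
            f"{spec.family!r} has no implicit TPMS field"
        )
    k = 2.0 * np.pi / spec.unit_cell_size
    cx, cy, cz = grid.voxel_centers()
    X = k * cx[:, None, None]
    Y = k * cy[None, :, None]
    Z = k * cz[None, None, :]
    if spec.family == "gyroid":
        vals = np.sin(X) * np.cos(Y) + np.sin(Y) * np.cos(Z) + np.sin(Z) * np.cos(X)
    else:
        vals = np.cos(X) + np.cos(Y) + np.cos(Z)
    return grid.with_values(vals)


def unit_cell_grid(spec: ScaffoldSpec, n_cells: int = 1,
                   spacing: float | None = None) -> ImageVolume:
    """A voxel grid covering ``n_cells`` whole unit cells along each axis."""
    h = spacing if spacing is not None else spec.voxel_spacing
    n = max(8, int(round(spec.unit_cell_size / h)))
    h_eff = spec.unit_cell_size / n  # snap so whole cells tile exactly
    m = n * n_cells
    return ImageVolume(np.zeros((m, m, m)), (h_eff, h_eff, h_eff))


def volume_fraction(mask: ImageVolume, region: np.ndarray | None = None) -> float:
    """Solid voxel count over total voxel count (within ``region`` if given)."""
    solid = mask.values.astype(bool)
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if not region.any():
            raise ValueError("empty region: volume fraction undefined")
        return float(solid[region].mean())
    if solid.size == 0:
        raise ValueError("empty region: volume fraction undefined")
    return float(solid.mean())


def calibrate_iso_level(field: ImageVolume, target_volume_fraction: float,
                        tol: float = 1e-3, max_iter: int = 60) -> float:
    """Bisect for the iso-level t with frac(field <= t) within tol of target.

    The solid phase is the sub-level set, so the solid fraction is a
    non-decreasing step function of t and bisection converges.
    """
    if not 0 < target_volume_fraction < 1:
        raise ValueError("target_volume_fraction must lie in (0, 1)")
    v = np.asarray(field.values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise CalibrationError("field is constant; iso-level calibration impossible")

    def frac(t: float) -> float:
        return float((v <= t).mean())

    if frac(lo) > target_volume_fraction + tol or frac(hi) < target_volume_fraction - tol:
        raise CalibrationError("target volume fraction unattainable in field range")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target_volume_fraction) <= tol:
            return mid
        if f < target_volume_fraction:
            lo = mid
        else:
            hi = mid
    # The solid fraction is a step function of t on a finite grid; when the
    # target falls inside a quantization step the bracket midpoint is the
    # attainable optimum (within one step of voxel-count granularity).
    mid = 0.5 * (lo + hi)
    if abs(frac(mid) - target_volume_fraction) <= max(5 * tol, 100.0 / v.size):
        return mid
    raise CalibrationError(
        f"calibration failed: best fraction {frac(mid):.4f} vs target {target_volume_fraction}"
    )


def voxelize(field: ImageVolume, iso: float) -> ImageVolume:
    """Binary solid mask: solid where field <= iso (grid metadata preserved)."""
    return field.with_values(np.asarray(field.values) <= iso)


def generate_scaffold(spec: ScaffoldSpec, n_cells: int = 1,
                      tol: float = 1e-3) -> tuple[ImageVolume, float]:
    """Convenience: field -> calibrated iso -> mask for a TPMS spec.

    Returns (solid mask over whole unit cells, iso-level used).
    """
    grid = unit_cell_grid(spec, n_cells=n_cells)
    f = tpms_field(spec, grid)
    iso = calibrate_iso_level(f, spec.target_volume_fraction, tol=tol)
    return voxelize(f, iso), iso


# ---------------------------------------------------------------------------
# Pore and strut metrics
# ---------------------------------------------------------------------------

def _periodic_edt(phase: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance transform of ``phase`` with periodic wrap.

    Computed on a 3x tiling, central tile returned; exact for distances
    below one period, which covers any physical pore.
    """
    tiled = np.tile(phase, (3, 3, 3))
    d = ndimage.distance_transform_edt(tiled, sampling=spacing)
    nx, ny, nz = phase.shape
    return d[nx:2 * nx, ny:2 * ny, nz:2 * nz]


def _percolating_component(phase: np.ndarray, periodic: bool) -> tuple[np.ndarray, bool]:
    """Largest component of ``phase`` that spans the domain along some axis.

    Returns (component mask, percolates_flag). For periodic domains a
    component percolates if, on a 2x tiling along an axis, it connects the
    two copies; the simpler face-touching test is used, which is equivalent
    for the structures handled here.
    """
    lbl, n = ndimage.label(phase)
    if n == 0:
        return np.zeros_like(phase, dtype=bool), False
    best, best_size, perc = None, -1, False
    for comp in range(1, n + 1):
        m = lbl == comp
        size = int(m.sum())
        spans = any(
            m.take(0, axis=a).any() and m.take(-1, axis=a).any() for a in range(3)
        )
        if spans and (not perc or size > best_size):
            best, best_size, perc = m, size, True
        elif not perc and size > best_size:
            best, best_size = m, size
    return best, perc


def pore_size(mask: ImageVolume, periodic: bool = True) -> tuple[float, bool]:
    """Diameter (mm) of the largest sphere fitting through the void.

    Returns (diameter, percolating). The diameter is twice the maximum of
    the void-phase distance transform restricted to the percolating void
    component (largest component if none percolates, flagged False).
    """
    solid = mask.values.astype(bool)
    void = ~solid
    if not void.any():
        raise ValueError("all-solid mask: no pore")
    comp, perc = _percolating_component(void, periodic)
    if periodic and solid.any():
        d = _periodic_edt(void, mask.spacing)
    else:
        # non-periodic: the sphere must fit inside the domain, so the
        # outside counts as solid (one padded layer bounds the transform)
        padded = np.pad(void, 1, constant_values=False)
        d = ndimage.distance_transform_edt(padded, sampling=mask.spacing)
        d = d[1:-1, 1:-1, 1:-1]
    dmax = float(d[comp].max()) if comp is not None and comp.any() else 0.0
    return 2.0 * dmax, perc


def strut_size(mask: ImageVolume) -> float:
    """Local thickness (mm) of the solid at its thinnest point.

    Twice the minimum of the solid-phase distance transform over the solid
    skeleton (medial axis), i.e. the narrowest load path.
    """
    from skimage.morphology import skeletonize

    solid = mask.values.astype(bool)
    if not solid.any():
        raise ValueError("all-void mask: no solid strut")
    d = ndimage.distance_transform_edt(solid, sampling=mask.spacing)
    skel = skeletonize(solid)
    if not skel.any():
        # Degenerate (e.g. single-voxel-thick solid): fall back to max radius.
        return 2.0 * float(d[solid].max())
    return 2.0 * float(d[skel].min())


# ---------------------------------------------------------------------------
# BCC beam lattice
# ---------------------------------------------------------------------------

def _bcc_segments(cell: float, bbox_lo, bbox_hi, rotation_deg: float) -> np.ndarray:
    """Corner-to-center beam segments of a BCC tiling covering the bbox.

    Returns an (n, 2, 3) array of segment endpoints in mm. The lattice is
    rotated about the z (build) axis before clipping to the bbox margin.
    """
    theta = np.deg2rad(rotation_deg)
    R = np.array([
        [np.cos(theta), -np.sin(theta), 0.0],
        [np.sin(theta), np.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    center = 0.5 * (np.asarray(bbox_lo) + np.asarray(bbox_hi))
    # bbox corners in the (rotated) lattice frame -> cell index ranges
    corners_mm = np.array([
        [x, y, z]
        for x in (bbox_lo[0], bbox_hi[0])
        for y in (bbox_lo[1], bbox_hi[1])
        for z in (bbox_lo[2], bbox_hi[2])
    ])
    local = (corners_mm - center) @ R  # R^T applied from the right
    lo_idx = np.floor(local.min(axis=0) / cell).astype(int) - 1
    hi_idx = np.ceil(local.max(axis=0) / cell).astype(int) + 1
    segs = []
    corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                       dtype=float)
    for i in range(lo_idx[0], hi_idx[0] + 1):
        for j in range(lo_idx[1], hi_idx[1] + 1):
            for k in range(lo_idx[2], hi_idx[2] + 1):
                lo = np.array([i, j, k], dtype=float) * cell
                c = lo + 0.5 * cell
                for corner in corners:
                    p = (lo + corner * cell)
                    segs.append([p, c])
    segs = np.asarray(segs)
    # rotate the lattice about its origin, recentre on the bbox
    segs = segs @ R.T + center
    # drop segments entirely outside the bbox (with one-cell margin)
    lo_m = np.asarray(bbox_lo) - cell
    hi_m = np.asarray(bbox_hi) + cell
    keep = np.all((segs.max(axis=1) >= lo_m) & (segs.min(axis=1) <= hi_m), axis=1)
    segs = segs[keep]
    # deduplicate (corner beams are shared between adjacent cells)
    key = np.round(segs.reshape(-1, 6) / (1e-6 * cell)).astype(np.int64)
    _, uniq = np.unique(key, axis=0, return_index=True)
    return segs[np.sort(uniq)]


def _capsule_voxelize(grid: ImageVolume, segments: np.ndarray, radius: float) -> np.ndarray:
    """Union of capsules (segment + radius) rasterized on the grid."""
    out = np.zeros(grid.shape, dtype=bool)
    sp = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    shape = np.asarray(grid.shape)
    cx, cy, cz = grid.voxel_centers()
    for a, b in segments:
        lo = np.minimum(a, b) - radius - sp
        hi = np.maximum(a, b) + radius + sp
        i0 = np.maximum(np.floor((lo - origin) / sp).astype(int), 0)
        i1 = np.minimum(np.ceil((hi - origin) / sp).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        X = cx[i0[0]:i1[0]][:, None, None]
        Y = cy[i0[1]:i1[1]][None, :, None]
        Z = cz[i0[2]:i1[2]][None, None, :]
        ab = b - a
        L2 = float(ab @ ab)
        px, py, pz = X - a[0], Y - a[1], Z - a[2]
        if L2 > 0:
            t = np.clip((px * ab[0] + py * ab[1] + pz * ab[2]) / L2, 0.0, 1.0)
        else:
            t = 0.0
        dx = px - t * ab[0]
        dy = py - t * ab[1]
        dz = pz - t * ab[2]
        d2 = dx * dx + dy * dy + dz * dz
        out[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= radius * radius
    return out


def bcc_lattice(spec: ScaffoldSpec, region_mask: ImageVolume) -> ImageVolume:
    """Voxelized BCC beam lattice filling the region mask.

    Beams join cube corners to body centers; the whole lattice is rotated
    ``lattice_rotation`` degrees about the build (z) axis. Beam nodes lying
    within one cell of the region boundary are projected (warped) onto the
    nearest boundary surface voxel so no beam terminates free in space, and
    beams entirely outside the region are dropped.
    """
    if spec.family != "bcc_beam":
        raise UnsupportedFamilyError("bcc_lattice requires a bcc_beam spec")
    region = region_mask.values.astype(bool)
    if not region.any():
        return region_mask.with_values(np.zeros_like(region))
    radius = spec.strut_or_beam_size / 2.0
    sp = np.asarray(region_mask.spacing)
    origin = np.asarray(region_mask.origin)
    # bbox of the region in mm
    idx = np.argwhere(region)
    lo = origin + idx.min(axis=0) * sp
    hi = origin + (idx.max(axis=0) + 1) * sp
    segs = _bcc_segments(spec.unit_cell_size, lo, hi, spec.lattice_rotation)

    # signed distance to region surface (negative inside), for warping
    inside_d = ndimage.distance_transform_edt(region, sampling=sp)
    surface = region & ~ndimage.binary_erosion(region)
    if surface.any():
        _, surf_idx = ndimage.distance_transform_edt(
            ~surface, sampling=sp, return_indices=True
        )
    else:
        surf_idx = None

    def node_state(p: np.ndarray) -> tuple[bool, float]:
        """(inside_region, distance_inside) at point p (mm)."""
        ijk = np.floor((p - origin) / sp).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= region.shape):
            return False, 0.0
        return bool(region[tuple(ijk)]), float(inside_d[tuple(ijk)])

    def project(p: np.ndarray) -> np.ndarray:
        ijk = np.clip(np.floor((p - origin) / sp).astype(int), 0,
                      np.asarray(region.shape) - 1)
        tgt = np.array([surf_idx[a][tuple(ijk)] for a in range(3)])
        return origin + (tgt + 0.5) * sp

    warped = []
    for a, b in segs:
        ends = []
        n_inside = 0
        for p in (a, b):
            ins, d_in = node_state(p)
            if ins:
                n_inside += 1
            near_boundary = (not ins) or d_in < spec.unit_cell_size
            if not ins and surf_idx is not None:
                p = project(p)
            elif ins and near_boundary and surf_idx is not None and d_in < radius:
                # nodes grazing the surface snap onto it
                p = project(p)
            ends.append(p)
        if n_inside == 0:
            continue  # beam entirely outside the envelope
        warped.append(ends)
    if not warped:
        return region_mask.with_values(np.zeros_like(region))
    mask = _capsule_voxelize(region_mask, np.asarray(warped), radius)
    mask &= region
    return region_mask.with_values(mask)
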