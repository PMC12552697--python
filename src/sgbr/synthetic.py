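"""Synthetic phantoms: defect geometry, load cases, and emulated CT volumes.

Real subject-specific CT data is replaced by a simplified rectangular-beam
bone segment: a bone bar with a centred segmental defect (default 6 cm)
bridged by a scaffold frame whose outer shell is the gyroid-architecture
polymer and whose core envelope holds the resorbable ceramic beam lattice.
Host-bone interface patches sit at both cut faces, a condylar fixation
patch at the posterior end face, and a masticatory load patch on the
anterior top surface. Everything is a pure function of (spec, seed).

The CT emulator maps labels to scanner intensities, applies Gaussian
partial-volume blur and additive noise, and returns the ground-truth
labels alongside — the artefact structure (bright ceramic haloes that leak
into the bone intensity window) that the segmentation procedure's
dilate-and-subtract step exists to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .image import ImageVolume, LABELS
from .geometry import (ScaffoldSpec, tpms_field, calibrate_iso_level, voxelize,
                       bcc_lattice, GYROID_FRAME, BCC_TCP_LATTICE)
from .voxfem import LoadCase, DirichletBC, Load, BONDED, frictional
from .materials import MU_BONE_SCAFFOLD, MU_BONE_SCREW

HOST = LABELS["host_bone"]
SCAFFOLD = LABELS["scaffold_solid"]
TCP = LABELS["tcp_lattice"]
NEW_BONE = LABELS["new_bone"]
SCREW = LABELS["screw"]

# Default CT intensity map (scanner units): new bone falls in the
# 1800-5300 bone window, the ceramic lattice and metal screws above 5300,
# the radiolucent polymer and soft tissue below 1800.
DEFAULT_INTENSITIES = {
    LABELS["void"]: 500.0,
    HOST: 3200.0,
    SCAFFOLD: 900.0,
    TCP: 6500.0,
    NEW_BONE: 3000.0,
    SCREW: 8000.0,
}


@dataclass
class PhantomSpec:
    """Geometry of the synthetic defect segment (lengths in mm)."""

    segment_length: float = 130.0
    cross_section: tuple[float, float] = (17.5, 17.5)
    defect_length: float = 60.0
    scaffold: ScaffoldSpec = dc_field(
        default_factory=lambda: ScaffoldSpec(**GYROID_FRAME))
    lattice: ScaffoldSpec = dc_field(
        default_factory=lambda: ScaffoldSpec(**BCC_TCP_LATTICE))
    screw_patches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.defect_length >= self.segment_length:
            raise ValueError("defect must be shorter than the segment")


@dataclass
class Phantom:
    """Label volume plus named voxel patches for loading and analysis."""

    labels: ImageVolume
    masks: dict
    spec: PhantomSpec


def make_phantom(spec: PhantomSpec, spacing: float = 3.5) -> Phantom:
    """Build the labelled defect-segment phantom on a grid of given spacing.

    The defect spans exactly ``defect_length`` along x (cell counts snap to
    the nearest whole voxel). The scaffold frame occupies the outer shell
    of the defect cross-section; the interior envelope is the ceramic
    lattice region. Deterministic for a fixed spec.
    """
    nx = max(3, int(round(spec.segment_length / spacing)))
    ny = max(3, int(round(spec.cross_section[0] / spacing)))
    nz = max(3, int(round(spec.cross_section[1] / spacing)))
    n_def = int(round(spec.defect_length / spacing))
    if n_def >= nx:
        raise ValueError("scaffold larger than the bone segment")
    i0 = (nx - n_def) // 2
    i1 = i0 + n_def

    vol = np.full((nx, ny, nz), HOST, dtype=np.int16)
    # defect interior: frame shell = scaffold, core = ceramic lattice
    shell = np.zeros((ny, nz), dtype=bool)
    shell[0, :] = shell[-1, :] = True
    shell[:, 0] = shell[:, -1] = True
    for i in range(i0, i1):
        vol[i][shell] = SCAFFOLD
        vol[i][~shell] = TCP
    if min(ny, nz) <= 2:  # degenerate thin sections: all scaffold
        vol[i0:i1][vol[i0:i1] == TCP] = SCAFFOLD

    masks = {}
    masks["defect"] = np.zeros_like(vol, dtype=bool)
    masks["defect"][i0:i1] = True
    masks["host"] = vol == HOST
    masks["frame"] = vol == SCAFFOLD
    masks["lattice_envelope"] = vol == TCP

    # screw patches: lateral-surface host voxels flanking each cut face
    screw = np.zeros_like(vol, dtype=bool)
    n_scr = max(0, int(spec.screw_patches))
    for s in range(n_scr):
        off = 1 + s
        for i in (i0 - off, i1 - 1 + off):
            if 0 <= i < nx:
                screw[i, 0, nz // 2] = vol[i, 0, nz // 2] == HOST
                screw[i, -1, nz // 2] = vol[i, -1, nz // 2] == HOST
    vol[screw] = SCREW
    masks["screws"] = screw

    labels = ImageVolume(vol, (spacing, spacing, spacing))

    fixed = np.zeros_like(vol, dtype=bool)
    fixed[-1] = True  # posterior (condylar) end face
    load = np.zeros_like(vol, dtype=bool)
    n_load = max(1, i0 // 3)
    load[:n_load, :, -1] = True  # anterior top surface (premolar area)
    masks["fixed_patch"] = fixed
    masks["load_patch"] = load

    host = vol == HOST
    near_host = ndimage.binary_dilation(
        host, structure=ndimage.generate_binary_structure(3, 1))
    masks["interface"] = (vol == SCAFFOLD) & near_host
    return Phantom(labels=labels, masks=masks, spec=spec)


def make_load_case(phantom: Phantom, bite_force: float = 450.0,
                   scenario: str = "bonded") -> LoadCase:
    """Mastication-style load case on the phantom.

    The posterior end face is fully fixed (condylar immobilisation) and a
    downward force of ``bite_force`` N is distributed over the anterior
    top-surface patch. ``scenario`` sets the bone-scaffold interface:
    'bonded' (osseointegration, tie) or 'frictional' (no osseointegration,
    mu = 0.1); the bone-screw interface is frictional with mu = 0.3 when
    screws are present.
    """
    masks = phantom.masks
    if not masks["fixed_patch"].any() or not masks["load_patch"].any():
        raise ValueError("phantom lacks constraint or load patches")
    modes = {}
    if scenario == "frictional":
        modes[frozenset({HOST, SCAFFOLD})] = frictional(MU_BONE_SCAFFOLD)
    elif scenario == "bonded":
        modes[frozenset({HOST, SCAFFOLD})] = BONDED
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if masks["screws"].any():
        modes[frozenset({HOST, SCREW})] = frictional(MU_BONE_SCREW)
    return LoadCase(
        dirichlet=[DirichletBC(masks["fixed_patch"], (0, 1, 2), face="+x")],
        loads=[Load(masks["load_patch"], (0.0, 0.0, -float(bite_force)),
                    face="+z")],
        interface_mode=modes,
    )


# ---------------------------------------------------------------------------
# Fine-scale CT phantom
# ---------------------------------------------------------------------------

def make_ct_phantom(spec: PhantomSpec | None = None, spacing: float = 0.05,
                    roi_mm: float = 6.0, n_bone_blobs: int = 6,
                    seed: int = 0) -> Phantom:
    """Resolved micro-CT-scale phantom patch with known new-bone blobs.

    A cube of side ``roi_mm`` at the host-bone/scaffold interface: one face
    is host bone, the rest is gyroid scaffold with the ceramic beam
    lattice crossing the interior, and ``n_bone_blobs`` ellipsoidal
    new-bone deposits seeded in the void (several touching the lattice
    beams, reproducing the halo-contamination geometry).
    """
    rng = np.random.default_rng(seed)
    spec = spec or PhantomSpec()
    n = int(round(roi_mm / spacing))
    grid = ImageVolume(np.zeros((n, n, n)), (spacing,) * 3)
    f = tpms_field(spec.scaffold, grid)
    iso = calibrate_iso_level(f, spec.scaffold.target_volume_fraction)
    gyroid = voxelize(f, iso).values.astype(bool)

    vol = np.zeros((n, n, n), dtype=np.int16)
    host_n = max(2, int(round(0.1 * n)))
    vol[:host_n] = HOST
    region = np.zeros((n, n, n), dtype=bool)
    core0, core1 = int(0.3 * n), int(0.85 * n)
    region[core0:core1, n // 4: 3 * n // 4, n // 4: 3 * n // 4] = True
    lattice = bcc_lattice(spec.lattice, grid.with_values(region)).values.astype(bool)
    scaffold_zone = np.zeros_like(region)
    scaffold_zone[host_n:] = True
    vol[scaffold_zone & gyroid & ~lattice] = SCAFFOLD
    vol[lattice & scaffold_zone] = TCP

    # ellipsoidal new-bone deposits in the remaining void; some apposed to
    # (tangent to) lattice beams, reproducing the halo-adjacency geometry
    cx, cy, cz = grid.voxel_centers()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    d_tcp = ndimage.distance_transform_edt(~lattice, sampling=spacing) \
        if lattice.any() else None
    for b in range(n_bone_blobs):
        radii = rng.uniform(0.3, 0.8, 3)
        if b < n_bone_blobs // 3 and d_tcp is not None:
            # centre sits one blob-radius plus a small clearance off the
            # beam surface: apposed to the strut's partial-volume halo but
            # outside the compensating offset band
            r = float(radii.min())
            band = (vol == 0) & (np.abs(d_tcp - (r + 0.3)) < 0.05)
            cand = np.argwhere(band)
            if len(cand) == 0:
                continue
            c = (cand[rng.integers(len(cand))] + 0.5) * spacing
            radii[:] = r
        else:
            # free deposits clear of the beams: the offset subtraction must
            # not eat into them (bone in the lattice forms discrete islands)
            margin = int(0.15 * n)
            ok = np.ones((n, n, n), dtype=bool)
            ok[:max(host_n + 2, margin)] = False
            ok[-margin:] = False
            ok[:, :margin, :] = ok[:, -margin:, :] = False
            ok[:, :, :margin] = ok[:, :, -margin:] = False
            if d_tcp is not None:
                ok &= d_tcp > float(radii.max()) + 0.3
            cand = np.argwhere(ok)
            if len(cand) == 0:
                continue
            c = (cand[rng.integers(len(cand))] + 0.5) * spacing
        blob = ((X - c[0]) / radii[0]) ** 2 + ((Y - c[1]) / radii[1]) ** 2 \
            + ((Z - c[2]) / radii[2]) ** 2 <= 1.0
        vol[blob & (vol == 0)] = NEW_BONE

    labels = ImageVolume(vol, (spacing,) * 3)
    masks = {
        "native_bone": vol == HOST,
        "frame": vol == SCAFFOLD,
        "lattice_envelope": region & scaffold_zone,
        "tcp": vol == TCP,
        "new_bone_truth": vol == NEW_BONE,
    }
    return Phantom(labels=labels, masks=masks, spec=spec)


def make_ct(labels: ImageVolume, intensity_map: dict | None = None,
            blur_sigma: float = 0.05, noise_sd: float = 150.0,
            seed: int = 0) -> tuple[ImageVolume, ImageVolume]:
    """Emulated CT intensity volume plus paired ground-truth labels.

    Labels map to intensities, a Gaussian point-spread blur (sigma in mm)
    produces partial-volume contamination, and white Gaussian noise is
    added. Deterministic for a fixed seed.
    """
    imap = DEFAULT_INTENSITIES if intensity_map is None else intensity_map
    vol = labels.values
    missing = set(np.unique(vol)) - set(imap)
    if missing:
        raise ValueError(f"intensity map misses labels {sorted(missing)}")
    intens = np.zeros(vol.shape, dtype=float)
    for lab, v in imap.items():
        intens[vol == lab] = v
    if blur_sigma > 0:
        sig_vox = [blur_sigma / s for s in labels.spacing]
        intens = ndimage.gaussian_filter(intens, sig_vox)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intens = intens + rng.normal(0.0, noise_sd, vol.shape)
    return labels.with_values(intens), labels.with_values(vol.copy())
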