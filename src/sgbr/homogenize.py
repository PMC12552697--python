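"""FE homogenization of scaffold unit cells partially infilled with bone.

The scaffold interior is treated as a periodic microstructure: a unit cell
of scaffold solid whose void space progressively fills with new bone as the
local bone density rises. For a ladder of densities spanning 0.05 to
1.62 g/cm^3 the cell is infilled (a conformal layer growing from the solid
surfaces, mirroring bone apposition on scaffold walls), and two effective
tensors are computed with periodic boundary conditions:

* the 6x6 homogenized elasticity tensor (six independent macroscopic
  strain cases, volume-averaged stress), and
* the 3x3 homogenized diffusivity tensor of the osteoblast-carrying phase
  (three macroscopic gradient cases, volume-averaged flux), relative to a
  unit intrinsic diffusivity.

The density-to-volume-fraction map is linear: the new-bone fill fraction
is (rho - rho_min) / (rho_full - rho_min) with rho_min = 0.05 and
rho_full = 1.62 g/cm^3 (fully mineralized bone).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .image import ImageVolume
from .materials import MaterialModel, isotropic_stiffness
from .voxfem import OFFSETS, _XI, _shape_gradients, hex_quadrature

RHO_MIN = 0.05   # g/cm^3, floor of the sampled density range
RHO_FULL = 1.62  # g/cm^3, fully mineralized bone

# soft-phase modulus ratio used to keep the periodic system non-singular
VOID_STIFFNESS_RATIO = 1e-6


def density_to_fill_fraction(rho) -> np.ndarray:
    """Linear map from bone density (g/cm^3) to void fill fraction [0, 1]."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < RHO_MIN - 1e-9) or np.any(rho > RHO_FULL + 1e-9):
        raise ValueError(f"density out of range [{RHO_MIN}, {RHO_FULL}]")
    return np.clip((rho - RHO_MIN) / (RHO_FULL - RHO_MIN), 0.0, 1.0)


def infill_unit_cell(cell_mask: ImageVolume, bone_density: float,
                     mode: str = "conformal", seed: int = 0) -> ImageVolume:
    """Deposit new bone into the void of a unit cell at the given density.

    Returns a label volume: 0 void, 1 scaffold solid, 2 new bone. In
    ``conformal`` mode bone occupies void voxels in increasing order of
    (periodic) distance from the scaffold surface — the apposition pattern
    seen on scaffold walls; ``random`` fills a uniform random subset.
    """
    phi = float(density_to_fill_fraction(bone_density))
    solid = cell_mask.values.astype(bool)
    void_idx = np.argwhere(~solid)
    n_fill = int(round(phi * len(void_idx)))
    labels = np.where(solid, 1, 0).astype(np.int16)
    if n_fill == 0:
        return cell_mask.with_values(labels)
    if n_fill >= len(void_idx):
        labels[~solid] = 2
        return cell_mask.with_values(labels)
    if mode == "conformal" and solid.any():
        tiled = np.tile(~solid, (3, 3, 3))
        d = ndimage.distance_transform_edt(tiled, sampling=cell_mask.spacing)
        nx, ny, nz = solid.shape
        d = d[nx:2 * nx, ny:2 * ny, nz:2 * nz]
        dv = d[~solid]
        # deterministic: distance first, then lexicographic voxel index
        order = np.lexsort((void_idx[:, 2], void_idx[:, 1], void_idx[:, 0], dv))
    elif mode == "random" or not solid.any():
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(void_idx))
    else:
        raise ValueError(f"unknown infill mode {mode!r}")
    chosen = void_idx[order[:n_fill]]
    labels[tuple(chosen.T)] = 2
    return cell_mask.with_values(labels)


# ---------------------------------------------------------------------------
# Periodic cell solves
# ---------------------------------------------------------------------------

def _periodic_conn(shape) -> tuple[np.ndarray, int]:
    """Element-to-node connectivity on a fully periodic voxel grid."""
    nx, ny, nz = shape
    elems = np.indices(shape).reshape(3, -1).T
    conn = np.empty((len(elems), 8), dtype=np.int64)
    for a, (oi, oj, ok) in enumerate(OFFSETS):
        conn[:, a] = (((elems[:, 0] + oi) % nx) * ny + (elems[:, 1] + oj) % ny) \
            * nz + (elems[:, 2] + ok) % nz
    return conn, nx * ny * nz


def _solve_pinned_multi(K: sp.csr_matrix, rhs: np.ndarray,
                        pinned: np.ndarray) -> np.ndarray:
    """Solve K x = rhs for several right-hand sides (columns) with the
    pinned dofs removed; one factorization shared across columns."""
    ndof = K.shape[0]
    free = np.setdiff1d(np.arange(ndof), pinned)
    Kff = K[free][:, free].tocsc()
    sol = np.zeros((ndof, rhs.shape[1]))
    if Kff.shape[0] == 0:
        return sol
    rhs_f = rhs[free]
    scale = np.abs(rhs_f).max()
    nonzero = [c for c in range(rhs.shape[1])
               if np.abs(rhs_f[:, c]).max() > 1e-14 * max(scale, 1.0)]
    if not nonzero:  # homogeneous cell: zero fluctuation exactly
        return sol
    if Kff.shape[0] <= 60_000:
        lu = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A")
        sol[np.ix_(free, nonzero)] = lu.solve(rhs_f[:, nonzero])
    else:
        d = Kff.diagonal()
        M = sp.diags(1.0 / np.where(d > 0, d, 1.0))
        for c in nonzero:
            x, info = spla.cg(Kff, rhs_f[:, c], M=M, rtol=1e-10,
                              maxiter=50_000)
            if info != 0:
                raise RuntimeError(f"periodic cell solve failed (CG info={info})")
            sol[free, c] = x
    return sol


_VOIGT_STRAINS = np.eye(6)


def _strain_matrix(voigt: np.ndarray) -> np.ndarray:
    e = voigt
    return np.array([
        [e[0], e[5] / 2, e[4] / 2],
        [e[5] / 2, e[1], e[3] / 2],
        [e[4] / 2, e[3] / 2, e[2]],
    ])


def homogenize_stiffness(labels: ImageVolume, materials: dict) -> np.ndarray:
    """Effective 6x6 elasticity tensor of a periodic unit cell.

    ``materials`` maps each label to a MaterialModel; labels absent from the
    map are treated as void (soft phase, modulus VOID_STIFFNESS_RATIO times
    the stiffest constituent, keeping the system well posed).
    """
    vol = labels.values
    h = labels.spacing
    labs_present = [int(l) for l in np.unique(vol)]
    solid_labels = [l for l in labs_present if l in materials]
    if not solid_labels:
        warnings.warn("fully void cell: zero effective stiffness")
        return np.zeros((6, 6))
    E_ref = max(materials[l].E for l in solid_labels)
    C_by_label = {}
    for l in labs_present:
        if l in materials:
            C_by_label[l] = materials[l].stiffness_matrix()
        else:
            C_by_label[l] = isotropic_stiffness(VOID_STIFFNESS_RATIO * E_ref, 0.3)

    conn, n_nodes = _periodic_conn(vol.shape)
    ndof = 3 * n_nodes
    edof = np.empty((len(conn), 24), dtype=np.int64)
    edof[:, 0::3] = 3 * conn
    edof[:, 1::3] = 3 * conn + 1
    edof[:, 2::3] = 3 * conn + 2

    Bs, detJw, _ = hex_quadrature(h)
    labs_flat = vol.reshape(-1)
    from .voxfem import element_stiffness
    ke_by_label = {l: element_stiffness(C, h) for l, C in C_by_label.items()}
    ke_all = np.stack([ke_by_label[int(l)] for l in labs_flat])
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    K = sp.coo_matrix((ke_all.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

    # local corner coordinates of a voxel (same for every element)
    x_loc = OFFSETS * np.asarray(h)  # (8, 3)
    C_e = np.stack([C_by_label[int(l)] for l in labs_flat])
    V = vol.size * float(np.prod(h))
    C_eff = np.zeros((6, 6))
    pinned = np.array([0, 1, 2])
    Bbar = Bs.mean(axis=0)  # volume-averaged strain operator per element

    rhs = np.zeros((ndof, 6))
    u_affs = []
    for col, eps_v in enumerate(_VOIGT_STRAINS):
        E_mat = _strain_matrix(eps_v)
        u_aff = (x_loc @ E_mat.T).reshape(24)  # same for every element
        u_affs.append(u_aff)
        fe = ke_all @ u_aff                    # (n_el, 24)
        np.add.at(rhs[:, col], edof.ravel(), -fe.ravel())
    W = _solve_pinned_multi(K, rhs, pinned)
    for col, eps_v in enumerate(_VOIGT_STRAINS):
        w_e = W[:, col][edof]
        strain_avg = eps_v + np.einsum("ab,nb->na", Bbar, w_e)
        sigma = np.einsum("nab,nb->na", C_e, strain_avg)
        C_eff[:, col] = sigma.mean(axis=0)
    # enforce exact symmetry (symmetric to solver tolerance by construction)
    return 0.5 * (C_eff + C_eff.T)


def homogenize_diffusivity(labels: ImageVolume, diffusive_phase) -> np.ndarray:
    """Effective 3x3 diffusivity of a periodic cell, unit intrinsic value.

    ``diffusive_phase`` is the set of labels carrying diffusivity 1; all
    other labels are blocking (a tiny epsilon keeps the system well posed).
    """
    vol = labels.values
    h = labels.spacing
    diffusive = np.isin(vol, list(diffusive_phase))
    if not diffusive.any():
        warnings.warn("no diffusive phase: zero effective diffusivity")
        return np.zeros((3, 3))
    eps_d = 1e-6
    d_e = np.where(diffusive.reshape(-1), 1.0, eps_d)

    conn, n_nodes = _periodic_conn(vol.shape)
    # scalar element "conductivity" matrix from trilinear gradients
    gp = 1.0 / np.sqrt(3.0)
    grads = np.stack([_shape_gradients(gp * _XI[a], np.asarray(h))
                      for a in range(8)])  # (8 gauss, 8 nodes, 3)
    detJw = float(np.prod(h)) / 8.0
    ke_unit = np.einsum("gad,gbd->ab", grads, grads) * detJw
    rows = np.repeat(conn, 8, axis=1).ravel()
    cols = np.tile(conn, (1, 8)).ravel()
    data = (d_e[:, None, None] * ke_unit).ravel()
    K = sp.coo_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()

    x_loc = OFFSETS * np.asarray(h)
    grad_avg_op = grads.mean(axis=0)  # (8, 3)
    V = vol.size * float(np.prod(h))
    D_eff = np.zeros((3, 3))
    rhs = np.zeros((n_nodes, 3))
    for col in range(3):
        g = np.zeros(3)
        g[col] = 1.0
        c_aff = x_loc @ g  # (8,)
        fe = (d_e[:, None]) * (ke_unit @ c_aff)[None, :]
        np.add.at(rhs[:, col], conn.ravel(), -fe.ravel())
    W = _solve_pinned_multi(K, rhs, np.array([0]))
    for col in range(3):
        g = np.zeros(3)
        g[col] = 1.0
        w_e = W[:, col][conn]
        grad = g[None, :] + w_e @ grad_avg_op  # (n_el, 3)
        flux = d_e[:, None] * grad
        D_eff[:, col] = flux.mean(axis=0)
    return 0.5 * (D_eff + D_eff.T)


# ---------------------------------------------------------------------------
# Property table over the density range
# ---------------------------------------------------------------------------

@dataclass
class EffectivePropertyTable:
    """Homogenized stiffness/diffusivity versus in-fill bone density.

    Rows are sampled uniformly over [0.05, 1.62] g/cm^3; queries
    interpolate linearly between rows and clamp outside the range.
    """

    densities: np.ndarray       # (n,), g/cm^3, strictly increasing
    C_eff: np.ndarray           # (n, 6, 6), MPa
    D_eff: np.ndarray           # (n, 3, 3), relative to intrinsic D
    unit_cell_descriptor: str = ""

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.C_eff = np.asarray(self.C_eff, dtype=float)
        self.D_eff = np.asarray(self.D_eff, dtype=float)
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("densities must be strictly increasing")

    def _interp(self, table: np.ndarray, rho) -> np.ndarray:
        rho = np.clip(np.asarray(rho, dtype=float), self.densities[0],
                      self.densities[-1])
        flat = table.reshape(len(self.densities), -1)
        out = np.empty(rho.shape + (flat.shape[1],))
        for c in range(flat.shape[1]):
            out[..., c] = np.interp(rho, self.densities, flat[:, c])
        return out.reshape(rho.shape + table.shape[1:])

    def stiffness_at(self, rho) -> np.ndarray:
        return self._interp(self.C_eff, rho)

    def diffusivity_at(self, rho) -> np.ndarray:
        return self._interp(self.D_eff, rho)

    def to_json(self, path) -> None:
        payload = {
            "densities": self.densities.tolist(),
            "C_eff": self.C_eff.tolist(),
            "D_eff": self.D_eff.tolist(),
            "unit_cell_descriptor": self.unit_cell_descriptor,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "EffectivePropertyTable":
        with open(path) as fh:
            p = json.load(fh)
        return cls(np.asarray(p["densities"]), np.asarray(p["C_eff"]),
                   np.asarray(p["D_eff"]), p.get("unit_cell_descriptor", ""))


def build_property_table(cell_mask: ImageVolume, materials: dict,
                         n_samples: int = 8, scaffold_label: int = 1,
                         new_bone_label: int = 2, infill_mode: str = "conformal",
                         descriptor: str = "") -> EffectivePropertyTable:
    """Sample effective tensors uniformly over the bone-density range.

    ``materials`` must map ``scaffold_label`` and ``new_bone_label`` to
    MaterialModels; void is the soft phase. Diffusion is carried by the
    new-bone phase.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    densities = np.linspace(RHO_MIN, RHO_FULL, n_samples)
    Cs, Ds = [], []
    for rho in densities:
        cell = infill_unit_cell(cell_mask, float(rho), mode=infill_mode)
        # infill labels: 1 = scaffold, 2 = new bone
        mats = {1: materials[scaffold_label], 2: materials[new_bone_label]}
        Cs.append(homogenize_stiffness(cell, mats))
        if (cell.values == 2).any():
            Ds.append(homogenize_diffusivity(cell, {2}))
        else:
            Ds.append(np.zeros((3, 3)))  # no bone deposited yet
    return EffectivePropertyTable(densities, np.stack(Cs), np.stack(Ds),
                                  unit_cell_descriptor=descriptor)
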